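"""Packaged worked-example fixtures: reference summary tables.

These small CSVs encode the reference aggregate counts of the study
population this package's defaults emulate — the cross-table of
tissue HER2 category against CTC-HER2 status, the response counts by
baseline count class and by CTC-HER2 status, the follow-up response
counts, the enumeration summary, and the best-response list — and are
the inputs to the reproduction harness in :mod:`ctcher2.pipeline`.
``generate_worked_fixtures`` copies them into a user directory.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO
from pathlib import Path

import pandas as pd

from .records import ContingencyTable

__all__ = [
    "FIXTURE_FILES",
    "load_fixture_frame",
    "load_table2",
    "load_table3_counts",
    "load_followup",
    "load_enumeration_summary",
    "load_responses",
    "generate_worked_fixtures",
]

FIXTURE_FILES = (
    "table2.csv",
    "table3_counts.csv",
    "followup.csv",
    "enumeration_summary.csv",
    "responses.csv",
)


def _read(name: str, root=None) -> str:
    if root is not None:
        path = Path(root) / name
        if not path.is_file():
            raise FileNotFoundError(f"fixture missing: {path}")
        return path.read_text(encoding="utf-8")
    ref = resources.files("ctcher2").joinpath("data", name)
    if not ref.is_file():
        raise FileNotFoundError(f"packaged fixture missing: {name}")
    return ref.read_text(encoding="utf-8")


def load_fixture_frame(name: str, root=None) -> pd.DataFrame:
    return pd.read_csv(StringIO(_read(name, root)))


def load_table2(root=None) -> ContingencyTable:
    """CTC-HER2 status (rows) by tissue HER2 category (columns), among
    patients with at least one baseline CTC."""
    df = load_fixture_frame("table2.csv", root)
    return ContingencyTable(
        df.iloc[:, 1:].to_numpy(),
        row_labels=list(df["ctc_status"]),
        col_labels=list(df.columns[1:]),
    )


def _two_by_two(df: pd.DataFrame) -> ContingencyTable:
    return ContingencyTable(
        df.iloc[:, 1:].to_numpy(),
        row_labels=list(df.iloc[:, 0]),
        col_labels=list(df.columns[1:]),
    )


def load_table3_counts(root=None) -> dict[str, ContingencyTable]:
    """Two 2x2 responder tables: by baseline count class ('count') and,
    within the high-count stratum, by CTC-HER2 status ('her2')."""
    df = load_fixture_frame("table3_counts.csv", root)
    return {
        var: _two_by_two(sub.drop(columns="variable").reset_index(drop=True))
        for var, sub in df.groupby("variable", sort=False)
    }


def load_followup(root=None) -> ContingencyTable:
    """Follow-up PR counts among patients whose CTC count fell below the
    cutoff under therapy, split by pre-therapy CTC-HER2 status."""
    return _two_by_two(load_fixture_frame("followup.csv", root))


def load_enumeration_summary(root=None) -> pd.DataFrame:
    return load_fixture_frame("enumeration_summary.csv", root)


def load_responses(root=None) -> list[str]:
    return list(load_fixture_frame("responses.csv", root)["best_response"])


def generate_worked_fixtures(outdir) -> list[Path]:
    """Write every packaged fixture CSV into ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_FILES:
        path = outdir / name
        path.write_text(_read(name), encoding="utf-8")
        written.append(path)
    return written
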