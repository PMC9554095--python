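import numpy as np
import pytest

from ctcher2 import CellRecord, GatingThresholds, ScoringScheme


@pytest.fixture
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture
def thresholds() -> GatingThresholds:
    return GatingThresholds()


def make_cell(
    sample="S1",
    cid="c1",
    dapi=500.0,
    ck=300.0,
    cd45=5.0,
    her2=50.0,
    **kw,
) -> CellRecord:
    return CellRecord(
        sample_id=sample,
        cell_id=cid,
        mfi_dapi=dapi,
        mfi_ck=ck,
        mfi_cd45=cd45,
        mfi_her2=her2,
        **kw,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
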