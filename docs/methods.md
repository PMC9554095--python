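# Methods

This note documents the statistical procedures, conventions and design
choices behind `ctcher2`, and what its synthetic data can and cannot
establish about real cohorts.

## The measurement model

A blood draw (2.0 ml by default; the volume is recorded and never
rescaled) is enriched for epithelial cells and immunostained in four
channels: DAPI (nuclei), pan-cytokeratin (epithelial), CD45
(leukocyte), HER2. The pipeline receives one row per detected object
with a mean fluorescence intensity (MFI, arbitrary units) per channel.
MFIs are stored as given; whether and how background is subtracted is
the imaging front end's concern (see below), not the data model's.

## Gating

A cell is a **CTC** iff DAPI+ and CK+ and CD45−; **WBC** iff DAPI+ and
CD45+ (CK ignored — CD45 positivity excludes); **REJECTED** iff DAPI−;
**AMBIGUOUS** otherwise (nucleated but marker-silent). "Positive"
means MFI ≥ threshold, "negative" means MFI < threshold, so the gate is
a total function with deterministic boundary behavior. The numeric
thresholds (default 50 a.u. per channel) are an artifact parameter:
the assay this emulates called cells by visual microscopy review, so
the thresholds exist to make synthetic fixtures controllable, and are
configurable everywhere.

Counts are dichotomized at a cutoff of 3 CTCs per draw. Both
comparators are first-class — `GE` (HIGH iff count ≥ 3; the
diagnostic/prognostic convention) and `GT` (HIGH iff count > 3) —
because both conventions appear in practice; the default is `GE`.

## HER2 scoring and the patient-level call

Per-CTC HER2 MFIs map to four staining levels by analogy with tissue
IHC: H0 [0, 100), H1 [100, 400), H2 [400, 600), H3 [600, ∞) a.u.
The source ranges are ambiguous at shared endpoints ("0–100 /
100–400"); intervals here are half-open on the left edge, making the
bin a total, monotone function of MFI. All three edges are
configurable.

A patient with ≥ 1 CTC is **CTC-HER2+** when the H2 fraction strictly
exceeds the ratio cutoff (default 12% — exactly 12% is negative, per
the strict ">" in the definition) or at least one CTC is H3. Patients
with zero CTCs are **UNEVALUABLE**, not negative, and are excluded from
agreement tables.

`derive_ratio_cutoff` re-derives the ratio cutoff from a calibration
set of per-patient H2 ratios labeled by tissue IHC class. The
criterion is Youden's J = sensitivity + specificity − 1 (the standard
single-threshold ROC criterion; the original derivation says only "ROC
analysis", so the criterion is a documented default rather than a
claim), scanned over the observed ratio values with a patient called
positive when ratio > threshold; ties break toward the smaller
threshold. Degenerate inputs (one class, or no threshold with J > 0)
raise rather than return an arbitrary value.

## Diagnostic statistics

* ROC: empirical curve over unique score thresholds ("higher = more
  positive", predict positive at score ≥ threshold). AUC by the
  Mann–Whitney identity with ties counted 1/2; AUC CI by the
  Hanley–McNeil standard error. AUC is invariant under strictly
  increasing score transforms (property-tested).
* Proportions: Wilson score 95% intervals with z = 1.959964. Wilson is
  fixed because it reproduces the worked-example interval pairs
  (55.7–80.1 for 36/52; 72.2/72.25–100 for 10/10), which
  Clopper–Pearson, Agresti–Coull and Jeffreys do not. At k = 0 and
  k = n the closed-form endpoint (0 or 1) is returned exactly rather
  than through floating point.
* Welch's t (two-sided, Welch–Satterthwaite df, via scipy) and Pearson
  r (two-sided p, via scipy). Two zero-variance samples with equal
  means give t = 0, p = 1 by convention.

## Exact contingency-table tests

`fisher_exact_2x2` and `fisher_freeman_halton` share one enumeration
engine: every non-negative integer table with the observed margins is
generated by margin-constrained recursion, and the two-sided p is the
total multivariate-hypergeometric probability of tables whose point
probability does not exceed the observed one (the point-probability
rule, which reproduces the printed p-values of the standard clinical
packages; the doubling rule does not). Probabilities are evaluated in
log space via log-gamma, but the "does not exceed" comparison uses
exact big-integer products of cell factorials — with margins fixed,
P(T) ∝ 1/∏ nᵢⱼ!, so ties resolve exactly and no floating-point
tolerance is needed. Tables beyond 4×4 or N = 200 (or whose margins
admit more than 5·10⁶ tables) raise a capacity error; there is
deliberately no chi-square fallback. A table with a zero margin
returns p = 1 flagged degenerate: no evidence against independence is
obtainable. The 2×2 odds ratio is the sample OR ad/bc, with the
Haldane +0.5 correction when a cell is zero.

Cohen's κ uses the standard (p_o − p_e)/(1 − p_e) on square tables;
non-square input is refused so that any category collapse is an
explicit caller decision. Note: the published κ for the worked
agreement table is not reproducible under either binary collapse (both
give ≈ 0.36–0.40, not 0.191); the collapse used at the source is
unstated, so κ is reported but not treated as a reproduction check.

## Survival

Kaplan–Meier curves are fit with lifelines; the median is the earliest
time with S(t) ≤ 0.5, reported as "not reached" (None) when the curve
never gets there. The log-rank (Mantel–Cox) machinery is implemented
directly from pooled event-time risk tables (Breslow-style tie
handling: all events at a time against the full risk set), with the
K-group chi-square on K−1 df. The hazard ratio is the Mantel–Haenszel
O/E form HR = (O₁/E₁)/(O₂/E₂) with CI exp(log HR ± z√(1/E₁ + 1/E₂)) —
the convention of the classic clinical graphing packages — rather than
Cox regression, which is out of scope. Subjects with zero follow-up
are excluded with a warning; a group with zero events yields a
degenerate HR with a warning rather than NaN.

A caveat measured during development and reflected in the acceptance
script: the O/E-ratio estimator is consistent for the hazard ratio only
locally. Under complete follow-up of exponential arms with a true HR
of 0.387 it converges to ≈ 0.44; under administrative censoring at
12–30 months (the study-like condition the generator uses) it is
essentially unbiased (mean ≈ 0.391 across seeds). Hazard-ratio
recovery is therefore always simulated with censored follow-up.

## Synthetic cohorts

The generator emulates a single-draw study: 15/13/24 patients in the
tissue HER2-negative/-low/-positive classes plus 10 healthy donors,
scalable with composition preserved.

* **Counts** are zero-inflated negative binomial per class (defaults:
  structural-zero probabilities 1/15, 4/13, 5/24 — matching the
  per-class detection fractions 14/15, 9/13, 19/24 — NB means
  35/12/55, dispersion r = 1, cap 683 per draw). Values are drawn by
  stratified inverse-CDF (Latin-hypercube) sampling within each class:
  the marginal distribution is exactly the ZINB, but a finite cohort
  tracks the planted zero fraction and mean to well under 1% at
  n = 2000. The price is that counts are exchangeable rather than
  independent across patients — appropriate for a generator whose role
  is to realize fixed study conditions, but a cohort drawn this way
  slightly understates the cohort-to-cohort variability of real
  sampling, and tests passing on it say nothing about estimator
  behavior under iid sampling.
* **CTC-HER2 status** is assigned first: within each class the planted
  positivity rate (0, 4/9, 10/19 among evaluable patients) is realized
  exactly — round(rate·n) positives placed at random — for the same
  reason. Bin occupancies are then drawn from status-conditional
  multinomial templates and minimally repaired so the realized bins
  always encode the drawn status (a designated negative never holds an
  H3 cell or an H2 excess; a designated positive always triggers the
  call). Negative templates must carry zero H3 weight; violating that
  (or requesting positives from a template with no H2/H3 mass) is a
  validation error. Planted rates are therefore exact by
  construction, not emergent from the mixture — the generator does not
  model the joint count–positivity dependence a mechanistic mixture
  would induce.
* **Per-cell MFIs** are log-normal components truncated to their bin's
  intensity range (medians 45/200/490/800 a.u., σ 0.6/0.45/0.12/0.35),
  so bin occupancy is exact; DAPI/CK/CD45 channels are drawn to satisfy
  (CTCs) or violate (spiked leukocytes, Poisson mean 40 per sample) the
  gate.
* **Outcomes** exist for treated (tissue HER2+) patients: objective
  response with probability 0.833 (low count class), 0.60 (high count,
  CTC-HER2+), 0.0 (high count, CTC-HER2−); responders split 10/90
  CR/PR, non-responders 9:2 SD:PD. PFS/OS are exponential with
  high-count PFS median 9.2 months, OS median 36 months, planted
  low-vs-high hazard ratio 0.387 for both, and administrative
  censoring uniform on [12, 30] months.
* All randomness flows from one seeded numpy Generator; identical seed
  and spec give byte-identical cohorts.

What the synthetic cohort does **not** emulate: measurement error in
MFIs (bins are exact by construction), within-patient correlation of
staining beyond the status conditioning, doublets/clusters, assay
failures, accrual-time structure in censoring, or any dependence of
response on covariates other than count class and CTC-HER2 status.
Green end-to-end tests demonstrate that the pipeline's bookkeeping and
statistics are correct, not that the biological model is.

## Imaging front end

Synthetic fields are four-channel arrays (channels-first; order DAPI,
CK, CD45, HER2; 0-based (row, col) pixel coordinates). Each planted
cell contributes a flat-topped disc of its per-channel amplitude
(optional Gaussian-smoothed rim, default hard edge) over a constant
background, plus additive Gaussian noise. Flat tops are used instead
of Gaussian peaks deliberately: the quantifier reports the mean
intensity over the object mask, and a Gaussian profile would bias that
mean well below the planted amplitude, defeating amplitude-recovery
checks. The closed form "peak pixel = background + amplitude" holds
either way.

Quantification: global Otsu threshold on DAPI, 8-connectivity
labeling, objects of 20–2000 px kept; per-channel MFI = mean over the
object mask minus the median of non-object pixels in that channel
(clipped at 0). A mask covering more than 25% of the field is treated
as Otsu splitting pure background noise and yields no objects. Cells
planted closer than the sum of their radii are flagged `merged` in the
ground truth, and such layouts may segment into fewer objects than were
planted. The measurement region is the whole object mask (the
alternative — nucleus-only — is a configurable choice left to the
caller via segmentation parameters). MFIs are on the same arbitrary
scale as the scoring-scheme edges, so amplitudes around 50–900 a.u.
exercise all four bins.

## Worked-example reproduction

`reproduce_worked_examples` recomputes, from the packaged fixture tables alone,
15 headline statistics (detection rate; sensitivity/specificity with
Wilson CIs at the ≥3 cutoff; the agreement table's Freeman–Halton p,
concordance and per-class positivity rates; the three responder-table
Fisher p-values; ORR/DCR) through the same library entry points the
pipeline uses. Pass/fail is decided at the reference's printed
precision (1 decimal for percentages, 3 for p-values), rounding
half-up; a computed value also passes if the reference equals it after
rounding through an intermediate display with one extra decimal. The
second path exists because published values are typically transcribed
from software displays — e.g. a Wilson bound of 72.2467% shown as
72.25% and printed as 72.3% — and both paths keep agreement within
half a unit of the last printed digit.

## Problem sizes and tolerances

Defaults used by the test suite and `scripts/acceptance.py`, chosen as
the package's own working sizes: oracle-equivalence checks run 200
random tables (N ≤ 60) against exact-rational brute force at 1e-10;
cutoff derivation is checked against an exhaustive midpoint scan on
200 instances (n ≤ 50); moment recovery uses a 2000-patient cohort at
3% relative tolerance; positivity recovery ±5 points; hazard-ratio
recovery uses 2000 subjects per arm (censored, as above); imaging
recovery runs ~100 random non-colliding fields at ≤1% noise with exact
count recovery and <5% MFI bias. Determinism contracts (same
seed → byte-identical cohorts and reports) are tested at the file
level.
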