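# Methods

## The measurement model

Lung lobes are photographed against a printed grid of 5 × 5 mm² squares;
one grid square spanning *n* pixels per side gives `mm_per_px = 5/n` (a
100-pixel square gives 0.05 mm/px, so a 400-pixel nodule is 1.0 mm²).
Melanized B16F10 nodules absorb strongly in red, while blood and bruising
contaminate mostly green and blue, so only the red channel of the lobe
selection is quantified.

**Kapur (maximum-entropy) thresholding.** For a 256-bin histogram with
probabilities `p_i`, the threshold `t` maximizes `H_low(t) + H_high(t)`,
the Shannon entropies (natural log) of the histogram renormalized within
levels ≤ t and > t. Conventions: `0·ln 0 := 0`; thresholds leaving either
class with zero mass are excluded; ties break to the lowest qualifying
level; 256 fixed bins, no smoothing. The implementation uses cumulative
sums; the test suite checks it against a deliberately naive per-threshold
exhaustive search on 1,000 random histograms, exactly.

**Tumor is the dark class.** The original interactive workflow rendered
nodules as the "white" pixels of the thresholded binary image, but the
underlying red intensities of melanized tissue are low, so this package
assigns tumor to the at-or-below-threshold class by default. The
convention is exposed (`tumor_is_dark=False`, `--tumor-is-light`) for
datasets with opposite contrast. A single-level histogram (e.g. a
nodule-free lobe of perfectly uniform tone) cannot be split; burden is
reported as 0 with a `degenerate_histogram` flag and a warning.

**Nodule counting** uses 8-connected components with a default size floor
of `min_px = 5` to reject single-pixel speckle; touching nodules merge
into one component, matching visual counting.

## Growth calibration from cross-sections

Each mouse is measured once (destructive sampling), so records are
independent observations and both growth families are fit by ordinary
least squares in log coordinates:

* power: `ln A = ln A0 + B·ln t`
* exponential: `ln A = ln A0 + k·t`

Log-space fitting matches the multiplicative error structure of
engraftment and measurement variability; it differs from untransformed
nonlinear least squares, which would overweight the largest burdens.
Zero-area records have no defined log and are excluded (the count is
reported); a configurable `area_floor` pseudo-count is available but off
by default. Fitting requires at least two positive-area records at two
distinct days.

Derived kinetics are closed-form: predictions `A0·t^B` / `A0·e^(k·t)`;
doubling time `ln2/k` (size-independent) or `t(S)·(2^(1/B) − 1)` with
`t(S) = (S/A0)^(1/B)` (power-law doubling slows as the tumor grows);
suppression fold = ratio of predicted burdens, strictly increasing in day
when the control exponent exceeds the treated one.

**Variance–mean scaling.** Per (group, day) cell with ≥ 2 mice, the
sample mean and SD of areas enter an OLS fit of log SD on log mean.
Lognormal per-mouse amplitudes under deterministic growth preserve the
coefficient of variation across days, so the slope is 1; constant additive
scatter would give slope 0.

## Survival projection

The growth exponent is calibrated once on a multi-timepoint reference
cohort and then frozen; it is never refit per mouse. Each mouse's single
`(area, day)` point fixes its amplitude and threshold crossing:

* power: `A0_i = area/day^B`, `t* = (threshold/A0_i)^(1/B)`
* exponential: `A0_i = area·e^(−k·day)`, `t* = ln(threshold/A0_i)/k`

with `threshold = 300 mm²` by default. Edge cases, decided here because
the procedure's source leaves them open:

* **Zero-area mice** have no estimable curve; they are excluded from
  projection and enter the projected Kaplan–Meier curve right-censored at
  their measurement day.
* **Mice at or above threshold** get `t* ≤ day`; a projected death cannot
  predate observed survival, so they enter the KM curve as events at
  their measurement day and are flagged `above_threshold`.
* All other projected mice are events (no censoring), so the projected KM
  curve is fully specified.

The KM estimator is the standard product limit; with no censoring it
equals the empirical survival function. Group comparison is the
Mantel–Cox log-rank test: at each distinct event time, observed-minus-
expected events in one group with hypergeometric variance; the statistic
`(ΣO − ΣE)²/ΣV` is referred to chi-square with 1 df, two-sided, with no
multiplicity correction (one comparison per experiment). Both KM and
log-rank are cross-checked against `lifelines` in the test suite only.
Projection defaults to the power family; both families are supported and
no winner between them is declared.

## Growth versus phagocytosis

`dB/dt = (g − φ·max(P − P0, 0))·B`, with `g` the intrinsic proliferation
rate (/day), `φ` the clearance efficiency (/day per unit density), `P` a
*fixed* snapshot density of phagocytic macrophages and `P0` the
inactivated baseline. The rectification at `P = P0` prevents a phagocyte
deficit from boosting growth; linear suppression in `P` is the minimal
form consistent with exponential solutions — no carrying capacity or
saturation is assumed. `P` carries arbitrary density units: only the
product `φ·(P − P0)` is identifiable from burden data, a documented
non-identifiability. Absolute macrophage densities are not used as fit
targets anywhere.

`fit_decay` regresses `ln B` on `t` inside a window covering the
clearance-dominated regression phase (default days 0–8, inclusive,
configurable) and returns `τ = −1/slope`, raising `NoDecayError` for a
non-negative slope. `fit_burden_vs_phagocytes` fits
`ln B = c0 − c1·(P − P0)` across snapshot pairs; a negative `c1` (burden
increasing with macrophage density) is returned with a
`sign_violated` flag rather than an error, since noisy snapshots can
transiently violate the expected sign.

## Synthetic-data generator

The generator emulates the study conditions, not their biology in full:

* **Cohorts**: `area = A0_i · growth(day) · noise`, with `A0_i` lognormal
  (median = cohort amplitude, geometric SD = `dispersion`) and noise
  lognormal (median 1, geometric SD = `noise_gsd`). Lognormal amplitude is
  the minimal multiplicative model for per-mouse engraftment differences
  and reproduces the observed variance–mean scaling; multiplicative noise
  keeps burdens positive. Defaults: untreated power A0 = 0.0019, B = 4.1;
  treated power A0 = 0.0087, B = 3.0; exponential A0 = 0.05, k = 0.45;
  sacrifice days {10, 12, 14, 16, 20} with 10 mice/day. The noise
  magnitudes are not reported for the original cohorts; geometric SDs of
  1.6 (engraftment) and 1.3 (measurement) are package defaults giving
  realistic inter-littermate scatter (log-scale SD ≈ 0.54, i.e. ~70%
  coefficient of variation), chosen once and used everywhere.
* **Images**: a lobe ellipse with constant-intensity circular nodules in
  the red channel, uniform clutter in green/blue, optional Gaussian pixel
  noise. Ground truth (painted fraction, merged component count) is
  returned alongside. Texture, specular highlights, bruising gradients and
  real histology are deliberately absent — passing image tests shows the
  thresholding chain is correct, not that it is robust to photographic
  artifacts.
* **Trajectories**: `B0·e^(−t/τ)` up to `regrowth_day` (default 10, when
  clearance ceases), then exponential regrowth, with multiplicative noise.

All generators are driven by `numpy.random.default_rng(seed)`: identical
spec + seed gives bit-identical output.

## Problem sizes and numerical choices

Recovery studies use 20 cohorts (power and exponential) and 50
trajectories, sizes at which the mean recovered parameter is stable to
well under the 10% tolerances asserted. The variance–mean slope check
uses 9 sacrifice days × 4,000 mice so that sampling error in per-cell SDs
(the dominant noise term) keeps the slope within ±0.01. Log-rank and KM
cross-checks agree with `lifelines` to 1e−6; projection round-trips
(forward-evaluating the per-mouse curve at its crossing day) hold to
1e−9 relative; ODE finite-difference residuals to 1e−6 at step 1e−5.

Pipeline runs derive per-stage seeds from the global seed via
`numpy.random.SeedSequence`, and the manifest records stages, parameters,
seed and versions so deterministic stages re-run byte-identically.

## Known limitations

* Cross-sectional calibration cannot separate within-mouse growth from
  between-mouse engraftment; the projection inherits the cohort exponent
  and attributes all residual variation to the amplitude.
* Projected survival treats the burden threshold as a sharp death
  criterion; clinically, deterioration is rapid but not instantaneous.
* The phagocytosis model takes `P` as a static covariate; macrophage
  dynamics, antibody dose–response and spatial structure are out of scope.
* The image module quantifies photographs of excised lobes, not histology
  sections, and performs no grid-corner detection: the calibration
  constant is supplied by the user.
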