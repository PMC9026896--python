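# metkit

Tools for quantifying lung-metastasis burden and its growth kinetics in
preclinical mouse models, built around the B16F10 melanoma tail-vein model
in which macrophage phagocytosis (CD47 disruption plus tumor-opsonizing
antibody) suppresses metastatic growth.

The experimental design is *destructive*: each mouse yields a single burden
measurement at its sacrifice day, so growth curves must be calibrated
across animals and survival can only be *projected* from single-timepoint
measurements. `metkit` implements that whole chain:

1. **Image quantification** (`metkit.imaging`) — melanized nodules are dark
   in the red channel of a lobe photograph taken against a printed
   5 × 5 mm² calibration grid. The red histogram over the lobe selection is
   auto-thresholded with Kapur's maximum-entropy criterion, the dark class
   is counted as tumor, and pixel counts convert to mm² through the grid
   constant. Nodules are counted as 8-connected components above a size
   floor.
2. **Growth calibration** (`metkit.growth`) — cross-sectional cohorts are
   fit by least squares in log coordinates to either

   * power law: `Area = A0 · t^B`, or
   * exponential: `Area = A0 · e^(k·t)`,

   with `t` in days post-inoculation. Derived kinetics: predictions,
   doubling times (`ln 2 / k`, or `t(S)·(2^(1/B) − 1)` for the power law),
   control-to-treated suppression folds, and the slope of log SD versus
   log mean across cohort cells (≈ 1 under multiplicative inter-mouse
   variability).
3. **Survival projection** (`metkit.survival`) — with the cohort exponent
   frozen, each mouse's single `(area, day)` point fixes its individual
   amplitude `A0_i`; the day its curve crosses a critical burden threshold
   (300 mm² by default) is its projected survival time. Projected times
   build Kaplan–Meier product-limit curves, compared by the Mantel–Cox
   log-rank test.
4. **Growth versus phagocytosis** (`metkit.phago`) — burden follows
   `dB/dt = (g − φ·max(P − P0, 0))·B`, where `P` is the phagocytic
   macrophage density and `P0` its inactivated baseline. The solution is
   exponential; when clearance dominates, burden decays as `exp(−t/τ)` and
   `fit_decay` recovers τ from a regression-phase trajectory.
5. **Synthetic data** (`metkit.synthetic`) — seeded generators for
   cross-sectional cohorts (lognormal per-mouse engraftment amplitude ×
   deterministic growth × lognormal measurement noise), lobe photographs
   with known ground truth, and treated decay-then-regrowth trajectories.
6. **Pipeline & CLI** (`metkit.pipeline`, `metkit` executable) —
   `simulate | quant | fit | project | compare | phago | run` subcommands
   and a TOML-configured end-to-end runner that writes a reproducibility
   manifest.

## Worked example

```python
import metkit as mk

ctrl_records, _ = mk.gen_cohort(mk.untreated_power_spec(seed=1))
tx_records, _ = mk.gen_cohort(mk.treated_power_spec(seed=2))

ctrl_fit = mk.fit_growth(ctrl_records, family="power")
tx_fit = mk.fit_growth(tx_records, family="power")
print(f"control:  A0 = {ctrl_fit.amplitude:.4f} mm^2, B = {ctrl_fit.exponent:.2f}")
print(f"treated:  A0 = {tx_fit.amplitude:.4f} mm^2, B = {tx_fit.exponent:.2f}")
print(f"suppression at day 16: {mk.suppression_fold(ctrl_fit, tx_fit, 16):.1f}-fold")

ctrl_proj = mk.project_cohort(ctrl_records, mk.ProjectionConfig.from_fit(ctrl_fit))
tx_proj = mk.project_cohort(tx_records, mk.ProjectionConfig.from_fit(tx_fit))
print(f"median projected survival: control {ctrl_proj.median_crossing_day:.1f} d, "
      f"treated {tx_proj.median_crossing_day:.1f} d")

chi2, p = mk.logrank((ctrl_proj.event_times, ctrl_proj.events),
                     (tx_proj.event_times, tx_proj.events))
print(f"log-rank: chi2 = {chi2:.1f}, p = {p:.2e}")
```

prints

```
control:  A0 = 0.0027 mm^2, B = 3.95
treated:  A0 = 0.0142 mm^2, B = 2.81
suppression at day 16: 4.5-fold
median projected survival: control 18.6 d, treated 33.8 d
log-rank: chi2 = 119.9, p = 6.56e-28
```

Two cohorts of 50 mice are simulated at the calibrated untreated
(A0 = 0.0019, B = 4.1) and treated (A0 = 0.0087, B = 3.0) power laws; the
fits recover the generating exponents from the noisy cross-sections, the
treated burden at day 16 is suppressed ~4.5-fold, and projecting each
mouse against the 300 mm² threshold separates the groups' survival curves
decisively. The same chain runs from the shell:

```sh
metkit simulate cohort --group untreated --seed 1 --out ctrl.csv
metkit fit ctrl.csv --family power
metkit project ctrl.csv --calibrate-from ctrl.csv --threshold 300 --out proj.csv
```

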