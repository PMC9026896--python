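"""Growth-law calibration from cross-sectional cohorts.

Lung metastatic burden in the B16F10 tail-vein model is measured
destructively: each mouse contributes a single (day, area) observation at
its sacrifice day, so growth curves are calibrated *across* animals.  Two
families describe burden versus days post-inoculation:

* power law:    Area = A0 * t**B
* exponential:  Area = A0 * exp(k * t)

Both are fit by ordinary least squares after a log transform (power law on
log-log axes, exponential on semi-log axes), which matches the
multiplicative noise structure of engraftment and measurement variability.
Derived kinetic quantities (predictions, doubling times, suppression folds,
variance-mean scaling) are all closed-form consequences of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats

Family = Literal["exponential", "power"]

_FAMILIES = ("exponential", "power")


@dataclass(frozen=True)
class BurdenRecord:
    """One mouse's burden measurement at its (single) sacrifice day."""

    mouse_id: str
    group: str
    day: float
    area_mm2: float
    nodule_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.area_mm2 < 0:
            raise ValueError(f"area_mm2 must be >= 0, got {self.area_mm2}")


@dataclass(frozen=True)
class GrowthFit:
    """Calibrated growth law.

    ``exponent`` is B (unitless) for the power family and k (per day) for
    the exponential family.  ``amplitude`` is A0 in mm².
    """

    family: Family
    amplitude: float
    exponent: float
    stderr_exponent: float = float("nan")
    n_obs: int = 2
    residual_sd_log: float = float("nan")
    n_zero_excluded: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.n_obs < 2:
            raise ValueError("n_obs must be >= 2")


def _check_family(family: str) -> None:
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}, got {family!r}")


def fit_growth(
    records: Iterable[BurdenRecord],
    family: Family,
    area_floor: float = 0.0,
) -> GrowthFit:
    """Calibrate a growth law from cross-sectional records by log-space OLS.

    Power family regresses ln(area) on ln(day); exponential regresses
    ln(area) on day.  The amplitude is ``exp(intercept)``.  Records with
    zero area cannot enter a log fit and are excluded (their count is kept
    in ``n_zero_excluded``) unless ``area_floor`` > 0, in which case areas
    are clipped from below at the floor instead.

    Parameters
    ----------
    records
        Burden records; each mouse appears once (destructive sampling).
    family
        ``"power"`` or ``"exponential"``.
    area_floor
        Optional pseudo-count floor in mm²; 0 disables it.

    Raises
    ------
    ValueError
        If fewer than two usable records remain or all usable records
        share a single sacrifice day.
    """
    _check_family(family)
    recs = list(records)
    n_zero = 0
    days, areas = [], []
    for r in recs:
        if r.day <= 0:
            raise ValueError(f"day must be > 0 for fitting, got {r.day}")
        a = r.area_mm2
        if area_floor > 0:
            a = max(a, area_floor)
        if a <= 0:
            n_zero += 1
            continue
        days.append(r.day)
        areas.append(a)
    if len(areas) < 2:
        raise ValueError("need >= 2 records with positive area to fit")
    t = np.asarray(days, dtype=float)
    y = np.log(np.asarray(areas, dtype=float))
    x = np.log(t) if family == "power" else t
    if np.ptp(x) == 0:
        raise ValueError("need >= 2 distinct sacrifice days to fit")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(len(y) - 2, 1)
    return GrowthFit(
        family=family,
        amplitude=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        stderr_exponent=float(res.stderr),
        n_obs=len(y),
        residual_sd_log=float(np.sqrt(np.sum(resid**2) / dof)),
        n_zero_excluded=n_zero,
    )


def predict_area(fit: GrowthFit, day: float) -> float:
    """Evaluate the fitted growth law at ``day`` (> 0), in mm²."""
    day = float(day)
    if day <= 0 and fit.family == "power":
        raise ValueError("power-law prediction requires day > 0")
    if fit.family == "power":
        return fit.amplitude * day**fit.exponent
    return fit.amplitude * float(np.exp(fit.exponent * day))


def doubling_time(fit: GrowthFit, at_area: float = 1.0) -> float:
    """Time in days for burden to double, evaluated at ``at_area`` mm².

    Exponential growth doubles in ln2/k regardless of size.  Power-law
    growth decelerates in relative terms: starting from the day t(S) at
    which the curve reaches S, doubling takes t(S) * (2**(1/B) - 1).
    """
    if at_area <= 0:
        raise ValueError("at_area must be > 0")
    if fit.exponent <= 0:
        raise ValueError("doubling time undefined for non-positive exponent")
    if fit.family == "exponential":
        return float(np.log(2.0) / fit.exponent)
    t_s = (at_area / fit.amplitude) ** (1.0 / fit.exponent)
    return float(t_s * (2.0 ** (1.0 / fit.exponent) - 1.0))


def crossing_time(fit: GrowthFit, threshold_mm2: float) -> float:
    """Day at which the fitted curve reaches ``threshold_mm2``."""
    if threshold_mm2 <= 0:
        raise ValueError("threshold must be > 0")
    if fit.exponent <= 0:
        raise ValueError("crossing time undefined for non-positive exponent")
    if fit.family == "power":
        return float((threshold_mm2 / fit.amplitude) ** (1.0 / fit.exponent))
    return float(np.log(threshold_mm2 / fit.amplitude) / fit.exponent)


def suppression_fold(fit_ctrl: GrowthFit, fit_tx: GrowthFit, day: float) -> float:
    """Control-to-treated burden ratio at ``day`` (how many-fold smaller the
    treated burden is)."""
    if day <= 0:
        raise ValueError("day must be > 0")
    denom = predict_area(fit_tx, day)
    if denom == 0:
        raise ValueError("treated prediction is zero")
    return predict_area(fit_ctrl, day) / denom


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares slope of log(SD) versus log(mean) across cohort cells."""

    slope: float
    intercept: float
    stderr: float
    ci95: tuple[float, float]
    n_cells: int
    cell_means: tuple[float, ...] = field(repr=False, default=())
    cell_sds: tuple[float, ...] = field(repr=False, default=())


def variance_mean_scaling(
    records: Iterable[BurdenRecord],
    min_cell_size: int = 2,
) -> ScalingFit:
    """Variance-mean scaling of burdens across (group, day) cohort cells.

    For each cell with at least ``min_cell_size`` mice, compute the sample
    mean and SD of areas, then fit log(SD) on log(mean) by OLS.  A slope of
    1 is the signature of multiplicative (lognormal-amplitude) inter-mouse
    variability under deterministic growth: the coefficient of variation is
    then the same at every sacrifice day.
    """
    cells: dict[tuple[str, float], list[float]] = {}
    for r in records:
        cells.setdefault((r.group, r.day), []).append(r.area_mm2)
    means, sds = [], []
    for areas in cells.values():
        if len(areas) < min_cell_size:
            continue
        arr = np.asarray(areas, dtype=float)
        m = arr.mean()
        s = arr.std(ddof=1)
        if m > 0 and s > 0:
            means.append(m)
            sds.append(s)
    if len(means) < 3:
        raise ValueError(
            f"need >= 3 cells with >= {min_cell_size} mice and positive "
            f"mean/SD, got {len(means)}"
        )
    x = np.log(np.asarray(means))
    y = np.log(np.asarray(sds))
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2) if len(x) > 2 else float("inf")
    return ScalingFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        ci95=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        n_cells=len(means),
        cell_means=tuple(means),
        cell_sds=tuple(sds),
    )
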