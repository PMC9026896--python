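"""Seeded synthetic data: cohorts, lobe photographs, treated trajectories.

Everything downstream consumes outputs of this module, so the whole
pipeline is testable without animal data or photograph archives.  Three
generators emulate the study design:

* ``gen_cohort`` — destructive cross-sectional sampling: each simulated
  mouse carries a lognormal engraftment amplitude (its own A0), grows
  deterministically along the cohort growth law, and is measured once at
  its sacrifice day with multiplicative lognormal measurement noise.
* ``gen_lobe_image`` — an RGB photograph of a lung lobe on a calibrated
  grid background: a lighter lobe ellipse with dark circular melanized
  nodules in the red channel, and independent clutter in the green/blue
  channels so that red-channel selection matters downstream.
* ``gen_trajectory`` — a treated longitudinal trajectory that decays as
  exp(-t/tau) while clearance dominates and regrows exponentially after a
  stated day.

Default parameters mirror the calibrated in vivo growth laws: power-law
untreated (A0 = 0.0019 mm², B = 4.1) and treated (A0 = 0.0087 mm²,
B = 3.0), exponential (A0 = 0.05 mm², k = 0.45 /day), decay time constant
tau = 1.55 days.  Engraftment and measurement noise magnitudes are not
reported for the original cohorts; geometric SDs of 1.6 (engraftment) and
1.3 (measurement) are package defaults chosen to give realistic order-of-
magnitude scatter between littermates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .growth import BurdenRecord, Family

# Calibrated in vivo parameters used as generator defaults.
UNTREATED_POWER = {"amplitude": 0.0019, "exponent": 4.1}
TREATED_POWER = {"amplitude": 0.0087, "exponent": 3.0}
UNTREATED_EXPONENTIAL = {"amplitude": 0.05, "exponent": 0.45}
DECAY_TAU_DAYS = 1.55

DEFAULT_DISPERSION_GSD = 1.6   # per-mouse engraftment amplitude, geometric SD
DEFAULT_NOISE_GSD = 1.3        # multiplicative measurement noise, geometric SD


# ---------------------------------------------------------------------------
# cross-sectional cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Specification of one simulated cross-sectional cohort."""

    group_label: str
    family: Family
    amplitude_median: float          # mm² (median A0 across mice)
    exponent: float                  # B (power) or k per day (exponential)
    sacrifice_days: tuple[float, ...]
    mice_per_day: int
    dispersion: float = DEFAULT_DISPERSION_GSD  # geometric SD of A0, >= 1
    noise_gsd: float = DEFAULT_NOISE_GSD        # geometric SD of noise, >= 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "power"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.amplitude_median <= 0:
            raise ValueError("amplitude_median must be > 0")
        if self.dispersion < 1:
            raise ValueError("dispersion (geometric SD) must be >= 1")
        if self.noise_gsd < 1:
            raise ValueError("noise_gsd (geometric SD) must be >= 1")
        if len(self.sacrifice_days) == 0:
            raise ValueError("sacrifice_days must be nonempty")
        if any(d <= 0 for d in self.sacrifice_days):
            raise ValueError("sacrifice_days must be strictly positive")
        if self.mice_per_day <= 0:
            raise ValueError("mice_per_day must be a positive count")
        object.__setattr__(self, "sacrifice_days", tuple(float(d) for d in self.sacrifice_days))


def _growth_factor(family: Family, exponent: float, day: np.ndarray) -> np.ndarray:
    if family == "power":
        return day**exponent
    return np.exp(exponent * day)


def gen_cohort(spec: CohortSpec) -> tuple[list[BurdenRecord], dict[str, float]]:
    """Simulate one destructive-sampling cohort.

    Each of ``mice_per_day`` mice per sacrifice day draws an engraftment
    amplitude A0_i from a lognormal with median ``amplitude_median`` and
    geometric SD ``dispersion``, then its measured area is

        area_i = A0_i * growth(day_i) * noise_i

    with lognormal measurement noise of geometric SD ``noise_gsd`` (median
    1, so burdens are unbiased on the log scale and never negative).  Each
    mouse appears at exactly one day.

    Returns
    -------
    (records, amplitudes)
        The burden records and a mapping mouse_id -> true A0_i (ground
        truth for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[BurdenRecord] = []
    truth: dict[str, float] = {}
    sigma_a = np.log(spec.dispersion)
    sigma_n = np.log(spec.noise_gsd)
    idx = 0
    for day in spec.sacrifice_days:
        amps = spec.amplitude_median * np.exp(sigma_a * rng.standard_normal(spec.mice_per_day))
        noise = np.exp(sigma_n * rng.standard_normal(spec.mice_per_day))
        growth = _growth_factor(spec.family, spec.exponent, np.asarray(day))
        areas = amps * growth * noise
        for a0, area in zip(amps, areas):
            mouse_id = f"{spec.group_label}_m{idx:04d}"
            records.append(
                BurdenRecord(
                    mouse_id=mouse_id,
                    group=spec.group_label,
                    day=float(day),
                    area_mm2=float(area),
                )
            )
            truth[mouse_id] = float(a0)
            idx += 1
    return records, truth


def untreated_power_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Default untreated power-law cohort at the calibrated parameters."""
    kw = dict(
        group_label="untreated",
        family="power",
        amplitude_median=UNTREATED_POWER["amplitude"],
        exponent=UNTREATED_POWER["exponent"],
        sacrifice_days=(10.0, 12.0, 14.0, 16.0, 20.0),
        mice_per_day=10,
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def treated_power_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Default anti-Tyrp1-treated power-law cohort."""
    kw = dict(
        group_label="treated",
        family="power",
        amplitude_median=TREATED_POWER["amplitude"],
        exponent=TREATED_POWER["exponent"],
        sacrifice_days=(10.0, 12.0, 14.0, 16.0, 20.0),
        mice_per_day=10,
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def exponential_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Default cohort under the calibrated exponential law."""
    kw = dict(
        group_label="exponential",
        family="exponential",
        amplitude_median=UNTREATED_EXPONENTIAL["amplitude"],
        exponent=UNTREATED_EXPONENTIAL["exponent"],
        sacrifice_days=(10.0, 12.0, 14.0, 16.0, 20.0),
        mice_per_day=10,
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


# ---------------------------------------------------------------------------
# lobe photographs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Specification of one synthetic lobe photograph.

    The lobe is an ellipse of ``lobe_axes`` (row, col) semi-axes in pixels
    at ``lung_red_level`` in the red channel; nodules are darker circles
    (melanin absorbs red) at ``nodule_red_level``.  Green and blue carry
    independent clutter.  ``mm_per_px`` is the grid calibration constant.
    """

    lobe_axes: tuple[int, int] = (90, 140)
    nodule_count: int = 10
    nodule_radius_px: int = 8
    lung_red_level: int = 160
    nodule_red_level: int = 40
    pixel_noise_sd: float = 0.0
    mm_per_px: float = 0.05
    seed: int = 0
    background_red_level: int = 220

    def __post_init__(self) -> None:
        for name in ("lung_red_level", "nodule_red_level", "background_red_level"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if self.nodule_red_level >= self.lung_red_level:
            raise ValueError("nodule_red_level must be below lung_red_level (melanin is dark)")
        if self.nodule_count < 0:
            raise ValueError("nodule_count must be >= 0")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        if min(self.lobe_axes) <= 0:
            raise ValueError("lobe_axes must be positive")
        if self.nodule_count > 0 and self.nodule_radius_px >= min(self.lobe_axes):
            raise ValueError("nodule radius larger than lobe")


@dataclass(frozen=True)
class LobeImage:
    """RGB pixel array with grid calibration and the lobe selection mask."""

    pixels: np.ndarray          # H x W x 3, uint8
    mm_per_px: float
    lobe_mask: np.ndarray       # H x W, bool

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        if not np.any(self.lobe_mask):
            raise ValueError("lobe_mask must be nonempty")


def gen_lobe_image(spec: ImageSpec) -> tuple[LobeImage, dict[str, float]]:
    """Render a synthetic lobe photograph with known ground truth.

    Nodule centers are placed uniformly inside the ellipse shrunk by the
    nodule radius, so every circle fits within the lobe; overlaps are
    allowed and the ground-truth count merges touching nodules into one
    connected component (8-connectivity), matching how they would be
    counted on the real photograph.

    Returns
    -------
    (image, ground_truth)
        ground_truth has keys ``tumor_fraction`` (nodule pixels / lobe
        pixels) and ``nodule_count`` (merged components).
    """
    rng = np.random.default_rng(spec.seed)
    ay, ax = spec.lobe_axes
    pad = 12
    h, w = 2 * ay + 2 * pad, 2 * ax + 2 * pad
    cy, cx = h / 2 - 0.5, w / 2 - 0.5
    yy, xx = np.mgrid[0:h, 0:w]
    lobe_mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    red = np.full((h, w), float(spec.background_red_level))
    red[lobe_mask] = spec.lung_red_level

    nodule_mask = np.zeros((h, w), dtype=bool)
    r = spec.nodule_radius_px
    for _ in range(spec.nodule_count):
        # rejection-sample a center inside the radius-shrunk ellipse
        while True:
            ny = rng.uniform(cy - (ay - r), cy + (ay - r))
            nx = rng.uniform(cx - (ax - r), cx + (ax - r))
            if ((ny - cy) / (ay - r)) ** 2 + ((nx - cx) / (ax - r)) ** 2 <= 1.0:
                break
        nodule_mask |= (yy - ny) ** 2 + (xx - nx) ** 2 <= r**2
    nodule_mask &= lobe_mask
    red[nodule_mask] = spec.nodule_red_level

    if spec.pixel_noise_sd > 0:
        red = red + rng.normal(0.0, spec.pixel_noise_sd, size=red.shape)
    red = np.clip(np.round(red), 0, 255).astype(np.uint8)

    # independent clutter in green/blue: blood, bruising, discoloration
    green = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
    blue = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
    pixels = np.stack([red, green, blue], axis=-1)

    from skimage import measure  # local import keeps module load light

    n_components = int(measure.label(nodule_mask, connectivity=2).max())
    truth = {
        "tumor_fraction": float(nodule_mask.sum() / lobe_mask.sum()),
        "nodule_count": n_components,
    }
    return LobeImage(pixels=pixels, mm_per_px=spec.mm_per_px, lobe_mask=lobe_mask), truth


# ---------------------------------------------------------------------------
# treated longitudinal trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Treated trajectory: exponential clearance-dominated decay followed by
    regrowth once clearance ceases."""

    burden0: float = 1.0
    decay_tau: float = DECAY_TAU_DAYS      # days
    regrowth_day: float = 10.0             # clearance ceases after this day
    regrowth_rate: float = 0.2             # per day
    sample_days: tuple[float, ...] = tuple(float(d) for d in range(0, 9))
    noise_gsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burden0 <= 0:
            raise ValueError("burden0 must be > 0")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if self.noise_gsd < 1:
            raise ValueError("noise_gsd must be >= 1")
        object.__setattr__(self, "sample_days", tuple(float(d) for d in self.sample_days))


def trajectory_mean(spec: TrajectorySpec, t: np.ndarray) -> np.ndarray:
    """Noiseless burden: B0·exp(-t/tau) up to regrowth_day, then exponential
    regrowth at regrowth_rate from the trough."""
    t = np.asarray(t, dtype=float)
    trough = spec.burden0 * np.exp(-spec.regrowth_day / spec.decay_tau)
    return np.where(
        t <= spec.regrowth_day,
        spec.burden0 * np.exp(-t / spec.decay_tau),
        trough * np.exp(spec.regrowth_rate * (t - spec.regrowth_day)),
    )


def gen_trajectory(spec: TrajectorySpec):
    """Sample a treated trajectory at ``sample_days`` with multiplicative
    lognormal noise of geometric SD ``noise_gsd``."""
    from .phago import Trajectory  # avoid circular import at module load

    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sample_days, dtype=float)
    mean = trajectory_mean(spec, t)
    noise = np.exp(np.log(spec.noise_gsd) * rng.standard_normal(t.size))
    return Trajectory(days=tuple(t.tolist()), burden=tuple((mean * noise).tolist()))
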