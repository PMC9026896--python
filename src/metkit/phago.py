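"""Growth-versus-phagocytosis model and clearance-dominated decay fits.

Tumor burden B grows at an intrinsic per-day rate g and is cleared in
proportion to the density of activated phagocytic macrophages above an
inactivated baseline P0:

    dB/dt = (g - phi * max(P - P0, 0)) * B

P is a fixed covariate (a snapshot macrophage density, not a dynamic
population), so the solution is a pure exponential whose sign is set by
the competition between proliferation and clearance.  The rectification
at P = P0 keeps a phagocyte deficit from spuriously boosting growth.
Only the product phi*(P - P0) is identifiable from burden data alone; P
carries arbitrary density units.

When clearance dominates, burden decays as exp(-t/tau); ``fit_decay``
recovers tau from a regression-phase trajectory (the treated A549 liver
metastases fit tau = 1.55 days over the first eight days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PhagoParams:
    """Rates of the growth-versus-phagocytosis balance.

    g : intrinsic tumor proliferation rate, per day.
    phi : clearance efficiency, per day per unit phagocyte density.
    P0 : inactivated/baseline macrophage density (arbitrary density units).
    B_init : initial burden, mm².
    """

    g: float
    phi: float
    P0: float = 0.0
    B_init: float = 1.0

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.P0 < 0:
            raise ValueError("P0 must be >= 0")
        if self.B_init <= 0:
            raise ValueError("B_init must be > 0")

    def net_rate(self, P: float) -> float:
        """g - phi * max(P - P0, 0), per day."""
        return self.g - self.phi * max(P - self.P0, 0.0)


@dataclass(frozen=True)
class Trajectory:
    """Longitudinal (day, burden) series."""

    days: tuple[float, ...]
    burden: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.burden):
            raise ValueError("days and burden must have equal lengths")
        d = np.asarray(self.days, dtype=float)
        if d.size >= 2 and not np.all(np.diff(d) > 0):
            raise ValueError("days must be strictly increasing")


def solve_burden(params: PhagoParams, P: float, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form burden B(t) = B_init * exp(net_rate * t) for t >= 0.

    At P = P0 the suppression term vanishes and growth is unsuppressed;
    at g = phi*(P - P0) the rates balance and burden is constant; a net
    negative rate gives exponential regression with time constant
    1/|net rate|.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = params.B_init * np.exp(params.net_rate(P) * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


class NoDecayError(ValueError):
    """Raised when a trajectory does not decay over the fit window."""


def fit_decay(
    traj: Trajectory,
    window: tuple[float, float] = (0.0, 8.0),
) -> float:
    """Exponential decay time constant tau from a regression-phase trajectory.

    Ordinary least squares of ln(burden) on day over points with positive
    burden inside ``window`` (inclusive); tau = -1/slope.  The default
    window covers the clearance-dominated first eight days, before
    regrowth sets in.

    Raises
    ------
    NoDecayError
        If the fitted slope is >= 0 (no decay).
    ValueError
        If fewer than 3 usable points fall in the window.
    """
    t = np.asarray(traj.days, dtype=float)
    b = np.asarray(traj.burden, dtype=float)
    keep = (t >= window[0]) & (t <= window[1]) & (b > 0)
    t, b = t[keep], b[keep]
    if t.size < 3:
        raise ValueError(f"need >= 3 positive-burden points in window {window}, got {t.size}")
    res = stats.linregress(t, np.log(b))
    if res.slope >= 0:
        raise NoDecayError(f"no decay: fitted slope {res.slope:.4g} >= 0")
    return float(-1.0 / res.slope)


@dataclass(frozen=True)
class SuppressionFit:
    """Exponential-suppression fit of burden versus macrophage density.

    ln(B) = c0 - c1 * (P - P0) at a fixed observation time: ``c0`` is the
    log-burden at baseline density and ``c1`` the per-density suppression
    coefficient (= phi * observation time; phi itself is identifiable only
    if the observation time is known).
    """

    c0: float
    c1: float
    stderr_c1: float
    r_squared: float
    sign_violated: bool  # burden increasing in P contradicts suppression


def fit_burden_vs_phagocytes(
    pairs: Sequence[tuple[float, float]],
    P0: float = 0.0,
) -> SuppressionFit:
    """Fit ln(B) = c0 - c1*(P - P0) across (density, burden) pairs.

    Burden should decrease monotonically in phagocyte density under the
    suppression model; a fitted c1 < 0 (burden increasing in P) is
    returned with ``sign_violated=True`` rather than raised, since noisy
    snapshots can transiently violate the sign.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 (P, B) pairs")
    p = np.asarray([q[0] for q in pairs], dtype=float) - P0
    b = np.asarray([q[1] for q in pairs], dtype=float)
    if np.any(b <= 0):
        raise ValueError("burdens must be > 0 for a log fit")
    if np.ptp(p) == 0:
        raise ValueError("degenerate: all P values equal")
    res = stats.linregress(p, np.log(b))
    c1 = -res.slope
    return SuppressionFit(
        c0=float(res.intercept),
        c1=float(c1),
        stderr_c1=float(res.stderr),
        r_squared=float(res.rvalue**2),
        sign_violated=bool(c1 < 0),
    )
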