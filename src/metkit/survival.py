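"""Single-timepoint survival projection and projected Kaplan-Meier curves.

Destructive sampling yields one burden measurement per mouse, so observed
survival and tumor growth cannot both be followed in the same animal.  The
projection procedure bridges the two: a growth exponent is calibrated once
on a multi-timepoint reference cohort and then frozen; each mouse's single
(area, day) measurement determines its individual amplitude A0_i ("allowed
to vary for the best fit", reflecting engraftment differences); and the day
at which the individual curve crosses a critical burden threshold (300 mm²
by default) is that mouse's projected survival time.  Projected times feed
a standard Kaplan-Meier product-limit curve, and groups are compared with
the Mantel-Cox log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .growth import BurdenRecord, Family, GrowthFit

DEFAULT_THRESHOLD_MM2 = 300.0

Flag = Literal["ok", "above_threshold", "zero_area"]


@dataclass(frozen=True)
class ProjectionConfig:
    """Frozen cohort-level exponent and critical burden threshold."""

    family: Family = "power"
    exponent: float = 4.1
    threshold_mm2: float = DEFAULT_THRESHOLD_MM2

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "power"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.exponent <= 0:
            raise ValueError("exponent must be > 0")
        if self.threshold_mm2 <= 0:
            raise ValueError("threshold_mm2 must be > 0")

    @classmethod
    def from_fit(cls, fit: GrowthFit, threshold_mm2: float = DEFAULT_THRESHOLD_MM2):
        return cls(family=fit.family, exponent=fit.exponent, threshold_mm2=threshold_mm2)


@dataclass(frozen=True)
class ProjectionResult:
    """Per-mouse amplitude and projected threshold-crossing day.

    ``event_time`` is the day the mouse contributes to the projected KM
    curve and ``event`` whether that contribution is an event: projected
    crossings are events; a crossing earlier than the measurement day
    (mouse already above threshold) enters at the measurement day, since a
    projected death cannot predate observed survival; zero-area mice have
    no estimable curve and are right-censored at their measurement day.
    """

    mouse_id: str
    amplitude_i: float          # mm²; nan for zero-area mice
    crossing_day: float         # days; nan for zero-area mice
    measurement_day: float
    flag: Flag = "ok"
    event_time: float = float("nan")
    event: bool = True


def project_mouse(
    area: float,
    day: float,
    config: ProjectionConfig,
    mouse_id: str = "",
) -> ProjectionResult:
    """Project one mouse's threshold-crossing day from a single measurement.

    With the frozen exponent, the individual amplitude and crossing day are
    closed-form:

    * power:        A0_i = area / day**B,   t* = (threshold / A0_i)**(1/B)
    * exponential:  A0_i = area * e**(-k·day),  t* = ln(threshold / A0_i) / k

    A mouse measured at or above threshold gets ``t* <= day``; it is
    flagged ``"above_threshold"`` and enters the projected KM curve at its
    measurement day.  ``area == 0`` gives no estimable curve: flagged
    ``"zero_area"`` and right-censored at the measurement day.
    """
    if day <= 0:
        raise ValueError("day must be > 0")
    if area < 0:
        raise ValueError("area must be >= 0")
    if area == 0:
        return ProjectionResult(
            mouse_id=mouse_id,
            amplitude_i=float("nan"),
            crossing_day=float("nan"),
            measurement_day=day,
            flag="zero_area",
            event_time=day,
            event=False,
        )
    thr = config.threshold_mm2
    if config.family == "power":
        b = config.exponent
        amp = area / day**b
        crossing = (thr / amp) ** (1.0 / b)
    else:
        k = config.exponent
        amp = area * math.exp(-k * day)
        crossing = math.log(thr / amp) / k
    flag: Flag = "above_threshold" if area >= thr and crossing <= day * (1 + 1e-12) else "ok"
    event_time = max(crossing, day) if flag == "above_threshold" else crossing
    return ProjectionResult(
        mouse_id=mouse_id,
        amplitude_i=amp,
        crossing_day=crossing,
        measurement_day=day,
        flag=flag,
        event_time=event_time,
        event=True,
    )


@dataclass(frozen=True)
class CohortProjection:
    results: tuple[ProjectionResult, ...]
    median_crossing_day: float
    n_zero_area: int
    n_above_threshold: int

    @property
    def event_times(self) -> tuple[float, ...]:
        return tuple(r.event_time for r in self.results)

    @property
    def events(self) -> tuple[bool, ...]:
        return tuple(r.event for r in self.results)


def project_cohort(
    records: Iterable[BurdenRecord],
    config: ProjectionConfig,
) -> CohortProjection:
    """Apply :func:`project_mouse` to every record (one per mouse).

    The summary median is taken over projected crossing days of mice with
    an estimable curve.
    """
    results = tuple(
        project_mouse(r.area_mm2, r.day, config, mouse_id=r.mouse_id) for r in records
    )
    if not results:
        raise ValueError("no records to project")
    crossings = [r.crossing_day for r in results if r.flag != "zero_area"]
    median = float(np.median(crossings)) if crossings else float("nan")
    return CohortProjection(
        results=results,
        median_crossing_day=median,
        n_zero_area=sum(r.flag == "zero_area" for r in results),
        n_above_threshold=sum(r.flag == "above_threshold" for r in results),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` are the distinct times at which anything happens
    (event or censoring), in increasing order; ``survival_prob[i]`` is
    S(t) just after ``event_times[i]``; ``n_at_risk[i]`` counts subjects
    at risk just before it.
    """

    event_times: tuple[float, ...]
    survival_prob: tuple[float, ...]
    n_at_risk: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first time."""
        s = 1.0
        for ti, si in zip(self.event_times, self.survival_prob):
            if ti <= t:
                s = si
            else:
                break
        return s

    def median(self) -> float:
        """Smallest time with S(t) <= 0.5, or nan if never reached."""
        for ti, si in zip(self.event_times, self.survival_prob):
            if si <= 0.5:
                return ti
        return float("nan")


def build_km(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``events[i]`` is True for an observed event at ``times[i]`` and False
    for right-censoring.  With no censoring the estimate reduces to the
    empirical survival function S(t) = #{time > t} / n.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if t.size != e.size:
        raise ValueError("times and events must align")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    distinct = np.unique(t)
    s = 1.0
    out_t, out_s, out_n = [], [], []
    for ti in distinct:
        at_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & e))
        if d > 0:
            s *= 1.0 - d / at_risk
        out_t.append(float(ti))
        out_s.append(s)
        out_n.append(at_risk)
    return KMCurve(tuple(out_t), tuple(out_s), tuple(out_n))


def logrank(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> tuple[float, float]:
    """Mantel-Cox log-rank test between two groups.

    At each distinct event time the observed events in group A are compared
    with the expectation under the null (events distributed by at-risk
    proportions), with hypergeometric variance; the statistic
    (sum O - sum E)² / sum V is chi-square with 1 df.  Returns
    ``(chi_square, p_value)``; with no events anywhere the statistic is 0
    and p = 1.
    """
    ta = np.asarray(group_a[0], dtype=float)
    ea = np.asarray(group_a[1], dtype=bool)
    tb = np.asarray(group_b[0], dtype=float)
    eb = np.asarray(group_b[1], dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(all_t[all_e])
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = all_t >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((all_t == ti) & all_e).sum())
        d_a = int(((all_t == ti) & all_e & in_a).sum())
        if n == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
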