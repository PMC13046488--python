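"""Cross-sample analytics: drug-class concordance, xenograft event
times, and the in-vitro / in-vivo agreement summaries.

Drugs sharing a mechanism of action should elicit correlated LD50
profiles across a sample cohort; that correlation is a consistency
check of the whole assay.  The in-vivo side tracks leukemia burden as
the percentage of human CD45+ cells in mouse peripheral blood; an
event is the first linearly interpolated crossing of a burden
threshold (25% by default) or leukemia-related morbidity, whichever
comes first.  Treatment effect is summarised as the leukemia growth
delay ratio — median event-free survival of treated over control mice
— and compared against ex vivo LD50s by rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CohortSeries",
    "EventTime",
    "profile_correlation",
    "event_time",
    "growth_delay_ratio",
    "sensitivity_vs_outcome",
]


@dataclass
class CohortSeries:
    """One mouse's weekly hCD45 burden measurements."""

    days: np.ndarray
    hcd45_pct: np.ndarray
    group: str = ""
    morbidity_day: float | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.hcd45_pct = np.asarray(self.hcd45_pct, dtype=float)
        if len(self.days) != len(self.hcd45_pct) or len(self.days) == 0:
            raise ValueError("days and hCD45 series must be equal-length and non-empty")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("measurement days must be strictly increasing")
        if np.any((self.hcd45_pct < 0) | (self.hcd45_pct > 100)):
            raise ValueError("hCD45 percentages must lie in [0, 100]")


@dataclass
class EventTime:
    time_days: float
    observed: bool  # False = censored at last observation


def profile_correlation(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between two per-sample response vectors.

    Pearson product-moment by default; ``method="spearman"`` for the
    rank-based variant.  Zero variance in either vector leaves the
    coefficient undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def event_time(
    series: CohortSeries,
    threshold: float = 25.0,
    morbidity_day: float | None = None,
) -> EventTime:
    """First crossing of the burden threshold, or morbidity if earlier.

    Burden between measurements is interpolated linearly on the raw
    percentage scale.  A first measurement already at or above the
    threshold is an event at that day.  With no crossing and no
    morbidity the mouse is censored at its last observation.
    """
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must lie strictly between 0 and 100")
    morbidity_day = morbidity_day if morbidity_day is not None else series.morbidity_day
    days, vals = series.days, series.hcd45_pct
    crossing: float | None = None
    if vals[0] >= threshold:
        crossing = float(days[0])
    else:
        for i in range(len(days) - 1):
            lo, hi = vals[i], vals[i + 1]
            if lo < threshold <= hi:
                frac = (threshold - lo) / (hi - lo)
                crossing = float(days[i] + frac * (days[i + 1] - days[i]))
                break
    if crossing is not None and morbidity_day is not None:
        return EventTime(time_days=min(crossing, float(morbidity_day)), observed=True)
    if crossing is not None:
        return EventTime(time_days=crossing, observed=True)
    if morbidity_day is not None:
        return EventTime(time_days=float(morbidity_day), observed=True)
    return EventTime(time_days=float(days[-1]), observed=False)


def growth_delay_ratio(
    treated: list[EventTime],
    control: list[EventTime],
) -> tuple[float, bool]:
    """Median treated EFS divided by median control EFS.

    Censored mice enter at their censoring day; the returned flag is
    True when a censored time is at or beyond either group's median,
    i.e. when censoring may dominate the ratio.
    """
    if not treated or not control:
        raise ValueError("both groups must be non-empty")
    t_times = np.array([e.time_days for e in treated], dtype=float)
    c_times = np.array([e.time_days for e in control], dtype=float)
    t_med, c_med = float(np.median(t_times)), float(np.median(c_times))
    if c_med == 0:
        raise ValueError("control median event time is zero; ratio undefined")
    censored_dominant = any(
        not e.observed and e.time_days >= med
        for group, med in ((treated, t_med), (control, c_med))
        for e in group
    )
    return t_med / c_med, censored_dominant


def sensitivity_vs_outcome(
    ld50s_nM: np.ndarray,
    growth_delay_ratios: np.ndarray,
) -> tuple[float, float]:
    """Spearman rank correlation of ex vivo LD50 against in vivo growth
    delay.

    Censored LD50s are expected to be pre-encoded at twice the highest
    tested concentration.  A strong negative correlation means lower
    LD50 (more sensitive ex vivo) tracks longer survival benefit.
    """
    x = np.asarray(ld50s_nM, dtype=float)
    y = np.asarray(growth_delay_ratios, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
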