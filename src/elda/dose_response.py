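"""Dose-time-response surfaces, LD50 with censoring, AUC, and library
triage.

A drug's normalized viability traces are averaged over replicates into
a (dose x time) surface.  LD50 at an evaluation time is the dose where
viability crosses 50%, found by linear interpolation in log10-dose —
appropriate for the 1:5 geometric dilution series; with five points in
duplicate a parametric logistic fit is deliberately avoided.  When
viability never drops to 50% even at the top dose, the LD50 is
right-censored and reported as twice the highest tested concentration.
AUC integrates viability/100 over time for each dose (normalized to the
integrated span, so 1 = no effect and 0 = instant total kill) and
averages over doses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import PlateLayout, WellRole, nearest_frame_at_or_before
from .normalization_qc import NormalizedTrace

__all__ = [
    "DoseResponseSurface",
    "LD50Result",
    "build_surface",
    "ld50",
    "auc",
    "triage_panel",
]


@dataclass
class DoseResponseSurface:
    """Replicate-averaged pct_control viability over (dose x time)."""

    drug_id: str
    sample_id: str
    doses_nM: np.ndarray  # ascending
    times_min: np.ndarray
    viability: np.ndarray  # (n_doses, n_times)
    spread: np.ndarray  # replicate range per cell
    n_replicates: np.ndarray  # per dose
    flags: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_nM, dtype=float)
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses must be positive and strictly increasing")

    def viability_at(self, time_h: float) -> np.ndarray:
        idx = nearest_frame_at_or_before(self.times_min, time_h)
        return self.viability[:, idx]


@dataclass
class LD50Result:
    ld50_nM: float
    censored: bool
    below_range: bool = False
    non_monotone: bool = False


def build_surface(
    traces: dict[str, NormalizedTrace],
    layout: PlateLayout,
    aggregate: str = "mean",
) -> DoseResponseSurface:
    """Group one drug's treatment-well traces into a dose x time surface.

    All traces must belong to treatment wells of a single (sample,
    drug).  Replicates at a dose are averaged (median behind
    ``aggregate`` for n >= 3); the replicate range is recorded and a
    single-replicate dose is flagged.
    """
    if not traces:
        raise ValueError("no traces given")
    by_addr = {w.address: w for w in layout}
    wells = []
    for addr in traces:
        w = by_addr.get(addr)
        if w is None:
            raise ValueError(f"well {addr} is not on the plate map")
        if w.role is not WellRole.treatment:
            raise ValueError(f"well {addr} has role {w.role.value}, expected treatment")
        wells.append(w)
    drugs = {w.drug_id for w in wells}
    samples = {w.sample_id for w in wells}
    if len(drugs) != 1 or len(samples) != 1:
        raise ValueError(f"traces span multiple drugs/samples: {drugs} / {samples}")
    drug, sample = drugs.pop(), samples.pop()

    doses = np.array(sorted({w.concentration_nM for w in wells}), dtype=float)
    times = np.asarray(next(iter(traces.values())).times_min, dtype=float)
    flags: list[str] = []
    viability = np.full((len(doses), len(times)), np.nan)
    spread = np.zeros_like(viability)
    n_rep = np.zeros(len(doses), dtype=int)
    for i, dose in enumerate(doses):
        series = []
        for w in wells:
            if w.concentration_nM == dose:
                tr = traces[w.address]
                if tr.pct_control is None:
                    raise ValueError(f"well {w.address} lacks control-normalized values")
                series.append(np.asarray(tr.pct_control, dtype=float))
        stackd = np.vstack(series)
        n_rep[i] = len(series)
        if len(series) == 1:
            flags.append(f"single_replicate_dose_{dose:g}nM")
        if aggregate == "median" and len(series) >= 3:
            viability[i] = np.median(stackd, axis=0)
        else:
            viability[i] = stackd.mean(axis=0)
        spread[i] = stackd.max(axis=0) - stackd.min(axis=0)
    return DoseResponseSurface(
        drug_id=str(drug),
        sample_id=str(sample),
        doses_nM=doses,
        times_min=times,
        viability=viability,
        spread=spread,
        n_replicates=n_rep,
        flags=flags,
    )


def ld50(surface: DoseResponseSurface, time_h: float | None = None) -> LD50Result:
    """Dose reducing viability to 50% at the evaluation time.

    Rules, in order:

    * viability > 50% at the highest dose -> right-censored, reported
      as 2 x max dose;
    * viability < 50% already at the lowest dose -> the lowest dose,
      flagged below-range (no extrapolation);
    * otherwise the lowest-dose bracket where viability crosses 50%,
      interpolated linearly in log10-dose.  A dose hitting exactly 50%
      is returned as-is.  Multiple brackets (non-monotone surface) use
      the lowest and carry a flag.
    """
    if time_h is None:
        idx = len(surface.times_min) - 1
    else:
        idx = nearest_frame_at_or_before(surface.times_min, time_h)
    v = np.asarray(surface.viability[:, idx], dtype=float)
    d = np.asarray(surface.doses_nM, dtype=float)
    ok = np.isfinite(v)
    v, d = v[ok], d[ok]
    if len(v) == 0:
        raise ValueError("no finite viability values at the requested time")
    if v[-1] > 50.0:
        return LD50Result(ld50_nM=2.0 * float(d[-1]), censored=True)
    exact = np.flatnonzero(np.isclose(v, 50.0))
    if exact.size:
        return LD50Result(ld50_nM=float(d[exact[0]]), censored=False)
    if v[0] < 50.0:
        return LD50Result(ld50_nM=float(d[0]), censored=False, below_range=True)
    brackets = [
        i for i in range(len(d) - 1) if (v[i] - 50.0) * (v[i + 1] - 50.0) < 0
    ]
    i = brackets[0]
    frac = (v[i] - 50.0) / (v[i] - v[i + 1])
    log_ld50 = np.log10(d[i]) + frac * (np.log10(d[i + 1]) - np.log10(d[i]))
    return LD50Result(
        ld50_nM=float(10.0 ** log_ld50),
        censored=False,
        non_monotone=len(brackets) > 1,
    )


def auc(surface: DoseResponseSurface, over: str = "time_mean_dose") -> float:
    """Bounded area under the dose-time-response surface.

    Default definition: for each dose, the trapezoidal integral of
    viability/100 over time, normalized by the integrated duration
    (so each dose contributes a number in [0, 1]); the per-dose values
    are then averaged.  ``over="dose_sum"`` instead averages the
    per-time dose means the same way — both stay in [0, 1].
    """
    t = np.asarray(surface.times_min, dtype=float)
    if len(t) < 2:
        raise ValueError("AUC needs at least two time points")
    v = np.asarray(surface.viability, dtype=float) / 100.0
    span = t[-1] - t[0]
    if over == "time_mean_dose":
        per_dose = np.trapezoid(v, t, axis=1) / span
        return float(per_dose.mean())
    if over == "dose_sum":
        per_time = v.mean(axis=0)
        return float(np.trapezoid(per_time, t) / span)
    raise ValueError(f"unknown AUC definition {over!r}")


def triage_panel(
    min_active_conc_nM: pd.DataFrame,
    preselect_threshold_nM: float = 500.0,
) -> dict[str, list[str]]:
    """Three-way triage of a drug library from a pilot screen.

    ``min_active_conc_nM`` is a drugs x samples table of the minimal
    concentration at which the drug showed activity in that sample,
    with NaN meaning inactive even at the top dose.  Drugs inactive in
    every sample are discarded; drugs active in at least one sample at
    or below the preselection threshold (0.5 uM by default) are
    pre-selected; the remainder — active only above the threshold —
    are discarded as weak.  The three sets are disjoint and cover the
    library.
    """
    df = min_active_conc_nM
    vals = df.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("concentrations must be non-negative")
    inactive_mask = np.all(np.isnan(vals), axis=1)
    with np.errstate(all="ignore"):
        min_conc = np.nanmin(np.where(np.isnan(vals), np.inf, vals), axis=1)
    preselect_mask = ~inactive_mask & (min_conc <= preselect_threshold_nM)
    weak_mask = ~inactive_mask & ~preselect_mask
    drugs = np.asarray(df.index)
    return {
        "discarded_inactive": sorted(drugs[inactive_mask].tolist()),
        "discarded_weak": sorted(drugs[weak_mask].tolist()),
        "preselected": sorted(drugs[preselect_mask].tolist()),
    }
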