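"""Two-step normalization and assay-validity rules.

Raw live-pixel area is first expressed as a percentage of the same
well's value at the baseline frame (frame W, the first frame with a
complete motion window) — this absorbs the large well-to-well spread
in how many cells actually land in the photographed field.  Each well
is then expressed as a percentage of the mean of the vehicle-control
wells at the same time point, which absorbs drug-independent death or
proliferation.  Primary leukemia cells survive poorly ex vivo, so a
run is only trusted when its drug-free controls stay viable: mean
control viability above 60% of baseline at 60 h validates the assay,
below 50% discards it, and the band in between is accepted only when
the drug-response curves show a credible dose ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .plate_model import (
    AcquisitionConfig,
    AnalysisConfig,
    PlateLayout,
    WellRole,
    nearest_frame_at_or_before,
)
from .motion_viability import ViabilityTrace

__all__ = [
    "NormalizedTrace",
    "normalize_within_well",
    "normalize_to_control",
    "evaluate_qc",
    "triage_exclusion_rate",
]

_EPS = 1e-9


@dataclass
class NormalizedTrace:
    """A well's viability as % of its own baseline and, once the plate's
    controls are known, as % of the control mean."""

    times_min: np.ndarray
    raw_area: np.ndarray
    pct_baseline: np.ndarray
    pct_control: np.ndarray | None = None
    static_start: bool = False
    well: object | None = None
    flags: list[str] = field(default_factory=list)


def normalize_within_well(
    trace: ViabilityTrace,
    static_floor: float = 0.0,
    well: object | None = None,
) -> NormalizedTrace:
    """Express a raw trace as % of its first defined value.

    The baseline is the trace's first entry (frame index W), defined as
    100% viability.  A baseline at or below ``static_floor`` (default:
    exactly zero) means the well started the recording with essentially
    no moving cells; it is flagged ``static_start`` and must be
    excluded from control means downstream.
    """
    raw = np.asarray(trace.raw_area, dtype=float)
    baseline = raw[0]
    if baseline <= static_floor:
        return NormalizedTrace(
            times_min=np.asarray(trace.times_min, dtype=float),
            raw_area=raw,
            pct_baseline=np.full_like(raw, np.nan),
            static_start=True,
            well=well if well is not None else trace.well,
            flags=["static_start"],
        )
    return NormalizedTrace(
        times_min=np.asarray(trace.times_min, dtype=float),
        raw_area=raw,
        pct_baseline=100.0 * raw / baseline,
        static_start=False,
        well=well if well is not None else trace.well,
    )


def normalize_to_control(
    well_pct_baseline: np.ndarray,
    control_pct_baselines: list[np.ndarray],
) -> np.ndarray:
    """Express a well as % of the mean vehicle-control at each time.

    Requires at least two usable control series.  Times where the
    control mean vanishes are returned as NaN.
    """
    if len(control_pct_baselines) < 2:
        raise ValueError("control-mean normalization needs at least 2 control wells")
    well = np.asarray(well_pct_baseline, dtype=float)
    controls = np.vstack([np.asarray(c, dtype=float) for c in control_pct_baselines])
    if controls.shape[1] != well.shape[0]:
        raise ValueError("control traces and well trace have different lengths")
    mean = controls.mean(axis=0)
    out = np.full_like(well, np.nan)
    ok = mean > _EPS
    out[ok] = 100.0 * well[ok] / mean[ok]
    return out


def _dose_response_pattern_ok(
    surfaces: dict,
    spearman_max: float,
    effect_ceiling: float = 90.0,
) -> bool:
    """Conditional-band check: do drug curves order by dose?

    Among drugs showing any effect (endpoint viability below
    ``effect_ceiling``% at some dose), at least half must have endpoint
    viability non-increasing in dose with Spearman rank correlation at
    or below ``spearman_max`` across the tested doses.
    """
    n_effect = 0
    n_pass = 0
    for surface in surfaces.values():
        endpoint = np.asarray(surface.viability)[:, -1]
        doses = np.asarray(surface.doses_nM)
        valid = np.isfinite(endpoint)
        if valid.sum() < 3 or np.nanmin(endpoint) >= effect_ceiling:
            continue
        n_effect += 1
        rho = stats.spearmanr(doses[valid], endpoint[valid]).statistic
        if np.isfinite(rho) and rho <= spearman_max:
            n_pass += 1
    if n_effect == 0:
        return False
    return n_pass >= 0.5 * n_effect


def evaluate_qc(
    control_traces: dict[str, list[NormalizedTrace]],
    surfaces: dict,
    acquisition: AcquisitionConfig | None = None,
    analysis: AnalysisConfig | None = None,
    registration_flags: dict[str, list[str]] | None = None,
    positive_controls: dict[str, NormalizedTrace] | None = None,
    layout: PlateLayout | None = None,
) -> dict:
    """Assay-validity verdict per sample.

    Mean control viability (% of baseline) at the nearest acquired
    frame at or before ``qc_time_h``:

    * >= 60%  -> valid
    * <= 50%  -> invalid
    * in between -> conditional, resolved by the dose-response pattern
      check over that sample's drug surfaces.

    A sample whose controls all started static is invalid outright.
    Registration flags and the positive-control drug-activity flag are
    annotations only; they never flip a verdict.
    """
    acquisition = acquisition or AcquisitionConfig()
    analysis = analysis or AnalysisConfig()
    report: dict = {"samples": {}, "qc_time_h": acquisition.qc_time_h}
    for sample, controls in control_traces.items():
        usable = [c for c in controls if not c.static_start]
        n_static = len(controls) - len(usable)
        entry: dict = {
            "n_control_wells": len(controls),
            "n_static_start": n_static,
            "static_start_flag": n_static > 0,
        }
        if not usable:
            entry["verdict"] = "invalid"
            entry["control_viability_at_qc_time"] = 0.0
            entry["notes"] = "controls largely non-viable (static) at start"
        else:
            idx = nearest_frame_at_or_before(usable[0].times_min, acquisition.qc_time_h)
            viab = float(np.mean([c.pct_baseline[idx] for c in usable]))
            entry["control_viability_at_qc_time"] = viab
            sample_surfaces = {k: v for k, v in surfaces.items() if k[0] == sample}
            if viab >= 60.0:
                entry["verdict"] = "valid"
            elif viab <= 50.0:
                entry["verdict"] = "invalid"
            else:
                ok = _dose_response_pattern_ok(
                    sample_surfaces, analysis.dose_response_spearman_max
                )
                entry["verdict"] = "conditional_valid" if ok else "invalid"
                entry["dose_response_check"] = bool(ok)
        report["samples"][sample] = entry

    if registration_flags:
        flagged = {w: f for w, f in registration_flags.items() if f}
        if flagged:
            report["registration_flags"] = flagged

    if positive_controls and layout is not None:
        activity: dict[str, bool] = {}
        for w in layout.wells_by_role(WellRole.positive_control):
            tr = positive_controls.get(w.address)
            if tr is None or tr.pct_control is None or tr.static_start:
                continue
            endpoint = tr.pct_control[-1]
            if np.isfinite(endpoint):
                activity[str(w.drug_id)] = bool(endpoint < 50.0)
        if activity:
            report["positive_control_active"] = activity
    return report


def triage_exclusion_rate(n_screened: int, n_failed: int) -> float:
    """Percentage of screened samples excluded by QC.

    Returned as an exact percentage; summaries round to the nearest
    integer percent (6 failures among 31 samples reports as 19%).
    """
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not (0 <= n_failed <= n_screened):
        raise ValueError("n_failed must lie between 0 and n_screened")
    return 100.0 * n_failed / n_screened
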