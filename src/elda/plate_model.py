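"""Plate-level data model, file I/O and run orchestration.

A screening run is a 384-well plate (rows A-P, columns 1-24) imaged by
bright-field time-lapse microscopy, one multi-page TIFF stack per well.
Each well is assigned a role by the plate map: vehicle control (solvent
only), positive control (a reference cell line at the top drug dose),
treatment, or empty.  This module owns the plate map / stack / config
containers and the end-to-end ``run_plate_analysis`` orchestration that
chains registration, motion-based viability scoring, normalization, QC
and dose-response summarisation.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "WellRole",
    "AcquisitionConfig",
    "AnalysisConfig",
    "RunConfig",
    "WellSpec",
    "PlateLayout",
    "FrameStack",
    "PlateReport",
    "well_address",
    "parse_well_address",
    "read_plate_map",
    "write_plate_map",
    "read_stack",
    "expected_frames",
    "load_config",
    "run_plate_analysis",
]

_ROWS = "ABCDEFGHIJKLMNOP"


class WellRole(str, Enum):
    vehicle_control = "vehicle_control"
    positive_control = "positive_control"
    treatment = "treatment"
    empty = "empty"


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging schedule and geometry of one run.

    Parameters
    ----------
    frame_interval_min:
        Minutes between consecutive frames (default 30).
    total_duration_h:
        Imaging span in hours (default 96; runs of 80-96 h are common).
    frame_height, frame_width:
        Native sensor geometry in pixels (1536 x 2048 at 5x).
    motion_window:
        Number of consecutive frames ``W`` pooled by the running maximum
        projection; the default 6 frames at 30-min spacing is a 3-h
        motion horizon.
    qc_time_h:
        Hour at which control viability is judged for assay validity.
    """

    frame_interval_min: float = 30.0
    total_duration_h: float = 96.0
    frame_height: int = 1536
    frame_width: int = 2048
    motion_window: int = 6
    qc_time_h: float = 60.0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.total_duration_h <= 0:
            raise ValueError("total_duration_h must be positive")
        if self.motion_window < 2:
            raise ValueError("motion_window must be at least 2")

    @property
    def motion_horizon_min(self) -> float:
        """Time span covered by one motion window, in minutes."""
        return self.motion_window * self.frame_interval_min


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the image-analysis pipeline.

    ``background_radius_px`` must exceed a cell diameter so the
    morphological background envelope slides over cells; 50 px matches
    the reference 5x magnification and should be scaled with pixel size.
    ``blur_sigma_px`` defaults to a fraction of the cell radius chosen
    so the bright motion rings merge into solid spots without flattening
    them into the noise.  ``pre_smooth_px`` applies one small uniform
    Gaussian to every registered frame so that sub-pixel resampling,
    which softens frames by a phase-dependent amount, cannot masquerade
    as motion.  Binarization of the blurred difference is hysteretic:
    the strong threshold ``max(k_abs, k_rel * S)`` detects motion, and
    connected pixels above ``weak_fraction`` of it delimit each spot's
    extent, closing the rings so they fill to whole cells.  ``S`` is
    the bright-structure scale of the current frame (the median of its
    cell-brightness plateau — stable from frame to frame and largely
    independent of how densely cells cover the field) and ``k_abs``
    (when None) is a floor at three times the sensor noise.  The
    relative term makes the mask invariant to global intensity
    rescaling; the absolute floor keeps empty wells empty.
    """

    background_radius_px: int = 50
    cell_radius_px: float = 8.0
    blur_sigma_px: float | None = None
    pre_smooth_px: float = 0.75
    k_rel: float = 0.12
    weak_fraction: float = 0.5
    k_abs: float | None = None
    max_object_area_px: int | None = None
    reg_mode: str = "chain"  # "chain" or "reference"
    max_shift_frac: float = 0.10
    subpixel: bool = True
    interp_order: int = 1
    shift_deadband_px: float = 0.1
    fill_holes: bool = True
    trace_smooth_frames: int = 3  # odd; 1 disables temporal de-flicker
    evaluation_time_h: float | None = None  # None -> last acquired frame
    dose_response_spearman_max: float = -0.8

    @property
    def sigma(self) -> float:
        if self.blur_sigma_px is not None:
            return self.blur_sigma_px
        return max(1.0, self.cell_radius_px / 5.0)


@dataclass(frozen=True)
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def well_address(row: int, col: int) -> str:
    """Render 0-based (row, col) as the conventional 'A01' address."""
    if not (0 <= row < len(_ROWS)) or not (0 <= col < 24):
        raise ValueError(f"well position out of 384-well range: ({row}, {col})")
    return f"{_ROWS[row]}{col + 1:02d}"


def parse_well_address(addr: str) -> tuple[int, int]:
    """Parse 'B07' into 0-based (row, col)."""
    m = re.fullmatch(r"([A-Pa-p])(\d{1,2})", addr.strip())
    if not m:
        raise ValueError(f"malformed well address: {addr!r}")
    row = _ROWS.index(m.group(1).upper())
    col = int(m.group(2)) - 1
    if not (0 <= col < 24):
        raise ValueError(f"column out of range in well address: {addr!r}")
    return row, col


@dataclass(frozen=True)
class WellSpec:
    """One well's assignment on the plate map."""

    row: int
    col: int
    role: WellRole
    drug_id: str | None = None
    concentration_nM: float | None = None
    replicate: int = 1
    sample_id: str = ""

    def __post_init__(self) -> None:
        well_address(self.row, self.col)  # validates the range
        if self.role in (WellRole.treatment, WellRole.positive_control):
            if self.drug_id in (None, ""):
                raise ValueError(f"{self.address}: {self.role.value} well lacks a drug_id")
            if self.concentration_nM is None:
                raise ValueError(f"{self.address}: {self.role.value} well lacks a concentration")
            if self.concentration_nM <= 0:
                raise ValueError(f"{self.address}: concentration must be positive")
        elif self.role is WellRole.vehicle_control:
            if self.drug_id not in (None, "") or self.concentration_nM is not None:
                raise ValueError(f"{self.address}: vehicle control must not carry a drug")

    @property
    def address(self) -> str:
        return well_address(self.row, self.col)


@dataclass
class PlateLayout:
    """Validated collection of well assignments.

    The reference layout places 31 drugs at five concentrations (1:5
    geometric dilution) in duplicate, alongside 10 vehicle-control
    wells; any layout with at least two vehicle controls per sample and
    geometric dose series is accepted.
    """

    wells: list[WellSpec]
    dilution_factor: float = 5.0
    n_concentrations: int = 5
    n_replicates: int = 2

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.wells:
            if w.address in seen:
                raise ValueError(f"duplicate well address: {w.address}")
            seen.add(w.address)
        for sample in self.samples():
            n_vehicle = sum(
                1
                for w in self.wells
                if w.sample_id == sample and w.role is WellRole.vehicle_control
            )
            if n_vehicle < 2:
                raise ValueError(
                    f"sample {sample!r} has {n_vehicle} vehicle-control wells; "
                    "control-mean normalization needs at least 2"
                )
        self._check_geometric_series()

    def _check_geometric_series(self, rtol: float = 1e-6) -> None:
        for drug in self.drugs():
            concs = sorted(
                {
                    w.concentration_nM
                    for w in self.wells
                    if w.drug_id == drug and w.role is WellRole.treatment
                }
            )
            if len(concs) < 2:
                continue
            ratios = [concs[i + 1] / concs[i] for i in range(len(concs) - 1)]
            for r in ratios:
                if not math.isclose(r, ratios[0], rel_tol=rtol):
                    raise ValueError(
                        f"drug {drug!r}: concentrations {concs} are not a geometric series"
                    )

    def samples(self) -> list[str]:
        return sorted({w.sample_id for w in self.wells if w.role is not WellRole.empty})

    def drugs(self) -> list[str]:
        return sorted(
            {w.drug_id for w in self.wells if w.role is WellRole.treatment and w.drug_id}
        )

    def wells_by_role(self, role: WellRole, sample_id: str | None = None) -> list[WellSpec]:
        return [
            w
            for w in self.wells
            if w.role is role and (sample_id is None or w.sample_id == sample_id)
        ]

    def __iter__(self):
        return iter(self.wells)

    def __len__(self) -> int:
        return len(self.wells)


@dataclass
class FrameStack:
    """One well's grayscale time series (T x H x W) with timestamps in
    minutes since imaging start."""

    frames: np.ndarray
    timestamps_min: np.ndarray
    well: WellSpec | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.timestamps_min = np.asarray(self.timestamps_min, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if len(self.timestamps_min) != self.frames.shape[0]:
            raise ValueError("timestamps length must match frame count")
        if np.any(np.diff(self.timestamps_min) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)) or self.frames.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def expected_frames(config: AcquisitionConfig, n_wells: int = 1) -> int:
    """Number of frames after time zero over the full acquisition.

    96 h at 30-min intervals gives 192 frames per well; multiplied over
    a full 384-well plate that is 73,728 images.  Non-divisible
    durations round down with a warning.
    """
    total_min = config.total_duration_h * 60.0
    ratio = total_min / config.frame_interval_min
    n = int(math.floor(ratio + 1e-9))
    if abs(ratio - n) > 1e-9:
        warnings.warn(
            f"total duration {config.total_duration_h} h is not a multiple of the "
            f"{config.frame_interval_min}-min frame interval; rounding down to {n} frames",
            stacklevel=2,
        )
    return n * n_wells


_PLATE_MAP_COLUMNS = ["well", "role", "drug", "concentration_nM", "replicate", "sample"]


def read_plate_map(path: str | Path, **layout_kwargs) -> PlateLayout:
    """Read a plate-map CSV (columns well, role, drug, concentration_nM,
    replicate, sample) into a validated :class:`PlateLayout`."""
    df = pd.read_csv(path, dtype={"well": str, "role": str, "drug": str, "sample": str})
    missing = [c for c in _PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map is missing columns: {missing}")
    wells = []
    for rec in df.itertuples(index=False):
        role_token = str(rec.role).strip()
        try:
            role = WellRole(role_token)
        except ValueError:
            raise ValueError(f"unknown role token {role_token!r} in well {rec.well}") from None
        row, col = parse_well_address(str(rec.well))
        drug = None if pd.isna(rec.drug) or rec.drug == "" else str(rec.drug)
        conc = None if pd.isna(rec.concentration_nM) else float(rec.concentration_nM)
        repl = 1 if pd.isna(rec.replicate) else int(rec.replicate)
        sample = "" if pd.isna(rec.sample) else str(rec.sample)
        wells.append(
            WellSpec(
                row=row,
                col=col,
                role=role,
                drug_id=drug,
                concentration_nM=conc,
                replicate=repl,
                sample_id=sample,
            )
        )
    return PlateLayout(wells=wells, **layout_kwargs)


def write_plate_map(layout: PlateLayout, path: str | Path) -> None:
    """Inverse of :func:`read_plate_map`; round-trips every field."""
    rows = []
    for w in layout.wells:
        rows.append(
            {
                "well": w.address,
                "role": w.role.value,
                "drug": w.drug_id or "",
                "concentration_nM": "" if w.concentration_nM is None else w.concentration_nM,
                "replicate": w.replicate,
                "sample": w.sample_id,
            }
        )
    pd.DataFrame(rows, columns=_PLATE_MAP_COLUMNS).to_csv(path, index=False)


def read_stack(
    path: str | Path,
    config: AcquisitionConfig | None = None,
    well: WellSpec | None = None,
) -> FrameStack:
    """Load a multi-page grayscale TIFF as a :class:`FrameStack`.

    Pages are taken in acquisition order.  Timestamps are synthesized
    as ``i * frame_interval`` when the file carries none.
    """
    config = config or AcquisitionConfig()
    with tifffile.TiffFile(str(path)) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: mixed page dimensions {sorted(shapes)}")
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < config.motion_window:
        raise ValueError(
            f"{path}: stack has {frames.shape[0]} frames, fewer than the "
            f"motion window of {config.motion_window}"
        )
    timestamps = np.arange(frames.shape[0]) * config.frame_interval_min
    return FrameStack(frames=frames.astype(np.float32), timestamps_min=timestamps, well=well)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration mirroring the config dataclasses."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    acq = AcquisitionConfig(**data.get("acquisition", {}))
    ana = AnalysisConfig(**data.get("analysis", {}))
    return RunConfig(acquisition=acq, analysis=ana)


def nearest_frame_at_or_before(timestamps_min: np.ndarray, time_h: float) -> int:
    """Index of the latest timestamp at or before ``time_h`` hours."""
    target = time_h * 60.0
    idx = int(np.searchsorted(np.asarray(timestamps_min), target + 1e-9) - 1)
    if idx < 0:
        raise ValueError(f"no acquired frame at or before {time_h} h")
    return idx


# --------------------------------------------------------------------------
# Orchestration


@dataclass
class PlateReport:
    """End-to-end analysis products for one plate."""

    traces: pd.DataFrame
    qc: dict
    drug_summary: pd.DataFrame
    surfaces: dict
    incomplete_drugs: list[str]
    shifts: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traces.to_csv(outdir / "traces.csv", index=False)
        with open(outdir / "qc.json", "w") as fh:
            json.dump(self.qc, fh, indent=2, sort_keys=True)
        self.drug_summary.to_csv(outdir / "drug_summary.csv", index=False)
        if self.shifts is not None:
            self.shifts.to_csv(outdir / "shifts.csv", index=False)


def run_plate_analysis(
    stacks: Mapping[str, FrameStack],
    layout: PlateLayout,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    save_overlays: bool = False,
) -> PlateReport:
    """Run the full pipeline on one plate.

    ``stacks`` maps well addresses ('A01') to raw frame stacks.  Wells
    are registered, scored for membrane motion, normalized within-well
    and to the vehicle-control mean, QC'ed, and summarised per drug as
    LD50/AUC.  The run is deterministic: identical inputs give
    identical outputs.  A treatment well without a stack flags its drug
    incomplete but does not abort the run.
    """
    from . import dose_response as dr
    from . import motion_viability as mv
    from . import normalization_qc as nq
    from . import registration as reg

    config = config or RunConfig()
    acq, ana = config.acquisition, config.analysis
    W = acq.motion_window

    normalized: dict[str, nq.NormalizedTrace] = {}
    reg_flags: dict[str, list[str]] = {}
    missing_wells: list[str] = []
    traces_rows: list[dict] = []
    shift_rows: list[dict] = []
    overlay_store: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    analyzed_wells = [w for w in layout if w.role is not WellRole.empty]
    for w in analyzed_wells:
        stack = stacks.get(w.address)
        if stack is None:
            missing_wells.append(w.address)
            continue
        registered = reg.register_stack(stack, config=ana)
        reg_flags[w.address] = registered.flags
        for t, (dy, dx) in enumerate(registered.shifts):
            shift_rows.append({"well": w.address, "frame": t, "dy_px": dy, "dx_px": dx})
        trace, motion = mv.viability_trace(registered, acquisition=acq, analysis=ana)
        normalized[w.address] = nq.normalize_within_well(trace, well=w)
        if save_overlays:
            overlay_store[w.address] = (
                registered.frames[-1],
                motion.masks[-1],
            )

    # control-mean normalization, per sample
    for sample in layout.samples():
        controls = [
            normalized[w.address]
            for w in layout.wells_by_role(WellRole.vehicle_control, sample)
            if w.address in normalized
        ]
        usable = [c for c in controls if not c.static_start]
        for w in analyzed_wells:
            if w.sample_id != sample or w.address not in normalized:
                continue
            tr = normalized[w.address]
            if len(usable) >= 2:
                tr.pct_control = nq.normalize_to_control(
                    tr.pct_baseline, [c.pct_baseline for c in usable]
                )
            else:
                tr.pct_control = np.full_like(tr.pct_baseline, np.nan)

    for w in analyzed_wells:
        if w.address not in normalized:
            continue
        tr = normalized[w.address]
        for i in range(len(tr.times_min)):
            traces_rows.append(
                {
                    "well": w.address,
                    "sample": w.sample_id,
                    "role": w.role.value,
                    "drug": w.drug_id or "",
                    "concentration_nM": w.concentration_nM,
                    "time_min": tr.times_min[i],
                    "raw_area_px": tr.raw_area[i],
                    "pct_baseline": tr.pct_baseline[i],
                    "pct_control": tr.pct_control[i] if tr.pct_control is not None else np.nan,
                }
            )

    # dose-response surfaces from treatment wells only
    surfaces: dict[tuple[str, str], dr.DoseResponseSurface] = {}
    incomplete: set[str] = set()
    summary_rows: list[dict] = []
    for sample in layout.samples():
        for drug in layout.drugs():
            t_wells = [
                w
                for w in layout.wells_by_role(WellRole.treatment, sample)
                if w.drug_id == drug
            ]
            if not t_wells:
                continue
            if any(w.address not in normalized for w in t_wells):
                incomplete.add(drug)
            present = [w for w in t_wells if w.address in normalized]
            if not present:
                continue
            try:
                surface = dr.build_surface(
                    {w.address: normalized[w.address] for w in present}, layout
                )
            except ValueError:
                incomplete.add(drug)
                continue
            surfaces[(sample, drug)] = surface
            eval_t = (
                ana.evaluation_time_h
                if ana.evaluation_time_h is not None
                else surface.times_min[-1] / 60.0
            )
            res = dr.ld50(surface, time_h=eval_t)
            try:
                auc_val = dr.auc(surface)
            except ValueError:
                auc_val = np.nan
            summary_rows.append(
                {
                    "sample": sample,
                    "drug": drug,
                    "time_h": eval_t,
                    "ld50_nM": res.ld50_nM,
                    "ld50_censored": res.censored,
                    "below_range": res.below_range,
                    "non_monotone": res.non_monotone,
                    "auc": auc_val,
                    "incomplete": drug in incomplete,
                }
            )

    qc = nq.evaluate_qc(
        {s: [normalized[w.address]
             for w in layout.wells_by_role(WellRole.vehicle_control, s)
             if w.address in normalized]
         for s in layout.samples()},
        surfaces,
        acquisition=acq,
        analysis=ana,
        registration_flags=reg_flags,
        positive_controls={
            w.address: normalized[w.address]
            for s in layout.samples()
            for w in layout.wells_by_role(WellRole.positive_control, s)
            if w.address in normalized
        },
        layout=layout,
    )
    if missing_wells:
        qc["missing_wells"] = sorted(missing_wells)

    summary_cols = [
        "sample", "drug", "time_h", "ld50_nM", "ld50_censored",
        "below_range", "non_monotone", "auc", "incomplete",
    ]
    report = PlateReport(
        traces=pd.DataFrame(
            traces_rows,
            columns=[
                "well", "sample", "role", "drug", "concentration_nM",
                "time_min", "raw_area_px", "pct_baseline", "pct_control",
            ],
        ),
        qc=qc,
        drug_summary=pd.DataFrame(summary_rows, columns=summary_cols),
        surfaces=surfaces,
        incomplete_drugs=sorted(incomplete),
        shifts=pd.DataFrame(shift_rows, columns=["well", "frame", "dy_px", "dx_px"]),
    )
    if outdir is not None:
        report.write(outdir)
        if save_overlays:
            from . import motion_viability as mv2

            overlay_dir = Path(outdir) / "overlays"
            overlay_dir.mkdir(exist_ok=True)
            for addr, (frame, mask) in overlay_store.items():
                mv2.render_overlay(frame, mask, path=overlay_dir / f"{addr}.png")
    return report
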