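"""Membrane-motion detection: the label-free viability signal.

Non-adherent leukemia cells held in a collagen matrix barely translate,
but live cells continuously wobble their membrane; dead cells are
perfectly still.  The detector exploits this: after background
flattening, a running per-pixel maximum over a trailing window of W
consecutive frames (default 6 frames = 3 h at 30-min spacing) captures
everywhere a membrane has been during the window.  Subtracting the
current frame from that projection leaves bright rings along moving
membranes only; a Gaussian blur merges each ring into a solid spot,
and thresholding plus hole filling yields a per-frame "live pixel"
mask.  Viability is the summed pixel area of that mask — area, not
cell count, so partially overlapping cells and debris do not require
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import disk, opening

from .plate_model import AcquisitionConfig, AnalysisConfig
from .registration import RegisteredStack

__all__ = [
    "MotionMap",
    "ViabilityTrace",
    "subtract_background",
    "running_max",
    "motion_difference",
    "rings_to_spots",
    "viability_trace",
    "render_overlay",
    "bright_structure_scale",
    "estimate_sensor_noise",
    "estimate_noise_floor",
    "smooth_trace",
]


@dataclass
class MotionMap:
    """Per-frame live-pixel masks for frame indices >= W, with optional
    intermediate layers for debugging."""

    frame_indices: np.ndarray  # indices t >= W into the source stack
    masks: np.ndarray  # (len(frame_indices), H, W) boolean
    live_area: np.ndarray  # pixel counts, same length
    layers: dict | None = None

    def __post_init__(self) -> None:
        counted = self.masks.sum(axis=(1, 2))
        if not np.array_equal(counted, self.live_area):
            raise ValueError("live_area must equal the mask pixel counts")


@dataclass
class ViabilityTrace:
    """Raw live pixel area per defined frame (t >= W)."""

    times_min: np.ndarray
    raw_area: np.ndarray
    frame_indices: np.ndarray
    well: object | None = None


def subtract_background(frame: np.ndarray, radius: int) -> np.ndarray:
    """Flatten illumination with a grayscale morphological opening.

    The opening with a disc wider than a cell slides under cell-scale
    bright structure but follows smooth illumination, so subtracting it
    leaves cells bright on a near-zero background (the rolling-ball
    idea expressed with a flat structuring element).  The radius must
    exceed a cell diameter; 50 px suits the reference 5x scale.
    """
    if radius <= 0:
        raise ValueError("background radius must be positive")
    frame = np.asarray(frame, dtype=np.float32)
    footprint = disk(radius, decomposition="sequence")
    background = opening(frame, footprint)
    return np.clip(frame - background, 0.0, None)


def running_max(stack: np.ndarray, W: int) -> np.ndarray:
    """Trailing-window per-pixel maximum projection.

    ``out[i]`` is the per-pixel maximum over source frames
    ``t-W+1 ... t`` with ``t = i + W - 1``; the output therefore has
    ``T - W + 1`` frames, the first complete window ending at frame
    index ``W - 1``.
    """
    if W < 2:
        raise ValueError("motion window must span at least 2 frames")
    stack = np.asarray(stack)
    if stack.shape[0] < W:
        raise ValueError(f"stack has {stack.shape[0]} frames, fewer than the window {W}")
    windows = sliding_window_view(stack, W, axis=0)
    return windows.max(axis=-1)


def motion_difference(maxproj: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Projection minus current frame, clipped at zero.

    Bright exactly where intensity appeared somewhere in the window but
    is absent now — i.e. along membranes that moved.  A static scene
    gives an identically zero difference.
    """
    maxproj = np.asarray(maxproj, dtype=np.float32)
    frame = np.asarray(frame, dtype=np.float32)
    if maxproj.shape != frame.shape:
        raise ValueError(f"shape mismatch: {maxproj.shape} vs {frame.shape}")
    return np.clip(maxproj - frame, 0.0, None)


def estimate_sensor_noise(frame: np.ndarray) -> float:
    """Robust per-pixel noise sigma from adjacent-pixel differences.

    Differencing neighbouring pixels cancels smooth structure and
    plateau interiors; the median absolute difference is immune to the
    minority of cell-edge pixels, and 1.4826/sqrt(2) converts it to the
    sigma of a single pixel under Gaussian noise.
    """
    d = np.diff(np.asarray(frame, dtype=np.float32), axis=1)
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def bright_structure_scale(cleaned: np.ndarray) -> float:
    """Intensity scale of the bright (cell-body) plateau of a
    background-subtracted frame.

    The median of the pixels above half the 99.9th percentile sits in
    the middle of the cell-brightness plateau, so it tracks global
    intensity rescaling but barely moves when more cells of the same
    brightness enter the field — unlike a fixed image-wide percentile,
    whose position inside the plateau depends on how much of the frame
    cells occupy.
    """
    cleaned = np.asarray(cleaned)
    p_hi = float(np.percentile(cleaned, 99.9))
    if p_hi <= 0:
        return 0.0
    sel = cleaned > 0.5 * p_hi
    return float(np.median(cleaned[sel])) if sel.any() else p_hi


def smooth_trace(values: np.ndarray, window: int) -> np.ndarray:
    """Temporal median with edge replication; window 1 is a no-op.

    A short odd median window removes single-frame detection flicker
    (cells whose blurred ring grazes the threshold) without biasing
    the kinetics at 30-min resolution.
    """
    if window <= 1:
        return np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    v = np.asarray(values, dtype=float)
    half = window // 2
    padded = np.pad(v, half, mode="edge")
    return np.median(sliding_window_view(padded, window), axis=-1)


def estimate_noise_floor(blurred: np.ndarray) -> float:
    """Noise floor of a blurred difference image.

    Motion signal lives in the upper tail of the blurred difference, so
    the noise scale is taken one-sidedly from the lower quantiles: with
    sigma estimated from the 25th-to-50th percentile gap (0.6745 sigma
    for a Gaussian), median + 5 sigma is a floor that pure noise
    essentially never crosses, yet bright rings cannot inflate.  This
    self-calibrates on any well without assuming a cell-free region.
    """
    q25, q50 = np.percentile(blurred, [25.0, 50.0])
    sigma = (q50 - q25) / 0.6745
    return float(q50 + 5.0 * sigma)


def rings_to_spots(
    diff: np.ndarray,
    sigma: float,
    k_rel: float = 0.12,
    k_abs: float | None = None,
    signal_scale: float | None = None,
    weak_fraction: float = 0.5,
    fill_holes: bool = True,
    max_hole_area: int | None = None,
    max_object_area: int | None = None,
) -> np.ndarray:
    """Blur the motion rings into solid spots and binarize.

    Binarization is hysteretic: pixels above the strong threshold
    ``max(k_abs, k_rel * S)`` seed detections, which then extend over
    connected pixels above ``weak_fraction`` of it.  Motion rings are
    bright only where the membrane happened to move against the window
    maximum, so single-threshold masks leave arc gaps; the weak
    envelope is continuous, closing each ring so it fills to a whole
    cell, while detection sensitivity stays governed by the strong
    threshold (``weak_fraction=1`` recovers plain thresholding).

    ``S`` anchors the relative term: the caller passes the
    cell-brightness plateau scale of the background-subtracted frame
    (see :func:`bright_structure_scale`); when not given, the 99.9th
    percentile of the blurred difference itself is used, which
    suffices for a standalone call.  ``k_abs`` (estimated from the
    blurred difference when not given) keeps pure-noise images empty.
    Holes inside connected components are filled so each moving cell
    becomes one solid spot; ``max_hole_area`` restricts filling to
    ring-interior-sized holes, preventing chance loops of neighbouring
    spots from swallowing large background pockets.  An optional
    component-area cap drops oversized objects (e.g. large motile
    stromal cells).
    """
    if sigma <= 0:
        raise ValueError("blur sigma must be positive")
    if not (0.0 < weak_fraction <= 1.0):
        raise ValueError("weak_fraction must lie in (0, 1]")
    diff = np.asarray(diff, dtype=np.float32)
    blurred = ndimage.gaussian_filter(diff, sigma)
    if not np.any(blurred > 0):
        return np.zeros(diff.shape, dtype=bool)
    if k_abs is None:
        k_abs = estimate_noise_floor(blurred)
    if signal_scale is None:
        signal_scale = float(np.percentile(blurred, 99.9))
    threshold = max(k_abs, k_rel * signal_scale)
    if weak_fraction < 1.0:
        mask = apply_hysteresis_threshold(
            blurred, weak_fraction * threshold, threshold
        )
    else:
        mask = blurred > threshold
    if fill_holes and mask.any():
        filled = ndimage.binary_fill_holes(mask)
        if max_hole_area is None:
            mask = filled
        else:
            holes = filled & ~mask
            labels, n = ndimage.label(holes)
            if n:
                sizes = ndimage.sum_labels(holes, labels, index=np.arange(1, n + 1))
                keep = np.flatnonzero(sizes <= max_hole_area) + 1
                mask = mask | np.isin(labels, keep)
    if max_object_area is not None and mask.any():
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        drop = np.flatnonzero(sizes > max_object_area) + 1
        if drop.size:
            mask &= ~np.isin(labels, drop)
    return mask


def viability_trace(
    stack: RegisteredStack,
    acquisition: AcquisitionConfig | None = None,
    analysis: AnalysisConfig | None = None,
    keep_layers: bool = False,
) -> tuple[ViabilityTrace, MotionMap]:
    """Full motion pipeline for one registered stack.

    Composition per frame ``t >= W``: background subtraction -> running
    max over the trailing window ``t-W+1..t`` -> difference from the
    current frame -> blur/threshold/fill -> summed live pixel area.
    The first defined value falls at frame index W (time point 6 by
    default, 3 h into imaging), because a cell can only be judged
    live or dead once a full motion window precedes it.
    """
    acquisition = acquisition or AcquisitionConfig()
    analysis = analysis or AnalysisConfig()
    W = acquisition.motion_window
    frames = np.asarray(stack.frames, dtype=np.float32)
    T = frames.shape[0]
    if T < W + 1:
        raise ValueError(f"need at least W+1 = {W + 1} frames, got {T}")

    raw_frames = frames
    if analysis.pre_smooth_px > 0:
        # uniform softening so phase-dependent resampling blur from
        # sub-pixel registration cannot read as membrane motion
        frames = np.stack(
            [ndimage.gaussian_filter(f, analysis.pre_smooth_px) for f in frames]
        )
    cleaned = np.stack(
        [subtract_background(frames[t], analysis.background_radius_px) for t in range(T)]
    )
    proj = running_max(cleaned, W)  # proj[i] covers frames i..i+W-1

    frame_indices = np.arange(W, T)
    masks = np.empty((len(frame_indices), *frames.shape[1:]), dtype=bool)
    diffs = [] if keep_layers else None
    for j, t in enumerate(frame_indices):
        # trailing window ending at t starts at t-W+1 -> proj index t-W+1
        diff = motion_difference(proj[t - W + 1], cleaned[t])
        k_abs = analysis.k_abs
        if k_abs is None:
            # safety floor at 3x the sensor noise: irrelevant wherever
            # cells set the relative term, decisive in empty wells.
            # Estimated on the unsmoothed frame — pre-smoothing and
            # the clipping in background subtraction would both bias
            # the estimate low.
            k_abs = 3.0 * estimate_sensor_noise(raw_frames[t])
        masks[j] = rings_to_spots(
            diff,
            sigma=analysis.sigma,
            k_rel=analysis.k_rel,
            k_abs=k_abs,
            signal_scale=bright_structure_scale(cleaned[t]),
            weak_fraction=analysis.weak_fraction,
            fill_holes=analysis.fill_holes,
            max_hole_area=int(2 * np.pi * analysis.cell_radius_px ** 2),
            max_object_area=analysis.max_object_area_px,
        )
        if keep_layers:
            diffs.append(diff)

    live_area = masks.sum(axis=(1, 2))
    layers = None
    if keep_layers:
        layers = {"cleaned": cleaned, "maxproj": proj, "difference": np.stack(diffs)}
    trace = ViabilityTrace(
        times_min=np.asarray(stack.timestamps_min)[frame_indices],
        raw_area=smooth_trace(live_area, analysis.trace_smooth_frames),
        frame_indices=frame_indices,
        well=stack.well,
    )
    return trace, MotionMap(
        frame_indices=frame_indices, masks=masks, live_area=live_area, layers=layers
    )


def render_overlay(
    frame: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.5,
    path: str | None = None,
) -> np.ndarray:
    """Pseudo-color live pixels red on the grayscale frame.

    Returns an (H, W, 3) uint8 image; writes a PNG when ``path`` is
    given.
    """
    frame = np.asarray(frame, dtype=np.float32)
    mask = np.asarray(mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {mask.shape}")
    lo, hi = float(frame.min()), float(frame.max())
    gray = (frame - lo) / (hi - lo) if hi > lo else np.zeros_like(frame)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    red = np.zeros_like(rgb)
    red[..., 0] = 1.0
    rgb[mask] = (1 - alpha) * rgb[mask] + alpha * red[mask]
    out = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    if path is not None:
        iio.imwrite(str(path), out)
    return out
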