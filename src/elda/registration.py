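"""Translational drift correction for well time-lapse stacks.

Plate drift and stage vibration move the whole field of view between
frames; uncorrected, a perfectly still (dead) cell would masquerade as
a moving (live) one.  Shifts are estimated by Fourier phase
cross-correlation and applied as sub-pixel translations with
replicate-edge fill, either frame-to-previous with accumulation
("chain", robust to slow content change over long time lapses) or
frame-to-reference ("reference").  Only translations are modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .plate_model import AnalysisConfig, FrameStack

__all__ = ["RegisteredStack", "estimate_shift", "register_stack"]


@dataclass
class RegisteredStack:
    """Aligned frames plus the per-frame (dy, dx) shifts, in pixels,
    of each raw frame relative to the reference frame."""

    frames: np.ndarray
    timestamps_min: np.ndarray
    shifts: np.ndarray
    reference_index: int = 0
    flags: list[str] = field(default_factory=list)
    well: object | None = None

    def __post_init__(self) -> None:
        ref_shift = self.shifts[self.reference_index]
        if not np.allclose(ref_shift, 0.0, atol=1e-9):
            raise ValueError("shift at the reference frame must be (0, 0)")


def estimate_shift(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    upsample_factor: int = 20,
) -> tuple[float, float]:
    """Displacement (dy, dx) of ``frame_b`` relative to ``frame_a``.

    The returned shift is the translation that ``frame_b``'s content
    has undergone: if ``frame_b == roll(frame_a, (3, -2))`` the result
    is (3, -2).  Applying the negated shift to ``frame_b`` re-aligns it
    with ``frame_a``.  Sub-pixel precision comes from local upsampling
    of the cross-correlation peak.  A constant (zero-variance) frame
    carries no registration information and yields (0, 0) plus a
    warning.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant frame: shift is undefined, returning (0, 0)", stacklevel=2)
        return (0.0, 0.0)
    # a frame whose bright structure does not rise above the noise has
    # no usable registration content; correlating noise yields a
    # random-walk drift that would fabricate motion
    for f in (a, b):
        noise = 1.4826 * np.median(np.abs(np.diff(f, axis=1))) / np.sqrt(2.0)
        structure = np.percentile(f, 99.5) - np.median(f)
        if noise > 0 and structure < 4.0 * noise:
            warnings.warn(
                "low-content frame: registration unreliable, returning (0, 0)",
                stacklevel=2,
            )
            return (0.0, 0.0)
    # phase_cross_correlation returns the shift that registers the
    # moving image onto the reference, i.e. minus the displacement.
    shift, _, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample_factor, normalization=None
    )
    return (float(-shift[0]), float(-shift[1]))


def _apply_shift(
    frame: np.ndarray, shift: tuple[float, float], subpixel: bool, order: int = 1
) -> np.ndarray:
    # linear interpolation: higher-order splines and Fourier shifts
    # overshoot at the sharp disc/ring edges, and the phase-dependent
    # overshoot masquerades as motion in the downstream difference
    dy, dx = shift
    if not subpixel:
        dy, dx = round(dy), round(dx)
        order = 0
    if dy == 0 and dx == 0:
        return frame
    return ndimage.shift(frame, (dy, dx), order=order, mode="nearest")


def register_stack(
    stack: FrameStack,
    config: AnalysisConfig | None = None,
    reference_index: int = 0,
) -> RegisteredStack:
    """Align every frame of a stack to the reference frame.

    In "chain" mode each frame is estimated against its predecessor
    and the displacements are accumulated; in "reference" mode each
    frame is estimated directly against the reference.  Shifts whose
    magnitude exceeds ``max_shift_frac`` of the frame size are applied
    but flagged for the well's QC record, as are zero-variance frames.
    """
    config = config or AnalysisConfig()
    frames = np.asarray(stack.frames, dtype=np.float32)
    T = frames.shape[0]
    if T < 2:
        raise ValueError("registration needs at least two frames")
    shifts = np.zeros((T, 2), dtype=float)
    flags: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if config.reg_mode == "chain":
            cum = np.zeros(2)
            for t in range(1, T):
                step = estimate_shift(frames[t - 1], frames[t])
                cum = cum + np.asarray(step)
                shifts[t] = cum
        elif config.reg_mode == "reference":
            for t in range(T):
                if t == reference_index:
                    continue
                shifts[t] = estimate_shift(frames[reference_index], frames[t])
        else:
            raise ValueError(f"unknown registration mode {config.reg_mode!r}")
    if caught:
        flags.append("constant_frame")

    max_dy = config.max_shift_frac * frames.shape[1]
    max_dx = config.max_shift_frac * frames.shape[2]
    if np.any(np.abs(shifts[:, 0]) > max_dy) or np.any(np.abs(shifts[:, 1]) > max_dx):
        flags.append("large_shift")

    # re-zero relative to the chosen reference so the contract holds in
    # chain mode too (frame 0 is the chain anchor by construction).
    shifts = shifts - shifts[reference_index]

    # deadband: resample a frame only once its estimated shift departs
    # from the currently applied one by more than the estimator's own
    # noise, so jitter-level estimates do not smear static content
    applied = np.zeros_like(shifts)
    db = config.shift_deadband_px
    current = np.zeros(2)
    for t in range(T):
        if np.any(np.abs(shifts[t] - current) > db):
            current = shifts[t].copy()
        applied[t] = current
    applied[reference_index] = 0.0

    aligned = np.empty_like(frames)
    for t in range(T):
        aligned[t] = _apply_shift(
            frames[t], (-applied[t, 0], -applied[t, 1]), config.subpixel, config.interp_order
        )
    return RegisteredStack(
        frames=aligned,
        timestamps_min=np.asarray(stack.timestamps_min, dtype=float),
        shifts=shifts,
        reference_index=reference_index,
        flags=flags,
        well=stack.well,
    )
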