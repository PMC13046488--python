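"""Synthetic bright-field time-lapse generator with per-cell ground
truth.

The simulator renders the phenomenology the analysis pipeline must
detect or resist: leukemic blasts appear as bright discs outlined by a
dark membrane ring (the lens-like look of non-adherent cells in phase
contrast); live blasts wobble their membrane a little every frame
while their centers stay put (the collagen matrix pins positions);
dead blasts freeze completely; a few large, elongated, highly motile
stromal cells wander by random walk and can drag nearby blasts —
alive or dead — with them, the main viability-inflating artifact;
the whole field drifts with the stage, sits under an illumination
gradient fixed to the camera, and carries Gaussian sensor noise.
Drug action follows an exponential death hazard whose rate is a Hill
function of dose.  Everything is reproducible from the seed, and each
well ships its ground truth: per-cell states, center tracks and true
live pixel area per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .plate_model import (
    AcquisitionConfig,
    FrameStack,
    PlateLayout,
    WellRole,
    WellSpec,
)

__all__ = [
    "SceneConfig",
    "KillModel",
    "GroundTruth",
    "simulate_well",
    "simulate_plate",
    "acquisition_for_scene",
    "analysis_for_scene",
]


@dataclass(frozen=True)
class SceneConfig:
    """Scene content and optics for one simulated well.

    The reduced default geometry (256 x 256, 48 frames at 30-min
    spacing, i.e. a 24-h run) keeps simulations tractable; a full-scale
    2,048 x 1,536 / 192-frame well uses the same renderer.  The default
    of 100 blasts in a 256 x 256 field is the reduced-geometry
    equivalent of the assay's 4,000 cells per well; ``n_stroma`` keeps
    the assay's stroma-to-blast ratio of 100 stromal cells per 4,000
    blasts (1:40), hence 2 stromal cells by default.  ``jitter_amplitude``
    is the per-frame membrane wobble of live cells in pixels; its
    default of 1 px is a synthetic choice making live/dead separation
    non-trivial but solvable, not a measured value.
    """

    n_live: int = 100
    n_dead: int = 0
    cell_radius: float = 8.0
    n_stroma: int = 2
    stroma_size: float = 16.0
    jitter_amplitude: float = 1.0
    drift: tuple[float, float] = (0.0, 0.0)  # (dy, dx) px per frame
    illumination_gradient: float = 0.15
    noise_sigma: float = 2.0
    height: int = 256
    width: int = 256
    n_frames: int = 48
    frame_interval_min: float = 30.0
    seed: int = 0
    background: float = 30.0
    cell_brightness: float = 70.0
    ring_depth: float = 18.0
    ring_width: float = 2.0
    stroma_brightness: float = 55.0
    stroma_step: float = 2.0
    drag_fraction: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_live, self.n_dead, self.n_stroma) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.jitter_amplitude < 0:
            raise ValueError("jitter_amplitude must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")


@dataclass(frozen=True)
class KillModel:
    """Dose-dependent exponential death hazard.

    The hazard is ``baseline + max_hazard * c^s / (c^s + c50^s)``; each
    blast's death time is an independent exponential draw.  The default
    ``max_hazard`` is calibrated so that a 24-h exposure at the
    half-effect concentration kills half the cells — which makes
    ``c50_nM`` the 24-h LD50 by construction and gives the pipeline a
    known truth to recover.
    """

    concentration_nM: float
    c50_nM: float = 20.0
    hill_slope: float = 2.0
    max_hazard_per_h: float = 2.0 * math.log(2.0) / 24.0
    baseline_hazard_per_h: float = 0.0

    def hazard_per_h(self) -> float:
        c = self.concentration_nM
        if c < 0:
            raise ValueError("concentration must be non-negative")
        if c == 0:
            return self.baseline_hazard_per_h
        cs = c ** self.hill_slope
        return self.baseline_hazard_per_h + self.max_hazard_per_h * cs / (
            cs + self.c50_nM ** self.hill_slope
        )


@dataclass
class GroundTruth:
    """Per-cell and per-frame truth for one simulated well."""

    cell_type: np.ndarray  # 'blast' or 'stroma'
    death_time_h: np.ndarray  # inf = never dies; <= 0 = dead at start
    tracks: np.ndarray  # (n_frames, n_cells, 2) centers (y, x), scene coords
    alive: np.ndarray  # (n_frames, n_blasts) bool
    true_live_count: np.ndarray  # per frame
    true_live_area_px: np.ndarray  # per frame, sum of live blast disc areas
    displacement_events: list[tuple[int, int, float]] = field(default_factory=list)
    # (frame, blast index, displacement magnitude in px)

    def true_viability_pct(self, baseline_index: int) -> np.ndarray:
        """True viability normalized exactly as the pipeline normalizes:
        % of the live area at the baseline frame."""
        base = self.true_live_area_px[baseline_index]
        if base == 0:
            return np.full(len(self.true_live_area_px), np.nan)
        return 100.0 * self.true_live_area_px / base


def _place_centers(
    rng: np.random.Generator,
    n: int,
    height: int,
    width: int,
    radius: float,
    min_sep: float,
    existing: np.ndarray | None = None,
    existing_sep: float | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Rejection-sampled centers with a soft minimum separation, also
    honouring a (possibly different) separation from ``existing``
    centers."""
    margin = radius + 2.0
    centers: list[np.ndarray] = []
    prior = [] if existing is None else [np.asarray(p) for p in existing]
    prior_sep = existing_sep if existing_sep is not None else min_sep

    def shortfall(c: np.ndarray) -> float:
        worst = 0.0
        for p in centers:
            worst = max(worst, min_sep - float(np.hypot(*(c - p))))
        for p in prior:
            worst = max(worst, prior_sep - float(np.hypot(*(c - p))))
        return worst

    for _ in range(n):
        best, best_short = None, np.inf
        for _ in range(max_tries):
            c = rng.uniform([margin, margin], [height - margin, width - margin])
            s = shortfall(c)
            if s <= 0.0:
                best = c
                break
            if s < best_short:  # crowded: keep the least-overlapping spot
                best, best_short = c, s
        centers.append(best)
    return np.array(centers).reshape(n, 2)


def _render_blast(
    canvas: np.ndarray,
    cy: float,
    cx: float,
    r0: float,
    coeffs: np.ndarray,
    brightness: float,
    ring_depth: float,
    ring_width: float,
) -> None:
    """Draw one bright-disc/dark-ring blast with a perturbed boundary.

    The membrane radius is ``r0 + a0 + a2 cos(2t+p2) + a3 cos(3t+p3)``;
    edges are ~1 px linear ramps for sub-pixel rendering.
    """
    h, w = canvas.shape
    r_max = r0 + ring_width + abs(coeffs[0]) + abs(coeffs[1]) + abs(coeffs[3]) + 2.0
    y0, y1 = int(max(0, cy - r_max)), int(min(h, cy + r_max + 1))
    x0, x1 = int(max(0, cx - r_max)), int(min(w, cx + r_max + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=np.float32)[:, None] - cy
    xx = np.arange(x0, x1, dtype=np.float32)[None, :] - cx
    rr = np.hypot(yy, xx)
    th = np.arctan2(yy, xx)
    a0, a2, p2, a3, p3 = coeffs
    r_b = r0 + a0 + a2 * np.cos(2 * th + p2) + a3 * np.cos(3 * th + p3)
    w_outer = np.clip((r_b - rr) / 0.8 + 0.5, 0.0, 1.0)  # 1 inside the membrane
    w_inner = np.clip((r_b - ring_width - rr) / 0.8 + 0.5, 0.0, 1.0)  # 1 in cytoplasm
    canvas[y0:y1, x0:x1] += brightness * w_inner - ring_depth * (w_outer - w_inner)


def _render_stroma(
    canvas: np.ndarray,
    cy: float,
    cx: float,
    major: float,
    minor: float,
    angle: float,
    brightness: float,
) -> None:
    """Elongated bright Gaussian blob for a mesenchymal stromal cell."""
    h, w = canvas.shape
    r_max = 2.5 * major
    y0, y1 = int(max(0, cy - r_max)), int(min(h, cy + r_max + 1))
    x0, x1 = int(max(0, cx - r_max)), int(min(w, cx + r_max + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=np.float32)[:, None] - cy
    xx = np.arange(x0, x1, dtype=np.float32)[None, :] - cx
    u = np.cos(angle) * xx + np.sin(angle) * yy
    v = -np.sin(angle) * xx + np.cos(angle) * yy
    canvas[y0:y1, x0:x1] += brightness * np.exp(
        -0.5 * (u ** 2 / major ** 2 + v ** 2 / minor ** 2)
    )


def simulate_well(
    scene: SceneConfig,
    kill: KillModel | None = None,
) -> tuple[FrameStack, GroundTruth]:
    """Render one well's time-lapse stack and its ground truth.

    Blasts whose requested footprint exceeds 60% of the frame raise an
    overcrowding error.  Identical (scene, kill) inputs always produce
    identical pixels.

    Each phenomenon draws from its own random substream (live cells,
    pre-dead cells, stroma, drug deaths, sensor noise), so perturbing
    one ingredient — adding dead cells, say — leaves every other
    realization untouched.  Perturbation experiments then compare like
    with like.
    """
    rng_live, rng_dead, rng_stroma, rng_kill, rng_noise = (
        np.random.default_rng(s) for s in np.random.SeedSequence(scene.seed).spawn(5)
    )
    h, w = scene.height, scene.width
    n_blasts = scene.n_live + scene.n_dead
    blast_area = n_blasts * math.pi * scene.cell_radius ** 2
    stroma_area = scene.n_stroma * math.pi * scene.stroma_size * (scene.stroma_size / 3.0)
    if blast_area + stroma_area > 0.6 * h * w:
        raise ValueError(
            f"overcrowded scene: requested cell area {blast_area + stroma_area:.0f} px "
            f"exceeds 60% of the {h}x{w} frame"
        )

    min_sep = 2.0 * scene.cell_radius
    live_centers = _place_centers(rng_live, scene.n_live, h, w, scene.cell_radius, min_sep)
    # dead cells keep clear of live membranes' wobble-plus-blur reach
    # so that inserting them does not occlude genuine motion signal:
    # a live ring extends to ~r + jitter and its blurred detection
    # halo roughly another cell radius beyond
    dead_centers = _place_centers(
        rng_dead,
        scene.n_dead,
        h,
        w,
        scene.cell_radius,
        min_sep,
        existing=live_centers,
        existing_sep=3.0 * scene.cell_radius,
    )
    centers = np.vstack([live_centers, dead_centers])
    # death times: pre-dead blasts at t<=0, live blasts by drug hazard
    death_h = np.full(n_blasts, np.inf)
    death_h[scene.n_live:] = 0.0
    if kill is not None and scene.n_live > 0:
        hz = kill.hazard_per_h()
        if hz > 0:
            death_h[: scene.n_live] = rng_kill.exponential(1.0 / hz, size=scene.n_live)
        elif hz < 0:
            raise ValueError("hazard must be non-negative")

    # frozen membrane shape per blast; live shapes refreshed each frame
    jit = scene.jitter_amplitude
    def draw_coeffs(rng: np.random.Generator, size: int) -> np.ndarray:
        a0 = rng.normal(0.0, 0.35 * jit, size)
        a2 = rng.normal(0.0, 0.45 * jit, size)
        a3 = rng.normal(0.0, 0.35 * jit, size)
        p2 = rng.uniform(0, 2 * np.pi, size)
        p3 = rng.uniform(0, 2 * np.pi, size)
        return np.stack([a0, a2, p2, a3, p3], axis=1)

    coeffs = np.vstack(
        [draw_coeffs(rng_live, scene.n_live), draw_coeffs(rng_dead, scene.n_dead)]
    ) if n_blasts else np.zeros((0, 5))

    stroma_pos = _place_centers(
        rng_stroma, scene.n_stroma, h, w, scene.stroma_size, min_sep=scene.stroma_size
    )
    stroma_angle = rng_stroma.uniform(0, 2 * np.pi, scene.n_stroma)

    # illumination gradient fixed in camera coordinates
    gy = np.linspace(-0.5, 0.5, h, dtype=np.float32)[:, None]
    gx = np.linspace(-0.5, 0.5, w, dtype=np.float32)[None, :]
    illum = 1.0 + scene.illumination_gradient * 0.5 * (gy + gx)

    dt_h = scene.frame_interval_min / 60.0
    frames = np.empty((scene.n_frames, h, w), dtype=np.float32)
    tracks = np.empty((scene.n_frames, n_blasts + scene.n_stroma, 2))
    alive = np.empty((scene.n_frames, n_blasts), dtype=bool)
    events: list[tuple[int, int, float]] = []
    pos = centers.copy()

    for t in range(scene.n_frames):
        time_h = t * dt_h
        is_alive = time_h < death_h
        alive[t] = is_alive

        # stromal random walk, dragging contacted blasts
        if scene.n_stroma:
            steps = rng_stroma.normal(0.0, scene.stroma_step, size=(scene.n_stroma, 2))
            if t > 0:
                for s in range(scene.n_stroma):
                    new = stroma_pos[s] + steps[s]
                    new[0] = np.clip(new[0], scene.stroma_size, h - scene.stroma_size)
                    new[1] = np.clip(new[1], scene.stroma_size, w - scene.stroma_size)
                    step = new - stroma_pos[s]
                    stroma_pos[s] = new
                    if n_blasts:
                        d = np.hypot(*(pos - stroma_pos[s]).T)
                        contact = d < scene.stroma_size / 2.0 + scene.cell_radius
                        for b in np.flatnonzero(contact):
                            disp = scene.drag_fraction * step
                            pos[b] = pos[b] + disp
                            events.append((t, int(b), float(np.hypot(*disp))))

        # live membranes take a fresh wobble each frame; a constant
        # number of draws per frame keeps the stream aligned across
        # scenes that differ only in who has died
        if t > 0 and jit > 0 and scene.n_live:
            fresh = draw_coeffs(rng_live, scene.n_live)
            live_part = is_alive[: scene.n_live]
            coeffs[: scene.n_live][live_part] = fresh[live_part]

        cum_drift = np.asarray(scene.drift) * t
        canvas = np.zeros((h, w), dtype=np.float32)
        for b in range(n_blasts):
            _render_blast(
                canvas,
                pos[b, 0] + cum_drift[0],
                pos[b, 1] + cum_drift[1],
                scene.cell_radius,
                coeffs[b],
                scene.cell_brightness,
                scene.ring_depth,
                scene.ring_width,
            )
        for s in range(scene.n_stroma):
            _render_stroma(
                canvas,
                stroma_pos[s, 0] + cum_drift[0],
                stroma_pos[s, 1] + cum_drift[1],
                scene.stroma_size / 2.0,
                scene.stroma_size / 5.0,
                stroma_angle[s],
                scene.stroma_brightness,
            )
        frame = illum * (scene.background + canvas)
        frame += rng_noise.normal(0.0, scene.noise_sigma, size=(h, w)).astype(np.float32)
        frames[t] = np.clip(frame, 0.0, None)
        tracks[t, :n_blasts] = pos
        tracks[t, n_blasts:] = stroma_pos

    cell_area = math.pi * scene.cell_radius ** 2
    gt = GroundTruth(
        cell_type=np.array(["blast"] * n_blasts + ["stroma"] * scene.n_stroma),
        death_time_h=np.concatenate([death_h, np.full(scene.n_stroma, np.inf)]),
        tracks=tracks,
        alive=alive,
        true_live_count=alive.sum(axis=1),
        true_live_area_px=alive.sum(axis=1) * cell_area,
        displacement_events=events,
    )
    stack = FrameStack(
        frames=frames,
        timestamps_min=np.arange(scene.n_frames) * scene.frame_interval_min,
    )
    return stack, gt


def acquisition_for_scene(scene: SceneConfig) -> AcquisitionConfig:
    """Acquisition settings matching a simulated scene's schedule."""
    return AcquisitionConfig(
        frame_interval_min=scene.frame_interval_min,
        total_duration_h=(scene.n_frames * scene.frame_interval_min) / 60.0,
        frame_height=scene.height,
        frame_width=scene.width,
    )


def analysis_for_scene(scene: SceneConfig, **overrides):
    """Analysis settings scaled to a simulated scene's cell size.

    The background radius is set to three cell radii (comfortably above
    one cell diameter, as the background operator requires); everything
    else keeps library defaults unless overridden.
    """
    from .plate_model import AnalysisConfig

    kwargs = dict(
        background_radius_px=int(round(3 * scene.cell_radius)),
        cell_radius_px=scene.cell_radius,
    )
    kwargs.update(overrides)
    return AnalysisConfig(**kwargs)


def _well_seed(master_seed: int, well: WellSpec) -> int:
    return (master_seed * 1_000 + well.row * 24 + well.col) % (2 ** 31 - 1)


def simulate_plate(
    layout: PlateLayout,
    scene: SceneConfig | None = None,
    kill_models: dict[str, KillModel] | None = None,
    seed: int = 0,
) -> tuple[dict[str, FrameStack], dict[str, GroundTruth]]:
    """Simulate every non-empty well of a plate layout.

    Vehicle-control wells receive no kill model; treatment and
    positive-control wells take the per-drug kill parameters from
    ``kill_models`` evaluated at the well's concentration.  Each well
    draws from a sub-seed derived from the master seed and the well
    address, so the plate is reproducible well-by-well.
    """
    scene = scene or SceneConfig()
    kill_models = kill_models or {}
    stacks: dict[str, FrameStack] = {}
    truths: dict[str, GroundTruth] = {}
    for well in layout:
        if well.role is WellRole.empty:
            continue
        well_scene = replace(scene, seed=_well_seed(seed, well))
        kill = None
        if well.role in (WellRole.treatment, WellRole.positive_control) and well.drug_id:
            base = kill_models.get(well.drug_id)
            if base is not None:
                kill = replace(base, concentration_nM=float(well.concentration_nM))
        stack, gt = simulate_well(well_scene, kill)
        stack.well = well
        stacks[well.address] = stack
        truths[well.address] = gt
    return stacks, truths
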