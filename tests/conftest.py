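"""Shared fixtures: memoized simulated wells and pipeline runs.

Simulating and analyzing a well is the expensive step, and several
tests interrogate the same scenes; results are memoized per scene
configuration for the session.
"""

from __future__ import annotations

import numpy as np
import pytest

from elda.motion_viability import viability_trace
from elda.registration import RegisteredStack, register_stack
from elda.synth_timelapse import (
    SceneConfig,
    acquisition_for_scene,
    analysis_for_scene,
    simulate_well,
)

_AREA_CACHE: dict = {}


def scene_area_trace(scene: SceneConfig, register: bool = True) -> np.ndarray:
    """Raw live-pixel-area trace of a simulated scene, memoized."""
    key = (scene, register)
    if key not in _AREA_CACHE:
        stack, _ = simulate_well(scene)
        ana = analysis_for_scene(scene)
        acq = acquisition_for_scene(scene)
        if register:
            registered = register_stack(stack, ana)
        else:
            registered = RegisteredStack(
                frames=stack.frames,
                timestamps_min=stack.timestamps_min,
                shifts=np.zeros((stack.n_frames, 2)),
            )
        trace, _ = viability_trace(registered, acq, ana)
        _AREA_CACHE[key] = trace.raw_area
    return _AREA_CACHE[key]


@pytest.fixture(scope="session")
def area_trace():
    return scene_area_trace


@pytest.fixture(scope="session")
def live100_area():
    """Area trace of the reference all-live scene (100 cells, no stroma)."""
    return scene_area_trace(SceneConfig(n_live=100, n_stroma=0, seed=1))


@pytest.fixture(scope="session")
def mixed_5050_area():
    """Area trace of the half-live/half-dead scene at equal cell size."""
    return scene_area_trace(SceneConfig(n_live=50, n_dead=50, n_stroma=0, seed=1))


@pytest.fixture(scope="session")
def static_area():
    """Area trace of the all-dead (fully static) scene."""
    return scene_area_trace(SceneConfig(n_live=0, n_dead=100, n_stroma=0, seed=2))
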