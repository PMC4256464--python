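from __future__ import annotations

import numpy as np
import pytest

from goldstereo.scene import LabellingModel, SceneParams, make_scene, simulate_study


@pytest.fixture(scope="session")
def default_scene():
    return make_scene(SceneParams(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study: 2 experiments x 3 micrographs/condition."""
    annotations, truth = simulate_study(
        SceneParams(),
        LabellingModel(),
        n_experiments=2,
        micrographs_per_condition=3,
        seed=101,
    )
    return annotations, truth


def random_polylines(rng: np.random.Generator, n_segments: int, extent: float = 4000.0):
    """A random open polyline with the requested number of segments."""
    start = rng.uniform(0.0, extent, size=2)
    steps = rng.uniform(-extent / 8, extent / 8, size=(n_segments, 2))
    return np.vstack([start, start + np.cumsum(steps, axis=0)])
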