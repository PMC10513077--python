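"""Shared fixtures: synthetic scene sets and trained segmentation models."""

import numpy as np
import pytest

from podometry.segmentation import TrainConfig, train
from podometry.synthetic import SceneParams, generate_glomerulus_scene


@pytest.fixture(scope="session")
def scene_bench():
    """The 20-scene benchmark set used for training-quality checks."""
    return [generate_glomerulus_scene(SceneParams(seed=100 + i))
            for i in range(20)]


@pytest.fixture(scope="session")
def bench_models(scene_bench):
    """Tuft and nuclei networks trained on the benchmark scene set."""
    cfg = TrainConfig(epochs=3, seed=0)
    return {task: train(scene_bench, task, cfg) for task in ("tuft", "nuclei")}


@pytest.fixture()
def tiny_scene():
    return generate_glomerulus_scene(SceneParams(
        frame_size_px=(160, 160), n_glomeruli=1, tuft_radius_um=(5.0, 7.0),
        nuclei_per_glomerulus=(3, 5), nucleus_radius_um=(1.5, 2.0), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
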