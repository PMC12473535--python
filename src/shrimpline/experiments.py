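"""Scaled-down reference experiments reproducible on one CPU.

The full-scale study behind this package trains on thousands of annotated
bodies at 848x480.  These helpers define the package's own desk-scale
analogue: single-body 96x96 scenes (body length drawn so the body fits the
crop, same default calibration, curvature and width as the full-size
generator), a 20-scene training set, and a 100-body measurement benchmark
comparing the learned route against the classical baselines.  Problem
sizes are deliberately small so the whole study runs in minutes.
"""

from __future__ import annotations

import numpy as np

from .evaluation import MetricsReport, heldout_f1, run_pipeline
from .model import CenterlineNet, ModelConfig, TrainConfig, make_training_set, train
from .skeleton import Calibration
from .synthetic import DEFAULT_MM_PER_PX, Scene, SceneConfig, generate_scene

#: Training schedule for the desk-scale model: 30 epochs, the study's
#: initial learning rate (0.02, momentum SGD), multi-step decay scaled to
#: the shorter run.
SMALL_TRAIN = dict(epochs=30, lr=0.02, lr_milestones=(18, 26))


def crop_scene_config(seed: int, size: int = 96) -> SceneConfig:
    """Single-instance scene that fits a ``size`` x ``size`` crop.

    Body length is drawn from 30-46 mm (57-87 px at the default
    calibration) so a curved body fits the crop with margin; width and
    curvature match the full-size generator defaults.
    """
    return SceneConfig(
        image_height=size,
        image_width=size,
        n_instances=1,
        body_length_range_mm=(30.0, 46.0),
        seed=seed,
    )


def make_crop_scenes(n: int, seed0: int, size: int = 96) -> list[Scene]:
    return [generate_scene(crop_scene_config(seed0 + i, size)) for i in range(n)]


def train_reference_model(
    seed: int = 0,
    n_train: int = 20,
    model_cfg: ModelConfig = ModelConfig(),
) -> tuple[CenterlineNet, list[float], list[Scene]]:
    """Train the reference model on ``n_train`` crop scenes.

    Returns (net, per-epoch loss history, training scenes).  Scene seeds
    are offset from ``seed`` so training data and weights both derive from
    the single given seed.
    """
    scenes = make_crop_scenes(n_train, seed0=seed * 10_000 + 100)
    samples = make_training_set(scenes)
    cfg = TrainConfig(seed=seed, **SMALL_TRAIN)
    net, history = train(samples, model_cfg, cfg)
    return net, history, scenes


def heldout_scenes(seed: int = 0, n: int = 8) -> list[Scene]:
    """Held-out crop scenes disjoint from the training seeds."""
    return make_crop_scenes(n, seed0=seed * 10_000 + 90_000)


def benchmark_scenes(seed: int = 0, n_scenes: int = 9) -> list[Scene]:
    """The measurement benchmark: full-size default scenes (>= 100 bodies).

    Uses the generator's default study conditions (848x480, 12 curved
    bodies of 40-110 mm per scene); only the seed varies.
    """
    return [
        generate_scene(SceneConfig(seed=seed * 10_000 + 50_000 + i))
        for i in range(n_scenes)
    ]


def run_benchmark(
    net: CenterlineNet,
    seed: int = 0,
    n_scenes: int = 9,
    methods: tuple[str, ...] = ("learned", "morph", "pcfm", "vdbm"),
) -> MetricsReport:
    """Measure the benchmark bodies by every method on ground-truth masks."""
    scenes = benchmark_scenes(seed, n_scenes)
    cal = Calibration(mm_per_px=DEFAULT_MM_PER_PX)
    return run_pipeline(scenes, net, cal, list(methods), use_truth_masks=True)


def reference_f1(net: CenterlineNet, seed: int = 0) -> float:
    """Held-out pixel F1 of a trained reference model at threshold 0.5."""
    return heldout_f1(net, heldout_scenes(seed))
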