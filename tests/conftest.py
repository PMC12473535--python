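import numpy as np
import pytest

import shrimpline as sl
from shrimpline import experiments


@pytest.fixture(scope="session")
def reference_model():
    """The desk-scale reference model, trained once per session (seed 0).

    Returns (net, loss_history): 20 single-body 96x96 scenes, 30 epochs.
    Shared by the learning-signal, benchmark and recovery tests.
    """
    net, history, _ = experiments.train_reference_model(seed=0)
    return net, history


@pytest.fixture(scope="session")
def crop_scenes():
    """A dozen single-body 96x96 scenes with ground truth."""
    return experiments.make_crop_scenes(12, seed0=777_000)


@pytest.fixture()
def straight_capsule():
    """A straight horizontal body (tapered ends) in a 60x160 frame."""
    spine = np.stack([np.full(200, 30.0), np.linspace(20.0, 140.0, 200)], axis=1)
    return sl.build_instance(spine, r_max=5.0, shape=(60, 160), mm_per_px=1.0)


@pytest.fixture()
def true_capsule():
    """A constant-radius capsule (rectangle + half-disk caps), radius 5.

    Its medial axis has the closed form: the spine shortened by one cap
    radius at each end.
    """
    from shrimpline.synthetic import InstanceTruth, polyline_length, rasterize_swept_body

    spine = np.stack([np.full(200, 30.0), np.linspace(20.0, 140.0, 200)], axis=1)
    mask = rasterize_swept_body(spine, np.full(200, 5.0), (60, 160))
    lpx = polyline_length(spine)
    return InstanceTruth(
        mask=mask, centerline_polyline=spine, true_length_px=lpx, true_length_mm=lpx
    )


@pytest.fixture()
def s_shaped_body():
    """An S-shaped body whose centerline is not a function of x."""
    t = np.linspace(0.0, 1.0, 400)
    spine = np.stack(
        [60.0 + 45.0 * np.sin(4.0 * np.pi * t), 30.0 + 90.0 * t], axis=1
    )
    return sl.build_instance(spine, r_max=6.0, shape=(120, 150), mm_per_px=1.0)
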