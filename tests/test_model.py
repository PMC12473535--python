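import math

import numpy as np
import pytest

import shrimpline as sl
from shrimpline.model import (
    CenterlineNet,
    ModelConfig,
    TrainConfig,
    concat_input,
    dice_bce_grad,
    dice_bce_loss,
    fuse_inputs,
    make_target,
    train,
)


def manual_dice_bce(pred, target, beta, eps):
    """Direct term-by-term evaluation of the composite loss formula."""
    pred = [float(v) for row in pred for v in row]
    target = [float(v) for row in target for v in row]
    inter = sum(t * p for t, p in zip(target, pred))
    dice = 1.0 - (2.0 * inter + eps) / (sum(target) + sum(pred) + eps)
    n = len(pred)
    bce = -sum(
        t * math.log(p + eps) + (1 - t) * math.log(1 - p + eps)
        for t, p in zip(target, pred)
    ) / n
    return dice + beta * bce


class TestFusion:
    def test_identity_kernel_returns_rgb(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (5, 7, 3))
        mask = (rng.uniform(size=(5, 7)) > 0.5).astype(np.uint8)
        w = np.hstack([np.eye(3), np.zeros((3, 1))])
        out = fuse_inputs(img, mask, w, np.zeros(3))
        assert np.allclose(out, img)

    def test_zero_mask_ignores_mask_column(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (4, 4, 3))
        mask = np.zeros((4, 4), dtype=np.uint8)
        w1 = rng.normal(size=(3, 4))
        w2 = w1.copy()
        w2[:, 3] = rng.normal(size=3)  # change only the mask column
        b = rng.normal(size=3)
        assert np.allclose(
            fuse_inputs(img, mask, w1, b), fuse_inputs(img, mask, w2, b)
        )

    def test_two_by_two_matches_hand_computation(self):
        img = np.array(
            [[[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]],
             [[0.7, 0.8, 0.9], [0.0, 0.5, 1.0]]]
        )
        mask = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        w = np.array(
            [[0.5, 0.0, 0.0, 1.0],
             [0.0, 0.5, 0.0, -1.0],
             [0.0, 0.0, 0.5, 0.0]]
        )
        b = np.array([0.1, 0.0, -0.1])
        out = fuse_inputs(img, mask, w, b)
        for r in range(2):
            for c in range(2):
                vec = [img[r, c, 0], img[r, c, 1], img[r, c, 2], mask[r, c]]
                for k in range(3):
                    expect = b[k] + sum(w[k, j] * vec[j] for j in range(4))
                    assert out[r, c, k] == pytest.approx(expect, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="disagree"):
            fuse_inputs(
                np.zeros((4, 4, 3)), np.zeros((5, 4)), np.zeros((3, 4)), np.zeros(3)
            )


class TestLoss:
    def test_matches_hand_evaluation_on_small_grids(self):
        pred2 = [[0.9, 0.1], [0.2, 0.8]]
        target2 = [[1, 0], [0, 1]]
        assert dice_bce_loss(
            np.array(pred2), np.array(target2), 1.0, 1e-6
        ) == pytest.approx(manual_dice_bce(pred2, target2, 1.0, 1e-6), abs=1e-9)

        pred3 = [[0.05, 0.9, 0.5], [0.3, 0.99, 0.01], [0.6, 0.2, 0.75]]
        target3 = [[0, 1, 1], [0, 1, 0], [1, 0, 1]]
        for beta in (0.5, 1.0, 2.0):
            assert dice_bce_loss(
                np.array(pred3), np.array(target3), beta, 1e-6
            ) == pytest.approx(
                manual_dice_bce(pred3, target3, beta, 1e-6), abs=1e-9
            )

    def test_perfect_binary_prediction_is_near_zero(self):
        t = np.array([[1, 0, 1], [0, 1, 0]], dtype=float)
        assert dice_bce_loss(t, t, 1.0, 1e-6) < 1e-4

    def test_disjoint_prediction_dice_term_near_one(self):
        t = np.array([[1, 0], [0, 0]], dtype=float)
        p = 1.0 - t
        # beta=0 isolates the Dice term
        assert dice_bce_loss(p, t, 0.0, 1e-6) == pytest.approx(1.0, abs=1e-5)

    def test_beta_zero_reduces_to_dice_exactly(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, (6, 6))
        t = (rng.uniform(size=(6, 6)) > 0.5).astype(float)
        eps = 1e-6
        inter = np.sum(t * p)
        dice = 1.0 - (2 * inter + eps) / (t.sum() + p.sum() + eps)
        assert dice_bce_loss(p, t, 0.0, eps) == pytest.approx(dice, rel=1e-12)

    def test_nonnegative_and_permutation_invariant(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(0, 1, (5, 5))
            t = (rng.uniform(size=(5, 5)) > 0.7).astype(float)
            loss = dice_bce_loss(p, t)
            assert loss >= 0.0
            perm = rng.permutation(25)
            loss_p = dice_bce_loss(
                p.ravel()[perm].reshape(5, 5), t.ravel()[perm].reshape(5, 5)
            )
            assert loss == pytest.approx(loss_p, rel=1e-12)


class TestTarget:
    def test_single_point_dilates_to_3x3_block(self):
        t = make_target(np.array([[5.0, 5.0]]), (11, 11))
        assert t.sum() == 9
        assert t[4:7, 4:7].all()

    def test_horizontal_polyline_area(self):
        # 21 rasterized pixels dilated by a 3x3 element: 3 rows x 23 cols
        t = make_target(np.array([[10.0, 5.0], [10.0, 25.0]]), (21, 40))
        assert t.sum() == 3 * 23
        assert t[9:12, 4:27].all()

    def test_target_superset_of_rasterization(self):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.uniform(-2, 2, (15, 2)), axis=0) + 20
        t = make_target(pts, (48, 48))
        for r, c in np.round(pts).astype(int):
            assert t[r, c] == 1

    def test_empty_polyline_rejected(self):
        with pytest.raises(ValueError):
            make_target(np.empty((0, 2)), (10, 10))


class TestForward:
    CFG = ModelConfig(
        encoder_depth=2, base_channels=4, aspp_rates=(1, 2), decoder_channels=(8, 4)
    )

    def test_output_range_and_shape(self):
        net = CenterlineNet(self.CFG, seed=2)
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (20, 28, 3)).astype(np.uint8)
        mask = (rng.uniform(size=(20, 28)) > 0.5).astype(np.uint8)
        prob = net.forward(img, mask)
        assert prob.shape == (20, 28)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_padding_handles_non_divisible_sizes(self):
        net = CenterlineNet(self.CFG, seed=2)
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (13, 17, 3))
        mask = np.ones((13, 17), dtype=np.uint8)
        assert net.forward(img, mask).shape == (13, 17)

    def test_forward_is_deterministic(self):
        net = CenterlineNet(self.CFG, seed=7)
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (16, 16, 3))
        mask = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
        assert np.array_equal(net.forward(img, mask), net.forward(img, mask))

    def test_constant_input_gives_near_constant_output(self):
        net = CenterlineNet(self.CFG, seed=3)
        img = np.full((24, 24, 3), 0.5)
        mask = np.ones((24, 24), dtype=np.uint8)
        prob = net.forward(img, mask)
        # boundary padding breaks exact translation invariance; interior
        # response to a constant field stays nearly flat
        assert np.ptp(prob) < 0.2

    def test_gradients_match_finite_differences(self):
        net = CenterlineNet(self.CFG, seed=1)
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (12, 12, 3))
        mask = (rng.uniform(size=(12, 12)) > 0.5).astype(np.uint8)
        target = (rng.uniform(size=(12, 12)) > 0.8).astype(float)
        x4 = concat_input(img, mask)

        prob = net.forward_concat(x4)
        for p in net.params():
            p.grad[...] = 0.0
        net.backward_from_prob(dice_bce_grad(prob, target, 1.0, 1e-6))

        eps = 1e-6
        check = rng2 = np.random.default_rng(9)
        params = net.params()
        for pi in (0, 1, 4, len(params) - 1):
            flat = params[pi].value.reshape(-1)
            k = int(check.integers(flat.size))
            old = flat[k]
            flat[k] = old + eps
            lp = dice_bce_loss(net.forward_concat(x4), target, 1.0, 1e-6)
            flat[k] = old - eps
            lm = dice_bce_loss(net.forward_concat(x4), target, 1.0, 1e-6)
            flat[k] = old
            numeric = (lp - lm) / (2 * eps)
            analytic = params[pi].grad.reshape(-1)[k]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestTraining:
    def _tiny_dataset(self, n=4):
        scenes = [
            sl.generate_scene(
                sl.SceneConfig(
                    image_height=48,
                    image_width=48,
                    n_instances=1,
                    body_length_range_mm=(14.0, 20.0),
                    body_width_px_range=(5.0, 8.0),
                    seed=400 + i,
                )
            )
            for i in range(n)
        ]
        from shrimpline.model import make_training_set

        return make_training_set(scenes, crop_size=48)

    CFG = ModelConfig(
        encoder_depth=2, base_channels=4, aspp_rates=(1, 2), decoder_channels=(8, 4)
    )

    def test_same_seed_gives_identical_history(self):
        data = self._tiny_dataset()
        tc = TrainConfig(epochs=3, seed=5)
        _, h1 = train(data, self.CFG, tc)
        _, h2 = train(data, self.CFG, tc)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], self.CFG, TrainConfig(epochs=1))

    def test_predict_threshold_semantics(self):
        net = CenterlineNet(self.CFG, seed=0)
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (16, 16, 3))
        mask = np.ones((16, 16), dtype=np.uint8)
        prob = net.forward(img, mask)
        band = sl.predict_instance(img, mask, net, threshold=0.5)
        assert np.array_equal(band.astype(bool), prob >= 0.5)
        # a threshold above the map's maximum gives an empty band
        hi = min(float(prob.max()) + 0.01, 0.999)
        assert sl.predict_instance(img, mask, net, threshold=hi).sum() == 0

    def test_save_load_round_trip(self, tmp_path):
        net = CenterlineNet(self.CFG, seed=6)
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (16, 16, 3))
        mask = np.ones((16, 16), dtype=np.uint8)
        path = tmp_path / "m.npz"
        net.save(path)
        net2 = CenterlineNet.load(path)
        assert np.array_equal(net.forward(img, mask), net2.forward(img, mask))
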