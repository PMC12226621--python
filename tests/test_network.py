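"""Initialization network: layer backprop, composite loss, training, inference."""

import numpy as np
import pytest

from angioreg.geometry import CArmGeometry, Projection2D
from angioreg.network import (
    InitNetConfig,
    PoseRegressionCNN,
    composite_loss,
    predict_initial_pose,
    radiological_pose,
    train_init_network,
)
from angioreg.network.layers import Conv2d, Linear
from angioreg.network.training import geodesic_terms_gradient
from angioreg.phantom import OffsetSamplerParams, training_pairs
from angioreg.se3 import RigidTransform, compose, exp, identity


def numeric_grad(f, x, h=1e-6):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        x[idx] += h
        fp = f()
        x[idx] -= 2 * h
        fm = f()
        x[idx] += h
        g[idx] = (fp - fm) / (2 * h)
    return g


class TestLayers:
    @pytest.mark.parametrize("stride,padding,k", [(1, 1, 3), (2, 1, 3), (2, 0, 1)])
    def test_conv_backward_matches_numeric(self, stride, padding, k):
        rng = np.random.default_rng(0)
        conv = Conv2d(2, 3, kernel_size=k, stride=stride, padding=padding, rng=rng)
        x = rng.normal(size=(2, 2, 6, 6))
        w_out = rng.normal(size=conv.forward(x).shape)  # random loss weights

        def loss():
            return float((conv.forward(x) * w_out).sum())

        loss()
        dx = conv.backward(w_out)
        assert np.allclose(dx, numeric_grad(loss, x), atol=1e-6)
        assert np.allclose(conv.dW, numeric_grad(loss, conv.W), atol=1e-6)
        assert np.allclose(conv.db, numeric_grad(loss, conv.b), atol=1e-6)

    def test_linear_backward_matches_numeric(self):
        rng = np.random.default_rng(1)
        lin = Linear(5, 4, rng=rng)
        x = rng.normal(size=(3, 5))
        w_out = rng.normal(size=(3, 4))

        def loss():
            return float((lin.forward(x) * w_out).sum())

        loss()
        dx = lin.backward(w_out)
        assert np.allclose(dx, numeric_grad(loss, x), atol=1e-6)
        assert np.allclose(lin.dW, numeric_grad(loss, lin.W), atol=1e-6)

    def test_model_backward_matches_numeric_on_subset(self):
        """End-to-end check: gradient of a scalar head output w.r.t. a few
        randomly chosen parameters of every layer."""
        rng = np.random.default_rng(2)
        net = PoseRegressionCNN(widths=(4, 8), input_size=16, seed=0)
        x = rng.normal(size=(1, 2, 16, 16))
        w_out = rng.normal(size=(1, 6))

        def loss():
            return float((net.forward(x) * w_out).sum())

        loss()
        net.backward(w_out)
        for p, g in zip(net.params, net.grads):
            flat_idx = rng.integers(0, p.size, size=min(3, p.size))
            for fi in np.unique(flat_idx):
                idx = np.unravel_index(fi, p.shape)
                h = 1e-6
                p[idx] += h
                fp = loss()
                p[idx] -= 2 * h
                fm = loss()
                p[idx] += h
                assert g[idx] == pytest.approx((fp - fm) / (2 * h), rel=1e-4, abs=1e-7)


class TestCompositeLoss:
    def test_zero_at_perfect_match(self):
        img = Projection2D(values=np.eye(8))
        t = exp(np.array([0.1, 0, 0, 5, 0, 0]))
        assert composite_loss(t, t, img, img, f=1000, lambda_weight=0.5) == pytest.approx(0.0, abs=1e-6)

    def test_half_overlap_dice(self):
        """Equal-area masks with 50% intersection: 1 - 2*(A/2)/(2A) = 0.5."""
        a = Projection2D(values=np.array([[1.0, 1.0, 0.0, 0.0]]))
        b = Projection2D(values=np.array([[0.0, 1.0, 1.0, 0.0]]))
        t = identity()
        assert composite_loss(t, t, a, b, f=1000, lambda_weight=1.0) == pytest.approx(0.5, abs=1e-6)

    def test_both_images_empty_dice_term_vanishes(self):
        """Additive smoothing makes two empty projections a perfect match."""
        empty = Projection2D(values=np.zeros((4, 4)))
        t = identity()
        assert composite_loss(t, t, empty, empty, f=1000, lambda_weight=1.0) == pytest.approx(0.0, abs=1e-9)

    def test_lambda_zero_is_dice_only(self):
        a = Projection2D(values=np.array([[1.0, 0.0]]))
        b = Projection2D(values=np.array([[0.0, 1.0]]))
        pred, target = exp(np.array([0.2, 0, 0, 9, 0, 0])), identity()
        assert composite_loss(pred, target, a, b, f=1000, lambda_weight=0.0) == pytest.approx(
            1.0, abs=1e-5
        )

    def test_geodesic_gradient_matches_numeric(self):
        rng = np.random.default_rng(3)
        target = exp(np.concatenate([rng.normal(size=3) * 0.2, rng.normal(size=3) * 10]))
        v = np.concatenate([rng.normal(size=3) * 0.2, rng.normal(size=3) * 10])
        val, grad = geodesic_terms_gradient(v, target, f=900.0)
        for j in range(6):
            h = 1e-6
            vp, vm = v.copy(), v.copy()
            vp[j] += h
            vm[j] -= h
            fd = (geodesic_terms_gradient(vp, target, 900.0)[0] - geodesic_terms_gradient(vm, target, 900.0)[0]) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)


@pytest.fixture(scope="module")
def small_pairs(vein_volume, geom64):
    return list(training_pairs(vein_volume, RigidTransform(), geom64, 10, OffsetSamplerParams(seed=1)))


class TestTraining:
    def test_zero_epochs_returns_initial_weights(self, small_pairs, geom64, vein_volume):
        cfg = InitNetConfig(epochs=0, seed=4)
        net, history = train_init_network(small_pairs, cfg, geom64, vein_volume, RigidTransform())
        ref = PoseRegressionCNN(widths=(16, 32, 64), input_size=64, seed=4)
        assert history == []
        for p, q in zip(net.params, ref.params):
            assert np.array_equal(p, q)

    def test_smoke_training_reduces_loss(self, small_pairs, geom64, vein_volume):
        cfg = InitNetConfig(epochs=8, seed=0)
        net, history = train_init_network(small_pairs, cfg, geom64, vein_volume, RigidTransform())
        assert len(history) == 8
        assert history[-1] < history[0]

    def test_training_reproducible(self, small_pairs, geom64, vein_volume):
        cfg = InitNetConfig(epochs=2, seed=6)
        net1, h1 = train_init_network(small_pairs, cfg, geom64, vein_volume, RigidTransform())
        net2, h2 = train_init_network(small_pairs, cfg, geom64, vein_volume, RigidTransform())
        assert h1 == h2
        for p, q in zip(net1.params, net2.params):
            assert np.array_equal(p, q)

    def test_lambda_enters_only_through_loss(self, small_pairs, geom64, vein_volume):
        h_a = train_init_network(small_pairs, InitNetConfig(epochs=1, lambda_weight=0.0, seed=6), geom64, vein_volume, RigidTransform())[1]
        h_b = train_init_network(small_pairs, InitNetConfig(epochs=1, lambda_weight=0.1, seed=6), geom64, vein_volume, RigidTransform())[1]
        assert h_a[0] != h_b[0]

    def test_memorizes_single_pair(self, vein_volume, geom64, geom128):
        """Overfitting one pair must beat the uncorrected base pose."""
        from angioreg.evaluate import mpe

        pairs = list(training_pairs(vein_volume, RigidTransform(), geom64, 1, OffsetSamplerParams(seed=13)))
        fixed, moving, offset, target = pairs[0]
        cfg = InitNetConfig(epochs=150, batch_size=1, seed=0)
        net, history = train_init_network(pairs, cfg, geom64, vein_volume, RigidTransform())
        base = compose(RigidTransform(), offset)
        pred = predict_initial_pose(net, vein_volume, fixed, base, geom64)
        assert mpe(RigidTransform(), pred, vein_volume, geom128) < mpe(RigidTransform(), base, vein_volume, geom128)

    def test_weight_persistence_round_trip(self, tmp_path):
        net = PoseRegressionCNN(widths=(4, 8), input_size=32, seed=3)
        net.save(tmp_path / "w.npz")
        back = PoseRegressionCNN.load(tmp_path / "w.npz")
        assert back.input_size == 32
        for p, q in zip(net.params, back.params):
            assert np.array_equal(p, q)


class TestInference:
    def test_zero_output_returns_base_pose(self, vein_volume, geom64, dsa_segmentation):
        net = PoseRegressionCNN(widths=(4, 8), input_size=64, seed=0)
        for layer in (net.head_rot, net.head_trans):
            layer.W[...] = 0.0
            layer.b[...] = 0.0
        base = exp(np.array([0.05, 0, 0, 3, 0, 0]))
        from skimage.transform import resize

        fixed = Projection2D(
            values=(resize(dsa_segmentation.values, (64, 64), order=1) > 0.5).astype(float),
            kind="dsa_segmentation",
        )
        pred = predict_initial_pose(net, vein_volume, fixed, base, geom64)
        assert np.allclose(pred.matrix(), base.matrix(), atol=1e-12)

    def test_untrained_network_returns_valid_pose(self, vein_volume, geom64, dsa_segmentation):
        net = PoseRegressionCNN(seed=1)
        from skimage.transform import resize

        fixed = Projection2D(
            values=(resize(dsa_segmentation.values, (64, 64), order=1) > 0.5).astype(float),
            kind="dsa_segmentation",
        )
        pred = predict_initial_pose(net, vein_volume, fixed, RigidTransform(), geom64)
        assert np.all(np.isfinite(pred.matrix()))
        assert np.allclose(pred.rotation.T @ pred.rotation, np.eye(3), atol=1e-9)


class TestRadiologicalPose:
    def test_zero_angles_identity(self):
        geom = CArmGeometry(1000, 64, 64, 4.0)
        assert np.allclose(radiological_pose(geom).matrix(), np.eye(4), atol=1e-15)

    def test_primary_rotation_matrix(self):
        geom = CArmGeometry(1000, 64, 64, 4.0, primary_angle=90.0)
        t = radiological_pose(geom)
        expected = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        assert np.allclose(t.rotation, expected, atol=1e-12)
        assert np.allclose(t.translation, 0.0)

    def test_extrinsic_composition_order(self):
        """primary about z first, then secondary about the fixed x axis."""
        geom = CArmGeometry(1000, 64, 64, 4.0, primary_angle=30.0, secondary_angle=20.0)
        t = radiological_pose(geom)
        pa, sa = np.deg2rad(30), np.deg2rad(20)
        rz = np.array([[np.cos(pa), -np.sin(pa), 0], [np.sin(pa), np.cos(pa), 0], [0, 0, 1]])
        rx = np.array([[1, 0, 0], [0, np.cos(sa), -np.sin(sa)], [0, np.sin(sa), np.cos(sa)]])
        assert np.allclose(t.rotation, rx @ rz, atol=1e-12)
        assert not np.allclose(t.rotation, rz @ rx, atol=1e-6)
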