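"""Network construction, loss functions, training mechanics, inference."""

import numpy as np
import pytest

from kneeforge._autodiff import Adam, Tensor, no_grad, softmax_lastdim
from kneeforge.cel_unet import (
    LossConfig,
    NetworkConfig,
    build_cel_unet,
    build_unet,
    boundary_distance_map,
    combined_edge_loss,
    compute_loss,
    distance_cross_entropy_loss,
    focal_loss,
    load_checkpoint,
    predict_volume,
    save_checkpoint,
    soft_dice_loss,
    train,
)
from kneeforge.core import CTVolume, ConfigurationError, DataQualityError

TINY = dict(input_patch=8, depth=2, base_channels=2, classes=3)


def random_probs(rng, shape, classes=3):
    return rng.dirichlet(np.ones(classes), size=shape)


class TestArchitecture:
    def test_output_shapes(self):
        m = build_cel_unet(NetworkConfig(input_patch=16, depth=3, base_channels=4, seed=0))
        x = Tensor(np.zeros((1, 16, 16, 16, 1), dtype=np.float32))
        seg, edge = m.forward(x)
        assert seg.shape == (1, 16, 16, 16, 3)
        assert edge.shape == (1, 16, 16, 16, 3)

    def test_baseline_has_single_head(self):
        m = build_unet(NetworkConfig(input_patch=16, depth=3, base_channels=4, seed=0))
        seg, edge = m.forward(Tensor(np.zeros((1, 16, 16, 16, 1), dtype=np.float32)))
        assert seg.shape == (1, 16, 16, 16, 3)
        assert edge is None

    def test_edge_branch_off_equals_baseline_bitwise(self):
        cfg = NetworkConfig(input_patch=16, depth=3, base_channels=4, seed=9,
                            edge_branch=False)
        a = build_cel_unet(cfg)
        b = build_unet(NetworkConfig(input_patch=16, depth=3, base_channels=4, seed=9))
        x = np.random.default_rng(0).random((1, 16, 16, 16, 1)).astype(np.float32)
        with no_grad():
            sa, _ = a.forward(Tensor(x))
            sb, _ = b.forward(Tensor(x))
        assert np.array_equal(sa.data, sb.data)

    def test_equal_seed_equal_init(self):
        cfg = NetworkConfig(**TINY, seed=3)
        p1 = build_cel_unet(cfg).parameters()
        p2 = build_cel_unet(cfg).parameters()
        assert all(np.array_equal(p1[k].data, p2[k].data) for k in p1)

    def test_encoder_shared_between_variants(self):
        cfg = NetworkConfig(**TINY, seed=4)
        cel = build_cel_unet(cfg).parameters()
        base = build_unet(cfg).parameters()
        enc_keys = [k for k in cel if k.startswith("enc")]
        assert enc_keys
        assert all(np.array_equal(cel[k].data, base[k].data) for k in enc_keys)

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            NetworkConfig(input_patch=20, depth=4)


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy(self, rng):
        p = random_probs(rng, (4, 4, 4))
        oh = np.eye(3)[rng.integers(0, 3, (4, 4, 4))]
        ce = -np.mean(np.log((p * oh).sum(-1) + 1e-12))
        assert abs(focal_loss(p, oh, gamma=0.0).item() - ce) < 1e-12

    def test_perfect_prediction_is_zero(self):
        oh = np.eye(3)[np.ones((3, 3, 3), dtype=int)]
        assert focal_loss(oh.astype(float), oh, gamma=2.0).item() == pytest.approx(0.0, abs=1e-9)

    def test_single_voxel_hand_value(self):
        p = np.array([[[[0.5, 0.5, 0.0]]]])
        oh = np.array([[[[1.0, 0.0, 0.0]]]])
        expect = 0.25 * np.log(2.0)
        assert abs(focal_loss(p, oh, gamma=2.0).item() - expect) < 1e-9

    def test_unnormalized_rejected(self):
        bad = np.full((2, 2, 2, 3), 0.9)
        with pytest.raises(DataQualityError, match="normalized"):
            focal_loss(bad, bad)


class TestDistanceCrossEntropy:
    def test_beta_zero_is_cross_entropy(self, rng):
        p = random_probs(rng, (4, 4, 4))
        lab = rng.integers(0, 3, (4, 4, 4))
        oh = np.eye(3)[lab]
        ce = -np.mean(np.log((p * oh).sum(-1) + 1e-12))
        assert abs(distance_cross_entropy_loss(p, oh, lab, dce_beta=0.0).item() - ce) < 1e-12

    def test_uniform_target_equals_cross_entropy(self, rng):
        p = random_probs(rng, (4, 4, 4))
        lab = np.ones((4, 4, 4), dtype=int)
        oh = np.eye(3)[lab]
        ce = -np.mean(np.log((p * oh).sum(-1) + 1e-12))
        assert abs(distance_cross_entropy_loss(p, oh, lab, dce_beta=5.0).item() - ce) < 1e-12

    def test_boundary_voxel_weight(self):
        lab = np.zeros((1, 1, 4), dtype=int)
        lab[0, 0, 2:] = 1
        d = boundary_distance_map(lab)
        assert d[0, 0, 1] == 0.0 and d[0, 0, 2] == 0.0  # both sides of the interface
        assert d[0, 0, 0] == 1.0

    def test_weights_match_brute_force_distance_oracle(self, rng):
        lab = (rng.random((10, 10, 10)) > 0.7).astype(int)
        d = boundary_distance_map(lab)
        # brute force: boundary voxel set, then exhaustive min distance
        boundary = np.zeros_like(lab, dtype=bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            sl2 = [slice(None)] * 3
            sl[ax] = slice(None, -1)
            sl2[ax] = slice(1, None)
            diff = lab[tuple(sl)] != lab[tuple(sl2)]
            boundary[tuple(sl)] |= diff
            boundary[tuple(sl2)] |= diff
        bpts = np.argwhere(boundary)
        all_pts = np.argwhere(np.ones_like(lab, dtype=bool))
        brute = np.sqrt(((all_pts[:, None, :] - bpts[None]) ** 2).sum(-1)).min(1)
        assert np.allclose(d.ravel(), brute, atol=1e-9)


class TestCombinedEdgeLoss:
    def test_lambda_zero_equals_region(self, rng):
        p = random_probs(rng, (1, 4, 4, 4))
        oh = np.eye(3)[rng.integers(0, 3, (1, 4, 4, 4))]
        total, terms = combined_edge_loss(p, None, oh, None, LossConfig(lambda_edge=0.0))
        region = 0.5 * (soft_dice_loss(p, oh).item()
                        - np.mean(np.log((p * oh).sum(-1) + 1e-12)))
        assert abs(total.item() - region) < 1e-12

    def test_perfect_predictions_near_zero(self):
        oh = np.eye(3)[np.ones((1, 4, 4, 4), dtype=int)].astype(float)
        edge = np.zeros((1, 4, 4, 4, 3))
        edge[..., 1] = 1.0
        total, _ = combined_edge_loss(oh, edge, oh, edge, LossConfig())
        assert total.item() == pytest.approx(0.0, abs=1e-4)  # soft-Dice epsilon

    def test_uniform_half_edge_prediction_hand_formula(self):
        """pred_edge = 0.5 everywhere on a 50% edge map: the per-class soft
        Dice is (2*0.5*E + eps)/(0.5*N + E + eps) with E = N/2."""
        n = 4**3
        oh = np.eye(3)[np.zeros((1, 4, 4, 4), dtype=int)].astype(float)
        gt_edge = np.zeros((1, 4, 4, 4, 3))
        gt_edge[0, :2, :, :, :] = 1.0  # half the voxels are edge, per class
        pred_edge = np.full((1, 4, 4, 4, 3), 0.5)
        total, terms = combined_edge_loss(oh, pred_edge, oh, gt_edge, LossConfig())
        E = n / 2
        expect_edge = 1.0 - (2 * 0.5 * E) / (0.5 * n + E)
        assert terms["edge"] == pytest.approx(expect_edge, abs=1e-5)

    def test_missing_edge_ground_truth_rejected(self, rng):
        p = random_probs(rng, (1, 4, 4, 4))
        oh = np.eye(3)[rng.integers(0, 3, (1, 4, 4, 4))]
        with pytest.raises(DataQualityError, match="edge"):
            combined_edge_loss(p, None, oh, None, LossConfig(lambda_edge=1.0))

    def test_monotone_in_lambda_edge(self, rng):
        p = random_probs(rng, (1, 4, 4, 4))
        oh = np.eye(3)[rng.integers(0, 3, (1, 4, 4, 4))]
        pe = rng.random((1, 4, 4, 4, 3))
        ge = (rng.random((1, 4, 4, 4, 3)) > 0.8).astype(float)
        totals = [combined_edge_loss(p, pe, oh, ge, LossConfig(lambda_edge=l))[0].item()
                  for l in (0.0, 0.5, 1.0, 2.0)]
        assert all(a <= b + 1e-12 for a, b in zip(totals, totals[1:]))

    def test_non_negative(self, rng):
        for _ in range(5):
            p = random_probs(rng, (1, 4, 4, 4))
            oh = np.eye(3)[rng.integers(0, 3, (1, 4, 4, 4))]
            pe = rng.random((1, 4, 4, 4, 3))
            ge = (rng.random((1, 4, 4, 4, 3)) > 0.8).astype(float)
            assert combined_edge_loss(p, pe, oh, ge, LossConfig())[0].item() >= 0.0


class TestTraining:
    def _tiny_dataset(self, rng, n=3, p=8):
        ds = []
        for _ in range(n):
            x = rng.random((p, p, p)).astype(np.float32)
            y = np.zeros((p, p, p), dtype=np.int64)
            y[2:6, 2:6, 2:6] = 1
            e = np.zeros((3, p, p, p), dtype=bool)
            e[1, 2, 2:6, 2:6] = True
            ds.append((x, y, e))
        return ds

    def test_one_step_decreases_loss_at_three_seeds(self, rng):
        for seed in (0, 1, 2):
            cfg = NetworkConfig(**TINY, seed=seed)
            m = build_cel_unet(cfg)
            ds = self._tiny_dataset(np.random.default_rng(seed))
            x = ds[0][0][None, ..., None]
            y = ds[0][1][None]
            e = np.moveaxis(ds[0][2][None], 1, -1).astype(np.float32)
            opt = Adam(m.parameters().values(), lr=1e-4)
            L0, _ = compute_loss(m.forward(Tensor(x)), y, e, LossConfig(), 3)
            opt.zero_grad()
            L0.backward()
            opt.step()
            L1, _ = compute_loss(m.forward(Tensor(x)), y, e, LossConfig(), 3)
            assert L1.item() < L0.item()

    def test_zero_steps_leaves_weights_unchanged(self, rng):
        m = build_cel_unet(NetworkConfig(**TINY, seed=0))
        before = {k: p.data.copy() for k, p in m.parameters().items()}
        train(m, self._tiny_dataset(rng), steps=0, seed=0, log_every=0)
        assert all(np.array_equal(before[k], p.data) for k, p in m.parameters().items())

    def test_same_seed_identical_loss_curves(self, rng):
        ds = self._tiny_dataset(np.random.default_rng(5))
        curves = []
        for _ in range(2):
            m = build_cel_unet(NetworkConfig(**TINY, seed=7))
            st = train(m, ds, steps=5, batch_size=1, seed=11, log_every=0)
            curves.append([h["total"] for h in st.loss_history])
        assert curves[0] == curves[1]

    def test_empty_dataset_rejected(self):
        m = build_cel_unet(NetworkConfig(**TINY, seed=0))
        with pytest.raises(DataQualityError, match="empty"):
            train(m, [], steps=1)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        m = build_cel_unet(NetworkConfig(**TINY, seed=2))
        save_checkpoint(m, tmp_path / "w.npz", loss_cfg=LossConfig())
        m2 = load_checkpoint(tmp_path / "w.npz")
        assert m2.cfg == m.cfg
        assert all(np.array_equal(a.data, b.data) for a, b in
                   zip(m.parameters().values(), m2.parameters().values()))


class TestPredictVolume:
    def test_constant_background_model_gives_empty_labels(self):
        m = build_cel_unet(NetworkConfig(**TINY, seed=0))
        # force the segmentation head to emit class 0 everywhere
        m.seg_head.w.data[:] = 0.0
        m.seg_head.b.data[:] = np.array([10.0, 0.0, 0.0], dtype=np.float32)
        ct = CTVolume(np.random.default_rng(0).random((12, 12, 12)))
        labels, scores = predict_volume(m, ct, patch_size=8)
        assert not labels.voxels.any()
        assert scores.shape == (3, 12, 12, 12)

    def test_single_patch_volume_matches_direct_forward(self):
        m = build_cel_unet(NetworkConfig(**TINY, seed=1))
        v = np.random.default_rng(1).random((8, 8, 8))
        labels, scores = predict_volume(m, CTVolume(v), patch_size=8)
        with no_grad():
            seg, _ = m.forward(Tensor(v.astype(np.float32)[None, ..., None]))
            direct = np.moveaxis(softmax_lastdim(seg).data[0], -1, 0)
        assert np.allclose(scores, direct, atol=1e-6)
        assert np.array_equal(labels.voxels, np.argmax(direct, axis=0))

    def test_unnormalized_volume_rejected(self):
        m = build_cel_unet(NetworkConfig(**TINY, seed=0))
        with pytest.raises(DataQualityError, match="normalized"):
            predict_volume(m, CTVolume(np.full((8, 8, 8), 500.0)), patch_size=8)
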