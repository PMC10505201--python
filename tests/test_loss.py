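import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import confdepth as cd
from confdepth.errors import DimensionError, DomainError, EmptyBatchError, EmptyImageError
from confdepth.loss import ScalePyramid

from conftest import make_instance


def uniform_cfg(**kw):
    return cd.WeightConfig(mask_kind="uniform", **kw)


class TestWeightOf:
    def test_hard_mask_boundary(self):
        cfg = cd.WeightConfig("hard", threshold=0.5)
        assert cd.weight_of(0.5, cfg) == 1.0  # threshold included
        assert cd.weight_of(0.499, cfg) == 0.0
        assert cd.weight_of(1.0, cfg) == 1.0

    def test_soft_mask_values(self):
        cfg = cd.WeightConfig("soft", threshold=0.5, sharpness=10.0)
        assert cd.weight_of(1.0, cfg) == 1.0
        assert cd.weight_of(0.5, cfg) == pytest.approx(np.exp(-5.0))
        assert cd.weight_of(0.49, cfg) == 0.0

    def test_uniform_ignores_confidence(self):
        cfg = uniform_cfg(threshold=0.9, sharpness=50.0)
        assert cd.weight_of(0.0, cfg) == 1.0
        assert cd.weight_of(1.0, cfg) == 1.0

    def test_domain_error(self):
        with pytest.raises(DomainError):
            cd.weight_of(1.2, cd.WeightConfig("hard"))
        with pytest.raises(DomainError):
            cd.weight_of(-0.1, cd.WeightConfig("soft"))

    @given(
        q1=st.floats(0, 1),
        q2=st.floats(0, 1),
        kind=st.sampled_from(["hard", "soft", "uniform"]),
        theta=st.floats(0, 1),
        lam=st.floats(0, 50),
    )
    def test_monotone_in_confidence(self, q1, q2, kind, theta, lam):
        cfg = cd.WeightConfig(kind, threshold=theta, sharpness=lam)
        lo, hi = min(q1, q2), max(q1, q2)
        assert cd.weight_of(lo, cfg) <= cd.weight_of(hi, cfg)

    def test_vectorized(self):
        cfg = cd.WeightConfig("soft", threshold=0.5, sharpness=10.0)
        q = np.array([[0.0, 0.5], [0.75, 1.0]])
        w = cd.weight_of(q, cfg)
        np.testing.assert_allclose(
            w, [[0.0, np.exp(-5.0)], [np.exp(-2.5), 1.0]]
        )


class TestDataTerm:
    def test_zero_residual(self, rng):
        gt = cd.InverseDepthMap(rng.uniform(0, 1, (4, 4)))
        conf = cd.ConfidenceMap(rng.uniform(0, 1, (4, 4)))
        mask = cd.ValidityMask(np.ones((4, 4), bool))
        assert cd.cw_ssi_mse(gt, gt, conf, mask, cd.WeightConfig("soft")) == 0.0

    def test_hand_example_uniform(self):
        gt = cd.InverseDepthMap(np.zeros((2, 2)))
        pred = cd.InverseDepthMap(np.array([[1.0, -1.0], [2.0, 0.0]]))
        conf = cd.ConfidenceMap(np.ones((2, 2)))
        mask = cd.ValidityMask(np.ones((2, 2), bool))
        # (1/8)(1 + 1 + 4 + 0)
        assert cd.cw_ssi_mse(pred, gt, conf, mask, uniform_cfg()) == pytest.approx(0.75)

    def test_hand_example_hard_mask(self):
        gt = cd.InverseDepthMap(np.zeros((2, 2)))
        pred = cd.InverseDepthMap(np.array([[1.0, -1.0], [2.0, 0.0]]))
        conf = cd.ConfidenceMap(np.array([[0.9, 0.9], [0.2, 0.9]]))
        mask = cd.ValidityMask(np.ones((2, 2), bool))
        cfg = cd.WeightConfig("hard", threshold=0.5)
        # residual-2 pixel masked out but still counted in M
        assert cd.cw_ssi_mse(pred, gt, conf, mask, cfg) == pytest.approx(0.25)

    def test_empty_image(self):
        gt = cd.InverseDepthMap(np.zeros((2, 2)))
        conf = cd.ConfidenceMap(np.ones((2, 2)))
        mask = cd.ValidityMask(np.zeros((2, 2), bool))
        with pytest.raises(EmptyImageError):
            cd.cw_ssi_mse(gt, gt, conf, mask, uniform_cfg())


class TestPyramid:
    def test_single_level_is_residual(self, rng):
        pred = cd.InverseDepthMap(rng.uniform(0, 1, (4, 6)))
        gt = cd.InverseDepthMap(rng.uniform(0, 1, (4, 6)))
        mask = cd.ValidityMask(np.ones((4, 6), bool))
        pyr = cd.build_pyramid(pred, gt, np.ones((4, 6)), mask, 1)
        assert len(pyr.levels) == 1
        np.testing.assert_allclose(pyr.levels[0][0], pred.values - gt.values)

    def test_constant_residual_all_levels(self):
        pred = cd.InverseDepthMap(np.full((8, 8), 3.0))
        gt = cd.InverseDepthMap(np.zeros((8, 8)))
        mask = cd.ValidityMask(np.ones((8, 8), bool))
        pyr = cd.build_pyramid(pred, gt, np.ones((8, 8)), mask, 4)
        assert len(pyr.levels) == 4
        for resid, _, valid in pyr.levels:
            np.testing.assert_allclose(resid[valid], 3.0)

    def test_checkerboard_cancels_at_level_two(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 2.0 - 1.0
        pred = cd.InverseDepthMap(board)
        gt = cd.InverseDepthMap(np.zeros((4, 4)))
        mask = cd.ValidityMask(np.ones((4, 4), bool))
        pyr = cd.build_pyramid(pred, gt, np.ones((4, 4)), mask, 2)
        np.testing.assert_allclose(pyr.levels[1][0], 0.0, atol=1e-15)

    def test_level_shapes_ceil(self):
        pred = cd.InverseDepthMap(np.zeros((5, 7)))
        mask = cd.ValidityMask(np.ones((5, 7), bool))
        pyr = cd.build_pyramid(pred, pred, np.ones((5, 7)), mask, 3)
        assert [lvl[0].shape for lvl in pyr.levels] == [(5, 7), (3, 4), (2, 2)]

    def test_truncation_warns_not_raises(self):
        pred = cd.InverseDepthMap(np.zeros((4, 4)))
        mask = cd.ValidityMask(np.ones((4, 4), bool))
        with pytest.warns(UserWarning, match="truncat"):
            pyr = cd.build_pyramid(pred, pred, np.ones((4, 4)), mask, 6)
        assert len(pyr.levels) == 3


class TestGradientTerm:
    def test_constant_residual_vanishes(self):
        pred = cd.InverseDepthMap(np.full((8, 8), 2.0))
        gt = cd.InverseDepthMap(np.zeros((8, 8)))
        mask = cd.ValidityMask(np.ones((8, 8), bool))
        pyr = cd.build_pyramid(pred, gt, np.ones((8, 8)), mask, 4)
        assert cd.cw_gradient_term(pyr) == 0.0

    def test_forward_difference_hand_example(self):
        # 1x4 residual row [0, 1, 3, 3]: (1/4)(|1| + |2| + |0|) = 0.75
        pyr = ScalePyramid(
            levels=[(
                np.array([[0.0, 1.0, 3.0, 3.0]]),
                np.ones((1, 4)),
                np.ones((1, 4), bool),
            )],
            m_full=4,
        )
        assert cd.cw_gradient_term(pyr) == pytest.approx(0.75)

    def test_difference_needs_both_pixels_weighted(self):
        resid = np.array([[0.0, 5.0, 1.0, 1.0]])
        weights = np.array([[1.0, 0.0, 1.0, 1.0]])
        pyr = ScalePyramid(
            levels=[(resid, weights, np.ones((1, 4), bool))], m_full=4
        )
        # only the 1->1 difference survives; contributions touching the
        # zero-weight pixel are dropped entirely
        assert cd.cw_gradient_term(pyr) == pytest.approx(0.0)


class TestImageLoss:
    def test_exact_affine_gives_zero(self, rng):
        gt = rng.uniform(0.2, 1.0, (8, 8))
        conf = rng.uniform(0.0, 1.0, (8, 8))
        frame = cd.SupervisionFrame(
            cd.InverseDepthMap(gt), cd.ConfidenceMap(conf)
        )
        pred = cd.InverseDepthMap(7.0 * gt + 2.0)
        out = cd.image_loss(pred, frame, cd.LossConfig())
        assert out.total == pytest.approx(0.0, abs=1e-12)

    def test_fully_masked_image(self, rng):
        gt = rng.uniform(0.2, 1.0, (6, 6))
        conf = np.full((6, 6), 0.3)
        frame = cd.SupervisionFrame(cd.InverseDepthMap(gt), cd.ConfidenceMap(conf))
        cfg = cd.LossConfig(weight=cd.WeightConfig("hard", threshold=0.5))
        out = cd.image_loss(cd.InverseDepthMap(gt * 2), frame, cfg)
        assert out.total == 0.0 and out.effective_pixels == 0

    def test_shape_mismatch(self, small_pair):
        pred, frame = small_pair
        with pytest.raises(DimensionError):
            cd.image_loss(cd.InverseDepthMap(np.ones((3, 3))), frame)

    def test_matches_independent_reference(self):
        """Dual-implementation oracle: an explicit-loop reference."""
        pred, frame = make_instance(99, shape=(8, 8))
        for kind in ("uniform", "hard", "soft"):
            cfg = cd.LossConfig(
                gradient_weight=0.5,
                scale_levels=3,
                weight=cd.WeightConfig(kind, 0.5, 10.0),
            )
            mine = cd.image_loss(pred, frame, cfg)
            ref = reference_image_loss(pred, frame, cfg)
            assert mine.total == pytest.approx(ref, abs=1e-10)


def reference_image_loss(pred, frame, cfg):
    """Straightforward loop-based recomputation of the per-image loss."""
    h, w = pred.shape
    q = frame.confidence.values
    valid = frame.mask.flags & np.isfinite(pred.values)

    def wfun(qv):
        if cfg.weight.mask_kind == "uniform":
            return 1.0
        if qv < cfg.weight.threshold:
            return 0.0
        if cfg.weight.mask_kind == "hard":
            return 1.0
        return float(np.exp(cfg.weight.sharpness * (qv - 1.0)))

    wgrid = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            if valid[i, j]:
                wgrid[i, j] = wfun(q[i, j])

    sel = valid & (wgrid > 0)
    xs, ys = pred.values[sel], frame.disparity.values[sel]
    n = len(xs)
    sx, sy = xs.sum(), ys.sum()
    sxx, sxy = (xs * xs).sum(), (xs * ys).sum()
    det = n * sxx - sx * sx
    s = (n * sxy - sx * sy) / det
    t = (sxx * sy - sx * sxy) / det
    if s <= 0:
        return 0.0
    aligned = s * pred.values + t

    m = int(valid.sum())
    data = 0.0
    for i in range(h):
        for j in range(w):
            if valid[i, j]:
                data += wgrid[i, j] * (aligned[i, j] - frame.disparity.values[i, j]) ** 2
    data /= 2.0 * m

    # pyramid: weighted 2x2 pooling of residuals, mean pooling of weights
    resid = np.where(valid, aligned - frame.disparity.values, 0.0)
    wlvl, rlvl, vlvl = wgrid.copy(), resid.copy(), valid.copy()
    grad = 0.0
    for level in range(cfg.scale_levels):
        if level > 0:
            hh, ww = rlvl.shape
            nh, nw = (hh + 1) // 2, (ww + 1) // 2
            nr = np.zeros((nh, nw))
            nw_ = np.zeros((nh, nw))
            nv = np.zeros((nh, nw), bool)
            for i in range(nh):
                for j in range(nw):
                    block = [
                        (2 * i + di, 2 * j + dj)
                        for di in range(2)
                        for dj in range(2)
                    ]
                    inside = [(a, b) for a, b in block if a < hh and b < ww]
                    wsum = sum(wlvl[a, b] for a, b in inside)
                    nw_[i, j] = wsum / 4.0
                    if wsum > 0:
                        nr[i, j] = sum(wlvl[a, b] * rlvl[a, b] for a, b in inside) / wsum
                    else:
                        nr[i, j] = sum(rlvl[a, b] for a, b in inside) / 4.0
                    nv[i, j] = len(inside) == 4 and all(vlvl[a, b] for a, b in inside)
            rlvl, wlvl, vlvl = nr, nw_, nv
        hh, ww = rlvl.shape
        eff = vlvl & (wlvl > 0)
        for i in range(hh):
            for j in range(ww):
                if j + 1 < ww and eff[i, j] and eff[i, j + 1]:
                    grad += (wlvl[i, j] + wlvl[i, j + 1]) / 2 * abs(
                        rlvl[i, j + 1] - rlvl[i, j]
                    )
                if i + 1 < hh and eff[i, j] and eff[i + 1, j]:
                    grad += (wlvl[i, j] + wlvl[i + 1, j]) / 2 * abs(
                        rlvl[i + 1, j] - rlvl[i, j]
                    )
    grad /= m
    return data + cfg.gradient_weight * grad


class TestBatchLoss:
    def test_single_image_batch(self, small_pair):
        pred, frame = small_pair
        total, parts = cd.batch_loss([pred], [frame])
        assert total == cd.image_loss(pred, frame).total
        assert len(parts) == 1

    def test_duplicate_image(self, small_pair):
        pred, frame = small_pair
        total, _ = cd.batch_loss([pred, pred], [frame, frame])
        assert total == pytest.approx(cd.image_loss(pred, frame).total)

    def test_mean_of_two(self):
        p1, f1 = make_instance(1)
        p2, f2 = make_instance(2)
        total, _ = cd.batch_loss([p1, p2], [f1, f2])
        t1 = cd.image_loss(p1, f1).total
        t2 = cd.image_loss(p2, f2).total
        assert total == pytest.approx((t1 + t2) / 2, abs=1e-12)

    def test_empty_batch(self):
        with pytest.raises(EmptyBatchError):
            cd.batch_loss([], [])


class TestLossInvariants:
    @pytest.mark.parametrize("seed", [11, 23, 37])
    def test_scale_shift_invariance(self, seed):
        r = np.random.default_rng(seed)
        pred, frame = make_instance(seed)
        a = r.uniform(0.1, 10)
        b = r.uniform(-5, 5)
        base = cd.image_loss(pred, frame).total
        moved = cd.image_loss(
            cd.InverseDepthMap(a * pred.values + b), frame
        ).total
        assert moved == pytest.approx(base, rel=1e-8)

    def test_soft_lambda_zero_equals_hard(self, small_pair):
        pred, frame = small_pair
        hard = cd.LossConfig(weight=cd.WeightConfig("hard", 0.5))
        soft0 = cd.LossConfig(weight=cd.WeightConfig("soft", 0.5, sharpness=0.0))
        bh = cd.image_loss(pred, frame, hard)
        bs = cd.image_loss(pred, frame, soft0)
        assert bh == bs  # dataclass equality: bit-for-bit fields

    def test_nonnegative_and_zero_only_at_fit(self, small_pair):
        pred, frame = small_pair
        out = cd.image_loss(pred, frame)
        assert out.data_term >= 0 and out.gradient_term >= 0
        assert out.total > 0  # noisy supervision: residual cannot vanish

    @pytest.mark.parametrize("kind,changes", [("hard", False), ("soft", False), ("uniform", True)])
    def test_outlier_below_threshold(self, kind, changes):
        pred, frame = make_instance(5)
        cfg = cd.LossConfig(weight=cd.WeightConfig(kind, 0.5, 10.0))
        base = cd.image_loss(pred, frame, cfg).total
        low = (frame.confidence.values > 0) & (frame.confidence.values < 0.5)
        assert low.any()
        spiked = frame.disparity.values.copy()
        spiked[low] += 100.0
        frame2 = cd.SupervisionFrame(
            cd.InverseDepthMap(spiked), frame.confidence
        )
        after = cd.image_loss(pred, frame2, cfg).total
        if changes:
            assert after > base
        else:
            assert after == base
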