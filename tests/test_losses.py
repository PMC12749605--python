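"""Point-set loss values, subgradients, the differentiable surrogate,
cross-entropy and the combined objective."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    brute_average_hausdorff,
    continuous_average_hausdorff,
    points_of,
    random_blob_mask,
    random_noise_mask,
)
from sdhseg import autodiff as ad
from sdhseg.exceptions import EmptyTargetSet, InvalidWeights, ShapeMismatch
from sdhseg.geometry import BoundaryPointSet, diagonal, extract_boundary
from sdhseg.losses import (
    LossWeights,
    bce_loss,
    combined_loss,
    hausdorff_max,
    hdl_surrogate,
    mask_to_logits,
    sdhl_mask_pair,
    sdhl_point_set,
    sdhl_subgradients,
    sdhl_surrogate,
    weight_sweep,
)

S55 = (5, 5)


def _bps(pts, shape=S55):
    return points_of(np.zeros(shape), pts)


class TestPointSetLoss:
    def test_two_singletons(self):
        bd = sdhl_point_set(_bps([(0, 0)]), _bps([(3, 4)]))
        assert (bd.term_pg, bd.term_gp, bd.total) == (5.0, 5.0, 10.0)

    def test_identical_sets_vanish(self):
        p = _bps([(0, 0), (1, 3), (4, 4)])
        assert sdhl_point_set(p, p).total == 0.0

    def test_asymmetric_cardinality(self):
        bd = sdhl_point_set(_bps([(0, 0), (0, 2)]), _bps([(0, 0)]))
        assert bd.term_pg == pytest.approx(1.0)
        assert bd.term_gp == 0.0
        assert bd.total == pytest.approx(1.0)

    def test_empty_set_saturation(self):
        empty = BoundaryPointSet(np.zeros((0, 2), dtype=np.int64), S55)
        bd = sdhl_point_set(empty, _bps([(1, 1)]))
        assert bd.term_pg == bd.term_gp == diagonal(S55)
        assert sdhl_point_set(empty, empty).total == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatch):
            sdhl_point_set(_bps([(0, 0)]), _bps([(0, 0)], shape=(6, 6)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_symmetry_and_zero_law(self, seed):
        r = np.random.default_rng(seed)
        h, w = int(r.integers(2, 20)), int(r.integers(2, 20))
        p = extract_boundary(random_noise_mask(r, h, w))
        g = extract_boundary(random_noise_mask(r, h, w))
        ab = sdhl_point_set(p, g)
        ba = sdhl_point_set(g, p)
        assert ab.total == pytest.approx(ba.total, abs=1e-12)
        if not p.is_empty and not g.is_empty:
            assert (ab.total == 0.0) == np.array_equal(p.points, g.points)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_brute_force_oracle_equivalence(self, seed):
        r = np.random.default_rng(seed)
        h, w = int(r.integers(2, 24)), int(r.integers(2, 24))
        pm, gm = random_noise_mask(r, h, w), random_noise_mask(r, h, w)
        p, g = extract_boundary(pm), extract_boundary(gm)
        got = sdhl_point_set(p, g).total
        ref = brute_average_hausdorff(list(map(tuple, p.points)),
                                      list(map(tuple, g.points)), (h, w))
        assert got == pytest.approx(ref, abs=1e-9)

    def test_single_point_translation_length(self):
        p = _bps([(1, 1)], shape=(40, 40))
        for t in [(0, 3), (2, 2), (5, 12)]:
            g = _bps([(1 + t[0], 1 + t[1])], shape=(40, 40))
            assert sdhl_point_set(p, g).total == pytest.approx(2 * math.hypot(*t))


class TestMaxFormDiagnostic:
    def test_worst_case_dominates_average_direction(self):
        p = _bps([(0, 0), (0, 1)])
        g = _bps([(4, 4)])
        hmax = hausdorff_max(p, g)
        bd = sdhl_point_set(p, g)
        assert hmax >= bd.term_pg and hmax >= bd.term_gp
        assert hmax == pytest.approx(math.hypot(4, 4))


class TestSubgradients:
    def test_hand_fixture_unit_direction(self):
        sg = sdhl_subgradients(_bps([(0, 0)]), _bps([(3, 4)]))
        assert sg.d_by_p[0] == pytest.approx([-0.6, -0.8])
        assert sg.d_by_g[0] == pytest.approx([0.6, 0.8])

    def test_coincident_points_give_zero_vector(self):
        sg = sdhl_subgradients(_bps([(2, 2)]), _bps([(2, 2)]))
        assert np.all(sg.d_by_p == 0) and np.all(sg.d_by_g == 0)

    def test_empty_set_rejected(self):
        empty = BoundaryPointSet(np.zeros((0, 2), dtype=np.int64), S55)
        with pytest.raises(EmptyTargetSet):
            sdhl_subgradients(empty, _bps([(0, 0)]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_norm_bounds(self, seed):
        r = np.random.default_rng(seed)
        p = extract_boundary(random_noise_mask(r, 12, 12, 0.3))
        g = extract_boundary(random_noise_mask(r, 12, 12, 0.3))
        if p.is_empty or g.is_empty:
            return
        sg = sdhl_subgradients(p, g)
        assert np.linalg.norm(sg.d_by_p, axis=1).max() <= 1.0 / len(p) + 1e-12
        assert np.linalg.norm(sg.d_by_g, axis=1).max() <= 1.0 / len(g) + 1e-12

    def test_matches_finite_differences_of_continuous_loss(self, rng):
        """Central differences of H w.r.t. point coordinates (treated as
        continuous) agree with the analytic subgradients on non-tied sets.

        The reported per-point gradient follows a point's own directed term
        d_min(p_i, G)/|P|; when p_i additionally attains the reverse minimum
        for some g_j, the loss has an extra (1/|G|)(p_i - g_j)/||.|| cross
        contribution, so the finite difference must equal the sum of both.
        For points that attain no reverse minimum the reported gradient
        alone matches.
        """
        from sdhseg.geometry import min_distances

        for _ in range(5):
            p = rng.integers(0, 30, size=(5, 2))
            g = np.unique(p[:3] + rng.integers(6, 12, size=(3, 2)), axis=0)
            pset = points_of(np.zeros((64, 64)), p)
            gset = points_of(np.zeros((64, 64)), g)
            sg = sdhl_subgradients(pset, gset)
            pf = pset.points.astype(float)
            gf = gset.points.astype(float)
            cross = np.zeros_like(sg.d_by_p)
            for j, (d, l) in enumerate(min_distances(gset, pset)):
                if d > 0:
                    cross[l] += (pf[l] - gf[j]) / d / len(gf)
            eps = 1e-6
            for i in range(len(pf)):
                for axis in (0, 1):
                    plus, minus = pf.copy(), pf.copy()
                    plus[i, axis] += eps
                    minus[i, axis] -= eps
                    fd = (continuous_average_hausdorff(plus, gf)
                          - continuous_average_hausdorff(minus, gf)) / (2 * eps)
                    assert fd == pytest.approx(sg.d_by_p[i, axis] + cross[i, axis],
                                               rel=1e-5, abs=1e-9)
                    if not cross[i].any():
                        assert fd == pytest.approx(sg.d_by_p[i, axis], rel=1e-5, abs=1e-9)


class TestSurrogate:
    def test_perfect_prediction_is_zero(self):
        gt = np.zeros((8, 8), int)
        gt[2:5, 2:6] = 1
        assert float(sdhl_surrogate(mask_to_logits(gt), gt)) == 0.0

    def test_shifted_squares_match_point_set_loss(self):
        gt = np.zeros((5, 8), int)
        gt[1:4, 1:4] = 1
        pred = np.zeros((5, 8), int)
        pred[1:4, 3:6] = 1
        val = float(sdhl_surrogate(mask_to_logits(pred), gt))
        assert val == pytest.approx(sdhl_mask_pair(pred, gt).total, abs=1e-6)

    @pytest.mark.parametrize("case", ["pred_empty", "gt_empty", "both_empty"])
    def test_saturation_cases(self, case):
        blob = np.zeros((6, 7), int)
        blob[2:4, 2:5] = 1
        empty = np.zeros((6, 7), int)
        pred = empty if case in ("pred_empty", "both_empty") else blob
        gt = empty if case in ("gt_empty", "both_empty") else blob
        val = float(sdhl_surrogate(mask_to_logits(pred), gt))
        expect = 0.0 if case == "both_empty" else 2 * diagonal((6, 7))
        assert val == pytest.approx(expect, abs=1e-9)

    def test_hard_mask_agreement_on_random_pairs(self, rng):
        worst = 0.0
        for i in range(60):
            h, w = int(rng.integers(6, 64)), int(rng.integers(6, 64))
            pm = random_blob_mask(rng, h, w) if i % 2 else random_noise_mask(rng, h, w, 0.2)
            gm = random_blob_mask(rng, h, w) if i % 3 else random_noise_mask(rng, h, w, 0.2)
            val = float(sdhl_surrogate(mask_to_logits(pm), gm))
            worst = max(worst, abs(val - sdhl_mask_pair(pm, gm).total))
        assert worst < 1e-6

    def test_hdl_surrogate_matches_max_form_on_hard_masks(self, rng):
        for _ in range(20):
            pm = random_noise_mask(rng, 15, 15, 0.2)
            gm = random_noise_mask(rng, 15, 15, 0.2)
            val = float(hdl_surrogate(mask_to_logits(pm), gm))
            ref = hausdorff_max(extract_boundary(pm), extract_boundary(gm))
            assert val == pytest.approx(ref, abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        gt = np.zeros((10, 12), int)
        gt[3:7, 4:9] = 1
        logits = rng.normal(0, 2.0, (10, 12))
        logits[np.abs(logits) < 0.3] += 0.6  # keep pixels away from the threshold
        t = ad.Tensor(logits.copy(), requires_grad=True)
        out = sdhl_surrogate(t, gt)
        out.backward()
        eps = 1e-6
        for _ in range(40):
            i, j = int(rng.integers(0, 10)), int(rng.integers(0, 12))
            arr = logits.copy()
            arr[i, j] += eps
            up = float(sdhl_surrogate(arr, gt))
            arr[i, j] -= 2 * eps
            dn = float(sdhl_surrogate(arr, gt))
            fd = (up - dn) / (2 * eps)
            scale = max(abs(fd), abs(t.grad[i, j]))
            if scale > 1e-7:
                assert abs(fd - t.grad[i, j]) / scale < 1e-3

    def test_gradient_nonzero_for_imperfect_prediction(self):
        gt = np.zeros((8, 8), int)
        gt[2:6, 2:6] = 1
        logits = np.full((8, 8), -2.0)
        logits[1:3, 1:3] = 2.0  # misplaced blob
        t = ad.Tensor(logits, requires_grad=True)
        out = combined_loss(t, gt).total
        out.backward()
        assert np.abs(t.grad).max() > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatch):
            sdhl_surrogate(np.zeros((4, 4)), np.zeros((5, 5), int))

    def test_normalized_variant_scales_by_diagonal(self):
        gt = np.zeros((6, 8), int)
        gt[1:3, 1:3] = 1
        pred = np.zeros((6, 8), int)
        pred[3:5, 4:7] = 1
        raw = float(sdhl_surrogate(mask_to_logits(pred), gt))
        norm = float(sdhl_surrogate(mask_to_logits(pred), gt, normalize=True))
        assert norm == pytest.approx(raw / diagonal((6, 8)))


class TestBceAndCombined:
    def test_uninformative_logits_give_ln2(self):
        gt = (np.arange(16).reshape(4, 4) % 2).astype(int)
        assert float(bce_loss(np.zeros((4, 4)), gt)) == pytest.approx(math.log(2), rel=1e-6)

    def test_confident_correct_logit_contribution(self):
        val = float(bce_loss(np.full((1, 1), 10.0), np.ones((1, 1), int)))
        assert val == pytest.approx(math.log1p(math.exp(-10.0)), rel=1e-6)
        assert val == pytest.approx(4.54e-5, rel=1e-2)

    def test_perfect_confident_prediction_approaches_zero(self):
        gt = np.zeros((6, 6), int)
        gt[2:4, 2:4] = 1
        assert float(bce_loss(mask_to_logits(gt), gt)) == pytest.approx(0.0, abs=1e-12)

    def test_combined_degenerate_weights_reduce_to_bce(self, rng):
        gt = random_noise_mask(rng, 8, 8, 0.3)
        logits = rng.normal(size=(8, 8))
        c = combined_loss(logits, gt, LossWeights(1.0, 0.0))
        assert float(c.total) == pytest.approx(float(bce_loss(logits, gt)), rel=1e-6)

    def test_combined_is_linear_mix(self):
        gt = np.zeros((6, 6), int)
        gt[1:3, 1:3] = 1
        pred = np.zeros((6, 6), int)
        pred[3:5, 3:5] = 1
        logits = mask_to_logits(pred, magnitude=3.0)
        w = LossWeights(0.6, 0.4)
        c = combined_loss(logits, gt, w)
        assert float(c.total) == pytest.approx(0.6 * c.bce + 0.4 * c.sdhl, rel=1e-6)

    def test_perfect_prediction_zero_total(self):
        gt = np.zeros((8, 8), int)
        gt[2:5, 3:6] = 1
        c = combined_loss(mask_to_logits(gt), gt, LossWeights(0.6, 0.4))
        assert float(c.total) == pytest.approx(0.0, abs=1e-10)

    def test_invalid_weights_rejected(self):
        with pytest.raises(InvalidWeights):
            LossWeights(0.0, 0.0)
        with pytest.raises(InvalidWeights):
            LossWeights(-0.1, 0.5)


class TestWeightSweep:
    def test_grid_cardinality_and_ranges(self):
        calls = []

        def fake_eval(l1, l2):
            calls.append((l1, l2))
            return 0.5 + 0.1 * l1, 0.4 + 0.1 * l2

        frame = weight_sweep(fake_eval, grid_step=0.5)
        assert len(frame) == 4
        assert set(calls) == {(0.5, 0.5), (0.5, 1.0), (1.0, 0.5), (1.0, 1.0)}
        assert frame["dice"].between(0, 1).all() and frame["iou"].between(0, 1).all()

    def test_best_row_is_argmax(self):
        frame = weight_sweep(lambda l1, l2: (l1 * l2, l1), grid_step=0.5)
        best = frame.loc[frame["rank"] == 1].iloc[0]
        assert (best.lambda1, best.lambda2) == (1.0, 1.0)
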