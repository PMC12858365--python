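"""Evaluation protocol: separation, detection, Dice, depth-MAE, exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import qpactvi.evaluate as ev
from qpactvi.evaluate import (depthwise_vessel_mae, detect_tumors, dice,
                              mean_tumor_so2_pairs, scaled_overlap_threshold,
                              separate_vessels_tumors, skin_exclusion)


# ------------------------------------------------------------------- dice


def test_dice_closed_forms():
    a = np.zeros((10, 10, 10), bool)
    a[:5] = True
    assert dice(a, a) == 1.0
    b = np.zeros_like(a)
    b[5:] = True
    assert dice(a, b) == 0.0
    assert dice(np.zeros_like(a), np.zeros_like(a)) == 1.0  # both-empty convention
    c = np.zeros_like(a)
    c[:, :, :] = False
    a2 = np.zeros_like(a); a2.ravel()[:100] = True
    b2 = np.zeros_like(a); b2.ravel()[50:150] = True
    assert dice(a2, b2) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        dice(np.zeros((2, 2)), np.zeros((3, 3)))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**24 - 1))
def test_dice_symmetric_and_monotone_under_overlap_growth(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((6, 6, 6)) > 0.6
    b = rng.random((6, 6, 6)) > 0.6
    assert dice(a, b) == dice(b, a)
    # moving one non-overlapping b voxel into the overlap (sizes fixed)
    movable = np.argwhere(b & ~a)
    dest = np.argwhere(a & ~b)
    if len(movable) and len(dest):
        b2 = b.copy()
        b2[tuple(movable[0])] = False
        b2[tuple(dest[0])] = True
        assert dice(a, b2) >= dice(a, b)


# ------------------------------------------------------------- separation


def test_tube_is_vessel_and_ball_is_tumor():
    zz, yy, xx = np.mgrid[:48, :48, :48]
    tube = (np.abs(yy - 12) <= 2) & (np.abs(zz - 12) <= 2)
    ball = (xx - 30) ** 2 + (yy - 34) ** 2 + (zz - 34) ** 2 <= 8**2
    v, t = separate_vessels_tumors(tube)
    assert v.sum() > 0 and t.sum() == 0
    v, t = separate_vessels_tumors(ball)
    assert v.sum() == 0 and t.sum() > 0
    v, t = separate_vessels_tumors(tube | ball)
    assert (v & ball).sum() == 0 and (t & tube).sum() == 0
    assert not (v & t).any()
    # vessel u tumor = post-morphology components
    ball_s = ndimage.binary_dilation(ndimage.binary_erosion(ball)) & ball
    tube_s = ndimage.binary_dilation(ndimage.binary_erosion(tube)) & tube
    assert np.array_equal(v | t, ball_s | tube_s)


def test_empty_mask_yields_empty_masks():
    v, t = separate_vessels_tumors(np.zeros((8, 8, 8), bool))
    assert v.sum() == 0 and t.sum() == 0


def test_exactly_half_vessel_evidence_is_tumor(monkeypatch):
    """The component rule is strict: exactly 50% vessel-labeled voxels -> tumor."""
    mask = np.zeros((10, 10, 10), bool)
    mask[2:8, 2:8, 2:8] = True  # one cube component
    # voxels surviving erosion-then-dilation: the component actually classified
    ball = ev._ball(1)
    opened = ndimage.binary_dilation(ndimage.binary_erosion(mask, ball), ball) & mask
    idx = np.argwhere(opened)
    assert len(idx) % 2 == 0

    def fake_frangi_half(vol, sigmas, black_ridges):
        resp = np.zeros_like(vol)
        resp[tuple(idx[: len(idx) // 2].T)] = 1.0
        return resp

    monkeypatch.setattr(ev, "frangi", fake_frangi_half)
    v, t = separate_vessels_tumors(mask)
    assert v.sum() == 0 and t.sum() > 0

    def fake_frangi_majority(vol, sigmas, black_ridges):
        resp = np.zeros_like(vol)
        resp[tuple(idx[: len(idx) // 2 + 1].T)] = 1.0
        return resp

    monkeypatch.setattr(ev, "frangi", fake_frangi_majority)
    v, t = separate_vessels_tumors(mask)
    assert v.sum() > 0 and t.sum() == 0


# -------------------------------------------------------------- detection


def test_strict_overlap_boundary():
    """501 overlapping voxels detect a tumor; exactly 500 do not."""
    true_inst = np.zeros((20, 20, 20), int)
    true_inst[:10, :20, :20] = 1  # 4000-voxel tumor
    pred = np.zeros_like(true_inst, bool)
    pred.ravel()[:501] = True
    assert detect_tumors(pred, true_inst, min_overlap_voxels=500) == {
        "tp": 1, "fp": 0, "fn": 0}
    pred2 = np.zeros_like(pred)
    pred2.ravel()[:500] = True
    assert detect_tumors(pred2, true_inst, min_overlap_voxels=500) == {
        "tp": 0, "fp": 0, "fn": 1}
    assert detect_tumors(np.zeros_like(pred), true_inst)["fn"] == 1


def test_detection_threshold_scales_with_tumor_volume():
    assert scaled_overlap_threshold(3808) == pytest.approx(500.0)
    assert scaled_overlap_threshold(1904) == pytest.approx(250.0)


def _random_instances(rng, shape, n_blobs, radius):
    vol = np.zeros(shape, int)
    for i in range(1, n_blobs + 1):
        c = rng.integers(radius, np.array(shape) - radius)
        zz, yy, xx = np.mgrid[:shape[0], :shape[1], :shape[2]]
        vol[(xx - c[2]) ** 2 + (yy - c[1]) ** 2 + (zz - c[0]) ** 2
            <= radius**2] = i
    return vol


def test_detection_counts_match_bruteforce_oracle():
    rng = np.random.default_rng(20)
    for case in range(25):
        shape = (24, 24, 24)
        true_inst = _random_instances(rng, shape, rng.integers(1, 3), 4)
        pred = rng.random(shape) > rng.uniform(0.5, 0.9)
        thr = int(rng.integers(5, 60))
        got = detect_tumors(pred, true_inst, min_overlap_voxels=thr)
        # brute force: loop every true id and every predicted component
        tp = fn = 0
        ids = [i for i in np.unique(true_inst) if i > 0]
        for i in ids:
            if (pred & (true_inst == i)).sum() > thr:
                tp += 1
            else:
                fn += 1
        plab, n = ndimage.label(pred, structure=np.ones((3, 3, 3)))
        fp = 0
        for c in range(1, n + 1):
            comp = plab == c
            if comp.sum() > thr and not any(
                    (comp & (true_inst == i)).sum() > thr for i in ids):
                fp += 1
        assert got == {"tp": tp, "fp": fp, "fn": fn}, f"case {case}"


def test_detection_invariant_to_instance_relabeling():
    rng = np.random.default_rng(21)
    true_inst = _random_instances(rng, (20, 20, 20), 2, 4)
    pred = ndimage.binary_dilation(true_inst == 1, iterations=1)
    a = detect_tumors(pred, true_inst, min_overlap_voxels=10)
    relabeled = np.where(true_inst == 1, 5, np.where(true_inst == 2, 9, 0))
    assert detect_tumors(pred, relabeled, min_overlap_voxels=10) == a


# ----------------------------------------------------------- depth-MAE


def test_depth_mae_offsets_and_bruteforce():
    rng = np.random.default_rng(22)
    shape = (16, 16, 16)
    depth = rng.uniform(0, 12, shape)
    mask = rng.random(shape) > 0.5
    true = rng.random(shape)
    table = depthwise_vessel_mae(true + 0.05, true, mask, depth, bin_width_mm=3.0)
    for _, row in table.iterrows():
        if row.n_voxels:
            assert row.mae == pytest.approx(0.05, abs=1e-12)
    zero = depthwise_vessel_mae(true, true, mask, depth, bin_width_mm=3.0)
    assert (zero.loc[zero.n_voxels > 0, "mae"] == 0).all()
    for case in range(20):
        pred = rng.random(shape)
        w = rng.uniform(1.5, 4.0)
        table = depthwise_vessel_mae(pred, true, mask, depth, bin_width_mm=w)
        for _, row in table.iterrows():
            sel = mask & (depth >= row.depth_lo_mm) & (depth < row.depth_hi_mm)
            assert row.n_voxels == sel.sum()
            if sel.any():
                err = np.abs(pred[sel] - true[sel])
                assert row.mae == pytest.approx(err.mean(), abs=1e-12)
                assert row["std"] == pytest.approx(err.std(), abs=1e-12)
            else:
                assert np.isnan(row.mae)


# ------------------------------------------------------ tumor sO2 pairing


def test_tumor_so2_pairs_exact_and_offset():
    true_inst = np.zeros((16, 16, 16), int)
    true_inst[2:8, 2:8, 2:8] = 1
    so2 = np.random.default_rng(23).random((16, 16, 16))
    pairs = mean_tumor_so2_pairs(so2, true_inst, so2, true_inst,
                                 location_tags={1: "middle"},
                                 min_overlap_voxels=10)
    assert len(pairs) == 1
    t, e, tag = pairs[0]
    assert t == pytest.approx(e) and tag == "middle"
    pairs = mean_tumor_so2_pairs(so2 + 0.1, true_inst, so2, true_inst,
                                 min_overlap_voxels=10)
    assert pairs[0][1] == pytest.approx(pairs[0][0] + 0.1)


def test_tumor_so2_pairs_match_masked_mean_oracle():
    rng = np.random.default_rng(24)
    for _ in range(10):
        shape = (14, 14, 14)
        true_inst = _random_instances(rng, shape, 2, 3)
        pred_inst = _random_instances(rng, shape, 2, 4)
        t_so2, p_so2 = rng.random(shape), rng.random(shape)
        pairs = mean_tumor_so2_pairs(p_so2, pred_inst, t_so2, true_inst,
                                     min_overlap_voxels=0)
        for t_mean, e_mean, _ in pairs:
            matches = [
                (i, j) for i in np.unique(true_inst) if i > 0
                for j in np.unique(pred_inst) if j > 0
                if t_so2[true_inst == i].mean() == pytest.approx(t_mean)
                and p_so2[pred_inst == j].mean() == pytest.approx(e_mean)
            ]
            assert matches


def test_unmatched_predictions_yield_no_pairs():
    true_inst = np.zeros((10, 10, 10), int)
    true_inst[:3] = 1
    pred_inst = np.zeros_like(true_inst)
    pred_inst[7:] = 1  # disjoint: FP only, no pair
    so2 = np.ones((10, 10, 10))
    assert mean_tumor_so2_pairs(so2, pred_inst, so2, true_inst,
                                min_overlap_voxels=5) == []


# ---------------------------------------------------------- skin exclusion


def test_skin_exclusion_threshold_and_oracle():
    rng = np.random.default_rng(25)
    depth = rng.uniform(0, 2, (12, 12, 12))
    mask = rng.random((12, 12, 12)) > 0.4
    assert np.array_equal(skin_exclusion(mask, depth, exclude_mm=0.0), mask)
    out = skin_exclusion(mask, depth, exclude_mm=0.6)
    np.testing.assert_array_equal(out, mask & (depth >= 0.6))
    d2 = np.full((2, 1, 1), 0.5)
    d2[1] = 0.7
    m2 = np.ones((2, 1, 1), bool)
    kept = skin_exclusion(m2, d2)
    assert not kept[0, 0, 0] and kept[1, 0, 0]
    vol = rng.random((12, 12, 12))
    vout = skin_exclusion(vol, depth, exclude_mm=0.6)
    np.testing.assert_array_equal(vout, np.where(depth >= 0.6, vol, 0))
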