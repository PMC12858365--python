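"""Dual-task network: shapes, gradients, losses, augmentation, training."""

import numpy as np
import pytest

from qpactvi.dl import (LossConfig, NetworkConfig, TrainingConfig,
                        augment_rotation, build_network, composite_loss,
                        curriculum_eta, predict, shell_mask, train)
from qpactvi.dl.autograd import Tensor
from qpactvi.grids import GridSpec

TINY = NetworkConfig(levels=3, base_channels=4, seed=1)


# -------------------------------------------------------------- shell mask


def test_shell_mask_depth_semantics():
    grid = GridSpec((40, 40, 40), 1.0, origin=(-19.5, -19.5, -19.5))
    X, Y, Z = grid.meshgrid()
    ball = np.sqrt(X**2 + Y**2 + Z**2) <= 18.0
    shell = shell_mask(ball, grid, depth_mm=15.0)
    from scipy import ndimage

    depth = ndimage.distance_transform_edt(ball, sampling=1.0)
    assert shell[depth == 1].all()          # surface voxels included
    assert not shell[depth > 15.5].any()    # 20 mm-deep voxels excluded
    with pytest.raises(ValueError):
        shell_mask(np.zeros((4, 4, 4), bool), grid)


def test_depth_matches_bruteforce_nearest_surface():
    from qpactvi.dl import surface_depth_map

    rng = np.random.default_rng(3)
    mask = np.zeros((16, 16, 16), bool)
    mask[4:12, 3:13, 5:11] = True
    mask[rng.integers(4, 12, 5), rng.integers(3, 13, 5), rng.integers(5, 11, 5)] = True
    depth = surface_depth_map(mask, 0.7)
    outside = np.argwhere(~mask)
    inside = np.argwhere(mask)
    sel = inside[rng.choice(len(inside), 40, replace=False)]
    for p in sel:
        brute = 0.7 * np.sqrt(((outside - p) ** 2).sum(axis=1).min())
        assert depth[tuple(p)] == pytest.approx(brute, abs=1e-9)


# ----------------------------------------------------------------- network


def test_forward_shapes_range_and_param_determinism():
    net = build_network(TINY)
    x = np.random.default_rng(0).random((1, 3, 16, 16, 16))
    so2, seg = net.forward(Tensor(x))
    for out in (so2, seg):
        assert out.data.shape == (1, 1, 16, 16, 16)
        assert (out.data > 0).all() and (out.data < 1).all()
    assert build_network(TINY).n_params() == net.n_params()
    state = net.state_dict()
    for a, b in zip(state, build_network(TINY).state_dict()):
        np.testing.assert_array_equal(a, b)


def test_indivisible_input_rejected_with_padding_hint():
    net = build_network(TINY)
    with pytest.raises(ValueError, match="pad"):
        net.forward(np.zeros((1, 3, 15, 16, 16)))


def test_attention_ablation_changes_output():
    x = np.random.default_rng(1).random((1, 3, 8, 8, 8))
    with_att = build_network(NetworkConfig(levels=2, base_channels=4, seed=2,
                                           attention=True))
    without = build_network(NetworkConfig(levels=2, base_channels=4, seed=2,
                                          attention=False))
    a, _ = with_att.forward(x)
    b, _ = without.forward(x)
    assert not np.allclose(a.data, b.data)


# ------------------------------------------------------------------- loss


def _random_pred(shape, seed):
    rng = np.random.default_rng(seed)
    return (Tensor(rng.uniform(0.05, 0.95, shape)),
            Tensor(rng.uniform(0.05, 0.95, shape)))


def test_composite_loss_matches_elementwise_oracle():
    shape = (1, 1, 6, 6, 6)
    pred_so2, pred_seg = _random_pred(shape, 7)
    rng = np.random.default_rng(8)
    t_so2 = rng.random(shape)
    t_seg = (rng.random(shape) > 0.6).astype(float)
    cfg = LossConfig(eta=0.8, target_weight=10.0, dice_smoothing=1.0)
    total, comps = composite_loss(pred_so2, pred_seg, t_so2, t_seg, cfg)
    # independent elementwise implementation
    w = 1.0 + 9.0 * t_seg
    wn = w / w.mean()
    reg = np.mean(wn * (pred_so2.data - t_so2) ** 2)
    p = pred_seg.data
    bce = np.mean(-wn * (t_seg * np.log(p) + (1 - t_seg) * np.log(1 - p)))
    dice_l = 1 - (2 * (p * t_seg).sum() + 1.0) / (p.sum() + t_seg.sum() + 1.0)
    assert comps["reg"] == pytest.approx(reg, abs=1e-6)
    assert comps["bce"] == pytest.approx(bce, abs=1e-6)
    assert comps["dice_loss"] == pytest.approx(dice_l, abs=1e-6)
    assert total.item() == pytest.approx(reg + 0.8 * (bce + dice_l), abs=1e-6)
    assert all(comps[k] >= 0 for k in ("reg", "bce", "dice_loss"))


def test_eta_zero_reduces_to_regression_and_monotonicity():
    shape = (1, 1, 4, 4, 4)
    pred_so2, pred_seg = _random_pred(shape, 9)
    t_so2 = np.random.default_rng(10).random(shape)
    t_seg = np.zeros(shape)
    t_seg[0, 0, :2] = 1.0
    t0, c0 = composite_loss(pred_so2, pred_seg, t_so2, t_seg, LossConfig(eta=0.0))
    assert t0.item() == pytest.approx(c0["reg"], abs=1e-12)
    totals = [composite_loss(pred_so2, pred_seg, t_so2, t_seg,
                             LossConfig(eta=e))[0].item() for e in (0.0, 0.5, 2.0)]
    assert totals[0] < totals[1] < totals[2]  # Lseg > 0 here


def test_perfect_predictions_reach_loss_floors():
    shape = (1, 1, 4, 4, 4)
    t_seg = np.zeros(shape)
    t_seg[0, 0, 1:3, 1:3, 1:3] = 1.0
    t_so2 = np.random.default_rng(11).random(shape)
    total, comps = composite_loss(Tensor(t_so2.copy()), Tensor(t_seg.copy()),
                                  t_so2, t_seg, LossConfig(eta=1.0))
    assert comps["reg"] == 0.0
    assert comps["bce"] <= 1e-10
    assert comps["dice_loss"] <= 1e-10  # 1 - (2I+s)/(2I+s) = 0 at exact match


def test_non_binary_truth_rejected():
    shape = (1, 1, 4, 4, 4)
    pred_so2, pred_seg = _random_pred(shape, 12)
    with pytest.raises(ValueError, match="binary"):
        composite_loss(pred_so2, pred_seg, np.zeros(shape),
                       np.full(shape, 0.5), LossConfig())


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(eta=-1.0)
    with pytest.raises(ValueError):
        LossConfig(dice_smoothing=0.0)


# ------------------------------------------------------------ augmentation


def test_rotation_identity_and_composition():
    from scipy import ndimage as ndi

    rng = np.random.default_rng(13)
    # smooth continuous maps: interpolation error is meaningful only below
    # the field's correlation length
    vol = ndi.gaussian_filter(rng.random((3, 64, 64, 8)), (0, 2, 2, 1))
    zz, yy, _ = np.mgrid[:64, :64, :8]
    vessels = (np.hypot(zz - 20, yy - 32) <= 4) | (np.hypot(zz - 40, yy - 28) <= 3)
    sample = {"input": vol, "seg": vessels.astype(float)}
    for k in (0, 20):
        out = augment_rotation(sample, k=k)
        np.testing.assert_array_equal(out["input"], vol)
        np.testing.assert_array_equal(out["seg"], vessels)
    k = 7
    once = augment_rotation(sample, k=k)
    back = augment_rotation(once, k=20 - k)
    assert set(np.unique(back["seg"])).issubset({0.0, 1.0})
    inter = np.logical_and(back["seg"] > 0.5, vessels).sum()
    dice = 2 * inter / (back["seg"].sum() + vessels.sum())
    assert dice >= 0.95
    mid = np.abs(back["input"] - vol)[:, 16:48, 16:48, :]
    assert mid.mean() < 0.1  # linear interpolation tolerance, fixed a priori


def test_curriculum_ramp():
    cfg = LossConfig(eta=2.0, curriculum_ramp_fraction=0.2)
    etas = [curriculum_eta(cfg, e, 10) for e in range(10)]
    assert etas[0] == pytest.approx(1.0)  # half-way up the 2-epoch ramp
    assert etas[1] == pytest.approx(2.0)
    assert all(e == 2.0 for e in etas[2:])


# ---------------------------------------------------------------- training


def _toy_dataset(n=2, size=8, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        seg = np.zeros((size, size, size))
        seg[2:5, 2:5, 2:5] = 1.0
        out.append({"input": rng.random((3, size, size, size)),
                    "so2": rng.random((size, size, size)), "seg": seg})
    return out


def test_training_is_seeded_and_curriculum_degenerates():
    data = _toy_dataset()
    cfg = NetworkConfig(levels=2, base_channels=2, seed=3)
    tcfg = TrainingConfig(epochs=2, seed=5, step_size=1e-3, augment=False)
    h1 = train(build_network(cfg), data, tcfg, LossConfig(eta=1.0))
    h2 = train(build_network(cfg), data, tcfg, LossConfig(eta=1.0))
    assert [c["total"] for c in h1] == [c["total"] for c in h2]
    # a constant schedule (ramp fraction ~ 0) equals a fixed-eta run step for step
    h3 = train(build_network(cfg), data, tcfg,
               LossConfig(eta=1.0, curriculum_ramp_fraction=1e-9))
    h4 = train(build_network(cfg), data, tcfg,
               LossConfig(eta=1.0, curriculum_ramp_fraction=0.5))
    assert [c["total"] for c in h3] == [c["total"] for c in h1]  # ramp saturated at epoch 0
    assert h4[0]["eta"] == pytest.approx(1.0)  # 2-epoch run, 1-epoch ramp
    with pytest.raises(ValueError, match="empty"):
        train(build_network(cfg), [], tcfg, LossConfig())
    with pytest.raises(ValueError):
        TrainingConfig(step_size=0.0)


def test_predict_threshold_and_shell_restriction():
    class _Stub:
        def __init__(self, value):
            self.value = value

        def forward(self, x):
            shape = (1, 1) + x.data.shape[2:]
            return Tensor(np.full(shape, 0.7)), Tensor(np.full(shape, self.value))

    shell = np.zeros((8, 8, 8), bool)
    shell[:, :, :4] = True
    x = np.zeros((3, 8, 8, 8))
    assert predict(_Stub(0.4), x, shell).seg_mask.sum() == 0
    assert predict(_Stub(0.5), x, shell).seg_mask.sum() == 0  # strict >
    est = predict(_Stub(0.5 + 1e-6), x, shell)
    assert est.seg_mask.sum() == shell.sum()
    assert not est.seg_mask[~shell].any()
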