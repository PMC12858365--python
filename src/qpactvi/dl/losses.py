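"""Composite training loss: weighted regression + weighted segmentation.

    L_total = L_reg + eta * L_seg

where L_reg is a voxel-weighted mean squared error on the sO2 map and
L_seg combines voxel-weighted binary cross-entropy with a smoothed Dice
loss. Voxel weights emphasize the target structures (arteries, veins,
viable tumor), countering the extreme class imbalance of sparse vessels in
a large volume. A curriculum schedule ramps eta over early epochs so the
regression task stabilizes before the segmentation term dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["LossConfig", "composite_loss", "curriculum_eta"]


@dataclass(frozen=True)
class LossConfig:
    eta: float = 1.0
    target_weight: float = 10.0  # voxel weight on target structures, 1 elsewhere
    dice_smoothing: float = 1.0
    bce_eps: float = 1e-7
    curriculum_ramp_fraction: float = 0.2  # eta ramps linearly over this epoch share

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.dice_smoothing <= 0:
            raise ValueError("dice_smoothing must be > 0")


def curriculum_eta(config: LossConfig, epoch: int, n_epochs: int) -> float:
    """Linear ramp of eta from 0 to its final value over the ramp fraction."""
    ramp = max(1, int(np.ceil(config.curriculum_ramp_fraction * n_epochs)))
    return config.eta * min(1.0, (epoch + 1) / ramp)


def _voxel_weights(true_seg: np.ndarray, target_weight: float) -> np.ndarray:
    return 1.0 + (target_weight - 1.0) * true_seg


def composite_loss(
    pred_so2: Tensor,
    pred_seg: Tensor,
    true_so2: np.ndarray,
    true_seg: np.ndarray,
    config: LossConfig,
    eta: float | None = None,
) -> tuple[Tensor, dict]:
    """Total loss tensor plus per-component values for logging.

    ``true_seg`` must be binary; ``eta`` overrides the config value (the
    curriculum schedule passes the per-epoch value).
    """
    true_so2 = np.asarray(true_so2, dtype=float)
    true_seg = np.asarray(true_seg, dtype=float)
    if pred_so2.data.shape != true_so2.shape or pred_seg.data.shape != true_seg.shape:
        raise ValueError("prediction/truth shape mismatch")
    uniq = np.unique(true_seg)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"truth segmentation must be binary, found values {uniq[:5]}")
    eta = config.eta if eta is None else float(eta)

    w = _voxel_weights(true_seg, config.target_weight)
    w_mean = w.mean()

    # weighted MSE on sO2
    diff = ag.add(pred_so2, Tensor(-true_so2))
    reg = ag.mean(ag.mul(Tensor(w / w_mean), ag.square(diff)))

    # weighted binary cross-entropy (predictions already in (0,1) via sigmoid)
    eps = config.bce_eps
    p = pred_seg
    log_p = ag.log(p, eps)
    log_1mp = ag.log(ag.add(Tensor(np.ones(())), ag.neg(p)), eps)
    bce_terms = ag.add(ag.mul(Tensor(-true_seg * w / w_mean), log_p),
                       ag.mul(Tensor(-(1.0 - true_seg) * w / w_mean), log_1mp))
    bce = ag.mean(bce_terms)

    # smoothed Dice loss: 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s)
    s = config.dice_smoothing
    inter = ag.sum_(ag.mul(p, Tensor(true_seg)))
    denom_val = float(pred_seg.data.sum() + true_seg.sum()) + s
    # denominator treated exactly: d(num/den)/dp = (2t*den - num)/den^2
    num = ag.add(ag.const_mul(inter, 2.0), Tensor(np.asarray(s)))
    psum = ag.sum_(p)

    def _dice(num_t: Tensor, psum_t: Tensor) -> Tensor:
        tsum = float(true_seg.sum())
        out_data = 1.0 - num_t.data / (psum_t.data + tsum + s)

        def backward(g):
            den = psum_t.data + tsum + s
            if num_t.requires_grad:
                num_t._accumulate(-g / den)
            if psum_t.requires_grad:
                psum_t._accumulate(g * num_t.data / den**2)

        return Tensor(out_data, parents=(num_t, psum_t), backward=backward)

    dice_loss = _dice(num, psum)
    seg = ag.add(bce, dice_loss)
    total = ag.add(reg, ag.const_mul(seg, eta))
    components = {
        "reg": reg.item(),
        "bce": bce.item(),
        "dice_loss": dice_loss.item(),
        "seg": seg.item(),
        "eta": eta,
        "total": total.item(),
    }
    return total, components
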