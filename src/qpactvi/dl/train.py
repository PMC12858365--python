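"""Toy-scale training loop: Adam, z-rotation augmentation, eta curriculum.

Full-scale training of the dual-task network (hundreds of phantom pairs at
0.25 mm over hundreds of epochs) is out of scope for a desk-scale study;
this loop is the same procedure at small volume sizes and short schedules,
sufficient for overfit sanity checks and direction-only comparisons against
the unmixing baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .autograd import Tensor
from .losses import LossConfig, composite_loss, curriculum_eta
from .model import DualTaskNet

__all__ = ["TrainingConfig", "QpactEstimate", "Adam", "augment_rotation",
           "train", "predict"]

#: rotation step matching the 20-fold azimuthal symmetry of the illuminators
ROTATION_STEP_DEG = 18.0


@dataclass(frozen=True)
class TrainingConfig:
    step_size: float = 1e-5
    batch_size: int = 2
    epochs: int = 10
    seed: int = 0
    augment: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step size must be > 0")


@dataclass
class QpactEstimate:
    """Network output: whole-volume sO2, segmentation probability, and the
    binary mask (prob > 0.5, restricted to the evaluation shell)."""

    so2: np.ndarray
    seg_prob: np.ndarray
    seg_mask: np.ndarray
    meta: dict = field(default_factory=dict)


class Adam:
    """Adaptive-moment optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def augment_rotation(sample: dict, k: int | None = None,
                     rng: np.random.Generator | None = None) -> dict:
    """Rotate a training sample about z by k * 18 degrees.

    ``k`` is drawn uniformly from {0..19} when not given. Continuous maps
    (inputs, sO2) use linear interpolation; binary masks use nearest
    neighbor and remain binary. Volumes are (..., x, y, z); the rotation
    acts in the (x, y) plane.
    """
    if k is None:
        rng = rng or np.random.default_rng()
        k = int(rng.integers(0, 20))
    k = k % 20
    if k == 0:
        return {key: np.array(v, copy=True) for key, v in sample.items()}
    angle = k * ROTATION_STEP_DEG
    out = {}
    for key, vol in sample.items():
        vol = np.asarray(vol)
        axes = (vol.ndim - 3, vol.ndim - 2)  # (x, y) plane
        binary = vol.dtype == bool or set(np.unique(vol)).issubset({0, 1})
        rot = ndimage.rotate(vol.astype(float), angle, axes=axes, reshape=False,
                             order=0 if binary else 1, mode="constant", cval=0.0)
        out[key] = rot > 0.5 if binary else rot
    return out


def train(
    model: DualTaskNet,
    dataset: list[dict],
    training_config: TrainingConfig,
    loss_config: LossConfig,
) -> list[dict]:
    """Seeded training; returns per-step loss history.

    ``dataset`` entries are dicts with keys ``input`` (3, D, H, W), ``so2``
    (D, H, W) and ``seg`` (binary, D, H, W). The curriculum eta schedule is
    applied per epoch. A non-finite loss aborts with diagnostics.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(training_config.seed)
    opt = Adam(model.params(), training_config.step_size, training_config.beta1,
               training_config.beta2, training_config.adam_eps)
    history: list[dict] = []
    n = len(dataset)
    for epoch in range(training_config.epochs):
        eta = curriculum_eta(loss_config, epoch, training_config.epochs)
        order = rng.permutation(n)
        for start in range(0, n, training_config.batch_size):
            batch_idx = order[start:start + training_config.batch_size]
            samples = []
            for i in batch_idx:
                s = dataset[i]
                if training_config.augment:
                    s = augment_rotation(s, k=int(rng.integers(0, 20)))
                samples.append(s)
            x = np.stack([s["input"] for s in samples])
            t_so2 = np.stack([s["so2"] for s in samples])[:, None]
            t_seg = np.stack([s["seg"].astype(float) for s in samples])[:, None]
            opt.zero_grad()
            pred_so2, pred_seg = model.forward(Tensor(x))
            total, comps = composite_loss(pred_so2, pred_seg, t_so2, t_seg,
                                          loss_config, eta=eta)
            if not np.isfinite(comps["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start}: {comps}"
                )
            total.backward()
            opt.step()
            comps["epoch"] = epoch
            history.append(comps)
    return history


def predict(model: DualTaskNet, input_volumes: np.ndarray,
            shell: np.ndarray) -> QpactEstimate:
    """Forward pass plus shell-restricted thresholding of the segmentation.

    The mask uses a strict threshold: probability exactly 0.5 is excluded.
    """
    x = np.asarray(input_volumes, dtype=float)
    if x.ndim == 4:
        x = x[None]
    so2_t, seg_t = model.forward(Tensor(x))
    so2 = so2_t.data[0, 0]
    seg_prob = seg_t.data[0, 0]
    if seg_prob.shape != shell.shape:
        raise ValueError(f"shell shape {shell.shape} does not match output {seg_prob.shape}")
    seg_mask = (seg_prob > 0.5) & shell.astype(bool)
    return QpactEstimate(so2=so2, seg_prob=seg_prob, seg_mask=seg_mask)
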