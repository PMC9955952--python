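"""Loss terms of the multi-task objective.

The total objective combines four terms with fixed weights::

    L = 0.5 * dice + 0.5 * bce + 1.0 * margin + 0.0005 * mse

Dice and binary cross-entropy supervise the 5 sigmoid segmentation
channels (4 ordinal + BPH); a margin loss on the two class-capsule
lengths supervises the grade branch; a mean-squared error between the
masked-capsule reconstruction and the encoder features regularizes the
capsule branch, scaled far down so it cannot dominate.

Every function accepts autodiff :class:`~piradscaps.autodiff.Tensor`
inputs (plain arrays are wrapped), so the same code path serves training
and the closed-form unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from piradscaps.autodiff import Tensor

DICE_EPS = 1e-6
BCE_CLAMP = 1e-7
MARGIN_POS = 0.9
MARGIN_NEG = 0.1
MARGIN_LAMBDA = 0.5


@dataclass(frozen=True)
class LossWeights:
    """Fixed combination weights of the four loss terms."""

    w_dice: float = 0.5
    w_bce: float = 0.5
    w_margin: float = 1.0
    w_recon: float = 0.0005

    def __post_init__(self):
        if min(self.w_dice, self.w_bce, self.w_margin, self.w_recon) < 0:
            raise ValueError("loss weights must be non-negative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_loss(pred: Tensor | np.ndarray, gt: Tensor | np.ndarray,
              eps: float = DICE_EPS) -> Tensor:
    """Soft dice loss, averaged over channels.

    ``1 - (2·Σpg + ε)/(Σp + Σg + ε)`` per channel, with the sums taken
    over batch and spatial axes, then the channel mean.  Inputs are
    ``(N, C, H, W)`` (or any layout with channels on axis 1).
    """
    p, g = _as_tensor(pred), _as_tensor(gt)
    _check_same_shape(p, g)
    axes = tuple(i for i in range(p.ndim) if i != 1)
    inter = (p * g).sum(axis=axes)
    denom = p.sum(axis=axes) + g.sum(axis=axes)
    dice = (2.0 * inter + eps) / (denom + eps)
    return (1.0 - dice).mean()


def bce_loss(pred: Tensor | np.ndarray, gt: Tensor | np.ndarray) -> Tensor:
    """Mean pixelwise binary cross-entropy over all channels."""
    p, g = _as_tensor(pred), _as_tensor(gt)
    _check_same_shape(p, g)
    pc = p.clip(BCE_CLAMP, 1.0 - BCE_CLAMP)
    ll = g * pc.log() + (1.0 - g) * (1.0 - pc).log()
    return -ll.mean()


def margin_loss(lengths: Tensor | np.ndarray, target: np.ndarray,
                m_pos: float = MARGIN_POS, m_neg: float = MARGIN_NEG,
                lam: float = MARGIN_LAMBDA) -> Tensor:
    """Hinge-squared margin loss on class-capsule lengths.

    ``Σ_k T_k·max(0, m⁺−‖v_k‖)² + λ(1−T_k)·max(0, ‖v_k‖−m⁻)²`` averaged
    over the batch.  ``target`` holds integer class indices (per item) or
    a one-hot matrix matching ``lengths``.
    """
    v = _as_tensor(lengths)
    if np.any(v.data < 0) or np.any(v.data > 1):
        raise ValueError("capsule lengths must lie in [0, 1]")
    t = np.asarray(target)
    if t.ndim == v.ndim - 1:  # class indices -> one-hot
        onehot = np.zeros(v.shape, np.float32)
        np.put_along_axis(onehot, t[..., None].astype(int), 1.0, axis=-1)
        t = onehot
    if t.shape != v.shape:
        raise ValueError(f"target shape {t.shape} does not match lengths {v.shape}")
    t = Tensor(t.astype(np.float32))
    present = t * (m_pos - v).relu() ** 2
    absent = lam * (1.0 - t) * (v - m_neg).relu() ** 2
    per_item = (present + absent).sum(axis=-1)
    return per_item.mean()


def masked_mse(recon: Tensor | np.ndarray, target: Tensor | np.ndarray) -> Tensor:
    """Mean squared error between reconstruction and encoder features.

    "Masked" refers to the reconstruction being computed from the single
    selected class capsule (the other zeroed), not to a spatial mask; the
    gradient is not propagated into the target features.
    """
    r, t = _as_tensor(recon), _as_tensor(target)
    _check_same_shape(r, t)
    diff = r - t.detach()
    return (diff * diff).mean()


def total_loss(dice: Tensor | float, bce: Tensor | float, margin: Tensor | float,
               mse: Tensor | float, weights: LossWeights = LossWeights()) -> Tensor:
    """Weighted sum ``0.5·dice + 0.5·bce + margin + 0.0005·mse``."""
    parts = [_as_tensor(x) for x in (dice, bce, margin, mse)]
    for part in parts:
        if not np.all(np.isfinite(part.data)):
            raise FloatingPointError("non-finite loss component")
    d, b, m, r = parts
    return weights.w_dice * d + weights.w_bce * b + weights.w_margin * m + weights.w_recon * r
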