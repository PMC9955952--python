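"""Optimization loop, learning-rate schedule, and patient-level cross-validation.

The published schedule is Adam from ``lr0 = 0.002`` decayed by 0.8 every
20 epochs, 300 epochs at slice-batch 256; the desk profile keeps the
schedule but shrinks the budget (30 epochs) so the pipeline trains on a
CPU.  Because the inter-slice recurrence needs case-contiguous ordered
slices, one optimization step processes one case's full slice sequence;
``batch_size`` is the nominal slice batch and maps to
``ceil(batch_size / mean slices per case)`` cases per step.

Splits are at patient level: a patient's slices never appear in both
train and validation, and the trainer asserts this on every step.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from piradscaps.autodiff import Tensor, concat
from piradscaps import losses as L
from piradscaps.network import CapsOrdinalSegNet, NetworkConfig
from piradscaps.nn import Adam
from piradscaps.phantom import Case
from piradscaps.preprocess import prepare_training_case, sample_augment_params, apply_transform


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (paper scale by default, ``desk()`` for CPU)."""

    lr0: float = 0.002
    decay_factor: float = 0.8
    decay_every: int = 20
    epochs: int = 300
    batch_size: int = 256
    seed: int = 0
    folds: int = 5
    augment: bool = True
    clip_norm: float | None = 5.0  # global gradient-norm clip; None disables
    loss_weights: L.LossWeights = field(default_factory=L.LossWeights)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 < self.decay_factor <= 1:
            raise ValueError("decay_factor must lie in (0, 1]")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        kwargs = dict(epochs=30, batch_size=8)
        kwargs.update(overrides)
        return cls(**kwargs)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Stepwise-decayed learning rate ``lr0 · f^⌊epoch / every⌋``."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every)


@dataclass(frozen=True)
class FoldSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]


def make_folds(patient_ids: list[str], k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Shuffled patient-level partition into k folds of near-equal size."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} patients into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split([ids[i] for i in order], k)
    splits = []
    for i in range(k):
        val = tuple(chunks[i])
        train = tuple(pid for j, c in enumerate(chunks) for pid in c if j != i)
        splits.append(FoldSplit(train_ids=train, val_ids=val))
    return splits


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def _augment_case(prep: dict, rng: np.random.Generator) -> dict:
    """One geometric transform applied to all slices of a case alike.

    A shared transform keeps the slice sequence spatially aligned for the
    recurrence; labels (zonal channel, masks) use nearest-neighbour.
    """
    params = sample_augment_params(rng)
    inputs = np.empty_like(prep["inputs"])
    seg = np.empty_like(prep["seg_gt"])
    for s in range(inputs.shape[0]):
        for c in range(inputs.shape[1]):
            inputs[s, c] = apply_transform(prep["inputs"][s, c], params,
                                           order=0 if c == 2 else 1)
        for k in range(seg.shape[1]):
            seg[s, k] = apply_transform(prep["seg_gt"][s, k], params, order=0)
    out = dict(prep)
    out["inputs"], out["seg_gt"] = inputs, seg
    return out


def _clip_grad_norm(model: CapsOrdinalSegNet, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    grads = [p.grad for p in model.parameters() if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale
    return norm


def case_loss(model: CapsOrdinalSegNet, prep: dict,
              weights: L.LossWeights) -> tuple[Tensor, dict[str, float]]:
    """Forward one prepared case and assemble the four-term objective."""
    x = Tensor(prep["inputs"])
    out = model.forward(x, target_grade=prep["grade"])
    seg = concat([out["ordinal"], out["bph"]], axis=1)
    gt = Tensor(prep["seg_gt"])
    dice = L.dice_loss(seg, gt)
    bce = L.bce_loss(seg, gt)
    lesioned = np.flatnonzero(prep["has_lesion"])
    if lesioned.size:
        lengths = out["grade_lengths"][lesioned]
        margin = L.margin_loss(lengths, prep["grade"][lesioned])
    else:
        margin = Tensor(np.float32(0.0))
    mse = L.masked_mse(out["reconstruction"], out["features"])
    total = L.total_loss(dice, bce, margin, mse, weights)
    parts = {"dice_loss": dice.item(), "bce_loss": bce.item(),
             "margin_loss": margin.item(), "recon_mse": mse.item(),
             "total_loss": total.item()}
    return total, parts


def validation_dice(model: CapsOrdinalSegNet, preps: list[dict]) -> float:
    """Mean 3-D dice of the thresholded any-lesion channel on val cases."""
    from piradscaps.evaluation import dice_coefficient
    vals = []
    for prep in preps:
        out = model.forward(Tensor(prep["inputs"]))
        pred = out["ordinal"].data[:, 0] >= 0.5
        gt = prep["seg_gt"][:, 0] > 0.5
        vals.append(dice_coefficient(pred, gt))
    return float(np.mean(vals)) if vals else float("nan")


def train_model(train_cases: list[Case], cfg: TrainConfig,
                net_cfg: NetworkConfig | None = None,
                val_cases: list[Case] | None = None,
                verbose: bool = False) -> tuple[CapsOrdinalSegNet, pd.DataFrame]:
    """Train a model on whole cases; returns the best-validation model.

    The per-epoch history logs every loss term, the learning rate and the
    validation dice; with a validation set the returned model carries the
    weights of the epoch with the highest validation dice, otherwise the
    final weights.
    """
    if not train_cases:
        raise ValueError("empty training set")
    net_cfg = net_cfg or NetworkConfig.desk()
    model = CapsOrdinalSegNet(net_cfg)
    optimizer = Adam(model.parameters(), lr=cfg.lr0)
    rng = np.random.default_rng(cfg.seed)

    train_ids = {c.patient_id for c in train_cases}
    val_ids = {c.patient_id for c in (val_cases or [])}
    if train_ids & val_ids:
        raise ValueError(f"patient leakage between train and val: {train_ids & val_ids}")

    preps = {c.patient_id: prepare_training_case(c) for c in train_cases}
    val_preps = [prepare_training_case(c) for c in (val_cases or [])]

    history: list[dict] = []
    best_state, best_dice = None, -np.inf
    order = [c.patient_id for c in train_cases]
    for epoch in range(cfg.epochs):
        optimizer.lr = lr_at(epoch, cfg)
        rng.shuffle(order)
        sums: dict[str, float] = {}
        for pid in order:
            assert pid in train_ids and pid not in val_ids  # no patient leakage
            prep = preps[pid]
            if cfg.augment:
                prep = _augment_case(prep, rng)
            total, parts = case_loss(model, prep, cfg.loss_weights)
            model.zero_grad()
            total.backward()
            if cfg.clip_norm is not None:
                _clip_grad_norm(model, cfg.clip_norm)
            optimizer.step()
            for k, v in parts.items():
                sums[k] = sums.get(k, 0.0) + v
        row = {"epoch": epoch, "lr": optimizer.lr}
        row.update({k: v / len(order) for k, v in sums.items()})
        if val_preps:
            vd = validation_dice(model, val_preps)
            row["val_dice"] = vd
            if vd > best_dice:
                best_dice, best_state = vd, model.state_dict()
        history.append(row)
        if verbose:
            print(f"epoch {epoch:3d} lr {row['lr']:.5f} "
                  f"loss {row['total_loss']:.4f} val {row.get('val_dice', float('nan')):.3f}")
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def train_fold(cases: list[Case], split: FoldSplit, cfg: TrainConfig,
               net_cfg: NetworkConfig | None = None,
               verbose: bool = False) -> tuple[CapsOrdinalSegNet, pd.DataFrame]:
    """Train on a fold's training patients, validate on its held-out patients."""
    by_id = {c.patient_id: c for c in cases}
    train = [by_id[p] for p in split.train_ids]
    val = [by_id[p] for p in split.val_ids]
    return train_model(train, cfg, net_cfg=net_cfg, val_cases=val, verbose=verbose)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, model: CapsOrdinalSegNet,
                    history: pd.DataFrame | None = None) -> None:
    """Single-file ``.npz`` checkpoint: weights + architecture config."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)
    if history is not None:
        history.to_csv(os.path.splitext(path)[0] + "_history.csv", index=False)


def load_checkpoint(path: str) -> CapsOrdinalSegNet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        for key in ("encoder_widths", "recon_hidden"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = CapsOrdinalSegNet(NetworkConfig(**cfg_dict))
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model
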