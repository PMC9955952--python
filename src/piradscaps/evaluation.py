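"""Image- and patient-level evaluation metrics.

Two families of quantities are produced:

* overlap — the Dice coefficient per slice (image level, averaged over
  lesion-bearing slices) and per stacked case volume (patient level);
* detection/classification — confusion counts at PI-RADS cutoffs
  (≥ 3, ≥ 4, = 5) and for the binary low/high grade, with accuracy,
  sensitivity, specificity, PPV, NPV and F1 derived from them.

A predicted lesion matches a ground-truth lesion when their overlap
reaches a (configurable) IoU of 0.1 — "same location" in the lenient
sense of radiological reading.  At the patient level the decision is
made on the index lesion, defined as the patient's largest ground-truth
lesion.  Rates with zero denominators are reported as ``None`` rather
than coerced to 0, so averages are never silently inflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_IOU = 0.1


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """``2|P∩G| / (|P|+|G|)``; defined as 1.0 when both masks are empty."""
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def aggregate_dice(pairs: list[tuple[np.ndarray, np.ndarray]], level: str) -> float:
    """Mean dice over a cohort of (predicted, ground-truth) mask volumes.

    ``level='image'`` averages per-slice dice over all lesion-bearing
    slices (slices whose ground truth is non-empty) pooled across
    patients; ``level='patient'`` computes one 3-D dice per stacked case
    volume and averages over patients.
    """
    if not pairs:
        raise ValueError("aggregate_dice needs at least one (pred, gt) pair")
    if level == "patient":
        return float(np.mean([dice_coefficient(p, g) for p, g in pairs]))
    if level == "image":
        vals = []
        for p, g in pairs:
            for s in range(np.asarray(g).shape[0]):
                if np.asarray(g)[s].any():
                    vals.append(dice_coefficient(np.asarray(p)[s], np.asarray(g)[s]))
        if not vals:
            raise ValueError("no lesion-bearing slices in ground truth")
        return float(np.mean(vals))
    raise ValueError(f"level must be 'image' or 'patient', got {level!r}")


def interslice_consistency(mask_volume: np.ndarray) -> float:
    """Mean dice between adjacent-slice masks of one predicted volume.

    Pairs where both slices are empty are skipped; a volume with no
    informative adjacent pair scores 1.0 (vacuously consistent).
    """
    vol = np.asarray(mask_volume).astype(bool)
    vals = [
        dice_coefficient(vol[s], vol[s + 1])
        for s in range(vol.shape[0] - 1)
        if vol[s].any() or vol[s + 1].any()
    ]
    return float(np.mean(vals)) if vals else 1.0


# ---------------------------------------------------------------------------
# detection / classification counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class Cutoff:
    """A PI-RADS decision rule on class labels (1..4 = PI-RADS 2..5)."""

    name: str
    kind: str  # "ge" or "eq"
    cls: int

    def test(self, cls: int) -> bool:
        return cls >= self.cls if self.kind == "ge" else cls == self.cls


#: the cutoff set reported by the cohort evaluation
CUTOFFS = (
    Cutoff("PI-RADS>=3", "ge", 2),
    Cutoff("PI-RADS>=4", "ge", 3),
    Cutoff("PI-RADS=5", "eq", 4),
)


@dataclass
class EvalFinding:
    """A lesion for matching: mask volume plus its (predicted or GT) class."""

    mask: np.ndarray  # (S, H, W) bool
    cls: int  # class label 0..4

    @property
    def n_voxels(self) -> int:
        return int(np.asarray(self.mask).astype(bool).sum())


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    union = int((a | b).sum())
    return int((a & b).sum()) / union if union else 0.0


def match_and_count(pred: list[list[EvalFinding]], gt: list[list[EvalFinding]],
                    cutoff: Cutoff, level: str = "patient",
                    iou_threshold: float = DEFAULT_IOU) -> ConfusionCounts:
    """Cutoff-stratified confusion counts over a cohort.

    ``pred`` and ``gt`` hold one list of findings per patient, in the
    same order.  At patient level the unit is the patient, judged on its
    index (largest) ground-truth lesion; at image level the unit is the
    slice, judged on the maximum ground-truth class present.  A positive
    unit is a true positive only if a predicted finding passing the
    cutoff overlaps the qualifying ground truth (IoU ≥ threshold, in 3-D
    at patient level and in-plane at image level).
    """
    if len(pred) != len(gt):
        raise ValueError("pred and gt cohorts differ in length")
    if level not in ("patient", "image"):
        raise ValueError(f"level must be 'patient' or 'image', got {level!r}")
    tp = fp = fn = tn = 0
    for preds, gts in zip(pred, gt):
        if level == "patient":
            index = max(gts, key=lambda f: f.n_voxels) if gts else None
            if index is not None and cutoff.test(index.cls):
                hit = any(cutoff.test(p.cls)
                          and _iou(p.mask, index.mask) >= iou_threshold
                          for p in preds)
                tp += hit
                fn += not hit
            else:
                alarm = any(cutoff.test(p.cls) and p.n_voxels > 0 for p in preds)
                fp += alarm
                tn += not alarm
        else:
            n_slices = (gts[0].mask.shape[0] if gts else
                        preds[0].mask.shape[0] if preds else 0)
            for s in range(n_slices):
                qual = [g for g in gts if cutoff.test(g.cls) and np.asarray(g.mask)[s].any()]
                if qual:
                    hit = any(
                        cutoff.test(p.cls)
                        and _iou(np.asarray(p.mask)[s], np.asarray(g.mask)[s]) >= iou_threshold
                        for p in preds for g in qual)
                    tp += hit
                    fn += not hit
                else:
                    alarm = any(cutoff.test(p.cls) and np.asarray(p.mask)[s].any()
                                for p in preds)
                    fp += alarm
                    tn += not alarm
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def binary_counts(pred_flags, gt_flags) -> ConfusionCounts:
    """Confusion counts for paired binary (e.g. high/low grade) calls."""
    p = np.asarray(pred_flags, dtype=bool)
    g = np.asarray(gt_flags, dtype=bool)
    if p.shape != g.shape:
        raise ValueError("flag vectors differ in shape")
    return ConfusionCounts(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)), tn=int(np.sum(~p & ~g)),
    )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, PPV, NPV, F1 from raw counts.

    Zero-denominator rates are ``None`` (undefined), never 0.
    """
    def ratio(num, den):
        return num / den if den > 0 else None

    sens = ratio(c.tp, c.tp + c.fn)
    ppv = ratio(c.tp, c.tp + c.fp)
    f1 = None
    if sens is not None and ppv is not None and (sens + ppv) > 0:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "sensitivity": sens,
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ppv,
        "npv": ratio(c.tn, c.tn + c.fn),
        "f1": f1,
    }


def report_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble evaluation rows (cutoff × level) into one tidy table."""
    return pd.DataFrame(rows, columns=[
        "level", "cutoff", "tp", "fp", "fn", "tn",
        "accuracy", "sensitivity", "specificity", "ppv", "npv", "f1",
    ])
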