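"""Case-level inference and cohort evaluation.

Glue between the trained network and the reporting/metric layers: run a
case through preprocessing and the model, post-process into findings,
and score whole cohorts at both evaluation levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from piradscaps.autodiff import Tensor
from piradscaps import evaluation as ev
from piradscaps.network import CapsOrdinalSegNet
from piradscaps.phantom import Case
from piradscaps.postprocess import LesionFinding, extract_findings, select_final_channel
from piradscaps.preprocess import crop_window, crop_volume, prepare_training_case


@dataclass
class CasePrediction:
    """Everything the model inferred for one case, in crop coordinates."""

    patient_id: str
    ordinal_probs: np.ndarray  # (S, 4, size, size)
    bph_probs: np.ndarray  # (S, 1, size, size)
    grade_lengths: np.ndarray  # (S, 2) capsule lengths (low, high)
    final_mask: np.ndarray  # (S, size, size) bool
    pirads_scope: int  # class label; 0 = no lesion predicted
    findings: list[LesionFinding] = field(default_factory=list)
    crop_corner: tuple[int, int] = (0, 0)

    @property
    def high_grade(self) -> bool:
        """Patient-level grade call: capsule lengths averaged over
        predicted lesion slices (all slices when none predicted)."""
        sel = self.final_mask.any(axis=(1, 2))
        lengths = self.grade_lengths[sel] if sel.any() else self.grade_lengths
        mean = lengths.mean(axis=0)
        return bool(mean[1] >= mean[0])

    @property
    def slice_high_grade(self) -> np.ndarray:
        return self.grade_lengths[:, 1] >= self.grade_lengths[:, 0]


def predict_case(model: CapsOrdinalSegNet, case: Case,
                 threshold: float = 0.5) -> CasePrediction:
    """Preprocess, forward, and post-process one case."""
    prep = prepare_training_case(case, size=model.config.crop_size)
    out = model.forward(Tensor(prep["inputs"]))
    ordinal = out["ordinal"].data
    grade_lengths = out["grade_lengths"].data
    corner = crop_window(case.zonal, model.config.crop_size)
    zonal_crop = crop_volume(case.zonal, corner, model.config.crop_size)
    mask, scope = select_final_channel(ordinal, threshold)
    findings = extract_findings(ordinal, grade_lengths, zonal_crop,
                                case.voxel_size, threshold)
    return CasePrediction(
        patient_id=case.patient_id,
        ordinal_probs=ordinal,
        bph_probs=out["bph"].data,
        grade_lengths=grade_lengths,
        final_mask=mask,
        pirads_scope=scope,
        findings=findings,
        crop_corner=corner,
    )


def _gt_findings_cropped(case: Case, corner, size) -> list[ev.EvalFinding]:
    return [
        ev.EvalFinding(mask=crop_volume(lesion.mask.astype(np.uint8), corner, size) > 0,
                       cls=lesion.pirads_class)
        for lesion in case.lesions
    ]


def _pred_findings(pred: CasePrediction) -> list[ev.EvalFinding]:
    return [ev.EvalFinding(mask=f.mask, cls=pred.pirads_scope) for f in pred.findings]


def evaluate_cohort(preds: list[CasePrediction], cases: list[Case],
                    iou_threshold: float = ev.DEFAULT_IOU) -> dict:
    """Dice, cutoff-stratified metrics, and binary grade metrics.

    Returns a dict with ``dice_image`` / ``dice_patient``, a tidy
    ``table`` (one row per cutoff × level), and raw count objects.
    Cutoff rows use the channel-selection scope of the decoder branch;
    the ``grade`` rows use the capsule branch's low/high calls.
    """
    if len(preds) != len(cases):
        raise ValueError("predictions and cases differ in length")
    by_id = {c.patient_id: c for c in cases}
    size = preds[0].final_mask.shape[-1] if preds else 100

    dice_pairs = []
    pred_sets, gt_sets = [], []
    patient_pred_grade, patient_gt_grade = [], []
    slice_pred_grade, slice_gt_grade = [], []
    for pred in preds:
        case = by_id[pred.patient_id]
        corner = pred.crop_corner
        gt_lesion = crop_volume((case.label_map > 0).astype(np.uint8), corner, size) > 0
        dice_pairs.append((pred.final_mask, gt_lesion))
        pred_sets.append(_pred_findings(pred))
        gt_sets.append(_gt_findings_cropped(case, corner, size))
        if case.lesions:
            patient_gt_grade.append(case.index_lesion().high_grade)
            patient_pred_grade.append(pred.high_grade)
            labels = crop_volume(case.label_map, corner, size)
            slice_max = labels.reshape(labels.shape[0], -1).max(axis=1)
            sel = slice_max > 0
            slice_gt_grade.extend((slice_max[sel] >= 3).tolist())
            slice_pred_grade.extend(pred.slice_high_grade[sel].tolist())

    results = {
        "dice_patient": ev.aggregate_dice(dice_pairs, "patient"),
        "dice_image": ev.aggregate_dice(dice_pairs, "image"),
    }
    rows = []
    for level in ("image", "patient"):
        for cutoff in ev.CUTOFFS:
            counts = ev.match_and_count(pred_sets, gt_sets, cutoff, level=level,
                                        iou_threshold=iou_threshold)
            rows.append({"level": level, "cutoff": cutoff.name,
                         **_count_cols(counts), **ev.metrics_from_counts(counts)})
    grade_counts = {
        "image": ev.binary_counts(slice_pred_grade, slice_gt_grade),
        "patient": ev.binary_counts(patient_pred_grade, patient_gt_grade),
    }
    for level, counts in grade_counts.items():
        rows.append({"level": level, "cutoff": "high-grade",
                     **_count_cols(counts), **ev.metrics_from_counts(counts)})
    results["table"] = ev.report_frame(rows)
    results["grade_counts"] = grade_counts
    return results


def _count_cols(c: ev.ConfusionCounts) -> dict:
    return {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
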