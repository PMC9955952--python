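"""From raw per-slice predictions to lesion findings and a structured report.

The decoder emits 4 ordinal channels per slice.  Over a whole case
volume, each channel is binarized and the channel with the most
non-zero voxels becomes the final cancer segmentation; because channel
``k`` codes "PI-RADS ≥ k+1", that choice also fixes the PI-RADS scope.
On an exactly nested (ground-truth-like) encoding all populated
channels tie, so ties break toward the higher channel, which recovers
the encoded class.  Connected components of the final mask become
individual findings, localized against the zonal mask (majority
intersection) and the image midline, and measured from the pixel grid
(area = pixels × resolution², max over slices; volume adds slice
thickness).  Findings are written as a machine-readable JSON report, a
Markdown summary, and contour overlays on T2/ADC.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from piradscaps.phantom import ZONE_TZ, ZONE_PZ

REPORT_SCHEMA_VERSION = "1.0"
MIN_COMPONENT_VOXELS = 5


@dataclass
class LesionFinding:
    """One reported lesion with localization, grading and dimensions."""

    finding_id: str
    mask: np.ndarray  # (S, H, W) bool
    pirads_scope: int  # class label k: "PI-RADS >= k+1" on the ordinal code
    grade: str  # "low" or "high" from the capsule branch
    grade_probs: tuple[float, float]  # (low, high) capsule lengths
    zone: str
    side: str
    area_mm2: float
    volume_mm3: float
    equiv_diameter_mm: float
    slice_range: tuple[int, int]  # 1-based inclusive

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d.pop("mask")
        return d


def select_final_channel(ordinal_probs: np.ndarray,
                         threshold: float = 0.5) -> tuple[np.ndarray, int]:
    """Choose the ordinal channel with the most supra-threshold voxels.

    Parameters
    ----------
    ordinal_probs
        ``(S, 4, H, W)`` per-slice channel probabilities for one case.
    threshold
        Binarization threshold.

    Returns
    -------
    (mask, scope)
        The selected channel's binary volume ``(S, H, W)`` and the
        PI-RADS scope as a class label (``k*+1``, i.e. "class ≥ scope");
        an all-empty prediction returns an empty mask and scope 0.
    """
    probs = np.asarray(ordinal_probs)
    if probs.ndim != 4 or probs.shape[1] != 4:
        raise ValueError(f"expected (S, 4, H, W) ordinal stack, got {probs.shape}")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("ordinal probabilities must lie in [0, 1]")
    binary = probs >= threshold
    counts = binary.sum(axis=(0, 2, 3))
    if counts.max() == 0:
        return np.zeros_like(binary[:, 0]), 0
    # ties break toward the higher channel: argmax on the reversed array
    k_star = 3 - int(np.argmax(counts[::-1]))
    return binary[:, k_star], k_star + 1


def split_lesions(mask: np.ndarray,
                  min_voxels: int = MIN_COMPONENT_VOXELS) -> list[np.ndarray]:
    """3-D 26-connected components, discarding specks below ``min_voxels``."""
    vol = np.asarray(mask).astype(bool)
    labels, count = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=int))
    comps = []
    for lab in range(1, count + 1):
        comp = labels == lab
        if comp.sum() >= min_voxels:
            comps.append(comp)
    comps.sort(key=lambda c: int(c.sum()), reverse=True)
    return comps


def locate_lesion(lesion_mask: np.ndarray, zonal_mask: np.ndarray,
                  radiological: bool = False) -> tuple[str, str]:
    """Zone by majority intersection with the zonal mask; side by midline.

    A lesion whose centroid column is left of the image midpoint is
    "left" in image convention (``radiological=True`` swaps the labels,
    mirroring how films are hung); a centroid exactly on the midline is
    assigned "right".  A lesion with no prostate overlap is flagged
    "extraprostatic".
    """
    lesion = np.asarray(lesion_mask).astype(bool)
    if not lesion.any():
        raise ValueError("cannot locate an empty lesion mask")
    zonal = np.asarray(zonal_mask)
    if lesion.shape != zonal.shape:
        raise ValueError("lesion and zonal masks differ in shape")
    tz = int((lesion & (zonal == ZONE_TZ)).sum())
    pz = int((lesion & (zonal == ZONE_PZ)).sum())
    if tz == 0 and pz == 0:
        zone = "extraprostatic"
    else:
        zone = "TZ" if tz >= pz else "PZ"
    width = lesion.shape[-1]
    centroid_col = ndimage.center_of_mass(lesion)[-1]
    side = "left" if centroid_col < width / 2 else "right"
    if radiological:
        side = {"left": "right", "right": "left"}[side]
    return zone, side


def lesion_dimensions(lesion_mask: np.ndarray, in_plane_resolution: float,
                      slice_thickness: float) -> dict[str, float]:
    """Area (max per-slice), volume, and equivalent diameter in mm units."""
    if in_plane_resolution <= 0 or slice_thickness <= 0:
        raise ValueError("resolutions must be positive")
    lesion = np.asarray(lesion_mask).astype(bool)
    if not lesion.any():
        raise ValueError("cannot measure an empty lesion mask")
    per_slice = lesion.sum(axis=(1, 2))
    area = float(per_slice.max()) * in_plane_resolution ** 2
    volume = float(lesion.sum()) * in_plane_resolution ** 2 * slice_thickness
    return {
        "area_mm2": area,
        "volume_mm3": volume,
        "equiv_diameter_mm": 2.0 * float(np.sqrt(area / np.pi)),
    }


def extract_findings(ordinal_probs: np.ndarray, grade_lengths: np.ndarray,
                     zonal: np.ndarray, voxel_size: tuple[float, float, float],
                     threshold: float = 0.5,
                     min_voxels: int = MIN_COMPONENT_VOXELS) -> list[LesionFinding]:
    """Full post-processing of one case's raw predictions.

    ``grade_lengths`` is the per-slice ``(S, 2)`` capsule-length matrix;
    a finding's grade probabilities average the lengths over the slices
    the finding occupies.
    """
    mask, scope = select_final_channel(ordinal_probs, threshold)
    findings = []
    for i, comp in enumerate(split_lesions(mask, min_voxels)):
        zone, side = locate_lesion(comp, zonal)
        dims = lesion_dimensions(comp, voxel_size[0], voxel_size[2])
        slices = np.flatnonzero(comp.any(axis=(1, 2)))
        probs = np.asarray(grade_lengths)[slices].mean(axis=0)
        findings.append(LesionFinding(
            finding_id=f"finding_{i + 1}",
            mask=comp,
            pirads_scope=scope,
            grade="high" if probs[1] >= probs[0] else "low",
            grade_probs=(float(probs[0]), float(probs[1])),
            zone=zone,
            side=side,
            area_mm2=dims["area_mm2"],
            volume_mm3=dims["volume_mm3"],
            equiv_diameter_mm=dims["equiv_diameter_mm"],
            slice_range=(int(slices[0]) + 1, int(slices[-1]) + 1),
        ))
    return findings


# ---------------------------------------------------------------------------
# structured report
# ---------------------------------------------------------------------------

def generate_report(findings: list[LesionFinding], patient_id: str, out_dir: str,
                    t2: np.ndarray | None = None, adc: np.ndarray | None = None,
                    scope_label: str | None = None) -> dict[str, str]:
    """Write JSON + Markdown reports (and T2/ADC contour overlays if given).

    Returns the paths written, keyed ``json`` / ``markdown`` /
    ``overlay_t2`` / ``overlay_adc``.
    """
    os.makedirs(out_dir, exist_ok=True)
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "patient_id": patient_id,
        "n_findings": len(findings),
        "no_lesion_detected": len(findings) == 0,
        "findings": [f.to_jsonable() for f in findings],
    }
    paths = {}
    json_path = os.path.join(out_dir, f"{patient_id}_report.json")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    paths["json"] = json_path

    lines = [f"# Prostate mpMRI report — {patient_id}", ""]
    if not findings:
        lines.append("No lesion detected.")
    for f in findings:
        lines += [
            f"## {f.finding_id}",
            f"- PI-RADS scope: >= {f.pirads_scope + 1} (ordinal channel {f.pirads_scope})",
            f"- grade: {f.grade} (low {f.grade_probs[0]:.2f} / high {f.grade_probs[1]:.2f})",
            f"- location: {f.zone}, {f.side}",
            f"- max area {f.area_mm2:.1f} mm², volume {f.volume_mm3:.1f} mm³, "
            f"equivalent diameter {f.equiv_diameter_mm:.1f} mm",
            f"- slices {f.slice_range[0]}–{f.slice_range[1]}",
            "",
        ]
    md_path = os.path.join(out_dir, f"{patient_id}_report.md")
    with open(md_path, "w") as fh:
        fh.write("\n".join(lines))
    paths["markdown"] = md_path

    if t2 is not None and findings:
        paths.update(_overlays(findings, patient_id, out_dir, t2, adc))
    return paths


def _overlays(findings, patient_id, out_dir, t2, adc) -> dict[str, str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    union = np.zeros_like(findings[0].mask)
    for f in findings:
        union |= f.mask
    s = int(np.argmax(union.sum(axis=(1, 2))))
    paths = {}
    for name, vol in (("t2", t2), ("adc", adc)):
        if vol is None:
            continue
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(vol[s], cmap="gray")
        ax.contour(union[s].astype(float), levels=[0.5], colors="r", linewidths=1.0)
        ax.set_axis_off()
        ax.set_title(f"{patient_id} slice {s + 1} ({name.upper()})")
        path = os.path.join(out_dir, f"{patient_id}_overlay_{name}.png")
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths[f"overlay_{name}"] = path
    return paths
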