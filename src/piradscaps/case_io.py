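"""Reading clinical-format cases and writing predictions as NIfTI.

Conventions: arrays are ``(slices, rows, cols)`` in memory with the
slice axis stored last on disk; voxel indices are 0-based.  The zonal
mask is a required input — zonal segmentation is upstream of this
package — and all companion volumes must share the T2 grid.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from piradscaps.phantom import Case, load_volume, save_volume


class CaseValidationError(ValueError):
    """Raised when companion volumes disagree with the T2 geometry."""


def read_case(t2_path: str, adc_path: str, zonal_path: str,
              label_path: str | None = None, bph_path: str | None = None,
              patient_id: str = "case") -> tuple[Case, np.ndarray]:
    """Load one case; returns the :class:`Case` plus the T2 affine.

    The ADC volume must already be resampled to the T2 grid (use
    :func:`piradscaps.preprocess.resample_to_grid` otherwise); shape or
    spacing mismatches raise :class:`CaseValidationError`.
    """
    t2, voxel = load_volume(t2_path)
    affine = nib.load(t2_path).affine.copy()
    adc, adc_voxel = load_volume(adc_path)
    zonal, zon_voxel = load_volume(zonal_path)
    for name, vol, vx in (("adc", adc, adc_voxel), ("zonal", zonal, zon_voxel)):
        if vol.shape != t2.shape:
            raise CaseValidationError(
                f"{name} shape {vol.shape} does not match T2 {t2.shape}")
        if not np.allclose(vx, voxel, rtol=1e-3):
            raise CaseValidationError(
                f"{name} spacing {vx} does not match T2 {voxel}")
    label = np.zeros(t2.shape, np.uint8)
    if label_path:
        label, _ = load_volume(label_path)
        if label.shape != t2.shape:
            raise CaseValidationError("label map does not match T2 shape")
    bph = np.zeros(t2.shape, np.uint8)
    if bph_path:
        bph, _ = load_volume(bph_path)
        if bph.shape != t2.shape:
            raise CaseValidationError("BPH mask does not match T2 shape")
    case = Case(
        patient_id=patient_id,
        t2=t2.astype(np.float32),
        adc=adc.astype(np.float32),
        zonal=zonal.astype(np.uint8),
        label_map=label.astype(np.uint8),
        bph_mask=bph.astype(np.uint8),
        lesions=[],
        voxel_size=tuple(float(v) for v in voxel),
    )
    return case, affine


def uncrop_mask(mask: np.ndarray, corner: tuple[int, int],
                full_shape: tuple[int, int, int]) -> np.ndarray:
    """Place a cropped (S, size, size) mask back on the original grid."""
    s, size, _ = mask.shape
    out = np.zeros(full_shape, dtype=mask.dtype)
    y0, x0 = corner
    ys0, ys1 = max(y0, 0), min(y0 + size, full_shape[1])
    xs0, xs1 = max(x0, 0), min(x0 + size, full_shape[2])
    if ys1 > ys0 and xs1 > xs0:
        out[:, ys0:ys1, xs0:xs1] = mask[:, ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0]
    return out


def write_prediction_mask(mask: np.ndarray, path: str,
                          affine: np.ndarray | None = None,
                          voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a binary mask volume, preserving the source affine if given."""
    if affine is not None:
        img = nib.Nifti1Image(np.transpose(mask.astype(np.uint8), (2, 1, 0)), affine)
        nib.save(img, path)
    else:
        save_volume(mask.astype(np.uint8), voxel_size, path)
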