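"""Deterministic input preparation and stochastic training augmentation.

The non-augmented path is fully deterministic per case: grid resampling
(linear for intensities, nearest for labels), per-volume z-score
normalization, and a prostate-centred ``100×100`` crop shared by all
slices of a case so the inter-slice recurrence sees spatially aligned
sequences.  Augmentation (shift / scale / horizontal flip, identical for
image and mask) applies to training batches only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from piradscaps.encoding import encode_label_map
from piradscaps.phantom import Case

CROP_SIZE = 100


class DegenerateInputError(ValueError):
    """Raised for inputs with no usable signal (constant volume, empty mask)."""


class ModeError(RuntimeError):
    """Raised when a training-only operation is invoked in eval mode."""


@dataclass
class SliceInput:
    """One network input slice: channels T2, ADC, zonal, fixed order."""

    tensor: np.ndarray  # (3, size, size) float32
    slice_index: int  # 1-based, ordered base to apex
    patient_id: str


# ---------------------------------------------------------------------------
# resampling and normalization
# ---------------------------------------------------------------------------

def resample_to_grid(volume: np.ndarray, target_shape: tuple[int, ...],
                     source_spacing=None, target_spacing=None,
                     is_label: bool = False) -> np.ndarray:
    """Resample ``volume`` onto ``target_shape``.

    Linear interpolation for intensity volumes, nearest-neighbour for
    label volumes (no new label values are introduced).  Spacings are
    validated when given; the geometric mapping is defined by the shape
    ratio, which is the spacing ratio for a fixed field of view.
    """
    for spacing in (source_spacing, target_spacing):
        if spacing is not None and np.any(np.asarray(spacing) <= 0):
            raise ValueError(f"spacings must be positive, got {spacing}")
    vol = np.asarray(volume)
    if len(target_shape) != vol.ndim:
        raise ValueError(f"target_shape {target_shape} does not match ndim {vol.ndim}")
    if tuple(target_shape) == vol.shape:
        return vol.copy()
    factors = [t / s for t, s in zip(target_shape, vol.shape)]
    out = ndimage.zoom(vol, factors, order=0 if is_label else 1,
                       mode="nearest", grid_mode=True)
    # zoom can be off by one voxel on awkward ratios; enforce the contract
    slices = tuple(slice(0, t) for t in target_shape)
    if out.shape != tuple(target_shape):
        pad = [(0, max(0, t - o)) for t, o in zip(target_shape, out.shape)]
        out = np.pad(out, pad, mode="edge")[slices]
    return out.astype(vol.dtype if is_label else np.float32)


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Per-volume z-score: zero mean, unit standard deviation."""
    vol = np.asarray(volume, dtype=np.float32)
    sd = float(vol.std())
    if sd == 0.0:
        raise DegenerateInputError("cannot normalize a constant volume")
    return (vol - vol.mean()) / sd


# ---------------------------------------------------------------------------
# prostate-centred cropping
# ---------------------------------------------------------------------------

def crop_window(zonal: np.ndarray, size: int = CROP_SIZE) -> tuple[int, int]:
    """Top-left corner of the ``size``² window centred on the 3-D zonal centroid."""
    if not np.any(zonal > 0):
        raise DegenerateInputError("zonal mask is empty: no prostate to crop to")
    _, cy, cx = ndimage.center_of_mass(zonal > 0)
    return int(round(cy)) - size // 2, int(round(cx)) - size // 2


def crop_volume(vol: np.ndarray, corner: tuple[int, int], size: int = CROP_SIZE) -> np.ndarray:
    """Extract the window from every slice, zero-padding out-of-bounds parts."""
    s, h, w = vol.shape
    y0, x0 = corner
    out = np.zeros((s, size, size), dtype=vol.dtype)
    ys0, ys1 = max(y0, 0), min(y0 + size, h)
    xs0, xs1 = max(x0, 0), min(x0 + size, w)
    if ys1 > ys0 and xs1 > xs0:
        out[:, ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = vol[:, ys0:ys1, xs0:xs1]
    return out


def crop_to_prostate(case: Case, size: int = CROP_SIZE, normalize: bool = True,
                     apex_to_base: bool = False) -> list[SliceInput]:
    """Assemble the per-slice three-channel network inputs of a case.

    T2 and ADC are z-scored per volume; the zonal channel keeps its label
    structure scaled to ``{0, 0.5, 1}``.  Slices are ordered base to apex
    (ascending index) unless ``apex_to_base`` reverses them.
    """
    corner = crop_window(case.zonal, size)
    t2 = crop_volume(normalize_intensity(case.t2) if normalize else case.t2, corner, size)
    adc = crop_volume(normalize_intensity(case.adc) if normalize else case.adc, corner, size)
    zon = crop_volume(case.zonal, corner, size).astype(np.float32) / 2.0
    order = range(case.n_slices - 1, -1, -1) if apex_to_base else range(case.n_slices)
    return [
        SliceInput(
            tensor=np.stack([t2[s], adc[s], zon[s]]).astype(np.float32),
            slice_index=s + 1,
            patient_id=case.patient_id,
        )
        for s in order
    ]


def prepare_training_case(case: Case, size: int = CROP_SIZE) -> dict[str, np.ndarray]:
    """Inputs plus supervision targets on the shared crop window.

    Returns ``inputs`` (S,3,size,size), ``seg_gt`` (S,5,size,size) — the
    4 nested ordinal channels then the BPH channel — per-slice binary
    ``grade`` labels (max lesion class on the slice ≥ PI-RADS 4) and a
    ``has_lesion`` flag marking slices that carry lesion pixels.
    """
    slices = crop_to_prostate(case, size=size)
    inputs = np.stack([sl.tensor for sl in slices])
    corner = crop_window(case.zonal, size)
    labels = crop_volume(case.label_map, corner, size)
    bph = crop_volume(case.bph_mask, corner, size)
    ordinal = encode_label_map(labels.astype(np.int64))  # (4, S, size, size)
    seg_gt = np.concatenate([ordinal.transpose(1, 0, 2, 3),
                             bph[:, None].astype(np.uint8)], axis=1)
    slice_max = labels.reshape(labels.shape[0], -1).max(axis=1)
    return {
        "inputs": inputs.astype(np.float32),
        "seg_gt": seg_gt.astype(np.float32),
        "grade": (slice_max >= 3).astype(np.int64),
        "has_lesion": slice_max > 0,
    }


# ---------------------------------------------------------------------------
# training-time augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    shift: tuple[float, float]  # (dy, dx) pixels
    scale: float
    flip: bool


def sample_augment_params(rng: np.random.Generator, max_shift: float = 10.0,
                          scale_range: tuple[float, float] = (0.9, 1.1),
                          flip_prob: float = 0.5) -> AugmentParams:
    return AugmentParams(
        shift=(float(rng.uniform(-max_shift, max_shift)),
               float(rng.uniform(-max_shift, max_shift))),
        scale=float(rng.uniform(*scale_range)),
        flip=bool(rng.uniform() < flip_prob),
    )


def apply_transform(plane: np.ndarray, params: AugmentParams, order: int) -> np.ndarray:
    """Apply flip → scale-about-centre → shift to one 2-D plane."""
    out = np.asarray(plane)
    if params.flip:
        out = out[:, ::-1]
    if params.scale != 1.0 or params.shift != (0.0, 0.0):
        c = (np.asarray(out.shape) - 1) / 2.0
        matrix = np.eye(2) / params.scale
        offset = c - matrix @ c - np.asarray(params.shift) / params.scale
        out = ndimage.affine_transform(out.astype(np.float32), matrix, offset=offset,
                                       order=order, mode="constant", cval=0.0)
    return out.astype(np.float32)


def augment_batch(inputs: np.ndarray, masks: np.ndarray, rng: np.random.Generator,
                  training: bool = True,
                  label_channels: tuple[int, ...] = (2,)) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform per sample to image and mask alike.

    ``inputs`` is (N,C,H,W) with intensity channels interpolated linearly
    and ``label_channels`` (the zonal map) nearest-neighbour; ``masks``
    (N,K,H,W) are always nearest-neighbour.  Calling this in eval mode is
    an error — validation data must bypass augmentation entirely.
    """
    if not training:
        raise ModeError("augment_batch is training-only; validation uses raw inputs")
    out_i = np.empty_like(inputs)
    out_m = np.empty_like(masks)
    for i in range(inputs.shape[0]):
        params = sample_augment_params(rng)
        for c in range(inputs.shape[1]):
            order = 0 if c in label_channels else 1
            out_i[i, c] = apply_transform(inputs[i, c], params, order=order)
        for k in range(masks.shape[1]):
            out_m[i, k] = apply_transform(masks[i, k], params, order=0)
    return out_i, out_m


def maybe_augment(inputs, masks, rng, training: bool):
    """Training batches are augmented; validation batches pass through."""
    if not training:
        return inputs, masks
    return augment_batch(inputs, masks, rng, training=True)
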