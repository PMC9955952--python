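"""Synthetic mpMRI phantom cases.

Each case emulates the structure of a prostate mpMRI study: a T2-weighted
volume, an ADC map on the same grid, a zonal mask separating transition
zone (TZ) from peripheral zone (PZ), and ground-truth lesion / benign
nodule (BPH) masks with per-lesion PI-RADS classes.

Geometry is a two-tissue ellipsoid model: the prostate is an ellipsoid
spanning most of the 9–14 slices, the TZ an inner ellipsoid shifted
anteriorly, and the PZ the remainder.  Lesions are smoothed ellipsoidal
blobs placed inside a zone whose contrast deepens with PI-RADS class —
increasingly hypointense on T2 and lower on ADC — and whose size grows
with class, mirroring the role of dimension in PI-RADS assessment.  BPH
nodules are well-circumscribed, mildly hyperintense TZ blobs that are
nearly iso-intense on ADC.  The ADC volume is rendered through a coarser
acquisition grid (1.17 mm/px versus 0.68 mm/px for T2) before being
resampled back, then independent Gaussian noise is added to both
contrasts.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

ZONE_BG, ZONE_TZ, ZONE_PZ = 0, 1, 2
ZONE_NAMES = {ZONE_TZ: "TZ", ZONE_PZ: "PZ"}

# multiplicative signal drop inside a lesion, indexed by class label 1..4
_T2_DEPTH = (0.18, 0.30, 0.42, 0.55)
_ADC_DEPTH = (0.25, 0.38, 0.52, 0.68)


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed inside its zone."""


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generation parameters.

    ``class_probs`` are the frequencies of PI-RADS 2/3/4/5 among lesions;
    the defaults follow the lesion-category mix of a realistic clinical
    cohort (14/28/34/24 %).  Resolutions are mm per pixel in plane.
    """

    image_size: int = 256
    n_slices_range: tuple[int, int] = (9, 14)
    t2_resolution: float = 0.68
    adc_resolution: float = 1.17
    slice_thickness: float = 5.0
    class_probs: tuple[float, float, float, float] = (0.14, 0.28, 0.34, 0.24)
    bph_prob: float = 0.7
    pz_prob: float = 0.7
    min_lesions: int = 1
    max_lesions: int = 3
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_probs) - 1.0) > 1e-8:
            raise ValueError("class_probs must sum to 1")
        lo, hi = self.n_slices_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("n_slices_range must lie within [1, 50]")


@dataclass
class Lesion:
    """One ground-truth finding: a boolean mask plus its annotation."""

    lesion_id: str
    mask: np.ndarray  # (S, H, W) bool
    pirads_class: int  # class label 1..4 == PI-RADS 2..5
    zone: str  # "TZ" or "PZ"

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def high_grade(self) -> bool:
        """PI-RADS 4/5 (class labels 3 and 4) count as high grade."""
        return self.pirads_class >= 3


@dataclass
class Case:
    """One phantom patient: aligned volumes plus ground truth."""

    patient_id: str
    t2: np.ndarray  # (S, H, W) float32
    adc: np.ndarray  # (S, H, W) float32
    zonal: np.ndarray  # (S, H, W) uint8 in {0, TZ, PZ}
    label_map: np.ndarray  # (S, H, W) uint8 per-pixel class 0..4
    bph_mask: np.ndarray  # (S, H, W) uint8
    lesions: list[Lesion] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (0.68, 0.68, 5.0)  # (dy, dx, dz) mm

    @property
    def n_slices(self) -> int:
        return self.t2.shape[0]

    def index_lesion(self) -> Lesion:
        """The largest ground-truth lesion (per-patient index lesion)."""
        if not self.lesions:
            raise ValueError(f"case {self.patient_id} has no lesions")
        return max(self.lesions, key=lambda l: l.n_voxels)

    def validate(self) -> None:
        shapes = {self.t2.shape, self.adc.shape, self.zonal.shape,
                  self.label_map.shape, self.bph_mask.shape}
        if len(shapes) != 1:
            raise ValueError("case volumes disagree in shape")
        prostate = self.zonal > 0
        for lesion in self.lesions:
            if np.any(lesion.mask & ~prostate):
                raise ValueError(f"lesion {lesion.lesion_id} leaves the prostate")


def _ellipsoid(shape, center, semi):
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return (((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2) <= 1.0


def _soft(mask: np.ndarray, sigma_plane: float = 1.2) -> np.ndarray:
    return ndimage.gaussian_filter(mask.astype(np.float32), (0.4, sigma_plane, sigma_plane))


def generate_case(config: PhantomConfig, rng: np.random.Generator,
                  patient_id: str = "case_0000", max_retries: int = 50) -> Case:
    """Render one phantom case; bit-identical for identical ``rng`` state."""
    n = config.image_size
    s = int(rng.integers(config.n_slices_range[0], config.n_slices_range[1] + 1))
    shape = (s, n, n)

    # prostate and zonal geometry
    cy, cx = n / 2 + rng.uniform(-5, 5), n / 2 + rng.uniform(-5, 5)
    cz = (s - 1) / 2 + rng.uniform(-0.5, 0.5)
    a_pl = n * rng.uniform(0.20, 0.24)
    semi_pros = (s * 0.48, a_pl * 0.85, a_pl)
    prostate = _ellipsoid(shape, (cz, cy, cx), semi_pros)
    tz_center = (cz, cy - 0.12 * semi_pros[1], cx)
    tz = _ellipsoid(shape, tz_center, tuple(0.62 * np.asarray(semi_pros))) & prostate
    zonal = np.zeros(shape, np.uint8)
    zonal[prostate] = ZONE_PZ
    zonal[tz] = ZONE_TZ

    t2 = np.full(shape, 0.30, np.float32)
    adc = np.full(shape, 0.45, np.float32)
    t2[zonal == ZONE_TZ] = 0.55
    t2[zonal == ZONE_PZ] = 0.80
    adc[zonal == ZONE_TZ] = 0.70
    adc[zonal == ZONE_PZ] = 0.80
    t2 = ndimage.gaussian_filter(t2, (0.4, 1.5, 1.5))
    adc = ndimage.gaussian_filter(adc, (0.4, 1.5, 1.5))

    # lesions with class-graded contrast and size
    n_lesions = int(rng.integers(config.min_lesions, config.max_lesions + 1))
    lesions: list[Lesion] = []
    label_map = np.zeros(shape, np.uint8)
    for i in range(n_lesions):
        cls = 1 + int(rng.choice(4, p=config.class_probs))
        zone_id = ZONE_PZ if rng.uniform() < config.pz_prob else ZONE_TZ
        r_pl = 4.0 + 2.0 * cls + rng.uniform(0.0, 2.0)
        r_z = rng.uniform(1.0, 1.0 + 0.6 * cls)
        mask = None
        for _ in range(max_retries):
            cand = np.argwhere(zonal[1:-1] == zone_id)
            if cand.size == 0:
                break
            pz_, py_, px_ = cand[rng.integers(len(cand))]
            blob = _ellipsoid(shape, (pz_ + 1, py_, px_), (r_z, r_pl, r_pl))
            blob &= prostate
            inside = blob & (zonal == zone_id)
            if inside.sum() >= 12 and inside.sum() >= 0.4 * blob.sum():
                mask = blob
                break
        if mask is None:
            raise PlacementError(
                f"could not place a class-{cls} lesion in {ZONE_NAMES[zone_id]} "
                f"after {max_retries} tries")
        soft = _soft(mask)
        t2 *= 1.0 - _T2_DEPTH[cls - 1] * soft
        adc *= 1.0 - _ADC_DEPTH[cls - 1] * soft
        label_map[mask] = np.maximum(label_map[mask], cls)
        lesions.append(Lesion(f"lesion_{i + 1}", mask, cls, ZONE_NAMES[zone_id]))

    # benign nodules: well-circumscribed, mildly hyperintense TZ blobs
    bph_mask = np.zeros(shape, np.uint8)
    if rng.uniform() < config.bph_prob:
        for j in range(int(rng.integers(1, 3))):
            cand = np.argwhere((zonal[1:-1] == ZONE_TZ) & (label_map[1:-1] == 0))
            if cand.size == 0:
                break
            pz_, py_, px_ = cand[rng.integers(len(cand))]
            r = rng.uniform(3.0, 6.5)
            blob = _ellipsoid(shape, (pz_ + 1, py_, px_), (rng.uniform(0.8, 1.6), r, r))
            blob &= tz
            if blob.sum() < 8:
                continue
            soft = _soft(blob, sigma_plane=0.6)
            t2 *= 1.0 + rng.uniform(0.10, 0.25) * soft
            adc *= 1.0 + rng.uniform(-0.05, 0.05) * soft
            bph_mask[blob] = 1

    # ADC passes through its coarser acquisition grid before alignment
    coarse = max(8, int(round(n * config.t2_resolution / config.adc_resolution)))
    adc_lo = ndimage.zoom(adc, (1.0, coarse / n, coarse / n), order=1)
    adc = ndimage.zoom(adc_lo, (1.0, n / adc_lo.shape[1], n / adc_lo.shape[2]), order=1)
    adc = adc[:, :n, :n].astype(np.float32)

    t2 = t2 + rng.normal(0.0, config.noise_sigma, shape).astype(np.float32)
    adc = adc + rng.normal(0.0, config.noise_sigma, shape).astype(np.float32)

    case = Case(
        patient_id=patient_id,
        t2=np.clip(t2, 0.0, 2.0).astype(np.float32),
        adc=np.clip(adc, 0.0, 2.0).astype(np.float32),
        zonal=zonal,
        label_map=label_map,
        bph_mask=bph_mask,
        lesions=lesions,
        voxel_size=(config.t2_resolution, config.t2_resolution, config.slice_thickness),
    )
    case.validate()
    return case


def generate_cohort(n_cases: int, config: PhantomConfig | None = None) -> list[Case]:
    """Independent seeded cases ``case_0000 .. case_{n-1}``."""
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    config = config or PhantomConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(n_cases)
    return [
        generate_case(config, np.random.default_rng(seeds[i]), patient_id=f"case_{i:04d}")
        for i in range(n_cases)
    ]


# ---------------------------------------------------------------------------
# disk I/O: NIfTI volumes + CSV manifest
# ---------------------------------------------------------------------------

_VOLUMES = ("t2", "adc", "zonal", "label_map", "bph_mask")


def _affine(voxel_size) -> np.ndarray:
    dy, dx, dz = voxel_size
    return np.diag([dx, dy, dz, 1.0])


def save_volume(vol: np.ndarray, voxel_size, path: str) -> None:
    """Write an (S, H, W) array as NIfTI with the slice axis last."""
    img = nib.Nifti1Image(np.transpose(vol, (2, 1, 0)), _affine(voxel_size))
    img.header.set_zooms((voxel_size[1], voxel_size[0], voxel_size[2]))
    nib.save(img, path)


def load_volume(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zx, zy, zz = img.header.get_zooms()[:3]
    return data, (float(zy), float(zx), float(zz))


def write_cohort(cases: list[Case], directory: str) -> pd.DataFrame:
    """Write one NIfTI per volume plus a manifest of findings.

    The manifest has one row per lesion and per benign nodule with
    columns ``patient_id, lesion_id, kind, pirads_class, zone, n_voxels``.
    """
    os.makedirs(directory, exist_ok=True)
    rows = []
    for case in cases:
        cdir = os.path.join(directory, case.patient_id)
        os.makedirs(cdir, exist_ok=True)
        for name in _VOLUMES:
            vol = getattr(case, name)
            save_volume(vol, case.voxel_size, os.path.join(cdir, f"{name}.nii.gz"))
        for lesion in case.lesions:
            save_volume(lesion.mask.astype(np.uint8), case.voxel_size,
                        os.path.join(cdir, f"{lesion.lesion_id}.nii.gz"))
            rows.append({
                "patient_id": case.patient_id, "lesion_id": lesion.lesion_id,
                "kind": "lesion", "pirads_class": lesion.pirads_class,
                "zone": lesion.zone, "n_voxels": lesion.n_voxels,
            })
        labels, count = ndimage.label(case.bph_mask)
        for j in range(1, count + 1):
            rows.append({
                "patient_id": case.patient_id, "lesion_id": f"bph_{j}",
                "kind": "bph", "pirads_class": 0, "zone": "TZ",
                "n_voxels": int((labels == j).sum()),
            })
    manifest = pd.DataFrame(rows, columns=["patient_id", "lesion_id", "kind",
                                           "pirads_class", "zone", "n_voxels"])
    manifest.to_csv(os.path.join(directory, "manifest.csv"), index=False)
    return manifest


def read_cohort(directory: str) -> list[Case]:
    """Read back a cohort written by :func:`write_cohort`."""
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    cases = []
    for pid in sorted(p for p in os.listdir(directory)
                      if os.path.isdir(os.path.join(directory, p))):
        cdir = os.path.join(directory, pid)
        vols = {}
        voxel_size = None
        for name in _VOLUMES:
            vols[name], voxel_size = load_volume(os.path.join(cdir, f"{name}.nii.gz"))
        lesions = []
        sub = manifest[(manifest.patient_id == pid) & (manifest.kind == "lesion")]
        for _, row in sub.iterrows():
            mask, _ = load_volume(os.path.join(cdir, f"{row.lesion_id}.nii.gz"))
            lesions.append(Lesion(row.lesion_id, mask.astype(bool),
                                  int(row.pirads_class), row.zone))
        cases.append(Case(
            patient_id=pid,
            t2=vols["t2"].astype(np.float32),
            adc=vols["adc"].astype(np.float32),
            zonal=vols["zonal"].astype(np.uint8),
            label_map=vols["label_map"].astype(np.uint8),
            bph_mask=vols["bph_mask"].astype(np.uint8),
            lesions=lesions,
            voxel_size=voxel_size,
        ))
    return cases
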