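"""From voxel detections to calcium lesions and per-artery volume scores.

The quantification pipeline mirrors clinical CCTA calcium scoring: a
scan-specific detection threshold (aortic blood-pool mean + 3 SD), region
growing of the network's detected voxels into supra-threshold neighbours,
3D connected-component labeling under six-voxel (face) connectivity, and
rule-based false-positive reduction (lesions < 1 mm^3, > 500 mm^3, or
outside the 10-mm-dilated heart are discarded). The reported quantity is
the volume score (voxel count x voxel volume, mm^3); the Agatston score is
deliberately out of scope because it is not defined for contrast scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_ct import ARTERY_NAMES, CacudaError, CTVolume, LesionLabelMap, as_label_array

_STRUCT6 = ndimage.generate_binary_structure(3, 1)

FIXED_130 = "fixed_130"
AORTA_MEAN_PLUS_3SD = "aorta_mean_plus_3sd"


class ScoringError(CacudaError):
    pass


@dataclass(frozen=True)
class ScanThreshold:
    """Calcium detection threshold of one scan.

    For the aorta method the invariant ``threshold = mean + 3 * sd`` holds
    exactly (population standard deviation).
    """

    threshold_hu: float
    roi_mean_hu: float | None
    roi_sd_hu: float | None
    method: str

    def __post_init__(self) -> None:
        if self.method not in (FIXED_130, AORTA_MEAN_PLUS_3SD):
            raise ScoringError(f"unknown threshold method {self.method!r}")
        if self.method == AORTA_MEAN_PLUS_3SD:
            expect = self.roi_mean_hu + 3.0 * self.roi_sd_hu
            if abs(self.threshold_hu - expect) > 1e-9 * max(1.0, abs(expect)):
                raise ScoringError("threshold != mean + 3*sd")


def fixed_threshold() -> ScanThreshold:
    """The conventional 130 HU non-contrast threshold."""
    return ScanThreshold(130.0, None, None, FIXED_130)


def compute_scan_threshold(volume: CTVolume,
                           aorta_roi: tuple[tuple[int, int, int], tuple[int, int, int]]
                           ) -> ScanThreshold:
    """Scan-specific threshold ``mean_ROI + 3 * SD_ROI`` from an aortic ROI box.

    ``aorta_roi`` is a half-open index box ``((x0, y0, z0), (x1, y1, z1))``
    placed in the ascending aorta. The standard deviation is the population
    SD of the ROI voxels.
    """
    (x0, y0, z0), (x1, y1, z1) = aorta_roi
    shape = volume.shape
    if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
            and 0 <= z0 < z1 <= shape[2]):
        raise ScoringError(f"ROI {aorta_roi} not inside volume of shape {shape}")
    roi = volume.voxels[x0:x1, y0:y1, z0:z1].astype(np.float64)
    mean = float(roi.mean())
    sd = float(roi.std())  # population SD
    return ScanThreshold(mean + 3.0 * sd, mean, sd, AORTA_MEAN_PLUS_3SD)


@dataclass
class Lesion:
    """One 6-connected calcium component."""

    artery: int  # 1=LAD, 2=LCX, 3=RCA
    voxel_indices: np.ndarray  # (N, 3)
    volume_mm3: float
    centroid_mm: tuple[float, float, float]
    peak_hu: float | None = None

    @property
    def artery_name(self) -> str:
        return ARTERY_NAMES[self.artery]

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)


@dataclass
class ScoreReport:
    """Per-artery and total calcium volume of one scan."""

    volume_mm3: dict[str, float]
    n_lesions: dict[str, int]
    removed: list[tuple[Lesion, str]] = field(default_factory=list)

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(self.volume_mm3.values()))

    @property
    def total_lesions(self) -> int:
        return int(sum(self.n_lesions.values()))


# ---------------------------------------------------------------------------
# Region growing
# ---------------------------------------------------------------------------

def grow_lesions(detected: LesionLabelMap | np.ndarray, volume: CTVolume,
                 threshold: ScanThreshold) -> LesionLabelMap:
    """Flood-fill detected voxels into 6-connected supra-threshold neighbours.

    Every supra-threshold component that contains at least one detected
    voxel is labeled entirely with the majority artery label of its seed
    voxels (ties to the lower class id). Detected voxels that themselves sit
    below the threshold keep their own label. Idempotent on its own output.
    """
    det = as_label_array(detected)
    if det.shape != volume.shape:
        raise ScoringError("detected map and volume must be aligned")
    out = np.zeros_like(det)
    if not (det > 0).any():
        return LesionLabelMap(out)
    mask = volume.voxels > threshold.threshold_hu
    comp, n = ndimage.label(mask, structure=_STRUCT6)
    seeds = det > 0
    seed_comp = comp[seeds]
    seed_lab = det[seeds]
    in_mask = seed_comp > 0
    if in_mask.any():
        # majority artery label per seeded component; bincount argmax breaks
        # ties toward the lower class id
        n_cls = 4
        counts = np.zeros((n + 1, n_cls), dtype=np.int64)
        np.add.at(counts, (seed_comp[in_mask], seed_lab[in_mask]), 1)
        seeded = counts[:, 1:].sum(axis=1) > 0
        majority = counts[:, 1:].argmax(axis=1) + 1
        fill = np.where(seeded, majority, 0).astype(det.dtype)
        out = fill[comp]
    out[seeds] = np.where(seed_comp > 0, out[seeds], seed_lab)
    return LesionLabelMap(out)


# ---------------------------------------------------------------------------
# Lesion extraction
# ---------------------------------------------------------------------------

def extract_lesions(labels: LesionLabelMap | np.ndarray,
                    spacing_mm: tuple[float, float, float],
                    hu: np.ndarray | None = None) -> list[Lesion]:
    """Connected components per artery class under 6-connectivity.

    Components are computed independently per class, so lesions of different
    arteries touching each other remain distinct. Returned in deterministic
    order (artery, centroid).
    """
    arr = as_label_array(labels)
    spacing = np.asarray(spacing_mm, dtype=float)
    voxvol = float(np.prod(spacing))
    lesions: list[Lesion] = []
    for cls in (1, 2, 3):
        comp, n = ndimage.label(arr == cls, structure=_STRUCT6)
        if n == 0:
            continue
        idx_all = np.argwhere(comp > 0)
        comp_ids = comp[tuple(idx_all.T)]
        order = np.argsort(comp_ids, kind="stable")
        idx_all, comp_ids = idx_all[order], comp_ids[order]
        bounds = np.searchsorted(comp_ids, np.arange(1, n + 2))
        for ci in range(n):
            idx = idx_all[bounds[ci]:bounds[ci + 1]]
            centroid = tuple((idx.mean(axis=0) * spacing).tolist())
            peak = float(hu[tuple(idx.T)].max()) if hu is not None else None
            lesions.append(Lesion(cls, idx, len(idx) * voxvol, centroid, peak))
    lesions.sort(key=lambda L: (L.artery, L.centroid_mm))
    return lesions


def lesions_to_label_map(lesions: list[Lesion], shape) -> LesionLabelMap:
    """Rasterize a lesion list back into a label map."""
    out = np.zeros(shape, dtype=np.uint8)
    for les in lesions:
        out[tuple(les.voxel_indices.T)] = les.artery
    return LesionLabelMap(out)


# ---------------------------------------------------------------------------
# Heart mask and FP reduction
# ---------------------------------------------------------------------------

def _sphere_structure(spacing_mm, diameter_mm: float) -> np.ndarray:
    r = diameter_mm / 2.0
    half = [int(np.floor(r / s)) for s in spacing_mm]
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, spacing_mm)],
                        indexing="ij")
    return sum(g ** 2 for g in grids) <= r ** 2 + 1e-9


def make_heart_mask(heart_mask: np.ndarray,
                    spacing_mm: tuple[float, float, float],
                    dilation_diameter_mm: float = 10.0) -> np.ndarray:
    """Dilate a heart segmentation with a discrete sphere of physical diameter.

    The spherical structuring element is converted to voxels per-axis by the
    spacing, so the dilation is (approximately) isotropic in millimetres on
    anisotropic grids. The output is a superset of the input.
    """
    mask = np.asarray(heart_mask).astype(bool)
    if not mask.any():
        raise ScoringError("empty heart mask")
    if dilation_diameter_mm <= 0:
        return mask.copy()
    struct = _sphere_structure(spacing_mm, dilation_diameter_mm)
    return ndimage.binary_dilation(mask, structure=struct)


def fp_reduction(lesions: list[Lesion], dilated_heart_mask: np.ndarray,
                 spacing_mm: tuple[float, float, float],
                 min_volume_mm3: float = 1.0,
                 max_volume_mm3: float = 500.0
                 ) -> tuple[list[Lesion], list[tuple[Lesion, str]]]:
    """Rule-based false-positive reduction.

    Discards lesions with volume strictly below ``min_volume_mm3`` (noise),
    strictly above ``max_volume_mm3`` (exceeding plausible calcium volume),
    or with centroid outside the dilated heart mask. Returns the kept
    lesions and the removed ones with the rule that fired.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    shape = np.asarray(dilated_heart_mask.shape)
    kept: list[Lesion] = []
    removed: list[tuple[Lesion, str]] = []
    for les in lesions:
        if les.volume_mm3 < min_volume_mm3:
            removed.append((les, "too_small"))
            continue
        if les.volume_mm3 > max_volume_mm3:
            removed.append((les, "too_large"))
            continue
        cvox = np.clip(np.rint(np.asarray(les.centroid_mm) / spacing).astype(int),
                       0, shape - 1)
        if not dilated_heart_mask[tuple(cvox)]:
            removed.append((les, "outside_heart"))
            continue
        kept.append(les)
    return kept, removed


# ---------------------------------------------------------------------------
# Per-scan score
# ---------------------------------------------------------------------------

def score_scan(volume: CTVolume, detected: LesionLabelMap | np.ndarray,
               threshold: ScanThreshold, heart_mask: np.ndarray,
               dilation_diameter_mm: float = 10.0,
               apply_fp_reduction: bool = True
               ) -> tuple[ScoreReport, list[Lesion]]:
    """Full quantification of one scan: grow -> extract -> FP-reduce -> sum.

    Returns the per-artery volume report and the kept lesion list.
    """
    grown = grow_lesions(detected, volume, threshold)
    lesions = extract_lesions(grown, volume.spacing_mm, hu=volume.voxels)
    removed: list[tuple[Lesion, str]] = []
    if apply_fp_reduction:
        dilated = make_heart_mask(heart_mask, volume.spacing_mm, dilation_diameter_mm)
        lesions, removed = fp_reduction(lesions, dilated, volume.spacing_mm)
    vol = {name: 0.0 for name in ARTERY_NAMES.values()}
    cnt = {name: 0 for name in ARTERY_NAMES.values()}
    for les in lesions:
        vol[les.artery_name] += les.volume_mm3
        cnt[les.artery_name] += 1
    return ScoreReport(vol, cnt, removed), lesions
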