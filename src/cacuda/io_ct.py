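"""Volume I/O and resampling for cardiac CT.

Conventions used throughout the package:

* Voxel arrays are indexed ``[x, y, z]`` with ``z`` the slice axis (axial
  slices are ``volume[:, :, k]``).
* Indices are 0-based; the physical position of voxel ``(i, j, k)`` is
  ``origin_mm + index * spacing_mm`` (half-open extents).
* Intensities are Hounsfield Units (HU). Files are read/written through
  SimpleITK, so NIfTI (``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``)
  are supported transparently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

HU_MIN = -1100.0
HU_MAX = 3100.0

#: Label coding of the per-voxel calcium classes. Left-main (LM) lesions are
#: by convention folded into LAD and are never a separate class.
BACKGROUND, LAD, LCX, RCA = 0, 1, 2, 3
ARTERY_NAMES = {LAD: "LAD", LCX: "LCX", RCA: "RCA"}


class CacudaError(Exception):
    """Base class for errors raised by this package."""


class VolumeFormatError(CacudaError):
    """Image on disk or in memory does not satisfy the 3D HU-volume contract."""


class ResampleError(CacudaError):
    """Requested slice re-gridding is invalid for the given volume."""


@dataclass
class CTVolume:
    """A 3D HU grid with anisotropic voxel spacing.

    Parameters
    ----------
    voxels:
        3D ``float32`` array of HU values, axis order ``(x, y, z)``.
    spacing_mm:
        Per-axis voxel size ``(sx, sy, sz)`` in millimetres.
    origin_mm:
        Physical position of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"CTVolume requires a 3D array, got ndim={self.voxels.ndim}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise VolumeFormatError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise VolumeFormatError("HU values must be finite")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise VolumeFormatError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz


@dataclass
class LesionLabelMap:
    """Integer grid aligned to a :class:`CTVolume`; 0=bg, 1=LAD, 2=LCX, 3=RCA."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeFormatError("label map must be integer-typed")
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, LAD, LCX, RCA])
        if bad.size:
            raise VolumeFormatError(f"label values outside {{0,1,2,3}}: {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


def as_label_array(labels: "LesionLabelMap | np.ndarray") -> np.ndarray:
    """Accept either a :class:`LesionLabelMap` or a raw integer array."""
    if isinstance(labels, LesionLabelMap):
        return labels.labels
    return LesionLabelMap(np.asarray(labels)).labels


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _to_sitk(voxels: np.ndarray, spacing_mm, origin_mm) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our in-memory order is (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.T))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    img.SetOrigin(tuple(float(o) for o in origin_mm))
    return img


def read_volume(path: str | Path) -> CTVolume:
    """Read a 3D HU volume (NIfTI or MetaImage).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    VolumeFormatError
        If the image is not a 3D scalar volume or violates the HU contract.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # unreadable / unsupported file
        raise VolumeFormatError(f"cannot read image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, got {img.GetDimension()}D"
        )
    arr = sitk.GetArrayFromImage(img).T.astype(np.float32)
    return CTVolume(arr, img.GetSpacing(), img.GetOrigin())


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume; round-trips voxels bit-exactly (float32) and spacing to 1e-6 mm."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(volume.voxels.astype(np.float32), volume.spacing_mm,
                             volume.origin_mm), str(path))


def read_label_map(path: str | Path) -> LesionLabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise VolumeFormatError(f"{path}: expected a 3D label image")
    arr = sitk.GetArrayFromImage(img).T
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise VolumeFormatError(f"{path}: non-integer label values")
        arr = rounded.astype(np.uint8)
    return LesionLabelMap(arr)


def write_label_map(labels: LesionLabelMap | np.ndarray,
                    spacing_mm, path: str | Path,
                    origin_mm=(0.0, 0.0, 0.0)) -> None:
    arr = as_label_array(labels)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(arr.astype(np.uint8), spacing_mm, origin_mm), str(path))


def write_mask(mask: np.ndarray, spacing_mm, path: str | Path,
               origin_mm=(0.0, 0.0, 0.0)) -> None:
    sitk.WriteImage(_to_sitk(mask.astype(np.uint8), spacing_mm, origin_mm), str(Path(path)))


def read_mask(path: str | Path) -> np.ndarray:
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img).T.astype(bool)


# ---------------------------------------------------------------------------
# Slice re-gridding
# ---------------------------------------------------------------------------

def _slab_windows(n_in: int, dz_in: float, thickness: float, increment: float):
    """Output slab centers and member input-slice indices.

    The slice axis is modeled with overlapping slabs: input slice ``i`` sits
    at ``i * dz_in`` (origin-relative); the extent is half-open with total
    length ``n_in * dz_in``. Output slab ``k`` is centered at
    ``thickness/2 - dz_in/2 + k * increment`` and averages the input slices
    whose centers fall within ``+/- (thickness - dz_in)/2`` of the slab
    center, i.e. whose own slab lies inside the output slab.
    """
    eps = 1e-9
    extent = n_in * dz_in
    n_out = int(np.floor((extent - thickness) / increment + eps)) + 1
    if n_out < 1:
        raise ResampleError(
            f"slice extent {extent} mm cannot host a {thickness} mm slab"
        )
    half = (thickness - dz_in) / 2.0
    centers = thickness / 2.0 - dz_in / 2.0 + increment * np.arange(n_out)
    members = []
    in_pos = dz_in * np.arange(n_in)
    for c in centers:
        idx = np.nonzero(np.abs(in_pos - c) <= half + eps)[0]
        if idx.size == 0:
            raise ResampleError(
                f"output slab at {c:.3f} mm covers zero input slices "
                f"(thickness {thickness} < input spacing {dz_in}?)"
            )
        members.append(idx)
    return centers, members


def resample_volume(volume: CTVolume, new_thickness_mm: float,
                    new_increment_mm: float) -> CTVolume:
    """Re-grid the slice axis to a new thickness/increment pair.

    Each output slice is the average of the input slices inside its
    ``new_thickness_mm`` window (slab-averaging model of slice thickness);
    the in-plane grid is unchanged. Requires ``thickness >= increment``
    (overlapping-slice convention).
    """
    if new_thickness_mm <= 0 or new_increment_mm <= 0:
        raise ResampleError("thickness and increment must be positive")
    if new_thickness_mm < new_increment_mm:
        raise ResampleError(
            f"thickness ({new_thickness_mm}) must be >= increment ({new_increment_mm})"
        )
    dz = volume.spacing_mm[2]
    centers, members = _slab_windows(volume.shape[2], dz, new_thickness_mm,
                                     new_increment_mm)
    out = np.empty(volume.shape[:2] + (len(members),), dtype=np.float32)
    for k, idx in enumerate(members):
        out[:, :, k] = volume.voxels[:, :, idx].mean(axis=2)
    origin = list(volume.origin_mm)
    origin[2] += float(centers[0])
    spacing = (volume.spacing_mm[0], volume.spacing_mm[1], float(new_increment_mm))
    return CTVolume(out, spacing, tuple(origin))


def resample_labels(labels: LesionLabelMap | np.ndarray, spacing_mm,
                    new_thickness_mm: float, new_increment_mm: float) -> np.ndarray:
    """Nearest-neighbour slice re-gridding for label maps (labels are never averaged)."""
    arr = as_label_array(labels)
    if new_thickness_mm <= 0 or new_increment_mm <= 0:
        raise ResampleError("thickness and increment must be positive")
    if new_thickness_mm < new_increment_mm:
        raise ResampleError("thickness must be >= increment")
    dz = spacing_mm[2]
    centers, _ = _slab_windows(arr.shape[2], dz, new_thickness_mm, new_increment_mm)
    nearest = np.clip(np.rint(centers / dz).astype(int), 0, arr.shape[2] - 1)
    return arr[:, :, nearest]
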