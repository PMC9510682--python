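"""Synthetic two-domain cardiac CT phantoms with ground-truth calcium labels.

The generator emulates the study design that motivates this package: a
*source* domain of non-contrast cardiac CT (NCCT), where coronary calcium is
the only tissue above the conventional 130 HU threshold, and a *target*
domain of contrast-enhanced coronary CT angiography (CCTA), where the
iodinated contrast raises the whole arterial lumen above 130 HU so that only
a scan-specific threshold (aortic blood-pool mean + 3 SD) separates calcium
from lumen. That intensity relationship — not anatomical realism — is what
the voxel classifier and the domain-adaptation stage consume, so the
geometry is deliberately schematic:

* an air background with an ellipsoidal soft-tissue "body",
* skeletal structures (spine, sternum, ribs) of heterogeneous bone density —
  in chest CT without contrast these are the dominant supra-threshold
  tissue, so they are what a calcium detector must mostly learn to reject,
* an ellipsoidal heart: a myocardial shell of slightly elevated HU around a
  blood-pool compartment that takes blood HU in NCCT and the scan's contrast
  level in CCTA (contrast fills the cardiac chambers, not just the coronary
  lumen — the dominant appearance difference between the two domains),
* three tubular coronary arteries (LAD anterior, LCX left, RCA right)
  running down the heart surface,
* an ascending-aorta cylinder containing the thresholding ROI,
* calcified lesions as compact ellipsoidal blobs attached to the artery
  walls, with volumes drawn from a log-normal fitted to a published clinical
  summary (median 7.1 mm^3, quartiles 1.6 / 29.2 mm^3, 95th percentile
  188 mm^3),
* optional extra-coronary decoy calcifications near the aortic valve and
  root: *curvilinear* arcs on the aortic wall, the shape aortic and valvular
  calcium takes in practice and the classic false positive of automatic
  calcium scoring. Compact-versus-curvilinear shape, not position alone,
  is what separates decoys from coronary lesions.

Every sample is bit-reproducible from its integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm

from .io_ct import (
    ARTERY_NAMES,
    CacudaError,
    CTVolume,
    LesionLabelMap,
    write_label_map,
    write_mask,
    write_volume,
)

SOURCE_NCCT = "source_ncct"
TARGET_CCTA = "target_ccta"

#: Fixed calcium-detection threshold used in non-contrast CT.
NCCT_THRESHOLD_HU = 130.0

#: Published training-set summary of per-lesion calcium volume (mm^3).
CAC_VOLUME_QUANTILES = {0.25: 1.6, 0.50: 7.1, 0.75: 29.2, 0.95: 188.0}

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class PhantomError(CacudaError):
    pass


def fit_lognormal_to_quantiles(quantiles: dict[float, float] | None = None
                               ) -> tuple[float, float]:
    """Fit (mu, sigma) of a log-normal to printed quantiles by least squares.

    A log-normal satisfies ``log q_p = mu + sigma * z_p`` with ``z_p`` the
    standard-normal quantile, so the two parameters are the intercept and
    slope of a straight line through the printed ``(z_p, log q_p)`` points —
    solved exactly for two quantiles and in the least-squares sense for more.
    """
    if quantiles is None:
        quantiles = CAC_VOLUME_QUANTILES
    if len(quantiles) < 2:
        raise PhantomError("need at least two quantiles to fit a log-normal")
    probs = np.array(sorted(quantiles))
    z = norm.ppf(probs)
    y = np.log([quantiles[p] for p in sorted(quantiles)])
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(z), z]), y, rcond=None)
    mu, sigma = float(coef[0]), float(coef[1])
    if sigma <= 0:
        raise PhantomError("quantiles imply non-increasing distribution")
    return mu, sigma


#: Default lesion-volume model: log-normal fitted to CAC_VOLUME_QUANTILES.
LESION_VOLUME_LOGNORMAL = fit_lognormal_to_quantiles()


@dataclass
class PhantomParams:
    """Knobs of the phantom generator. Defaults are the desk-scale study conditions."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    domain: str = SOURCE_NCCT
    #: per-scan contrast level of the arterial/aortic lumen (target domain only)
    lumen_hu_range: tuple[float, float] = (250.0, 600.0)
    tissue_hu: float = 35.0
    heart_hu: float = 55.0
    blood_hu: float = 45.0  # unenhanced lumen (source domain)
    noise_sd_hu: float = 10.0
    lesion_count_range: tuple[int, int] = (0, 6)
    lesion_volume_lognormal: tuple[float, float] = LESION_VOLUME_LOGNORMAL
    #: physical cap on a single lesion (truncated resampling). The fitted
    #: log-normal extrapolates a tail far beyond anything anatomically
    #: plausible for a 2 mm-radius coronary artery; 625 mm^3 is the largest
    #: clinically reported lesion in the source data this phantom emulates.
    lesion_volume_max_mm3: float = 625.0
    #: HU margin of lesion voxels above the applicable detection threshold
    lesion_hu_offset: float = 170.0
    extracoronary_prob: float = 0.6
    artery_radius_mm: float = 2.0
    aorta_radius_mm: float = 10.0
    #: per-scan random rotation of the cardiac complex (degrees per axis);
    #: emulates the pose variability of a clinical cohort
    pose_rotation_deg: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise PhantomError(f"bad grid_shape {self.grid_shape}")
        if int(np.prod(self.grid_shape)) < 32 ** 3:
            raise PhantomError("grid volume must be at least 32^3 voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomError("spacing must be positive")
        if self.domain not in (SOURCE_NCCT, TARGET_CCTA):
            raise PhantomError(f"unknown domain {self.domain!r}")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise PhantomError(f"bad lesion_count_range {self.lesion_count_range}")
        if self.noise_sd_hu < 0 or self.lesion_hu_offset <= 0:
            raise PhantomError("noise_sd_hu must be >= 0 and lesion_hu_offset > 0")
        if not (0.0 <= self.extracoronary_prob <= 1.0):
            raise PhantomError("extracoronary_prob must be a probability")
        if self.lesion_volume_lognormal[1] <= 0:
            raise PhantomError("lesion volume log-sd must be positive")


@dataclass
class PhantomSample:
    """One generated scan: image, reference labels, heart mask, aorta ROI."""

    volume: CTVolume
    labels: LesionLabelMap
    heart_mask: np.ndarray
    #: half-open index box ((x0, y0, z0), (x1, y1, z1)) inside the ascending aorta
    aorta_roi: tuple[tuple[int, int, int], tuple[int, int, int]]
    domain: str
    seed: int
    lumen_hu: float | None
    threshold_hu: float
    n_lesions_placed: int
    n_lesions_dropped: int
    reference_volume_mm3: dict[str, float]
    decoy_voxels: int

    @property
    def total_reference_volume_mm3(self) -> float:
        return float(sum(self.reference_volume_mm3.values()))


# ---------------------------------------------------------------------------
# Geometry helpers (all in physical mm; physical = index * spacing)
# ---------------------------------------------------------------------------

def _grids(params: PhantomParams):
    nx, ny, nz = params.grid_shape
    sx, sy, sz = params.spacing_mm
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    return np.meshgrid(x, y, z, indexing="ij")


def _ellipsoid_mask(X, Y, Z, center, semi) -> np.ndarray:
    return (((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2) <= 1.0


def _artery_curve(semi, phi_deg: float, rng: np.random.Generator,
                  n_pts: int = 90) -> np.ndarray:
    """Heart-frame points (mm) of one coronary artery on the heart surface."""
    phi = math.radians(phi_deg + rng.uniform(-8.0, 8.0))
    psi = np.radians(np.linspace(32.0, 142.0, n_pts))
    # small lateral wobble so the tube is a curve, not a perfect arc
    wob = rng.uniform(-0.08, 0.08)
    pts = np.stack([
        semi[0] * np.sin(psi) * np.cos(phi + wob * np.sin(3 * psi)),
        semi[1] * np.sin(psi) * np.sin(phi + wob * np.sin(3 * psi)),
        semi[2] * np.cos(psi),
    ], axis=1)
    return pts


def _rotation_matrix(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    """Random small 3D rotation (Euler angles uniform in +/- max_deg)."""
    ax, ay, az = np.radians(rng.uniform(-max_deg, max_deg, size=3))
    cx, sx_ = math.cos(ax), math.sin(ax)
    cy, sy_ = math.cos(ay), math.sin(ay)
    cz, sz_ = math.cos(az), math.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
    Ry = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
    Rz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _tube_mask(shape, spacing, curve_pts: np.ndarray, radius_mm: float) -> np.ndarray:
    """Voxels within ``radius_mm`` of a polyline, via a KD-tree on curve samples."""
    lo = np.maximum(np.floor((curve_pts.min(0) - radius_mm) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((curve_pts.max(0) + radius_mm) / spacing).astype(int) + 1,
                    shape)
    mask = np.zeros(shape, dtype=bool)
    if np.any(hi <= lo):
        return mask
    ix = np.arange(lo[0], hi[0])
    iy = np.arange(lo[1], hi[1])
    iz = np.arange(lo[2], hi[2])
    X, Y, Z = np.meshgrid(ix * spacing[0], iy * spacing[1], iz * spacing[2],
                          indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dist, _ = cKDTree(curve_pts).query(pts, k=1)
    sub = (dist <= radius_mm).reshape(X.shape)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def _blob_voxels(center_mm, volume_mm3, shape, spacing,
                 rng: np.random.Generator) -> np.ndarray:
    """Voxel indices of an ellipsoidal blob of approximately the given volume."""
    r0 = (3.0 * max(volume_mm3, 1e-3) / (4.0 * math.pi)) ** (1.0 / 3.0)
    u = rng.uniform(0.75, 1.35, size=3)
    u /= np.prod(u) ** (1.0 / 3.0)
    semi = np.maximum(r0 * u, 1e-3)
    lo = np.maximum(np.floor((np.asarray(center_mm) - semi) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((np.asarray(center_mm) + semi) / spacing).astype(int) + 1,
                    shape)
    if np.any(hi <= lo):
        return np.empty((0, 3), dtype=int)
    ix, iy, iz = (np.arange(lo[d], hi[d]) for d in range(3))
    X, Y, Z = np.meshgrid(ix * spacing[0], iy * spacing[1], iz * spacing[2],
                          indexing="ij")
    inside = (((X - center_mm[0]) / semi[0]) ** 2
              + ((Y - center_mm[1]) / semi[1]) ** 2
              + ((Z - center_mm[2]) / semi[2]) ** 2) <= 1.0
    idx = np.argwhere(inside)
    if idx.size == 0:
        # sub-voxel lesion: nearest voxel to the center
        nearest = np.rint(np.asarray(center_mm) / spacing).astype(int)
        if np.all(nearest >= 0) and np.all(nearest < shape):
            return nearest[None, :]
        return np.empty((0, 3), dtype=int)
    return idx + lo


def _touches(blob_idx: np.ndarray, occupied: np.ndarray) -> bool:
    """True if a blob overlaps or is 6-adjacent to already-occupied voxels."""
    if blob_idx.size == 0 or not occupied.any():
        return False
    shape = occupied.shape
    for off in ((0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)):
        nb = blob_idx + np.asarray(off)
        ok = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
        if ok.any() and occupied[tuple(nb[ok].T)].any():
            return True
    return False


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_phantom(params: PhantomParams) -> PhantomSample:
    """Generate one phantom scan; bit-deterministic for a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(n) for n in params.grid_shape)
    spacing = np.asarray(params.spacing_mm, dtype=float)
    extent = np.asarray(shape) * spacing
    X, Y, Z = _grids(params)

    body_center = extent / 2.0
    body_semi = 0.46 * extent
    heart_center = body_center + np.array([
        rng.uniform(-3.0, 3.0), rng.uniform(-3.0, 3.0), rng.uniform(-6.0, 0.0)])
    heart_semi = np.array([26.0, 24.0, 30.0]) * rng.uniform(0.92, 1.08, size=3)
    heart_semi = np.minimum(heart_semi, 0.85 * body_semi)
    R = _rotation_matrix(rng, params.pose_rotation_deg)

    body = _ellipsoid_mask(X, Y, Z, body_center, body_semi)

    # heart-frame coordinates of every voxel: q = R^T (p - heart_center)
    DX, DY, DZ = X - heart_center[0], Y - heart_center[1], Z - heart_center[2]
    QX = R[0, 0] * DX + R[1, 0] * DY + R[2, 0] * DZ
    QY = R[0, 1] * DX + R[1, 1] * DY + R[2, 1] * DZ
    QZ = R[0, 2] * DX + R[1, 2] * DY + R[2, 2] * DZ

    def _heart_ellipsoid(semi):
        return ((QX / semi[0]) ** 2 + (QY / semi[1]) ** 2
                + (QZ / semi[2]) ** 2) <= 1.0

    heart = _heart_ellipsoid(heart_semi)
    # cardiac blood pool: inner compartment of the heart; takes the same
    # contrast level as the arterial lumen in the target domain
    chamber = _heart_ellipsoid(0.72 * heart_semi)

    def _to_world(rel_pts: np.ndarray) -> np.ndarray:
        return heart_center + rel_pts @ R.T

    # coronary arteries: anterior (LAD), subject-left (LCX), subject-right (RCA)
    curves = {
        1: _to_world(_artery_curve(heart_semi, 90.0, rng)),
        2: _to_world(_artery_curve(heart_semi, 0.0, rng)),
        3: _to_world(_artery_curve(heart_semi, 180.0, rng)),
    }
    tubes = {a: _tube_mask(shape, spacing, c, params.artery_radius_mm)
             for a, c in curves.items()}
    tube_union = tubes[1] | tubes[2] | tubes[3]

    # ascending aorta: cylinder rising from the posterior heart base (tilted
    # with the cardiac pose); holds the thresholding ROI.
    ax_h = np.array([0.0, -0.45 * heart_semi[1]])
    z_lo_h = 0.25 * heart_semi[2]
    z_hi_h = 1.25 * heart_semi[2]
    aorta = ((((QX - ax_h[0])) ** 2 + ((QY - ax_h[1])) ** 2)
             <= params.aorta_radius_mm ** 2) & (QZ >= z_lo_h) & (QZ <= z_hi_h) & body

    # ROI box inside the aorta (the phantom analogue of the manually placed
    # ascending-aorta bounding box used for scan-specific thresholding)
    roi_half_mm = np.array([5.0, 5.0, 6.0])
    roi_center = _to_world(np.array([ax_h[0], ax_h[1], z_lo_h + 16.0]))
    roi_lo = np.maximum(np.rint((roi_center - roi_half_mm) / spacing).astype(int), 0)
    roi_hi = np.minimum(np.rint((roi_center + roi_half_mm) / spacing).astype(int) + 1,
                        shape)
    roi_slices = tuple(slice(int(a), int(b)) for a, b in zip(roi_lo, roi_hi))

    # skeletal structures: spine (posterior), sternum (anterior), rib arcs.
    # Bone is heterogeneous (trabecular texture) and mostly brighter than
    # 130 HU, so in the source domain it dominates the candidate background.
    bone = np.zeros(shape, dtype=bool)
    spine_y = body_center[1] - 0.72 * body_semi[1]
    spine_x = body_center[0] + rng.uniform(-3.0, 3.0)
    bone |= ((X - spine_x) ** 2 + (Y - spine_y) ** 2) <= 11.0 ** 2
    stern_y = body_center[1] + 0.78 * body_semi[1]
    stern_x = body_center[0] + rng.uniform(-3.0, 3.0)
    bone |= ((X - stern_x) ** 2 + (Y - stern_y) ** 2) <= 6.0 ** 2
    rib_r = 0.88 * min(body_semi[0], body_semi[1])
    for side in (-1.0, 1.0):
        for zk in np.linspace(0.18, 0.82, 4):
            a0 = math.pi / 2 - side * rng.uniform(0.35, 0.55)
            ang = a0 + side * np.linspace(0.0, rng.uniform(1.6, 2.2), 40)
            zr = zk * extent[2] + rng.uniform(-3.0, 3.0) \
                + 8.0 * np.linspace(0.0, 1.0, 40)  # ribs slope downward
            rib = np.stack([body_center[0] + side * rib_r * np.cos(ang),
                            body_center[1] + rib_r * np.sin(ang) * 0.9,
                            zr], axis=1)
            bone |= _tube_mask(shape, spacing, rib, 3.5)
    bone &= body

    # --- intensities -------------------------------------------------------
    vol = np.full(shape, -1000.0, dtype=np.float64)
    vol[body] = params.tissue_hu
    n_bone = int(bone.sum())
    if n_bone:
        vol[bone] = (rng.uniform(220.0, 420.0)
                     + rng.normal(0.0, 60.0, size=n_bone))
        np.maximum(vol, -1000.0, out=vol)
    vol[heart] = params.heart_hu
    if params.domain == TARGET_CCTA:
        lumen_hu = float(rng.uniform(*params.lumen_hu_range))
    else:
        lumen_hu = None
    lumen_value = params.blood_hu if lumen_hu is None else lumen_hu
    vol[chamber] = lumen_value
    vol[aorta] = lumen_value
    vol[tube_union & body] = lumen_value
    vol += rng.normal(0.0, params.noise_sd_hu, size=shape)

    roi_vox = vol[roi_slices]
    if params.domain == TARGET_CCTA:
        threshold = float(roi_vox.mean() + 3.0 * roi_vox.std())
    else:
        threshold = NCCT_THRESHOLD_HU

    # --- lesions -----------------------------------------------------------
    labels = np.zeros(shape, dtype=np.uint8)
    occupied = np.zeros(shape, dtype=bool)  # lesions + decoys, for separation
    n_target = int(rng.integers(params.lesion_count_range[0],
                                params.lesion_count_range[1] + 1))
    mu, sigma = params.lesion_volume_lognormal
    placed = 0
    dropped = 0
    for _ in range(n_target):
        artery = int(rng.integers(1, 4))
        vol_mm3 = float(rng.lognormal(mu, sigma))
        for _redraw in range(50):  # truncated resampling at the physical cap
            if vol_mm3 <= params.lesion_volume_max_mm3:
                break
            vol_mm3 = float(rng.lognormal(mu, sigma))
        else:
            vol_mm3 = params.lesion_volume_max_mm3
        ok = False
        for _attempt in range(6):
            curve = curves[artery]
            k = int(rng.integers(8, len(curve) - 8))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction) + 1e-12
            center = curve[k] + direction * params.artery_radius_mm * rng.uniform(0.4, 1.0)
            blob = _blob_voxels(center, vol_mm3, shape, spacing, rng)
            if blob.size == 0:
                continue
            if aorta[tuple(blob.T)].any() or bone[tuple(blob.T)].any():
                # lesions do not sit inside the aorta or bone; contact at this
                # grid resolution would merge candidate clusters artificially
                continue
            if not body[tuple(blob.T)].all():
                continue
            if _touches(blob, occupied):
                continue  # would merge with another lesion/decoy
            labels[tuple(blob.T)] = artery
            occupied[tuple(blob.T)] = True
            ok = True
            break
        if ok:
            placed += 1
        else:
            dropped += 1

    # decoy extra-coronary calcification: a curvilinear arc on the aortic
    # wall near the valve plane (aortic-root / valve calcification), same
    # density as true calcium, background class. Its elongated shape — not
    # merely its position — is what distinguishes it from coronary lesions.
    decoy_voxels = 0
    if rng.random() < params.extracoronary_prob:
        for _attempt in range(8):
            ang0 = rng.uniform(0.0, 2.0 * math.pi)
            span = math.radians(rng.uniform(100.0, 220.0))
            z0 = z_lo_h + rng.uniform(0.0, 10.0)
            tilt = rng.uniform(-0.05, 0.05)  # slight helix along the wall
            ang = np.linspace(ang0, ang0 + span, 60)
            arc = _to_world(np.stack([
                ax_h[0] + params.aorta_radius_mm * np.cos(ang),
                ax_h[1] + params.aorta_radius_mm * np.sin(ang),
                z0 + tilt * params.aorta_radius_mm * (ang - ang0),
            ], axis=1))
            arc_mask = _tube_mask(shape, spacing, arc, 1.3)
            blob = np.argwhere(arc_mask)
            if blob.size == 0:
                continue
            dist_ok = all(cKDTree(c).query(blob * spacing, k=1)[0].min()
                          > params.artery_radius_mm + 3.0 for c in curves.values())
            if not dist_ok:
                continue
            if not body[tuple(blob.T)].all():
                continue
            if _touches(blob, occupied):
                continue
            occupied[tuple(blob.T)] = True
            noise = rng.normal(0.0, params.noise_sd_hu, size=len(blob))
            vol[tuple(blob.T)] = np.maximum(
                threshold + params.lesion_hu_offset + noise, threshold + 1.0)
            decoy_voxels = len(blob)
            break

    lesion_mask = labels > 0
    n_lesion_vox = int(lesion_mask.sum())
    if n_lesion_vox:
        noise = rng.normal(0.0, params.noise_sd_hu, size=n_lesion_vox)
        vol[lesion_mask] = np.maximum(
            threshold + params.lesion_hu_offset + noise, threshold + 1.0)

    np.clip(vol, -1024.0, 3071.0, out=vol)

    heart_mask = heart | ndimage.binary_dilation(tube_union, _STRUCT6) | lesion_mask

    voxvol = float(np.prod(spacing))
    ref_vol = {name: float((labels == a).sum()) * voxvol
               for a, name in ARTERY_NAMES.items()}

    sample = PhantomSample(
        volume=CTVolume(vol.astype(np.float32), tuple(spacing), (0.0, 0.0, 0.0)),
        labels=LesionLabelMap(labels),
        heart_mask=heart_mask,
        aorta_roi=(tuple(int(v) for v in roi_lo), tuple(int(v) for v in roi_hi)),
        domain=params.domain,
        seed=int(params.seed),
        lumen_hu=lumen_hu,
        threshold_hu=threshold,
        n_lesions_placed=placed,
        n_lesions_dropped=dropped,
        reference_volume_mm3=ref_vol,
        decoy_voxels=decoy_voxels,
    )
    _check_sample(sample)
    return sample


def _check_sample(sample: PhantomSample) -> None:
    """Post-generation invariants: labels inside the heart mask and above threshold."""
    lab = sample.labels.labels
    if np.any((lab > 0) & ~sample.heart_mask):
        raise PhantomError("labeled voxels outside the heart mask")
    if (lab > 0).any():
        lo = float(sample.volume.voxels[lab > 0].min())
        if lo < sample.threshold_hu:
            raise PhantomError(
                f"labeled voxel at {lo:.1f} HU below threshold {sample.threshold_hu:.1f}")


def generate_cohort(n_source: int, n_target: int, shared: PhantomParams,
                    seed: int) -> list[PhantomSample]:
    """Generate a two-domain cohort with reproducible per-sample seeds.

    Source samples come first. Each target sample draws its own lumen contrast
    level, emulating the varying contrast levels seen across CCTA scans.
    """
    if n_source < 0 or n_target < 0:
        raise PhantomError("cohort sizes must be non-negative")
    n = n_source + n_target
    if n == 0:
        return []
    child_seeds = np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF
    samples = []
    for i in range(n):
        domain = SOURCE_NCCT if i < n_source else TARGET_CCTA
        p = replace(shared, domain=domain, seed=int(child_seeds[i]))
        samples.append(generate_phantom(p))
    return samples


# ---------------------------------------------------------------------------
# On-disk cohorts
# ---------------------------------------------------------------------------

def write_sample(sample: PhantomSample, out_dir: str | Path, stem: str) -> dict:
    """Write image/label/mask as NIfTI and return the manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sp = sample.volume.spacing_mm
    write_volume(sample.volume, out_dir / f"{stem}_img.nii.gz")
    write_label_map(sample.labels, sp, out_dir / f"{stem}_label.nii.gz")
    write_mask(sample.heart_mask, sp, out_dir / f"{stem}_mask.nii.gz")
    row = {
        "sample_id": stem,
        "domain": sample.domain,
        "seed": sample.seed,
        "n_lesions": sample.n_lesions_placed,
        "threshold_hu": round(sample.threshold_hu, 3),
        "roi_lo": "x".join(str(v) for v in sample.aorta_roi[0]),
        "roi_hi": "x".join(str(v) for v in sample.aorta_roi[1]),
    }
    for name, v in sample.reference_volume_mm3.items():
        row[f"volume_{name.lower()}_mm3"] = round(v, 3)
    return row


def write_cohort(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    """Write a cohort plus a CSV manifest; returns the manifest path."""
    import pandas as pd

    out_dir = Path(out_dir)
    rows = []
    counters: dict[str, int] = {}
    for s in samples:
        short = "src" if s.domain == SOURCE_NCCT else "tgt"
        counters[short] = counters.get(short, 0) + 1
        rows.append(write_sample(s, out_dir, f"{short}{counters[short]:03d}"))
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
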