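"""Voxel-wise calcium detector: 2.5D orthogonal patches, generator/classifier split.

The detector classifies each candidate voxel from three co-centered 2D
patches on the orthogonal (axial, sagittal, coronal) planes. It is factored
into a feature generator ``G`` that maps patches to latent feature vectors
and a classifier ``C`` that predicts the class (background/LAD/LCX/RCA) from
the features; a discriminator ``D`` scores feature vectors as source vs
target during domain adaptation. The split is structural: ``C`` and ``D``
only ever see :class:`FeatureBatch`, never raw patches.

The generator's trunk is a small learned 2D convolution (filters shared
across the three planes) followed by dense layers; the classifier and
discriminator are dense heads. Forward and backward passes are written
directly in NumPy; parameters live in plain arrays, so training is
bit-reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_ct import CacudaError, CTVolume, LesionLabelMap, as_label_array

PAD_HU = -1000.0

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class ShapeError(CacudaError):
    pass


@dataclass
class NetConfig:
    """Architecture and preprocessing configuration.

    ``patch_size`` must be odd so the candidate voxel is the center pixel;
    65 px is the desk-scale default, 155 px matches clinical-resolution use.
    ``pool`` mean-pools each plane by that factor before the dense trunk.
    The HU window (``hu_center``, ``hu_width``) maps intensities to [0, 1].
    """

    patch_size: int = 65
    g_hidden: tuple[int, ...] = (128,)
    feature_dim: int = 64
    n_classes: int = 4
    d_widths: tuple[int, ...] = (32,)
    hu_center: float = 300.0
    hu_width: float = 1400.0
    pool: int = 1
    g_activation: str = "relu"
    #: (n_filters, kernel, stride) of the shared 2D conv applied to each
    #: orthogonal plane before the dense trunk; None for a pooled-MLP trunk
    g_conv: tuple[int, int, int] | None = (6, 5, 2)

    def __post_init__(self) -> None:
        if self.n_classes != 4:
            raise ShapeError("detector is defined for 4 classes (bg/LAD/LCX/RCA)")
        if self.patch_size % 2 != 1 or self.patch_size < 3:
            raise ShapeError("patch_size must be odd and >= 3")
        if self.pool < 1 or self.patch_size % self.pool != 0:
            raise ShapeError("pool must divide patch_size")
        if self.hu_width <= 0:
            raise ShapeError("hu_width must be positive")
        if self.g_conv is not None:
            self.g_conv = tuple(int(v) for v in self.g_conv)
            kf, k, s = self.g_conv
            if kf < 1 or s < 1 or not (1 <= k <= self.patch_size):
                raise ShapeError(f"bad conv spec {self.g_conv}")

    @property
    def pooled_size(self) -> int:
        return self.patch_size // self.pool

    @property
    def conv_out_size(self) -> int:
        if self.g_conv is None:
            raise ShapeError("no conv trunk configured")
        _, k, s = self.g_conv
        return (self.patch_size - k) // s + 1

    @property
    def input_dim(self) -> int:
        """Flattened width entering the dense trunk."""
        if self.g_conv is not None:
            return 3 * self.g_conv[0] * self.conv_out_size ** 2
        return 3 * self.pooled_size ** 2


@dataclass
class OrthoPatchSet:
    """Three co-centered normalized 2D patches around one candidate voxel."""

    axial: np.ndarray
    sagittal: np.ndarray
    coronal: np.ndarray
    center_index: tuple[int, int, int]


@dataclass
class FeatureBatch:
    """Latent feature vectors ``G(x)`` with their domain tag."""

    features: np.ndarray
    domain_tag: str = "source"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ShapeError("features must be (batch, feature_dim)")
        if not np.all(np.isfinite(self.features)):
            raise ShapeError("features must be finite")


def normalize_hu(values: np.ndarray, cfg: NetConfig) -> np.ndarray:
    """Map the configured HU window to [0, 1], clipping outside it."""
    lo = cfg.hu_center - cfg.hu_width / 2.0
    return np.clip((np.asarray(values, dtype=np.float32) - lo) / cfg.hu_width, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Candidate voxels and patch extraction
# ---------------------------------------------------------------------------

def candidate_voxels(volume: CTVolume, threshold_hu: float,
                     heart_mask: np.ndarray | None = None,
                     min_cluster: int = 3) -> np.ndarray:
    """Supra-threshold voxels in 6-connected clusters of >= ``min_cluster``.

    Mirrors the annotation convention that only regions of at least three
    adjacent voxels above the threshold are considered calcium candidates.
    Returns an ``(N, 3)`` index array in lexicographic order.
    """
    if not np.isfinite(threshold_hu):
        raise ShapeError("threshold must be finite")
    mask = volume.voxels > threshold_hu
    if heart_mask is not None:
        if heart_mask.shape != mask.shape:
            raise ShapeError("heart mask shape mismatch")
        mask &= heart_mask.astype(bool)
    if not mask.any():
        return np.empty((0, 3), dtype=np.int64)
    comp, n = ndimage.label(mask, structure=_STRUCT6)
    sizes = np.bincount(comp.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_cluster
    return np.argwhere(keep[comp]).astype(np.int64)


class PatchExtractor:
    """Extracts normalized orthogonal patch batches from one volume.

    The volume is normalized once and padded with the normalized equivalent
    of -1000 HU so that patches at the volume border keep their size.
    """

    def __init__(self, volume: CTVolume, cfg: NetConfig):
        self.cfg = cfg
        self.shape = volume.shape
        h = cfg.patch_size // 2
        self.h = h
        norm = normalize_hu(volume.voxels, cfg)
        pad_val = float(normalize_hu(np.array([PAD_HU]), cfg)[0])
        self.padded = np.pad(norm, h, mode="constant", constant_values=pad_val)

    def batch(self, centers: np.ndarray, rng: np.random.Generator | None = None,
              jitter: int = 0) -> np.ndarray:
        """Return ``(N, 3, p, p)`` patch stacks for the given centers.

        With ``rng`` and ``jitter > 0`` the patch center is randomly shifted
        by up to ``jitter`` voxels per axis (training augmentation; the
        classified voxel is unchanged). Inference calls are deterministic.
        """
        centers = np.asarray(centers, dtype=np.int64).reshape(-1, 3)
        if np.any(centers < 0) or np.any(centers >= np.asarray(self.shape)):
            raise ShapeError("patch centers must lie inside the volume")
        if rng is not None and jitter > 0:
            shift = rng.integers(-jitter, jitter + 1, size=centers.shape)
            centers = np.clip(centers + shift, 0, np.asarray(self.shape) - 1)
        p = self.cfg.patch_size
        out = np.empty((len(centers), 3, p, p), dtype=np.float32)
        V = self.padded
        h = self.h
        for i, (cx, cy, cz) in enumerate(centers):
            # padded coordinates of the center are (c + h)
            out[i, 0] = V[cx:cx + p, cy:cy + p, cz + h]            # axial (x,y)
            out[i, 1] = V[cx + h, cy:cy + p, cz:cz + p]            # sagittal (y,z)
            out[i, 2] = V[cx:cx + p, cy + h, cz:cz + p]            # coronal (x,z)
        return out


def extract_patches(volume: CTVolume, centers, cfg: NetConfig,
                    rng: np.random.Generator | None = None,
                    jitter: int = 0) -> list[OrthoPatchSet]:
    """Orthogonal patch sets for a list of candidate voxel centers."""
    centers = np.asarray(centers, dtype=np.int64).reshape(-1, 3)
    if len(centers) == 0:
        return []
    ex = PatchExtractor(volume, cfg)
    stacks = ex.batch(centers, rng=rng, jitter=jitter)
    return [OrthoPatchSet(s[0], s[1], s[2], tuple(int(v) for v in c))
            for s, c in zip(stacks, centers)]


# ---------------------------------------------------------------------------
# Networks (NumPy MLPs with explicit gradients)
# ---------------------------------------------------------------------------

class _MLPCore:
    """Shared machinery: parameter list of (W, b) pairs, nonlinear hidden layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 activation: str = "relu"):
        if activation not in ("relu", "tanh"):
            raise ShapeError(f"unknown activation {activation!r}")
        self.activation = activation
        self.params: list[np.ndarray] = []
        gain = 2.0 if activation == "relu" else 1.0  # He / Xavier scaling
        for a, b in zip(dims[:-1], dims[1:]):
            self.params.append(rng.normal(0.0, np.sqrt(gain / a), size=(a, b)))
            self.params.append(np.zeros(b))

    def copy(self):
        import copy as _copy
        new = _copy.copy(self)
        new.params = [p.copy() for p in self.params]
        return new

    def _affine_stack(self, x: np.ndarray, params: list[np.ndarray] | None = None):
        """Forward through the dense layers; returns output + activation cache."""
        if params is None:
            params = self.params
        acts = [x]
        n_layers = len(params) // 2
        for li in range(n_layers):
            W, b = params[2 * li], params[2 * li + 1]
            z = acts[-1] @ W + b
            if li < n_layers - 1:
                z = np.tanh(z) if self.activation == "tanh" else np.maximum(z, 0.0)
            acts.append(z)
        return acts[-1], acts

    def _affine_grads(self, acts, dout, params: list[np.ndarray] | None = None):
        """Backprop through the dense layers; returns (grads, d_input)."""
        if params is None:
            params = self.params
        grads = [None] * len(params)
        n_layers = len(params) // 2
        d = dout
        for li in reversed(range(n_layers)):
            W = params[2 * li]
            a_in = acts[li]
            if li < n_layers - 1:
                a_out = acts[li + 1]
                d = d * (1.0 - a_out ** 2) if self.activation == "tanh" \
                    else d * (a_out > 0)
            grads[2 * li] = a_in.T @ d
            grads[2 * li + 1] = d.sum(axis=0)
            d = d @ W.T
        return grads, d


def _im2col_indices(p: int, k: int, s: int) -> np.ndarray:
    """Flat gather indices of all k x k windows at stride s in a p x p plane."""
    q = (p - k) // s + 1
    starts = np.arange(q) * s
    win = np.arange(k)
    rows = (starts[:, None] + win[None, :])          # (q, k)
    # window (a, b) covers rows[a] x rows[b]
    idx = (rows[:, None, :, None] * p + rows[None, :, None, :])
    return idx.reshape(q * q, k * k)


class FeatureGenerator(_MLPCore):
    """G: orthogonal patches -> latent feature vector.

    The trunk is a single learned 2D convolution (filters shared across the
    three orthogonal planes) followed by a dense stack. The conv layer is
    what makes the generator respond *coherently* to region-wise intensity
    changes — each filter's DC gain shifts every activation inside a
    contrast-enhanced region by the same amount — which is both how real
    detectors behave under a contrast domain shift and what adversarial
    feature alignment recalibrates. A pooled-MLP trunk (``g_conv=None``)
    remains available.
    """

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        super().__init__([cfg.input_dim, *cfg.g_hidden, cfg.feature_dim], rng,
                         activation=cfg.g_activation)
        self._n_dense = len(self.params)
        if cfg.g_conv is not None:
            kf, k, s = cfg.g_conv
            gain = 2.0 if cfg.g_activation == "relu" else 1.0
            Wc = rng.normal(0.0, np.sqrt(gain / (k * k)), size=(k * k, kf))
            self.params = [Wc, np.zeros(kf)] + self.params
            self._col_idx = _im2col_indices(cfg.patch_size, k, s)

    def _dense_params(self):
        return self.params[-self._n_dense:]

    def _check(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.cfg.patch_size:
            raise ShapeError(
                f"expected (N, 3, {self.cfg.patch_size}, {self.cfg.patch_size}) "
                f"patches, got {x.shape}")
        return x

    def _nonlin(self, z):
        return np.tanh(z) if self.activation == "tanh" else np.maximum(z, 0.0)

    def forward(self, patches: np.ndarray):
        x = self._check(patches)
        n = len(x)
        if self.cfg.g_conv is None:
            k = self.cfg.pool
            if k > 1:
                q = self.cfg.pooled_size
                x = x.reshape(n, 3, q, k, q, k).mean(axis=(3, 5))
            feats, acts = self._affine_stack(x.reshape(n, -1), self._dense_params())
            return feats, (None, None, acts)
        Wc, bc = self.params[0], self.params[1]
        cols = x.reshape(n * 3, -1)[:, self._col_idx]      # (3n, Q, k*k)
        ac = self._nonlin(cols @ Wc + bc)                  # (3n, Q, F)
        feats, acts = self._affine_stack(ac.reshape(n, -1), self._dense_params())
        return feats, (cols, ac, acts)

    def backward(self, cache, dfeat):
        cols, ac, acts = cache
        dense_grads, dh = self._affine_grads(acts, dfeat, self._dense_params())
        if self.cfg.g_conv is None:
            return dense_grads
        dac = dh.reshape(ac.shape)
        dzc = dac * (1.0 - ac ** 2) if self.activation == "tanh" \
            else dac * (ac > 0)
        dWc = np.tensordot(cols, dzc, axes=([0, 1], [0, 1]))
        dbc = dzc.sum(axis=(0, 1))
        return [dWc, dbc] + dense_grads


class Classifier(_MLPCore):
    """C: latent features -> class probabilities over {bg, LAD, LCX, RCA}."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        super().__init__([cfg.feature_dim, cfg.n_classes], rng)

    def forward(self, features: np.ndarray):
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != self.cfg.feature_dim:
            raise ShapeError(f"expected (N, {self.cfg.feature_dim}) features")
        logits, acts = self._affine_stack(features)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p, acts

    def backward_ce(self, acts, probs, labels, weight: float = 1.0):
        """Gradients of mean cross-entropy; returns (param grads, dfeatures)."""
        n = len(probs)
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits *= weight / n
        return self._affine_grads(acts, dlogits)


class Discriminator(_MLPCore):
    """D: latent features -> domain score (sigmoid in (0,1), or linear critic)."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator,
                 critic: str = "sigmoid"):
        self.cfg = cfg
        if critic not in ("sigmoid", "linear"):
            raise ShapeError(f"unknown critic type {critic!r}")
        self.critic = critic
        super().__init__([cfg.feature_dim, *cfg.d_widths, 1], rng)

    def forward(self, features: np.ndarray):
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != self.cfg.feature_dim:
            raise ShapeError(f"expected (N, {self.cfg.feature_dim}) features")
        z, acts = self._affine_stack(features)
        z = z[:, 0]
        if self.critic == "sigmoid":
            score = 1.0 / (1.0 + np.exp(-z))
        else:
            score = z
        return score, (acts, z)

    def backward(self, cache, dlogit):
        """Gradients w.r.t. the pre-sigmoid logit; returns (grads, dfeatures)."""
        acts, _ = cache
        return self._affine_grads(acts, np.asarray(dlogit).reshape(-1, 1))


# Thin functional surface -----------------------------------------------------

def forward_G(G: FeatureGenerator, patches: np.ndarray,
              domain_tag: str = "source") -> FeatureBatch:
    feats, _ = G.forward(patches)
    return FeatureBatch(feats, domain_tag)


def forward_C(C: Classifier, batch: FeatureBatch) -> np.ndarray:
    """Class probabilities; rows sum to 1 (within 1e-6)."""
    probs, _ = C.forward(batch.features)
    return probs


def forward_D(D: Discriminator, batch: FeatureBatch) -> np.ndarray:
    """One bounded domain score per feature vector (sigmoid critic: in (0,1))."""
    scores, _ = D.forward(batch.features)
    return scores


# ---------------------------------------------------------------------------
# Whole-volume prediction
# ---------------------------------------------------------------------------

def predict_volume(volume: CTVolume, G: FeatureGenerator, C: Classifier,
                   threshold_hu: float, heart_mask: np.ndarray | None,
                   cfg: NetConfig, chunk: int = 512) -> LesionLabelMap:
    """Classify every candidate voxel of a scan into a label map.

    Candidates are supra-threshold 6-connected clusters of at least three
    voxels; every candidate gets the argmax class of ``C(G(patches))``.
    Non-candidates are background. Ties resolve toward background, then the
    lowest class id (argmax returns the first maximum, and class 0 is
    background, which implements exactly that policy).
    """
    centers = candidate_voxels(volume, threshold_hu, heart_mask)
    labels = np.zeros(volume.shape, dtype=np.uint8)
    if len(centers) == 0:
        return LesionLabelMap(labels)
    ex = PatchExtractor(volume, cfg)
    for start in range(0, len(centers), chunk):
        sub = centers[start:start + chunk]
        probs = forward_C(C, forward_G(G, ex.batch(sub)))
        cls = probs.argmax(axis=1).astype(np.uint8)
        labels[tuple(sub.T)] = cls
    return LesionLabelMap(labels)


# ---------------------------------------------------------------------------
# Candidate datasets for training
# ---------------------------------------------------------------------------

@dataclass
class CandidateDataset:
    """Candidate patches of a labeled cohort, with per-epoch jitter augmentation."""

    extractors: list[PatchExtractor]
    centers: list[np.ndarray]
    labels: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (len(self.extractors) == len(self.centers) == len(self.labels)):
            raise ShapeError("per-scan lists must have equal length")

    @property
    def n_examples(self) -> int:
        return int(sum(len(c) for c in self.centers))

    def epoch(self, rng: np.random.Generator | None = None, jitter: int = 2):
        """All candidate patches (optionally jittered) and their labels."""
        xs, ys = [], []
        for ex, cen, lab in zip(self.extractors, self.centers, self.labels):
            if len(cen) == 0:
                continue
            xs.append(ex.batch(cen, rng=rng, jitter=jitter if rng is not None else 0))
            ys.append(np.asarray(lab))
        if not xs:
            return (np.empty((0, 3, 1, 1), dtype=np.float32), np.empty(0, dtype=int))
        return np.concatenate(xs), np.concatenate(ys)


def build_candidate_dataset(volumes: list[CTVolume],
                            label_maps: list[LesionLabelMap | np.ndarray] | None,
                            thresholds: list[float],
                            cfg: NetConfig,
                            max_bg_per_scan: int | None = None) -> CandidateDataset:
    """Candidate voxels + reference labels for a cohort (labels optional).

    ``max_bg_per_scan`` caps the background candidates kept per scan by a
    deterministic stride (bone alone yields thousands of supra-threshold
    voxels per non-contrast scan, far more than needed for training).
    """
    extractors, centers, labels = [], [], []
    for i, vol in enumerate(volumes):
        cen = candidate_voxels(vol, thresholds[i])
        if label_maps is None:
            lab = np.zeros(len(cen), dtype=np.int64)
        else:
            arr = as_label_array(label_maps[i])
            lab = (arr[tuple(cen.T)].astype(np.int64) if len(cen) else
                   np.zeros(0, dtype=np.int64))
        if max_bg_per_scan is not None and (lab == 0).sum() > max_bg_per_scan:
            bg = np.nonzero(lab == 0)[0]
            step = max(1, len(bg) // max_bg_per_scan)
            keep = np.concatenate([np.nonzero(lab > 0)[0], bg[::step][:max_bg_per_scan]])
            keep.sort()
            cen, lab = cen[keep], lab[keep]
        extractors.append(PatchExtractor(vol, cfg))
        centers.append(cen)
        labels.append(lab)
    return CandidateDataset(extractors, centers, labels)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(path: str | Path, cfg: NetConfig, G: FeatureGenerator,
               C: Classifier, D: Discriminator | None = None) -> None:
    """Save G/C(/D) parameters with the config embedded."""
    arrays = {f"g_{i}": p for i, p in enumerate(G.params)}
    arrays.update({f"c_{i}": p for i, p in enumerate(C.params)})
    if D is not None:
        arrays.update({f"d_{i}": p for i, p in enumerate(D.params)})
        arrays["d_critic"] = np.array(D.critic)
    arrays["config_json"] = np.array(json.dumps(asdict(cfg)))
    with open(Path(path), "wb") as fh:  # keep the exact path (no .npz appended)
        np.savez(fh, **arrays)


def load_model(path: str | Path):
    """Load a checkpoint; returns (cfg, G, C, D-or-None)."""
    data = np.load(Path(path), allow_pickle=False)
    cfg = NetConfig(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in json.loads(str(data["config_json"])).items()})
    rng = np.random.default_rng(0)
    G = FeatureGenerator(cfg, rng)
    C = Classifier(cfg, rng)
    G.params = [data[f"g_{i}"] for i in range(len(G.params))]
    C.params = [data[f"c_{i}"] for i in range(len(C.params))]
    D = None
    if "d_0" in data:
        D = Discriminator(cfg, rng, critic=str(data["d_critic"]))
        D.params = [data[f"d_{i}"] for i in range(len(D.params))]
    return cfg, G, C, D
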