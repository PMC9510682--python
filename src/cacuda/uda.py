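"""Adversarial unsupervised domain adaptation of the calcium detector.

The detector's feature generator ``G`` (trained supervised on the labeled
source domain) is adapted to an unlabeled target domain by aligning the two
feature distributions adversarially: a discriminator ``D`` is trained to
tell source features from target features by maximizing

    L_adv = E_t[ log D(G(x_t)) ] - E_s[ log D(G(x_s)) ]

while ``G`` is trained to minimize ``L_adv + alpha * L_cls``, where ``L_cls``
is the source-domain cross-entropy through the *frozen* classifier ``C`` —
the constraint that prevents adversarial updates from forgetting the
classification task. The schedule follows the Wasserstein-GAN heuristics:
the discriminator is pretrained alone, then updated ``d_steps_per_g`` times
per generator step with its weights clipped to a compact box after every
update; both are optimized with RMSProp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_ct import CacudaError
from .network import CandidateDataset, Classifier, Discriminator, FeatureGenerator

_EPS_SCORE = 1e-7


class UdaError(CacudaError):
    pass


class UdaDivergenceError(UdaError):
    """Adversarial loss exceeded the configured bound; training aborted."""


@dataclass
class UdaConfig:
    """Adaptation hyper-parameters. Defaults are the published schedule."""

    alpha: float = 2.0
    d_pretrain_iters: int = 1000
    d_steps_per_g: int = 20
    clip_low: float = -0.1
    clip_high: float = 0.1
    lr_d: float = 5e-4
    lr_g: float = 5e-5
    optimizer: str = "rmsprop"
    epochs: int = 200
    batch_size: int = 32
    critic: str = "sigmoid"
    divergence_bound: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise UdaError("alpha must be >= 0")
        if not (self.clip_low < 0.0 < self.clip_high):
            raise UdaError("clip bounds must straddle zero")
        if self.lr_d <= 0 or self.lr_g <= 0:
            raise UdaError("learning rates must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise UdaError("bad batch size or epoch count")


@dataclass
class SourceTrainConfig:
    """Supervised source-domain training (Adam, cross-entropy, balanced batches)."""

    epochs: int = 30
    batch_size: int = 32
    lr: float = 5e-4
    jitter: int = 2
    seed: int = 0


@dataclass
class TrainState:
    """Iteration counters and running losses of an adaptation run."""

    d_steps: int = 0
    g_steps: int = 0
    log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def adversarial_loss(d_source_scores: np.ndarray,
                     d_target_scores: np.ndarray) -> float:
    """``mean(log d_target) - mean(log d_source)``.

    ``G`` minimizes this quantity, ``D`` maximizes it. Scores are clamped to
    ``[1e-7, 1 - 1e-7]`` before the logarithm so the loss is defined at the
    boundary of the sigmoid range.
    """
    ds = np.asarray(d_source_scores, dtype=np.float64)
    dt = np.asarray(d_target_scores, dtype=np.float64)
    if ds.size == 0 or dt.size == 0:
        raise UdaError("score batches must be non-empty")
    if np.any(ds <= 0) or np.any(ds >= 1) or np.any(dt <= 0) or np.any(dt >= 1):
        raise UdaError("scores must lie in the open interval (0, 1)")
    ds = np.clip(ds, _EPS_SCORE, 1.0 - _EPS_SCORE)
    dt = np.clip(dt, _EPS_SCORE, 1.0 - _EPS_SCORE)
    return float(np.mean(np.log(dt)) - np.mean(np.log(ds)))


def classification_loss(class_probs: np.ndarray, reference_labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of normalized predictions."""
    p = np.asarray(class_probs, dtype=np.float64)
    y = np.asarray(reference_labels)
    if p.ndim != 2 or len(p) != len(y):
        raise UdaError("probs must be (N, K) matching N labels")
    if np.any(y < 0) or np.any(y >= p.shape[1]):
        raise UdaError(f"labels must lie in [0, {p.shape[1] - 1}]")
    return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None))))


# ---------------------------------------------------------------------------
# Optimizers (plain NumPy, parameter lists)
# ---------------------------------------------------------------------------

class RMSProp:
    def __init__(self, params: list[np.ndarray], lr: float,
                 rho: float = 0.99, eps: float = 1e-8):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self.sq = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, s in zip(self.params, grads, self.sq):
            s *= self.rho
            s += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s) + self.eps)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.lr = params, lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def clip_discriminator(D: Discriminator, cfg: UdaConfig) -> Discriminator:
    """Clamp every discriminator parameter into [clip_low, clip_high]. Idempotent."""
    for p in D.params:
        np.clip(p, cfg.clip_low, cfg.clip_high, out=p)
    return D


# ---------------------------------------------------------------------------
# Minibatch plumbing
# ---------------------------------------------------------------------------

class _Stream:
    """Endless shuffled minibatches over an array (optionally with labels)."""

    def __init__(self, X: np.ndarray, y: np.ndarray | None,
                 batch: int, rng: np.random.Generator):
        if len(X) == 0:
            raise UdaError("empty batch stream")
        self.X, self.y, self.batch, self.rng = X, y, batch, rng

    def next(self):
        idx = self.rng.integers(0, len(self.X), size=min(self.batch, len(self.X)))
        if self.y is None:
            return self.X[idx]
        return self.X[idx], self.y[idx]


def _adv_logit_grads(z_s: np.ndarray, z_t: np.ndarray, sign: float,
                     critic: str) -> tuple[np.ndarray, np.ndarray]:
    """d(sign * L_adv)/dz for source and target logit batches.

    For the sigmoid critic, ``log D = -softplus(-z)`` so
    ``d log D / dz = sigmoid(-z)``; the linear critic uses the scores
    directly (Wasserstein-style), so the derivative is constant.
    """
    if critic == "sigmoid":
        gt = sign * _sigmoid(-z_t) / len(z_t)
        gs = -sign * _sigmoid(-z_s) / len(z_s)
    else:
        gt = sign * np.ones_like(z_t) / len(z_t)
        gs = -sign * np.ones_like(z_s) / len(z_s)
    return gs, gt


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _adv_loss_from_logits(z_s: np.ndarray, z_t: np.ndarray, critic: str) -> float:
    if critic == "sigmoid":
        # log sigmoid(z) = -softplus(-z), computed stably
        return float(np.mean(-np.logaddexp(0.0, -z_t)) - np.mean(-np.logaddexp(0.0, -z_s)))
    return float(np.mean(z_t) - np.mean(z_s))


def _d_update(G, D, opt_d, stream_s, stream_t, cfg: UdaConfig) -> float:
    """One discriminator ascent step on L_adv, followed by weight clipping."""
    xs = stream_s.next()
    xt = stream_t.next()
    if isinstance(xs, tuple):
        xs = xs[0]
    fs, _ = G.forward(xs)
    ft, _ = G.forward(xt)
    _, cache_s = D.forward(fs)
    _, cache_t = D.forward(ft)
    z_s, z_t = cache_s[1], cache_t[1]
    loss = _adv_loss_from_logits(z_s, z_t, cfg.critic)
    # ascent on L_adv == descent on -L_adv
    gs, gt = _adv_logit_grads(z_s, z_t, -1.0, cfg.critic)
    grads_s, _ = D.backward(cache_s, gs)
    grads_t, _ = D.backward(cache_t, gt)
    opt_d.step([a + b for a, b in zip(grads_s, grads_t)])
    clip_discriminator(D, cfg)
    return loss


# ---------------------------------------------------------------------------
# Training procedures
# ---------------------------------------------------------------------------

def pretrain_discriminator(G: FeatureGenerator, D: Discriminator,
                           source_batches, target_batches,
                           cfg: UdaConfig) -> Discriminator:
    """Train D alone for ``d_pretrain_iters`` with G (and C) untouched.

    ``source_batches``/``target_batches`` are objects with a ``next()``
    method yielding patch (or feature-input) arrays, e.g. :class:`_Stream`s
    built by :func:`train_uda`, or arrays (wrapped internally).
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(source_batches, np.ndarray):
        source_batches = _Stream(source_batches, None, cfg.batch_size, rng)
    if isinstance(target_batches, np.ndarray):
        target_batches = _Stream(target_batches, None, cfg.batch_size, rng)
    opt_d = RMSProp(D.params, cfg.lr_d)
    for _ in range(cfg.d_pretrain_iters):
        _d_update(G, D, opt_d, source_batches, target_batches, cfg)
    return D


def train_uda(G: FeatureGenerator, C: Classifier, D: Discriminator,
              labeled_source: tuple[np.ndarray, np.ndarray],
              unlabeled_target: np.ndarray,
              cfg: UdaConfig,
              adv_source: np.ndarray | None = None) -> tuple[FeatureGenerator, list[dict]]:
    """Adapt ``G`` to the target domain; ``C`` is frozen throughout.

    Parameters
    ----------
    labeled_source:
        ``(patches, labels)`` of source-domain candidate voxels; drives the
        classification constraint ``L_cls``.
    unlabeled_target:
        unlabeled target-domain patch array; drives the adversarial loss.
    adv_source:
        source-domain patches for the adversarial pairing. When the two
        domains' candidate sets have different class compositions, pass
        patches drawn with the *same sampling protocol* as
        ``unlabeled_target`` (e.g. random in-heart locations in both
        domains), so the discriminator sees appearance differences rather
        than composition differences. Defaults to the labeled candidates.

    Returns the adapted generator (modified in place) and a per-iteration
    log with columns iteration / l_adv / l_cls / d_acc.
    """
    Xs, ys = labeled_source
    Xt = unlabeled_target
    if len(Xs) == 0 or len(Xt) == 0:
        raise UdaError("both domains need at least one candidate patch")
    rng = np.random.default_rng(cfg.seed)
    stream_cls = _Stream(Xs, ys, cfg.batch_size, rng)
    stream_s = (_Stream(adv_source, None, cfg.batch_size, rng)
                if adv_source is not None else stream_cls)
    stream_t = _Stream(Xt, None, cfg.batch_size, rng)

    opt_d = RMSProp(D.params, cfg.lr_d)
    opt_g = RMSProp(G.params, cfg.lr_g)

    state = TrainState()
    # -- discriminator pretraining on the frozen source-trained generator
    for _ in range(cfg.d_pretrain_iters):
        _d_update(G, D, opt_d, stream_s, stream_t, cfg)
        state.d_steps += 1

    g_steps_per_epoch = max(1, math.ceil(len(Xt) / cfg.batch_size))
    total_g = cfg.epochs * g_steps_per_epoch
    for it in range(total_g):
        for _ in range(cfg.d_steps_per_g):
            _d_update(G, D, opt_d, stream_s, stream_t, cfg)
            state.d_steps += 1

        # -- one generator step: minimize L_adv + alpha * L_cls (D, C frozen)
        xs = stream_s.next()
        if isinstance(xs, tuple):
            xs = xs[0]
        xt = stream_t.next()
        fs, acts_s = G.forward(xs)
        ft, acts_t = G.forward(xt)
        _, cache_s = D.forward(fs)
        _, cache_t = D.forward(ft)
        z_s, z_t = cache_s[1], cache_t[1]
        l_adv = _adv_loss_from_logits(z_s, z_t, cfg.critic)
        if abs(l_adv) > cfg.divergence_bound:
            raise UdaDivergenceError(
                f"|L_adv| = {abs(l_adv):.2f} exceeded bound {cfg.divergence_bound} "
                f"at generator step {it}")
        gs, gt = _adv_logit_grads(z_s, z_t, +1.0, cfg.critic)
        _, dfeat_s = D.backward(cache_s, gs)
        _, dfeat_t = D.backward(cache_t, gt)
        grads = [a + b for a, b in zip(G.backward(acts_t, dfeat_t),
                                       G.backward(acts_s, dfeat_s))]

        l_cls = 0.0
        if cfg.alpha > 0:
            xc, yc = stream_cls.next()
            fc, acts_c_gen = G.forward(xc)
            probs, acts_c = C.forward(fc)
            l_cls = classification_loss(probs, yc)
            _, dfeat_cls = C.backward_ce(acts_c, probs, yc, weight=cfg.alpha)
            grads = [a + b for a, b in zip(grads, G.backward(acts_c_gen, dfeat_cls))]

        opt_g.step(grads)
        state.g_steps += 1

        d_acc = 0.5 * (np.mean(_sigmoid(z_t) > 0.5) + np.mean(_sigmoid(z_s) <= 0.5))
        state.log.append({"iteration": it, "l_adv": l_adv, "l_cls": l_cls,
                          "d_acc": float(d_acc)})
    return G, state.log


def train_source_detector(G: FeatureGenerator, C: Classifier,
                          source_data: CandidateDataset | tuple[np.ndarray, np.ndarray],
                          cfg: SourceTrainConfig) -> tuple[FeatureGenerator, Classifier, list[dict]]:
    """Supervised training of the detector (G + C jointly) on the source domain.

    Uses Adam with categorical cross-entropy on class-balanced minibatches of
    candidate voxels; patch centers are re-jittered every epoch as
    augmentation when a :class:`CandidateDataset` is given.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(G.params + C.params, cfg.lr)
    log: list[dict] = []
    it = 0
    for epoch in range(cfg.epochs):
        if isinstance(source_data, CandidateDataset):
            X, y = source_data.epoch(rng, jitter=cfg.jitter)
        else:
            X, y = source_data
        if len(X) == 0 or not np.any(y > 0):
            raise UdaError("source cohort has no calcium candidates — nothing to learn")
        by_class = [np.nonzero(y == k)[0] for k in range(C.cfg.n_classes)]
        present = [idx for idx in by_class if len(idx)]
        n_batches = max(1, math.ceil(len(X) / cfg.batch_size))
        for _ in range(n_batches):
            # class-balanced batch: classes drawn uniformly among those present
            cls_pick = rng.integers(0, len(present), size=cfg.batch_size)
            idx = np.array([present[c][rng.integers(0, len(present[c]))]
                            for c in cls_pick])
            feats, acts_g = G.forward(X[idx])
            probs, acts_c = C.forward(feats)
            loss = classification_loss(probs, y[idx])
            grads_c, dfeat = C.backward_ce(acts_c, probs, y[idx])
            grads_g = G.backward(acts_g, dfeat)
            opt.step(grads_g + grads_c)
            log.append({"iteration": it, "epoch": epoch, "loss": loss})
            it += 1
    return G, C, log
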