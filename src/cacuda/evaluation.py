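"""Agreement between automatic and reference calcium scoring.

Volume-wise metrics compare label maps voxel-by-voxel (per artery and for
total calcium, where the total is label-agnostic: an artery mislabel still
counts as detected calcium). Lesion-wise metrics match predicted to
reference lesions by shared voxels within the same artery. Cohort summaries
report mean (population SD) across scans, excluding zero-calcium scans from
sensitivity/F1 averages but including them in false-positive volumes.

Agreement of volume scores is summarized with Spearman rank correlation and
Bland-Altman 95% limits of agreement. Because scoring errors grow with the
calcium burden, the limits are heteroskedastic: the absolute differences
|auto - reference| are regressed on the square root of the pairwise mean,
and — absolute differences of a centered normal error being half-normal —
the fitted absolute difference is multiplied by 1.96 * (pi/2)^0.5 to obtain
the 95% limits  +/- 1.96 * (pi/2)^0.5 * (b + a * mean^0.5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_ct import ARTERY_NAMES, CacudaError, LesionLabelMap, as_label_array
from .scoring import Lesion

HALF_NORMAL_FACTOR = 1.96 * math.sqrt(math.pi / 2.0)

_KEYS = ("LAD", "LCX", "RCA", "total")


class EvaluationError(CacudaError):
    pass


@dataclass
class ScanEval:
    """Per-scan detection metrics, per artery and for total calcium.

    Volume fields are in mm^3; sensitivity/F1 entries are ``None`` (flagged
    undefined) when the corresponding reference is empty.
    """

    tp_volume_mm3: dict[str, float] = field(default_factory=dict)
    fn_volume_mm3: dict[str, float] = field(default_factory=dict)
    fp_volume_mm3: dict[str, float] = field(default_factory=dict)
    sensitivity_volume: dict[str, float | None] = field(default_factory=dict)
    f1_volume: dict[str, float | None] = field(default_factory=dict)
    tp_lesions: dict[str, int] = field(default_factory=dict)
    fn_lesions: dict[str, int] = field(default_factory=dict)
    fp_lesions: dict[str, int] = field(default_factory=dict)
    sensitivity_lesion: dict[str, float | None] = field(default_factory=dict)
    f1_lesion: dict[str, float | None] = field(default_factory=dict)
    n_fragmented: int = 0


def _rates(tp: float, fn: float, fp: float) -> tuple[float | None, float | None]:
    sens = tp / (tp + fn) if tp + fn > 0 else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else None
    return sens, f1


def volume_overlap_eval(pred: LesionLabelMap | np.ndarray,
                        ref: LesionLabelMap | np.ndarray,
                        spacing_mm) -> ScanEval:
    """Voxel-overlap volumes and rates per artery plus label-agnostic total."""
    p = as_label_array(pred)
    r = as_label_array(ref)
    if p.shape != r.shape:
        raise EvaluationError(f"shape mismatch {p.shape} vs {r.shape}")
    voxvol = float(np.prod(np.asarray(spacing_mm, dtype=float)))
    ev = ScanEval()
    for cls, name in ARTERY_NAMES.items():
        pm, rm = p == cls, r == cls
        tp = float(np.count_nonzero(pm & rm)) * voxvol
        fn = float(np.count_nonzero(rm & ~pm)) * voxvol
        fp = float(np.count_nonzero(pm & ~rm)) * voxvol
        ev.tp_volume_mm3[name], ev.fn_volume_mm3[name], ev.fp_volume_mm3[name] = tp, fn, fp
        ev.sensitivity_volume[name], ev.f1_volume[name] = _rates(tp, fn, fp)
    pm, rm = p > 0, r > 0
    tp = float(np.count_nonzero(pm & rm)) * voxvol
    fn = float(np.count_nonzero(rm & ~pm)) * voxvol
    fp = float(np.count_nonzero(pm & ~rm)) * voxvol
    ev.tp_volume_mm3["total"], ev.fn_volume_mm3["total"], ev.fp_volume_mm3["total"] = tp, fn, fp
    ev.sensitivity_volume["total"], ev.f1_volume["total"] = _rates(tp, fn, fp)
    return ev


def lesion_match_eval(pred_lesions: list[Lesion], ref_lesions: list[Lesion],
                      into: ScanEval | None = None) -> ScanEval:
    """Lesion-wise matching: a prediction is true-positive if it shares at
    least one voxel with a reference lesion of the same artery.

    A reference lesion matched by several predicted fragments counts once
    for sensitivity (fragments are tallied in ``n_fragmented``); predictions
    overlapping no reference are false-positive lesions.
    """
    ev = into if into is not None else ScanEval()
    ref_sets = [(L.artery, {tuple(v) for v in L.voxel_indices}) for L in ref_lesions]
    matched = np.zeros(len(ref_sets), dtype=bool)
    match_count = np.zeros(len(ref_sets), dtype=int)
    fp_by: dict[str, int] = {k: 0 for k in _KEYS[:3]}
    for pl in pred_lesions:
        pset = {tuple(v) for v in pl.voxel_indices}
        hit = False
        for j, (art, rset) in enumerate(ref_sets):
            if art == pl.artery and not pset.isdisjoint(rset):
                matched[j] = True
                match_count[j] += 1
                hit = True
        if not hit:
            fp_by[pl.artery_name] += 1
    ev.n_fragmented = int(np.count_nonzero(match_count > 1))
    for cls, name in ARTERY_NAMES.items():
        refs = [j for j, (art, _) in enumerate(ref_sets) if art == cls]
        tp = int(matched[refs].sum()) if refs else 0
        fn = len(refs) - tp
        fp = fp_by[name]
        ev.tp_lesions[name], ev.fn_lesions[name], ev.fp_lesions[name] = tp, fn, fp
        ev.sensitivity_lesion[name], ev.f1_lesion[name] = _rates(tp, fn, fp)
    tp = int(matched.sum())
    fn = len(ref_sets) - tp
    fp = sum(fp_by.values())
    ev.tp_lesions["total"], ev.fn_lesions["total"], ev.fp_lesions["total"] = tp, fn, fp
    ev.sensitivity_lesion["total"], ev.f1_lesion["total"] = _rates(tp, fn, fp)
    return ev


def _mean_sd(values: list[float]) -> dict:
    if not values:
        return {"mean": None, "sd": None, "n": 0}
    a = np.asarray(values, dtype=float)
    return {"mean": float(a.mean()), "sd": float(a.std()), "n": int(a.size)}


def aggregate_cohort(evals: list[ScanEval], key: str = "total") -> dict:
    """Mean (population SD) of per-scan metrics across a cohort.

    Sensitivity and F1 are averaged only over scans where they are defined
    (nonzero reference); FP volume and FP lesion counts are averaged over
    all scans, so zero-calcium scans contribute their false positives.
    """
    if not evals:
        raise EvaluationError("need at least one scan")
    if key not in _KEYS:
        raise EvaluationError(f"unknown aggregation key {key!r}")
    out = {}
    for metric in ("sensitivity_volume", "f1_volume",
                   "sensitivity_lesion", "f1_lesion"):
        vals = [getattr(e, metric).get(key) for e in evals]
        out[metric] = _mean_sd([v for v in vals if v is not None])
    out["fp_volume_mm3"] = _mean_sd([e.fp_volume_mm3.get(key, 0.0) for e in evals])
    out["fp_lesions"] = _mean_sd([float(e.fp_lesions.get(key, 0)) for e in evals])
    return out


# ---------------------------------------------------------------------------
# Correlation and agreement
# ---------------------------------------------------------------------------

def spearman_corr(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns ``nan`` (with a warning) for constant input, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise EvaluationError("need two equal-length 1D sequences of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("Spearman correlation undefined for constant input",
                      stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class BlandAltmanFit:
    """Heteroskedastic 95% limits of agreement.

    ``limit(mean) = +/- 1.96 * (pi/2)^0.5 * (b + a * mean^0.5)`` where
    ``(b, a)`` are intercept and slope of the ordinary-least-squares
    regression of |auto - reference| on the square root of the pairwise
    mean. The half-normal factor converts a fitted mean absolute difference
    into the 95% bound of the underlying centered normal error.
    """

    a: float
    b: float
    means: np.ndarray
    differences: np.ndarray
    degenerate: bool = False
    half_normal_factor: float = HALF_NORMAL_FACTOR

    def limit(self, mean) -> np.ndarray:
        """Magnitude of the symmetric 95% limit at the given mean volume(s)."""
        m = np.asarray(mean, dtype=float)
        return self.half_normal_factor * (self.b + self.a * np.sqrt(m))


def bland_altman_fit(auto_volumes, ref_volumes) -> BlandAltmanFit:
    """Fit the nonuniform-difference agreement model to paired volume scores."""
    a_v = np.asarray(auto_volumes, dtype=float)
    r_v = np.asarray(ref_volumes, dtype=float)
    if a_v.shape != r_v.shape or a_v.ndim != 1 or len(a_v) < 3:
        raise EvaluationError("need paired 1D volume lists of length >= 3")
    m = (a_v + r_v) / 2.0
    d = a_v - r_v
    if np.all(d == 0):
        warnings.warn("all differences are zero; agreement model degenerate",
                      stacklevel=2)
        return BlandAltmanFit(0.0, 0.0, m, d, degenerate=True)
    X = np.column_stack([np.ones_like(m), np.sqrt(m)])
    coef, *_ = np.linalg.lstsq(X, np.abs(d), rcond=None)
    return BlandAltmanFit(a=float(coef[1]), b=float(coef[0]), means=m,
                          differences=d)


def simulate_heteroskedastic_differences(a: float, b: float, n: int,
                                         rng: np.random.Generator,
                                         mean_range: tuple[float, float] = (3.0, 1500.0)
                                         ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic paired-score differences with the agreement model as truth.

    Differences are centered normal with scale
    ``(b + a * mean^0.5) * (pi/2)^0.5``, so the expected absolute difference
    is exactly ``b + a * mean^0.5`` and an OLS fit of |d| on ``mean^0.5``
    recovers ``(b, a)``. Because the error scale grows with the mean, the
    mean volumes are drawn in two clusters at the ends of ``mean_range`` —
    small-burden pairs anchor the intercept where errors are small, and
    high-burden pairs pin the slope (the classical two-point design for a
    straight line). Returns ``(means, differences)``.
    """
    lo, hi = mean_range
    m = np.concatenate([rng.uniform(lo, 7.0 * lo, size=n // 2),
                        rng.uniform(0.55 * hi, hi, size=n - n // 2)])
    scale = (b + a * np.sqrt(m)) * math.sqrt(math.pi / 2.0)
    if np.any(scale <= 0):
        raise EvaluationError("mean_range implies non-positive difference scale")
    d = scale * rng.normal(size=n)
    return m, d
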