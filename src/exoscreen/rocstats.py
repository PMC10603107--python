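"""Single-marker diagnostic statistics.

Empirical and kernel-smoothed ROC curves, trapezoidal AUC with
Hanley-McNeil standard errors, Mann-Whitney tests, the ROC arc-length
statistic, and the joint (AUC, arc length) classification of markers as
monotone or non-monotone.

The arc-length statistic exists because a marker whose case and control
distributions differ in spread but not location can have AUC near 0.5 and
still be informative: its ROC curve bows away from the diagonal on both
sides.  Arc length separates such non-monotone markers (length > 1.6, AUC
in [0.35, 0.65]) from uninformative ones (length near sqrt(2)) and from
monotone markers (length near 2 with extreme AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "RocCurve",
    "RocClassifierConfig",
    "MarkerEvaluation",
    "empirical_roc",
    "auc",
    "auc_se_ci",
    "mann_whitney",
    "smooth_roc",
    "roc_length",
    "classify_marker",
    "evaluate_marker",
    "h_score",
]


@dataclass
class RocCurve:
    """Ordered (FPR, TPR) polyline from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    estimator: Literal["empirical", "kde_smooth"]
    n_pos: int
    n_neg: int
    bandwidths: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if self.fpr.shape != self.tpr.shape or self.fpr.ndim != 1:
            raise ValueError("fpr and tpr must be 1-d arrays of equal length")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0):
            raise ValueError("curve must start at (0,0)")
        if not (self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("curve must end at (1,1)")
        if np.any(np.diff(self.fpr) < -1e-12):
            raise ValueError("fpr must be non-decreasing")
        for arr in (self.fpr, self.tpr):
            if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
                raise ValueError("coordinates must lie in [0,1]")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass(frozen=True)
class RocClassifierConfig:
    """Thresholds of the joint (AUC, arc length) marker classification."""

    monotone_length: float = 2.0
    length_tolerance: float = 0.02   # a smooth estimate never attains 2 exactly
    monotone_auc_hi: float = 0.8
    monotone_auc_lo: float = 0.2
    nonmono_length: float = 1.6
    nonmono_auc_band: tuple[float, float] = (0.35, 0.65)

    def __post_init__(self) -> None:
        if not 0 < self.length_tolerance < 0.5:
            raise ValueError("length_tolerance must be in (0, 0.5)")


@dataclass
class MarkerEvaluation:
    """Per-marker summary: AUC with SE/CI, one-tailed p, arc length, class."""

    marker: str
    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    p_one_tailed: float
    roc_length: float
    classification: Literal["monotone", "non_monotone", "neither"]

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("auc out of [0,1]")
        if not self.ci_lower <= self.auc <= self.ci_upper:
            raise ValueError("CI must bracket the AUC")


# ---------------------------------------------------------------------------
# Empirical ROC
# ---------------------------------------------------------------------------

def empirical_roc(pos: Sequence[float], neg: Sequence[float]) -> RocCurve:
    """Tie-aware empirical ROC step curve.

    Thresholds sweep the pooled distinct scores from high to low; scores tied
    at a threshold move TPR and FPR simultaneously, producing a diagonal
    segment, which keeps trapezoidal AUC exactly equal to the tie-corrected
    Mann-Whitney U / (n_pos * n_neg).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("scores must be finite")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    for t in thresholds:
        tp += int(np.sum(pos == t))
        fp += int(np.sum(neg == t))
        tpr.append(tp / pos.size)
        fpr.append(fp / neg.size)
    return RocCurve(
        fpr=np.array(fpr), tpr=np.array(tpr),
        estimator="empirical", n_pos=pos.size, n_neg=neg.size,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_se_ci(
    auc_value: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Hanley-McNeil standard error and normal CI, truncated to [0,1]."""
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 observations per class")
    a = float(auc_value)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(stats.norm.ppf(0.5 + level / 2))
    lo = max(0.0, a - z * se)
    hi = min(1.0, a + z * se)
    return se, lo, hi


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Mann-Whitney U of x versus y with midrank ties.

    Returns (U_x, two-tailed p, one-tailed p).  The exact null distribution
    is used when both samples have n <= 8 and there are no ties; otherwise
    the tie-corrected normal approximation.  The one-tailed p is taken in
    the direction observed in the sample (the tail containing U_x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u, p2 = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    direction = "greater" if u >= x.size * y.size / 2 else "less"
    _, p1 = stats.mannwhitneyu(x, y, alternative=direction, method="auto")
    return float(u), float(p2), float(p1)


# ---------------------------------------------------------------------------
# Kernel-smoothed ROC
# ---------------------------------------------------------------------------

def _silverman(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * x.size ** (-0.2)


def smooth_roc(
    pos: Sequence[float],
    neg: Sequence[float],
    bandwidth_rule: str | tuple[float, float] = "silverman",
    n_grid: int = 2001,
) -> RocCurve:
    """Gaussian-kernel smoothed ROC: ROC(t) = 1 - Fpos(Fneg^{-1}(1 - t)).

    Group score distributions are estimated by Gaussian-kernel CDFs with
    per-group Silverman bandwidths (or a fixed (h_neg, h_pos) pair), and the
    curve is evaluated on a dense FPR grid.  Falls back to the empirical
    curve with a warning if either group has zero spread.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 3 or neg.size < 3:
        raise ValueError("need at least 3 scores per group for smoothing")
    if isinstance(bandwidth_rule, str):
        if bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
        h_neg, h_pos = _silverman(neg), _silverman(pos)
    else:
        h_neg, h_pos = float(bandwidth_rule[0]), float(bandwidth_rule[1])
    if h_neg <= 0 or h_pos <= 0:
        warnings.warn(
            "zero variance in a score group; falling back to empirical ROC",
            RuntimeWarning,
        )
        return empirical_roc(pos, neg)

    lo = min(neg.min() - 6 * h_neg, pos.min() - 6 * h_pos)
    hi = max(neg.max() + 6 * h_neg, pos.max() + 6 * h_pos)
    xgrid = np.linspace(lo, hi, 4001)
    f_neg = ndtr((xgrid[:, None] - neg[None, :]) / h_neg).mean(axis=1)
    t = np.linspace(0.0, 1.0, n_grid)
    # invert the control CDF by monotone interpolation, then read off the
    # case survival at those cutoffs
    cutoffs = np.interp(1.0 - t, f_neg, xgrid)
    tpr = 1.0 - ndtr((cutoffs[:, None] - pos[None, :]) / h_pos).mean(axis=1)
    tpr = np.clip(tpr, 0.0, 1.0)
    tpr = np.maximum.accumulate(tpr)  # numerical monotonicity along the sweep
    fpr = np.concatenate([[0.0], t, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return RocCurve(
        fpr=fpr, tpr=tpr, estimator="kde_smooth",
        n_pos=pos.size, n_neg=neg.size, bandwidths=(h_neg, h_pos),
    )


def roc_length(curve: RocCurve) -> float:
    """Polygonal arc length of the ROC curve: sum of sqrt(dFPR^2 + dTPR^2).

    2 for perfect monotone separation, sqrt(2) for the chance diagonal.
    Uses exact summation so the axis-aligned steps of a perfectly separating
    empirical curve telescope to exactly 2.
    """
    import math

    return math.fsum(np.hypot(np.diff(curve.fpr), np.diff(curve.tpr)))


def classify_marker(
    auc_value: float, length: float, cfg: RocClassifierConfig | None = None
) -> str:
    """Joint (AUC, arc length) classification: monotone / non_monotone / neither.

    Monotone: length within tolerance of 2 and AUC outside (lo, hi).
    Non-monotone: length > 1.6 and AUC inside the central band.  Monotone
    takes precedence if both fire.
    """
    cfg = cfg or RocClassifierConfig()
    monotone = length >= cfg.monotone_length - cfg.length_tolerance and (
        auc_value > cfg.monotone_auc_hi or auc_value < cfg.monotone_auc_lo
    )
    lo, hi = cfg.nonmono_auc_band
    nonmono = length > cfg.nonmono_length and lo <= auc_value <= hi
    if monotone:
        return "monotone"
    if nonmono:
        return "non_monotone"
    return "neither"


def evaluate_marker(
    marker: str,
    pos: Sequence[float],
    neg: Sequence[float],
    cfg: RocClassifierConfig | None = None,
    smooth: bool = True,
) -> MarkerEvaluation:
    """Full single-marker evaluation: empirical AUC/SE/CI/p plus the smooth
    arc length and the monotone / non-monotone classification."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    emp = empirical_roc(pos, neg)
    a = auc(emp)
    se, lo, hi = auc_se_ci(a, emp.n_pos, emp.n_neg)
    _, _, p1 = mann_whitney(pos, neg)
    curve = smooth_roc(pos, neg) if smooth and min(pos.size, neg.size) >= 3 else emp
    length = roc_length(curve)
    return MarkerEvaluation(
        marker=marker,
        auc=a,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        p_one_tailed=p1,
        roc_length=length,
        classification=classify_marker(a, length, cfg),
    )


# ---------------------------------------------------------------------------
# IHC helper
# ---------------------------------------------------------------------------

def h_score(area_fractions: Sequence[float]) -> float:
    """IHC H-score: 0*a0 + 1*a1 + 2*a2 + 3*a3 for percent areas summing to 100."""
    a = np.asarray(area_fractions, dtype=float)
    if a.shape != (4,):
        raise ValueError("need exactly four area fractions (0, 1+, 2+, 3+)")
    if np.any(a < 0):
        raise ValueError("area fractions must be non-negative")
    if abs(a.sum() - 100.0) > 1e-6:
        raise ValueError(f"area fractions must sum to 100, got {a.sum()}")
    return float(np.dot(a, [0.0, 1.0, 2.0, 3.0]))
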