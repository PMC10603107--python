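"""Multi-marker panel selection and screening-performance statistics.

Every non-empty subset of the candidate markers is fit as a logistic
regression of case/control status on log-transformed intensities and the
subset with minimum AIC wins.  The winning model's intercept-free linear
term, sum(beta_i * log(x_i)), is the combined marker score; its operating
characteristics are then evaluated: Youden-optimal cutoff, sensitivity at a
forced specificity (0.998 for a screening test), and positive predictive
value at a population prevalence (1/2500 for postmenopausal women).

Natural logs are used for the marker transform; the log base only rescales
coefficients and leaves rankings, sensitivity, specificity and PPV
unchanged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

import statsmodels.api as sm

from .io_tables import MarkerPanel

DEFAULT_PREVALENCE = 1.0 / 2500.0
DEFAULT_TARGET_SPECIFICITY = 0.998
RIDGE_LAMBDA = 1e-4  # slope-only penalty used when the MLE does not exist

__all__ = [
    "CombinationModel",
    "ScreeningPerformance",
    "fit_logistic",
    "exhaustive_search",
    "linear_score",
    "youden_cutoff",
    "sensitivity_at_specificity",
    "ppv",
    "evaluate_fixed_combination",
    "case_control_arrays",
]


@dataclass
class CombinationModel:
    """A fitted logistic model over a marker subset."""

    markers: tuple[str, ...]
    coefficients: np.ndarray          # per marker, on log intensities
    intercept: float
    log_likelihood: float
    aic: float
    n_obs: int
    separation: bool = False          # ridge-stabilized fallback was used
    converged: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        k = len(self.markers) + 1
        if abs(self.aic - (2 * k - 2 * self.log_likelihood)) > 1e-8:
            raise ValueError("AIC inconsistent with log-likelihood")

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "separation": self.separation,
            "transform": "natural_log",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombinationModel":
        return cls(
            markers=tuple(d["markers"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            log_likelihood=float(d["log_likelihood"]),
            aic=float(d["aic"]),
            n_obs=int(d["n_obs"]),
            separation=bool(d.get("separation", False)),
        )


@dataclass
class ScreeningPerformance:
    """Operating point of a score: cutoff, sens/spec, Youden J, PPV."""

    sensitivity: float
    specificity: float
    cutoff: float
    ppv: float
    prevalence: float = DEFAULT_PREVALENCE

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


# ---------------------------------------------------------------------------
# Label handling
# ---------------------------------------------------------------------------

def case_control_arrays(
    panel: MarkerPanel,
    markers: Sequence[str],
    case_label: str = "case",
    control_label: str = "control",
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with X = log intensities over markers, y = 1 for cases."""
    for m in markers:
        if m not in panel.intensities.columns:
            raise KeyError(f"marker {m!r} not in panel")
    mask = panel.labels.isin([case_label, control_label]).to_numpy()
    sub = panel.intensities.loc[mask, list(markers)]
    y = (panel.labels[mask] == case_label).to_numpy(dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("both classes must be present")
    return np.log(sub.to_numpy(dtype=float)), y


# ---------------------------------------------------------------------------
# Logistic fitting
# ---------------------------------------------------------------------------

def _loglik(beta: np.ndarray, X1: np.ndarray, y: np.ndarray) -> float:
    eta = X1 @ beta
    # numerically stable log-likelihood of the Bernoulli GLM
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _ridge_logistic(X1: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Slope-penalized logistic fit; the intercept is not penalized."""

    def neg_pen(beta: np.ndarray) -> float:
        return -_loglik(beta, X1, y) + lam * float(np.sum(beta[1:] ** 2))

    def grad(beta: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-(X1 @ beta)))
        g = -X1.T @ (y - p)
        g[1:] += 2 * lam * beta[1:]
        return g

    res = optimize.minimize(
        neg_pen, np.zeros(X1.shape[1]), jac=grad, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    return res.x


def fit_logistic(
    panel: MarkerPanel,
    subset: Sequence[str],
    case_label: str = "case",
    control_label: str = "control",
) -> CombinationModel:
    """Maximum-likelihood logistic fit of case/control on log intensities.

    Under perfect separation the MLE does not exist; the fit is then redone
    with a weak ridge penalty on the slopes and flagged via ``separation``.
    The reported log-likelihood and AIC are always the unpenalized values at
    the returned coefficients.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    X, y = case_control_arrays(panel, subset, case_label, control_label)
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("need at least 3 observations per class")
    X1 = np.column_stack([np.ones(len(y)), X])

    params = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X1).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            params = None

    separation = (
        params is None
        or not np.all(np.isfinite(params))
        or not converged
        or np.max(np.abs(params)) > 1e3
    )
    if separation:
        params = _ridge_logistic(X1, y, RIDGE_LAMBDA)
        warnings.warn(
            f"perfect or quasi-separation for subset {tuple(subset)}; "
            "ridge-stabilized fit returned",
            RuntimeWarning,
        )
    llf = _loglik(params, X1, y)
    k = len(subset) + 1
    return CombinationModel(
        markers=tuple(subset),
        coefficients=params[1:],
        intercept=float(params[0]),
        log_likelihood=llf,
        aic=2 * k - 2 * llf,
        n_obs=len(y),
        separation=separation,
        converged=converged or separation,
    )


def exhaustive_search(
    panel: MarkerPanel,
    candidates: Sequence[str],
    case_label: str = "case",
    control_label: str = "control",
) -> tuple[CombinationModel, list[CombinationModel]]:
    """Fit all 2^k - 1 non-empty marker subsets; return the minimum-AIC model.

    Ties are broken by fewer markers, then lexicographically by marker
    names.  Individual fit failures are recorded and skipped, not fatal.
    """
    candidates = list(candidates)
    if not 1 <= len(candidates) <= 20:
        raise ValueError("need between 1 and 20 candidate markers")
    models: list[CombinationModel] = []
    failures: list[tuple[tuple[str, ...], str]] = []
    with warnings.catch_warnings():
        # per-subset separation warnings are summarized once below
        warnings.simplefilter("ignore", RuntimeWarning)
        for r in range(1, len(candidates) + 1):
            for subset in itertools.combinations(candidates, r):
                try:
                    models.append(
                        fit_logistic(panel, subset, case_label, control_label)
                    )
                except Exception as exc:  # recorded, not fatal
                    failures.append((subset, str(exc)))
    n_sep = sum(m.separation for m in models)
    if n_sep:
        warnings.warn(
            f"{n_sep} of {len(models)} subset fits were ridge-stabilized "
            "(perfect or quasi-separation)",
            RuntimeWarning,
        )
    if not models:
        raise RuntimeError(f"every subset fit failed: {failures}")
    best = min(models, key=lambda m: (m.aic, len(m.markers), tuple(sorted(m.markers))))
    return best, models


def linear_score(model: CombinationModel, panel: MarkerPanel) -> pd.Series:
    """Per-sample combined marker score sum(beta_i * log(x_i)), no intercept."""
    for m in model.markers:
        if m not in panel.intensities.columns:
            raise KeyError(f"marker {m!r} missing from panel")
    sub = panel.intensities[list(model.markers)]
    vals = sub.to_numpy(dtype=float)
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive intensity for sample {sub.index[i]!r}, "
            f"marker {sub.columns[j]!r}"
        )
    return pd.Series(
        np.log(vals) @ model.coefficients, index=sub.index, name="score"
    )


# ---------------------------------------------------------------------------
# Operating points
# ---------------------------------------------------------------------------

def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2 if s.size > 1 else np.empty(0)
    return np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])


def youden_cutoff(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    prevalence: float = DEFAULT_PREVALENCE,
) -> ScreeningPerformance:
    """Cutoff maximizing Youden J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints of adjacent distinct pooled scores plus
    sentinels below/above the range; a sample is positive if score > cutoff.
    Ties prefer higher specificity, then the lower cutoff.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    cuts = _candidate_cutoffs(np.concatenate([pos, neg]))
    sens = (pos[None, :] > cuts[:, None]).mean(axis=1)
    spec = (neg[None, :] <= cuts[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    order = np.lexsort((cuts, -spec, -j))  # max J, then max spec, then min cutoff
    i = order[0]
    return ScreeningPerformance(
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
        cutoff=float(cuts[i]),
        ppv=ppv(float(sens[i]), float(spec[i]), prevalence),
        prevalence=prevalence,
    )


def sensitivity_at_specificity(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    target_spec: float = DEFAULT_TARGET_SPECIFICITY,
) -> tuple[float, float]:
    """Sensitivity at the smallest cutoff with empirical specificity >= target.

    With fewer controls than 1/(1 - target), e.g. 20 controls at target
    0.998, the only admissible cutoffs sit above the control maximum, so the
    achieved empirical specificity is 1.0.
    """
    if not 0 < target_spec <= 1:
        raise ValueError("target specificity must be in (0, 1]")
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    cuts = _candidate_cutoffs(np.concatenate([pos, neg]))
    spec = (neg[None, :] <= cuts[:, None]).mean(axis=1)
    ok = np.nonzero(spec >= target_spec)[0]
    i = ok[0]  # cutoffs ascending; spec is non-decreasing so this is smallest
    sens = float((pos > cuts[i]).mean())
    return sens, float(cuts[i])


def ppv(sensitivity: float, specificity: float, prevalence: float = DEFAULT_PREVALENCE) -> float:
    """Positive predictive value: sens*p / (sens*p + (1 - spec)(1 - p))."""
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    num = sensitivity * prevalence
    den = num + (1 - specificity) * (1 - prevalence)
    if den == 0:
        warnings.warn("PPV denominator is zero; returning 0", RuntimeWarning)
        return 0.0
    return num / den


def evaluate_fixed_combination(
    model: CombinationModel,
    panel: MarkerPanel,
    target_spec: float = DEFAULT_TARGET_SPECIFICITY,
    prevalence: float = DEFAULT_PREVALENCE,
    case_label: str = "case",
    control_label: str = "control",
) -> ScreeningPerformance:
    """Apply a fixed combination to a panel without refitting.

    Computes the linear score, forces the target specificity to pick the
    cutoff, and reports sensitivity and PPV.  PPV uses the forced target
    specificity (the screening operating point), not the achieved empirical
    specificity, which is 1.0 whenever the control count cannot resolve
    1 - target.
    """
    scores = linear_score(model, panel)
    pos = scores[panel.labels == case_label].to_numpy()
    neg = scores[panel.labels == control_label].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"panel lacks {case_label!r} or {control_label!r} samples"
        )
    sens, cutoff = sensitivity_at_specificity(pos, neg, target_spec)
    return ScreeningPerformance(
        sensitivity=sens,
        specificity=target_spec,
        cutoff=cutoff,
        ppv=ppv(sens, target_spec, prevalence),
        prevalence=prevalence,
    )
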