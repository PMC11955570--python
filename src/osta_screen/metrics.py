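"""Diagnostic-accuracy statistics for dichotomous screening rules.

The unit of analysis is a 2x2 confusion matrix of a binary screening rule
against a binary reference diagnosis. From it we derive the standard metric
set — sensitivity, specificity, predictive values, the positive likelihood
ratio, the Youden index J = sens + spec - 1 — each proportion with an exact
(Clopper–Pearson) confidence interval, plus the area under the two-point ROC
curve of the dichotomized predictor, AUC = (sens + spec) / 2, with a DeLong
variance. Paired AUCs measured on the same subjects are compared with the
DeLong test computed from midrank structural components.

Degenerate denominators yield NaN metric values (and ``inf`` for LR+ when
specificity is 1), never a global failure, so that report shapes stay stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "CutoffPerformance",
    "DelongComparison",
    "confusion",
    "clopper_pearson",
    "wilson",
    "proportion_ci",
    "evaluate",
    "auc_binary",
    "delong_auc",
    "delong_compare",
    "pearson_r",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def cases(self) -> int:
        return self.tp + self.fn

    @property
    def non_cases(self) -> int:
        return self.fp + self.tn


def confusion(predicted_positive, diseased) -> ConfusionMatrix:
    """Cross-tabulate a binary screening call against the reference diagnosis."""
    pred = np.asarray(predicted_positive, dtype=bool)
    dis = np.asarray(diseased, dtype=bool)
    if pred.shape != dis.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {dis.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(pred & dis)),
        fp=int(np.sum(pred & ~dis)),
        tn=int(np.sum(~pred & ~dis)),
        fn=int(np.sum(~pred & dis)),
    )


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial interval from Beta quantiles.

    Lower bound is 0 when x = 0 and upper bound is 1 when x = n.
    """
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def wilson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval (optional alternative to the exact interval)."""
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    z = stats.norm.ppf(1 - alpha / 2)
    p = x / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


_CI_METHODS = {"clopper-pearson": clopper_pearson, "wilson": wilson}


def proportion_ci(x: int, n: int, alpha: float = 0.05,
                  method: str = "clopper-pearson") -> tuple[float, float]:
    try:
        fn = _CI_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}")
    return fn(x, n, alpha)


@dataclass(frozen=True)
class CutoffPerformance:
    """Full metric row for one screening rule at one site (one table row).

    Proportions are stored as fractions at full precision; display rounding
    belongs to the report layer. Undefined metrics are NaN; ``lr_plus`` is
    ``inf`` when specificity is exactly 1 and sensitivity is positive.
    """

    site: Optional[str]
    cutoff: Optional[float]
    cm: ConfusionMatrix
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sens_ci: tuple[float, float]
    specificity: float
    spec_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    lr_plus: float
    youden: float
    stratum: Optional[str] = None

    @property
    def n(self) -> int:
        return self.cm.n


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def _ci_or_nan(x: int, n: int, alpha: float, method: str) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    return proportion_ci(x, n, alpha, method)


def evaluate(cm: ConfusionMatrix, alpha: float = 0.05, *, site: Optional[str] = None,
             cutoff: Optional[float] = None, stratum: Optional[str] = None,
             ci_method: str = "clopper-pearson") -> CutoffPerformance:
    """Compute the full metric row for one confusion matrix."""
    sens = _ratio(cm.tp, cm.cases)
    spec = _ratio(cm.tn, cm.non_cases)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    if math.isnan(sens) or math.isnan(spec):
        lr = float("nan")
        youden = float("nan")
        auc, auc_ci = float("nan"), (float("nan"), float("nan"))
    else:
        lr = float("inf") if spec == 1.0 and sens > 0 else (
            float("nan") if spec == 1.0 else sens / (1 - spec))
        youden = sens + spec - 1
        auc, auc_ci = auc_binary(cm, alpha)
    return CutoffPerformance(
        site=site, cutoff=cutoff, stratum=stratum, cm=cm,
        auc=auc, auc_ci=auc_ci,
        sensitivity=sens, sens_ci=_ci_or_nan(cm.tp, cm.cases, alpha, ci_method),
        specificity=spec, spec_ci=_ci_or_nan(cm.tn, cm.non_cases, alpha, ci_method),
        ppv=ppv, ppv_ci=_ci_or_nan(cm.tp, cm.tp + cm.fp, alpha, ci_method),
        npv=npv, npv_ci=_ci_or_nan(cm.tn, cm.tn + cm.fn, alpha, ci_method),
        lr_plus=lr, youden=youden,
    )


# ---------------------------------------------------------------------------
# AUC machinery (DeLong structural components via midranks)

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _components(scores: np.ndarray, diseased: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the case (V10) and non-case (V01) structural components.

    Higher score = more disease-like. Ties handled through midranks, so the
    AUC equals the tie-corrected Mann–Whitney statistic U / (m * n).
    """
    pos = scores[diseased]
    neg = scores[~diseased]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both diseased and non-diseased subjects are required")
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    return float(auc), v10, v01


def delong_auc(scores, diseased, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC of a (possibly tied/dichotomous) score with a DeLong Wald CI."""
    scores = np.asarray(scores, dtype=float)
    diseased = np.asarray(diseased, dtype=bool)
    if scores.shape != diseased.shape:
        raise ValueError("scores and diseased must have matching shapes")
    auc, v10, v01 = _components(scores, diseased)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def auc_binary(cm: ConfusionMatrix, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Two-point ROC area of a dichotomized test: (sens + spec) / 2.

    The CI uses the DeLong variance of the 0/1 predictor, reconstructed from
    the confusion-matrix counts.
    """
    if cm.cases == 0 or cm.non_cases == 0:
        raise ValueError("AUC requires at least one case and one non-case")
    scores = np.concatenate([
        np.ones(cm.tp), np.zeros(cm.fn),  # cases
        np.ones(cm.fp), np.zeros(cm.tn),  # non-cases
    ])
    diseased = np.concatenate([
        np.ones(cm.cases, dtype=bool), np.zeros(cm.non_cases, dtype=bool)
    ])
    return delong_auc(scores, diseased, alpha)


@dataclass(frozen=True)
class DelongComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float


def delong_compare(scores_a, scores_b, diseased) -> DelongComparison:
    """Paired DeLong test for two predictors measured on the same subjects.

    Returns the two AUCs, their difference, and the two-sided z test. When
    the variance of the difference is zero (e.g. identical predictors) the
    statistic is defined as 0 and p = 1 if the AUCs agree, otherwise p = 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    diseased = np.asarray(diseased, dtype=bool)
    if not (a.shape == b.shape == diseased.shape):
        raise ValueError("both predictors and the diagnosis must be paired per subject")
    auc_a, v10_a, v01_a = _components(a, diseased)
    auc_b, v10_b, v01_b = _components(b, diseased)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var_delta = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    delta = auc_a - auc_b
    if var_delta <= 0 or math.isclose(var_delta, 0.0, abs_tol=1e-15):
        z = 0.0
        p = 1.0 if math.isclose(delta, 0.0, abs_tol=1e-12) else 0.0
    else:
        z = delta / math.sqrt(var_delta)
        p = 2 * float(stats.norm.sf(abs(z)))
    return DelongComparison(auc_a=auc_a, auc_b=auc_b, delta=delta, z=z, p=p)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
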