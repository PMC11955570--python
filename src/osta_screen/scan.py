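"""Cutoff scanning, Youden-optimal cutoff selection, and predictor comparison.

The evaluation design: a risk score (lower = riskier) is dichotomized at each
candidate cutoff with positivity ``score <= cutoff``; each (site, cutoff)
pair yields a full metric row against osteoporosis at that site (the "any"
site uses the worst available T-score). The recommended cutoff maximizes the
Youden index, ties broken toward the higher — more sensitive — cutoff, the
sensible direction for a screening rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as _cls
from .metrics import (
    ConfusionMatrix,
    CutoffPerformance,
    DelongComparison,
    confusion,
    delong_compare,
    evaluate,
    proportion_ci,
)

__all__ = [
    "ScanSpec",
    "PredictorSpec",
    "ComparisonRow",
    "disease_indicator",
    "scan",
    "optimal_cutoff",
    "compare_predictors",
]

ALL_SITES = ("lumbar", "femoral_neck", "total_hip", "any")


@dataclass(frozen=True)
class ScanSpec:
    """What to scan: cutoffs (strictly increasing), sites, optional age strata."""

    cutoffs: Sequence[float] = tuple(range(-4, 5))
    sites: Sequence[str] = ALL_SITES
    age_strata: Optional[Sequence[tuple[float, float]]] = None  # [lo, hi) in years

    def __post_init__(self):
        cuts = list(self.cutoffs)
        if not cuts or any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be a non-empty strictly increasing sequence")
        unknown = set(self.sites) - set(ALL_SITES)
        if unknown:
            raise ValueError(f"unknown sites: {sorted(unknown)}")
        if self.age_strata is not None:
            strata = sorted(self.age_strata)
            for (lo1, hi1), (lo2, _) in zip(strata, strata[1:]):
                if lo2 < hi1:
                    raise ValueError("age strata must not overlap")


def disease_indicator(cohort: pd.DataFrame, site: str) -> np.ndarray:
    """Osteoporosis indicator at one site; NaN where the site is missing.

    Returned as a float array: 1.0 diseased, 0.0 not, NaN unmeasured. For
    ``site="any"`` the worst available T-score decides and a value is defined
    whenever at least one site was measured.
    """
    if site == "any":
        t = np.column_stack([
            pd.to_numeric(cohort[c], errors="coerce").to_numpy(dtype=float)
            for c in _cls.T_COLUMNS.values() if c in cohort.columns
        ])
        if t.size == 0:
            raise ValueError("cohort has no T-score columns")
        with np.errstate(invalid="ignore"):
            worst = np.nanmin(t, axis=1)
        out = np.where(np.isnan(worst), np.nan, (worst <= _cls.OSTEOPOROSIS_T).astype(float))
        return out
    col = _cls.T_COLUMNS[site]
    if col not in cohort.columns:
        raise ValueError(f"cohort lacks column {col!r} for site {site!r}")
    t = pd.to_numeric(cohort[col], errors="coerce").to_numpy(dtype=float)
    return np.where(np.isnan(t), np.nan, (t <= _cls.OSTEOPOROSIS_T).astype(float))


def _evaluate_subset(scores: np.ndarray, disease: np.ndarray, cutoff: float,
                     alpha: float, site: str, stratum: Optional[str]) -> CutoffPerformance:
    ok = ~np.isnan(disease) & ~np.isnan(scores)
    pred = scores[ok] <= cutoff
    dis = disease[ok] > 0.5
    cm = confusion(pred, dis) if ok.any() else None
    if cm is None:
        raise ValueError("no evaluable subjects")
    return evaluate(cm, alpha, site=site, cutoff=cutoff, stratum=stratum)


def scan(cohort: pd.DataFrame, scores, spec: ScanSpec,
         alpha: float = 0.05) -> list[CutoffPerformance]:
    """One metric row per (site, cutoff[, stratum]); positivity is score <= cutoff.

    Subjects missing the site's T-score are dropped for that site only. Rows
    for strata with no cases carry NaN sensitivity rather than being omitted.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(cohort):
        raise ValueError("scores must align with the cohort rows")
    age = pd.to_numeric(cohort["age"], errors="coerce").to_numpy(dtype=float) \
        if spec.age_strata is not None else None
    rows: list[CutoffPerformance] = []
    for site in spec.sites:
        disease = disease_indicator(cohort, site)
        strata: list[tuple[Optional[str], np.ndarray]]
        if spec.age_strata is None:
            strata = [(None, np.ones(len(cohort), dtype=bool))]
        else:
            strata = [(f"[{lo:g},{hi:g})", (age >= lo) & (age < hi))
                      for lo, hi in spec.age_strata]
        for label, mask in strata:
            d = np.where(mask, disease, np.nan)
            for cutoff in spec.cutoffs:
                rows.append(_evaluate_subset(scores, d, cutoff, alpha, site, label))
    return rows


def optimal_cutoff(rows: Sequence[CutoffPerformance]) -> float:
    """Cutoff with maximal Youden index; ties go to the higher cutoff."""
    usable = [r for r in rows if not np.isnan(r.youden)]
    if not usable:
        raise ValueError("no rows with a defined Youden index")
    best = max(usable, key=lambda r: (r.youden, r.cutoff))
    return best.cutoff


@dataclass(frozen=True)
class PredictorSpec:
    """A named binary screening rule: positive calls per subject."""

    name: str
    positive: np.ndarray  # bool per cohort row

    def __post_init__(self):
        object.__setattr__(self, "positive", np.asarray(self.positive, dtype=bool))


@dataclass(frozen=True)
class ComparisonRow:
    name: str
    performance: CutoffPerformance
    p_vs_reference: Optional[float]  # None for the reference itself
    delong: Optional[DelongComparison]


def compare_predictors(cohort: pd.DataFrame, predictors: Sequence[PredictorSpec],
                       site: str = "any", reference: Optional[str] = None,
                       alpha: float = 0.05) -> list[ComparisonRow]:
    """Head-to-head comparison of binary screening rules on one cohort.

    Each rule gets the full metric row (AUC with DeLong CI, sens/spec with
    exact CIs) plus a paired DeLong p-value against the reference predictor
    (the first one listed if not named).
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors to compare")
    names = [p.name for p in predictors]
    if len(set(names)) != len(names):
        raise ValueError("predictor names must be unique")
    ref_name = reference if reference is not None else names[0]
    if ref_name not in names:
        raise ValueError(f"reference {ref_name!r} not among predictors")
    disease = disease_indicator(cohort, site)
    ok = ~np.isnan(disease)
    for p in predictors:
        if p.positive.shape[0] != len(cohort):
            raise ValueError(f"predictor {p.name!r} not aligned with the cohort")
    dis = disease[ok] > 0.5
    ref = next(p for p in predictors if p.name == ref_name)
    rows = []
    for p in predictors:
        cm = confusion(p.positive[ok], dis)
        perf = evaluate(cm, alpha, site=site, cutoff=None)
        if p.name == ref_name:
            rows.append(ComparisonRow(p.name, perf, None, None))
        else:
            dl = delong_compare(p.positive[ok].astype(float),
                                ref.positive[ok].astype(float), dis)
            rows.append(ComparisonRow(p.name, perf, dl.p, dl))
    return rows
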