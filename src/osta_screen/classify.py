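"""WHO T-score classification and cohort exclusion filtering.

A site-level T-score maps to the WHO diagnostic categories:

* osteoporosis: T <= -2.5
* osteopenia:   -2.5 < T < -1.0
* normal:       T >= -1.0

The reference diagnosis for screening evaluation is "osteoporosis at any
site": a subject is diseased when the worst (minimum) available T-score is
at or below -2.5. Both boundaries are inclusive on the side stated above, so
the three categories partition the real line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "T_COLUMNS",
    "EXCLUSION_REASONS",
    "OSTEOPOROSIS_T",
    "NORMAL_T",
    "Diagnosis",
    "classify_site",
    "classify_any_site",
    "classify_cohort",
    "apply_exclusions",
]

SITES = ("lumbar", "femoral_neck", "total_hip")
T_COLUMNS = {"lumbar": "t_lumbar", "femoral_neck": "t_femoral_neck", "total_hip": "t_total_hip"}

OSTEOPOROSIS_T = -2.5
NORMAL_T = -1.0

#: Exclusion reasons in reporting precedence order: a subject carrying several
#: flags is tallied once, under the first applicable reason.
EXCLUSION_REASONS = (
    "prior_treatment",
    "ckd",
    "malignancy",
    "hyperthyroid",
    "ra",
    "spine_hip_surgery",
    "incomplete_dxa",
)


@dataclass(frozen=True)
class Diagnosis:
    """Per-site WHO categories plus the worst-site summary diagnosis."""

    per_site: Mapping[str, str]
    any_site: str
    worst_t: float


def classify_site(t: float) -> str:
    """Map one T-score to its WHO category."""
    t = float(t)
    if not np.isfinite(t):
        raise ValueError(f"T-score must be finite, got {t}")
    if t <= OSTEOPOROSIS_T:
        return "osteoporosis"
    if t >= NORMAL_T:
        return "normal"
    return "osteopenia"


def classify_any_site(t_scores: Mapping[str, float] | Sequence[float]) -> Diagnosis:
    """Worst-site diagnosis from the available T-scores.

    ``t_scores`` is either a mapping ``site -> T`` (missing sites as NaN or
    absent) or a sequence ordered as ``SITES``. At least one T-score must be
    present; the summary category is determined by the minimum available T.
    """
    if isinstance(t_scores, Mapping):
        items = {s: t_scores.get(s, np.nan) for s in SITES}
    else:
        vals = list(t_scores)
        if len(vals) != len(SITES):
            raise ValueError(f"expected {len(SITES)} T-scores, got {len(vals)}")
        items = dict(zip(SITES, vals))
    per_site = {}
    available = []
    for site, t in items.items():
        if t is None or (isinstance(t, float) and np.isnan(t)) or (np.isreal(t) and np.isnan(float(t))):
            per_site[site] = "missing"
        else:
            per_site[site] = classify_site(t)
            available.append(float(t))
    if not available:
        raise ValueError("no T-score available at any site; subject should have been excluded")
    worst = min(available)
    return Diagnosis(per_site=per_site, any_site=classify_site(worst), worst_t=worst)


def classify_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append diagnosis columns (dx_<site>, dx_any, worst_t) to a cohort table.

    Rows with no T-score at any site raise; such subjects belong in the
    exclusion step, not here.
    """
    out = cohort.copy()
    t = np.column_stack([
        pd.to_numeric(out[T_COLUMNS[s]], errors="coerce").to_numpy(dtype=float)
        if T_COLUMNS[s] in out.columns else np.full(len(out), np.nan)
        for s in SITES
    ])
    if len(out) and np.any(np.all(np.isnan(t), axis=1)):
        n_bad = int(np.all(np.isnan(t), axis=1).sum())
        raise ValueError(f"{n_bad} subject(s) have no T-score at any site")

    def _cat(col: np.ndarray) -> np.ndarray:
        cats = np.where(col <= OSTEOPOROSIS_T, "osteoporosis",
                        np.where(col >= NORMAL_T, "normal", "osteopenia"))
        return np.where(np.isnan(col), "missing", cats)

    for i, site in enumerate(SITES):
        out[f"dx_{site}"] = _cat(t[:, i])
    worst = np.nanmin(t, axis=1) if len(out) else np.array([])
    out["worst_t"] = worst
    out["dx_any"] = _cat(worst)
    return out


def apply_exclusions(
    cohort: pd.DataFrame,
    reasons: Sequence[str] = EXCLUSION_REASONS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop flagged subjects; tally one reason per subject by precedence.

    Flag columns are named after the reasons; absent columns count as
    all-false. Returns the retained cohort and an ordered tally whose values
    sum to the number excluded.
    """
    tally = {r: 0 for r in reasons}
    flags = {}
    for r in reasons:
        if r in cohort.columns:
            col = cohort[r]
            flags[r] = col.fillna(False).astype(bool).to_numpy()
        else:
            flags[r] = np.zeros(len(cohort), dtype=bool)
    excluded = np.zeros(len(cohort), dtype=bool)
    for r in reasons:
        newly = flags[r] & ~excluded
        tally[r] = int(newly.sum())
        excluded |= flags[r]
    retained = cohort.loc[~excluded].copy()
    return retained, tally
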