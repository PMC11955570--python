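"""Recover integer confusion matrices from published rounded percentages.

Published screening-accuracy tables print sensitivity, specificity, PPV and
NPV to one decimal place but rarely the underlying 2x2 counts. Because those
metrics are ratios of small integers, the counts are usually *uniquely*
recoverable by exhaustive search: find the case count, non-case count, TP and
TN for which every printed percentage re-rounds correctly, simultaneously
across all rows of a column (all rows of one BMD site share the same case
and non-case denominators).

This is deliberately an enumeration, not algebra: it doubles as an
independent oracle for the metric layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .metrics import ConfusionMatrix

__all__ = ["PrintedRow", "matches_printed", "candidate_counts", "recover_row", "recover_site"]

_EPS = 1e-9


def matches_printed(printed_pct: float, numerator: int, denominator: int) -> bool:
    """Does numerator/denominator re-round (1 dp, in percent) to the printed value?"""
    if denominator <= 0:
        return False
    return abs(100.0 * numerator / denominator - printed_pct) <= 0.05 + _EPS


@dataclass(frozen=True)
class PrintedRow:
    """One published table row: percentages to 1 dp; None when not printed."""

    sens: float
    spec: float
    ppv: Optional[float] = None
    npv: Optional[float] = None
    label: Optional[str] = None


def candidate_counts(percents: Sequence[float], n_max: int, n_min: int = 1) -> list[int]:
    """Denominators n <= n_max for which every percentage is some k/n re-rounded."""
    out = []
    for n in range(n_min, n_max + 1):
        if all(any(matches_printed(p, k, n) for k in range(n + 1)) for p in percents):
            out.append(n)
    return out


def _tp_candidates(row: PrintedRow, cases: int, non_cases: int) -> list[tuple[int, int]]:
    tps = [k for k in range(cases + 1) if matches_printed(row.sens, k, cases)]
    tns = [k for k in range(non_cases + 1) if matches_printed(row.spec, k, non_cases)]
    out = []
    for tp in tps:
        for tn in tns:
            fp = non_cases - tn
            fn = cases - tp
            if row.ppv is not None and not matches_printed(row.ppv, tp, tp + fp):
                continue
            if row.npv is not None and not matches_printed(row.npv, tn, tn + fn):
                continue
            out.append((tp, tn))
    return out


def recover_row(row: PrintedRow, cases: int, non_cases: int) -> ConfusionMatrix:
    """Recover one row's 2x2 counts given known denominators.

    If several (TP, TN) pairs re-round correctly — which can happen when the
    printed precision does not pin the last unit — the pair closest to the
    unrounded targets is returned; all candidates agree with the printed
    table at its own precision.
    """
    cands = _tp_candidates(row, cases, non_cases)
    if not cands:
        raise ValueError(f"no integer confusion matrix matches row {row}")
    target_tp = cases * row.sens / 100.0
    target_tn = non_cases * row.spec / 100.0
    tp, tn = min(cands, key=lambda c: (abs(c[0] - target_tp) + abs(c[1] - target_tn)))
    return ConfusionMatrix(tp=tp, fp=non_cases - tn, tn=tn, fn=cases - tp)


def recover_site(rows: Sequence[PrintedRow], n_max: int,
                 cases: Optional[int] = None,
                 non_cases: Optional[int] = None) -> tuple[int, int, list[ConfusionMatrix]]:
    """Jointly recover (cases, non_cases) and every row's counts for one site.

    All rows must share denominators; ``n_max`` bounds cases + non_cases
    (the study's analysed sample size). Known denominators can be supplied to
    restrict the search. Raises if no consistent solution exists; if several
    (cases, non_cases) pairs are consistent, the smallest total is taken (the
    larger ones are integer multiples carrying no extra information).
    """
    sens_list = [r.sens for r in rows]
    spec_list = [r.spec for r in rows]
    case_cands = [cases] if cases is not None else candidate_counts(sens_list, n_max)
    solutions = []
    for c in case_cands:
        nc_cands = ([non_cases] if non_cases is not None
                    else candidate_counts(spec_list, n_max - c))
        for nc in nc_cands:
            try:
                cms = [recover_row(r, c, nc) for r in rows]
            except ValueError:
                continue
            solutions.append((c, nc, cms))
    if not solutions:
        raise ValueError("no (cases, non_cases) pair reproduces every printed row")
    solutions.sort(key=lambda s: (s[0] + s[1], s[0]))
    return solutions[0]
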