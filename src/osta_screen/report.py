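"""Report rendering in the layout of the published accuracy tables.

Three styles are supported, mirroring the conventional presentation:

* ``table2`` — per-site cutoff scan: AUC (95% CI), sensitivity, specificity,
  PPV, NPV, LR+, Youden index;
* ``table3`` — age-stratified sensitivity/specificity with exact CIs;
* ``table4`` — head-to-head predictor comparison with paired p-values.

Display rounding follows the tables: percentages to 1 decimal, AUC and
Youden to 3, LR+ to 2; p-values below 0.001 render as "<0.001"; an
undefined LR+ renders as "inf". A full-precision JSON sidecar is always
written next to the TSV so no information is lost to rounding.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

from .metrics import CutoffPerformance
from .scan import ComparisonRow

__all__ = ["render_report", "write_report", "rows_to_json"]


def _f(x: float, nd: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return f"{x:.{nd}f}"


def _pct(x: float) -> str:
    return "NA" if (x is None or math.isnan(x)) else f"{100 * x:.1f}"


def _ci_pct(ci: tuple[float, float]) -> str:
    lo, hi = ci
    if math.isnan(lo) or math.isnan(hi):
        return "NA"
    return f"{100 * lo:.1f}-{100 * hi:.1f}"


def _auc_ci(auc: float, ci: tuple[float, float]) -> str:
    if math.isnan(auc):
        return "NA"
    return f"{auc:.3f} ({ci[0]:.3f}-{ci[1]:.3f})"


def _p_value(p) -> str:
    if p is None:
        return ""
    if math.isnan(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _table2(rows: Sequence[CutoffPerformance]) -> list[list[str]]:
    header = ["site", "cutoff", "auc_95ci", "sensitivity_pct", "specificity_pct",
              "ppv_pct", "npv_pct", "lr_plus", "youden"]
    body = [[
        r.site or "",
        _f(r.cutoff, 0) if r.cutoff is not None else "",
        _auc_ci(r.auc, r.auc_ci),
        _pct(r.sensitivity), _pct(r.specificity),
        _pct(r.ppv), _pct(r.npv),
        _f(r.lr_plus, 2), _f(r.youden, 3),
    ] for r in rows]
    return [header] + body


def _table3(rows: Sequence[CutoffPerformance]) -> list[list[str]]:
    header = ["age_group", "site", "cutoff", "sensitivity_pct", "sens_95ci",
              "specificity_pct", "spec_95ci"]
    body = [[
        r.stratum or "all", r.site or "",
        _f(r.cutoff, 0) if r.cutoff is not None else "",
        _pct(r.sensitivity), _ci_pct(r.sens_ci),
        _pct(r.specificity), _ci_pct(r.spec_ci),
    ] for r in rows]
    return [header] + body


def _table4(rows: Sequence[ComparisonRow]) -> list[list[str]]:
    header = ["predictor", "auc_95ci", "p_value", "sensitivity_pct", "sens_95ci",
              "specificity_pct", "spec_95ci"]
    body = [[
        r.name,
        _auc_ci(r.performance.auc, r.performance.auc_ci),
        _p_value(r.p_vs_reference),
        _pct(r.performance.sensitivity), _ci_pct(r.performance.sens_ci),
        _pct(r.performance.specificity), _ci_pct(r.performance.spec_ci),
    ] for r in rows]
    return [header] + body


_STYLES = {"table2": _table2, "table3": _table3, "table4": _table4}


def render_report(rows, style: str) -> str:
    """Render rows as a TSV string in one of the table styles."""
    if not rows:
        raise ValueError("no rows to render")
    try:
        fn = _STYLES[style]
    except KeyError:
        raise ValueError(f"unknown style {style!r}; choose from {sorted(_STYLES)}")
    return "\n".join("\t".join(cells) for cells in fn(rows)) + "\n"


def _perf_record(r: CutoffPerformance) -> dict:
    return {
        "site": r.site, "cutoff": r.cutoff, "stratum": r.stratum,
        "tp": r.cm.tp, "fp": r.cm.fp, "tn": r.cm.tn, "fn": r.cm.fn,
        "auc": r.auc, "auc_ci": list(r.auc_ci),
        "sensitivity": r.sensitivity, "sens_ci": list(r.sens_ci),
        "specificity": r.specificity, "spec_ci": list(r.spec_ci),
        "ppv": r.ppv, "ppv_ci": list(r.ppv_ci),
        "npv": r.npv, "npv_ci": list(r.npv_ci),
        "lr_plus": r.lr_plus, "youden": r.youden,
    }


def rows_to_json(rows) -> list[dict]:
    """Full-precision records for the JSON sidecar."""
    out = []
    for r in rows:
        if isinstance(r, ComparisonRow):
            rec = _perf_record(r.performance)
            rec.update({"predictor": r.name, "p_vs_reference": r.p_vs_reference})
            out.append(rec)
        else:
            out.append(_perf_record(r))
    return out


def _sanitize(obj):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_sanitize(v) for v in obj]
    return obj


def write_report(rows, style: str, path) -> Path:
    """Write the TSV report plus a full-precision ``.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(render_report(rows, style), encoding="utf-8")
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".json" \
        else path.with_suffix(".full.json")
    sidecar.write_text(
        json.dumps(_sanitize(rows_to_json(rows)), indent=2), encoding="utf-8")
    return sidecar
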