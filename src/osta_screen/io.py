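"""Cohort CSV reading/writing with row-level validation and quarantine.

The cohort file is plain UTF-8 CSV with a header: mandatory columns ``id``,
``age``, ``weight``; optional ``height``, the three T-score columns
(``t_lumbar``, ``t_femoral_neck``, ``t_total_hip``, at least one of which
must exist), optional boolean exclusion-flag columns named after the
exclusion reasons, and any extra columns (tolerated, passed through).
Empty cells are missing values. Rows that fail to parse or violate the
plausibility ranges are quarantined with a reason instead of aborting the
run; missing mandatory columns are a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import EXCLUSION_REASONS, T_COLUMNS
from .scores import AGE_RANGE, WEIGHT_RANGE

__all__ = ["ReadReport", "read_cohort", "write_cohort"]

MANDATORY = ("id", "age", "weight")
T_COLS = tuple(T_COLUMNS.values())
HEIGHT_RANGE = (100.0, 250.0)


@dataclass
class ReadReport:
    """Outcome of a cohort read: typed rows plus quarantined rejects."""

    cohort: pd.DataFrame
    quarantine: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    @property
    def n_retained(self) -> int:
        return len(self.cohort)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantine)


def _numeric(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def read_cohort(path) -> ReadReport:
    """Read and validate a cohort CSV.

    Range checks: age within [18, 120] y, weight within [20, 250] kg, height
    (when present) within [100, 250] cm. A row whose T-scores are all missing
    is retained only if it carries an exclusion flag (it will leave at the
    exclusion step); otherwise it is quarantined.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in MANDATORY if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks mandatory column(s): {missing}")
    if not any(c in raw.columns for c in T_COLS):
        raise ValueError(
            f"cohort file {path} has none of the T-score columns {T_COLS}")

    df = pd.DataFrame({"id": raw["id"].astype(str)})
    quarantine: list[tuple[int, str]] = []
    bad = np.zeros(len(raw), dtype=bool)

    def _take(col: str, lo: float, hi: float, required: bool):
        vals = _numeric(raw[col])
        unparsable = raw[col].notna() & vals.isna()
        out_of_range = vals.notna() & ((vals < lo) | (vals > hi))
        absent = vals.isna() & ~unparsable
        for i in np.flatnonzero(unparsable):
            quarantine.append((int(i), f"{col}: cannot parse {raw[col].iloc[i]!r}"))
        for i in np.flatnonzero(out_of_range):
            quarantine.append((int(i), f"{col}: {vals.iloc[i]} outside [{lo}, {hi}]"))
        newly_bad = unparsable | out_of_range
        if required:
            for i in np.flatnonzero(absent):
                quarantine.append((int(i), f"{col}: missing"))
            newly_bad |= absent
        return vals, newly_bad

    for col, (lo, hi) in (("age", AGE_RANGE), ("weight", WEIGHT_RANGE)):
        vals, newly = _take(col, lo, hi, required=True)
        df[col] = vals
        bad |= newly.to_numpy()
    if "height" in raw.columns:
        vals, newly = _take("height", *HEIGHT_RANGE, required=False)
        df["height"] = vals
        bad |= newly.to_numpy()

    t_present = np.zeros(len(raw), dtype=bool)
    for col in T_COLS:
        if col in raw.columns:
            vals = _numeric(raw[col])
            unparsable = raw[col].notna() & vals.isna()
            for i in np.flatnonzero(unparsable):
                quarantine.append((int(i), f"{col}: cannot parse {raw[col].iloc[i]!r}"))
            bad |= unparsable.to_numpy()
            df[col] = vals
            t_present |= vals.notna().to_numpy()

    flagged = np.zeros(len(raw), dtype=bool)
    for reason in EXCLUSION_REASONS:
        if reason in raw.columns:
            truthy = raw[reason].str.strip().str.lower().isin(
                {"1", "true", "t", "yes", "y"}).fillna(False)
            df[reason] = truthy.to_numpy()
            flagged |= truthy.to_numpy()

    no_t = ~t_present & ~flagged & ~bad
    for i in np.flatnonzero(no_t):
        quarantine.append((int(i), "no T-score at any site and no exclusion flag"))
    bad |= no_t

    extra = [c for c in raw.columns if c not in df.columns]
    for c in extra:
        df[c] = raw[c]

    return ReadReport(cohort=df.loc[~bad].reset_index(drop=True),
                      quarantine=sorted(quarantine))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV (UTF-8, '.' decimal, empty cells for missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, na_rep="")
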