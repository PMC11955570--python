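"""Screening predictors computed from demographics.

Three rules are supported, all oriented so that *lower scores mean higher
osteoporosis risk* (for the age rule, positivity is ``age >= threshold``):

* the OSTA index, ``0.2 * (weight_kg - age_years)`` with the decimal part
  discarded (an integer score; typical range roughly -11 to 6 in elderly men);
* a KKOS-style additive score, the sum of an age-band score and a
  weight-band score taken from a configured lookup table; the real published
  coefficient table is not bundled — it is loaded from JSON configuration;
* the simple age-threshold rule used by several screening guidelines
  (refer everyone aged 70 or older for DXA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AGE_RANGE",
    "WEIGHT_RANGE",
    "ScoreTable",
    "osta_index",
    "kkos_score",
    "age_rule",
]

#: Plausibility ranges used by input validation (years, kg).
AGE_RANGE = (18.0, 120.0)
WEIGHT_RANGE = (20.0, 250.0)


def _check_range(name: str, value, lo: float, hi: float) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite value")
    if np.any(arr < lo) or np.any(arr > hi):
        bad = arr[(arr < lo) | (arr > hi)]
        raise ValueError(
            f"{name}: value {float(np.atleast_1d(bad)[0])} outside plausible "
            f"range [{lo}, {hi}]"
        )
    return arr


def osta_index(weight, age, *, rounding: str = "truncate"):
    """OSTA index: ``0.2 * (weight - age)`` with decimals discarded.

    Parameters
    ----------
    weight, age:
        Body weight in kg and age in years; scalars or arrays.
    rounding:
        ``"truncate"`` (default) discards the decimal part toward zero, so
        -2.1 becomes -2; ``"floor"`` rounds toward minus infinity. The
        truncate convention is the one consistent with the published score
        range of cohorts like this one (a raw minimum near -11.6 printed as
        -11).

    Returns
    -------
    int or ndarray of int
        The integer screening score; lower values indicate higher risk.
    """
    w = _check_range("weight", weight, *WEIGHT_RANGE)
    a = _check_range("age", age, *AGE_RANGE)
    raw = 0.2 * (w - a)
    if rounding == "truncate":
        out = np.trunc(raw)
    elif rounding == "floor":
        out = np.floor(raw)
    else:
        raise ValueError(f"rounding must be 'truncate' or 'floor', got {rounding!r}")
    out = out.astype(int)
    if np.isscalar(weight) and np.isscalar(age):
        return int(out)
    return out


@dataclass(frozen=True)
class ScoreTable:
    """Additive age-band + weight-band score table (KKOS style).

    Bands are half-open intervals ``[lower, upper)``; within each of the two
    lists the bands must be non-overlapping and contiguous (no gaps), so that
    they jointly cover ``[first lower, last upper)``.
    """

    name: str
    age_bands: Sequence[tuple[float, float, float]]
    weight_bands: Sequence[tuple[float, float, float]]

    def __post_init__(self):
        for label, bands in (("age_bands", self.age_bands), ("weight_bands", self.weight_bands)):
            if not bands:
                raise ValueError(f"{label}: empty band list")
            prev_hi = None
            for lo, hi, score in bands:
                if not (np.isfinite(lo) and np.isfinite(hi) and np.isfinite(score)):
                    raise ValueError(f"{label}: non-finite band ({lo}, {hi}, {score})")
                if hi <= lo:
                    raise ValueError(f"{label}: empty band [{lo}, {hi})")
                if prev_hi is not None and lo != prev_hi:
                    kind = "gap" if lo > prev_hi else "overlap"
                    raise ValueError(f"{label}: {kind} between {prev_hi} and {lo}")
                prev_hi = hi

    @staticmethod
    def _lookup(bands, value: float, label: str) -> float:
        lo0 = bands[0][0]
        hi_last = bands[-1][1]
        if not (lo0 <= value < hi_last):
            raise ValueError(
                f"{label} {value} outside table domain [{lo0}, {hi_last})"
            )
        for lo, hi, score in bands:
            if lo <= value < hi:
                return float(score)
        raise AssertionError("validated bands must cover the domain")

    def age_score(self, age: float) -> float:
        return self._lookup(self.age_bands, float(age), "age")

    def weight_score(self, weight: float) -> float:
        return self._lookup(self.weight_bands, float(weight), "weight")

    def total(self, age: float, weight: float) -> float:
        return self.age_score(age) + self.weight_score(weight)

    @property
    def age_domain(self) -> tuple[float, float]:
        return (self.age_bands[0][0], self.age_bands[-1][1])

    @property
    def weight_domain(self) -> tuple[float, float]:
        return (self.weight_bands[0][0], self.weight_bands[-1][1])

    @classmethod
    def from_json(cls, path) -> "ScoreTable":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            name=data["name"],
            age_bands=[tuple(b) for b in data["age_bands"]],
            weight_bands=[tuple(b) for b in data["weight_bands"]],
        )

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "age_bands": [list(b) for b in self.age_bands],
            "weight_bands": [list(b) for b in self.weight_bands],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def kkos_score(age, weight, table: ScoreTable):
    """Additive band score: age-band score + weight-band score.

    Accepts scalars or equal-length arrays; raises a domain error naming the
    offending value when age or weight falls outside the table's coverage.
    """
    a = np.atleast_1d(np.asarray(age, dtype=float))
    w = np.atleast_1d(np.asarray(weight, dtype=float))
    if a.shape != w.shape:
        raise ValueError("age and weight must have matching shapes")
    out = np.array([table.total(ai, wi) for ai, wi in zip(a, w)])
    if np.isscalar(age) and np.isscalar(weight):
        return float(out[0])
    return out


def age_rule(age, threshold: float = 70.0):
    """Guideline age rule: positive (refer for DXA) iff ``age >= threshold``."""
    a = _check_range("age", age, *AGE_RANGE)
    out = a >= threshold
    if np.isscalar(age):
        return bool(out)
    return out
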