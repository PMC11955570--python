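"""Buderer sample-size planning for diagnostic accuracy studies.

The target is a confidence-interval half-width ``d`` for sensitivity or
specificity. The number of *diseased* subjects needed for sensitivity S is
``z^2 S(1-S) / d^2``; dividing by the prevalence P gives the total
enrollment. Specificity is symmetric with ``1 - P`` in the denominator:

    n_sens = ceil( z^2 * S(1-S) / (d^2 * P) )
    n_spec = ceil( z^2 * Sp(1-Sp) / (d^2 * (1-P)) )

with z the standard-normal quantile at (1 + confidence)/2. The study
enrollment floor is the larger of the two.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = ["SampleSizeSpec", "n_for_sensitivity", "n_for_specificity", "required_n"]


@dataclass(frozen=True)
class SampleSizeSpec:
    target_sens: float
    target_spec: float
    prevalence: float
    margin: float
    confidence: float = 0.95

    def __post_init__(self):
        for name in ("target_sens", "target_spec", "prevalence", "margin", "confidence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("target_sens", "target_spec"):
            t = getattr(self, name)
            if self.margin >= min(t, 1.0 - t):
                warnings.warn(
                    f"margin {self.margin} is not below min({name}, 1-{name}); "
                    "the interval may be uninformative", stacklevel=2)

    @property
    def z(self) -> float:
        return float(stats.norm.ppf((1.0 + self.confidence) / 2.0))


def _ceil_n(value: float) -> int:
    n = math.ceil(value - 1e-12)  # guard against FP noise just above an integer
    if n < 1:
        warnings.warn("computed sample size below 1; returning 1", stacklevel=3)
        return 1
    return n


def n_for_sensitivity(spec: SampleSizeSpec) -> int:
    """Total enrollment to pin sensitivity within +/- margin."""
    s = spec.target_sens
    return _ceil_n(spec.z ** 2 * s * (1.0 - s) / (spec.margin ** 2 * spec.prevalence))


def n_for_specificity(spec: SampleSizeSpec) -> int:
    """Total enrollment to pin specificity within +/- margin."""
    sp = spec.target_spec
    return _ceil_n(spec.z ** 2 * sp * (1.0 - sp) / (spec.margin ** 2 * (1.0 - spec.prevalence)))


def required_n(spec: SampleSizeSpec) -> dict[str, int]:
    """Both requirements and the enrollment floor (their maximum)."""
    ns = n_for_sensitivity(spec)
    np_ = n_for_specificity(spec)
    return {"n_sens": ns, "n_spec": np_, "n_required": max(ns, np_)}
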