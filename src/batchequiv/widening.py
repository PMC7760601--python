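"""Reference-scaled widening of the +/-10 % acceptance range.

For quality attributes so variable that no feasible sample size yields 80 %
power inside the fixed 90.00-111.11 % range, the acceptance limits can be
widened in proportion to the total variability of the reference product on
the log scale, the same mechanism regulators apply to Cmax for highly
variable drugs — but anchored to a 10 % range instead of 20 %:

    limits = exp( -kappa * s_R ), exp( +kappa * s_R ),

where s_R is the total log-scale standard deviation of the reference product
and the proportionality constant kappa is fixed so that the limits equal
exactly (0.9, 1/0.9) at a chosen anchor variability CV0:

    kappa = ln(1/0.9) / s_0,    s_0 = sqrt(ln(1 + (CV0/100)²)).

Here the exact lognormal CV-sigma relation is used (unlike the simulation
model's omega = CV/100); only this relation reproduces the regulatory-style
constants kappa(10) = 1.056, kappa(20) = 0.532, kappa(30) = 0.3589.

Widened limits are reported, never silently applied: the equivalence test
keeps the fixed range unless scaled limits are requested explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASE_LOG_LIMIT",
    "WideningSpec",
    "cv_to_sigma_total",
    "widening_constant",
    "widened_limits",
    "estimate_sigma_reference",
]

#: ln(1/0.9) ~ 0.10536, the log of the upper +/-10 % limit.
BASE_LOG_LIMIT: float = math.log(1.0 / 0.9)


def cv_to_sigma_total(cv: float) -> float:
    """Lognormal total log-scale SD for a percent CV: sqrt(ln(1 + (CV/100)²))."""
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    return math.sqrt(math.log1p((cv / 100.0) ** 2))


def widening_constant(cv0: float) -> float:
    """Proportionality constant kappa = ln(1/0.9) / s_0 for anchor CV0 (percent).

    kappa is strictly decreasing in cv0: the later widening starts, the gentler
    the scaling.
    """
    if cv0 <= 0:
        raise ValueError(f"cv0 must be > 0, got {cv0}")
    return BASE_LOG_LIMIT / cv_to_sigma_total(cv0)


def widened_limits(kappa: float, s_reference: float) -> tuple[float, float]:
    """Scaled acceptance limits (exp(-kappa*s_R), exp(+kappa*s_R)).

    Reciprocal by construction; collapse to (1, 1) at zero variability and
    equal (0.9, 1/0.9) at the anchor s_R = s_0.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if s_reference < 0:
        raise ValueError(f"s_reference must be >= 0, got {s_reference}")
    half = kappa * s_reference
    return (math.exp(-half), math.exp(half))


def estimate_sigma_reference(ref_values) -> float:
    """Total log-scale SD of reference measurements (sample SD, ddof=1).

    A helper for applying the widening rule to real data; it estimates total
    variability (inter- plus intra-batch) without decomposing it.
    """
    logs = np.log(np.asarray(ref_values, dtype=float).ravel())
    if logs.size < 2:
        raise ValueError("at least two reference values are required")
    return float(np.std(logs, ddof=1))


@dataclass(frozen=True)
class WideningSpec:
    """Widening rule anchored at total reference variability ``cv0`` (percent)."""

    cv0: float
    kappa: float = field(init=False)
    base_log_limit: float = field(init=False, default=BASE_LOG_LIMIT)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kappa", widening_constant(self.cv0))

    def limits_for_cv(self, cv_reference: float) -> tuple[float, float]:
        """Acceptance limits when the reference shows total CV ``cv_reference`` %."""
        return widened_limits(self.kappa, cv_to_sigma_total(cv_reference))

    def limits_for_sigma(self, s_reference: float) -> tuple[float, float]:
        return widened_limits(self.kappa, s_reference)
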