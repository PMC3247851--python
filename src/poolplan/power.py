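"""Approximate case-control power and minimum detectable odds ratio.

Pool-adjusted power calculations plug the *effective* sample sizes of the
case and control pools into an ordinary case-control power formula. This
module uses the allelic (per-chromosome) two-proportion normal
approximation: each group of ``ess`` individuals contributes ``2 * ess``
chromosomes; under a log-additive (multiplicative-odds) model a per-allele
odds ratio OR shifts the case risk-allele frequency to

    p_case = OR * p / (1 + p * (OR - 1)),

and the two-sided level-alpha z-test of the frequency difference has power

    Phi((|d| - z_{1-a/2} * se0) / se1)  +  Phi((-|d| - z_{1-a/2} * se0) / se1)

with ``d = p_case - p_control``, ``se0`` the pooled-null and ``se1`` the
alternative standard error. This is the standard approximation for allelic
trend tests in unmatched designs with common diseases treated as rare
(control frequencies ~ population frequencies); it is not intended to agree
bit-for-bit with any particular genetic power calculator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ParameterError, UnreachableError

__all__ = [
    "PowerSpec",
    "case_allele_frequency",
    "power_case_control",
    "minimum_detectable_or",
    "power_curve",
]


@dataclass
class PowerSpec:
    """Inputs of a pool-adjusted case-control power calculation."""

    ess_case: float
    ess_control: float
    p_risk: float
    odds_ratio: float = 1.0
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self):
        if self.ess_case <= 0 or self.ess_control <= 0:
            raise ParameterError("effective sample sizes must be > 0")
        if not 0 < self.p_risk < 1:
            raise ParameterError("p_risk must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ParameterError("odds_ratio must be > 0")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")


def case_allele_frequency(p_risk: float, odds_ratio: float) -> float:
    """Risk-allele frequency in cases under a per-allele odds ratio."""
    return odds_ratio * p_risk / (1.0 + p_risk * (odds_ratio - 1.0))


def power_case_control(spec: PowerSpec) -> float:
    """Two-sided power of the allelic two-proportion z-test."""
    m1 = 2.0 * spec.ess_case  # chromosomes
    m0 = 2.0 * spec.ess_control
    p0 = spec.p_risk
    p1 = case_allele_frequency(p0, spec.odds_ratio)
    d = p1 - p0
    pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
    se0 = math.sqrt(pbar * (1.0 - pbar) * (1.0 / m1 + 1.0 / m0))
    se1 = math.sqrt(p1 * (1.0 - p1) / m1 + p0 * (1.0 - p0) / m0)
    z = norm.ppf(1.0 - spec.alpha / 2.0)
    return float(
        norm.cdf((abs(d) - z * se0) / se1) + norm.cdf((-abs(d) - z * se0) / se1)
    )


def minimum_detectable_or(spec: PowerSpec, tol: float = 1e-4) -> float:
    """Smallest odds ratio > 1 detectable at ``spec.target_power``.

    Bisection on log(OR); power is strictly increasing in OR above 1, so the
    root is unique. Raises :class:`UnreachableError` if even an extreme odds
    ratio cannot reach the target power.
    """
    if not spec.alpha < spec.target_power < 1:
        raise ParameterError("target_power must be in (alpha, 1)")
    lo, hi = 0.0, math.log(1000.0)
    if power_case_control(replace(spec, odds_ratio=math.exp(hi))) < spec.target_power:
        raise UnreachableError(
            f"power {spec.target_power} unreachable even at OR = e^{hi:.0f}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_case_control(replace(spec, odds_ratio=math.exp(mid))) >= spec.target_power:
            hi = mid
        else:
            lo = mid
    return math.exp(hi)


def power_curve(spec: PowerSpec, odds_ratios) -> pd.DataFrame:
    """Power over a grid of odds ratios (columns ``or``, ``power``)."""
    ors = np.asarray(odds_ratios, dtype=float)
    powers = [power_case_control(replace(spec, odds_ratio=float(o))) for o in ors]
    return pd.DataFrame({"or": ors, "power": powers})
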