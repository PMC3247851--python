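"""Effective-sample-size planning for DNA-pooling GWAS.

A pool of N individuals measured with pooling error variance
``var(e_pooling)`` carries the information of fewer than N individually
genotyped samples. The loss is expressed through the relative sample size

    RSS = Vs / (Vs + var(e_pooling) / k),        Vs = p (1 - p) / (2 N),

where ``p`` is the average minor allele frequency on the array, ``Vs`` the
binomial sampling variance of the pool's true allele frequency, and ``k`` the
number of replicate arrays (replicates reduce the pooling variance by 1/k).
The effective sample size is ``N* = RSS * N`` (rounded to nearest).

``var(e_pooling) = var(e_array) + var(e_construction)``; the construction
part may be given explicitly or as an array:construction ratio read as shares
of the total pooling variance (ratio 7:3 means construction is 30% of the
total, i.e. ``var_pooling = var_array / 0.7``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .exceptions import ConfigurationError, ParameterError, UnreachableError

__all__ = [
    "DEFAULT_MAF_1M",
    "DEFAULT_MAF_660",
    "PlannerInput",
    "PlannerRow",
    "PlanningTable",
    "sampling_variance",
    "relative_sample_size",
    "effective_sample_size",
    "resolve_pooling_variance",
    "planning_table",
    "arrays_for_target_rss",
    "optimal_allocation",
    "cost_summary",
    "CostSummary",
]

#: Average HapMap CEU minor allele frequency of the 1M-class Illumina arrays.
DEFAULT_MAF_1M = 0.21
#: Average HapMap CEU minor allele frequency of the 660-class Illumina array.
DEFAULT_MAF_660 = 0.29


@dataclass
class PlannerInput:
    """Parameters describing one DNA pool for planning.

    Exactly one of ``var_construction`` (absolute) or ``ratio`` (an
    array:construction pair such as ``(7, 3)``, read as shares of total
    pooling variance) must be given.
    """

    var_array: float
    n_individuals: int
    avg_maf: float = DEFAULT_MAF_660
    var_construction: float | None = None
    ratio: tuple[float, float] | None = None
    k_max: int = 24
    reduce: str = "pooling"  # "pooling": 1/k applies to the whole var(e_pooling)

    def __post_init__(self):
        if self.var_array < 0:
            raise ParameterError("var_array must be >= 0")
        if not 0 < self.avg_maf <= 0.5:
            raise ParameterError("avg_maf must be in (0, 0.5]")
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be >= 1")
        if self.reduce not in ("pooling", "array-only"):
            raise ParameterError("reduce must be 'pooling' or 'array-only'")

    @property
    def sampling_variance(self) -> float:
        return sampling_variance(self.avg_maf, self.n_individuals)

    @property
    def var_pooling(self) -> float:
        return resolve_pooling_variance(self)

    def rss(self, k: int) -> float:
        """Relative sample size with k replicate arrays."""
        if k < 1 or k != int(k):
            raise ParameterError(f"k must be a positive integer, got {k}")
        if self.reduce == "pooling":
            reduced = self.var_pooling / k
        else:
            # only the array component averages over replicate arrays
            reduced = self.var_array / k + (self.var_pooling - self.var_array)
        Vs = self.sampling_variance
        return Vs / (Vs + reduced)

    def ess(self, k: int) -> int:
        """Effective sample size N* with k replicate arrays."""
        return effective_sample_size(self.rss(k), self.n_individuals)


@dataclass
class PlannerRow:
    """One line of a planning table."""

    k: int
    rss: float
    ess: int


@dataclass
class PlanningTable:
    """Planning table plus the diminishing-returns marker.

    ``diminishing_returns_k`` is the smallest k at which adding one more
    array gains fewer than ``threshold`` effective individuals (None if the
    gain never drops below the threshold within k_max).
    """

    rows: list[PlannerRow]
    diminishing_returns_k: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"k": r.k, "rss": r.rss, "ess": r.ess} for r in self.rows])

    def plot(self, ax=None, **kwargs):
        """Plot RSS versus number of replicate arrays."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        ax.plot(df["k"], df["rss"], marker="o", **kwargs)
        ax.set_xlabel("replicate arrays per pool (k)")
        ax.set_ylabel("relative sample size")
        ax.set_ylim(0, 1.02)
        return ax


def sampling_variance(p: float, N: int) -> float:
    """Binomial sampling variance Vs = p(1-p)/(2N) of a pool of N diploids."""
    if not 0 < p < 1:
        raise ParameterError(f"allele frequency must be in (0, 1), got {p}")
    if N < 1:
        raise ParameterError(f"pool size must be >= 1, got {N}")
    return p * (1.0 - p) / (2.0 * N)


def relative_sample_size(Vs: float, var_pooling: float, k: int) -> float:
    """RSS = Vs / (Vs + var_pooling / k) with k replicate arrays."""
    if k < 1 or k != int(k):
        raise ParameterError(f"k must be a positive integer, got {k}")
    if var_pooling < 0:
        raise ParameterError("var_pooling must be >= 0")
    return Vs / (Vs + var_pooling / k)


def effective_sample_size(rss: float, N: int) -> int:
    """N* = RSS * N, rounded to the nearest integer."""
    if not 0 < rss <= 1:
        raise ParameterError(f"rss must be in (0, 1], got {rss}")
    return int(round(rss * N))


def resolve_pooling_variance(inp: PlannerInput) -> float:
    """Total pooling variance from an explicit construction term or a ratio.

    Ratio ``(a, c)`` is read as shares of the total:
    ``var_pooling = var_array * (a + c) / a``.
    """
    if (inp.var_construction is None) == (inp.ratio is None):
        raise ConfigurationError(
            "give exactly one of var_construction or ratio (array:construction)"
        )
    if inp.var_construction is not None:
        if inp.var_construction < 0:
            raise ParameterError("var_construction must be >= 0")
        return inp.var_array + inp.var_construction
    a, c = inp.ratio
    if a <= 0 or c < 0:
        raise ParameterError(f"invalid array:construction ratio {inp.ratio}")
    return inp.var_array * (a + c) / a


def planning_table(inp: PlannerInput, dess_threshold: float = 1.0) -> PlanningTable:
    """RSS and N* for k = 1..k_max, with a diminishing-returns marker."""
    rows = [PlannerRow(k, inp.rss(k), inp.ess(k)) for k in range(1, inp.k_max + 1)]
    marker = None
    for prev, cur in zip(rows, rows[1:]):
        if cur.ess - prev.ess < dess_threshold:
            marker = cur.k
            break
    return PlanningTable(rows=rows, diminishing_returns_k=marker)


def arrays_for_target_rss(inp: PlannerInput, target_rss: float) -> int:
    """Smallest number of replicate arrays achieving RSS >= target.

    Closed form: RSS >= t  <=>  k >= t * var_pooling / (Vs * (1 - t)).
    """
    if not 0 < target_rss < 1:
        raise UnreachableError(
            f"target RSS must be in (0, 1), got {target_rss}"
        )
    vp = inp.var_pooling
    if vp == 0:
        return 1
    exact = target_rss * vp / (inp.sampling_variance * (1.0 - target_rss))
    k = max(1, math.ceil(exact - 1e-12))  # guard float fuzz at exact boundaries
    while inp.rss(k) < target_rss:  # safety: never trust the closed form blindly
        k += 1
    return k


def optimal_allocation(
    total_arrays: int, poolA: PlannerInput, poolB: PlannerInput
) -> tuple[int, int]:
    """Split a budget of arrays between two pools to maximize power.

    The case-control frequency-difference variance contributed by estimation
    error is ``var_poolingA/kA + var_poolingB/kB``; the split minimizing it is
    found by exhaustive scan, ties broken toward the more balanced split
    (then toward the smaller kA). With equal pooling variances the optimum is
    the equal split, regardless of pool sizes.
    """
    if total_arrays < 2:
        raise ParameterError("need at least 2 arrays (1 per pool)")
    vA, vB = poolA.var_pooling, poolB.var_pooling
    best = None
    for kA in range(1, total_arrays):
        kB = total_arrays - kA
        objective = vA / kA + vB / kB
        key = (objective, abs(kA - kB), kA)
        if best is None or key < best[0]:
            best = (key, (kA, kB))
    return best[1]


@dataclass
class CostSummary:
    pooling_cost: float
    individual_cost: float
    percent: float


def cost_summary(
    n_pools: int, arrays_per_pool: int, array_price: float, n_individuals: int
) -> CostSummary:
    """Cost of a pooled design versus individually genotyping every sample."""
    if min(n_pools, arrays_per_pool, n_individuals) < 1 or array_price <= 0:
        raise ParameterError("all cost inputs must be positive")
    pooling = n_pools * arrays_per_pool * array_price
    individual = n_individuals * array_price
    return CostSummary(pooling, individual, 100.0 * pooling / individual)
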