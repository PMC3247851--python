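"""Variance-component decomposition from paired allelotyping arrays.

The error in a pool-derived allele-frequency estimate has two main sources:
the array measurement itself and the physical construction of the pool
(quantification and pipetting of the individual DNAs). Writing the estimate
on array *x* of pool *a* as ``p~_ax = p^_a + e_array_x`` (plus a construction
error shared by all arrays of a constructed pool), the components are
separated by contrasting pairs of arrays:

* **Type A** — two arrays of the *same* pool. The only error source is the
  array:  ``var(e_array) = var(p~_a1 - p~_a2) / 2``.
* **Type B** — arrays of two *independently constructed but identical* pools
  (same individuals). Array and construction errors both enter:
  ``var(e_pooling-1) = var(p~_a1 - p~_b2) / 2``.
* **Type C** — arrays of pools of *different* individuals. Binomial sampling
  of individuals adds a per-SNP variance ``V~`` that must be subtracted:
  ``var(e_pooling-2) = (1/(n-2)) * sum_i [ (p~_a1,i - p~_b2,i)^2 - V~_i ] / 2``.

Here ``var(d)`` of a SNP-wise difference is computed as
``(1/(n-2)) * sum_i d_i^2`` over the n SNPs shared by the two tables, and
``V~_i = p1(1-p1)/(2 Na) + p2(1-p2)/(2 Nb)`` from the observed pair of
frequencies (diploid individuals, hence 2N chromosomes per pool). When a pool
is measured on more than two arrays, the best estimate of each component is
the average over all possible array pairings.

Pool-construction variance is obtained by subtraction,
``var(e_construction) = var(e_pooling) - var(e_array)``, clamped at zero.

The module exposes both a functional surface (one estimator per comparison
type) and a model/results pair: :class:`PooledExperiment` holds the frequency
tables and pool metadata of an experiment, and its :meth:`~PooledExperiment.fit`
returns a :class:`VarianceDecomposition` with per-batch and per-pool
estimates and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    InsufficientOverlapError,
    InsufficientReplicatesError,
    MisuseError,
)
from .io_beads import FrequencyTable, build_frequency_table, filter_beads
from .normalize import normalize_array

__all__ = [
    "PoolMeta",
    "VarianceEstimate",
    "paired_diff_variance",
    "array_variance_pair",
    "array_variance_pool",
    "pooling_variance_replicate",
    "binomial_pair_variance",
    "pooling_variance_nonidentical",
    "construction_variance",
    "decompose_experiment",
    "flag_outlier_arrays",
    "PooledExperiment",
    "VarianceDecomposition",
    "read_pool_metadata",
]


@dataclass
class PoolMeta:
    """Metadata of one DNA pool."""

    pool_id: str
    n_individuals: int
    batch_id: str | None = None
    replicate_of: str | None = None

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ConfigurationError(
                f"pool {self.pool_id!r}: n_individuals must be >= 1"
            )


@dataclass
class VarianceEstimate:
    """A labelled variance component with its provenance.

    ``value`` is on the squared allele-frequency scale and non-negative after
    clamping; ``value_before_clamp`` preserves the raw (possibly negative)
    estimate for diagnostics.
    """

    kind: str  # array | pooling_replicate | pooling_nonidentical | construction
    value: float
    n_snps: int
    n_pairings: int
    negative_before_clamp: bool = False
    value_before_clamp: float | None = None
    fraction_of_pooling: float | None = None


def paired_diff_variance(
    ft1: FrequencyTable, ft2: FrequencyTable
) -> tuple[float, int]:
    """Variance of the SNP-wise frequency difference between two arrays.

    Computed as ``(1/(n-2)) * sum_i (p1_i - p2_i)^2`` over the n SNPs in the
    intersection of the two tables; requires n > 2.
    """
    shared = ft1.data.index.intersection(ft2.data.index)
    n = len(shared)
    if n <= 2:
        raise InsufficientOverlapError(
            f"arrays {ft1.array_id!r} and {ft2.array_id!r} share only {n} SNPs"
        )
    d = ft1.data["freq"].loc[shared].to_numpy() - ft2.data["freq"].loc[shared].to_numpy()
    return float(np.sum(d * d) / (n - 2)), n


def array_variance_pair(ft1: FrequencyTable, ft2: FrequencyTable) -> VarianceEstimate:
    """Type A estimate from one pair of replicate arrays of the same pool."""
    value, n = paired_diff_variance(ft1, ft2)
    return VarianceEstimate(kind="array", value=value / 2.0, n_snps=n, n_pairings=1)


def array_variance_pool(tables: Sequence[FrequencyTable]) -> VarianceEstimate:
    """Type A estimate for one pool: average over all C(k, 2) array pairings."""
    if len(tables) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicate arrays, got {len(tables)}"
        )
    pairs = [array_variance_pair(a, b) for a, b in combinations(tables, 2)]
    return VarianceEstimate(
        kind="array",
        value=float(np.mean([p.value for p in pairs])),
        n_snps=int(round(np.mean([p.n_snps for p in pairs]))),
        n_pairings=len(pairs),
    )


def pooling_variance_replicate(
    tablesA: Sequence[FrequencyTable],
    tablesB: Sequence[FrequencyTable],
    metaA: PoolMeta,
    metaB: PoolMeta,
) -> VarianceEstimate:
    """Type B estimate from two independently constructed identical pools.

    Averages ``var(p~_a - p~_b)/2`` over all cross pairings (one array from
    each pool). The two pools must be linked as construction replicates.
    """
    linked = metaA.replicate_of == metaB.pool_id or metaB.replicate_of == metaA.pool_id
    if not linked:
        raise MisuseError(
            f"pools {metaA.pool_id!r} and {metaB.pool_id!r} are not construction replicates"
        )
    values, ns = [], []
    for ta in tablesA:
        for tb in tablesB:
            v, n = paired_diff_variance(ta, tb)
            values.append(v / 2.0)
            ns.append(n)
    return VarianceEstimate(
        kind="pooling_replicate",
        value=float(np.mean(values)),
        n_snps=int(round(np.mean(ns))),
        n_pairings=len(values),
    )


def binomial_pair_variance(p1, p2, Na: int, Nb: int, denominator: str = "2N"):
    """Per-SNP binomial sampling variance ``V~`` of a frequency difference.

    ``p1(1-p1)/(2 Na) + p2(1-p2)/(2 Nb)`` under the default diploid ("2N")
    convention — the variance of a difference of two independent pool
    frequencies. ``denominator="N"`` divides by the individual counts instead.
    Accepts scalars or arrays.
    """
    if denominator == "2N":
        da, db = 2.0 * Na, 2.0 * Nb
    elif denominator == "N":
        da, db = float(Na), float(Nb)
    else:
        raise ConfigurationError(f"denominator must be '2N' or 'N', got {denominator!r}")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    out = p1 * (1.0 - p1) / da + p2 * (1.0 - p2) / db
    return float(out) if out.ndim == 0 else out


def pooling_variance_nonidentical(
    tablesA: Sequence[FrequencyTable],
    tablesB: Sequence[FrequencyTable],
    metaA: PoolMeta,
    metaB: PoolMeta,
    denominator: str = "2N",
) -> VarianceEstimate:
    """Type C estimate from two pools of different individuals.

    Per cross pairing: ``(1/(n-2)) * sum_i [(p~_a,i - p~_b,i)^2 - V~_i] / 2``
    with ``V~_i`` from the observed pair of frequencies. The average over
    pairings may be negative (the correction overshoots); it is clamped at
    zero with the raw value retained.
    """
    values, ns = [], []
    for ta in tablesA:
        for tb in tablesB:
            shared = ta.data.index.intersection(tb.data.index)
            n = len(shared)
            if n <= 2:
                raise InsufficientOverlapError(
                    f"arrays {ta.array_id!r} and {tb.array_id!r} share only {n} SNPs"
                )
            pa = ta.data["freq"].loc[shared].to_numpy()
            pb = tb.data["freq"].loc[shared].to_numpy()
            v = binomial_pair_variance(
                pa, pb, metaA.n_individuals, metaB.n_individuals, denominator
            )
            values.append(float(np.sum((pa - pb) ** 2 - v) / (n - 2) / 2.0))
            ns.append(n)
    raw = float(np.mean(values))
    return VarianceEstimate(
        kind="pooling_nonidentical",
        value=max(0.0, raw),
        n_snps=int(round(np.mean(ns))),
        n_pairings=len(values),
        negative_before_clamp=raw < 0,
        value_before_clamp=raw,
    )


def construction_variance(
    pooling: VarianceEstimate, array: VarianceEstimate
) -> VarianceEstimate:
    """Pool-construction variance by subtraction, clamped at zero.

    Also reports the construction share of the pooling variance
    (``fraction_of_pooling``, 0 when the pooling variance is 0).
    """
    if pooling.kind not in ("pooling_replicate", "pooling_nonidentical"):
        raise MisuseError(f"first argument must be a pooling estimate, got {pooling.kind!r}")
    if array.kind != "array":
        raise MisuseError(f"second argument must be an array estimate, got {array.kind!r}")
    raw = pooling.value - array.value
    value = max(0.0, raw)
    fraction = value / pooling.value if pooling.value > 0 else 0.0
    return VarianceEstimate(
        kind="construction",
        value=value,
        n_snps=pooling.n_snps,
        n_pairings=pooling.n_pairings,
        negative_before_clamp=raw < 0,
        value_before_clamp=raw,
        fraction_of_pooling=fraction,
    )


def flag_outlier_arrays(
    tables_by_pool: Mapping[str, Sequence[FrequencyTable]], factor: float = 5.0
) -> list[str]:
    """Flag arrays whose mean within-pool pairwise variance is extreme.

    A faulty array inflates every Type A pairing it participates in; an array
    is flagged when its mean pairwise estimate exceeds ``factor`` times the
    median over all arrays (pools with a single array are ignored). The
    flagged arrays are reported, not removed.
    """
    per_array: dict[str, list[float]] = {}
    for tables in tables_by_pool.values():
        if len(tables) < 2:
            continue
        for a, b in combinations(tables, 2):
            est = array_variance_pair(a, b).value
            per_array.setdefault(a.array_id, []).append(est)
            per_array.setdefault(b.array_id, []).append(est)
    if not per_array:
        return []
    means = {aid: float(np.mean(v)) for aid, v in per_array.items()}
    med = float(np.median(list(means.values())))
    if med == 0.0:
        return [aid for aid, m in means.items() if m > 0]
    return sorted(aid for aid, m in means.items() if m > factor * med)


@dataclass
class PoolDecomposition:
    """Per-pool variance components within one batch."""

    pool_id: str
    n_arrays: int
    array: VarianceEstimate | None
    pooling: VarianceEstimate | None
    construction: VarianceEstimate | None


@dataclass
class BatchDecomposition:
    """Variance components for one genotyping batch (or the whole experiment)."""

    batch_id: str
    array_mean: float
    array_min: float
    array_max: float
    n_array_estimates: int
    pools: dict[str, PoolDecomposition] = field(default_factory=dict)


class VarianceDecomposition:
    """Results of :meth:`PooledExperiment.fit`.

    Carries per-batch mean/range of the array variance, per-pool pooling and
    construction estimates, and the list of flagged outlier arrays.
    """

    def __init__(
        self,
        batches: dict[str, BatchDecomposition],
        flagged_arrays: list[str],
        denominator: str,
    ):
        self.batches = batches
        self.flagged_arrays = flagged_arrays
        self.denominator = denominator

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per (scope, kind) estimate."""
        rows = []
        for b in self.batches.values():
            rows.append(
                dict(scope=f"batch:{b.batch_id}", kind="array", value=b.array_mean,
                     n_snps=np.nan, n_pairings=b.n_array_estimates,
                     fraction_of_pooling=np.nan)
            )
            for p in b.pools.values():
                for est in (p.array, p.pooling, p.construction):
                    if est is None:
                        continue
                    rows.append(
                        dict(scope=f"pool:{p.pool_id}", kind=est.kind, value=est.value,
                             n_snps=est.n_snps, n_pairings=est.n_pairings,
                             fraction_of_pooling=est.fraction_of_pooling
                             if est.fraction_of_pooling is not None else np.nan)
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable decomposition table."""
        buf = io.StringIO()
        buf.write("Pooling variance decomposition\n")
        buf.write(f"  binomial denominator: {self.denominator}\n")
        for b in self.batches.values():
            buf.write(f"\nBatch {b.batch_id}\n")
            buf.write(
                f"  var(e_array): mean {b.array_mean:.3e} "
                f"(range {b.array_min:.3e} .. {b.array_max:.3e}, "
                f"{b.n_array_estimates} pool estimate(s))\n"
            )
            for p in b.pools.values():
                buf.write(f"  pool {p.pool_id} ({p.n_arrays} arrays)\n")
                if p.pooling is None:
                    buf.write("    var(e_pooling): unavailable (no partner pool)\n")
                    continue
                label = ("Type B" if p.pooling.kind == "pooling_replicate" else "Type C")
                buf.write(
                    f"    var(e_pooling) [{label}]: {p.pooling.value:.3e} "
                    f"({p.pooling.n_pairings} pairings)\n"
                )
                if p.construction is not None:
                    pct = 100.0 * (p.construction.fraction_of_pooling or 0.0)
                    clamp = " (clamped)" if p.construction.negative_before_clamp else ""
                    buf.write(
                        f"    var(e_construction): {p.construction.value:.3e} "
                        f"= {pct:.0f}% of pooling{clamp}\n"
                    )
        if self.flagged_arrays:
            buf.write(f"\nFlagged outlier arrays: {', '.join(self.flagged_arrays)}\n")
        return buf.getvalue()


def decompose_experiment(
    tables_by_pool: Mapping[str, Sequence[FrequencyTable]],
    metas: Mapping[str, PoolMeta],
    group_by_batch: bool = False,
    denominator: str = "2N",
    outlier_factor: float = 5.0,
) -> VarianceDecomposition:
    """Full decomposition of a multi-pool allelotyping experiment.

    Per batch (or globally), the array variance is the mean of the per-pool
    Type A estimates. Per pool, the pooling variance is Type B against its
    construction replicate when one exists, otherwise Type C against every
    other (non-replicate) pool, averaging all cross pairings involving the
    pool; the construction variance subtracts the batch mean array variance.
    """
    missing = set(tables_by_pool) - set(metas)
    if missing:
        raise ConfigurationError(f"no metadata for pool(s) {sorted(missing)}")

    def batch_of(pid: str) -> str:
        return (metas[pid].batch_id or "all") if group_by_batch else "all"

    def replicate_partner(pid: str) -> str | None:
        m = metas[pid]
        if m.replicate_of and m.replicate_of in tables_by_pool:
            return m.replicate_of
        for other, om in metas.items():
            if om.replicate_of == pid and other in tables_by_pool:
                return other
        return None

    batches: dict[str, BatchDecomposition] = {}
    for batch_id in sorted({batch_of(p) for p in tables_by_pool}):
        pool_ids = sorted(p for p in tables_by_pool if batch_of(p) == batch_id)
        array_ests = {
            p: array_variance_pool(tables_by_pool[p])
            for p in pool_ids
            if len(tables_by_pool[p]) >= 2
        }
        if not array_ests:
            raise InsufficientReplicatesError(
                f"batch {batch_id!r}: no pool has >= 2 replicate arrays; "
                "array variance cannot be estimated"
            )
        values = [e.value for e in array_ests.values()]
        batch = BatchDecomposition(
            batch_id=batch_id,
            array_mean=float(np.mean(values)),
            array_min=float(np.min(values)),
            array_max=float(np.max(values)),
            n_array_estimates=len(values),
        )
        mean_array = VarianceEstimate(
            kind="array",
            value=batch.array_mean,
            n_snps=int(round(np.mean([e.n_snps for e in array_ests.values()]))),
            n_pairings=int(np.sum([e.n_pairings for e in array_ests.values()])),
        )

        for pid in pool_ids:
            tables = tables_by_pool[pid]
            partner = replicate_partner(pid)
            pooling: VarianceEstimate | None = None
            if partner is not None and batch_of(partner) == batch_id:
                pooling = pooling_variance_replicate(
                    tables, tables_by_pool[partner], metas[pid], metas[partner]
                )
            else:
                others = [
                    q for q in pool_ids
                    if q != pid and replicate_partner(q) != pid and q != partner
                ]
                if others:
                    values_c, ns, n_pairs = [], [], 0
                    for q in others:
                        est = pooling_variance_nonidentical(
                            tables, tables_by_pool[q], metas[pid], metas[q], denominator
                        )
                        # re-average raw per-pairing means weighted by pairing count
                        values_c.append((est.value_before_clamp, est.n_pairings))
                        ns.append(est.n_snps)
                        n_pairs += est.n_pairings
                    raw = float(
                        np.sum([v * w for v, w in values_c]) / n_pairs
                    )
                    pooling = VarianceEstimate(
                        kind="pooling_nonidentical",
                        value=max(0.0, raw),
                        n_snps=int(round(np.mean(ns))),
                        n_pairings=n_pairs,
                        negative_before_clamp=raw < 0,
                        value_before_clamp=raw,
                    )
            constr = (
                construction_variance(pooling, mean_array) if pooling is not None else None
            )
            batch.pools[pid] = PoolDecomposition(
                pool_id=pid,
                n_arrays=len(tables),
                array=array_ests.get(pid),
                pooling=pooling,
                construction=constr,
            )
        batches[batch_id] = batch

    flagged = flag_outlier_arrays(tables_by_pool, factor=outlier_factor)
    return VarianceDecomposition(batches, flagged, denominator)


class PooledExperiment:
    """A pooled-allelotyping experiment: frequency tables plus pool metadata.

    Construct from per-array frequency tables (grouped by pool) or directly
    from a bead-level table via :meth:`from_beads`; :meth:`fit` estimates the
    variance components.
    """

    def __init__(
        self,
        tables_by_pool: Mapping[str, Sequence[FrequencyTable]],
        metas: Mapping[str, PoolMeta],
    ):
        self.tables_by_pool = {k: list(v) for k, v in tables_by_pool.items()}
        self.metas = dict(metas)

    @classmethod
    def from_frequency_tables(
        cls,
        tables: Sequence[FrequencyTable],
        metas: Mapping[str, PoolMeta],
        array_to_pool: Mapping[str, str] | None = None,
    ) -> "PooledExperiment":
        """Group a flat list of tables by pool.

        The pool of each array is taken from ``table.pool_id`` unless an
        explicit ``array_to_pool`` map is given.
        """
        grouped: dict[str, list[FrequencyTable]] = {}
        for t in tables:
            pid = array_to_pool.get(t.array_id) if array_to_pool else t.pool_id
            if pid is None:
                raise ConfigurationError(
                    f"array {t.array_id!r} has no pool assignment"
                )
            grouped.setdefault(pid, []).append(t)
        return cls(grouped, metas)

    @classmethod
    def from_beads(
        cls,
        beads: pd.DataFrame,
        metas: Mapping[str, PoolMeta],
        mode: str = "normalized",
    ) -> "PooledExperiment":
        """Filter beads, (optionally) normalize each array, build tables.

        ``mode`` is ``"normalized"`` (solve per-strip red scales) or
        ``"raw"`` (all scales 1).
        """
        if mode not in ("raw", "normalized"):
            raise ConfigurationError(f"mode must be 'raw' or 'normalized', got {mode!r}")
        kept, _ = filter_beads(beads)
        tables = []
        for _, array_beads in kept.groupby("array_id", sort=True):
            scales = None
            if mode == "normalized":
                solved = normalize_array(array_beads)
                scales = {sid: s.red_scale for sid, s in solved.items()}
            tables.append(build_frequency_table(array_beads, scales))
        return cls.from_frequency_tables(tables, metas)

    def fit(
        self,
        group_by_batch: bool = False,
        denominator: str = "2N",
        outlier_factor: float = 5.0,
    ) -> VarianceDecomposition:
        """Estimate array, pooling and construction variance components."""
        return decompose_experiment(
            self.tables_by_pool,
            self.metas,
            group_by_batch=group_by_batch,
            denominator=denominator,
            outlier_factor=outlier_factor,
        )


def read_pool_metadata(path) -> dict[str, PoolMeta]:
    """Read pool metadata TSV (pool_id, n_individuals, batch_id, replicate_of)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["pool_id", "n_individuals"]
    if not set(required) <= set(df.columns):
        raise ConfigurationError(
            f"pool metadata needs columns {required}, found {list(df.columns)}"
        )
    metas = {}
    for _, row in df.iterrows():
        metas[str(row["pool_id"])] = PoolMeta(
            pool_id=str(row["pool_id"]),
            n_individuals=int(row["n_individuals"]),
            batch_id=(str(row["batch_id"]) if "batch_id" in df.columns
                      and pd.notna(row.get("batch_id")) else None),
            replicate_of=(str(row["replicate_of"]) if "replicate_of" in df.columns
                          and pd.notna(row.get("replicate_of")) else None),
        )
    return metas
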