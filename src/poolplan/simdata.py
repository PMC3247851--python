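"""Synthetic bead-level pooled-array experiments with known ground truth.

The generative chain mirrors the error model used throughout the package.
Per SNP, a true population minor allele frequency is drawn, randomly
oriented (the green-labelled allele is the minor one with probability 1/2,
so strip means sit near 0.5 as on real arrays), and then:

1. **sampling** — a pool of N diploids realizes frequency
   Binomial(2N, p)/2N, shared by construction replicates;
2. **construction** — each physically constructed pool adds
   Normal(0, sd_construction), clipped to [0, 1];
3. **array** — each array adds Normal(0, sd_array), clipped;
4. **beads** — each of ``beads_per_snp`` beads reads the array frequency
   plus Normal(0, sd_bead), clipped, and converts it to a green/red
   intensity pair (total intensity drawn around ``intensity_scale``; a
   per-strip red-channel bias factor can be injected, which the
   normalization module should undo).

Errors are additive Gaussian on the frequency scale; clipping events are
counted and a warning flag is set when they exceed 1% of draws, since heavy
clipping breaks the additivity the variance estimators assume. Because the
per-SNP frequency on an array averages ``beads_per_snp`` noisy beads, the
array-level error variance seen by the estimators is
``sd_array**2 + sd_bead**2 / beads_per_snp`` (the *effective* injected array
variance).

Defaults emulate a normalized Illumina-style experiment: 17 beads per SNP,
array error SD 0.0182 (variance ~3.3e-4), construction error SD 0.0119
(construction ~30% of the pooling variance), MAF ~ Uniform(0.05, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io_beads import BEAD_COLUMNS, FrequencyTable, build_frequency_table, filter_beads
from .variance import PoolMeta, PooledExperiment

__all__ = [
    "SimConfig",
    "PoolSpec",
    "SimTruth",
    "SimulatedExperiment",
    "simulate_pool_frequencies",
    "simulate_experiment",
    "simulated_frequency_tables",
    "recovery_report",
    "make_strip_beads",
    "symmetric_frequency_grid",
]


@dataclass
class SimConfig:
    """Parameters of a simulated pooled-array experiment."""

    n_snps: int = 20_000
    n_strips: int = 4
    maf_law: tuple = ("uniform", 0.05, 0.5)
    n_individuals: int = 300
    sd_construction: float = 0.0119
    sd_array: float = 0.0182
    sd_bead: float = 0.02
    beads_per_snp: int = 17
    intensity_scale: float = 1000.0
    strip_red_bias: dict[str, float] | None = None
    frac_negative_beads: float = 0.0
    random_orientation: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("sd_construction", "sd_array", "sd_bead"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.beads_per_snp < 1:
            raise ConfigurationError("beads_per_snp must be >= 1")
        if not 0 <= self.frac_negative_beads < 1:
            raise ConfigurationError("frac_negative_beads must be in [0, 1)")

    @property
    def var_array_effective(self) -> float:
        """Array-level error variance seen by the estimators."""
        return self.sd_array**2 + self.sd_bead**2 / self.beads_per_snp


@dataclass
class PoolSpec:
    """One pool to simulate: label, number of replicate arrays, optional
    construction-replicate link."""

    pool_id: str
    n_arrays: int
    replicate_of: str | None = None


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    true_maf: np.ndarray
    oriented_freq: np.ndarray
    sample_freq: dict[str, np.ndarray]       # per replicate-root pool
    constructed_freq: dict[str, np.ndarray]  # per constructed pool
    array_freq: dict[str, np.ndarray]        # per array
    injected: dict[str, float]
    clip_fraction: float
    heavy_clipping: bool
    n_forced_negative: dict[str, int]
    snp_ids: np.ndarray
    strip_ids: np.ndarray


@dataclass
class SimulatedExperiment:
    """Bead tables per array plus ground truth and pool metadata."""

    beads: dict[str, pd.DataFrame]
    truth: SimTruth
    metas: dict[str, PoolMeta]
    arrays_by_pool: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(self.beads.values(), ignore_index=True)


def simulate_pool_frequencies(maf, N: int, rng: np.random.Generator) -> np.ndarray:
    """Realized pool allele frequencies: Binomial(2N, maf)/2N per SNP."""
    if N < 1:
        raise ConfigurationError("pool size must be >= 1")
    maf = np.asarray(maf, dtype=float)
    return rng.binomial(2 * N, maf) / (2.0 * N)


def _draw_maf(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=n)
    if kind == "fixed":
        return np.broadcast_to(np.asarray(law[1], dtype=float), (n,)).copy()
    raise ConfigurationError(f"unknown maf_law {law!r}")


def simulate_experiment(
    config: SimConfig, pools: Sequence[PoolSpec | tuple]
) -> SimulatedExperiment:
    """Simulate bead tables for a multi-pool experiment.

    ``pools`` lists :class:`PoolSpec` (or ``(pool_id, n_arrays[, replicate_of])``
    tuples). A pool whose ``replicate_of`` names another pool shares that
    pool's realized individual-sample frequencies but draws its own
    construction error. Identical config + seed yields identical output.
    """
    pools = [p if isinstance(p, PoolSpec) else PoolSpec(*p) for p in pools]
    ids = [p.pool_id for p in pools]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate pool ids in {ids}")
    by_id = {p.pool_id: p for p in pools}
    for p in pools:
        if p.replicate_of is not None and p.replicate_of not in by_id:
            raise ConfigurationError(
                f"pool {p.pool_id!r} marked replicate of unknown pool {p.replicate_of!r}"
            )

    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    snp_ids = np.array([f"snp{i:06d}" for i in range(n)])
    strip_labels = np.array([f"s{j}" for j in range(config.n_strips)])
    strip_of_snp = strip_labels[np.arange(n) % config.n_strips]
    bias_map = config.strip_red_bias or {}
    bias_of_snp = np.array([bias_map.get(s, 1.0) for s in strip_of_snp])

    maf = _draw_maf(config.maf_law, n, rng)
    if config.random_orientation:
        flip = rng.random(n) < 0.5
        oriented = np.where(flip, 1.0 - maf, maf)
    else:
        oriented = maf.copy()

    clip_events = 0
    clip_total = 0

    def clipped(x: np.ndarray) -> np.ndarray:
        nonlocal clip_events, clip_total
        out = np.clip(x, 0.0, 1.0)
        clip_events += int(np.count_nonzero(out != x))
        clip_total += x.size
        return out

    def root_of(p: PoolSpec) -> str:
        seen = {p.pool_id}
        while p.replicate_of is not None:
            if p.replicate_of in seen:
                raise ConfigurationError("cycle in replicate_of links")
            seen.add(p.replicate_of)
            p = by_id[p.replicate_of]
        return p.pool_id

    sample_freq: dict[str, np.ndarray] = {}
    for p in pools:
        r = root_of(p)
        if r not in sample_freq:
            sample_freq[r] = simulate_pool_frequencies(
                oriented, config.n_individuals, rng
            )

    constructed: dict[str, np.ndarray] = {}
    for p in pools:
        constructed[p.pool_id] = clipped(
            sample_freq[root_of(p)] + rng.normal(0.0, config.sd_construction, n)
            if config.sd_construction > 0
            else sample_freq[root_of(p)].copy()
        )

    beads: dict[str, pd.DataFrame] = {}
    array_freq: dict[str, np.ndarray] = {}
    n_forced: dict[str, int] = {}
    arrays_by_pool: dict[str, list[str]] = {p.pool_id: [] for p in pools}
    nb = config.beads_per_snp
    for p in pools:
        for x in range(1, p.n_arrays + 1):
            array_id = f"{p.pool_id}_arr{x}"
            arrays_by_pool[p.pool_id].append(array_id)
            p_arr = clipped(constructed[p.pool_id] + rng.normal(0.0, config.sd_array, n)) \
                if config.sd_array > 0 else constructed[p.pool_id].copy()
            array_freq[array_id] = p_arr
            f = p_arr[:, None] + rng.normal(0.0, config.sd_bead, (n, nb)) \
                if config.sd_bead > 0 else np.broadcast_to(p_arr[:, None], (n, nb)).copy()
            f = clipped(f)
            total = np.maximum(
                rng.normal(config.intensity_scale, 0.1 * config.intensity_scale, (n, nb)),
                1.0,
            )
            green = total * f
            red = total * (1.0 - f) * bias_of_snp[:, None]
            n_force = int(round(config.frac_negative_beads * n * nb))
            if n_force:
                idx = rng.choice(n * nb, size=n_force, replace=False)
                which_green = rng.random(n_force) < 0.5
                gflat, rflat = green.ravel(), red.ravel()
                gi = idx[which_green]
                ri = idx[~which_green]
                gflat[gi] = -np.abs(gflat[gi]) - 1.0
                rflat[ri] = -np.abs(rflat[ri]) - 1.0
            n_forced[array_id] = n_force
            beads[array_id] = pd.DataFrame(
                {
                    "array_id": array_id,
                    "pool_id": p.pool_id,
                    "strip_id": np.repeat(strip_of_snp, nb),
                    "snp_id": np.repeat(snp_ids, nb),
                    "green": green.ravel(),
                    "red": red.ravel(),
                },
                columns=BEAD_COLUMNS,
            )

    clip_fraction = clip_events / clip_total if clip_total else 0.0
    truth = SimTruth(
        true_maf=maf,
        oriented_freq=oriented,
        sample_freq=sample_freq,
        constructed_freq=constructed,
        array_freq=array_freq,
        injected={
            "var_array": config.sd_array**2,
            "var_bead": config.sd_bead**2,
            "var_array_effective": config.var_array_effective,
            "var_construction": config.sd_construction**2,
            "var_pooling_effective": config.var_array_effective
            + config.sd_construction**2,
        },
        clip_fraction=clip_fraction,
        heavy_clipping=clip_fraction > 0.01,
        n_forced_negative=n_forced,
        snp_ids=snp_ids,
        strip_ids=strip_of_snp,
    )
    metas = {
        p.pool_id: PoolMeta(
            pool_id=p.pool_id,
            n_individuals=config.n_individuals,
            replicate_of=p.replicate_of,
        )
        for p in pools
    }
    return SimulatedExperiment(beads, truth, metas, arrays_by_pool)


def simulated_frequency_tables(
    sim: SimulatedExperiment,
) -> dict[str, list[FrequencyTable]]:
    """Run the bead pipeline (filter + raw frequency tables) per pool."""
    out: dict[str, list[FrequencyTable]] = {}
    for pool_id, array_ids in sim.arrays_by_pool.items():
        tables = []
        for aid in array_ids:
            kept, _ = filter_beads(sim.beads[aid])
            tables.append(build_frequency_table(kept))
        out[pool_id] = tables
    return out


def recovery_report(
    config: SimConfig,
    pools: Sequence[PoolSpec | tuple],
    n_reps: int = 20,
    seeds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Bias of each recovered variance component over seeded replicates.

    Runs simulate -> bead pipeline -> variance decomposition per seed and
    compares the mean recovered component with the effective injected value.
    Columns: component, injected, mean_estimate, relative_error.
    """
    if seeds is None:
        seeds = [config.seed + i for i in range(n_reps)]
    arr, poolv, frac = [], [], []
    for s in seeds:
        sim = simulate_experiment(replace(config, seed=int(s)), pools)
        tables = simulated_frequency_tables(sim)
        fit = PooledExperiment(tables, sim.metas).fit()
        batch = fit.batches["all"]
        arr.append(batch.array_mean)
        pool_vals = [
            p.pooling.value for p in batch.pools.values() if p.pooling is not None
        ]
        if pool_vals:
            poolv.append(float(np.mean(pool_vals)))
        fr = [
            p.construction.fraction_of_pooling
            for p in batch.pools.values()
            if p.construction is not None
        ]
        if fr:
            frac.append(float(np.mean(fr)))

    inj = config.var_array_effective
    inj_pool = inj + config.sd_construction**2
    inj_frac = config.sd_construction**2 / inj_pool if inj_pool > 0 else 0.0
    rows = [("array", inj, float(np.mean(arr)))]
    if poolv:
        rows.append(("pooling", inj_pool, float(np.mean(poolv))))
    if frac:
        rows.append(("construction_fraction", inj_frac, float(np.mean(frac))))
    return pd.DataFrame(
        [
            {
                "component": c,
                "injected": i,
                "mean_estimate": m,
                "relative_error": (m - i) / i if i else np.nan,
            }
            for c, i, m in rows
        ]
    )


def make_strip_beads(
    frequencies,
    beads_per_snp: int = 17,
    red_bias: float = 1.0,
    intensity: float = 1000.0,
    array_id: str = "a1",
    pool_id: str = "p1",
    strip_id: str = "s1",
) -> pd.DataFrame:
    """Deterministic noiseless beads for one strip at given SNP frequencies.

    Every bead of SNP i reads exactly ``green = I * f_i`` and
    ``red = I * (1 - f_i) * red_bias`` — useful as exact ground truth for the
    normalization solver.
    """
    f = np.repeat(np.asarray(frequencies, dtype=float), beads_per_snp)
    snp = np.repeat(
        [f"snp{i:06d}" for i in range(len(frequencies))], beads_per_snp
    )
    return pd.DataFrame(
        {
            "array_id": array_id,
            "pool_id": pool_id,
            "strip_id": strip_id,
            "snp_id": snp,
            "green": intensity * f,
            "red": intensity * (1.0 - f) * red_bias,
        },
        columns=BEAD_COLUMNS,
    )


def symmetric_frequency_grid(n_pairs: int = 10, lo: float = 0.1) -> np.ndarray:
    """SNP frequencies symmetric about 0.5 (mean exactly 0.5)."""
    half = np.linspace(lo, 0.45, n_pairs)
    return np.concatenate([half, 1.0 - half])
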