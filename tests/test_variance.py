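"""Paired-array variance estimators and the experiment decomposition."""

import numpy as np
import pytest

from poolplan.exceptions import (
    InsufficientOverlapError,
    InsufficientReplicatesError,
    MisuseError,
)
from poolplan.variance import (
    PooledExperiment,
    PoolMeta,
    array_variance_pair,
    array_variance_pool,
    binomial_pair_variance,
    construction_variance,
    decompose_experiment,
    flag_outlier_arrays,
    paired_diff_variance,
    pooling_variance_nonidentical,
    pooling_variance_replicate,
    read_pool_metadata,
)

from conftest import make_ft, random_ft


def four_snp_pair():
    f1 = make_ft("a1", {"s1": 0.30, "s2": 0.40, "s3": 0.50, "s4": 0.60})
    f2 = make_ft("a2", {"s1": 0.31, "s2": 0.41, "s3": 0.51, "s4": 0.61})
    return f1, f2


class TestPairedDiffVariance:
    def test_identical_tables_zero(self):
        ft = make_ft("a1", [0.2, 0.4, 0.6, 0.8])
        assert paired_diff_variance(ft, ft)[0] == 0.0

    def test_hand_arithmetic(self):
        # 4 diffs of 0.01: sum d^2 = 4e-4, over n-2 = 2 -> 2e-4 (not the mean 1e-4)
        v, n = paired_diff_variance(*four_snp_pair())
        assert n == 4
        assert v == pytest.approx(2e-4)

    def test_intersection_only(self):
        f1 = make_ft("a1", {"s1": 0.2, "s2": 0.4, "s3": 0.6, "only1": 0.9})
        f2 = make_ft("a2", {"s1": 0.2, "s2": 0.4, "s3": 0.6, "only2": 0.1})
        v, n = paired_diff_variance(f1, f2)
        assert (v, n) == (0.0, 3)

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientOverlapError):
            paired_diff_variance(make_ft("a1", [0.1, 0.2]), make_ft("a2", [0.1, 0.2]))

    def test_symmetry(self, rng):
        f1, f2 = random_ft("a1", 20, rng), random_ft("a2", 20, rng)
        assert paired_diff_variance(f1, f2) == paired_diff_variance(f2, f1)

    def test_scaling_against_monte_carlo(self, rng):
        # diffs ~ N(0, s^2): estimator expectation is s^2 * n/(n-2)
        s, n, reps = 0.02, 100, 400
        vals = []
        for _ in range(reps):
            base = rng.uniform(0.2, 0.8, n)
            f1 = make_ft("a1", base + rng.normal(0, s / np.sqrt(2), n))
            f2 = make_ft("a2", base + rng.normal(0, s / np.sqrt(2), n))
            vals.append(paired_diff_variance(f1, f2)[0])
        assert np.mean(vals) == pytest.approx(s**2 * n / (n - 2), rel=0.05)


class TestArrayVariance:
    def test_pair_is_half_diff_variance(self):
        est = array_variance_pair(*four_snp_pair())
        assert est.value == pytest.approx(1e-4)
        assert est.kind == "array"

    def test_pool_averages_all_pairings(self, rng):
        tables = [random_ft(f"a{i}", 10, rng) for i in range(4)]
        est = array_variance_pool(tables)
        assert est.n_pairings == 6  # C(4,2)
        pair_vals = [
            array_variance_pair(tables[i], tables[j]).value
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        assert est.value == pytest.approx(np.mean(pair_vals))

    def test_single_array_rejected(self, rng):
        with pytest.raises(InsufficientReplicatesError):
            array_variance_pool([random_ft("a1", 5, rng)])


class TestPoolingVarianceReplicate:
    def test_requires_replicate_link(self, rng):
        ta, tb = [random_ft("a1", 5, rng)], [random_ft("b1", 5, rng)]
        ma = PoolMeta("a", 100)
        mb = PoolMeta("b", 100)
        with pytest.raises(MisuseError):
            pooling_variance_replicate(ta, tb, ma, mb)

    def test_identical_tables_zero_and_cross_count(self):
        t = [make_ft("a1", [0.2, 0.4, 0.6, 0.8]), make_ft("a2", [0.2, 0.4, 0.6, 0.8])]
        ma = PoolMeta("a", 100)
        mb = PoolMeta("b", 100, replicate_of="a")
        est = pooling_variance_replicate(t, t, ma, mb)
        assert est.value == 0.0
        assert est.n_pairings == 4  # 2 x 2 cross pairings
        assert est.kind == "pooling_replicate"


class TestBinomialPairVariance:
    def test_hand_arithmetic_2n(self):
        assert binomial_pair_variance(0.5, 0.5, 100, 100) == pytest.approx(2.5e-3)

    def test_degenerate_frequencies(self):
        assert binomial_pair_variance(0.0, 0.0, 10, 10) == 0.0

    def test_large_pool_limit(self):
        assert binomial_pair_variance(0.3, 0.4, 10**9, 10**9) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_denominator_switch(self):
        assert binomial_pair_variance(0.3, 0.4, 50, 60, denominator="N") == pytest.approx(
            2 * binomial_pair_variance(0.3, 0.4, 50, 60, denominator="2N")
        )


class TestPoolingVarianceNonidentical:
    def test_identical_tables_clamped_to_zero(self, rng):
        t = [random_ft("a1", 50, rng)]
        est = pooling_variance_nonidentical(
            t, t, PoolMeta("a", 100), PoolMeta("b", 100)
        )
        assert est.value == 0.0
        assert est.negative_before_clamp
        assert est.value_before_clamp < 0

    def test_huge_pools_no_correction(self, rng):
        # with N -> inf the correction vanishes: Type C = Type B numerically
        ta = [random_ft("a1", 30, rng)]
        tb = [random_ft("b1", 30, rng)]
        ma, mb = PoolMeta("a", 10**9), PoolMeta("b", 10**9, replicate_of="a")
        c_est = pooling_variance_nonidentical(ta, tb, ma, mb)
        b_est = pooling_variance_replicate(ta, tb, ma, mb)
        assert c_est.value == pytest.approx(b_est.value, rel=1e-6)

    def test_cross_pairing_count(self, rng):
        ta = [random_ft(f"a{i}", 10, rng) for i in range(4)]
        tb = [random_ft(f"b{i}", 10, rng) for i in range(3)]
        est = pooling_variance_nonidentical(
            ta, tb, PoolMeta("a", 100), PoolMeta("b", 100)
        )
        assert est.n_pairings == 12


class TestConstructionVariance:
    def test_hand_arithmetic(self):
        from poolplan.variance import VarianceEstimate

        p = VarianceEstimate("pooling_nonidentical", 4.0e-4, 100, 1)
        a = VarianceEstimate("array", 3.3e-4, 100, 1)
        c = construction_variance(p, a)
        assert c.value == pytest.approx(0.7e-4)
        assert c.fraction_of_pooling == pytest.approx(0.175)

    def test_clamped_when_array_exceeds_pooling(self):
        from poolplan.variance import VarianceEstimate

        p = VarianceEstimate("pooling_replicate", 2.0e-4, 100, 1)
        a = VarianceEstimate("array", 3.0e-4, 100, 1)
        c = construction_variance(p, a)
        assert c.value == 0.0
        assert c.negative_before_clamp
        assert c.fraction_of_pooling == 0.0

    def test_kind_mismatch(self):
        from poolplan.variance import VarianceEstimate

        a = VarianceEstimate("array", 3.0e-4, 100, 1)
        with pytest.raises(MisuseError):
            construction_variance(a, a)


class TestDecomposeExperiment:
    def test_twelve_pools_two_arrays(self, rng):
        tables = {
            f"p{i}": [random_ft(f"p{i}_a{j}", 8, rng) for j in range(2)]
            for i in range(12)
        }
        metas = {p: PoolMeta(p, 100) for p in tables}
        fit = decompose_experiment(tables, metas)
        batch = fit.batches["all"]
        assert batch.n_array_estimates == 12
        assert batch.array_min <= batch.array_mean <= batch.array_max

    def test_single_pool_pooling_unavailable(self, rng):
        tables = {"p0": [random_ft("a1", 8, rng), random_ft("a2", 8, rng)]}
        fit = decompose_experiment(tables, {"p0": PoolMeta("p0", 100)})
        pool = fit.batches["all"].pools["p0"]
        assert pool.array is not None
        assert pool.pooling is None
        assert "unavailable" in fit.summary()

    def test_no_replicate_arrays_anywhere(self, rng):
        tables = {"p0": [random_ft("a1", 8, rng)], "p1": [random_ft("b1", 8, rng)]}
        metas = {p: PoolMeta(p, 100) for p in tables}
        with pytest.raises(InsufficientReplicatesError):
            decompose_experiment(tables, metas)

    def test_replicate_pools_use_type_b(self, rng):
        tables = {
            "p0": [random_ft(f"p0_a{j}", 8, rng) for j in range(2)],
            "p0r": [random_ft(f"p0r_a{j}", 8, rng) for j in range(2)],
        }
        metas = {
            "p0": PoolMeta("p0", 100),
            "p0r": PoolMeta("p0r", 100, replicate_of="p0"),
        }
        fit = decompose_experiment(tables, metas)
        assert fit.batches["all"].pools["p0"].pooling.kind == "pooling_replicate"

    def test_batch_stratification(self, rng):
        tables = {
            f"p{i}": [random_ft(f"p{i}_a{j}", 8, rng) for j in range(2)]
            for i in range(4)
        }
        metas = {
            p: PoolMeta(p, 100, batch_id=("b1" if i < 2 else "b2"))
            for i, p in enumerate(tables)
        }
        fit = decompose_experiment(tables, metas, group_by_batch=True)
        assert set(fit.batches) == {"b1", "b2"}
        assert all(b.n_array_estimates == 2 for b in fit.batches.values())

    def test_outlier_array_flagged(self, rng):
        from conftest import make_ft

        tables = {}
        for i in range(4):
            base = rng.uniform(0.1, 0.9, 40)
            tables[f"p{i}"] = [
                make_ft(f"p{i}_a{j}", base + rng.normal(0, 0.01, 40))
                for j in range(2)
            ]
        bad = tables["p0"][1]
        bad.data["freq"] = np.clip(
            bad.data["freq"] + rng.normal(0, 0.2, len(bad.data)), 0, 1
        )
        flagged = flag_outlier_arrays(tables, factor=5.0)
        assert "p0_a1" in flagged


def test_pooled_experiment_from_frequency_tables(rng):
    tables = [random_ft(f"a{i}", 8, rng) for i in range(4)]
    metas = {"p0": PoolMeta("p0", 100), "p1": PoolMeta("p1", 100)}
    amap = {"a0": "p0", "a1": "p0", "a2": "p1", "a3": "p1"}
    model = PooledExperiment.from_frequency_tables(tables, metas, amap)
    fit = model.fit()
    assert set(fit.batches["all"].pools) == {"p0", "p1"}
    assert "var(e_array)" in fit.summary()


def test_read_pool_metadata(tmp_path):
    path = tmp_path / "pools.tsv"
    path.write_text(
        "pool_id\tn_individuals\tbatch_id\treplicate_of\n"
        "case\t300\tb1\t\n"
        "case_rep\t300\tb1\tcase\n"
    )
    metas = read_pool_metadata(path)
    assert metas["case"].n_individuals == 300
    assert metas["case"].replicate_of is None
    assert metas["case_rep"].replicate_of == "case"
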