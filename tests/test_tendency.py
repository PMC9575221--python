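import itertools

import numpy as np
import pytest

from spatialcci.lr_database import LRInteraction
from spatialcci.tendency import (
    DegenerateDistributionError,
    MissingGeneError,
    SpatialExpression,
    TendencyResult,
    classify_ranges,
    gene_distribution,
    normalize_counts,
    permutation_null,
    tendency_statistics,
)
from spatialcci.transport import WeightedPoints, wasserstein_lr


class TestGeneDistribution:
    def test_weights_normalized(self, square_slide):
        dist = gene_distribution(square_slide, ["geneA"])
        assert dist.weights == pytest.approx([0.5, 0.5])
        np.testing.assert_array_equal(
            dist.coords, [[0.0, 0.0], [1.0, 0.0]]
        )

    def test_complex_uses_elementwise_minimum(self):
        st = SpatialExpression(
            gene_ids=["A", "B"],
            spot_ids=["s1", "s2"],
            coords=np.array([[0.0, 0.0], [1.0, 0.0]]),
            values=np.array([[4.0, 0.0], [2.0, 3.0]]),
        )
        dist = gene_distribution(st, ["A", "B"])
        # min over subunits = (2, 0): all mass on the first spot
        assert len(dist) == 1
        assert dist.weights == pytest.approx([1.0])
        np.testing.assert_array_equal(dist.coords, [[0.0, 0.0]])

    def test_all_zero_gene_raises(self):
        st = SpatialExpression(
            gene_ids=["A"],
            spot_ids=["s1"],
            coords=np.array([[0.0, 0.0]]),
            values=np.array([[0.0]]),
        )
        with pytest.raises(DegenerateDistributionError):
            gene_distribution(st, ["A"])

    def test_missing_gene_raises(self, square_slide):
        with pytest.raises(MissingGeneError):
            gene_distribution(square_slide, ["nope"])


class TestNormalizeCounts:
    def test_library_scaling_equalizes_spot_totals(self):
        st = SpatialExpression(
            gene_ids=["A", "B"],
            spot_ids=["s1", "s2"],
            coords=np.zeros((2, 2)),
            values=np.array([[10.0, 1.0], [10.0, 1.0]]),
        )
        out = normalize_counts(st)
        dense = np.asarray(out.values)
        assert dense[:, 0] == pytest.approx(dense[:, 1])

    def test_custom_transform_clamps_negatives(self, square_slide):
        out = normalize_counts(square_slide, transform=lambda m: m - 1.5)
        assert np.asarray(out.values).min() == 0.0


class TestTendencyStatistics:
    def test_ratio_one_when_real_equals_mean(self):
        d_ratio, _, _ = tendency_statistics(2.0, np.array([1.0, 2.0, 3.0]))
        assert d_ratio == pytest.approx(1.0)

    def test_ratio_two_when_real_doubles_constant_null(self):
        d_ratio, _, _ = tendency_statistics(2.0, np.full(100, 1.0))
        assert d_ratio == pytest.approx(2.0)

    def test_add_one_pvalue_floor(self):
        # d_real below all 1000 permutations: p_left = 1/1001
        sims = np.linspace(1.0, 2.0, 1000)
        _, p_left, p_right = tendency_statistics(0.5, sims)
        assert p_left == pytest.approx(1 / 1001)
        assert p_right == pytest.approx(1.0)

    def test_degenerate_null_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            tendency_statistics(0.0, np.zeros(10))


class TestPermutationNull:
    def test_deterministic_given_seed(self, square_slide, simple_db):
        inter = simple_db.interactions[0]
        a = permutation_null(square_slide, inter, n_perm=3, seed=11)
        b = permutation_null(square_slide, inter, n_perm=3, seed=11)
        np.testing.assert_array_equal(a, b)
        c = permutation_null(square_slide, inter, n_perm=3, seed=12)
        assert not np.array_equal(a, c)

    def test_coincident_spots_give_zero(self, simple_db):
        st = SpatialExpression(
            gene_ids=["geneA", "geneB"],
            spot_ids=["s1", "s2"],
            coords=np.zeros((2, 2)),
            values=np.array([[1.0, 1.0], [2.0, 1.0]]),
        )
        sims = permutation_null(st, simple_db.interactions[0], n_perm=5, seed=0)
        np.testing.assert_allclose(sims, 0.0, atol=1e-9)

    def test_invalid_n_perm(self, square_slide, simple_db):
        with pytest.raises(ValueError):
            permutation_null(square_slide, simple_db.interactions[0], n_perm=0)

    def test_matches_exhaustive_enumeration(self, square_slide, simple_db):
        """The sampled null mean agrees with brute-force enumeration of all
        coordinate assignments on a 4-spot slide."""
        inter = simple_db.interactions[0]
        lv = square_slide.gene_values("geneA")
        rv = square_slide.gene_values("geneB")
        l_idx, r_idx = np.flatnonzero(lv), np.flatnonzero(rv)
        wl = lv[l_idx] / lv[l_idx].sum()
        wr = rv[r_idx] / rv[r_idx].sum()

        values = []
        for perm_l in itertools.permutations(range(4)):
            cl = square_slide.coords[np.asarray(perm_l)[l_idx]]
            for perm_r in itertools.permutations(range(4)):
                cr = square_slide.coords[np.asarray(perm_r)[r_idx]]
                values.append(
                    wasserstein_lr(
                        WeightedPoints(cl, wl), WeightedPoints(cr, wr), reg=1e-3
                    )
                )
        exhaustive_mean = np.mean(values)

        sims = permutation_null(square_slide, inter, n_perm=400, seed=5)
        mc_sd = np.std(values) / np.sqrt(len(sims))
        assert sims.mean() == pytest.approx(
            exhaustive_mean, abs=4 * mc_sd + 0.05 * exhaustive_mean
        )


def make_result(name, d_ratio, p_left, p_right):
    inter = LRInteraction(name, (f"L{name}",), (f"R{name}",))
    return TendencyResult(
        interaction=inter, d_real=d_ratio, d_sim_mean=1.0,
        d_ratio=d_ratio, p_left=p_left, p_right=p_right, n_perm=100,
    )


class TestClassifyRanges:
    def planted(self):
        rng = np.random.default_rng(0)
        results = []
        for i in range(16):
            # unremarkable interactions near the null
            results.append(
                make_result(
                    f"mid{i:02d}",
                    float(rng.uniform(0.9, 1.1)),
                    float(rng.uniform(0.2, 0.8)),
                    float(rng.uniform(0.2, 0.8)),
                )
            )
        planted_short = [
            make_result("short_a", 0.10, 1 / 101, 1.0),
            make_result("short_b", 0.15, 1 / 101, 1.0),
        ]
        planted_long = [
            make_result("long_a", 5.0, 1.0, 1 / 101),
            make_result("long_b", 4.0, 1.0, 1 / 101),
        ]
        return results + planted_short + planted_long

    def test_recovers_planted_extremes_exactly(self):
        out = classify_ranges(self.planted(), top_fraction=0.10, alpha=0.01)
        classes = {r.name: r.range_class for r in out}
        assert {n for n, c in classes.items() if c == "short"} == {
            "short_a", "short_b",
        }
        assert {n for n, c in classes.items() if c == "long"} == {
            "long_a", "long_b",
        }

    def test_partition_is_complete(self):
        out = classify_ranges(self.planted())
        assert len(out) == 20
        counts = {"short": 0, "medium": 0, "long": 0}
        for r in out:
            counts[r.range_class] += 1
        assert sum(counts.values()) == 20

    def test_candidate_sets_capped_at_top_fraction(self):
        rng = np.random.default_rng(1)
        results = [
            make_result(
                f"r{i:03d}",
                float(rng.uniform(0.5, 2.0)),
                float(rng.uniform(1e-4, 1.0)),
                float(rng.uniform(1e-4, 1.0)),
            )
            for i in range(100)
        ]
        out = classify_ranges(results, top_fraction=0.10, alpha=1.0 - 1e-9)
        n_short = sum(r.range_class == "short" for r in out)
        n_long = sum(r.range_class == "long" for r in out)
        assert n_short <= 10 and n_long <= 10

    def test_insignificant_pvalues_yield_no_calls(self):
        results = [
            make_result(f"r{i}", 0.1 + 0.1 * i, 0.02 + 0.01 * i, 0.9 - 0.01 * i)
            for i in range(20)
        ]
        out = classify_ranges(results, alpha=0.01)
        assert all(r.range_class == "medium" for r in out)

    def test_composite_strategy_also_recovers_extremes(self):
        out = classify_ranges(
            self.planted(), top_fraction=0.10, alpha=0.01, strategy="composite"
        )
        short = {r.name for r in out if r.range_class == "short"}
        assert short == {"short_a", "short_b"}
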