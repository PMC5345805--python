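from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from crabtree.io import Pathway, PathwaySet
from crabtree.pathways import (
    AnalysisConfig,
    correct_pvalues,
    empirical_pvalue,
    filter_pathways,
    length_bias_check,
    length_normalized_pvalue,
    null_distribution,
    pathway_score,
    run_directionality_analysis,
    directional_pathway_test,
)
from crabtree.synthetic import (
    PlantedEffect,
    SyntheticDEConfig,
    generate_de_table,
    generate_pathways,
)


def dmap(values: dict[str, int]) -> pd.Series:
    return pd.Series(values, name="direction", dtype=np.int8).rename_axis("gene_id")


@pytest.fixture
def ternary_universe(rng):
    """10 genes with fixed ternary values (used for exhaustive-null checks)."""
    values = [1, 1, -1, 0, 0, 1, -1, 0, 0, 1]
    return dmap({f"g{i}": v for i, v in enumerate(values)})


class TestFilterPathways:
    def _ps(self, sizes, category="metabolism"):
        return PathwaySet([
            Pathway(f"P{n}", frozenset(f"g{n}_{i}" for i in range(n)), category)
            for n in sizes])

    def test_small_pathways_dropped(self):
        ps = self._ps([3, 4, 5])
        universe = {g for p in ps for g in p.genes}
        kept = filter_pathways(ps, universe, min_genes=4)
        assert sorted(len(p) for p in kept) == [4, 5]

    def test_excluded_category_dropped(self):
        ps = PathwaySet([
            Pathway("A", frozenset(f"a{i}" for i in range(5)), "amino-acid-biosynthesis"),
            Pathway("B", frozenset(f"b{i}" for i in range(5)), "metabolism"),
        ])
        universe = {g for p in ps for g in p.genes}
        kept = filter_pathways(ps, universe,
                               excluded_categories={"amino-acid-biosynthesis"})
        assert [p.pathway_id for p in kept] == ["B"]

    def test_identity_when_nothing_filtered(self):
        ps = self._ps([4, 6])
        universe = {g for p in ps for g in p.genes}
        kept = filter_pathways(ps, universe)
        assert [p.genes for p in kept] == [p.genes for p in ps]

    def test_restriction_to_universe_precedes_size_check(self):
        # 5 genes but only 3 measured -> drops below min_genes
        p = Pathway("P", frozenset(["a", "b", "c", "d", "e"]))
        kept = filter_pathways(PathwaySet([p]), {"a", "b", "c", "x"})
        assert len(kept) == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            filter_pathways(self._ps([4]), set())


class TestPathwayScore:
    def test_hand_example(self):
        d = dmap({"g1": 1, "g2": 1, "g3": -1, "g4": 0})
        assert pathway_score(d, ["g1", "g2", "g3", "g4"]) == 1

    def test_all_zero_map(self):
        d = dmap({f"g{i}": 0 for i in range(5)})
        assert pathway_score(d, [f"g{i}" for i in range(5)]) == 0

    def test_missing_gene_errors(self):
        d = dmap({"g1": 1})
        with pytest.raises(KeyError):
            pathway_score(d, ["g1", "missing"])

    def test_random_maps_match_summation_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        for _ in range(100):
            vals = rng.choice([-1, 0, 1], size=50)
            d = dmap(dict(zip(genes, vals)))
            subset = rng.choice(genes, size=12, replace=False)
            expected = sum(vals[genes.index(g)] for g in subset)
            assert pathway_score(d, list(subset)) == expected


class TestNullDistribution:
    def test_degenerate_all_zero(self, rng):
        d = dmap({f"g{i}": 0 for i in range(20)})
        null = null_distribution(d, 5, n_perm=1000, rng=rng)
        assert (null == 0).all()

    def test_exhaustive_matches_hand_enumeration(self, ternary_universe):
        excluded = ["g0", "g1", "g2"]
        null = null_distribution(ternary_universe, 3, exclude=excluded,
                                 exhaustive=True)
        assert len(null) == 35  # C(7,3)
        vals = ternary_universe.drop(excluded).to_numpy()
        oracle = sorted(sum(c) for c in combinations(vals, 3))
        assert sorted(null.tolist()) == oracle

    def test_fixed_seed_reproducible(self, ternary_universe):
        a = null_distribution(ternary_universe, 4, n_perm=5000,
                              rng=np.random.default_rng(9))
        b = null_distribution(ternary_universe, 4, n_perm=5000,
                              rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_oversized_draw_rejected(self, ternary_universe):
        with pytest.raises(ValueError):
            null_distribution(ternary_universe, 8, exclude=["g0", "g1", "g2"])

    def test_montecarlo_tail_matches_exhaustive(self, ternary_universe):
        """Sampled tail probabilities agree with exact enumeration within
        binomial sampling error."""
        exclude = ["g0", "g5", "g9"]
        exact = null_distribution(ternary_universe, 3, exclude=exclude,
                                  exhaustive=True)
        sampled = null_distribution(ternary_universe, 3, exclude=exclude,
                                    n_perm=50_000,
                                    rng=np.random.default_rng(4))
        for s in (1, 2, -1):
            p_exact, _ = empirical_pvalue(s, exact)
            p_mc, _ = empirical_pvalue(s, sampled)
            tol = 3 * np.sqrt(p_exact * (1 - p_exact) / 50_000)
            assert abs(p_mc - p_exact) <= tol


class TestEmpiricalPvalue:
    @pytest.mark.parametrize("S, expected_p, expected_dir", [
        (2, 1 / 5, "up"),
        (-1, 2 / 5, "down"),
        (0, 1.0, "none"),
    ])
    def test_hand_counts(self, S, expected_p, expected_dir):
        null = [-2, -1, 0, 1, 2]
        p, direction = empirical_pvalue(S, null)
        assert p == pytest.approx(expected_p)
        assert direction == expected_dir

    def test_nonstrict_counting_includes_ties(self):
        p, _ = empirical_pvalue(2, [2, 2, 0, 0])
        assert p == 0.5

    def test_pseudocount_keeps_p_positive(self):
        p, _ = empirical_pvalue(5, [0, 0, 0])
        assert p == 0.0
        p, _ = empirical_pvalue(5, [0, 0, 0], pseudocount=True)
        assert p == pytest.approx(1 / 4)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1, [])


class TestCorrectPvalues:
    def test_multiplier_worked_example(self):
        assert correct_pvalues([0.0004], 118)[0] == pytest.approx(0.0472)

    def test_cap_at_one(self):
        assert correct_pvalues([0.5], 118)[0] == 1.0

    def test_single_pathway_identity(self):
        np.testing.assert_allclose(correct_pvalues([0.3, 0.01], 1), [0.3, 0.01])


class TestLengthNormalized:
    def test_equals_raw_pvalue_randomized(self, rng):
        for _ in range(100):
            null = rng.integers(-8, 9, size=200)
            S = int(rng.integers(-8, 9))
            n = int(rng.integers(4, 31))
            p_raw, _ = empirical_pvalue(S, null)
            p_len, s_avg = length_normalized_pvalue(S, n, null)
            assert p_len == p_raw
            assert s_avg == pytest.approx(S / n)

    def test_averaged_score_reported(self):
        p, s_avg = length_normalized_pvalue(2, 4, [0, 1, 2, -1])
        assert s_avg == 0.5

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            length_normalized_pvalue(1, 0, [0, 1])


class TestLengthBiasCheck:
    def test_perfect_monotone_gives_rho_one(self):
        df = pd.DataFrame({"p_raw": np.linspace(0.1, 0.9, 10),
                           "n": np.arange(4, 14)})
        rho, p = length_bias_check(df)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_two_results_rejected(self):
        df = pd.DataFrame({"p_raw": [0.1, 0.2], "n": [4, 5]})
        with pytest.raises(ValueError):
            length_bias_check(df)

    def test_constant_pvalues_undefined(self):
        df = pd.DataFrame({"p_raw": [0.5, 0.5, 0.5], "n": [4, 5, 6]})
        rho, p = length_bias_check(df)
        assert np.isnan(rho) and np.isnan(p)


class TestRunPipeline:
    def test_planted_pathway_recovered(self, rng):
        """A fully up-regulated 8-gene pathway planted in a 2,000-gene
        background must surface with the smallest corrected p and
        direction 'up'."""
        cfg = SyntheticDEConfig(n_genes=2000, n_pathways=20,
                                pathway_size_range=(8, 16),
                                background_misregulated=300, seed=21)
        pws = generate_pathways(cfg)
        target = next(p.pathway_id for p in pws if len(p) == 8)
        cfg.planted = (PlantedEffect(target, 1.0, +1),)
        tables = generate_de_table(cfg, pws)
        run = run_directionality_analysis(
            tables, pws, AnalysisConfig(seed=21, n_perm=20_000))
        res = run.results
        best = res.loc[res["p_corrected"].idxmin()]
        assert best["pathway_id"] == target
        assert best["direction"] == "up"
        assert (res["p_length_normalized"] == res["p_raw"]).all()

    def test_all_zero_directions_give_p_one(self):
        genes = [f"g{i}" for i in range(100)]
        d = dmap({g: 0 for g in genes})
        ps = PathwaySet([Pathway("A", frozenset(genes[:6])),
                         Pathway("B", frozenset(genes[10:18]))])
        run = directional_pathway_test(d, ps, AnalysisConfig(seed=0, n_perm=500))
        assert (run.results["p_raw"] == 1.0).all()
        assert (run.results["direction"] == "none").all()

    def test_same_seed_identical_output(self, small_de_config):
        pws = generate_pathways(small_de_config)
        tables = generate_de_table(small_de_config)
        cfg = AnalysisConfig(seed=5, n_perm=2000)
        r1 = run_directionality_analysis(tables, pws, cfg)
        r2 = run_directionality_analysis(tables, pws, cfg)
        pd.testing.assert_frame_equal(r1.results, r2.results)

    def test_results_independent_of_pathway_order(self, small_de_config):
        pws = generate_pathways(small_de_config)
        tables = generate_de_table(small_de_config)
        cfg = AnalysisConfig(seed=5, n_perm=2000)
        r1 = run_directionality_analysis(tables, pws, cfg)
        reversed_ps = PathwaySet(list(pws)[::-1])
        r2 = run_directionality_analysis(tables, reversed_ps, cfg)
        merged = r1.results.merge(r2.results, on="pathway_id",
                                  suffixes=("_a", "_b"))
        assert (merged["p_raw_a"] == merged["p_raw_b"]).all()

    def test_up_pvalue_monotone_in_planted_genes(self):
        """For a fixed null, converting more pathway genes to +1 never
        increases the 'up' p-value."""
        genes = [f"g{i}" for i in range(500)]
        base = {g: 0 for g in genes}
        background = np.random.default_rng(2).choice(genes[20:], 60,
                                                     replace=False)
        for i, g in enumerate(background):
            base[g] = 1 if i % 2 == 0 else -1
        pathway = genes[:10]
        rng_null = np.random.default_rng(7)
        prev_p = 1.1
        for k in range(0, 11):
            d = dict(base)
            for g in pathway[:k]:
                d[g] = 1
            dm = dmap(d)
            S = pathway_score(dm, pathway)
            null = null_distribution(dm, 10, exclude=pathway, n_perm=20_000,
                                     rng=np.random.default_rng(7))
            if S <= 0:
                continue
            p, _ = empirical_pvalue(S, null)
            assert p <= prev_p + 1e-12
            prev_p = p

    def test_score_conservation_over_pathways(self, small_de_config):
        pws = generate_pathways(small_de_config)
        tables = generate_de_table(small_de_config)
        run = run_directionality_analysis(
            tables, pws, AnalysisConfig(seed=1, n_perm=100))
        from crabtree.misregulation import (average_replicate_fold_changes,
                                            call_misregulated)
        d = call_misregulated(average_replicate_fold_changes(tables))
        membership = {}
        tested_ids = set(run.results["pathway_id"])
        for p in pws:
            if p.pathway_id in tested_ids:
                for g in p.genes:
                    membership[g] = membership.get(g, 0) + 1
        expected = sum(int(d.loc[g]) * c for g, c in membership.items())
        assert run.results["S"].sum() == expected
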