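"""Statistical layer: Wilcoxon, PGLS with Pagel's lambda, Spearman, coding."""

import itertools
import math

import dendropy
import numpy as np
import pytest
import scipy.stats as st

from norgscan.comparative import (
    average_lineage,
    build_covariance,
    code_assembly_levels,
    pgls_fit,
    run_paper_comparisons,
    spearman,
    wilcoxon_signed_rank,
)
from norgscan.synthetic import TraitSimConfig, simulate_traits, simulate_tree


def wilcoxon_enumeration_oracle(diffs):
    """Exact two-tailed p by brute force over all 2^n sign assignments."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    ranks = st.rankdata(np.abs(diffs))
    w_obs = min(ranks[np.array(diffs) > 0].sum(), ranks[np.array(diffs) < 0].sum())
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        wn = sum(r for r, s in zip(ranks, signs) if s < 0)
        if min(wp, wn) <= w_obs + 1e-12:
            count += 1
    return count / 2**n


class TestLineageAveraging:
    def test_two_species_mean(self):
        # e.g. a bdelloid lineage with NUMT counts 22 and 4 averages to 13
        out = average_lineage({"a": 22.0, "b": 4.0}, {"L1": ["a", "b"]})
        assert out[0].value == pytest.approx(13.0)

    def test_single_species_passthrough(self):
        out = average_lineage({"a": 53.0}, {"L1": ["a"]})
        assert out[0].value == 53.0

    def test_permutation_invariant(self):
        vals = {"a": 1.0, "b": 9.0}
        v1 = average_lineage(vals, {"L": ["a", "b"]})[0].value
        v2 = average_lineage(vals, {"L": ["b", "a"]})[0].value
        assert v1 == v2

    def test_missing_species_named(self):
        with pytest.raises(ValueError, match="'b'"):
            average_lineage({"a": 1.0}, {"L": ["a", "b"]})


class TestWilcoxon:
    def test_all_negative_differences(self):
        r = wilcoxon_signed_rank([(1, 2), (2, 4), (3, 6), (4, 8), (5, 10)])
        assert r.w_statistic == 0 and r.method == "exact"
        assert r.p_two_tailed == pytest.approx(2 / 32)

    def test_all_zero_differences(self):
        r = wilcoxon_signed_rank([(1.0, 1.0)] * 4)
        assert r.p_two_tailed == 1.0 and r.n_effective == 0 and r.method == "exact"

    def test_two_tailed_symmetry(self):
        pairs = [(1.0, 3.0), (5.0, 2.0), (2.0, 2.5), (8.0, 1.0), (0.5, 4.0)]
        p1 = wilcoxon_signed_rank(pairs).p_two_tailed
        p2 = wilcoxon_signed_rank([(b, a) for a, b in pairs]).p_two_tailed
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("n", range(3, 13))
    def test_exact_p_equals_enumeration(self, n):
        rng = np.random.default_rng(n)
        diffs = rng.standard_normal(n)
        pairs = [(float(d), 0.0) for d in diffs]
        r = wilcoxon_signed_rank(pairs)
        assert r.method == "exact"
        assert r.p_two_tailed == pytest.approx(wilcoxon_enumeration_oracle(diffs))

    def test_ties_fall_back_to_normal_approx(self):
        pairs = [(2.0, 1.0), (3.0, 2.0), (0.0, 1.0), (5.0, 4.0), (1.0, 2.0),
                 (7.0, 6.0)]
        r = wilcoxon_signed_rank(pairs)
        assert r.method == "normal_approx"

    def test_statistic_bounded(self):
        rng = np.random.default_rng(0)
        pairs = [(float(a), float(b)) for a, b in rng.normal(size=(15, 2))]
        r = wilcoxon_signed_rank(pairs)
        assert 0 <= r.w_statistic <= r.n_effective * (r.n_effective + 1) / 2


class TestCovariance:
    def test_star_tree_is_diagonal(self):
        star = dendropy.Tree.get(
            data="(" + ",".join(f"s{i}:1" for i in range(6)) + "):0;",
            schema="newick",
        )
        cov = build_covariance(star, [f"s{i}" for i in range(6)])
        assert np.allclose(cov.v_matrix, np.eye(6))

    def test_nested_topology(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,C:2):0;", schema="newick")
        cov = build_covariance(t, ["A", "B", "C"])
        assert cov.v_matrix[0, 1] == pytest.approx(1.0)
        assert cov.v_matrix[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(cov.v_matrix), 2.0)

    def test_symmetric_psd_on_random_trees(self):
        for seed in range(10):
            tree = simulate_tree(20, seed=seed)
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            v = build_covariance(tree, tips).v_matrix
            assert np.allclose(v, v.T)
            assert np.linalg.eigvalsh(v).min() > -1e-9

    def test_two_samples_rule_duplicates_tip(self):
        """A species contributing both NUMT and NUPT data enters twice,
        separated by a negligible branch, keeping V nonsingular."""
        t = dendropy.Tree.get(data="((A:1,B:1):1,C:2):0;", schema="newick")
        cov = build_covariance(t, ["A", "A", "B"])
        assert cov.v_matrix[0, 1] == pytest.approx(2.0 - 1e-8)
        assert cov.v_matrix[0, 0] == pytest.approx(2.0)
        np.linalg.cholesky(cov.with_lambda(1.0))  # must not raise

    def test_missing_tip_is_error(self):
        t = dendropy.Tree.get(data="(A:1,B:1):0;", schema="newick")
        with pytest.raises(ValueError, match="'Z'"):
            build_covariance(t, ["A", "Z"])


@pytest.fixture(scope="module")
def tree_cov():
    tree = simulate_tree(40, seed=11)
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    return build_covariance(tree, tips)


class TestPGLS:
    def test_lambda_zero_equals_ols(self, tree_cov):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        y = 1.5 * x + rng.standard_normal(40)
        res = pgls_fit(y, x, tree_cov, lambda_mode=0.0)
        ols = st.linregress(x, y)
        assert res.slope == pytest.approx(ols.slope, abs=1e-8)
        assert res.intercept == pytest.approx(ols.intercept, abs=1e-8)
        assert res.p_value == pytest.approx(ols.pvalue, rel=1e-6)
        assert res.r_squared == pytest.approx(ols.rvalue**2, abs=1e-8)

    def test_star_tree_equals_ols_for_every_lambda(self):
        star = dendropy.Tree.get(
            data="(" + ",".join(f"s{i}:1" for i in range(25)) + "):0;",
            schema="newick",
        )
        cov = build_covariance(star, [f"s{i}" for i in range(25)])
        rng = np.random.default_rng(2)
        x = rng.standard_normal(25)
        y = -0.7 * x + rng.standard_normal(25)
        ols = st.linregress(x, y)
        for lam in (0.0, 0.3, 0.7, 1.0, "ml"):
            res = pgls_fit(y, x, cov, lambda_mode=lam)
            assert res.slope == pytest.approx(ols.slope, abs=1e-8)

    def test_ml_lambda_is_grid_global_max(self, tree_cov):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        cfg_tree = simulate_tree(40, seed=11)
        y = simulate_traits(TraitSimConfig(cfg_tree, 0.7, 1.0, 1.0, x, seed=9),
                            tree_cov)
        res = pgls_fit(y, x, tree_cov, lambda_mode="ml")
        grid_best = max(
            pgls_fit(y, x, tree_cov, lambda_mode=g).log_likelihood
            for g in np.linspace(0, 1, 101)
        )
        assert res.log_likelihood >= grid_best - 1e-6

    def test_constant_predictor_is_error(self, tree_cov):
        with pytest.raises(ValueError, match="singular|constant"):
            pgls_fit(np.arange(40.0), np.ones(40), tree_cov)

    def test_log_transform_applied(self, tree_cov):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40)
        y = np.abs(rng.standard_normal(40)) * 100
        r_raw = pgls_fit(y, x, tree_cov, lambda_mode=0.0)
        r_log = pgls_fit(y, x, tree_cov, lambda_mode=0.0, transform="log10p1")
        ols = st.linregress(x, np.log10(1 + y))
        assert r_log.slope == pytest.approx(ols.slope, abs=1e-8)
        assert r_log.slope != pytest.approx(r_raw.slope)


class TestAssemblyCoding:
    LEVELS = {"a": "contig", "b": "scaffold", "c": "chromosome", "d": "complete"}

    def test_contig_vs_rest(self):
        codes = code_assembly_levels(self.LEVELS, "contig_vs_rest")
        assert codes == {"a": 1, "b": 2, "c": 2, "d": 2}

    def test_scaffold_vs_higher_excludes_contig(self):
        codes = code_assembly_levels(self.LEVELS, "scaffold_vs_higher")
        assert codes == {"b": 3, "c": 4, "d": 4}

    def test_unknown_level_is_error(self):
        with pytest.raises(ValueError, match="complete_genome"):
            code_assembly_levels({"x": "complete_genome"}, "contig_vs_rest")


class TestSpearman:
    def test_monotone_gives_one(self):
        r = spearman([1, 2, 3, 5, 8], [10, 20, 21, 40, 100])
        assert r.rho == pytest.approx(1.0)

    def test_reversal_negates_rho(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0, 7.0]
        y = [2.0, 3.0, 1.0, 9.0, 4.0, 8.0]
        assert spearman(x, [-v for v in y]).rho == pytest.approx(-spearman(x, y).rho)

    def test_rho_matches_scipy(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        mine = spearman(x, y)
        ref = st.spearmanr(x, y)
        assert mine.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_p_small_n(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal(6), rng.standard_normal(6)
        mine = spearman(x, y)
        rx, ry = st.rankdata(x), st.rankdata(y)
        rhos = [np.corrcoef(rx, p)[0, 1] for p in itertools.permutations(ry)]
        p_oracle = np.mean(np.abs(rhos) >= abs(mine.rho) - 1e-12)
        assert mine.p_value == pytest.approx(p_oracle)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestRunComparisons:
    def test_identical_columns_give_p_one(self):
        import pandas as pd

        df = pd.DataFrame({
            "tolerant_count": [1.0, 2, 3, 4, 5, 6],
            "control_count": [1.0, 2, 3, 4, 5, 6],
            "group": ["invertebrate"] * 3 + ["plant"] * 3,
        })
        res = run_paper_comparisons(df, metrics=("count",))
        assert (res["p_two_tailed"] == 1.0).all()
        assert set(res["subset"]) == {"all", "invertebrate", "plant"}

    def test_genome_size_halves_present(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "tolerant_count": rng.lognormal(size=10),
            "control_count": rng.lognormal(size=10),
            "mean_genome_size": rng.uniform(1e7, 1e9, size=10),
        })
        res = run_paper_comparisons(df, metrics=("count",))
        assert {"all", "small_genomes", "large_genomes"} <= set(res["subset"])
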