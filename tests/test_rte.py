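import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribote import rte as rte_mod
from ribote.rte import (
    average_replicates,
    compare_distributions,
    compute_rpkm,
    compute_rte,
    cross_condition_correlation,
    cross_gene_correlation,
    differential,
    exhaustive_null,
    filter_genes,
    scrambled_null,
    spearman_rows,
    summarize_rho,
    variability,
)

from conftest import make_table


class TestRpkm:
    def test_direct_arithmetic(self):
        # count 10, length 500 nt, column total 1e6 -> RPKM 20
        tab = make_table(
            [[10.0], [999990.0]], [500, 1000], [("A", "1")]
        )
        rpkm = compute_rpkm(tab)
        assert rpkm.values.iloc[0, 0] == pytest.approx(20.0)
        assert rpkm.values.iloc[1, 0] == pytest.approx(999990.0)  # 1 kb, ~1e6 total

    def test_zero_count_gives_zero(self):
        tab = make_table([[0.0], [100.0]], [500, 1000], [("A", "1")])
        assert compute_rpkm(tab).values.iloc[0, 0] == 0.0

    def test_algebraic_identity_per_column(self, count_tables):
        """sum_g RPKM_g * length_kb_g == 1e6 for every library."""
        mrna, _ = count_tables
        rpkm = compute_rpkm(mrna)
        sums = rpkm.values.mul(rpkm.gene_lengths / 1e3, axis=0).sum(axis=0)
        np.testing.assert_allclose(sums.to_numpy(), 1e6, rtol=1e-12)

    def test_zero_column_total_rejected(self):
        tab = make_table([[0.0, 1.0]], [300], [("A", "1"), ("A", "2")])
        with pytest.raises(ValueError, match="A"):
            compute_rpkm(tab)


class TestAverageReplicates:
    def test_mean_per_condition(self):
        tab = make_table(
            [[1.0, 2.0, 3.0, 10.0, 10.0, 10.0]], [300],
            [("A", "1"), ("A", "2"), ("A", "3"), ("B", "1"), ("B", "2"), ("B", "3")],
        )
        avg = average_replicates(tab)
        assert avg.loc["g0", "A"] == 2.0
        assert avg.loc["g0", "B"] == 10.0

    def test_matches_brute_force(self, rpkm_tables):
        mrna, _ = rpkm_tables
        avg = average_replicates(mrna)
        for cond in mrna.condition_ids[:3]:
            brute = mrna.values[cond].to_numpy().mean(axis=1)
            np.testing.assert_allclose(avg[cond].to_numpy(), brute)


class TestFilterGenes:
    def test_threshold_is_exclusive_at_10_to_1p5(self):
        means = pd.DataFrame({"A": [1.0, 30.0, 32.0, 100.0, 31.63]},
                             index=list("abcde"))
        kept = filter_genes(means)
        assert kept == ["c", "d", "e"]  # mean > 10**1.5 = 31.6228

    def test_rpkm_of_10_everywhere_filtered_out(self):
        means = pd.DataFrame(np.full((4, 12), 10.0))
        assert filter_genes(means) == []

    def test_min_convention_stricter_than_mean(self, rpkm_tables):
        mrna, _ = rpkm_tables
        avg = average_replicates(mrna)
        kept_mean = set(filter_genes(avg, convention="mean"))
        kept_min = set(filter_genes(avg, convention="min"))
        assert kept_min <= kept_mean


class TestComputeRte:
    def test_identity_when_tables_equal(self, rpkm_tables):
        mrna, _ = rpkm_tables
        mat = compute_rte(mrna, mrna)
        np.testing.assert_allclose(mat.values.to_numpy(), 1.0)

    def test_depth_rescaling_invariance(self, count_tables):
        """Doubling all footprint counts leaves RTE unchanged."""
        mrna, fp = count_tables
        from ribote.iofmt import ExpressionTable

        fp2 = ExpressionTable(fp.values * 2, fp.gene_lengths, "raw_counts")
        a = compute_rte(compute_rpkm(fp), compute_rpkm(mrna)).values
        b = compute_rte(compute_rpkm(fp2), compute_rpkm(mrna)).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)

    def test_two_gene_hand_computation(self):
        # raw counts -> RPKM -> ratio, checked against hand arithmetic
        mrna = make_table([[90.0], [10.0]], [300, 600], [("A", "1")])
        fp = make_table([[40.0], [60.0]], [300, 600], [("A", "1")])
        mat = compute_rte(compute_rpkm(fp), compute_rpkm(mrna))
        # gene0: fp RPKM = 40/(0.3*1e-4)=... ratio reduces to
        # (40/90) * (depth ratio 100/100) = 4/9; lengths cancel in the ratio
        assert mat.values.iloc[0, 0] == pytest.approx((40 / 100) / (90 / 100))
        assert mat.values.iloc[1, 0] == pytest.approx((60 / 100) / (10 / 100))

    def test_zero_mrna_flagged_undefined(self):
        mrna = make_table([[0.0], [10.0]], [300, 600], [("A", "1")], "rpkm")
        fp = make_table([[5.0], [5.0]], [300, 600], [("A", "1")], "rpkm")
        mat = compute_rte(fp, mrna)
        assert np.isnan(mat.values.iloc[0, 0])
        assert mat.undefined_genes == ["g0"]


class TestCrossGene:
    def test_proportional_means_give_r2_one(self):
        rng = np.random.default_rng(0)
        mrna = pd.Series(10 ** rng.normal(2, 0.5, size=500))
        res = cross_gene_correlation(mrna, 3.0 * mrna)
        assert res["pearson_r2_log10"] == pytest.approx(1.0)
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_permuted_axis_decorrelates(self):
        rng = np.random.default_rng(1)
        mrna = pd.Series(10 ** rng.normal(2, 0.5, size=2000))
        rte = pd.Series(rng.permutation(mrna.to_numpy()), index=mrna.index)
        res = cross_gene_correlation(mrna, rte)
        assert res["pearson_r2_log10"] < 0.01


class TestCrossCondition:
    def test_comonotone_vectors_give_plus_one(self):
        m = pd.DataFrame([np.arange(12.0)], index=["g"])
        r = pd.DataFrame([np.arange(12.0) ** 2 + 1], index=["g"])
        assert cross_condition_correlation(m, r).loc["g"] == pytest.approx(1.0)

    def test_constant_vector_reported_missing(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"])
        r = pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], index=["g"])
        assert np.isnan(cross_condition_correlation(m, r).loc["g"])

    def test_vectorized_spearman_matches_scipy(self, rpkm_tables, rte_matrix):
        """The fast rank-then-Pearson route agrees with scipy per gene."""
        mrna, _ = rpkm_tables
        avg = average_replicates(mrna).iloc[:40]
        rte_vals = rte_matrix.values.iloc[:40]
        fast = cross_condition_correlation(avg, rte_vals)
        for g in avg.index:
            ref = stats.spearmanr(avg.loc[g], rte_vals.loc[g]).statistic
            assert fast.loc[g] == pytest.approx(ref, abs=1e-12)

    def test_class_sign_recovery(self):
        """Median rho per simulated class matches the class definition at
        the study conditions (2000 genes, depth 5e6, dispersion 0.05)."""
        from ribote import synthetic

        design = synthetic.ConditionDesign.default()
        truth = synthetic.simulate_genes(n_genes=2000, effect_size_log2=2.0,
                                         design=design, seed=1)
        mrna, fp = synthetic.simulate_counts(truth, design, 5e6, 0.05, seed=101)
        mr = compute_rpkm(mrna)
        rho = cross_condition_correlation(
            average_replicates(mr), compute_rte(compute_rpkm(fp), mr).values
        )
        classes = pd.Series({t.gene_id: t.regulation_class for t in truth})
        med = rho.groupby(classes).median()
        assert med["concordant"] > 0.5
        assert med["antagonistic"] < -0.5
        assert -0.2 < med["stable"] < 0.2


class TestScrambledNull:
    def test_mean_near_zero_and_symmetric(self, rpkm_tables, rte_matrix):
        mrna, _ = rpkm_tables
        avg = average_replicates(mrna)
        null = scrambled_null(avg, rte_matrix.values, n_scrambles=50, seed=5)
        bound = 2 / np.sqrt(len(avg) * 50 * 11)
        assert abs(null.mean()) < bound
        # sign symmetry within Monte-Carlo error
        frac_pos = (null > 0).mean()
        assert abs(frac_pos - 0.5) < 3 / np.sqrt(null.size)

    def test_permutation_preserves_value_multiset(self, rte_matrix):
        rte_vals = rte_matrix.values.iloc[:5]
        rng = np.random.default_rng(0)
        idx = np.argsort(rng.random(rte_vals.shape), axis=1)
        permuted = np.take_along_axis(rte_vals.to_numpy(), idx, axis=1)
        np.testing.assert_allclose(
            np.sort(permuted, axis=1), np.sort(rte_vals.to_numpy(), axis=1)
        )

    def test_sampled_null_converges_to_exhaustive_at_four_conditions(self):
        """At 4 conditions all 24 permutations give the exact null; the
        sampled null converges to it (KS < 0.05 at 1e4 scrambles)."""
        mrna_vec = np.array([3.0, 1.0, 4.0, 2.0])
        rte_vec = np.array([10.0, 20.0, 5.0, 40.0])
        exact = exhaustive_null(mrna_vec, rte_vec)
        assert exact.size == 24
        assert exact.mean() == pytest.approx(0.0, abs=1e-12)
        m = pd.DataFrame([mrna_vec], index=["g"])
        r = pd.DataFrame([rte_vec], index=["g"])
        sampled = scrambled_null(m, r, n_scrambles=10_000, seed=3)
        ks = stats.ks_2samp(sampled, exact).statistic
        assert ks < 0.05


class TestCompareDistributions:
    def test_identical_samples(self):
        x = np.linspace(-1, 1, 200)
        res = compare_distributions(x, x)
        assert res["ks_statistic"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_null_calibration(self):
        """Two draws from one distribution give uniform p-values."""
        rng = np.random.default_rng(7)
        n_sig = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(size=500)
            b = rng.normal(size=500)
            if compare_distributions(a, b)["p_value"] < 0.05 :
                n_sig += 1
        assert 0 <= n_sig / reps <= 0.12


class TestDifferential:
    def _concordant_tables(self):
        """40 background genes plus 10 with +5 log2 mRNA and +1 log2 RTE in A."""
        rng = np.random.default_rng(0)
        n_bg, n_up = 40, 10
        genes = [f"bg{i}" for i in range(n_bg)] + [f"up{i}" for i in range(n_up)]
        base = np.full(n_bg + n_up, 100.0)
        cols = [("A", "1"), ("A", "2"), ("A", "3"), ("B", "1"), ("B", "2"), ("B", "3")]
        noise = lambda: rng.normal(1.0, 0.01, size=(n_bg + n_up, 3))
        mrna_a = base[:, None] * noise()
        mrna_a[n_bg:] *= 2.0**5
        mrna_b = base[:, None] * noise()
        fp_a = base[:, None] * noise()
        fp_a[n_bg:] *= 2.0**6  # mRNA x2^5, RTE x2
        fp_b = base[:, None] * noise()
        mrna = make_table(np.hstack([mrna_a, mrna_b]), np.full(n_bg + n_up, 300.0),
                          cols, "rpkm", genes=genes)
        fp = make_table(np.hstack([fp_a, fp_b]), np.full(n_bg + n_up, 300.0),
                        cols, "rpkm", genes=genes)
        return mrna, fp

    def test_construction_oracle_all_selected_concordant(self):
        mrna, fp = self._concordant_tables()
        res = differential(mrna, fp, "A", "B")
        assert sorted(res.selected_up) == sorted(f"up{i}" for i in range(10))
        assert res.selected_down == []
        assert res.fraction_up_rte_concordant == 1.0
        assert res.up_rte_ttest_p < 0.01

    def test_identical_conditions_select_nothing(self, rpkm_tables):
        mrna, fp = rpkm_tables
        from ribote.iofmt import ExpressionTable

        dup = mrna.values.copy()
        dup[("B", "1")] = dup[("Clim_0.1", "1")]
        dup[("B", "2")] = dup[("Clim_0.1", "2")]
        dup[("B", "3")] = dup[("Clim_0.1", "3")]
        tab = ExpressionTable(dup, mrna.gene_lengths, "rpkm")
        res = differential(tab, tab, "Clim_0.1", "B")
        assert res.selected_up == [] and res.selected_down == []

    def test_unknown_condition_rejected(self, rpkm_tables):
        mrna, fp = rpkm_tables
        with pytest.raises(ValueError, match="nope"):
            differential(mrna, fp, "nope", "Clim_0.1")


class TestVariability:
    def test_constant_vector(self):
        r = pd.DataFrame([[2.0] * 6], index=["g"])
        tab = variability(r)
        assert tab.loc["g", "variance"] == 0.0
        assert tab.loc["g", "fano"] == 0.0
        assert tab.loc["g", "cv"] == 0.0

    def test_hand_arithmetic(self):
        r = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        tab = variability(r)
        assert tab.loc["g", "mean"] == 2.0
        assert tab.loc["g", "variance"] == 1.0  # n-1 denominator
        assert tab.loc["g", "fano"] == 0.5
        assert tab.loc["g", "cv"] == 0.5

    def test_fano_cv_identity(self, rte_matrix):
        tab = variability(rte_matrix)
        ok = tab["mean"] > 0
        np.testing.assert_allclose(
            tab.loc[ok, "fano"], tab.loc[ok, "cv"] ** 2 * tab.loc[ok, "mean"]
        )

    def test_zero_mean_reported_missing(self):
        r = pd.DataFrame([[0.0, 0.0, 0.0]], index=["g"])
        tab = variability(r)
        assert np.isnan(tab.loc["g", "fano"]) and np.isnan(tab.loc["g", "cv"])


def test_summarize_rho_tail_fractions():
    rho = pd.Series([-0.9, -0.6, -0.1, 0.2, 0.7, np.nan])
    s = summarize_rho(rho)
    assert s["n"] == 5
    assert s["fraction_below"] == pytest.approx(2 / 5)
    assert s["fraction_above"] == pytest.approx(1 / 5)
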