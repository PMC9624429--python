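import numpy as np
import pandas as pd
import pytest

from ribote import classify
from ribote.classify import (
    FeatureSpec,
    build_features,
    condition_subset_contrast,
    feature_importance,
    label_by_median,
    pairwise_condition_codon_contrast,
    train_eval,
)
from ribote.codons import (
    background_frequencies,
    center_profile,
    codon_frequencies,
    group_contrast,
)
from ribote.rte import variability
from ribote.synthetic import GeneTruth, simulate_cds


@pytest.fixture(scope="module")
def centered_profiles(cds_models):
    bg = background_frequencies(cds_models)
    return {m.gene_id: center_profile(codon_frequencies(m), bg) for m in cds_models}


@pytest.fixture(scope="module")
def labels_and_features(truth, centered_profiles):
    labels = pd.Series(
        {t.gene_id: int(t.variability_class == "high") for t in truth}
    )
    feats = build_features(FeatureSpec(codon=True), codon_profiles=centered_profiles)
    return labels.loc[feats.index], feats


class TestLabelByMedian:
    def test_hand_split(self):
        tab = pd.DataFrame({"variance": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        assert label_by_median(tab).tolist() == [0, 0, 1, 1]

    def test_all_equal_all_low(self):
        tab = pd.DataFrame({"variance": [2.0] * 5})
        assert label_by_median(tab).sum() == 0

    def test_median_ties_fall_in_low_class(self):
        tab = pd.DataFrame({"variance": [1.0, 2.0, 2.0, 2.0, 5.0]})
        lab = label_by_median(tab)
        # classes differ by at most the number of median-valued genes
        assert abs((lab == 1).sum() - (lab == 0).sum()) <= 3


class TestBuildFeatures:
    def test_codon_block_width(self, centered_profiles):
        feats = build_features(FeatureSpec(codon=True), codon_profiles=centered_profiles)
        assert feats.shape[1] == 64

    def test_codon_mrna_rte_width(self, centered_profiles):
        ids = list(centered_profiles)
        extra = pd.Series(1.0, index=ids)
        feats = build_features(
            FeatureSpec(codon=True, mrna=True, rte=True),
            codon_profiles=centered_profiles,
            mrna_means=extra,
            rte_means=extra * 2,
        )
        assert feats.shape[1] == 66
        assert {"mrna_mean", "rte_mean"} <= set(feats.columns)

    def test_no_blocks_rejected(self):
        with pytest.raises(ValueError):
            build_features(FeatureSpec(codon=False))

    def test_unknown_block_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            FeatureSpec.from_names(["codno"])


class TestTrainEval:
    def test_deterministic_under_seed(self, labels_and_features):
        labels, feats = labels_and_features
        a = train_eval(feats, labels, n_repeats=2, n_trees=50, seed=9)
        b = train_eval(feats, labels, n_repeats=2, n_trees=50, seed=9)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)
        pd.testing.assert_series_equal(a.importances, b.importances)

    def test_informative_codon_features_classify_well(self, labels_and_features):
        labels, feats = labels_and_features
        report = train_eval(feats, labels, n_repeats=5, seed=1)
        assert report.metrics_mean["auc"] > 0.8
        assert report.confusion["TP"] + report.confusion["FN"] > 0
        # invariants of the report
        per = report.per_repeat
        assert ((per["auc"] >= 0) & (per["auc"] <= 1)).all()

    def test_permuted_labels_give_chance_auc(self, labels_and_features):
        """A fresh label permutation per repeat averages out labeling-specific
        chance associations; the mean AUC sits at 0.5."""
        labels, feats = labels_and_features
        rng = np.random.default_rng(3)
        aucs = []
        for i in range(10):
            permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            report = train_eval(feats, permuted, n_repeats=1, n_trees=100, seed=i)
            aucs.append(report.metrics_mean["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_tilted_codons_top_importances(self, truth):
        """With exactly four informative codons, they top the importance
        ranking."""
        models = simulate_cds(
            truth, high_var_codons=("AAA", "GAT"), low_var_codons=("CGT", "CTG"),
            bias_strength=0.5, seed=17,
        )
        bg = background_frequencies(models)
        profs = {m.gene_id: center_profile(codon_frequencies(m), bg) for m in models}
        labels = pd.Series({t.gene_id: int(t.variability_class == "high") for t in truth})
        feats = build_features(FeatureSpec(codon=True), codon_profiles=profs)
        report = train_eval(feats, labels.loc[feats.index], n_repeats=3, seed=5)
        top4 = set(feature_importance(report).index[:4])
        assert top4 == {"AAA", "GAT", "CGT", "CTG"}

    def test_small_class_rejected(self, labels_and_features):
        _, feats = labels_and_features
        tiny = pd.Series(0, index=feats.index)
        tiny.iloc[:5] = 1
        with pytest.raises(ValueError, match="per class"):
            train_eval(feats, tiny, n_repeats=1, seed=0)


class TestConditionSubsets:
    def test_full_set_matches_group_contrast(self, rte_matrix, centered_profiles):
        vtab = variability(rte_matrix)
        full = group_contrast(vtab, centered_profiles, n_top=100)["rho"]
        rhos = condition_subset_contrast(
            rte_matrix.values, centered_profiles, n_conditions=12, n_top=100, seed=0
        )
        assert rhos.shape == (1,)
        assert rhos[0] == pytest.approx(full)

    def test_contrast_strengthens_with_more_conditions(self, rte_matrix, centered_profiles):
        lo = condition_subset_contrast(
            rte_matrix.values, centered_profiles, n_conditions=2, n_draws=15,
            n_top=100, seed=1,
        )
        hi = condition_subset_contrast(
            rte_matrix.values, centered_profiles, n_conditions=10, n_draws=15,
            n_top=100, seed=1,
        )
        assert np.median(hi) <= np.median(lo)

    def test_bounds_checked(self, rte_matrix, centered_profiles):
        with pytest.raises(ValueError):
            condition_subset_contrast(rte_matrix.values, centered_profiles, n_conditions=1)


class TestPairwiseConditionContrast:
    def _replicated_rte(self, seed=0):
        """Genes shifted up in A or in B share codon usage; stable genes differ."""
        rng = np.random.default_rng(seed)
        n = 80
        ids = [f"g{i:05d}" for i in range(3 * n)]
        cols = pd.MultiIndex.from_tuples(
            [("A", str(r)) for r in range(3)] + [("B", str(r)) for r in range(3)],
            names=["condition", "replicate"],
        )
        vals = np.ones((3 * n, 6)) + rng.normal(0, 0.02, size=(3 * n, 6))
        vals[:n, :3] *= 3.0      # up in A
        vals[n:2 * n, 3:] *= 3.0  # up in B
        return pd.DataFrame(vals, index=ids, columns=cols), n

    def test_construction_oracle(self):
        rte_rep, n = self._replicated_rte()
        ids = list(rte_rep.index)
        # both up-groups draw from the high-variability codon profile; the
        # tilt spans many codons so the class signal dominates the group
        # sampling noise (which in-sample background centering leaves
        # anti-correlated between disjoint same-class sets)
        truths = [
            GeneTruth(g, "concordant", 100.0, 1.0, np.ones(2), np.ones(2),
                      "high" if i < 2 * n else "low",
                      "high_var" if i < 2 * n else "low_var", 450)
            for i, g in enumerate(ids)
        ]
        from ribote.synthetic import SENSE_CODONS

        rng = np.random.default_rng(1)
        pick = rng.permutation(61)
        hi = [SENSE_CODONS[i] for i in pick[:12]]
        lo = [SENSE_CODONS[i] for i in pick[12:24]]
        models = simulate_cds(truths, high_var_codons=hi, low_var_codons=lo,
                              bias_strength=0.8, seed=8)
        bg = background_frequencies(models)
        profs = {m.gene_id: center_profile(codon_frequencies(m), bg) for m in models}
        res = pairwise_condition_codon_contrast(rte_rep, profs, "A", "B")
        assert res["up_up_rho"] > 0
        assert res["up_stable_rho"] < 0
        assert -1 <= res["up_up_rho"] <= 1

    def test_identical_conditions_error(self, centered_profiles):
        ids = list(centered_profiles)[:60]
        cols = pd.MultiIndex.from_tuples(
            [("A", str(r)) for r in range(3)] + [("B", str(r)) for r in range(3)],
            names=["condition", "replicate"],
        )
        flat = pd.DataFrame(np.ones((60, 6)), index=ids, columns=cols)
        with pytest.raises(ValueError, match="shifted"):
            pairwise_condition_codon_contrast(flat, centered_profiles, "A", "B")
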