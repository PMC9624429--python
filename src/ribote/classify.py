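"""Random-forest classification of high/low cross-condition RTE variability.

Genes are labelled by a median split of a variability index (variance, Fano
or CV of RTE across conditions) and classified from sequence/expression
feature blocks: the 64 codon frequencies, mean mRNA level, mean RTE,
third-base composition, gene length, and pause-motif frequencies.  The
evaluation protocol repeats a random 80/20 split many times, trains a
200-tree forest (minimum leaf 5, sqrt feature subsampling) and aggregates
sensitivity, specificity, accuracy (threshold 0.5) and trapezoidal AUC,
plus a vertically averaged ROC and mean impurity-decrease importances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .codons import CodonProfile, group_contrast, profile_frame, set_profile, profile_correlation
from .rte import variability

__all__ = [
    "FeatureSpec",
    "RFReport",
    "label_by_median",
    "build_features",
    "train_eval",
    "feature_importance",
    "condition_subset_contrast",
    "pairwise_condition_codon_contrast",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature blocks enter the classifier."""

    codon: bool = True
    mrna: bool = False
    rte: bool = False
    third_base: bool = False
    length: bool = False
    pause_motifs: bool = False

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "FeatureSpec":
        valid = {f for f in cls.__dataclass_fields__}
        bad = set(names) - valid
        if bad:
            raise ValueError(f"unknown feature blocks: {sorted(bad)}")
        return cls(**{n: True for n in names})


def label_by_median(variability_table: pd.DataFrame, index: str | None = None) -> pd.Series:
    """Binary labels: 1 above the median of the chosen index, else 0.

    Exact-median genes land in the low class (and are counted in a log
    message), so class sizes differ by at most the number of median-valued
    genes.
    """
    col = index or variability_table.attrs.get("index", "variance")
    values = variability_table[col]
    median = values.median()
    at_median = int((values == median).sum())
    if values.nunique() == 1:
        log.warning("all variability values equal; every gene labelled low")
    elif at_median:
        log.info("%d genes at the exact median assigned to the low class", at_median)
    return (values > median).astype(int)


def build_features(
    spec: FeatureSpec,
    codon_profiles: Mapping[str, CodonProfile] | pd.DataFrame | None = None,
    mrna_means: pd.Series | None = None,
    rte_means: pd.Series | None = None,
    aux: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Concatenate the enabled feature blocks into one matrix.

    Columns keep their block names; no scaling is applied (tree model).
    """
    blocks: list[pd.DataFrame] = []
    if spec.codon:
        if codon_profiles is None:
            raise ValueError("codon block enabled but no profiles given")
        frame = (
            codon_profiles
            if isinstance(codon_profiles, pd.DataFrame)
            else profile_frame(codon_profiles)
        )
        blocks.append(frame)
    if spec.mrna:
        if mrna_means is None:
            raise ValueError("mrna block enabled but no mRNA means given")
        blocks.append(mrna_means.rename("mrna_mean").to_frame())
    if spec.rte:
        if rte_means is None:
            raise ValueError("rte block enabled but no RTE means given")
        blocks.append(rte_means.rename("rte_mean").to_frame())
    if spec.third_base or spec.length or spec.pause_motifs:
        if aux is None:
            raise ValueError("auxiliary block enabled but no aux frame given")
        cols = []
        if spec.third_base:
            cols += [c for c in aux.columns if c.startswith("third_")]
        if spec.length:
            cols += [c for c in aux.columns if c == "length_nt"]
        if spec.pause_motifs:
            cols += [c for c in aux.columns if c.startswith("motif_")]
        blocks.append(aux[cols])
    if not blocks:
        raise ValueError("at least one feature block must be enabled")
    features = pd.concat(blocks, axis=1, join="inner")
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return features


@dataclass
class RFReport:
    """Aggregated evaluation of the repeated-split random forest."""

    per_repeat: pd.DataFrame  # sensitivity, specificity, accuracy, auc
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray
    importances: pd.Series  # mean impurity decrease, descending
    confusion: dict[str, int]  # pooled TP/FN/TN/FP at the threshold
    n_discarded: int = 0

    def summary(self) -> pd.DataFrame:
        rows = {
            m: f"{self.metrics_mean[m]:.4g} +/- {self.metrics_sd[m]:.2g}"
            for m in ("sensitivity", "specificity", "accuracy", "auc")
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=["mean +/- sd"])


def train_eval(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 200,
    min_leaf: int = 5,
    train_frac: float = 0.8,
    n_repeats: int = 1000,
    threshold: float = 0.5,
    seed: int = 0,
    min_class_size: int = 50,
) -> RFReport:
    """The repeated random-split evaluation protocol.

    Each repeat draws a plain (unstratified) random 80/20 split, trains a
    forest of ``n_trees`` trees (min leaf ``min_leaf``, sqrt of the feature
    count tried per split) and scores the held-out genes.  Degenerate
    repeats whose training split contains a single class are discarded and
    redrawn so exactly ``n_repeats`` valid repeats are aggregated.
    """
    labels = labels.loc[features.index]
    y = labels.to_numpy()
    X = features.to_numpy(dtype=float)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < min_class_size:
        raise ValueError(
            f"need >= {min_class_size} samples per class, have {class_counts.tolist()}"
        )
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round(train_frac * n))
    grid = np.linspace(0.0, 1.0, 101)
    rows, tprs, imps = [], [], []
    tp = fn = tn = fp = 0
    discarded = 0
    done = 0
    while done < n_repeats:
        order = rng.permutation(n)
        tr, te = order[:n_train], order[n_train:]
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            discarded += 1
            continue
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            min_samples_leaf=min_leaf,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X[tr], y[tr])
        score = forest.predict_proba(X[te])[:, 1]
        pred = (score > threshold).astype(int)
        yt = y[te]
        tp_i = int(((pred == 1) & (yt == 1)).sum())
        fn_i = int(((pred == 0) & (yt == 1)).sum())
        tn_i = int(((pred == 0) & (yt == 0)).sum())
        fp_i = int(((pred == 1) & (yt == 0)).sum())
        tp, fn, tn, fp = tp + tp_i, fn + fn_i, tn + tn_i, fp + fp_i
        rows.append(
            {
                "sensitivity": tp_i / (tp_i + fn_i),
                "specificity": tn_i / (tn_i + fp_i),
                "accuracy": (tp_i + tn_i) / len(yt),
                "auc": roc_auc_score(yt, score),
            }
        )
        fpr, tpr, _ = roc_curve(yt, score)
        tprs.append(np.interp(grid, fpr, tpr))
        imps.append(forest.feature_importances_)
        done += 1
    per_repeat = pd.DataFrame(rows)
    importances = pd.Series(
        np.mean(imps, axis=0), index=features.columns
    ).sort_values(ascending=False)
    if discarded:
        log.info("train_eval: %d degenerate repeats discarded and redrawn", discarded)
    return RFReport(
        per_repeat=per_repeat,
        metrics_mean={c: float(per_repeat[c].mean()) for c in per_repeat},
        metrics_sd={c: float(per_repeat[c].std(ddof=1)) for c in per_repeat},
        fpr_grid=grid,
        mean_tpr=np.mean(tprs, axis=0),
        sd_tpr=np.std(tprs, axis=0, ddof=1) if len(tprs) > 1 else np.zeros_like(grid),
        importances=importances,
        confusion={"TP": tp, "FN": fn, "TN": tn, "FP": fp},
        n_discarded=discarded,
    )


def feature_importance(report: RFReport) -> pd.Series:
    """Mean impurity-decrease importances, descending."""
    return report.importances


def condition_subset_contrast(
    rte: pd.DataFrame,
    profiles: Mapping[str, CodonProfile],
    n_conditions: int,
    n_draws: int = 100,
    n_top: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Top/bottom codon contrast recomputed on condition subsets.

    For each subset of ``n_conditions`` of the columns (exhaustive when the
    number of combinations is <= ``n_draws``, otherwise sampled), the RTE
    variance is recomputed on the subset, the top/bottom ``n_top`` genes
    re-ranked, and the group codon correlation collected.
    """
    total = rte.shape[1]
    if not 2 <= n_conditions <= total:
        raise ValueError("n_conditions must be between 2 and the condition count")
    n_comb = math.comb(total, n_conditions)
    rng = np.random.default_rng(seed)
    if n_comb <= n_draws:
        subsets = list(combinations(range(total), n_conditions))
    else:
        subsets = [
            tuple(sorted(rng.choice(total, size=n_conditions, replace=False)))
            for _ in range(n_draws)
        ]
    rhos = []
    for cols in subsets:
        sub = rte.iloc[:, list(cols)]
        vtab = variability(sub, index="variance")
        rhos.append(group_contrast(vtab, profiles, n_top=n_top)["rho"])
    return np.array(rhos)


def pairwise_condition_codon_contrast(
    rte_replicates: pd.DataFrame,
    profiles: Mapping[str, CodonProfile],
    cond_a: str,
    cond_b: str,
    p_cut: float = 0.05,
) -> dict[str, float]:
    """Codon similarity of RTE-shifted gene groups between two conditions.

    Genes are classified by their RTE change between the conditions using a
    per-gene Welch t-test on replicate RTEs and the fold-change sign:
    up in A, up in B, or unchanged (p >= cut).  Reported: the correlation
    between the two up-groups' mean profiles, and each up-group against the
    unchanged group.
    """
    a = rte_replicates[cond_a]
    b = rte_replicates[cond_b]
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = pd.Series(res.pvalue, index=rte_replicates.index)
    delta = a.mean(axis=1) - b.mean(axis=1)
    up_a = list(p.index[(p < p_cut) & (delta > 0)])
    up_b = list(p.index[(p < p_cut) & (delta < 0)])
    stable = list(p.index[p >= p_cut])
    if not up_a or not up_b:
        raise ValueError(
            "no significantly shifted genes between the two conditions; "
            "check that they differ and replicates are present"
        )
    prof_a = set_profile(up_a, profiles, set_id=f"up_{cond_a}")
    prof_b = set_profile(up_b, profiles, set_id=f"up_{cond_b}")
    prof_s = set_profile(stable, profiles, set_id="unchanged")
    up_a_stable = profile_correlation(prof_a, prof_s)
    up_b_stable = profile_correlation(prof_b, prof_s)
    return {
        "up_up_rho": profile_correlation(prof_a, prof_b),
        "up_a_stable_rho": up_a_stable,
        "up_b_stable_rho": up_b_stable,
        "up_stable_rho": 0.5 * (up_a_stable + up_b_stable),
        "n_up_a": len(up_a),
        "n_up_b": len(up_b),
        "n_stable": len(stable),
    }
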