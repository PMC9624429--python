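"""Core relative-translation-efficiency (RTE) statistics.

RTE for a gene under a condition is the ratio of its depth- and
length-normalized footprint density (RPKM) to its mRNA RPKM — the relative
occupancy of ribosomal resources per mRNA.  This module owns RPKM
normalization, the expression filter, the RTE matrix, cross-gene and
per-gene cross-condition Spearman correlations, the scrambled permutation
null with its Kolmogorov-Smirnov comparison, the differential concordance
screen between conditions, and the cross-condition variability indices
(variance, Fano factor, CV).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iofmt import ExpressionTable

__all__ = [
    "RTEMatrix",
    "CorrelationReport",
    "DifferentialResult",
    "compute_rpkm",
    "average_replicates",
    "filter_genes",
    "compute_rte",
    "cross_gene_correlation",
    "cross_condition_correlation",
    "scrambled_null",
    "exhaustive_null",
    "compare_distributions",
    "correlation_report",
    "differential",
    "variability",
]


# ---------------------------------------------------------------------------
# normalization and filtering

def compute_rpkm(table: ExpressionTable) -> ExpressionTable:
    """Reads per kilobase per million mapped reads, per replicate column.

    RPKM = count / (length_kb * column_total_millions).  The algebraic
    identity sum_g RPKM_g * length_kb_g == 1e6 holds per column.
    """
    if table.value_kind != "raw_counts":
        raise ValueError("compute_rpkm expects a raw_counts table")
    totals = table.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero column total in {zero.index[0]}")
    length_kb = table.gene_lengths / 1e3
    rpkm = table.values.div(totals / 1e6, axis=1).div(length_kb, axis=0)
    return ExpressionTable(rpkm, table.gene_lengths, "rpkm")


def average_replicates(table: ExpressionTable | pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over replicates -> genes x conditions frame."""
    values = table.values if isinstance(table, ExpressionTable) else table
    out = values.T.groupby(level="condition", sort=False).mean().T
    return out


def filter_genes(
    mrna_rpkm: pd.DataFrame,
    log10_threshold: float = 1.5,
    convention: str = "mean",
) -> list[str]:
    """Expression filter: keep genes with log10(mRNA RPKM) above threshold.

    ``convention='mean'`` applies the cut to the mean RPKM over the
    (replicate-averaged) conditions; ``'min'`` requires every condition to
    pass.  Input order is preserved.
    """
    cut = 10.0 ** log10_threshold
    if convention == "mean":
        keep = mrna_rpkm.mean(axis=1) > cut
    elif convention == "min":
        keep = (mrna_rpkm > cut).all(axis=1)
    else:
        raise ValueError(f"unknown filter convention {convention!r}")
    return list(mrna_rpkm.index[keep])


# ---------------------------------------------------------------------------
# RTE

@dataclass
class RTEMatrix:
    """Replicate-averaged RTE per gene and condition.

    Entries where the mRNA RPKM is zero are undefined (NaN) and excluded
    downstream; ``replicate_values`` optionally retains per-replicate RTE.
    """

    values: pd.DataFrame  # genes x conditions
    replicate_values: pd.DataFrame | None = None
    normalization: str = "rpkm_ratio"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def undefined_genes(self) -> list[str]:
        return list(self.values.index[self.values.isna().any(axis=1)])


def compute_rte(
    fp_rpkm: ExpressionTable | pd.DataFrame,
    mrna_rpkm: ExpressionTable | pd.DataFrame,
) -> RTEMatrix:
    """RTE = footprint RPKM / mRNA RPKM, per gene per condition.

    Both inputs are already length- and depth-normalized, so the
    footprint-density-over-relative-mRNA definition reduces to this ratio.
    Replicate-level tables are averaged per condition first; the
    per-replicate ratio is retained when both tables carry replicates.
    """
    rep = None
    if isinstance(fp_rpkm, ExpressionTable) and isinstance(mrna_rpkm, ExpressionTable):
        if fp_rpkm.value_kind != "rpkm" or mrna_rpkm.value_kind != "rpkm":
            raise ValueError("compute_rte expects RPKM tables")
        with np.errstate(divide="ignore", invalid="ignore"):
            rep = fp_rpkm.values / mrna_rpkm.values.replace(0, np.nan)
    fp = average_replicates(fp_rpkm) if isinstance(fp_rpkm, ExpressionTable) else fp_rpkm
    mr = (
        average_replicates(mrna_rpkm)
        if isinstance(mrna_rpkm, ExpressionTable)
        else mrna_rpkm
    )
    if not fp.index.equals(mr.index) or list(fp.columns) != list(mr.columns):
        raise ValueError("footprint and mRNA tables must share genes and conditions")
    values = fp / mr.replace(0, np.nan)
    return RTEMatrix(values, replicate_values=rep)


# ---------------------------------------------------------------------------
# correlation structure

def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1)


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; NaN for constant rows."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def spearman_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho with average-rank ties (vectorized)."""
    return _pearson_rows(_rank_rows(a), _rank_rows(b))


def cross_gene_correlation(
    mean_mrna: pd.Series, mean_rte: pd.Series
) -> dict[str, float]:
    """Across-gene association of condition-mean mRNA level and mean RTE.

    Pearson R^2 is computed on log10-transformed values (positive entries
    only); Spearman rho on the raw values.
    """
    joined = pd.concat([mean_mrna, mean_rte], axis=1).dropna()
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    pos = (x > 0) & (y > 0)
    r, _ = stats.pearsonr(np.log10(x[pos]), np.log10(y[pos]))
    rho, _ = stats.spearmanr(x, y)
    return {"pearson_r2_log10": float(r**2), "spearman_rho": float(rho)}


def cross_condition_correlation(
    mrna: pd.DataFrame, rte: pd.DataFrame
) -> pd.Series:
    """Per-gene Spearman rho between mRNA level and RTE across conditions.

    Genes with a constant vector (or any undefined RTE) get NaN.
    """
    if mrna.shape[1] < 3:
        raise ValueError("need >= 3 conditions for cross-condition correlation")
    if not mrna.index.equals(rte.index):
        raise ValueError("mRNA and RTE matrices must share the gene index")
    rho = spearman_rows(mrna.to_numpy(float), rte.to_numpy(float))
    rho = np.where(rte.isna().any(axis=1) | mrna.isna().any(axis=1), np.nan, rho)
    return pd.Series(rho, index=mrna.index, name="spearman_rho")


def summarize_rho(rho: pd.Series | np.ndarray, tail: float = 0.5) -> dict[str, float]:
    r = pd.Series(rho).dropna()
    return {
        "median": float(r.median()),
        "fraction_below": float((r < -tail).mean()),
        "fraction_above": float((r > tail).mean()),
        "n": int(len(r)),
    }


def scrambled_null(
    mrna: pd.DataFrame,
    rte: pd.DataFrame,
    n_scrambles: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Permutation null for the per-gene cross-condition correlation.

    For each scramble, every gene's RTE vector is independently permuted
    across conditions (preserving its value multiset) and the Spearman rho
    against the unscrambled mRNA vector recomputed; the pooled rho values
    over genes and scrambles form the null distribution.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    rng = np.random.default_rng(seed)
    rm = _rank_rows(mrna.to_numpy(float))
    rr = _rank_rows(rte.to_numpy(float))
    valid = ~(rte.isna().any(axis=1) | mrna.isna().any(axis=1)).to_numpy()
    out = []
    for _ in range(n_scrambles):
        idx = np.argsort(rng.random(rr.shape), axis=1)
        permuted = np.take_along_axis(rr, idx, axis=1)
        rho = _pearson_rows(rm, permuted)
        out.append(rho[valid])
    return np.concatenate(out)


def exhaustive_null(mrna_vector: np.ndarray, rte_vector: np.ndarray) -> np.ndarray:
    """Exact permutation null for one gene: rho over all n! orderings.

    Tractable only for small condition counts; used to validate the sampled
    scrambled null.
    """
    n = len(rte_vector)
    if n > 8:
        raise ValueError("exhaustive enumeration limited to <= 8 conditions")
    perms = np.array(list(itertools.permutations(range(n))))
    rte_perms = np.asarray(rte_vector, float)[perms]
    rm = np.tile(stats.rankdata(mrna_vector), (len(perms), 1))
    return _pearson_rows(rm, _rank_rows(rte_perms))


def compare_distributions(
    actual_rho: np.ndarray | pd.Series, null_rho: np.ndarray
) -> dict[str, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    actual = pd.Series(actual_rho).dropna().to_numpy()
    res = stats.ks_2samp(actual, null_rho, method="asymp")
    return {"ks_statistic": float(res.statistic), "p_value": float(res.pvalue)}


@dataclass
class CorrelationReport:
    """Per-gene mRNA-RTE correlations with their permutation null."""

    per_gene_rho: pd.Series
    null_rho: np.ndarray
    summary: dict[str, float]
    null_summary: dict[str, float]
    ks_statistic: float
    ks_pvalue: float


def correlation_report(
    mrna: pd.DataFrame,
    rte: pd.DataFrame,
    n_scrambles: int = 50,
    seed: int = 0,
) -> CorrelationReport:
    rho = cross_condition_correlation(mrna, rte)
    null = scrambled_null(mrna, rte, n_scrambles=n_scrambles, seed=seed)
    ks = compare_distributions(rho, null)
    return CorrelationReport(
        per_gene_rho=rho,
        null_rho=null,
        summary=summarize_rho(rho),
        null_summary=summarize_rho(null),
        ks_statistic=ks["ks_statistic"],
        ks_pvalue=ks["p_value"],
    )


# ---------------------------------------------------------------------------
# differential concordance

@dataclass
class DifferentialResult:
    """Fold-change screen between two conditions with RTE concordance."""

    table: pd.DataFrame  # per-gene log2 FCs and mRNA t-test p
    cond_a: str
    cond_b: str
    selected_up: list[str] = field(default_factory=list)
    selected_down: list[str] = field(default_factory=list)
    fraction_up_rte_concordant: float = float("nan")
    fraction_down_rte_concordant: float = float("nan")
    up_rte_ttest_p: float = float("nan")
    down_rte_ttest_p: float = float("nan")


def differential(
    mrna_rpkm: ExpressionTable,
    fp_rpkm: ExpressionTable,
    cond_a: str,
    cond_b: str,
    genes: list[str] | None = None,
    lfc_cut: float = 4.0,
    p_cut: float = 0.05,
    pseudocount: float = 0.5,
) -> DifferentialResult:
    """Screen for mRNA-differential genes and test their RTE concordance.

    Genes with |log2 mRNA fold change| > ``lfc_cut`` (replicate-averaged
    RPKM, pseudocount added) and per-gene Welch t-test p < ``p_cut`` on the
    log2 replicate RPKMs are selected.  For each selected direction the
    fraction whose RTE fold change (in the same direction) exceeds 1 is
    reported, plus a Welch t-test of the selected genes' log2 RTE fold
    changes against those of all analyzed genes.
    """
    for cond in (cond_a, cond_b):
        if cond not in mrna_rpkm.condition_ids:
            raise ValueError(f"condition {cond!r} not in the design")
    if len(mrna_rpkm.replicate_ids(cond_a)) < 2 or len(mrna_rpkm.replicate_ids(cond_b)) < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    if genes is not None:
        mrna_rpkm = ExpressionTable(
            mrna_rpkm.values.loc[genes], mrna_rpkm.gene_lengths.loc[genes], "rpkm"
        )
        fp_rpkm = ExpressionTable(
            fp_rpkm.values.loc[genes], fp_rpkm.gene_lengths.loc[genes], "rpkm"
        )

    mr_avg = average_replicates(mrna_rpkm)
    rte = compute_rte(fp_rpkm, mrna_rpkm).values
    lfc_mrna = np.log2(
        (mr_avg[cond_a] + pseudocount) / (mr_avg[cond_b] + pseudocount)
    )
    lfc_rte = np.log2(
        (rte[cond_a] + pseudocount) / (rte[cond_b] + pseudocount)
    )
    rep_a = np.log2(mrna_rpkm.values[cond_a] + pseudocount)
    rep_b = np.log2(mrna_rpkm.values[cond_b] + pseudocount)
    tres = stats.ttest_ind(rep_a, rep_b, axis=1, equal_var=False)
    pvals = pd.Series(tres.pvalue, index=mr_avg.index)

    table = pd.DataFrame(
        {
            "log2_mrna_fc": lfc_mrna,
            "log2_rte_fc": lfc_rte,
            "mrna_ttest_p": pvals,
        }
    )
    sig = pvals < p_cut
    up = list(table.index[(lfc_mrna > lfc_cut) & sig])
    down = list(table.index[(lfc_mrna < -lfc_cut) & sig])

    def _concordance(selected: list[str], sign: int) -> tuple[float, float]:
        if not selected:
            return float("nan"), float("nan")
        sel = sign * lfc_rte.loc[selected].dropna()
        frac = float((sel > 0).mean())
        background = (sign * lfc_rte).dropna()
        p = float(stats.ttest_ind(sel, background, equal_var=False).pvalue)
        return frac, p

    frac_up, p_up = _concordance(up, +1)
    frac_down, p_down = _concordance(down, -1)
    return DifferentialResult(
        table=table,
        cond_a=cond_a,
        cond_b=cond_b,
        selected_up=up,
        selected_down=down,
        fraction_up_rte_concordant=frac_up,
        fraction_down_rte_concordant=frac_down,
        up_rte_ttest_p=p_up,
        down_rte_ttest_p=p_down,
    )


# ---------------------------------------------------------------------------
# variability indices

def variability(rte: pd.DataFrame | RTEMatrix, index: str = "variance") -> pd.DataFrame:
    """Cross-condition variability indices per gene with a median-split label.

    variance uses the n-1 denominator; Fano = variance/mean; CV = sd/mean
    (NaN where the mean is 0).  The binary ``high_variability`` label splits
    at the median of the chosen index (> median is high; exact-median genes
    fall in the low class).
    """
    values = rte.values if isinstance(rte, RTEMatrix) else rte
    if index not in ("variance", "fano", "cv"):
        raise ValueError(f"unknown variability index {index!r}")
    mean = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = (var / mean).where(mean > 0)
        cv = (np.sqrt(var) / mean).where(mean > 0)
    table = pd.DataFrame({"mean": mean, "variance": var, "fano": fano, "cv": cv})
    chosen = table[index]
    median = chosen.median()
    table["high_variability"] = (chosen > median).astype(int)
    table.attrs["index"] = index
    table.attrs["median"] = float(median)
    return table
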