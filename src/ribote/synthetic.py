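"""Synthetic inputs with the statistical structure the RTE analysis assumes.

Every generator is deterministic under a fixed seed and records a complete
truth table, so downstream stages (RPKM, RTE, correlation structure, codon
contrasts, the variability classifier, offset inference, trace fitting) can
be tested by parameter recovery without any external data.

The default condition design mirrors the study layout this package targets:
12 growth conditions (C-, N-, P-limited chemostats at 0.1 and 0.6 1/h, two
batch cultures, and N-/Leu-limited mutant chemostats), three biological
replicates each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .iofmt import AlignmentRecord, ExpressionTable, GeneModel, write_alignments

__all__ = [
    "Condition",
    "ConditionDesign",
    "GeneTruth",
    "simulate_genes",
    "simulate_cds",
    "simulate_counts",
    "simulate_footprint_reads",
    "simulate_polysome_trace",
    "simulate_lacz_series",
    "truth_table",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

# Class-linked codon preferences span many codons in real genomes, so the
# default tilt is dense: A/T-ending codons mark the high-variability class
# (led by AAA and GAT), G/C-ending codons the low-variability class (led by
# CGT and CTG).  None of the nine rare codons appears in either list, so
# rare-codon neutrality is preserved by construction.
DEFAULT_HIGH_VAR_CODONS = (
    "AAA", "GAT", "GAA", "ACT", "GCA", "AAT", "GGT", "CAA", "TCT", "GTA", "CAT", "TAT",
)
DEFAULT_LOW_VAR_CODONS = (
    "CGT", "CTG", "GCG", "CCG", "ACC", "GGC", "CAG", "TCG", "GTG", "AGC", "TGC", "CGC",
)


@dataclass(frozen=True)
class Condition:
    condition_id: str
    nutrient: str  # {C, N, P, other}
    growth_rate: float  # 1/h
    culture: str  # {chemostat, batch}


@dataclass
class ConditionDesign:
    conditions: list[Condition]
    n_replicates: int = 3

    def __post_init__(self) -> None:
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids must be unique")

    @property
    def condition_ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions]

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def columns(self) -> pd.MultiIndex:
        pairs = [
            (c.condition_id, str(r + 1))
            for c in self.conditions
            for r in range(self.n_replicates)
        ]
        return pd.MultiIndex.from_tuples(pairs, names=["condition", "replicate"])

    @classmethod
    def default(cls, n_replicates: int = 3) -> "ConditionDesign":
        """The 12-condition nutrient-limitation design (3 replicates)."""
        conds = [
            Condition("Clim_0.1", "C", 0.1, "chemostat"),
            Condition("Clim_0.6", "C", 0.6, "chemostat"),
            Condition("Nlim_0.1", "N", 0.1, "chemostat"),
            Condition("Nlim_0.6", "N", 0.6, "chemostat"),
            Condition("Plim_0.1", "P", 0.1, "chemostat"),
            Condition("Plim_0.6", "P", 0.6, "chemostat"),
            Condition("glucose_minimal", "other", 0.9, "batch"),
            Condition("rich_MOPS", "other", 1.8, "batch"),
            Condition("Nlim_rplA_0.1", "N", 0.1, "chemostat"),
            Condition("Nlim_rplA_0.6", "N", 0.6, "chemostat"),
            Condition("Leulim_leuB_0.1", "other", 0.1, "chemostat"),
            Condition("Leulim_leuB_0.6", "other", 0.6, "chemostat"),
        ]
        return cls(conds, n_replicates)


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene.

    Multipliers are per-condition factors applied to the baseline mRNA level
    and baseline RTE.  Concordant genes share the same log-multiplier for
    both; antagonistic genes carry opposite signs; stable genes have all
    multipliers equal to 1.
    """

    gene_id: str
    regulation_class: str  # {concordant, antagonistic, stable}
    baseline_mrna: float  # RPKM scale
    baseline_rte: float
    mrna_multipliers: np.ndarray  # per condition
    rte_multipliers: np.ndarray
    variability_class: str  # {high, low}
    codon_bias_profile: str  # {high_var, low_var}
    length_nt: int


def simulate_genes(
    n_genes: int = 2000,
    class_proportions: Mapping[str, float] | None = None,
    effect_size_log2: float = 2.0,
    design: ConditionDesign | None = None,
    seed: int = 0,
    baseline_mrna_log10_mean: float = 2.3,
    baseline_mrna_log10_sd: float = 0.5,
    min_codons: int = 100,
    max_codons: int = 400,
) -> list[GeneTruth]:
    """Draw a gene population with concordant/antagonistic/stable classes.

    Per-condition multipliers are lognormal(0, effect_size_log2 * ln 2):
    a shared standard-normal draw z per (gene, condition) gives the mRNA
    multiplier exp(sigma*z) and the RTE multiplier exp(+/-sigma*z) with the
    sign set by the class; stable genes have all multipliers fixed at 1.
    Genes with condition-varying RTE are labelled high-variability and get
    the high-variability codon bias profile.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10 (downstream statistics undefined)")
    if class_proportions is None:
        class_proportions = {"concordant": 0.25, "antagonistic": 0.25, "stable": 0.5}
    props = dict(class_proportions)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if effect_size_log2 <= 0:
        raise ValueError("effect_size_log2 must be > 0")
    design = design or ConditionDesign.default()
    n_cond = design.n_conditions
    sigma = effect_size_log2 * math.log(2)

    rng = np.random.default_rng(seed)
    classes = rng.choice(
        list(props.keys()), size=n_genes, p=list(props.values())
    )
    truths: list[GeneTruth] = []
    for i in range(n_genes):
        cls = str(classes[i])
        base_mrna = 10 ** rng.normal(baseline_mrna_log10_mean, baseline_mrna_log10_sd)
        base_rte = float(np.exp(rng.normal(0.0, 0.5)))
        if cls == "stable":
            m_mult = np.ones(n_cond)
            r_mult = np.ones(n_cond)
        else:
            z = rng.standard_normal(n_cond)
            m_mult = np.exp(sigma * z)
            r_mult = np.exp(sigma * z) if cls == "concordant" else np.exp(-sigma * z)
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        truths.append(
            GeneTruth(
                gene_id=f"g{i:05d}",
                regulation_class=cls,
                baseline_mrna=base_mrna,
                baseline_rte=base_rte,
                mrna_multipliers=m_mult,
                rte_multipliers=r_mult,
                variability_class="low" if cls == "stable" else "high",
                codon_bias_profile="low_var" if cls == "stable" else "high_var",
                length_nt=3 * n_codons,
            )
        )
    return truths


def truth_table(truth: Sequence[GeneTruth]) -> pd.DataFrame:
    """Flatten the truth list to a per-gene DataFrame (multipliers joined)."""
    rows = []
    for t in truth:
        rows.append(
            {
                "gene_id": t.gene_id,
                "regulation_class": t.regulation_class,
                "baseline_mrna": t.baseline_mrna,
                "baseline_rte": t.baseline_rte,
                "variability_class": t.variability_class,
                "codon_bias_profile": t.codon_bias_profile,
                "length_nt": t.length_nt,
                "mrna_multipliers": ",".join(f"{x:.6g}" for x in t.mrna_multipliers),
                "rte_multipliers": ",".join(f"{x:.6g}" for x in t.rte_multipliers),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _tilted_codon_probs(
    tilt_up: Iterable[str], tilt_down: Iterable[str], strength: float
) -> np.ndarray:
    """Exponentially tilt a uniform distribution over the 61 sense codons."""
    log_w = np.zeros(len(SENSE_CODONS))
    lam = 2.0 * strength
    for i, codon in enumerate(SENSE_CODONS):
        if codon in tilt_up:
            log_w[i] = lam
        elif codon in tilt_down:
            log_w[i] = -lam
    w = np.exp(log_w)
    return w / w.sum()


def simulate_cds(
    truth: Sequence[GeneTruth],
    high_var_codons: Sequence[str] = DEFAULT_HIGH_VAR_CODONS,
    low_var_codons: Sequence[str] = DEFAULT_LOW_VAR_CODONS,
    bias_strength: float = 0.5,
    seed: int = 0,
    utr_margin: int = 30,
) -> list[GeneModel]:
    """Emit CDS sequences whose codon usage tracks the variability class.

    High-variability genes draw body codons from a sense-codon background
    exponentially tilted toward ``high_var_codons`` and away from
    ``low_var_codons``; low-variability genes use the opposite tilt.  Every
    sequence starts with ATG, ends with a single stop codon, and has length
    divisible by 3.
    """
    if not 0 <= bias_strength <= 1:
        raise ValueError("bias_strength must be in [0, 1]")
    if set(high_var_codons) & set(low_var_codons):
        raise ValueError("high/low codon lists must be disjoint")
    for c in list(high_var_codons) + list(low_var_codons):
        if c not in SENSE_CODONS:
            raise ValueError(f"{c} is not a sense codon")
    rng = np.random.default_rng(seed)
    p_high = _tilted_codon_probs(high_var_codons, low_var_codons, bias_strength)
    p_low = _tilted_codon_probs(low_var_codons, high_var_codons, bias_strength)
    sense = np.array(SENSE_CODONS)
    models = []
    for t in truth:
        probs = p_high if t.codon_bias_profile == "high_var" else p_low
        n_body = t.length_nt // 3 - 2  # minus start and stop
        body = rng.choice(sense, size=n_body, p=probs)
        seq = "ATG" + "".join(body) + "TAA"
        models.append(
            GeneModel(
                t.gene_id,
                seq,
                start_codon_pos=utr_margin,
                transcript_length=utr_margin + len(seq) + utr_margin,
            )
        )
    return models


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    truth: Sequence[GeneTruth],
    design: ConditionDesign | None = None,
    sequencing_depth: float = 5e6,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Draw mRNA and footprint count tables from the gene truth.

    Expected counts per column are proportional to baseline x per-condition
    multiplier x gene length, normalized so each library sums to the given
    depth in expectation; footprint expectations carry the extra RTE factor.
    Replicates are independent negative-binomial draws.
    """
    if sequencing_depth < 0:
        raise ValueError("sequencing_depth must be >= 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    design = design or ConditionDesign.default()
    rng = np.random.default_rng(seed)

    genes = [t.gene_id for t in truth]
    lengths = np.array([t.length_nt for t in truth], dtype=float)
    base_m = np.array([t.baseline_mrna for t in truth])
    base_r = np.array([t.baseline_rte for t in truth])
    m_mult = np.stack([t.mrna_multipliers for t in truth])  # genes x cond
    r_mult = np.stack([t.rte_multipliers for t in truth])

    n_rep = design.n_replicates
    cols = design.columns()
    m_vals = np.zeros((len(genes), design.n_conditions * n_rep))
    f_vals = np.zeros_like(m_vals)
    for ci in range(design.n_conditions):
        w_m = base_m * m_mult[:, ci] * lengths
        w_f = base_m * m_mult[:, ci] * base_r * r_mult[:, ci] * lengths
        mu_m = sequencing_depth * w_m / w_m.sum() if sequencing_depth else np.zeros_like(w_m)
        mu_f = sequencing_depth * w_f / w_f.sum() if sequencing_depth else np.zeros_like(w_f)
        for ri in range(n_rep):
            m_vals[:, ci * n_rep + ri] = _nb_counts(rng, mu_m, dispersion)
            f_vals[:, ci * n_rep + ri] = _nb_counts(rng, mu_f, dispersion)

    lengths_s = pd.Series(lengths, index=genes)
    mrna = ExpressionTable(
        pd.DataFrame(m_vals, index=genes, columns=cols), lengths_s, "raw_counts"
    )
    fp = ExpressionTable(
        pd.DataFrame(f_vals, index=genes, columns=cols), lengths_s, "raw_counts"
    )
    return mrna, fp


def expected_rpkm(
    truth: Sequence[GeneTruth],
    design: ConditionDesign | None = None,
    sequencing_depth: float = 5e6,
    assay: str = "mrna",
) -> pd.DataFrame:
    """Noise-free RPKM implied by the truth (genes x conditions)."""
    design = design or ConditionDesign.default()
    genes = [t.gene_id for t in truth]
    lengths = np.array([t.length_nt for t in truth], dtype=float)
    base = np.array([t.baseline_mrna for t in truth])
    mult = np.stack([t.mrna_multipliers for t in truth]).copy()
    if assay == "footprint":
        base = base * np.array([t.baseline_rte for t in truth])
        mult *= np.stack([t.rte_multipliers for t in truth])
    elif assay != "mrna":
        raise ValueError("assay must be 'mrna' or 'footprint'")
    out = np.zeros_like(mult)
    for ci in range(design.n_conditions):
        w = base * mult[:, ci] * lengths
        mu = sequencing_depth * w / w.sum()
        # RPKM of the expected counts: mu * 1e9 / (length * depth)
        out[:, ci] = mu * 1e9 / (lengths * sequencing_depth)
    return pd.DataFrame(out, index=genes, columns=design.condition_ids)


def simulate_footprint_reads(
    gene_models: Sequence[GeneModel],
    true_a_offset: int = 11,
    reads_per_gene: int = 100,
    seed: int = 0,
    boundary_weight: float = 0.15,
    path: str | Path | None = None,
    min_len: int = 20,
    max_len: int = 45,
) -> list[AlignmentRecord]:
    """Place footprint reads with a known 3'-end offset from the A site.

    A-site codons are drawn uniformly along each CDS, except a fraction
    ``boundary_weight`` is concentrated at the start codon and the same at
    the stop codon (the elevated-density anchors offset inference exploits).
    Each read's 3' end sits ``true_a_offset`` nt downstream of the first
    nucleotide of its A-site codon.
    """
    if not gene_models:
        raise ValueError("gene_models must be non-empty")
    if not 0 < true_a_offset < min_len:
        raise ValueError("true_a_offset must lie in (0, min read length)")
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    for gm in gene_models:
        n_cod = gm.n_codons
        for _ in range(reads_per_gene):
            u = rng.random()
            if u < boundary_weight:
                codon = 0
            elif u < 2 * boundary_weight:
                codon = n_cod - 1  # the stop codon
            else:
                codon = int(rng.integers(0, n_cod))
            pos = gm.start_codon_pos + 3 * codon + true_a_offset
            if pos >= gm.transcript_length:
                pos = gm.transcript_length - 1
            length = int(rng.integers(min_len, max_len + 1))
            length = min(length, pos + 1)  # read must fit the transcript 5' end
            records.append(AlignmentRecord(gm.gene_id, int(pos), length))
    if path is not None:
        write_alignments(records, path)
    return records


def simulate_polysome_trace(
    peak_positions: Sequence[float],
    peak_areas: Sequence[float],
    peak_width: float | Sequence[float] = 0.15,
    background_amplitude: float = 0.0,
    background_decay: float = 3.0,
    noise_sd: float = 0.0,
    n_points: int = 2000,
    seed: int = 0,
    baseline: float = 0.0,
    x_max: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian ribosome peaks on an exponential nucleotide/tRNA background.

    trace(x) = sum_i area_i * N(x; pos_i, width_i) + A*exp(-k*x)
               + baseline + N(0, noise_sd)
    """
    widths = np.broadcast_to(np.asarray(peak_width, dtype=float), (len(peak_positions),))
    if (widths <= 0).any():
        raise ValueError("peak widths must be > 0")
    if len(peak_positions) != len(peak_areas):
        raise ValueError("positions and areas must have equal length")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, x_max, n_points)
    y = np.full_like(x, baseline)
    for pos, area, w in zip(peak_positions, peak_areas, widths):
        y += area * np.exp(-0.5 * ((x - pos) / w) ** 2) / (w * math.sqrt(2 * math.pi))
    y += background_amplitude * np.exp(-background_decay * x)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=x.shape)
    return x, y


def simulate_lacz_series(
    elongation_rate_aa_s: float = 20.0,
    lacz_length_aa: int = 1024,
    assay_lag_s: float = 10.0,
    sampling_interval_s: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float = 300.0,
    signal_rate: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated beta-galactosidase signal after induction.

    The first complete enzymes appear at T = length/rate + assay lag; the
    accumulated (integrated) signal then grows quadratically, so sqrt(signal)
    is linear in time beyond T with x-intercept T.
    """
    if elongation_rate_aa_s <= 0:
        raise ValueError("elongation rate must be > 0")
    if lacz_length_aa <= 0:
        raise ValueError("lacZ length must be > 0")
    rng = np.random.default_rng(seed)
    onset = lacz_length_aa / elongation_rate_aa_s + assay_lag_s
    t = np.arange(0.0, duration_s + 1e-9, sampling_interval_s)
    y = np.where(t > onset, signal_rate * (t - onset) ** 2, 0.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return t, y
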