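"""Codon-frequency vectors and codon-level comparative analyses.

A gene's codon profile is the 64-entry vector of codon proportions
(lexicographic order AAA..TTT, stop codons included).  Profiles can be
centered by subtracting the background frequencies of the analyzed gene
set; group contrasts compare mean centered profiles of gene sets (pathways,
top/bottom variability ranks) by Spearman correlation over the 64 codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iofmt import GeneModel

__all__ = [
    "CODON_ORDER",
    "RARE_CODONS",
    "CodonProfile",
    "AuxiliaryFeatures",
    "codon_frequencies",
    "background_frequencies",
    "center_profile",
    "set_profile",
    "profile_correlation",
    "group_contrast",
    "random_set_null",
    "auxiliary_features",
    "profile_frame",
]

log = logging.getLogger(__name__)

BASES = "ACGT"
CODON_ORDER = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
_CODON_INDEX = {c: i for i, c in enumerate(CODON_ORDER)}

# the nine rarest codons in E. coli; used for neutrality checks
RARE_CODONS = ("AGA", "AGG", "ATA", "CCC", "CGA", "CGG", "CTA", "GGA", "TTA")


@dataclass
class CodonProfile:
    """64-codon frequency vector for a gene or a gene set."""

    set_id: str
    frequencies: np.ndarray  # length 64, CODON_ORDER
    centered: bool = False
    n_genes: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (64,):
            raise ValueError("codon profile must have 64 entries")
        total = self.frequencies.sum()
        expected = 0.0 if self.centered else 1.0
        if abs(total - expected) > 1e-9:
            raise ValueError(
                f"{'centered' if self.centered else 'uncentered'} profile "
                f"sums to {total}, expected {expected}"
            )

    def __getitem__(self, codon: str) -> float:
        return float(self.frequencies[_CODON_INDEX[codon]])


@dataclass
class AuxiliaryFeatures:
    """Non-codon-vector sequence features used by the classifier."""

    gene_id: str
    third_base: dict[str, float]  # A/C/G/T frequencies at codon position 3
    length_nt: int
    pause_motifs: dict[str, float]


def _codons_of(gene_model: GeneModel) -> list[str]:
    seq = gene_model.cds_sequence
    if len(seq) % 3 != 0:
        raise ValueError(
            f"gene {gene_model.gene_id}: CDS length {len(seq)} not divisible by 3"
        )
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(
            f"gene {gene_model.gene_id}: ambiguous bases {sorted(bad)}"
        )
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _counts(gene_model: GeneModel) -> np.ndarray:
    counts = np.zeros(64)
    for codon in _codons_of(gene_model):
        counts[_CODON_INDEX[codon]] += 1
    return counts


def codon_frequencies(gene_model: GeneModel) -> CodonProfile:
    """Per-gene codon proportions over consecutive codons from position 0."""
    counts = _counts(gene_model)
    return CodonProfile(gene_model.gene_id, counts / counts.sum())


def background_frequencies(
    gene_models: Sequence[GeneModel],
    analyzed_set: Iterable[str] | None = None,
    weighting: str = "pooled",
) -> CodonProfile:
    """Background codon frequencies over the analyzed gene set.

    ``pooled`` (default) counts codons over the whole set, so long genes
    weigh more; ``equal`` averages per-gene frequency vectors instead.
    """
    if analyzed_set is not None:
        keep = set(analyzed_set)
        gene_models = [g for g in gene_models if g.gene_id in keep]
    if not gene_models:
        raise ValueError("empty analyzed set for background frequencies")
    if weighting == "pooled":
        counts = np.sum([_counts(g) for g in gene_models], axis=0)
        freqs = counts / counts.sum()
    elif weighting == "equal":
        freqs = np.mean(
            [codon_frequencies(g).frequencies for g in gene_models], axis=0
        )
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CodonProfile("background", freqs, n_genes=len(gene_models))


def center_profile(profile: CodonProfile, background: CodonProfile) -> CodonProfile:
    """Subtract background frequencies; the result sums to 0."""
    if profile.centered or background.centered:
        raise ValueError("center_profile expects uncentered inputs")
    return CodonProfile(
        profile.set_id,
        profile.frequencies - background.frequencies,
        centered=True,
        n_genes=profile.n_genes,
    )


def set_profile(
    gene_ids: Iterable[str],
    profiles: Mapping[str, CodonProfile],
    exclude: Iterable[str] = (),
    set_id: str = "set",
) -> CodonProfile:
    """Equal-gene-weight mean profile of a gene set, after exclusions.

    Used for pathway comparisons, where genes shared by both pathways are
    excluded before averaging.
    """
    excluded = set(exclude)
    members = [g for g in gene_ids if g not in excluded and g in profiles]
    if not members:
        raise ValueError(f"gene set {set_id!r} empty after exclusions")
    centered = profiles[members[0]].centered
    freqs = np.mean([profiles[g].frequencies for g in members], axis=0)
    return CodonProfile(set_id, freqs, centered=centered, n_genes=len(members))


def profile_correlation(profile_a: CodonProfile, profile_b: CodonProfile) -> float:
    """Spearman rho (average-rank ties) over the 64 codon entries."""
    rho, _ = stats.spearmanr(profile_a.frequencies, profile_b.frequencies)
    return float(rho)


def group_contrast(
    variability_table: pd.DataFrame,
    profiles: Mapping[str, CodonProfile],
    n_top: int = 200,
    ranking_key: str = "variance",
) -> dict:
    """Codon contrast between the top and bottom ``n_top`` genes of a ranking.

    Genes are ranked by ``ranking_key`` (a column of the variability table,
    e.g. RTE variance, or a mean-expression column); the mean centered
    profiles of the two extremes are compared by Spearman rho.  Rank ties
    are broken by stable gene-id order.
    """
    ranked = variability_table.sort_values(
        by=ranking_key, kind="mergesort"
    )  # stable: ties keep gene-id/input order
    genes = [g for g in ranked.index if g in profiles]
    if len(genes) < 2 * n_top:
        raise ValueError(f"need >= {2 * n_top} genes, have {len(genes)}")
    bottom_ids = genes[:n_top]
    top_ids = genes[-n_top:]
    top = set_profile(top_ids, profiles, set_id=f"top{n_top}")
    bottom = set_profile(bottom_ids, profiles, set_id=f"bottom{n_top}")
    return {
        "top_profile": top,
        "bottom_profile": bottom,
        "rho": profile_correlation(top, bottom),
        "top_ids": top_ids,
        "bottom_ids": bottom_ids,
    }


def random_set_null(
    profiles: Mapping[str, CodonProfile],
    set_size: int = 50,
    n_draws: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null rho distribution from pairs of disjoint random gene sets."""
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(profiles))
    if n_draws and len(ids) < 2 * set_size:
        raise ValueError("not enough genes for two disjoint sets")
    rhos = []
    for _ in range(n_draws):
        pick = rng.choice(ids, size=2 * set_size, replace=False)
        a = set_profile(pick[:set_size], profiles, set_id="a")
        b = set_profile(pick[set_size:], profiles, set_id="b")
        rhos.append(profile_correlation(a, b))
    return np.array(rhos)


def auxiliary_features(
    gene_model: GeneModel, motif_list: Sequence[str] = ()
) -> AuxiliaryFeatures:
    """Third-base composition, gene length, and pause-motif frequencies.

    A motif is a run of 2-3 adjacent codons (6 or 9 nt); its frequency is
    occurrences / (codon count - motif codon span + 1).
    """
    codons = _codons_of(gene_model)
    third = {b: 0.0 for b in BASES}
    for c in codons:
        third[c[2]] += 1
    n = len(codons)
    third = {b: v / n for b, v in third.items()}
    motifs: dict[str, float] = {}
    seq = gene_model.cds_sequence
    for motif in motif_list:
        if len(motif) % 3 != 0:
            raise ValueError(f"pause motif {motif!r} must span whole codons")
        span = len(motif) // 3
        windows = n - span + 1
        hits = sum(
            1 for i in range(windows) if seq[3 * i : 3 * i + len(motif)] == motif
        )
        motifs[motif] = hits / windows if windows > 0 else 0.0
    return AuxiliaryFeatures(gene_model.gene_id, third, gene_model.length_nt, motifs)


def profile_frame(profiles: Mapping[str, CodonProfile]) -> pd.DataFrame:
    """Stack per-gene profiles into a genes x 64 DataFrame."""
    ids = list(profiles)
    mat = np.stack([profiles[g].frequencies for g in ids])
    return pd.DataFrame(mat, index=ids, columns=list(CODON_ORDER))
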