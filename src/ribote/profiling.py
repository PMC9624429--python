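"""Read-level footprint processing.

Offset inference from 3'-aligned metagene histograms, A-site assignment,
gene-level counting, and averaged density profiles over the first/last
codons of each transcript.  Footprint reads outside 20-45 nt are discarded
before any positional analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iofmt import AlignmentRecord, ExpressionTable, GeneModel

__all__ = [
    "OffsetEstimate",
    "DensityProfile",
    "filter_reads",
    "infer_offsets",
    "assign_asite",
    "count_footprints",
    "metagene_profile",
]

log = logging.getLogger(__name__)


@dataclass
class OffsetEstimate:
    """3'-end offsets from the start/stop metagene peaks.

    ``offset_start`` / ``offset_stop`` are the raw argmax distances between
    read 3' ends and the first nucleotide of the start/stop codon.  The
    A-site offset defaults to the stop-codon argmax (optionally minus a
    one-nt boundary correction); the P site sits one codon upstream.
    """

    offset_start: int
    offset_stop: int
    a_site_offset: int
    tie_start: bool = False
    tie_stop: bool = False

    @property
    def p_site_offset(self) -> int:
        return self.a_site_offset + 3


@dataclass
class DensityProfile:
    """Per-gene A-site occupancy per codon."""

    per_gene: dict[str, np.ndarray]
    n_assigned: int = 0
    n_dropped: int = 0

    def gene_total(self, gene_id: str) -> float:
        return float(self.per_gene[gene_id].sum())


def filter_reads(
    records: Sequence[AlignmentRecord], min_len: int = 20, max_len: int = 45
) -> list[AlignmentRecord]:
    """Keep reads with min_len <= length <= max_len; log the removals."""
    kept = [r for r in records if min_len <= r.read_length <= max_len]
    removed = len(records) - len(kept)
    if removed:
        log.info("filter_reads: removed %d of %d reads by length", removed, len(records))
    return kept


def _metagene_argmax(
    records: Sequence[AlignmentRecord],
    anchors: Mapping[str, int],
    window: int,
) -> tuple[int, int, bool]:
    """Histogram of (3' end - anchor) over +/-window; smallest argmax wins."""
    offsets = np.arange(-window, window + 1)
    hist = np.zeros(offsets.size, dtype=int)
    for r in records:
        anchor = anchors.get(r.gene_id)
        if anchor is None:
            continue
        d = r.three_prime_pos - anchor
        if -window <= d <= window:
            hist[d + window] += 1
    n_in_window = int(hist.sum())
    peak = int(hist.max()) if n_in_window else 0
    winners = offsets[hist == peak] if n_in_window else np.array([0])
    tie = winners.size > 1
    if tie:
        log.warning("metagene argmax tie among offsets %s; smallest chosen", winners)
    return int(winners.min()), n_in_window, tie


def infer_offsets(
    records: Sequence[AlignmentRecord],
    gene_models: Sequence[GeneModel],
    window: int = 40,
    min_reads: int = 100,
    stop_peak_correction: int = 0,
) -> OffsetEstimate:
    """Infer the A-site offset from 3'-aligned start/stop metagene peaks.

    Both codons are high-density anchors, so the distance that maximizes the
    3'-end histogram around each is reported.  ``a_site_offset`` is the
    stop-codon argmax minus ``stop_peak_correction`` (0 by default; set 1 to
    reproduce the one-nt boundary convention under which a stop peak at
    12 nt maps to an 11 nt A-site offset).
    """
    starts = {g.gene_id: g.start_codon_pos for g in gene_models}
    stops = {g.gene_id: g.stop_codon_pos for g in gene_models}
    off_start, n_start, tie_start = _metagene_argmax(records, starts, window)
    off_stop, n_stop, tie_stop = _metagene_argmax(records, stops, window)
    if n_start + n_stop < min_reads:
        raise ValueError(
            f"only {n_start + n_stop} reads near start/stop codons "
            f"(need >= {min_reads}); supply more data"
        )
    return OffsetEstimate(
        offset_start=off_start,
        offset_stop=off_stop,
        a_site_offset=off_stop - stop_peak_correction,
        tie_start=tie_start,
        tie_stop=tie_stop,
    )


def assign_asite(
    records: Sequence[AlignmentRecord],
    gene_models: Sequence[GeneModel],
    offset: int = 11,
) -> DensityProfile:
    """Map each read to its A-site codon: nt = 3' end - offset.

    The codon index counts from the start codon; reads whose A site falls
    before codon 0 or past the stop codon are dropped (counted).
    """
    models = {g.gene_id: g for g in gene_models}
    per_gene = {g.gene_id: np.zeros(g.n_codons) for g in gene_models}
    assigned = dropped = 0
    for r in records:
        gm = models.get(r.gene_id)
        if gm is None:
            dropped += 1
            continue
        a_nt = r.three_prime_pos - offset
        codon = (a_nt - gm.start_codon_pos) // 3
        if 0 <= codon < gm.n_codons and a_nt >= 0:
            per_gene[gm.gene_id][codon] += 1
            assigned += 1
        else:
            dropped += 1
    return DensityProfile(per_gene, n_assigned=assigned, n_dropped=dropped)


def count_footprints(
    density: DensityProfile, gene_models: Sequence[GeneModel]
) -> ExpressionTable:
    """Sum assigned A-site reads per gene into a one-column count table."""
    genes = [g.gene_id for g in gene_models]
    counts = [density.per_gene[g].sum() for g in genes]
    cols = pd.MultiIndex.from_tuples([("all", "1")], names=["condition", "replicate"])
    values = pd.DataFrame({("all", "1"): counts}, index=genes)
    values.columns = cols
    lengths = pd.Series([g.length_nt for g in gene_models], index=genes, dtype=float)
    return ExpressionTable(values, lengths, "raw_counts")


def metagene_profile(
    density: DensityProfile,
    gene_models: Sequence[GeneModel],
    n_codons: int = 50,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average normalized A-site density over the first/last ``n_codons``.

    Each qualifying gene's codon densities are divided by that gene's mean
    codon density before averaging, so highly expressed genes do not
    dominate.  Genes shorter than 2*n_codons, or with zero total density,
    are excluded (count returned).
    """
    first, last, excluded = [], [], 0
    for gm in gene_models:
        vec = density.per_gene.get(gm.gene_id)
        if vec is None or gm.n_codons < 2 * n_codons or vec.sum() == 0:
            excluded += 1
            continue
        norm = vec / vec.mean()
        first.append(norm[:n_codons])
        last.append(norm[-n_codons:])
    if not first:
        raise ValueError("no qualifying genes for the metagene profile")
    if excluded:
        log.info("metagene_profile: excluded %d genes", excluded)
    return np.mean(first, axis=0), np.mean(last, axis=0), excluded
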