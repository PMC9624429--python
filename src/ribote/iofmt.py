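"""Readers and writers for the tabular and annotation formats the pipeline touches.

The shared in-memory containers live here: expression matrices (genes x
condition/replicate columns), coding-sequence gene models, pathway membership
maps, and transcript-coordinate footprint alignment records.  All coordinates
are 0-based, half-open; BED input is honored as such and the 3' end of an
interval on the coding strand is ``end - 1``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ExpressionTable",
    "GeneModel",
    "PathwayMap",
    "AlignmentRecord",
    "read_expression_table",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_pathway_map",
    "read_alignments",
    "write_alignments",
    "write_table",
]

_COLUMN_RE = re.compile(r"^(?P<condition>.+)_r(?P<replicate>\d+)$")


@dataclass
class ExpressionTable:
    """Genes x (condition, replicate) matrix of raw counts or RPKM.

    ``values`` is a DataFrame indexed by gene id with a two-level column
    index (condition, replicate).  ``gene_lengths`` is a Series of CDS
    lengths in nucleotides aligned to the same gene index.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series
    value_kind: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("raw_counts", "rpkm"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("values must carry (condition, replicate) columns")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][0]
            raise ValueError(f"missing entries in column {bad}")
        if (self.values.to_numpy() < 0).any():
            gi, ci = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValueError(
                f"negative value for gene {self.values.index[gi]!r} "
                f"in column {self.values.columns[ci]}"
            )
        self.gene_lengths = self.gene_lengths.reindex(self.values.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()][0]
            raise ValueError(f"no gene length for {missing!r}")
        if (self.gene_lengths < 3).any():
            raise ValueError("every gene length must be >= 3 nt")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        seen: list[str] = []
        for cond in self.values.columns.get_level_values(0):
            if cond not in seen:
                seen.append(cond)
        return seen

    def replicate_ids(self, condition: str) -> list[str]:
        return [r for c, r in self.values.columns if c == condition]

    def flat_frame(self) -> pd.DataFrame:
        """Flatten to single-level '<condition>_r<k>' columns plus length."""
        flat = self.values.copy()
        flat.columns = [f"{c}_r{r}" for c, r in self.values.columns]
        flat.insert(0, "length", self.gene_lengths)
        return flat


@dataclass
class GeneModel:
    """A coding sequence in transcript coordinates (coding strand).

    ``start_codon_pos``/``stop_codon_pos`` locate the first nucleotide of the
    start and stop codon on the transcript; ``transcript_length`` may exceed
    the CDS when UTR margins are present.
    """

    gene_id: str
    cds_sequence: str
    start_codon_pos: int = 0
    transcript_length: int | None = None

    def __post_init__(self) -> None:
        self.cds_sequence = self.cds_sequence.upper()
        if self.transcript_length is None:
            self.transcript_length = self.start_codon_pos + len(self.cds_sequence)
        if self.start_codon_pos + len(self.cds_sequence) > self.transcript_length:
            raise ValueError(f"CDS of {self.gene_id} exceeds transcript bounds")

    @property
    def length_nt(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    @property
    def stop_codon_pos(self) -> int:
        # first nucleotide of the final (stop) codon
        return self.start_codon_pos + self.length_nt - 3

    @property
    def ambiguous_bases(self) -> int:
        return sum(1 for b in self.cds_sequence if b not in "ACGT")


@dataclass
class PathwayMap:
    """pathway id -> set of member gene ids."""

    members: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, pathway_id: str) -> set[str]:
        return self.members[pathway_id]

    def __len__(self) -> int:
        return len(self.members)

    def unknown_genes(self, universe: Iterable[str]) -> dict[str, set[str]]:
        uni = set(universe)
        return {
            p: genes - uni for p, genes in self.members.items() if genes - uni
        }


@dataclass(frozen=True)
class AlignmentRecord:
    """A footprint read in transcript coordinates (0-based 3' end)."""

    gene_id: str
    three_prime_pos: int
    read_length: int

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.three_prime_pos < 0:
            raise ValueError("three_prime_pos must be >= 0")


def _parse_columns(
    columns: Sequence[str],
    column_map: Mapping[str, tuple[str, str]] | None,
) -> pd.MultiIndex:
    pairs = []
    for col in columns:
        if column_map is not None and col in column_map:
            pairs.append(tuple(column_map[col]))
            continue
        m = _COLUMN_RE.match(col)
        if m is None:
            raise ValueError(
                f"cannot parse column header {col!r}: expected "
                "'<condition>_r<replicate>' or an explicit column mapping"
            )
        pairs.append((m.group("condition"), m.group("replicate")))
    return pd.MultiIndex.from_tuples(pairs, names=["condition", "replicate"])


def read_expression_table(
    path: str | Path,
    format: str | None = None,
    value_kind: str = "rpkm",
    gene_lengths: pd.Series | str | Path | None = None,
    length_column: str = "length",
    column_map: Mapping[str, tuple[str, str]] | None = None,
    sheet_name: str | int = 0,
) -> ExpressionTable:
    """Read a genes x (condition, replicate) table from TSV/CSV/XLSX.

    The first column holds gene ids; value columns are named
    ``<condition>_r<k>`` unless ``column_map`` overrides.  Gene lengths come
    from a ``length`` column, a side Series, or a two-column side file.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt in ("tsv", "txt"):
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "csv":
        df = pd.read_csv(path, index_col=0)
    elif fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet_name, index_col=0)
    else:
        raise ValueError(f"unsupported expression-table format {fmt!r}")
    df.index = df.index.astype(str)

    if length_column in df.columns:
        lengths = df[length_column].astype(float)
        df = df.drop(columns=[length_column])
    elif isinstance(gene_lengths, (str, Path)):
        side = pd.read_csv(gene_lengths, sep="\t", index_col=0).iloc[:, 0]
        side.index = side.index.astype(str)
        lengths = side.astype(float)
    elif gene_lengths is not None:
        lengths = pd.Series(gene_lengths, dtype=float)
    elif value_kind == "raw_counts":
        raise ValueError(
            "raw_counts table requires a gene-length column or side file"
        )
    else:
        lengths = pd.Series(3.0, index=df.index)  # lengths unused for rpkm

    df.columns = _parse_columns(list(df.columns), column_map)
    return ExpressionTable(df.astype(float), lengths, value_kind)


def read_cds_fasta(path: str | Path, utr_margin: int = 0) -> list[GeneModel]:
    """Parse a per-gene CDS FASTA; ids are the first header token."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {path}")
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate FASTA ids: {', '.join(dupes)}")
    models = []
    for rec in records:
        seq = str(rec.seq).upper()
        n_ambig = sum(1 for b in seq if b not in "ACGT")
        if n_ambig:
            warnings.warn(f"{rec.id}: {n_ambig} non-ACGT characters")
        models.append(
            GeneModel(
                rec.id,
                seq,
                start_codon_pos=utr_margin,
                transcript_length=utr_margin + len(seq) + utr_margin,
            )
        )
    return models


def write_cds_fasta(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.gene_id}\n")
            for i in range(0, len(m.cds_sequence), 60):
                fh.write(m.cds_sequence[i : i + 60] + "\n")


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read a two-column TSV of pathway_id, gene_id rows."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty pathway file: {path}")
        return PathwayMap()
    if df.shape[1] < 2:
        raise ValueError("pathway file needs two columns: pathway_id, gene_id")
    pmap = PathwayMap()
    for pid, gid in zip(df.iloc[:, 0], df.iloc[:, 1]):
        pmap.members.setdefault(pid, set()).add(gid)
    return pmap


def read_alignments(
    path: str | Path,
    format: str = "tsv",
    transcript_lengths: Mapping[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Read transcript-coordinate footprint records from TSV or BED.

    TSV columns: gene_id, three_prime_pos, read_length.  BED6 (or BED3):
    chrom is the gene id, the interval is 0-based half-open on the coding
    strand, so the 3' end is ``end - 1`` and the read length the span.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if format == "tsv":
                gene, pos, length = parts[0], int(parts[1]), int(parts[2])
            elif format == "bed":
                gene, start, end = parts[0], int(parts[1]), int(parts[2])
                if end <= start:
                    raise ValueError(f"record {idx}: BED end <= start")
                pos, length = end - 1, end - start
            else:
                raise ValueError(f"unsupported alignment format {format!r}")
            if transcript_lengths is not None:
                tlen = transcript_lengths.get(gene)
                if tlen is not None and not 0 <= pos < tlen:
                    raise ValueError(
                        f"record {idx}: 3' position {pos} outside "
                        f"transcript {gene} (length {tlen})"
                    )
            records.append(AlignmentRecord(gene, pos, length))
    return records


def write_alignments(
    records: Iterable[AlignmentRecord], path: str | Path, format: str = "tsv"
) -> None:
    with open(path, "w") as fh:
        for r in records:
            if format == "tsv":
                fh.write(f"{r.gene_id}\t{r.three_prime_pos}\t{r.read_length}\n")
            elif format == "bed":
                start = r.three_prime_pos + 1 - r.read_length
                fh.write(f"{r.gene_id}\t{start}\t{r.three_prime_pos + 1}\n")
            else:
                raise ValueError(f"unsupported alignment format {format!r}")


def write_table(obj, path: str | Path, format: str = "tsv") -> None:
    """Write a tabular result with deterministic column order.

    Accepts an ExpressionTable, DataFrame, or Series; floats are serialized
    at 10 significant digits so a read/write round trip is stable to 1e-9
    relative error.
    """
    if isinstance(obj, ExpressionTable):
        df = obj.flat_frame()
    elif isinstance(obj, pd.Series):
        df = obj.to_frame()
    else:
        df = pd.DataFrame(obj)
    sep = {"tsv": "\t", "csv": ","}.get(format)
    if sep is None:
        if format == "xlsx":
            df.to_excel(path)
            return
        raise ValueError(f"unsupported table format {format!r}")
    df.to_csv(path, sep=sep, float_format="%.10g")
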