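"""Sequence and gene-table I/O plus strand-aware promoter extraction.

Coordinates are 0-based, half-open internally. Gene tables may declare 1-based
TSS coordinates via ``coord_base=1``; they are converted on read. Promoters are
the ``upstream`` bases 5' of the TSS on the gene's own strand, so minus-strand
promoters are reverse-complemented and every extracted sequence reads 5'->3'
toward the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored by its transcription start site.

    ``tss`` is a 0-based position on the forward strand of ``chrom``;
    ``strand`` is '+' or '-'.
    """

    name: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.tss < 0:
            raise ValueError(f"gene {self.name!r}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PromoterSeq:
    """An extracted promoter, oriented 5'->3' toward the gene's TSS.

    ``length`` equals the requested upstream span unless the window was
    clipped at a chromosome boundary.
    """

    gene: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"promoter of {self.gene!r} contains invalid symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping.

    Ids are the first whitespace-delimited token of each header. A sequence
    line appearing before any header is a parse error (Biopython would
    silently skip it).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(f"{path}: line {lineno}: sequence data before any FASTA header")
            break
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    """Write an id -> sequence mapping as wrapped FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_gene_table(path: str | Path, coord_base: int = 0) -> list[GeneRecord]:
    """Read a 4-column TSV (name, chrom, tss, strand; header required).

    ``coord_base=1`` converts 1-based TSS coordinates to the internal 0-based
    convention. Duplicate gene names and unknown strand symbols are rejected
    with the offending row identified.
    """
    if coord_base not in (0, 1):
        raise ValueError(f"coord_base must be 0 or 1, got {coord_base}")
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str, "strand": str})
    required = ["name", "chrom", "tss", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dupes = df["name"][df["name"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate gene names: {dupes}")
    genes: list[GeneRecord] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is line 1
        if row["strand"] not in ("+", "-"):
            raise ValueError(f"{path}: row {rowno}: unknown strand symbol {row['strand']!r}")
        tss = int(row["tss"]) - coord_base
        if tss < 0:
            raise ValueError(f"{path}: row {rowno}: negative tss for gene {row['name']!r}")
        genes.append(GeneRecord(name=row["name"], chrom=row["chrom"], tss=tss, strand=row["strand"]))
    return genes


def extract_promoter(genome: Mapping[str, str], gene: GeneRecord, upstream: int = 1000) -> PromoterSeq:
    """Extract the ``upstream`` bases 5' of the TSS on the gene's strand.

    For '+' genes this is the forward-strand interval [tss - upstream, tss);
    for '-' genes the reverse complement of [tss + 1, tss + 1 + upstream).
    Windows overhanging a chromosome boundary are clipped, so the returned
    promoter may be shorter than requested.
    """
    if upstream <= 0:
        raise ValueError(f"upstream must be positive, got {upstream}")
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not found for gene {gene.name!r}")
    chrom_seq = genome[gene.chrom]
    if gene.tss >= len(chrom_seq):
        raise ValueError(
            f"gene {gene.name!r}: tss {gene.tss} beyond end of {gene.chrom!r} (length {len(chrom_seq)})"
        )
    if gene.strand == "+":
        start = max(0, gene.tss - upstream)
        seq = chrom_seq[start:gene.tss]
    else:
        start = gene.tss + 1
        seq = reverse_complement(chrom_seq[start:start + upstream])
    if len(seq) < upstream:
        log.info("promoter of %s clipped at chromosome boundary: %d of %d bp", gene.name, len(seq), upstream)
    return PromoterSeq(gene=gene.name, seq=seq.upper())


def extract_promoters(
    genome: Mapping[str, str], genes: list[GeneRecord], upstream: int = 1000
) -> list[PromoterSeq]:
    """Vector convenience over :func:`extract_promoter`, order preserved."""
    return [extract_promoter(genome, g, upstream) for g in genes]
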