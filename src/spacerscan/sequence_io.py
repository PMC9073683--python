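"""FASTA/GFF3 input and strand-aware promoter extraction.

Promoters are the ``upstream_len`` (default 1000) bases immediately 5' of a
gene's annotated start. For minus-strand genes the extracted window is
reverse-complemented by default so every promoter reads 5'->3' relative to
its gene — the only convention under which the orientation of an asymmetric
motif pair (e.g. AAAG(N)ACGT vs ACGT(N)AAAG) is biologically meaningful.

Coordinates are 1-based inclusive in :class:`GeneAnnotation` (the GFF
convention, kept as-read); slicing is converted to 0-based half-open
internally at the point of use.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, FormatError, ReferenceLookupError

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _normalize_residues(raw: str) -> str:
    """Uppercase, map RNA U->T, and validate the alphabet."""
    residues = raw.upper().replace("U", "T")
    bad = set(residues) - VALID_BASES
    if bad:
        raise AlphabetError(f"invalid residues {sorted(bad)}; expected A/C/G/T/N")
    return residues


@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome/contig: identifier plus uppercase A/C/G/T/N residues."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"sequence {self.seq_id!r} is empty")
        object.__setattr__(self, "residues", _normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene feature with 1-based inclusive coordinates and strand."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: require 1 <= start <= end, "
                f"got start={self.start} end={self.end}"
            )


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    seq_id: str
    start: int  # 1-based inclusive, on the reference
    end: int  # 1-based inclusive
    strand: str
    residues: str
    truncated: bool  # shorter than requested (gene at contig edge)


@dataclass
class PromoterSet:
    """Extracted promoters plus the requested upstream length."""

    records: list[PromoterRecord] = field(default_factory=list)
    upstream_len: int = 1000

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        """Residue strings of all non-empty promoters, gene order preserved."""
        return [r.residues for r in self.records if r.residues]

    def total_bp(self) -> int:
        return sum(len(r.residues) for r in self.records)


def reverse_complement(residues: str) -> str:
    """Reverse complement over {A,C,G,T,N}. An involution; raises on other chars."""
    bad = set(residues) - VALID_BASES
    if bad:
        raise AlphabetError(f"cannot complement {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Residues are uppercased and validated. An empty file or sequence data
    before the first header is a :class:`FormatError`.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: sequence data before any FASTA header")
    records = [
        GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    sequences: list[GenomeSequence], path: str | os.PathLike, width: int = 80
) -> None:
    recs = [
        SeqRecord(Seq(g.residues), id=g.seq_id, description="") for g in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_gff3(
    genes: list[GeneAnnotation],
    path: str | os.PathLike,
    genomes: list[GenomeSequence] | None = None,
) -> None:
    """Write gene features as GFF3 (9 columns, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes or []:
            fh.write(f"##sequence-region {g.seq_id} 1 {len(g)}\n")
        for gene in genes:
            fh.write(
                f"{gene.seq_id}\tspacerscan\tgene\t{gene.start}\t{gene.end}\t."
                f"\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )


def read_gff_genes(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Extract feature-type ``gene`` rows from a GFF3 file.

    Non-gene rows are ignored. Strand symbols other than +/- and inverted
    coordinates raise :class:`FormatError`.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.start is None or feat.end is None or feat.start > feat.end:
            raise FormatError(f"{path}: gene {feat.id}: start > end")
        genes.append(
            GeneAnnotation(
                gene_id=feat.id,
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def extract_promoters(
    genomes: list[GenomeSequence],
    genes: list[GeneAnnotation],
    upstream_len: int = 1000,
    orient_to_gene: bool = True,
) -> PromoterSet:
    """Extract the ``upstream_len`` bases upstream of each gene.

    Plus strand: reference positions [start-upstream_len, start-1], truncated
    at position 1. Minus strand: positions [end+1, end+upstream_len],
    truncated at the chromosome end, reverse-complemented when
    ``orient_to_gene`` (the default) so the promoter reads 5'->3' relative
    to the gene. With ``orient_to_gene=False`` the raw plus-strand window is
    kept (sensitivity-analysis mode).

    Zero-length promoters (gene starting at position 1) are recorded with
    empty residues and ``truncated=True``.
    """
    by_id = {g.seq_id: g for g in genomes}
    records = []
    for gene in genes:
        if gene.seq_id not in by_id:
            raise ReferenceLookupError(
                f"gene {gene.gene_id!r}: unknown sequence {gene.seq_id!r}"
            )
        chrom = by_id[gene.seq_id].residues
        if gene.end > len(chrom):
            raise FormatError(
                f"gene {gene.gene_id!r} extends past end of {gene.seq_id!r}"
            )
        if gene.strand == "+":
            lo = max(1, gene.start - upstream_len)  # 1-based
            hi = gene.start - 1
            residues = chrom[lo - 1 : hi] if hi >= lo else ""
        else:
            lo = gene.end + 1
            hi = min(len(chrom), gene.end + upstream_len)
            residues = chrom[lo - 1 : hi] if hi >= lo else ""
            if orient_to_gene and residues:
                residues = reverse_complement(residues)
        records.append(
            PromoterRecord(
                gene_id=gene.gene_id,
                seq_id=gene.seq_id,
                start=lo if residues else gene.start,
                end=hi if residues else gene.start,
                strand=gene.strand,
                residues=residues,
                truncated=len(residues) < upstream_len,
            )
        )
    return PromoterSet(records=records, upstream_len=upstream_len)


def write_promoter_fasta(promoters: PromoterSet, path: str | os.PathLike) -> None:
    """Write promoters as FASTA with headers ``gene_id|seq_id|start-end|strand``."""
    with open(path, "w") as fh:
        for rec in promoters:
            if not rec.residues:
                continue
            fh.write(f">{rec.gene_id}|{rec.seq_id}|{rec.start}-{rec.end}|{rec.strand}\n")
            for i in range(0, len(rec.residues), 80):
                fh.write(rec.residues[i : i + 80] + "\n")


def read_promoter_fasta(path: str | os.PathLike) -> PromoterSet:
    """Re-read a promoter FASTA written by :func:`write_promoter_fasta`."""
    records = []
    max_len = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise FormatError(f"{path}: bad promoter header {rec.id!r}")
        gene_id, seq_id, span, strand = parts
        start_s, _, end_s = span.partition("-")
        residues = _normalize_residues(str(rec.seq))
        max_len = max(max_len, len(residues))
        records.append(
            PromoterRecord(
                gene_id=gene_id,
                seq_id=seq_id,
                start=int(start_s),
                end=int(end_s),
                strand=strand,
                residues=residues,
                truncated=False,
            )
        )
    if not records:
        raise FormatError(f"{path}: no promoter records")
    pset = PromoterSet(records=records, upstream_len=max_len)
    # re-derive the truncation flag against the inferred upstream length
    pset.records = [
        PromoterRecord(
            r.gene_id, r.seq_id, r.start, r.end, r.strand, r.residues,
            truncated=len(r.residues) < max_len,
        )
        for r in records
    ]
    return pset
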