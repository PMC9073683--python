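"""Exhaustive motif-pair scanning with variable spacers.

A :class:`MotifPairQuery` names an ordered motif pair, e.g. AAAG followed by
ACGT, and the allowed spacer range N (default 0-30 bp, the distance window
within which cooperative transcription-factor binding is typically
reported). Scanning enumerates *every* ordered co-occurrence
``left + spacer + right`` whose spacer length falls in the range:
overlapping motif occurrences all count, and one motif occurrence may
participate in several hits. Positions containing the ambiguity code N
never match.

Scanning is single-strand: promoters are expected to already be oriented
5'->3' relative to their gene (see :mod:`spacerscan.sequence_io`). A
both-strands mode exists for whole-genome sensitivity checks.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .errors import AlphabetError, FormatError
from .sequence_io import GenomeSequence, PromoterSet, reverse_complement

MOTIF_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MotifPairQuery:
    """An ordered motif pair plus an inclusive spacer-length range in bp."""

    left_motif: str
    right_motif: str
    min_spacer: int = 0
    max_spacer: int = 30
    label: str = ""

    def __post_init__(self) -> None:
        for motif in (self.left_motif, self.right_motif):
            if not motif:
                raise ValueError("motifs must be non-empty")
            if set(motif) - MOTIF_BASES:
                raise AlphabetError(f"motif {motif!r} not over A/C/G/T")
        if not (0 <= self.min_spacer <= self.max_spacer):
            raise ValueError(
                f"require 0 <= min_spacer <= max_spacer, got "
                f"[{self.min_spacer}, {self.max_spacer}]"
            )
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.left_motif}(N){self.right_motif}"
            )

    @property
    def spacer_range(self) -> range:
        return range(self.min_spacer, self.max_spacer + 1)

    def reversed_orientation(self) -> "MotifPairQuery":
        """The same pair scanned right-motif-first."""
        return MotifPairQuery(
            self.right_motif, self.left_motif, self.min_spacer, self.max_spacer
        )


@dataclass(frozen=True)
class PairHit:
    """One co-occurrence: left motif start (0-based), spacer length/sequence."""

    seq_id: str
    left_start: int
    spacer_len: int
    spacer_seq: str
    query_label: str
    strand: str = "+"


@dataclass
class SpacerFrequencyProfile:
    """Per-spacer-length pair counts over a set of scanned sequences."""

    query_label: str
    counts: dict[int, int]
    total_bp: int
    n_sequences: int

    def total_hits(self) -> int:
        return sum(self.counts.values())


def find_motif(residues: str, motif: str) -> list[int]:
    """All 0-based start positions of ``motif`` in ``residues``, overlaps included."""
    if not motif:
        raise ValueError("empty motif")
    positions = []
    start = residues.find(motif)
    while start != -1:
        positions.append(start)
        start = residues.find(motif, start + 1)
    return positions


def scan_pairs(
    residues: str,
    query: MotifPairQuery,
    seq_id: str = "seq",
    exclusive: bool = False,
) -> list[PairHit]:
    """Enumerate all pair hits of ``query`` in a single sequence.

    A hit is an ordered pair of occurrences (left at l, right at r) with
    spacer ``r - (l + |left|)`` inside the query range. Hits are returned
    sorted by (left_start, spacer_len). With ``exclusive=True`` hits whose
    spacer contains a further occurrence of either motif are suppressed
    (stricter sensitivity-analysis mode; off by default since exhaustive
    counting is the reproducible convention).
    """
    left_positions = find_motif(residues, query.left_motif)
    if not left_positions:
        return []
    right_positions = find_motif(residues, query.right_motif)
    if not right_positions:
        return []
    llen = len(query.left_motif)
    hits = []
    for lpos in left_positions:
        spacer_start = lpos + llen
        lo = bisect_left(right_positions, spacer_start + query.min_spacer)
        hi = bisect_right(right_positions, spacer_start + query.max_spacer)
        for rpos in right_positions[lo:hi]:
            spacer = residues[spacer_start:rpos]
            if exclusive and (
                query.left_motif in spacer or query.right_motif in spacer
            ):
                continue
            hits.append(
                PairHit(
                    seq_id=seq_id,
                    left_start=lpos,
                    spacer_len=rpos - spacer_start,
                    spacer_seq=spacer,
                    query_label=query.label,
                )
            )
    return hits


def _as_id_residue_pairs(sequences) -> list[tuple[str, str]]:
    """Accept raw strings, GenomeSequence objects, or a PromoterSet."""
    if isinstance(sequences, PromoterSet):
        return [(r.gene_id, r.residues) for r in sequences if r.residues]
    pairs = []
    for i, item in enumerate(sequences):
        if isinstance(item, GenomeSequence):
            pairs.append((item.seq_id, item.residues))
        elif isinstance(item, str):
            pairs.append((f"seq{i}", item))
        else:
            pairs.append((item[0], item[1]))
    return pairs


def profile(
    sequences,
    query: MotifPairQuery,
    both_strands: bool = False,
    exclusive: bool = False,
) -> SpacerFrequencyProfile:
    """Per-spacer hit counts across a sequence set.

    ``sequences`` may be raw strings, :class:`GenomeSequence` records,
    (id, residues) tuples, or a :class:`PromoterSet`. Hits never span two
    sequences. ``total_bp`` is the summed length of all scanned sequences
    (counted once even in both-strands mode, so the per-bp frequency stays
    comparable across modes).
    """
    pairs = _as_id_residue_pairs(sequences)
    if not pairs:
        raise ValueError("empty sequence set")
    counts = {n: 0 for n in query.spacer_range}
    total_bp = 0
    for seq_id, residues in pairs:
        total_bp += len(residues)
        for hit in scan_pairs(residues, query, seq_id=seq_id, exclusive=exclusive):
            counts[hit.spacer_len] += 1
        if both_strands:
            rc = reverse_complement(residues)
            for hit in scan_pairs(rc, query, seq_id=seq_id, exclusive=exclusive):
                counts[hit.spacer_len] += 1
    return SpacerFrequencyProfile(
        query_label=query.label,
        counts=counts,
        total_bp=total_bp,
        n_sequences=len(pairs),
    )


def scan_all(
    sequences, query: MotifPairQuery, exclusive: bool = False
) -> list[PairHit]:
    """All hits over a sequence set (same input flexibility as :func:`profile`)."""
    hits = []
    for seq_id, residues in _as_id_residue_pairs(sequences):
        hits.extend(scan_pairs(residues, query, seq_id=seq_id, exclusive=exclusive))
    return hits


def collect_spacers(hits: list[PairHit], spacer_len: int) -> list[str]:
    """Spacer sequences of all hits with the given length, scan order preserved."""
    return [h.spacer_seq for h in hits if h.spacer_len == spacer_len]


def write_hits_tsv(hits: list[PairHit], query: MotifPairQuery, path) -> None:
    """BED6-like TSV: seq_id, left start, right end (0-based half-open), label,
    spacer_len, strand."""
    pair_len = len(query.left_motif) + len(query.right_motif)
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tquery_label\tspacer_len\tstrand\n")
        for h in hits:
            end = h.left_start + pair_len + h.spacer_len
            fh.write(
                f"{h.seq_id}\t{h.left_start}\t{end}\t{h.query_label}\t"
                f"{h.spacer_len}\t{h.strand}\n"
            )


def write_profile_tsv(prof: SpacerFrequencyProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("spacer_len\tcount\tnormalized_count\n")
        for n in sorted(prof.counts):
            norm = prof.counts[n] / prof.total_bp if prof.total_bp else 0.0
            fh.write(f"{n}\t{prof.counts[n]}\t{norm:.6g}\n")


def read_profile_tsv(path) -> SpacerFrequencyProfile:
    counts = {}
    total_bp = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["spacer_len", "count"]:
            raise FormatError(f"{path}: not a profile TSV")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            n, count = int(parts[0]), int(parts[1])
            counts[n] = count
            if len(parts) > 2 and count and float(parts[2]) > 0:
                total_bp = round(count / float(parts[2]))
    return SpacerFrequencyProfile(
        query_label="", counts=counts, total_bp=total_bp or 0, n_sequences=0
    )
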