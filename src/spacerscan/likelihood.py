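"""Likelihood-of-occurrence statistic linking motif-bearing genes to
condition-regulated gene sets.

For a condition gene set A (genes up- or down-regulated under a condition)
and the motif-bearing set B (genes whose promoter carries at least one
left(N)right pair occurrence), the statistic is

    L = X / Y,   X = |A ∩ B| / |B|,   Y = P(A) = |A| / universe

i.e. the condition rate among motif-bearing genes relative to the
background condition rate. L = 1 is chance; conditions with L strictly
greater than 1.25 are flagged as associated. L is computed per spacer
length (B restricted to genes with a pair at that N) and overall
(B = union over the spacer range).
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass

from .errors import DegenerateInputError, FormatError
from .scan import MotifPairQuery, scan_pairs
from .sequence_io import PromoterSet

DEFAULT_THRESHOLD = 1.25

DIRECTIONS = {"up", "down", "up-down"}


@dataclass(frozen=True)
class GeneSet:
    """Genes regulated (up/down) under one condition."""

    condition: str
    direction: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {sorted(DIRECTIONS)}, got {self.direction!r}"
            )


@dataclass
class MotifGeneIndex:
    """Per-gene spacer-length hit counts for one orientation.

    ``counts[gene][N]`` is the number of pair hits at spacer N in that
    gene's promoter; genes with no hits are absent from ``counts`` but
    present in ``universe``.
    """

    orientation: str
    counts: dict[str, dict[int, int]]
    universe: frozenset[str]
    spacer_range: range

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def genes_at(self, spacer_len: int) -> set[str]:
        return {g for g, c in self.counts.items() if spacer_len in c}

    def genes_any(self, spacer_range=None) -> set[str]:
        rng = set(spacer_range if spacer_range is not None else self.spacer_range)
        return {g for g, c in self.counts.items() if rng & set(c)}


@dataclass
class LikelihoodResult:
    condition: str
    direction: str
    orientation: str
    spacer: int | str  # spacer length or "overall"
    n_A: int
    n_B: int
    n_AB: int
    universe: int
    X: float
    Y: float
    L: float
    flagged: bool


def build_motif_gene_index(
    promoters: PromoterSet, query: MotifPairQuery, min_hits: int = 1
) -> MotifGeneIndex:
    """Scan each promoter and index genes by the spacer lengths they carry.

    ``min_hits`` sets how many pair occurrences at a spacer length a
    promoter needs before the gene is indexed there (default 1; a single
    left(N)right co-occurrence already involves multiple elements).
    """
    if not len(promoters):
        raise ValueError("empty promoter set")
    counts: dict[str, dict[int, int]] = {}
    for rec in promoters:
        if not rec.residues:
            continue
        per_n: dict[int, int] = defaultdict(int)
        for hit in scan_pairs(rec.residues, query, seq_id=rec.gene_id):
            per_n[hit.spacer_len] += 1
        kept = {n: c for n, c in per_n.items() if c >= min_hits}
        if kept:
            counts[rec.gene_id] = kept
    return MotifGeneIndex(
        orientation=query.label,
        counts=counts,
        universe=frozenset(r.gene_id for r in promoters),
        spacer_range=query.spacer_range,
    )


def likelihood(
    gene_set: GeneSet,
    motif_genes: set[str],
    universe: frozenset[str] | set[str],
    spacer: int | str = "overall",
    orientation: str = "",
    threshold: float = DEFAULT_THRESHOLD,
) -> LikelihoodResult:
    """L = (|A∩B|/|B|) / (|A|/universe) for one condition/motif-set pair."""
    A = set(gene_set.gene_ids)
    B = set(motif_genes)
    if not B:
        raise DegenerateInputError("motif-bearing gene set B is empty")
    if not A:
        raise DegenerateInputError("condition gene set A is empty")
    if not A <= set(universe) or not B <= set(universe):
        raise ValueError("A and B must be subsets of the gene universe")
    X = len(A & B) / len(B)
    Y = len(A) / len(universe)
    L = X / Y
    return LikelihoodResult(
        condition=gene_set.condition,
        direction=gene_set.direction,
        orientation=orientation,
        spacer=spacer,
        n_A=len(A),
        n_B=len(B),
        n_AB=len(A & B),
        universe=len(universe),
        X=X,
        Y=Y,
        L=L,
        flagged=L > threshold,
    )


def overall_likelihood(
    index: MotifGeneIndex,
    gene_set: GeneSet,
    spacer_range=None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[LikelihoodResult, dict[int, LikelihoodResult | None]]:
    """Overall L (B = union of per-spacer gene sets) plus per-spacer results.

    Spacer lengths with no motif-bearing genes yield ``None`` in the
    per-spacer map rather than a 0/0 statistic.
    """
    rng = list(spacer_range if spacer_range is not None else index.spacer_range)
    union = index.genes_any(rng)
    if not union:
        raise DegenerateInputError("no motif-bearing genes in the spacer range")
    overall = likelihood(
        gene_set, union, index.universe, "overall", index.orientation, threshold
    )
    per_spacer: dict[int, LikelihoodResult | None] = {}
    for n in rng:
        genes_n = index.genes_at(n)
        per_spacer[n] = (
            likelihood(gene_set, genes_n, index.universe, n, index.orientation, threshold)
            if genes_n
            else None
        )
    return overall, per_spacer


def mean_per_spacer_likelihood(
    per_spacer: dict[int, LikelihoodResult | None]
) -> float:
    """Average of defined per-spacer L values (alternative overall summary)."""
    defined = [r.L for r in per_spacer.values() if r is not None]
    if not defined:
        raise DegenerateInputError("no spacer length has motif-bearing genes")
    return sum(defined) / len(defined)


def flag_conditions(
    results: list[LikelihoodResult], threshold: float = DEFAULT_THRESHOLD
) -> list[LikelihoodResult]:
    """Results with L strictly above the threshold, sorted by L descending."""
    return sorted(
        (r for r in results if r.L > threshold), key=lambda r: -r.L
    )


def read_gene_sets(path: str | os.PathLike) -> list[GeneSet]:
    """Read condition gene sets from a two-column TSV.

    Column 1 is ``condition_direction`` (direction suffix one of up, down,
    up-down after the final underscore), column 2 a gene id. Lines starting
    with '#' and a ``condition_direction<TAB>gene_id`` header are skipped.
    """
    groups: dict[tuple[str, str], set[str]] = defaultdict(set)
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{line_no}: expected 2 tab-separated columns")
            label, gene_id = parts
            if line_no == 1 and label == "condition_direction":
                continue
            condition, _, direction = label.rpartition("_")
            if not condition or direction not in DIRECTIONS:
                raise FormatError(
                    f"{path}:{line_no}: label {label!r} must end in _up, _down or _up-down"
                )
            groups[(condition, direction)].add(gene_id)
    return [
        GeneSet(condition=c, direction=d, gene_ids=frozenset(genes))
        for (c, d), genes in sorted(groups.items())
    ]


def write_likelihood_tsv(results: list[LikelihoodResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "condition\tdirection\torientation\tspacer\tn_A\tn_B\tn_AB\t"
            "universe\tX\tY\tL\tflagged\n"
        )
        for r in results:
            fh.write(
                f"{r.condition}\t{r.direction}\t{r.orientation}\t{r.spacer}\t"
                f"{r.n_A}\t{r.n_B}\t{r.n_AB}\t{r.universe}\t"
                f"{r.X:.6g}\t{r.Y:.6g}\t{r.L:.6g}\t{int(r.flagged)}\n"
            )
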