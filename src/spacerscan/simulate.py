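"""Synthetic genomes, planted motif pairs, and condition studies with known
statistical structure.

The background model is i.i.d. nucleotides at a configurable G/C content,
36% by default — the composition of the A. thaliana genome whose promoter
architecture this pipeline analyses. Gene models are laid out with a full
promoter-length margin on both sides so every synthetic promoter is
full-length. Planting substitutes ``left + spacer + right`` over the
background *in place* (never inserting), so coordinates and coverage stay
stable; background-generated accidental pairs are expected and permitted,
which is why truth tables guarantee only that planted sites are a subset of
what the scanner reports.

Three study generators emulate the analyses the pipeline supports:

* :func:`generate_enrichment_study` plants pairs at a single spacer length
  so that the promoter per-bp pair density is a chosen factor above the
  genome-wide density.
* :func:`generate_condition_study` builds promoters, determines the
  realized motif-bearing gene set B by scanning its own output, then
  samples a condition gene set A with P(A | B) = lift * P(A).
* :func:`generate_gene_groups` builds a gene x spacer count matrix with
  planted, well-separated row groups for clustering tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .likelihood import GeneSet, build_motif_gene_index
from .scan import MotifPairQuery
from .sequence_io import (
    GeneAnnotation,
    GenomeSequence,
    PromoterRecord,
    PromoterSet,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_probs(gc_content: float) -> np.ndarray:
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return np.array([at, gc, gc, at])  # A, C, G, T


def random_sequence(
    length: int, gc_content: float, rng: np.random.Generator, markov_rho: float = 0.0
) -> str:
    """i.i.d. background sequence; ``markov_rho`` > 0 switches to an order-1
    chain that repeats the previous base with probability rho (robustness
    checks only)."""
    p = _base_probs(gc_content)
    if markov_rho <= 0:
        idx = rng.choice(4, size=length, p=p)
    else:
        idx = np.empty(length, dtype=np.int64)
        idx[0] = rng.choice(4, p=p)
        repeats = rng.random(length) < markov_rho
        fresh = rng.choice(4, size=length, p=p)
        for i in range(1, length):
            idx[i] = idx[i - 1] if repeats[i] else fresh[i]
    return _BASES[idx].tobytes().decode()


@dataclass
class SyntheticGenomeConfig:
    seed: int
    n_chromosomes: int = 1
    chrom_length: int = 100_000
    gc_content: float = 0.36
    n_genes: int = 20
    gene_len: int = 1000
    promoter_len: int = 1000
    strand_policy: str = "random"  # "random" | "plus"
    markov_rho: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ConfigurationError("gc_content must be in (0, 1)")
        if self.strand_policy not in {"random", "plus"}:
            raise ConfigurationError("strand_policy must be 'random' or 'plus'")


def generate_genome(
    config: SyntheticGenomeConfig,
) -> tuple[list[GenomeSequence], list[GeneAnnotation]]:
    """Random genome plus non-overlapping gene models with full promoters.

    Each gene occupies a slot of ``gene_len + 2*promoter_len`` bp, leaving a
    promoter-length margin on both sides regardless of strand. Deterministic
    (byte-identical FASTA/GFF) for a given config.
    """
    rng = np.random.default_rng(config.seed)
    slot = config.gene_len + 2 * config.promoter_len
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    for n in per_chrom:
        if n * slot > config.chrom_length:
            raise ConfigurationError(
                f"cannot pack {n} genes of slot {slot} bp into "
                f"{config.chrom_length} bp"
            )
    genomes, genes = [], []
    for ci, n_on_chrom in enumerate(per_chrom):
        seq_id = f"chr{ci + 1}"
        genomes.append(
            GenomeSequence(
                seq_id,
                random_sequence(
                    config.chrom_length, config.gc_content, rng, config.markov_rho
                ),
            )
        )
        for gi in range(n_on_chrom):
            start = gi * slot + config.promoter_len + 1  # 1-based
            end = start + config.gene_len - 1
            strand = (
                "+"
                if config.strand_policy == "plus"
                else ("+" if rng.random() < 0.5 else "-")
            )
            genes.append(
                GeneAnnotation(
                    gene_id=f"{seq_id}_g{gi + 1:04d}",
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return genomes, genes


@dataclass
class PlantSpec:
    query: MotifPairQuery
    spacer_len: int
    n_plants: int
    region: str = "genome"  # "genome" | "intervals"
    spacer_policy: str = "random"  # "random" | "fixed"
    fixed_spacer: str | None = None
    gc_content: float = 0.36

    def __post_init__(self) -> None:
        if not (self.query.min_spacer <= self.spacer_len <= self.query.max_spacer):
            raise ConfigurationError("spacer_len outside the query's range")
        if self.spacer_policy == "fixed":
            if self.fixed_spacer is None or len(self.fixed_spacer) != self.spacer_len:
                raise ConfigurationError(
                    "fixed spacer policy needs a fixed_spacer of length spacer_len"
                )

    @property
    def site_len(self) -> int:
        return (
            len(self.query.left_motif) + self.spacer_len + len(self.query.right_motif)
        )


def _place_nonoverlapping(
    intervals: list[tuple[str, int, int]],
    site_len: int,
    n_plants: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Sample non-overlapping (seq_id, start) placements within intervals
    (0-based half-open), by rejection against already-occupied spans."""
    usable = [(sid, s, e) for sid, s, e in intervals if e - s >= site_len]
    if not usable:
        raise ConfigurationError("no interval can hold a planted site")
    weights = np.array([e - s - site_len + 1 for _, s, e in usable], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {}
    placements: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = 200 * max(n_plants, 1) + 1000
    while len(placements) < n_plants:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                f"could not place {n_plants} non-overlapping sites "
                f"(placed {len(placements)})"
            )
        i = rng.choice(len(usable), p=weights)
        sid, s, e = usable[i]
        pos = int(rng.integers(s, e - site_len + 1))
        spans = occupied.setdefault(sid, [])
        if any(pos < b and pos + site_len > a for a, b in spans):
            continue
        spans.append((pos, pos + site_len))
        placements.append((sid, pos))
    return placements


def plant_pairs(
    sequences: list[GenomeSequence],
    spec: PlantSpec,
    seed: int,
    intervals: list[tuple[str, int, int]] | None = None,
) -> tuple[list[GenomeSequence], list[dict]]:
    """Overwrite ``left + spacer + right`` at non-overlapping random sites.

    ``intervals`` (0-based half-open, per seq_id) restricts placement, e.g.
    to promoter windows; by default whole sequences are used. Returns the
    modified sequences and a truth table of planted sites
    (seq_id, position, spacer_len, spacer_seq).
    """
    rng = np.random.default_rng(seed)
    if intervals is None:
        intervals = [(g.seq_id, 0, len(g)) for g in sequences]
    if spec.n_plants == 0:
        return list(sequences), []
    placements = _place_nonoverlapping(intervals, spec.site_len, spec.n_plants, rng)
    buffers = {g.seq_id: bytearray(g.residues, "ascii") for g in sequences}
    truth = []
    for sid, pos in placements:
        if spec.spacer_policy == "fixed":
            spacer = spec.fixed_spacer
        else:
            spacer = random_sequence(spec.spacer_len, spec.gc_content, rng)
        site = spec.query.left_motif + spacer + spec.query.right_motif
        buffers[sid][pos : pos + len(site)] = site.encode()
        truth.append(
            {
                "seq_id": sid,
                "position": pos,
                "spacer_len": spec.spacer_len,
                "spacer_seq": spacer,
            }
        )
    planted = [GenomeSequence(g.seq_id, buffers[g.seq_id].decode()) for g in sequences]
    truth.sort(key=lambda t: (t["seq_id"], t["position"]))
    return planted, truth


# ---------------------------------------------------------------------------
# enrichment study


@dataclass
class EnrichmentStudyConfig:
    seed: int
    factor: float = 2.0  # target promoter/genome density ratio
    genome_length: int = 1_000_000
    n_genes: int = 100
    promoter_len: int = 1000
    gene_len: int = 1000
    gc_content: float = 0.36
    spacer_len: int = 10
    pair_density: float = 1e-3  # overall planted pairs per bp at spacer_len
    query: MotifPairQuery = field(
        default_factory=lambda: MotifPairQuery("AAAG", "ACGT", 0, 30)
    )


@dataclass
class EnrichmentStudy:
    genomes: list[GenomeSequence]
    genes: list[GeneAnnotation]
    truth: list[dict]
    config: EnrichmentStudyConfig


def generate_enrichment_study(config: EnrichmentStudyConfig) -> EnrichmentStudy:
    """Plant pairs so promoters carry ``factor`` times the genome-wide
    per-bp pair density at one spacer length.

    With promoter fraction p of the genome and overall density D, promoter
    density is f*D and non-promoter density (D - f*D*p)/(1 - p); this is
    infeasible when f*p >= 1. All genes are on the plus strand so planted
    promoter windows coincide with extracted promoters.
    """
    p = config.n_genes * config.promoter_len / config.genome_length
    if config.factor * p >= 1:
        raise ConfigurationError(
            f"factor {config.factor} infeasible at promoter fraction {p:.3f}"
        )
    genome_cfg = SyntheticGenomeConfig(
        seed=config.seed,
        n_chromosomes=1,
        chrom_length=config.genome_length,
        gc_content=config.gc_content,
        n_genes=config.n_genes,
        gene_len=config.gene_len,
        promoter_len=config.promoter_len,
        strand_policy="plus",
    )
    genomes, genes = generate_genome(genome_cfg)
    promoter_iv = [
        (g.seq_id, g.start - 1 - config.promoter_len, g.start - 1) for g in genes
    ]
    # complement of the promoter windows, chromosome by chromosome
    background_iv = []
    for chrom in genomes:
        cursor = 0
        for _, s, e in sorted(iv for iv in promoter_iv if iv[0] == chrom.seq_id):
            if s > cursor:
                background_iv.append((chrom.seq_id, cursor, s))
            cursor = max(cursor, e)
        if cursor < len(chrom):
            background_iv.append((chrom.seq_id, cursor, len(chrom)))

    promoter_bp = config.n_genes * config.promoter_len
    background_bp = config.genome_length - promoter_bp
    d_promoter = config.factor * config.pair_density
    d_background = (config.pair_density - d_promoter * p) / (1 - p)
    n_prom = round(d_promoter * promoter_bp)
    n_bg = round(d_background * background_bp)

    spec = PlantSpec(
        query=config.query,
        spacer_len=config.spacer_len,
        n_plants=n_prom,
        gc_content=config.gc_content,
    )
    genomes, truth_prom = plant_pairs(
        genomes, spec, seed=config.seed + 1, intervals=promoter_iv
    )
    spec_bg = PlantSpec(
        query=config.query,
        spacer_len=config.spacer_len,
        n_plants=n_bg,
        gc_content=config.gc_content,
    )
    genomes, truth_bg = plant_pairs(
        genomes, spec_bg, seed=config.seed + 2, intervals=background_iv
    )
    return EnrichmentStudy(
        genomes=genomes, genes=genes, truth=truth_prom + truth_bg, config=config
    )


# ---------------------------------------------------------------------------
# condition-likelihood study


@dataclass
class SyntheticStudyConfig:
    seed: int
    lift: float = 1.0
    n_genes: int = 2000
    promoter_len: int = 1000
    fraction_condition: float = 0.1  # |A| / universe
    planted_fraction: float = 0.1  # fraction of promoters given one planted pair
    gc_content: float = 0.36
    condition: str = "synthetic-condition"
    direction: str = "down"
    query: MotifPairQuery = field(
        default_factory=lambda: MotifPairQuery("AAAG", "ACGT", 0, 30)
    )

    def __post_init__(self) -> None:
        if self.lift < 0:
            raise ConfigurationError("lift must be >= 0")
        if not (0 < self.fraction_condition < 1):
            raise ConfigurationError("fraction_condition must be in (0, 1)")


@dataclass
class ConditionStudy:
    promoters: PromoterSet
    gene_set: GeneSet
    motif_genes: set[str]  # realized B (planted plus accidental pairs)
    realized_lift: float
    config: SyntheticStudyConfig


def generate_condition_study(config: SyntheticStudyConfig) -> ConditionStudy:
    """Promoters with planted pairs plus a condition set A at a chosen lift.

    Background promoters already contain accidental pairs, so B is
    determined by scanning the generated promoters, not from the plant list;
    A is then sampled so that |A ∩ B| = round(lift * |A| * |B| / universe),
    i.e. P(A | B) = lift * P(A). The realized lift (after rounding) is
    recorded.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    records = []
    n_planted = round(config.planted_fraction * n)
    for i in range(n):
        residues = random_sequence(config.promoter_len, config.gc_content, rng)
        if i < n_planted:
            spacer_len = int(
                rng.integers(config.query.min_spacer, config.query.max_spacer + 1)
            )
            site = (
                config.query.left_motif
                + random_sequence(spacer_len, config.gc_content, rng)
                + config.query.right_motif
            )
            pos = int(rng.integers(0, config.promoter_len - len(site) + 1))
            residues = residues[:pos] + site + residues[pos + len(site) :]
        records.append(
            PromoterRecord(
                gene_id=f"g{i:05d}",
                seq_id="synthetic",
                start=1,
                end=config.promoter_len,
                strand="+",
                residues=residues,
                truncated=False,
            )
        )
    promoters = PromoterSet(records=records, upstream_len=config.promoter_len)
    index = build_motif_gene_index(promoters, config.query)
    B = index.genes_any()
    universe = sorted(index.universe)
    n_A = round(config.fraction_condition * n)
    n_AB = round(config.lift * n_A * len(B) / n)
    if n_AB > min(n_A, len(B)) or (n_A - n_AB) > (n - len(B)):
        raise ConfigurationError(
            f"lift {config.lift} infeasible: |B|={len(B)}, |A|={n_A}, "
            f"universe={n}"
        )
    B_sorted = sorted(B)
    not_B = sorted(set(universe) - B)
    in_B = rng.choice(len(B_sorted), size=n_AB, replace=False)
    out_B = rng.choice(len(not_B), size=n_A - n_AB, replace=False)
    A = {B_sorted[i] for i in in_B} | {not_B[i] for i in out_B}
    realized = (n_AB / len(B)) / (n_A / n)
    return ConditionStudy(
        promoters=promoters,
        gene_set=GeneSet(
            condition=config.condition,
            direction=config.direction,
            gene_ids=frozenset(A),
        ),
        motif_genes=B,
        realized_lift=realized,
        config=config,
    )


# ---------------------------------------------------------------------------
# planted clustering groups


def generate_gene_groups(
    n_groups: int = 3,
    genes_per_group: int = 10,
    n_spacers: int = 31,
    signal: int = 5,
    noise: int = 1,
    seed: int = 0,
):
    """Gene x spacer count matrix with well-separated planted row groups.

    Each group concentrates ``signal`` counts (plus integer noise in
    [0, noise]) on its own block of 3 spacer columns; between/within
    separation far exceeds the within-group spread. Returns
    (GeneSpacerMatrix, {gene_id: group}).
    """
    import pandas as pd

    from .cluster import GeneSpacerMatrix

    if n_groups * 3 > n_spacers:
        raise ConfigurationError("n_spacers too small for the group blocks")
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    gene_ids = []
    for g in range(n_groups):
        block = range(g * 3, g * 3 + 3)
        for j in range(genes_per_group):
            gene_id = f"grp{g}_g{j:03d}"
            row = np.zeros(n_spacers, dtype=int)
            for col in block:
                row[col] = signal + int(rng.integers(0, noise + 1))
            rows.append(row)
            labels[gene_id] = g
            gene_ids.append(gene_id)
    df = pd.DataFrame(rows, index=gene_ids, columns=list(range(n_spacers)))
    return GeneSpacerMatrix(df), labels


def plant_in_promoters(
    genomes: list[GenomeSequence],
    genes: list[GeneAnnotation],
    spec: PlantSpec,
    seed: int,
    promoter_len: int = 1000,
) -> tuple[list[GenomeSequence], list[dict]]:
    """Plant sites inside the (strand-aware) promoter windows of genes.

    For minus-strand genes the site is written reverse-complemented so the
    gene-oriented promoter reads ``left + spacer + right``.
    """
    plus_iv, minus_iv = [], []
    for g in genes:
        if g.strand == "+":
            plus_iv.append((g.seq_id, max(0, g.start - 1 - promoter_len), g.start - 1))
        else:
            chrom_len = next(len(c) for c in genomes if c.seq_id == g.seq_id)
            minus_iv.append((g.seq_id, g.end, min(chrom_len, g.end + promoter_len)))
    truth_all: list[dict] = []
    out = list(genomes)
    rng = np.random.default_rng(seed)
    n_plus = int(
        rng.binomial(spec.n_plants, len(plus_iv) / max(len(plus_iv) + len(minus_iv), 1))
    ) if minus_iv else spec.n_plants
    for ivs, n_here, flip in ((plus_iv, n_plus, False), (minus_iv, spec.n_plants - n_plus, True)):
        if not ivs or n_here == 0:
            continue
        sub = PlantSpec(
            query=spec.query,
            spacer_len=spec.spacer_len,
            n_plants=n_here,
            spacer_policy=spec.spacer_policy,
            fixed_spacer=spec.fixed_spacer,
            gc_content=spec.gc_content,
        )
        if flip:
            # write the reverse complement of the site on the plus strand
            rc_left = reverse_complement(spec.query.right_motif)
            rc_right = reverse_complement(spec.query.left_motif)
            sub = PlantSpec(
                query=MotifPairQuery(
                    rc_left, rc_right, spec.query.min_spacer, spec.query.max_spacer
                ),
                spacer_len=spec.spacer_len,
                n_plants=n_here,
                spacer_policy=spec.spacer_policy,
                fixed_spacer=(
                    reverse_complement(spec.fixed_spacer)
                    if spec.fixed_spacer is not None
                    else None
                ),
                gc_content=spec.gc_content,
            )
        out, truth = plant_pairs(out, sub, seed=seed + (1 if flip else 0), intervals=ivs)
        truth_all.extend(truth)
    return out, truth_all
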