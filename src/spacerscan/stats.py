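"""Coverage normalization, promoter-vs-genome enrichment, shuffled controls,
and the statistical comparisons between orientations.

Raw pair counts are normalized by "genomic coverage" — the total number of
scanned base pairs of the region set (whole-genome length, or summed
promoter lengths) — giving a per-bp frequency. Enrichment at each spacer
length is the ratio of the promoter per-bp frequency to the genome per-bp
frequency; this is the dimensionless quantity in which an approximately
two-fold promoter enrichment of the AAAG/ACGT pair is expressed.

Shuffled controls are the 12 ordered combinations of the permuted left
tetramers {AAGA, AGAA, GAAA} with the permuted right tetramers
{CATG, GCAT, GTAC, TCAG}, none of which is itself a known cis-element.

Orientation comparisons pair the 31 per-spacer counts (N = 0..30) between
the two orientations: a paired two-tailed t-test at 30 df, plus a Pearson
correlation restricted by default to spacers 6..11 where the two
orientations share peaks and dips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError
from .scan import MotifPairQuery, SpacerFrequencyProfile

LEFT_CONTROLS = ("AAGA", "AGAA", "GAAA")
RIGHT_CONTROLS = ("CATG", "GCAT", "GTAC", "TCAG")


@dataclass
class NormalizedProfile:
    query_label: str
    normalized: dict[int, float]
    source: SpacerFrequencyProfile


@dataclass
class EnrichmentResult:
    """Per-spacer promoter/genome frequency ratios.

    Spacer lengths where the genome frequency is zero are listed in
    ``undefined`` and excluded from min/max, never silently set to zero.
    """

    query_label: str
    ratio: dict[int, float]
    undefined: set[int] = field(default_factory=set)

    @property
    def min_ratio(self) -> float:
        return min(self.ratio.values())

    @property
    def max_ratio(self) -> float:
        return max(self.ratio.values())


@dataclass
class ControlSet:
    orientation: str
    queries: list[MotifPairQuery]


@dataclass
class TestResult:
    kind: str  # "paired-t" | "pearson"
    statistic: float
    df: int
    pvalue: float
    n: int


def normalize_profile(profile: SpacerFrequencyProfile) -> NormalizedProfile:
    """Divide each spacer count by the total scanned bp of the region set."""
    if profile.total_bp <= 0:
        raise ValueError("profile has total_bp == 0; nothing was scanned")
    return NormalizedProfile(
        query_label=profile.query_label,
        normalized={n: c / profile.total_bp for n, c in profile.counts.items()},
        source=profile,
    )


def enrichment(
    promoter_norm: NormalizedProfile, genome_norm: NormalizedProfile
) -> EnrichmentResult:
    """Element-wise promoter/genome frequency ratio per spacer length."""
    if promoter_norm.query_label != genome_norm.query_label:
        raise ValueError(
            f"query labels differ: {promoter_norm.query_label!r} vs "
            f"{genome_norm.query_label!r}"
        )
    if set(promoter_norm.normalized) != set(genome_norm.normalized):
        raise ValueError("spacer ranges differ between the two profiles")
    ratio: dict[int, float] = {}
    undefined: set[int] = set()
    for n, p in promoter_norm.normalized.items():
        g = genome_norm.normalized[n]
        if g == 0:
            undefined.add(n)
        else:
            ratio[n] = p / g
    return EnrichmentResult(
        query_label=promoter_norm.query_label, ratio=ratio, undefined=undefined
    )


def make_control_queries(
    orientation: str = "left-first", min_spacer: int = 0, max_spacer: int = 30
) -> ControlSet:
    """The 12 shuffled-tetramer control pair queries for one orientation.

    ``left-first`` pairs each of AAGA/AGAA/GAAA before each of
    CATG/GCAT/GTAC/TCAG; ``right-first`` mirrors the order. Deterministic
    ordering (outer loop over the AAAG shuffles as listed).
    """
    if orientation not in {"left-first", "right-first"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    queries = []
    for left in LEFT_CONTROLS:
        for right in RIGHT_CONTROLS:
            if orientation == "left-first":
                queries.append(MotifPairQuery(left, right, min_spacer, max_spacer))
            else:
                queries.append(MotifPairQuery(right, left, min_spacer, max_spacer))
    return ControlSet(orientation=orientation, queries=queries)


def paired_t_test(x, y) -> TestResult:
    """Two-tailed paired Student's t-test.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample (n-1) standard deviation,
    df = n-1. Identical differences (zero variance) raise
    :class:`DegenerateInputError` rather than returning +/-inf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.ptp(d) == 0:
        raise DegenerateInputError("all paired differences are identical")
    res = sps.ttest_rel(x, y)
    return TestResult(
        kind="paired-t",
        statistic=float(res.statistic),
        df=n - 1,
        pvalue=float(res.pvalue),
        n=n,
    )


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical value of Student's t: the (1 - alpha/2) quantile."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.t.ppf(1 - alpha / 2, df))


def pearson(x, y) -> TestResult:
    """Sample Pearson correlation with its two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return TestResult(
        kind="pearson",
        statistic=float(res.statistic),
        df=x.size - 2,
        pvalue=float(res.pvalue),
        n=x.size,
    )


def orientation_comparison(
    profile_a: SpacerFrequencyProfile,
    profile_b: SpacerFrequencyProfile,
    correlation_spacers=range(6, 12),
) -> dict[str, TestResult]:
    """Paired t over the full shared spacer range plus Pearson over a subset.

    The default correlation window (spacers 6..11) is the region where the
    two orientations show common peaks and dips.
    """
    shared = sorted(set(profile_a.counts) & set(profile_b.counts))
    if len(shared) < 2:
        raise ValueError("profiles share fewer than 2 spacer lengths")
    a = [profile_a.counts[n] for n in shared]
    b = [profile_b.counts[n] for n in shared]
    out = {"paired_t": paired_t_test(a, b)}
    corr_keys = [n for n in correlation_spacers if n in set(shared)]
    if len(corr_keys) >= 3:
        out["pearson"] = pearson(
            [profile_a.counts[n] for n in corr_keys],
            [profile_b.counts[n] for n in corr_keys],
        )
    return out


def compare_to_controls(
    true_profile: SpacerFrequencyProfile,
    control_profiles: list[SpacerFrequencyProfile],
) -> list[tuple[str, TestResult]]:
    """Paired t-test of the true pair's per-spacer counts against each control."""
    shared = sorted(true_profile.counts)
    x = [true_profile.counts[n] for n in shared]
    results = []
    for ctrl in control_profiles:
        y = [ctrl.counts[n] for n in shared]
        try:
            results.append((ctrl.query_label, paired_t_test(x, y)))
        except DegenerateInputError:
            results.append(
                (ctrl.query_label, TestResult("paired-t", math.nan, len(x) - 1, math.nan, len(x)))
            )
    return results


def write_enrichment_tsv(
    prom_a: NormalizedProfile,
    prom_b: NormalizedProfile,
    result_a: EnrichmentResult,
    result_b: EnrichmentResult,
    path,
) -> None:
    """Per-spacer table for both orientations; '.' marks undefined ratios."""
    with open(path, "w") as fh:
        fh.write(
            "spacer_len\tcount_orient1\tcount_orient2\tnorm1\tnorm2\t"
            "ratio1\tratio2\n"
        )
        for n in sorted(prom_a.normalized):
            r1 = f"{result_a.ratio[n]:.6g}" if n in result_a.ratio else "."
            r2 = f"{result_b.ratio[n]:.6g}" if n in result_b.ratio else "."
            fh.write(
                f"{n}\t{prom_a.source.counts[n]}\t{prom_b.source.counts[n]}\t"
                f"{prom_a.normalized[n]:.6g}\t{prom_b.normalized[n]:.6g}\t"
                f"{r1}\t{r2}\n"
            )
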