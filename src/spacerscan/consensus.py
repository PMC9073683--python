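"""Per-position base composition of spacer sequences and consensus calling.

The consensus rule mirrors how a conserved position is declared in an
AT-rich genome: with a background G/C content near 36%, a G or C is already
noteworthy at a lower fraction than an A or T. A base is called when its
fraction of sequences *strictly* exceeds its class threshold — by default
0.40 for A/T and 0.25 for G/C. Positions where no base passes are N; when
several bases pass, the one with the highest fraction wins, and exact ties
are reported joined (e.g. "G/C"), matching how tied conserved sites are
tabulated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import DegenerateInputError

# tie-report ordering: A/T class first, then G/C
_BASE_ORDER = ("A", "T", "G", "C")


@dataclass
class PositionComposition:
    """Fractions of A/C/G/T at each position of equal-length spacers."""

    spacer_len: int
    n_sequences: int
    fractions: list[dict[str, float]]  # index 0 == position 1


@dataclass
class ConsensusRule:
    at_threshold: float = 0.40
    gc_threshold: float = 0.25
    tie_tolerance: float = 1e-9
    background_gc: float = 0.36  # genome G/C content motivating the split thresholds

    def __post_init__(self) -> None:
        for t in (self.at_threshold, self.gc_threshold):
            if not (0 < t < 1):
                raise ValueError("thresholds must lie in (0, 1)")

    def threshold_for(self, base: str) -> float:
        return self.at_threshold if base in "AT" else self.gc_threshold


@dataclass
class ConsensusString:
    """Per-position calls: A/C/G/T, N, or a joined tie such as 'G/C'."""

    calls: list[str]

    def __len__(self) -> int:
        return len(self.calls)

    def __str__(self) -> str:
        return " ".join(self.calls)


def composition(spacers: list[str]) -> PositionComposition:
    """Per-position base fractions over equal-length spacer strings."""
    if not spacers:
        raise ValueError("no spacer sequences supplied")
    length = len(spacers[0])
    if any(len(s) != length for s in spacers):
        raise ValueError("spacer sequences have unequal lengths")
    n = len(spacers)
    fractions = []
    for pos in range(length):
        counts = Counter(s[pos] for s in spacers)
        fractions.append({b: counts.get(b, 0) / n for b in "ACGT"})
    return PositionComposition(spacer_len=length, n_sequences=n, fractions=fractions)


def call_consensus(
    comp: PositionComposition, rule: ConsensusRule | None = None
) -> ConsensusString:
    """Apply the class thresholds position by position (strict inequality)."""
    rule = rule or ConsensusRule()
    calls = []
    for fracs in comp.fractions:
        passing = [b for b in _BASE_ORDER if fracs[b] > rule.threshold_for(b)]
        if not passing:
            calls.append("N")
            continue
        top = max(fracs[b] for b in passing)
        tied = [b for b in passing if top - fracs[b] <= rule.tie_tolerance]
        calls.append(tied[0] if len(tied) == 1 else "/".join(tied))
    return ConsensusString(calls=calls)


def consensus_table(
    hits_by_spacer: dict[int, list[str]], rule: ConsensusRule | None = None
) -> dict[int, ConsensusString]:
    """Consensus per spacer length; lengths with no spacers are omitted.

    Spacer length 0 maps to an empty consensus and is included only if
    present (its consensus has no positions to call).
    """
    out = {}
    for n in sorted(hits_by_spacer):
        spacers = hits_by_spacer[n]
        if not spacers or n == 0:
            continue
        out[n] = call_consensus(composition(spacers), rule)
    return out


def write_consensus_tsv(table: dict[int, ConsensusString], path) -> None:
    """Matrix TSV: one row per spacer length, one column per position."""
    if not table:
        raise DegenerateInputError("no consensus rows to write")
    max_len = max(len(c) for c in table.values())
    with open(path, "w") as fh:
        fh.write("spacer_len\t" + "\t".join(f"pos{i+1}" for i in range(max_len)) + "\n")
        for n in sorted(table):
            row = table[n].calls + [""] * (max_len - len(table[n]))
            fh.write(f"{n}\t" + "\t".join(row) + "\n")


def write_composition_tsv(comps: dict[int, PositionComposition], path) -> None:
    """Long-format dump: spacer_len, position, base, fraction."""
    with open(path, "w") as fh:
        fh.write("spacer_len\tposition\tbase\tfraction\n")
        for n in sorted(comps):
            for pos, fracs in enumerate(comps[n].fractions, start=1):
                for base in "ACGT":
                    fh.write(f"{n}\t{pos}\t{base}\t{fracs[base]:.6g}\n")
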