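"""Column profiles, consensus patterns, %ID/%similarity and prototype fusion.

The family's two subfamilies (PACAP-like: PACAP, PRP, VIP, PH, GHRH, SCT;
GCG-like: GCG, GLP1, GLP2, GIP) are compared over aligned mature-peptide
windows. Per-column residue frequencies yield a plurality consensus per
group or subfamily; the two subfamily consensuses are fused into a single
degenerate prototype pattern (wildcard 'x' at variable or conflicting
positions) used downstream as a search query. Group-specific signature
residues — conserved within one group and rare in all others — are
identified by frequency thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .maturome import PeptideSequence

GAP = "-"
WILDCARD = "x"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class AlignmentBlock:
    """Equal-length aligned peptide windows with group/subfamily labels."""

    members: List[PeptideSequence]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("AlignmentBlock requires at least one member")
        widths = {len(m.residues) for m in self.members}
        if len(widths) != 1:
            raise ValueError(f"members have unequal aligned lengths: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.members[0].residues)

    def __len__(self) -> int:
        return len(self.members)

    def subset(self, pred) -> "AlignmentBlock":
        kept = [m for m in self.members if pred(m)]
        return AlignmentBlock(kept)

    def by_group(self) -> Dict[str, "AlignmentBlock"]:
        groups: Dict[str, List[PeptideSequence]] = {}
        for m in self.members:
            groups.setdefault(m.group, []).append(m)
        return {g: AlignmentBlock(ms) for g, ms in groups.items()}

    def by_subfamily(self) -> Dict[str, "AlignmentBlock"]:
        subs: Dict[str, List[PeptideSequence]] = {}
        for m in self.members:
            subs.setdefault(m.subfamily, []).append(m)
        return {s: AlignmentBlock(ms) for s, ms in subs.items()}

    def column(self, pos: int) -> str:
        """Residues at 1-based column ``pos``."""
        return "".join(m.residues[pos - 1] for m in self.members)


@dataclass
class ColumnProfile:
    """Per-column residue counts and gap-excluded frequencies."""

    width: int
    counts: List[Dict[str, int]]
    gap_counts: List[int]

    def frequencies(self, pos: int) -> Dict[str, float]:
        """Frequencies at 1-based ``pos`` over non-gap residues.

        Returns an empty dict for an all-gap column.
        """
        c = self.counts[pos - 1]
        total = sum(c.values())
        if total == 0:
            return {}
        return {r: k / total for r, k in c.items()}

    def is_all_gap(self, pos: int) -> bool:
        return sum(self.counts[pos - 1].values()) == 0


def column_profile(block: AlignmentBlock) -> ColumnProfile:
    """Exact per-column residue counts; gaps excluded from frequencies."""
    counts: List[Dict[str, int]] = []
    gaps: List[int] = []
    for pos in range(1, block.width + 1):
        col = block.column(pos)
        c: Dict[str, int] = {}
        g = 0
        for r in col:
            if r == GAP:
                g += 1
            else:
                c[r] = c.get(r, 0) + 1
        counts.append(c)
        gaps.append(g)
    return ColumnProfile(block.width, counts, gaps)


@dataclass(frozen=True)
class ConsensusPattern:
    """Degenerate consensus: 1-based position -> residue, 'x' elsewhere."""

    width: int
    positions: Mapping[int, str]
    source: str = ""
    tau: float | None = None

    def __post_init__(self) -> None:
        for p, r in self.positions.items():
            if not (1 <= p <= self.width):
                raise ValueError(f"position {p} outside 1..{self.width}")
            if r not in AMINO_ACIDS:
                raise ValueError(f"invalid consensus residue {r!r} at {p}")
        object.__setattr__(self, "positions", dict(self.positions))

    @property
    def defined_positions(self) -> Set[int]:
        return set(self.positions)

    def to_string(self) -> str:
        return "".join(self.positions.get(p, WILDCARD) for p in range(1, self.width + 1))

    @classmethod
    def from_string(cls, s: str, source: str = "", tau: float | None = None) -> "ConsensusPattern":
        pos = {i + 1: r for i, r in enumerate(s.upper()) if r not in (WILDCARD.upper(), GAP)}
        return cls(width=len(s), positions=pos, source=source, tau=tau)

    def to_json(self) -> str:
        return json.dumps(
            {"width": self.width, "source": self.source, "tau": self.tau,
             "positions": {str(p): r for p, r in sorted(self.positions.items())}},
            indent=2,
        )


def derive_consensus(
    profile: ColumnProfile,
    tau: float = 0.5,
    tie_rule: str = "wildcard",
    source: str = "",
) -> ConsensusPattern:
    """Plurality consensus: position defined iff the most frequent residue
    reaches frequency ``tau`` and is the unique maximum; ties and all-gap
    columns become wildcards."""
    if not (0 < tau <= 1):
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    if tie_rule != "wildcard":
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    positions: Dict[int, str] = {}
    for p in range(1, profile.width + 1):
        freqs = profile.frequencies(p)
        if not freqs:
            continue
        best = max(freqs.values())
        winners = [r for r, f in freqs.items() if f == best]
        if len(winners) == 1 and best >= tau:
            positions[p] = winners[0]
    return ConsensusPattern(profile.width, positions, source=source, tau=tau)


@dataclass(frozen=True)
class SimilarityScheme:
    """Named partition of the 20 amino acids into similarity groups."""

    name: str
    groups: Tuple[frozenset, ...]

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError(f"overlapping similarity groups: {sorted(seen & g)}")
            seen |= g
        if seen != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - seen
            extra = seen - set(AMINO_ACIDS)
            raise ValueError(f"scheme must cover the 20 amino acids exactly "
                             f"(missing {sorted(missing)}, extra {sorted(extra)})")

    def similar(self, a: str, b: str) -> bool:
        if a == b:
            return True
        return any(a in g and b in g for g in self.groups)


def _parts(*specs: str) -> Tuple[frozenset, ...]:
    return tuple(frozenset(s) for s in specs)


#: Strong-similarity partition: aliphatic, aromatic, basic, acidic,
#: hydroxyl, amide, small, plus singletons C and P.
DEFAULT_SCHEME = SimilarityScheme(
    "strong", _parts("ILMV", "FWY", "KRH", "DE", "ST", "NQ", "AG", "C", "P"),
)


def _symbols(x) -> List[str]:
    """Per-column symbols of a peptide, pattern or plain string."""
    if isinstance(x, ConsensusPattern):
        return list(x.to_string())
    if isinstance(x, PeptideSequence):
        return list(x.residues)
    return list(str(x))


def _comparable(sa: Sequence[str], sb: Sequence[str]) -> List[Tuple[str, str]]:
    skip = {GAP, WILDCARD, WILDCARD.upper()}
    return [(a, b) for a, b in zip(sa, sb) if a not in skip and b not in skip]


def percent_identity(a, b) -> float:
    """100 x matches / comparable columns (both non-gap, non-wildcard).

    Returns NaN when no column is comparable. Symmetric in its arguments.
    """
    sa, sb = _symbols(a), _symbols(b)
    if len(sa) != len(sb):
        raise ValueError(f"width mismatch: {len(sa)} vs {len(sb)}")
    pairs = _comparable(sa, sb)
    if not pairs:
        return math.nan
    return 100.0 * sum(x == y for x, y in pairs) / len(pairs)


def percent_similarity(a, b, scheme: SimilarityScheme = DEFAULT_SCHEME) -> float:
    """Like :func:`percent_identity` but residues in the same similarity
    group also count as matches."""
    sa, sb = _symbols(a), _symbols(b)
    if len(sa) != len(sb):
        raise ValueError(f"width mismatch: {len(sa)} vs {len(sb)}")
    pairs = _comparable(sa, sb)
    if not pairs:
        return math.nan
    return 100.0 * sum(scheme.similar(x, y) for x, y in pairs) / len(pairs)


def fuse_prototype(cons_a: ConsensusPattern, cons_b: ConsensusPattern) -> ConsensusPattern:
    """Fuse two subfamily consensuses into one prototype pattern.

    A position is defined in the result when exactly one input defines it, or
    both define it with the same residue; positions where the inputs conflict
    — or neither defines — become wildcards. Commutative and idempotent.
    """
    if cons_a.width != cons_b.width:
        raise ValueError(f"width mismatch: {cons_a.width} vs {cons_b.width}")
    fused: Dict[int, str] = {}
    for p in range(1, cons_a.width + 1):
        ra = cons_a.positions.get(p)
        rb = cons_b.positions.get(p)
        if ra is not None and rb is not None:
            if ra == rb:
                fused[p] = ra
        elif ra is not None:
            fused[p] = ra
        elif rb is not None:
            fused[p] = rb
    return ConsensusPattern(
        cons_a.width, fused,
        source=f"fuse({cons_a.source or '?'},{cons_b.source or '?'})",
    )


def signature_residues(
    blocks: Mapping[str, AlignmentBlock],
    tau_in: float = 0.8,
    tau_out: float = 0.2,
) -> Dict[str, Set[Tuple[int, str]]]:
    """Group-specific signature residues.

    ``(p, r)`` is a signature of group ``g`` iff the frequency of residue
    ``r`` at 1-based position ``p`` within ``g`` is >= ``tau_in`` and its
    frequency at ``p`` in every other group is <= ``tau_out``.
    """
    if not (0 <= tau_in <= 1) or not (0 <= tau_out <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if len(blocks) < 2:
        raise ValueError("signature_residues requires at least two groups")
    widths = {b.width for b in blocks.values()}
    if len(widths) != 1:
        raise ValueError(f"blocks have unequal widths: {sorted(widths)}")
    width = widths.pop()
    profiles = {g: column_profile(b) for g, b in blocks.items()}
    out: Dict[str, Set[Tuple[int, str]]] = {g: set() for g in blocks}
    for g, prof in profiles.items():
        for p in range(1, width + 1):
            for r, f in prof.frequencies(p).items():
                if f < tau_in:
                    continue
                if all(profiles[h].frequencies(p).get(r, 0.0) <= tau_out
                       for h in profiles if h != g):
                    out[g].add((p, r))
    return out


# ---------------------------------------------------------------------------
# Subfamily consensus residue sets as printed in the comparative analysis of
# the vertebrate family (1-based positions on the 1-27 window). These serve
# as worked-example inputs for prototype fusion.

PACAP_LIKE_CONSENSUS = ConsensusPattern(
    27,
    {1: "H", 3: "D", 6: "F", 7: "T", 10: "Y", 16: "Q", 23: "L"},
    source="PACAP-like",
)

GCG_LIKE_CONSENSUS = ConsensusPattern(
    27,
    {1: "H", 2: "A", 4: "G", 5: "T", 6: "F", 8: "S", 9: "D", 11: "S",
     14: "L", 19: "A", 20: "K", 22: "F", 23: "V", 25: "W", 26: "L"},
    source="GCG-like",
)
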