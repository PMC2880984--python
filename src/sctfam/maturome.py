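"""Mature-peptide extraction by global alignment against reference peptides.

Hormone precursors carry the bioactive mature peptide embedded between a
signal peptide and other cleavage products. The family is compared over a
fixed window of the mature peptide — residues 1–27 for every group except
GLP1, where residues 5–32 (the single-exon-encoded segment) are used. This
module aligns a precursor to a reference mature peptide and reads off the
precursor residues occupying the reference window columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

# Subfamily membership of the ten vertebrate peptide groups.
PACAP_LIKE = "PACAP-like"
GCG_LIKE = "GCG-like"
GROUP_SUBFAMILY: Dict[str, str] = {
    "PACAP": PACAP_LIKE,
    "PRP": PACAP_LIKE,
    "VIP": PACAP_LIKE,
    "PH": PACAP_LIKE,
    "GHRH": PACAP_LIKE,
    "SCT": PACAP_LIKE,
    "GCG": GCG_LIKE,
    "GLP1": GCG_LIKE,
    "GLP2": GCG_LIKE,
    "GIP": GCG_LIKE,
}

# Default comparison window (1-based inclusive on the mature peptide) and
# per-group overrides. GLP1 uses 5-32: its first four residues lie outside
# the conserved single-exon core.
DEFAULT_WINDOW: Tuple[int, int] = (1, 27)
WINDOW_OVERRIDES: Dict[str, Tuple[int, int]] = {"GLP1": (5, 32)}

# Sequences excluded from comparisons at load time. Lamprey proglucagon-II
# GLP2 shares too little similarity with the other members (likely
# species-specific evolution) and would distort the group consensus.
DEFAULT_EXCLUDE_IDS = frozenset({"lamprey_proglucagonII_GLP2"})


@dataclass(frozen=True)
class PeptideSequence:
    """A mature-peptide window with taxonomic and group labels.

    ``window`` is 1-based inclusive on the mature peptide, matching the
    superscript residue numbering (H1 ... L27) used throughout.
    """

    id: str
    residues: str
    taxon: str = ""
    group: str = ""
    subfamily: str = ""
    window: Tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        lo, hi = self.window
        if hi - lo + 1 != len(self.residues):
            raise ValueError(
                f"{self.id}: window {self.window} length {hi - lo + 1} != "
                f"{len(self.residues)} residues"
            )
        if self.group in GROUP_SUBFAMILY:
            expected = GROUP_SUBFAMILY[self.group]
            if self.subfamily and self.subfamily != expected:
                raise ValueError(
                    f"{self.id}: group {self.group} belongs to subfamily "
                    f"{expected}, got {self.subfamily}"
                )
            if not self.subfamily:
                object.__setattr__(self, "subfamily", expected)

    def __len__(self) -> int:
        return len(self.residues)


def window_for_group(group: str) -> Tuple[int, int]:
    """Comparison window for a peptide group (GLP1 -> 5-32, else 1-27)."""
    return WINDOW_OVERRIDES.get(group, DEFAULT_WINDOW)


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def _default_matrix():
    return substitution_matrices.load("BLOSUM62")


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Needleman–Wunsch global alignment with affine gap penalties.

    A gap of length k costs ``gap_open + (k-1)*gap_extend``; terminal gaps
    are penalised like internal ones. ``matrix`` is any object indexable as
    ``matrix[x, y]`` (default BLOSUM62). The traceback is deterministic with
    tie-break diagonal > up (gap in b) > left (gap in a).
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    if matrix is None:
        matrix = _default_matrix()
    n, m = len(a), len(b)
    NEG = float("-inf")
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a.
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = float(matrix[ai, b[j - 1]])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_open,
                          Y[i][j - 1] - gap_extend)

    # Traceback. State preference M > X > Y encodes the diagonal > up > left
    # tie-break; -inf boundary cells make unreachable predecessors
    # self-excluding.
    mats = {"M": M, "X": X, "Y": Y}
    pref = {"M": 2, "X": 1, "Y": 0}

    def best_state(cands):
        return max(cands, key=lambda sv: (sv[1], pref[sv[0]]))[0]

    i, j = n, m
    state = best_state([(st, mats[st][i][j]) for st in ("M", "X", "Y")])
    score = mats[state][i][j]
    ra, rb = [], []
    while i > 0 or j > 0:
        if state == "M":
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            state = best_state([(st, mats[st][i - 1][j - 1]) for st in ("M", "X", "Y")])
            i, j = i - 1, j - 1
        elif state == "X":
            ra.append(a[i - 1])
            rb.append("-")
            state = best_state([
                ("M", M[i - 1][j] - gap_open),
                ("X", X[i - 1][j] - gap_extend),
                ("Y", Y[i - 1][j] - gap_open),
            ])
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            state = best_state([
                ("M", M[i][j - 1] - gap_open),
                ("X", X[i][j - 1] - gap_open),
                ("Y", Y[i][j - 1] - gap_extend),
            ])
            j -= 1
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    both = [(x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"]
    ident = 100.0 * sum(x == y for x, y in both) / len(both) if both else 0.0
    return AlignmentResult(aligned_a, aligned_b, score, ident)


@dataclass
class ExtractionResult:
    """Outcome of mature-peptide extraction, with provenance."""

    precursor_id: str
    reference_id: str
    identity_pct: float
    window: Tuple[int, int]
    peptide: Optional[PeptideSequence]

    @property
    def found(self) -> bool:
        return self.peptide is not None


def extract_mature(
    precursor: SequenceRecord,
    reference: PeptideSequence,
    window: Tuple[int, int] | None = None,
    min_identity: float = 25.0,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    taxon: str = "",
) -> ExtractionResult:
    """Extract the mature-peptide window of ``precursor`` by alignment.

    The precursor is globally aligned to the reference mature peptide; the
    precursor residues aligned to the reference window columns are returned,
    with '-' at reference positions the precursor does not cover. If the
    alignment identity over the reference falls below ``min_identity`` the
    precursor is reported as having no homologue (``peptide=None``) rather
    than raising.
    """
    window = window or reference.window
    aln = global_align(precursor.residues, reference.residues,
                       matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
    # Identity restricted to the columns the reference occupies.
    ref_cols = [(x, y) for x, y in zip(aln.aligned_a, aln.aligned_b) if y != "-"]
    ident = 100.0 * sum(x == y for x, y in ref_cols) / len(ref_cols)
    if ident < min_identity:
        logger.info("%s: identity %.1f%% to %s below floor %.1f%% — no homologue",
                    precursor.id, ident, reference.id, min_identity)
        return ExtractionResult(precursor.id, reference.id, ident, window, None)
    extracted = "".join(x for x, y in zip(aln.aligned_a, aln.aligned_b) if y != "-")
    pep = PeptideSequence(
        id=precursor.id,
        residues=extracted,
        taxon=taxon,
        group=reference.group,
        subfamily=reference.subfamily,
        window=window,
    )
    return ExtractionResult(precursor.id, reference.id, ident, window, pep)
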