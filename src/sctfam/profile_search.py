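"""Position-specific scoring matrix search with empirical significance.

A PSSM is compiled from an aligned block or a degenerate consensus pattern
as background-weighted log-odds (bits). Protein databases — or nucleotide
databases via six-frame translation — are scanned with a sliding window;
hit significance is estimated by a permutation null: residues are shuffled
within each database record and the best score of each shuffled database
forms the null distribution of the maximum.

This is a transparent desk-scale stand-in for profile-HMM / adjusted-BLAST
short-peptide searches: the statistic differs (empirical p on the database
maximum rather than an E-value) but plays the same filtering role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np

from .consensus_profile import AMINO_ACIDS, AlignmentBlock, ConsensusPattern, column_profile
from .seqio import NUCLEOTIDE, PROTEIN, SequenceRecord, translate_six_frames

logger = logging.getLogger(__name__)

AA_INDEX = {r: i for i, r in enumerate(AMINO_ACIDS)}
#: Residues scored with zero contribution wherever they occur in a window.
NEUTRAL_CHARS = "X*-"

UNIFORM_BACKGROUND: Dict[str, float] = {r: 1.0 / 20.0 for r in AMINO_ACIDS}


@dataclass
class PSSM:
    """Log-odds scores (bits) per (position, residue) with background model.

    ``scores`` has shape (width, 21): one column per amino acid in
    :data:`AMINO_ACIDS` order plus a trailing all-zero column used for
    neutral characters (X, stop, gap). Wildcard/all-gap alignment columns
    carry all-zero rows.
    """

    width: int
    scores: np.ndarray
    background: Dict[str, float]
    alpha: float

    def __post_init__(self) -> None:
        if self.scores.shape != (self.width, 21):
            raise ValueError(f"scores shape {self.scores.shape} != ({self.width}, 21)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM scores must be finite")
        tot = sum(self.background.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {tot}, not 1")

    def score_window(self, window: str) -> float:
        """Score one window (length == width); neutral chars contribute 0."""
        if len(window) != self.width:
            raise ValueError("window length != PSSM width")
        idx = encode_protein(window)
        return float(self.scores[np.arange(self.width), idx].sum())

    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


def encode_protein(s: str) -> np.ndarray:
    """Map a protein string to score-column indices (neutral chars -> 20)."""
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, 20, dtype=np.int64)
    for r, i in AA_INDEX.items():
        lut[ord(r)] = i
    return lut[arr]


def build_pssm(
    source: Union[AlignmentBlock, ConsensusPattern],
    background: Optional[Mapping[str, float]] = None,
    alpha: float = 1.0,
) -> PSSM:
    """Compile a PSSM from an alignment block or consensus pattern.

    score(p, r) = log2((count(p, r) + alpha * bg(r)) / ((n_p + alpha) * bg(r)))
    where n_p is the non-gap count in column p. A consensus pattern is
    treated as a single observation of its defined residue per position;
    wildcard and all-gap columns score zero everywhere.
    """
    bg = dict(background) if background is not None else dict(UNIFORM_BACKGROUND)
    if set(bg) != set(AMINO_ACIDS):
        raise ValueError("background must assign a frequency to each amino acid")
    if any(v <= 0 for v in bg.values()):
        raise ValueError("background frequencies must be strictly positive")
    if alpha < 0:
        raise ValueError("pseudocount alpha must be >= 0")

    if isinstance(source, ConsensusPattern):
        width = source.width
        cols: List[Dict[str, int]] = [
            ({source.positions[p]: 1} if p in source.positions else {})
            for p in range(1, width + 1)
        ]
    else:
        prof = column_profile(source)
        width = prof.width
        cols = [dict(prof.counts[p]) for p in range(width)]

    bgvec = np.array([bg[r] for r in AMINO_ACIDS])
    scores = np.zeros((width, 21))
    for p, counts in enumerate(cols):
        n = sum(counts.values())
        if n == 0:
            continue  # wildcard / all-gap column stays zero
        cnt = np.zeros(20)
        for r, k in counts.items():
            if r in AA_INDEX:
                cnt[AA_INDEX[r]] = k
        if alpha == 0:
            with np.errstate(divide="ignore"):
                col = np.log2(cnt / (n * bgvec))
            col[cnt == 0] = np.finfo(float).min  # replaced below
            # alpha=0 with unobserved residues gives -inf; clamp to a large
            # negative finite value so the matrix stays usable.
            col[~np.isfinite(col)] = -1000.0
        else:
            col = np.log2((cnt + alpha * bgvec) / ((n + alpha) * bgvec))
        scores[p, :20] = col
    return PSSM(width=width, scores=scores, background=bg, alpha=alpha)


@dataclass(frozen=True)
class SearchHit:
    """One PSSM window match. ``start`` is a 0-based offset in the scanned
    frame; for reading frame f on a nucleotide record the nucleotide offset
    is (|f|-1) + 3*start on the given strand."""

    db_id: str
    start: int
    frame: str  # "protein" or +1/+2/+3/-1/-2/-3
    score: float
    empirical_p: Optional[float] = None


def window_scores(pssm: PSSM, residues: str) -> np.ndarray:
    """Scores of every length-``width`` window of a protein string."""
    w = pssm.width
    n = len(residues)
    if n < w:
        return np.empty(0)
    idx = encode_protein(residues)
    nwin = n - w + 1
    acc = np.zeros(nwin)
    for j in range(w):
        acc += pssm.scores[j, idx[j : j + nwin]]
    return acc


def _frames(rec: SequenceRecord, translate: bool) -> List[tuple]:
    """(frame label, source id, protein residues) tuples for scanning."""
    if rec.alphabet == PROTEIN:
        return [("protein", rec.id, rec.residues)]
    if not translate:
        raise ValueError(f"record {rec.id!r} is nucleotide; pass translate=True")
    out = []
    for prot in translate_six_frames(rec):
        frame = prot.id.rsplit("|", 1)[1]
        out.append((frame, rec.id, prot.residues))
    return out


def scan_database(
    pssm: PSSM,
    db: Sequence[SequenceRecord],
    translate: bool = False,
    min_score: float = 0.0,
) -> List[SearchHit]:
    """Score every window of every (translated) frame; return hits with
    score >= ``min_score`` sorted by score desc, ties by (id, start) asc."""
    hits: List[SearchHit] = []
    for rec in db:
        for frame, rid, prot in _frames(rec, translate):
            if len(prot) < pssm.width:
                logger.info("record %s frame %s shorter than PSSM width; skipped",
                            rid, frame)
                continue
            sc = window_scores(pssm, prot)
            for start in np.nonzero(sc >= min_score)[0]:
                hits.append(SearchHit(rid, int(start), frame, float(sc[start])))
    hits.sort(key=lambda h: (-h.score, h.db_id, h.frame, h.start))
    return hits


def best_database_score(pssm: PSSM, db: Sequence[SequenceRecord],
                        translate: bool = False) -> float:
    """Maximum window score over the whole database (-inf if unscannable)."""
    best = -np.inf
    for rec in db:
        for frame, _rid, prot in _frames(rec, translate):
            if len(prot) < pssm.width:
                continue
            sc = window_scores(pssm, prot)
            if sc.size:
                best = max(best, float(sc.max()))
    return best


def empirical_significance(
    hit: SearchHit,
    pssm: PSSM,
    db: Sequence[SequenceRecord],
    n_shuffles: int = 200,
    seed: int = 0,
    translate: bool = False,
) -> SearchHit:
    """Attach a permutation p-value to a hit.

    For each of ``n_shuffles`` replicates, residues are permuted within each
    database record and the best window score of the shuffled database is
    recorded; with k replicates whose best score >= hit.score,
    p = (k + 1) / (n_shuffles + 1) (add-one estimator, so p is never 0).
    Deterministic given ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_shuffles):
        shuffled = []
        for rec in db:
            chars = np.array(list(rec.residues))
            rng.shuffle(chars)
            shuffled.append(SequenceRecord(rec.id, "".join(chars),
                                           alphabet=rec.alphabet))
        if best_database_score(pssm, shuffled, translate=translate) >= hit.score:
            k += 1
    return replace(hit, empirical_p=(k + 1) / (n_shuffles + 1))


def significant_hits(
    pssm: PSSM,
    db: Sequence[SequenceRecord],
    translate: bool = False,
    min_score: float = 0.0,
    n_shuffles: int = 200,
    seed: int = 0,
    p_max: float = 0.01,
) -> List[SearchHit]:
    """Scan, then keep hits whose permutation p-value is < ``p_max``.

    The permutation null (best score of each shuffled database) is computed
    once and reused for every candidate hit, which preserves the per-hit
    definition of :func:`empirical_significance` exactly.
    """
    hits = scan_database(pssm, db, translate=translate, min_score=min_score)
    if not hits:
        return []
    rng = np.random.default_rng(seed)
    null_best = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = []
        for rec in db:
            chars = np.array(list(rec.residues))
            rng.shuffle(chars)
            shuffled.append(SequenceRecord(rec.id, "".join(chars),
                                           alphabet=rec.alphabet))
        null_best[i] = best_database_score(pssm, shuffled, translate=translate)
    out = []
    for h in hits:
        k = int(np.sum(null_best >= h.score))
        p = (k + 1) / (n_shuffles + 1)
        if p < p_max:
            out.append(replace(h, empirical_p=p))
    return out
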