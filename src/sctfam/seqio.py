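"""Sequence input/output and translation utilities.

Thin layer over Biopython providing the record type used throughout the
package, FASTA round-tripping, and six-frame translation of nucleotide
records for translated profile searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"

# IUPAC unambiguous + unknowns; unknown residues are kept as X / N.
_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYX*-")
_NUCLEOTIDE_CHARS = set("ACGTN")

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; message names the offending line."""


@dataclass
class SequenceRecord:
    """A named sequence with an explicit alphabet.

    ``description`` is everything after the first whitespace in the FASTA
    header; it is carried through but ignored by all computations.
    """

    id: str
    residues: str
    alphabet: str = PROTEIN
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.residues = self.residues.upper()
        if self.alphabet not in (PROTEIN, NUCLEOTIDE):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = _PROTEIN_CHARS if self.alphabet == PROTEIN else _NUCLEOTIDE_CHARS
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, alphabet: str = PROTEIN) -> List[SequenceRecord]:
    """Parse a FASTA file into an ordered list of :class:`SequenceRecord`.

    Order is preserved, multi-line bodies are concatenated, the header is
    split at the first whitespace into id and description. Duplicate ids and
    sequence data before the first ``>`` are errors; an empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: List[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        if header is None:
            return
        body = "".join(chunks)
        if not body:
            raise FastaParseError(
                f"{path}: record starting at line {header_line} has no sequence"
            )
        fields = header.split(None, 1)
        rid = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate id {rid!r} (line {header_line})")
        seen.add(rid)
        records.append(SequenceRecord(rid, body, alphabet=alphabet, description=desc))

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {i}")
                header_line = i
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first '>' at line {i}"
                    )
                chunks.append(line)
        flush(header_line)

    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA, ``width`` residues per line."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def reverse_complement(rec: SequenceRecord) -> SequenceRecord:
    """Reverse complement of a nucleotide record (N stays N)."""
    if rec.alphabet != NUCLEOTIDE:
        raise ValueError("reverse_complement requires a nucleotide record")
    return SequenceRecord(
        rec.id,
        str(Seq(rec.residues).reverse_complement()),
        alphabet=NUCLEOTIDE,
        description=rec.description,
    )


def translate_six_frames(rec: SequenceRecord) -> List[SequenceRecord]:
    """Translate a nucleotide record in all six reading frames.

    Returns protein records in frame order +1, +2, +3, -1, -2, -3 with ids
    ``<id>|<frame>``. Standard genetic code; stop codons rendered as ``*``;
    codons containing N translate to X. Frame ``f`` with offset
    ``o = |f|-1`` on a length-``n`` sequence yields ``(n - o) // 3``
    residues; frames with zero complete codons are omitted from the list
    (so a 3 nt record yields only frames +1 and -1).
    """
    if rec.alphabet != NUCLEOTIDE:
        raise ValueError("translate_six_frames requires a nucleotide record")
    n = len(rec.residues)
    if n < 3:
        raise ValueError(f"record {rec.id!r}: length {n} < 3, cannot translate")

    out: List[SequenceRecord] = []
    rc = reverse_complement(rec).residues
    for frame in FRAMES:
        offset = int(frame[1]) - 1
        src = rec.residues if frame[0] == "+" else rc
        usable = (n - offset) // 3 * 3
        if usable == 0:
            continue
        codons = src[offset : offset + usable]
        prot = str(Seq(codons).translate())
        out.append(
            SequenceRecord(
                f"{rec.id}|{frame}",
                prot,
                alphabet=PROTEIN,
                description=f"frame={frame} source={rec.id}",
            )
        )
    return out
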