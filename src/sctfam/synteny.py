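"""Gene-neighborhood (synteny) comparison and gene-cluster testing.

Homologous genomic neighborhoods are compared for shared flanking genes and
conservation of gene order; loci on one chromosome are tested for physical
clustering within a maximum span. Homology between gene symbols is resolved
by an explicit user-supplied map (the module tests arrangement, not
homology inference). Coordinates are 0-based half-open internally;
published 1-based intervals — including minus-strand intervals printed
high-to-low — are normalised on ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

GeneTuple = Tuple[str, int, int, str]  # symbol, start, end, strand


@dataclass(frozen=True)
class Gene:
    symbol: str
    start: int
    end: int
    strand: str = "+"
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.symbol}: negative coordinate {self.start}")
        if self.start >= self.end:
            raise ValueError(f"{self.symbol}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.symbol}: invalid strand {self.strand!r}")


@dataclass
class GeneNeighborhood:
    """Ordered, stranded gene list on one chromosome/scaffold."""

    genome: str
    chrom: str
    genes: List[Gene]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("neighborhood must contain at least one gene")
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            dup = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in neighborhood: {dup}")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))

    @property
    def span(self) -> int:
        return self.genes[-1].end - self.genes[0].start

    @property
    def symbols(self) -> List[str]:
        return [g.symbol for g in self.genes]


def normalise_interval(a: int, b: int, one_based: bool = True) -> Tuple[int, int, str]:
    """Normalise a published interval to 0-based half-open (start, end, strand).

    Intervals printed high-to-low denote minus-strand genes; 1-based inclusive
    input is converted by decrementing the start.
    """
    strand = "+"
    if a > b:
        a, b = b, a
        strand = "-"
    if one_based:
        a -= 1
    return a, b, strand


def read_gene_table(path: str | Path, genome: str = "") -> List[GeneNeighborhood]:
    """Read a BED-like TSV (chrom, start, end, strand, symbol; 0-based
    half-open) into one neighborhood per chromosome.

    Lines starting with '#' are skipped; a header row is detected by a
    non-numeric start column. Validation errors name the line number.
    """
    path = Path(path)
    rows: List[Tuple[int, str, int, int, str, str]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected 5 tab-separated columns, "
                                 f"got {len(parts)}")
            chrom, start_s, end_s, strand, symbol = parts[:5]
            if ln == 1 and not start_s.lstrip("-").isdigit():
                continue  # header row
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            try:
                Gene(symbol, start, end, strand, chrom)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
            rows.append((ln, chrom, start, end, strand, symbol))
    by_chrom: Dict[str, List[Gene]] = {}
    for ln, chrom, start, end, strand, symbol in rows:
        by_chrom.setdefault(chrom, []).append(Gene(symbol, start, end, strand, chrom))
    out = []
    for chrom, genes in by_chrom.items():
        try:
            out.append(GeneNeighborhood(genome or path.stem, chrom, genes))
        except ValueError as exc:
            raise ValueError(f"{path}: chromosome {chrom}: {exc}") from exc
    return out


class HomologyMap:
    """Disjoint equivalence classes of gene symbols across genomes.

    Symbols absent from every class are treated as singleton classes keyed
    by the symbol itself.
    """

    def __init__(self, classes: Iterable[Iterable[str]]):
        self._class_of: Dict[str, FrozenSet[str]] = {}
        self.classes: List[FrozenSet[str]] = []
        for cls in classes:
            fs = frozenset(cls)
            if not fs:
                continue
            overlap = fs & self._class_of.keys()
            if overlap:
                raise ValueError(f"symbol(s) {sorted(overlap)} appear in more "
                                 f"than one homology class")
            self.classes.append(fs)
            for s in fs:
                self._class_of[s] = fs
        self.classes.sort(key=lambda fs: tuple(sorted(fs)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologyMap":
        """One class per line, tab-separated symbols."""
        classes = []
        with open(path) as fh:
            for line in fh:
                syms = [s for s in line.strip().split("\t") if s]
                if syms:
                    classes.append(syms)
        return cls(classes)

    def class_of(self, symbol: str) -> FrozenSet[str]:
        return self._class_of.get(symbol, frozenset([symbol]))

    def class_key(self, symbol: str) -> Tuple[str, ...]:
        return tuple(sorted(self.class_of(symbol)))


@dataclass
class SyntenyReport:
    """Outcome of a pairwise neighborhood comparison."""

    genome_a: str
    genome_b: str
    shared_classes: List[Tuple[str, ...]]
    order_conservation: int  # LCS length over shared-class order
    coordinates: Dict[str, List[dict]]

    @property
    def shared_count(self) -> int:
        return len(self.shared_classes)

    def __post_init__(self) -> None:
        if self.order_conservation > self.shared_count:
            raise ValueError("order-conservation length exceeds shared count")

    def to_json(self) -> str:
        return json.dumps(
            {"genome_a": self.genome_a, "genome_b": self.genome_b,
             "shared_count": self.shared_count,
             "shared_classes": [list(c) for c in self.shared_classes],
             "order_conservation": self.order_conservation,
             "coordinates": self.coordinates},
            indent=2,
        )


def _lcs_length(a: Sequence, b: Sequence) -> int:
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def shared_flanking(
    a: GeneNeighborhood,
    b: GeneNeighborhood,
    hmap: HomologyMap,
) -> SyntenyReport:
    """Shared homology classes between two neighborhoods, with gene-order
    conservation measured as the longest common subsequence of the shared
    classes in each neighborhood's positional order (first occurrence per
    class)."""
    keys_a = [hmap.class_key(s) for s in a.symbols]
    keys_b = [hmap.class_key(s) for s in b.symbols]
    shared = sorted(set(keys_a) & set(keys_b))
    shared_set = set(shared)

    def order(keys: List[Tuple[str, ...]]) -> List[Tuple[str, ...]]:
        seen = set()
        seq = []
        for k in keys:
            if k in shared_set and k not in seen:
                seen.add(k)
                seq.append(k)
        return seq

    lcs = _lcs_length(order(keys_a), order(keys_b))
    coords = {
        a.genome: [{"symbol": g.symbol, "chrom": a.chrom, "start": g.start,
                    "end": g.end, "strand": g.strand} for g in a.genes
                   if hmap.class_key(g.symbol) in shared_set],
        b.genome: [{"symbol": g.symbol, "chrom": b.chrom, "start": g.start,
                    "end": g.end, "strand": g.strand} for g in b.genes
                   if hmap.class_key(g.symbol) in shared_set],
    }
    return SyntenyReport(a.genome, b.genome, shared, lcs, coords)


def cluster_test(
    genes: Sequence,
    max_span: int = 1_000_000,
) -> Tuple[bool, int]:
    """Do loci on one chromosome form a cluster within ``max_span`` bp?

    ``genes`` is a sequence of :class:`Gene` / (symbol, start, end) tuples,
    or a :class:`GeneNeighborhood`. Span = max(end) - min(start); clustered
    iff span <= max_span. Mixed chromosomes (when recorded) are an error.
    """
    if isinstance(genes, GeneNeighborhood):
        items = genes.genes
    else:
        items = [g if isinstance(g, Gene) else Gene(g[0], g[1], g[2])
                 for g in genes]
    if not items:
        raise ValueError("cluster_test requires at least one gene")
    chroms = {g.chrom for g in items if g.chrom}
    if len(chroms) > 1:
        raise ValueError(f"genes span multiple chromosomes: {sorted(chroms)}")
    span = max(g.end for g in items) - min(g.start for g in items)
    return span <= max_span, span


# ---------------------------------------------------------------------------
# Worked-example inputs transcribed from the published comparative analysis.

#: C. elegans chromosome-I homologues of the vertebrate flanking genes,
#: printed 1-based (two minus-strand loci given high-to-low), normalised
#: here to 0-based half-open.
def _published_gene(symbol: str, a: int, b: int, chrom: str) -> Gene:
    start, end, strand = normalise_interval(a, b)
    return Gene(symbol, start, end, strand, chrom=chrom)


CELEGANS_CHRI_LOCI: List[Gene] = [
    _published_gene("src-1", 1566932, 1580204, "I"),
    _published_gene("M01A10.3", 5550508, 5549145, "I"),
    _published_gene("drh-3", 7820837, 7826373, "I"),
    _published_gene("abts-1", 8307558, 8296909, "I"),
]

#: Flanking genes shared between vertebrate genomes per family locus:
#: GCG/GLP shares KCNH7, IFIH1 and SLC4A10; PRP/PACAP shares YES1 and
#: METTL4; GHRH shares RPN2.
VERTEBRATE_SHARED_FLANKING: Dict[str, List[str]] = {
    "GCG/GLP": ["KCNH7", "IFIH1", "SLC4A10"],
    "PRP/PACAP": ["YES1", "METTL4"],
    "GHRH": ["RPN2"],
}
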