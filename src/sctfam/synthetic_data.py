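"""Synthetic peptide families, decoy databases and genome gene tables.

The generator emulates the evolutionary scenario the analysis assumes: a
single ancestral 27-residue peptide exon duplicated into two subfamilies,
each subfamily duplicated into several peptide groups, and each group
sampled across taxa along a shared species tree. Strongly conserved anchor
columns, group-specific signature columns with forced residues, mature
peptides embedded in longer precursors, decoy proteomes/nucleotide sets
free of the family motif, and genomes with implanted conserved flanking
blocks (plus a protostome-like decoy genome carrying the flanking
homologues scattered without a family gene) provide ground truth for every
downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .consensus_profile import AMINO_ACIDS, ConsensusPattern, DEFAULT_SCHEME, SimilarityScheme
from .maturome import PeptideSequence
from .seqio import NUCLEOTIDE, PROTEIN, SequenceRecord, translate_six_frames
from .synteny import Gene, GeneNeighborhood, HomologyMap, SyntenyReport

_AA = np.array(list(AMINO_ACIDS))


@dataclass
class FamilyConfig:
    """Parameters of the synthetic family.

    Substitution probabilities are per-column probabilities that a sequence
    differs from its immediate ancestor at that column; leaves diverge
    independently from their group ancestor. Anchor columns are near-frozen
    in every lineage; signature columns are near-frozen within their owner
    group and excluded from duplication divergence elsewhere, so each group
    retains a diagnostic residue.
    """

    width: int = 27
    n_subfamilies: int = 2
    groups_per_subfamily: int = 5
    n_taxa: int = 8
    anchor_columns: Tuple[int, ...] = (1, 3, 6, 7, 23)  # 1-based
    p_anchor: float = 0.02
    p_variable: float = 0.15
    subfamily_divergence: float = 0.7
    group_divergence: float = 0.25
    n_signature_per_group: int = 2
    signature_columns: Optional[Tuple[int, ...]] = None  # auto-chosen if None
    indel_prob: float = 0.0
    duplications_per_taxon: int = 0
    flank_len_range: Tuple[int, int] = (15, 40)
    n_decoy_proteins: int = 40
    decoy_protein_length: int = 300
    n_decoy_nt: int = 8
    decoy_nt_length: int = 600
    max_decoy_identity: float = 0.45
    n_flanking_genes: int = 4
    similarity_scheme: SimilarityScheme = field(default=DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        for name in ("p_anchor", "p_variable", "subfamily_divergence",
                     "group_divergence", "indel_prob", "max_decoy_identity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(not (1 <= c <= self.width) for c in self.anchor_columns):
            raise ValueError("anchor columns outside 1..width")
        if self.signature_columns is not None:
            bad = set(self.signature_columns) & set(self.anchor_columns)
            if bad:
                raise ValueError(
                    f"signature columns {sorted(bad)} overlap anchor columns")
            need = (self.n_subfamilies * self.groups_per_subfamily
                    * self.n_signature_per_group)
            if len(self.signature_columns) != need:
                raise ValueError(
                    f"need {need} signature columns, got {len(self.signature_columns)}")


@dataclass
class SpeciesTreeNode:
    """Ultrametric random species tree (root-to-leaf depth 1)."""

    taxa: Tuple[str, ...]
    length: float  # branch above this node
    children: Tuple["SpeciesTreeNode", ...] = ()

    def newick(self) -> str:
        if not self.children:
            return f"{self.taxa[0]}:{self.length:.4f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.4f}"


def _random_species_tree(taxa: Sequence[str], rng: np.random.Generator,
                         depth: float = 1.0, length: float = 0.0) -> SpeciesTreeNode:
    if len(taxa) == 1:
        return SpeciesTreeNode(tuple(taxa), length + depth)
    split_at = depth * rng.uniform(0.2, 0.8)
    k = int(rng.integers(1, len(taxa)))
    left, right = list(taxa[:k]), list(taxa[k:])
    child_depth = depth - split_at
    return SpeciesTreeNode(
        tuple(taxa), length,
        (
            _random_species_tree(left, rng, child_depth, split_at),
            _random_species_tree(right, rng, child_depth, split_at),
        ),
    )


def _substitute(residue: str, rng: np.random.Generator,
                scheme: SimilarityScheme, p_similar: float = 0.7) -> str:
    """Replace a residue: with probability ``p_similar`` by another member of
    its similarity group (if any), otherwise uniformly by any other residue."""
    group = [r for g in scheme.groups if residue in g for r in g if r != residue]
    if group and rng.random() < p_similar:
        return group[int(rng.integers(len(group)))]
    others = [r for r in AMINO_ACIDS if r != residue]
    return others[int(rng.integers(len(others)))]


def _diverge(seq: str, probs: np.ndarray, rng: np.random.Generator,
             scheme: SimilarityScheme) -> str:
    out = list(seq)
    hits = rng.random(len(seq)) < probs
    for i in np.nonzero(hits)[0]:
        out[i] = _substitute(out[i], rng, scheme)
    return "".join(out)




@dataclass
class GenomeSet:
    """Gene tables for two family-bearing genomes and a protostome-like
    decoy genome, with the homology map linking flanking-gene symbols."""

    neighborhoods: Dict[str, GeneNeighborhood]
    homology_map: HomologyMap
    implanted_classes: List[Tuple[str, ...]]
    decoy_genome: str = "decoy"


@dataclass
class SyntheticFamily:
    """Simulator output with ground truth for every downstream stage."""

    config: FamilyConfig
    seed: int
    ancestor: str
    subfamily_ancestors: Dict[str, str]
    group_ancestors: Dict[str, str]
    signatures: Dict[str, Set[Tuple[int, str]]]
    matures: List[PeptideSequence]
    precursors: List[SequenceRecord]
    species_tree_newick: str
    subfamily_of_group: Dict[str, str]
    decoy_proteome: List[SequenceRecord]
    decoy_nucleotides: List[SequenceRecord]
    genomes: GenomeSet

    @property
    def subfamily_labels(self) -> Dict[str, str]:
        """Leaf id -> subfamily, for monophyly checks."""
        return {m.id: m.subfamily for m in self.matures}


def _max_window_identity(protein: str, targets: Sequence[str], width: int) -> float:
    best = 0.0
    for t in targets:
        tarr = np.array(list(t))
        parr = np.array(list(protein))
        for s in range(0, len(protein) - width + 1):
            frac = float((parr[s : s + width] == tarr).mean())
            if frac > best:
                best = frac
    return best


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, 20, size=length)])


def _clean_decoy_protein(rng: np.random.Generator, length: int,
                         targets: Sequence[str], width: int,
                         ceiling: float) -> str:
    """Random protein guaranteed below the window-identity ceiling against
    every target motif (offending stretches are resampled)."""
    seq = _random_protein(rng, length)
    for _ in range(100):
        if _max_window_identity(seq, targets, width) <= ceiling:
            return seq
        seq = _random_protein(rng, length)
    raise RuntimeError("could not generate decoy below similarity ceiling")


def simulate_family(config: FamilyConfig, seed: int) -> SyntheticFamily:
    """Generate a synthetic peptide family with full ground truth.

    Deterministic: the same config and seed regenerate byte-identical
    sequences and tables.
    """
    rng = np.random.default_rng(seed)
    w = config.width
    scheme = config.similarity_scheme
    anchors0 = np.array([c - 1 for c in config.anchor_columns], dtype=int)

    subfam_names = [f"sub{i + 1}" for i in range(config.n_subfamilies)]
    groups: Dict[str, List[str]] = {
        s: [f"{s}g{j + 1}" for j in range(config.groups_per_subfamily)]
        for s in subfam_names
    }
    all_groups = [g for s in subfam_names for g in groups[s]]
    subfamily_of_group = {g: s for s in subfam_names for g in groups[s]}

    # Signature columns: disjoint across groups, never on anchors.
    if config.signature_columns is not None:
        sig_cols = list(config.signature_columns)
    else:
        free = [c for c in range(1, w + 1) if c not in config.anchor_columns]
        need = len(all_groups) * config.n_signature_per_group
        if need > len(free):
            raise ValueError(f"not enough non-anchor columns for {need} signatures")
        sig_cols = list(rng.choice(free, size=need, replace=False))
    sig_of_group: Dict[str, List[int]] = {}
    for k, g in enumerate(all_groups):
        lo = k * config.n_signature_per_group
        sig_of_group[g] = [int(c) for c in
                           sig_cols[lo : lo + config.n_signature_per_group]]

    # Ancestral exon and subfamily/group duplications.
    ancestor = _random_protein(rng, w)
    base_probs = np.full(w, config.p_variable)
    base_probs[anchors0] = config.p_anchor

    div_probs = np.full(w, config.subfamily_divergence)
    div_probs[anchors0] = 0.0
    subfamily_ancestors = {s: _diverge(ancestor, div_probs, rng, scheme)
                           for s in subfam_names}

    # Group divergence skips anchors and every signature column: non-owner
    # groups keep the subfamily-ancestor residue at signature columns, which
    # the forced residue is chosen to avoid, keeping signatures diagnostic.
    grp_probs = np.full(w, config.group_divergence)
    grp_probs[anchors0] = 0.0
    for c in sig_cols:
        grp_probs[int(c) - 1] = 0.0
    group_ancestors: Dict[str, str] = {}
    signatures: Dict[str, Set[Tuple[int, str]]] = {}
    for s in subfam_names:
        for g in groups[s]:
            ga = list(_diverge(subfamily_ancestors[s], grp_probs, rng, scheme))
            sigs: Set[Tuple[int, str]] = set()
            for c in sig_of_group[g]:
                # Forced residue distinct from every subfamily ancestor's
                # residue at this column, so it is diagnostic for the group.
                taken = {sa[c - 1] for sa in subfamily_ancestors.values()}
                choices = [r for r in AMINO_ACIDS if r not in taken]
                r = choices[int(rng.integers(len(choices)))]
                ga[c - 1] = r
                sigs.add((c, r))
            group_ancestors[g] = "".join(ga)
            signatures[g] = sigs

    # Taxon sampling. Each leaf diverges independently from its group
    # ancestor with the per-column probabilities, so realised per-column
    # substitution frequencies are binomial in the number of leaves — the
    # property parameter-recovery checks rely on. The generated species
    # tree is recorded as ground-truth metadata (taxon sampling depths),
    # not used to correlate substitutions across taxa.
    taxa = [f"tax{k + 1:02d}" for k in range(config.n_taxa)]
    tree = _random_species_tree(taxa, rng)
    matures: List[PeptideSequence] = []
    for g in all_groups:
        probs = base_probs.copy()
        for c in sig_of_group[g]:
            probs[c - 1] = config.p_anchor  # frozen within its own group
        leaf_seqs: Dict[str, str] = {
            t: _diverge(group_ancestors[g], probs, rng, scheme) for t in taxa}
        for t in taxa:
            copies = [("", leaf_seqs[t])]
            for d in range(config.duplications_per_taxon):
                extra = _diverge(leaf_seqs[t], probs * 0.5, rng, scheme)
                copies.append((chr(ord("a") + d + 1), extra))
            if config.duplications_per_taxon:
                copies[0] = ("a", copies[0][1])
            for suffix, seq in copies:
                if config.indel_prob and rng.random() < config.indel_prob:
                    var = [c for c in range(w) if c not in anchors0]
                    cut = var[int(rng.integers(len(var)))]
                    seq = seq[:cut] + "-" + seq[cut + 1 :]
                matures.append(PeptideSequence(
                    id=f"{g}_{t}{suffix}", residues=seq, taxon=t, group=g,
                    subfamily=subfamily_of_group[g], window=(1, w)))

    # Precursors: mature embedded between random flanks.
    lo, hi = config.flank_len_range
    precursors = []
    for m in matures:
        f5 = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        f3 = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        precursors.append(SequenceRecord(
            id=f"pre_{m.id}", residues=f5 + m.residues.replace("-", "") + f3,
            alphabet=PROTEIN,
            description=f"taxon={m.taxon} group={m.group} seed={seed}"))

    # Decoy databases, screened against the family motifs.
    targets = [ancestor] + list(subfamily_ancestors.values())
    decoy_proteome = [
        SequenceRecord(f"decoy_prot_{k + 1:03d}",
                       _clean_decoy_protein(rng, config.decoy_protein_length,
                                            targets, w, config.max_decoy_identity),
                       alphabet=PROTEIN, description=f"decoy seed={seed}")
        for k in range(config.n_decoy_proteins)
    ]
    nt = np.array(list("ACGT"))
    decoy_nucleotides = []
    for k in range(config.n_decoy_nt):
        for _ in range(100):
            seq = "".join(nt[rng.integers(0, 4, size=config.decoy_nt_length)])
            rec = SequenceRecord(f"decoy_nt_{k + 1:03d}", seq,
                                 alphabet=NUCLEOTIDE, description=f"decoy seed={seed}")
            frames = translate_six_frames(rec)
            if all(_max_window_identity(f.residues, targets, w)
                   <= config.max_decoy_identity for f in frames
                   if len(f.residues) >= w):
                decoy_nucleotides.append(rec)
                break
        else:
            raise RuntimeError("could not generate decoy nucleotide record")

    genomes = simulate_genomes(config, seed)

    return SyntheticFamily(
        config=config, seed=seed, ancestor=ancestor,
        subfamily_ancestors=subfamily_ancestors,
        group_ancestors=group_ancestors, signatures=signatures,
        matures=matures, precursors=precursors,
        species_tree_newick=tree.newick() + ";",
        subfamily_of_group=subfamily_of_group,
        decoy_proteome=decoy_proteome, decoy_nucleotides=decoy_nucleotides,
        genomes=genomes,
    )


def simulate_genomes(config: FamilyConfig, seed: int) -> GenomeSet:
    """Gene tables: two family-bearing genomes with an implanted, order-
    preserved flanking block around the family locus, and a decoy genome
    carrying homologues of the flanking genes scattered along one large
    chromosome (megabases apart) with no family gene."""
    # Independent stream: genome tables do not perturb sequence generation.
    rng = np.random.default_rng((seed, 7))
    nf = config.n_flanking_genes
    classes = []
    sym = {}
    for i in range(1, nf + 1):
        sa, sb, sd = f"FLK{i}", f"flk{i}", f"Cel-flk{i}"
        classes.append((sa, sb, sd))
        sym[i] = (sa, sb, sd)
    hmap = HomologyMap(classes)

    def build_block(genome: str, chrom: str, symbols: List[str],
                    family_symbol: Optional[str]) -> GeneNeighborhood:
        order = list(symbols)
        if family_symbol is not None:
            order.insert(nf // 2, family_symbol)
        genes = []
        pos = int(rng.integers(10_000, 50_000))
        for s in order:
            length = int(rng.integers(2_000, 15_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(s, pos, pos + length, strand, chrom=chrom))
            pos += length + int(rng.integers(5_000, 50_000))
        return GeneNeighborhood(genome, chrom, genes)

    neigh = {
        "genomeA": build_block("genomeA", "chr1", [sym[i][0] for i in range(1, nf + 1)], "FAM1"),
        "genomeB": build_block("genomeB", "scaf_12", [sym[i][1] for i in range(1, nf + 1)], "fam1"),
    }
    # Decoy: same homologues, one chromosome, > 2 Mb apart, no family gene.
    genes = []
    pos = int(rng.integers(100_000, 500_000))
    for i in range(1, nf + 1):
        length = int(rng.integers(2_000, 15_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(sym[i][2], pos, pos + length, strand, chrom="I"))
        pos += length + int(rng.integers(2_000_000, 4_000_000))
    neigh["decoy"] = GeneNeighborhood("decoy", "I", genes)
    implanted = [tuple(sorted(c)) for c in classes]
    return GenomeSet(neighborhoods=neigh, homology_map=hmap,
                     implanted_classes=sorted(implanted))


@dataclass
class RecoveryReport:
    """Scores of pipeline outputs against simulator ground truth.

    Metric definitions:
      consensus_position_accuracy — over the defined positions of each
        inferred subfamily consensus, the fraction whose residue equals the
        true subfamily ancestor at that position, averaged over subfamilies;
      signature_precision / signature_recall — on (group, position, residue)
        triples vs the configured signatures;
      monophyly_count — pass-through of the tree check (n_subfamilies = clean);
      search_top1 — 1.0 if the top database hit lies in a true family record;
      synteny_recall — fraction of implanted flanking classes recovered.
    """

    metrics: Dict[str, float]
    flags: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"metrics": self.metrics, "flags": self.flags,
                           "definitions": (self.__doc__ or "").strip()}, indent=2)


def recovery_report(
    truth: SyntheticFamily,
    consensus: Optional[Dict[str, ConsensusPattern]] = None,
    signatures: Optional[Dict[str, Set[Tuple[int, str]]]] = None,
    monophyly_count: Optional[int] = None,
    top_hit_id: Optional[str] = None,
    synteny: Optional[SyntenyReport] = None,
) -> RecoveryReport:
    """Score inferred pipeline outputs against the simulator's ground truth."""
    metrics: Dict[str, float] = {}
    flags: List[str] = []

    if consensus is not None:
        unknown = set(consensus) - set(truth.subfamily_ancestors)
        if unknown:
            raise ValueError(f"unknown subfamily ids in consensus: {sorted(unknown)}")
        accs = []
        for s, pat in consensus.items():
            true_seq = truth.subfamily_ancestors[s]
            if pat.width != len(true_seq):
                raise ValueError(f"consensus width mismatch for {s}")
            defined = sorted(pat.defined_positions)
            if not defined:
                accs.append(0.0)
                flags.append(f"consensus for {s} defines no positions")
                continue
            ok = sum(pat.positions[p] == true_seq[p - 1] for p in defined)
            accs.append(ok / len(defined))
        metrics["consensus_position_accuracy"] = float(np.mean(accs))

    if signatures is not None:
        unknown = set(signatures) - set(truth.signatures)
        if unknown:
            raise ValueError(f"unknown groups in signatures: {sorted(unknown)}")
        true_set = {(g, p, r) for g, ss in truth.signatures.items() for p, r in ss}
        inf_set = {(g, p, r) for g, ss in signatures.items() for p, r in ss}
        tp = len(true_set & inf_set)
        metrics["signature_recall"] = tp / len(true_set) if true_set else 1.0
        metrics["signature_precision"] = tp / len(inf_set) if inf_set else 0.0
        if not inf_set:
            flags.append("no signatures inferred")

    if monophyly_count is not None:
        metrics["monophyly_count"] = float(monophyly_count)

    if top_hit_id is not None:
        family_ids = {r.id for r in truth.precursors} | {m.id for m in truth.matures}
        base = top_hit_id.rsplit("|", 1)[0]
        metrics["search_top1"] = 1.0 if (top_hit_id in family_ids
                                         or base in family_ids) else 0.0

    if synteny is not None:
        implanted = set(truth.genomes.implanted_classes)
        found = {tuple(c) for c in synteny.shared_classes}
        metrics["synteny_recall"] = (len(implanted & found) / len(implanted)
                                     if implanted else 1.0)

    if not metrics:
        flags.append("no inferred outputs supplied")
    return RecoveryReport(metrics=metrics, flags=flags)
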