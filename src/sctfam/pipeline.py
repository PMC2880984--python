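"""End-to-end orchestration: simulate/load -> extract -> consensus ->
prototype -> profile search -> tree -> synteny -> recovery report.

The stage order mirrors the comparative workflow: mature-peptide windows
are assembled first, per-subfamily consensuses derived and fused into the
prototype, the prototype PSSM is searched against positive and decoy
databases with permutation significance, the family tree is built with
bootstrap and checked for the two-subfamily bipartition, and gene
neighborhoods are compared. Every artifact is persisted under the output
directory together with the resolved configuration, so a re-run with the
same seed reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from . import __version__
from .consensus_profile import (AlignmentBlock, ConsensusPattern, column_profile,
                                derive_consensus, fuse_prototype)
from .maturome import PeptideSequence, extract_mature
from .phylo import bootstrap_support, check_subfamily_monophyly, nj_tree, pdistance_matrix
from .profile_search import build_pssm, scan_database, significant_hits
from .seqio import SequenceRecord, write_fasta
from .synteny import cluster_test, shared_flanking
from .synthetic_data import FamilyConfig, SyntheticFamily, recovery_report, simulate_family

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure; message names the stage, prior artifacts are kept."""


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    ``seed`` is mandatory whenever a stochastic stage (simulation, search
    significance, bootstrap) is enabled.
    """

    outdir: Path
    seed: Optional[int] = None
    simulate: Dict[str, Any] = field(default_factory=dict)
    tau: float = 0.5
    pssm_alpha: float = 1.0
    n_shuffles: int = 200
    p_max: float = 0.01
    min_score: float = 0.0
    bootstrap_reps: int = 100
    max_span: int = 1_000_000
    tau_in: float = 0.8
    tau_out: float = 0.2
    min_extract_identity: float = 25.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise ValueError("config must set 'outdir'")
        raw["outdir"] = Path(raw["outdir"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        stochastic = bool(self.simulate) or self.n_shuffles > 0 or self.bootstrap_reps > 0
        if stochastic and self.seed is None:
            raise ValueError("seed is mandatory when stochastic stages are enabled")


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Run every stage; return the report dict (also written to report.json)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict[str, Any] = {
        "version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    # --- simulate ---------------------------------------------------------
    st = stage("simulate")
    try:
        fam_cfg = FamilyConfig(**config.simulate)
        fam = simulate_family(fam_cfg, seed=config.seed)
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc
    write_fasta(fam.precursors, out / "precursors.fasta")
    mature_recs = [SequenceRecord(m.id, m.residues.replace("-", "X"),
                                  description=f"taxon={m.taxon} group={m.group} "
                                              f"subfamily={m.subfamily}")
                   for m in fam.matures]
    write_fasta(mature_recs, out / "matures.fasta")
    write_fasta(fam.decoy_proteome, out / "decoy_proteome.fasta")
    write_fasta(fam.decoy_nucleotides, out / "decoy_nucleotides.fasta")
    (out / "species_tree.nwk").write_text(fam.species_tree_newick + "\n")
    st.update(n_matures=len(fam.matures), n_precursors=len(fam.precursors),
              n_decoy_proteins=len(fam.decoy_proteome))

    # --- extract ----------------------------------------------------------
    st = stage("extract")
    try:
        extracted: List[PeptideSequence] = []
        provenance = []
        refs = {g: PeptideSequence(id=f"ref_{g}", residues=seq, group=g,
                                   subfamily=fam.subfamily_of_group[g])
                for g, seq in fam.group_ancestors.items()}
        for pre in fam.precursors:
            meta = dict(kv.split("=") for kv in pre.description.split() if "=" in kv)
            ref = refs[meta["group"]]
            res = extract_mature(pre, ref, min_identity=config.min_extract_identity,
                                 taxon=meta.get("taxon", ""))
            provenance.append({"precursor": pre.id, "reference": ref.id,
                               "identity_pct": round(res.identity_pct, 2),
                               "found": res.found})
            if res.peptide is not None:
                extracted.append(dataclasses.replace(
                    res.peptide, id=pre.id.removeprefix("pre_")))
        if not extracted:
            raise ValueError("no mature peptides extracted")
        block = AlignmentBlock(extracted)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"extract: {exc}") from exc
    with open(out / "extraction.tsv", "w") as fh:
        fh.write("precursor\treference\tidentity_pct\tfound\n")
        for row in provenance:
            fh.write("{precursor}\t{reference}\t{identity_pct}\t{found}\n".format(**row))
    st.update(n_extracted=len(extracted), n_precursors=len(fam.precursors))

    # --- consensus + prototype -------------------------------------------
    st = stage("consensus")
    try:
        sub_blocks = block.by_subfamily()
        consensuses = {s: derive_consensus(column_profile(b), tau=config.tau, source=s)
                       for s, b in sub_blocks.items()}
        subs = sorted(consensuses)
        if len(subs) != 2:
            raise ValueError(f"expected 2 subfamilies, got {subs}")
        prototype = fuse_prototype(consensuses[subs[0]], consensuses[subs[1]])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"consensus: {exc}") from exc
    for s, pat in consensuses.items():
        (out / f"consensus_{s}.json").write_text(pat.to_json() + "\n")
    (out / "prototype.json").write_text(prototype.to_json() + "\n")
    write_fasta([SequenceRecord("prototype", prototype.to_string().replace("x", "X"),
                                description=f"tau={config.tau}")],
                out / "prototype.fasta")
    st.update(prototype=prototype.to_string(),
              defined_positions=len(prototype.positions))

    # --- profile search ---------------------------------------------------
    st = stage("search")
    try:
        pssm = build_pssm(prototype, alpha=config.pssm_alpha)
        pos_hits = scan_database(pssm, fam.precursors, min_score=config.min_score)
        decoy_sig = significant_hits(
            pssm, fam.decoy_proteome, min_score=config.min_score,
            n_shuffles=config.n_shuffles, seed=config.seed, p_max=config.p_max)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"search: {exc}") from exc
    with open(out / "hits.tsv", "w") as fh:
        fh.write("db_id\tframe\tstart\tscore_bits\tempirical_p\n")
        for h in pos_hits[:200]:
            fh.write(f"{h.db_id}\t{h.frame}\t{h.start}\t{h.score:.3f}\t\n")
        for h in decoy_sig:
            fh.write(f"{h.db_id}\t{h.frame}\t{h.start}\t{h.score:.3f}\t{h.empirical_p:.4g}\n")
    st.update(n_positive_hits=len(pos_hits),
              top_hit=pos_hits[0].db_id if pos_hits else None,
              n_decoy_significant=len(decoy_sig))

    # --- phylogeny --------------------------------------------------------
    st = stage("tree")
    try:
        tree, support = bootstrap_support(block, n_reps=config.bootstrap_reps,
                                          seed=config.seed)
        mono = check_subfamily_monophyly(tree, fam.subfamily_labels)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"tree: {exc}") from exc
    (out / "tree.nwk").write_text(str(tree).strip() + "\n")
    st.update(monophyly_count=mono,
              n_bipartitions=len(support),
              max_support=max(support.values()) if support else None)

    # --- synteny ----------------------------------------------------------
    st = stage("synteny")
    try:
        gs = fam.genomes
        rep = shared_flanking(gs.neighborhoods["genomeA"], gs.neighborhoods["genomeB"],
                              gs.homology_map)
        clustered, span = cluster_test(gs.neighborhoods["decoy"],
                                       max_span=config.max_span)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"synteny: {exc}") from exc
    (out / "synteny.json").write_text(rep.to_json() + "\n")
    st.update(shared_count=rep.shared_count, order_conservation=rep.order_conservation,
              decoy_clustered=clustered, decoy_span=span)

    # --- recovery ---------------------------------------------------------
    st = stage("recovery")
    try:
        inferred_sigs = None
        group_blocks = block.by_group()
        if len(group_blocks) >= 2:
            from .consensus_profile import signature_residues
            inferred_sigs = signature_residues(group_blocks, tau_in=config.tau_in,
                                               tau_out=config.tau_out)
        rec = recovery_report(
            fam,
            consensus=consensuses,
            signatures=inferred_sigs,
            monophyly_count=mono,
            top_hit_id=pos_hits[0].db_id if pos_hits else None,
            synteny=rep,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"recovery: {exc}") from exc
    (out / "recovery.json").write_text(rec.to_json() + "\n")
    st.update(**rec.metrics)

    _dump_json(report, out / "report.json")
    return report
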