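import numpy as np
import pytest

from sctfam.consensus_profile import (AlignmentBlock, ConsensusPattern,
                                      column_profile, derive_consensus,
                                      signature_residues)
from sctfam.seqio import write_fasta
from sctfam.synthetic_data import FamilyConfig, recovery_report, simulate_family


def test_config_validation():
    with pytest.raises(ValueError, match="outside"):
        FamilyConfig(p_variable=1.5)
    with pytest.raises(ValueError, match="overlap anchor"):
        FamilyConfig(anchor_columns=(1, 2), n_subfamilies=1,
                     groups_per_subfamily=1, n_signature_per_group=1,
                     signature_columns=(2,))


def test_zero_rate_limit_all_identical_to_ancestor():
    cfg = FamilyConfig(p_anchor=0.0, p_variable=0.0, subfamily_divergence=0.0,
                       group_divergence=0.0, n_signature_per_group=0,
                       n_subfamilies=1, groups_per_subfamily=2, n_taxa=4)
    fam = simulate_family(cfg, seed=5)
    for m in fam.matures:
        assert m.residues == fam.ancestor
    block = AlignmentBlock(fam.matures)
    for tau in (0.2, 0.7, 1.0):
        assert derive_consensus(column_profile(block), tau=tau).to_string() == \
            fam.ancestor


def test_zero_noise_groups_equal_their_ancestors():
    cfg = FamilyConfig(p_anchor=0.0, p_variable=0.0, n_taxa=4)
    fam = simulate_family(cfg, seed=2)
    by_group = AlignmentBlock(fam.matures).by_group()
    for g, block in by_group.items():
        for m in block.members:
            assert m.residues == fam.group_ancestors[g]
        cons = derive_consensus(column_profile(block), tau=1.0)
        assert cons.to_string() == fam.group_ancestors[g]
    sigs = signature_residues(by_group, tau_in=0.8, tau_out=0.2)
    for g in by_group:
        assert sigs[g] >= fam.signatures[g]


def test_same_seed_regenerates_identical_fasta(tmp_path):
    cfg = FamilyConfig(n_taxa=4)
    f1 = simulate_family(cfg, seed=9)
    f2 = simulate_family(cfg, seed=9)
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    write_fasta(f1.precursors, p1)
    write_fasta(f2.precursors, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert f1.species_tree_newick == f2.species_tree_newick
    g1 = {k: [ (g.symbol, g.start, g.end) for g in v.genes ]
          for k, v in f1.genomes.neighborhoods.items()}
    g2 = {k: [ (g.symbol, g.start, g.end) for g in v.genes ]
          for k, v in f2.genomes.neighborhoods.items()}
    assert g1 == g2
    f3 = simulate_family(cfg, seed=10)
    assert f3.ancestor != f1.ancestor


def test_realised_substitution_frequency_within_binomial_ci():
    """Per-column mismatch frequency vs the ancestor over 500 leaf
    sequences stays inside the 99% binomial interval of the configured
    per-column probability."""
    cfg = FamilyConfig(n_subfamilies=1, groups_per_subfamily=1, n_taxa=500,
                       subfamily_divergence=0.0, group_divergence=0.0,
                       n_signature_per_group=0, n_decoy_proteins=2,
                       n_decoy_nt=1)
    fam = simulate_family(cfg, seed=13)
    seqs = np.array([list(m.residues) for m in fam.matures])
    anc = np.array(list(fam.ancestor))
    freq = (seqs != anc).mean(axis=0)
    z = 2.576
    for col in range(cfg.width):
        p = cfg.p_anchor if (col + 1) in cfg.anchor_columns else cfg.p_variable
        half = z * np.sqrt(p * (1 - p) / cfg.n_taxa)
        assert abs(freq[col] - p) <= half + 1e-12, (col, freq[col], p)


def test_decoys_respect_similarity_ceiling():
    cfg = FamilyConfig(n_taxa=3, n_decoy_proteins=5, n_decoy_nt=2)
    fam = simulate_family(cfg, seed=21)
    anc = np.array(list(fam.ancestor))
    for rec in fam.decoy_proteome:
        arr = np.array(list(rec.residues))
        best = max((arr[s:s + cfg.width] == anc).mean()
                   for s in range(len(rec.residues) - cfg.width + 1))
        assert best <= cfg.max_decoy_identity


def test_duplications_produce_suffixed_copies():
    cfg = FamilyConfig(n_taxa=2, duplications_per_taxon=1,
                       n_decoy_proteins=2, n_decoy_nt=1)
    fam = simulate_family(cfg, seed=4)
    ids = {m.id for m in fam.matures}
    assert any(i.endswith("a") for i in ids) and any(i.endswith("b") for i in ids)
    assert len(fam.matures) == cfg.n_subfamilies * cfg.groups_per_subfamily * 2 * 2


# --- recovery report -------------------------------------------------------

@pytest.fixture(scope="module")
def small_family():
    return simulate_family(FamilyConfig(n_taxa=4, n_decoy_proteins=3,
                                        n_decoy_nt=1), seed=3)


def test_recovery_perfect_inference_scores_one(small_family):
    fam = small_family
    consensus = {s: ConsensusPattern(
        fam.config.width,
        {p: r for p, r in enumerate(seq, start=1)}, source=s)
        for s, seq in fam.subfamily_ancestors.items()}
    rep = recovery_report(fam, consensus=consensus,
                          signatures=fam.signatures,
                          monophyly_count=2)
    assert rep.metrics["consensus_position_accuracy"] == 1.0
    assert rep.metrics["signature_recall"] == 1.0
    assert rep.metrics["signature_precision"] == 1.0
    assert rep.metrics["monophyly_count"] == 2.0


def test_recovery_counts_wrong_positions(small_family):
    fam = small_family
    s = sorted(fam.subfamily_ancestors)[0]
    seq = fam.subfamily_ancestors[s]
    positions = {p: r for p, r in enumerate(seq, start=1)}
    wrong = {p: ("A" if seq[p - 1] != "A" else "C") for p in (1, 2, 3)}
    positions.update(wrong)  # 3 wrong of width defined
    pat = ConsensusPattern(fam.config.width, positions, source=s)
    rep = recovery_report(fam, consensus={s: pat})
    d = fam.config.width
    assert rep.metrics["consensus_position_accuracy"] == pytest.approx((d - 3) / d)


def test_recovery_empty_inference_flagged(small_family):
    fam = small_family
    rep = recovery_report(fam, signatures={g: set() for g in fam.signatures})
    assert rep.metrics["signature_recall"] == 0.0
    assert rep.metrics["signature_precision"] == 0.0
    assert any("no signatures" in f for f in rep.flags)


def test_recovery_identifier_mismatch_errors(small_family):
    fam = small_family
    with pytest.raises(ValueError, match="unknown"):
        recovery_report(fam, signatures={"nope": set()})
    with pytest.raises(ValueError, match="unknown"):
        recovery_report(fam, consensus={"nope": ConsensusPattern(27, {})})
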