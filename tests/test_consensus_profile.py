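import math
import random

import pytest

from sctfam.consensus_profile import (DEFAULT_SCHEME, GCG_LIKE_CONSENSUS,
                                      PACAP_LIKE_CONSENSUS, AlignmentBlock,
                                      ConsensusPattern, SimilarityScheme,
                                      column_profile, derive_consensus,
                                      fuse_prototype, percent_identity,
                                      percent_similarity, signature_residues)


def test_uniform_block_frequencies(block_factory):
    block = block_factory(["HSD", "HSD", "HSD", "HSD"])
    prof = column_profile(block)
    for pos, res in enumerate("HSD", start=1):
        assert prof.frequencies(pos) == {res: 1.0}


def test_column_counts_and_gap_exclusion(block_factory):
    prof = column_profile(block_factory(["H", "H", "H", "Y"]))
    assert prof.frequencies(1) == {"H": 0.75, "Y": 0.25}
    prof = column_profile(block_factory(["H", "-", "H", "-"]))
    assert prof.frequencies(1) == {"H": 1.0}
    assert prof.gap_counts[0] == 2


def test_consensus_threshold_sweep(block_factory):
    prof = column_profile(block_factory(["H", "H", "H", "Y"]))
    assert derive_consensus(prof, tau=0.6).positions == {1: "H"}
    assert derive_consensus(prof, tau=0.8).positions == {}


def test_consensus_single_sequence_and_tie(block_factory):
    prof = column_profile(block_factory(["HSDGT"]))
    assert derive_consensus(prof, tau=1.0).to_string() == "HSDGT"
    tied = column_profile(block_factory(["H", "H", "Y", "Y"]))
    assert derive_consensus(tied, tau=0.5).positions == {}


def test_consensus_of_copies_equals_sequence_any_tau(block_factory):
    prof = column_profile(block_factory(["HADGTF"] * 7))
    for tau in (0.1, 0.5, 1.0):
        assert derive_consensus(prof, tau=tau).to_string() == "HADGTF"


def test_invalid_tau_rejected(block_factory):
    prof = column_profile(block_factory(["H"]))
    for tau in (0.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            derive_consensus(prof, tau=tau)


def test_percent_identity_values():
    assert percent_identity("H" * 27, "H" * 27) == 100.0
    assert percent_identity("A" * 27, "C" * 27) == 0.0
    # 13 matching of 27 comparable columns
    a = "A" * 27
    b = "A" * 13 + "C" * 14
    assert round(percent_identity(a, b), 2) == 48.15


def test_percent_identity_edge_cases():
    with pytest.raises(ValueError, match="width"):
        percent_identity("AA", "AAA")
    assert math.isnan(percent_identity("x-", "-x"))  # nothing comparable


def test_percent_similarity_uses_scheme():
    # 10 columns: 4 identical, 2 similar (I~L, D~E), 4 dissimilar
    a = "AAAAIDKKKK"
    b = "AAAALEWWWW"
    assert percent_identity(a, b) == pytest.approx(40.0)
    assert percent_similarity(a, b) == pytest.approx(60.0)


def test_similarity_at_least_identity_random():
    rng = random.Random(1)
    for _ in range(50):
        a = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(20))
        b = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(20))
        assert percent_similarity(a, b) >= percent_identity(a, b)
        assert percent_similarity(a, b) == percent_similarity(b, a)


def test_similarity_scheme_must_partition():
    with pytest.raises(ValueError):
        SimilarityScheme("bad", (frozenset("ILMV"), frozenset("VA")))
    with pytest.raises(ValueError):
        SimilarityScheme("incomplete", (frozenset("ILMV"),))
    assert DEFAULT_SCHEME.similar("I", "L")
    assert not DEFAULT_SCHEME.similar("I", "D")


def test_fuse_prototype_printed_subfamily_consensuses():
    fused = fuse_prototype(PACAP_LIKE_CONSENSUS, GCG_LIKE_CONSENSUS)
    assert fused.to_string() == "HADGTFTSDYSxxLxQxxAKxFxxWLx"
    assert len(fused.defined_positions) == 18
    assert 23 not in fused.positions  # L/V conflict -> wildcard
    # agreement positions defined in both inputs
    both = PACAP_LIKE_CONSENSUS.defined_positions & GCG_LIKE_CONSENSUS.defined_positions
    agree = {p for p in both
             if PACAP_LIKE_CONSENSUS.positions[p] == GCG_LIKE_CONSENSUS.positions[p]}
    assert agree == {1, 6}


def test_fuse_prototype_properties_against_oracle():
    rng = random.Random(7)

    def random_pattern(width=12):
        pos = {p: rng.choice("ACDEFGHIKLMNPQRSTVWY")
               for p in range(1, width + 1) if rng.random() < 0.5}
        return ConsensusPattern(width, pos)

    for _ in range(40):
        A, B = random_pattern(), random_pattern()
        fused = fuse_prototype(A, B)
        # exhaustive position-by-position oracle
        for p in range(1, 13):
            ra, rb = A.positions.get(p), B.positions.get(p)
            if ra and rb:
                expect = ra if ra == rb else None
            else:
                expect = ra or rb
            assert fused.positions.get(p) == expect
        assert fuse_prototype(B, A).positions == fused.positions
        assert fuse_prototype(A, A).positions == A.positions
        conflicts = {p for p in A.defined_positions & B.defined_positions
                     if A.positions[p] != B.positions[p]}
        assert fused.defined_positions == \
            (A.defined_positions | B.defined_positions) - conflicts


def test_fuse_disjoint_is_union():
    A = ConsensusPattern(6, {1: "H", 3: "D"})
    B = ConsensusPattern(6, {2: "A", 5: "T"})
    assert fuse_prototype(A, B).positions == {1: "H", 2: "A", 3: "D", 5: "T"}
    with pytest.raises(ValueError, match="width"):
        fuse_prototype(A, ConsensusPattern(7, {}))


def test_signature_residues_constructed_case(block_factory):
    blocks = {
        "A": block_factory(["AAAAV", "AAAAV", "AAAAV"], group="A"),
        "B": block_factory(["AAAAK", "AAAAK", "AAAAK"], group="B"),
    }
    sigs = signature_residues(blocks, tau_in=0.9, tau_out=0.1)
    assert sigs["A"] == {(5, "V")}
    assert sigs["B"] == {(5, "K")}


def test_signature_residues_no_discrimination(block_factory):
    same = ["HSDGT", "HSDGT"]
    blocks = {"A": block_factory(same, group="A"),
              "B": block_factory(same, group="B")}
    sigs = signature_residues(blocks, tau_in=0.8, tau_out=0.2)
    assert sigs == {"A": set(), "B": set()}


def test_signature_monotone_in_tau_in(block_factory):
    rng = random.Random(3)
    blocks = {
        g: block_factory(["".join(rng.choice("AV") for _ in range(6))
                          for _ in range(5)], group=g)
        for g in ("A", "B", "C")
    }
    strict = signature_residues(blocks, tau_in=0.9, tau_out=0.3)
    loose = signature_residues(blocks, tau_in=0.0, tau_out=0.3)
    for g in blocks:
        assert strict[g] <= loose[g]
    with pytest.raises(ValueError):
        signature_residues(blocks, tau_in=1.2, tau_out=0.1)
    with pytest.raises(ValueError):
        signature_residues({"A": blocks["A"]})
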