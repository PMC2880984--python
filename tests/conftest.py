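import pytest

from sctfam.maturome import PeptideSequence
from sctfam.consensus_profile import AlignmentBlock


class MatchMatrix:
    """Simple match/mismatch scoring table indexable as matrix[x, y]."""

    def __init__(self, match=2.0, mismatch=-1.0):
        self.match, self.mismatch = match, mismatch

    def __getitem__(self, key):
        x, y = key
        return self.match if x == y else self.mismatch


@pytest.fixture
def match_matrix():
    return MatchMatrix()


def make_block(rows, group="G", subfamily="", taxon=""):
    """AlignmentBlock from plain residue strings (ids seq1, seq2, ...)."""
    width = len(rows[0])
    return AlignmentBlock([
        PeptideSequence(id=f"seq{i + 1}", residues=r, taxon=taxon, group=group,
                        subfamily=subfamily, window=(1, width))
        for i, r in enumerate(rows)
    ])


@pytest.fixture
def block_factory():
    return make_block
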