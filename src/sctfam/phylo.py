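"""Distance-based phylogeny: p-distances, neighbor-joining, bootstrap,
and subfamily-monophyly counting.

The scientific question downstream is topological — do the PACAP-like and
GCG-like peptides fall into two clean clades? — so a distance/NJ surrogate
with nonparametric bootstrap is used instead of likelihood machinery. NJ is
exact on additive distance matrices, which provides the oracle class for
testing.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .consensus_profile import AlignmentBlock, GAP

logger = logging.getLogger(__name__)


def pdistance_matrix(block: AlignmentBlock) -> DistanceMatrix:
    """Pairwise-deletion p-distances between block members.

    d(a, b) = mismatches / columns where both sequences are non-gap. A pair
    with zero comparable columns is an error naming the pair.
    """
    if len(block) < 3:
        raise ValueError("pdistance_matrix requires at least 3 members")
    ids = [m.id for m in block.members]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate member ids in block")
    seqs = np.array([list(m.residues) for m in block.members])
    nongap = seqs != GAP
    both = nongap[:, None, :] & nongap[None, :, :]
    comparable = both.sum(axis=2)
    bad = np.argwhere(np.triu(comparable == 0, k=1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
    mism = ((seqs[:, None, :] != seqs[None, :, :]) & both).sum(axis=2)
    d = mism / comparable
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining tree (unrooted, trifurcating at the root
    node of the returned representation).

    The Q-criterion minimum is tie-broken by the lowest (i, j) index pair in
    current join order; negative branch lengths are clamped to 0 with a log
    entry. The input matrix must be symmetric with a zero diagonal (enforced
    by :class:`skbio.DistanceMatrix`).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes: List[TreeNode] = [TreeNode(name=i) for i in ids]

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.info("negative branch length %.4g at %s clamped to 0", x, what)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        rowsum = D.sum(axis=1)
        Q = (m - 2) * D - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # Lowest (i, j) pair with i < j on ties: scan upper triangle in
        # row-major order via masked argmin.
        iu = np.triu_indices(m, k=1)
        qvals = Q[iu]
        kmin = int(np.argmin(qvals))  # argmin returns first == lowest pair
        i, j = int(iu[0][kmin]), int(iu[1][kmin])

        dij = D[i, j]
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, f"join({nodes[i].name},{nodes[j].name})")
        lj = clamp(lj, f"join({nodes[i].name},{nodes[j].name})")
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])

        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.delete(np.delete(D, (i, j), axis=0), (i, j), axis=1)
        dnew = np.delete(dnew, (i, j))
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dnew
        D[:-1, -1] = dnew
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]

    # Final three nodes joined at an unresolved root (unrooted trifurcation).
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length = clamp(la, f"terminal({a.name})")
    b.length = clamp(lb, f"terminal({b.name})")
    c.length = clamp(lc, f"terminal({c.name})")
    return TreeNode(children=[a, b, c])


def _bipartitions(tree: TreeNode) -> Set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted tree as canonical leaf sets.

    Each internal edge splits the leaves in two; the split is represented by
    whichever side sorts first, so representations agree across rootings.
    """
    leaves = frozenset(l.name for l in tree.tips())
    n = len(leaves)
    splits: Set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if 1 < len(side) < n - 1:
            other = leaves - side
            splits.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return splits


def bootstrap_support(
    block: AlignmentBlock,
    n_reps: int = 100,
    seed: int = 0,
) -> Tuple[TreeNode, Dict[frozenset, float]]:
    """Point-estimate NJ tree with bootstrap support on its bipartitions.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate NJ trees containing each bipartition of the
    point-estimate tree. Supports are written into the internal node names
    of the returned tree (newick-compatible) and also returned as a map.
    Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(pdistance_matrix(block))
    target = _bipartitions(tree)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    width = block.width
    members = block.members
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        resampled = []
        for m in members:
            res = "".join(m.residues[c] for c in cols)
            resampled.append(type(m)(id=m.id, residues=res, taxon=m.taxon,
                                     group=m.group, subfamily=m.subfamily,
                                     window=(1, width)))
        rep_tree = nj_tree(pdistance_matrix(AlignmentBlock(resampled)))
        rep_splits = _bipartitions(rep_tree)
        for s in target & rep_splits:
            counts[s] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    leaves_all = frozenset(l.name for l in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        key = min(side, leaves_all - side, key=lambda s: tuple(sorted(s)))
        if key in support:
            node.name = f"{support[key]:.0f}"
    return tree, support


def check_subfamily_monophyly(tree: TreeNode, labels: Mapping[str, str]) -> int:
    """Minimum number of label-pure maximal clades partitioning the leaves,
    minimised over all rootings of the (treated-as-unrooted) tree.

    Returns 2 when one internal edge cleanly separates the two label sets —
    the two-clade configuration. Every leaf must be labelled.
    """
    leaves = [l.name for l in tree.tips()]
    for name in leaves:
        if name not in labels:
            raise ValueError(f"unlabelled leaf {name!r}")
    if len(set(labels[l] for l in leaves)) == 1:
        return 1
    if len(leaves) == 1:
        return 1

    # Adjacency over the tree seen as unrooted.
    adj: Dict[int, List[int]] = {}
    label_of: Dict[int, str] = {}
    index: Dict[TreeNode, int] = {}
    for k, node in enumerate(tree.traverse(include_self=True)):
        index[node] = k
        adj[k] = []
    for node in tree.traverse(include_self=True):
        for child in node.children:
            adj[index[node]].append(index[child])
            adj[index[child]].append(index[node])
        if node.is_tip():
            label_of[index[node]] = labels[node.name]

    # f(u -> v): (pure label or None, count of maximal pure clades) for the
    # subtree on v's side of edge (u, v). Iterative post-order per directed
    # edge with memoisation.
    memo: Dict[Tuple[int, int], Tuple[Optional[str], int]] = {}

    def f(u: int, v: int) -> Tuple[Optional[str], int]:
        if (u, v) in memo:
            return memo[(u, v)]
        stack = [(u, v, False)]
        while stack:
            pu, pv, expanded = stack.pop()
            if (pu, pv) in memo:
                continue
            kids = [w for w in adj[pv] if w != pu]
            if not kids:
                memo[(pu, pv)] = (label_of[pv], 1)
                continue
            if not expanded:
                stack.append((pu, pv, True))
                stack.extend((pv, w, False) for w in kids)
                continue
            results = [memo[(pv, w)] for w in kids]
            labs = {lab for lab, _ in results}
            if len(labs) == 1 and None not in labs:
                memo[(pu, pv)] = (labs.pop(), 1)
            else:
                memo[(pu, pv)] = (None, sum(c for _, c in results))
        return memo[(u, v)]

    best = None
    for u in adj:
        for v in adj[u]:
            if u < v:
                _, cu = f(v, u)
                _, cv = f(u, v)
                total = cu + cv
                best = total if best is None else min(best, total)
    return best if best is not None else 1
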