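"""Population trees from pairwise f2 drift distances.

f2 distances are additive along a drift tree for populations related by
pure splits, so neighbour joining recovers the split topology, the tree is
rooted on a user-named outgroup (splitting its edge at the midpoint), and
branch lengths are refit by non-negative least squares.  The fraction of
variance in the pairwise distances explained by the fitted tree is the
goodness-of-fit statistic: introgression between populations depresses
their pairwise f2 below additivity and both lowers this fraction and can
relocate leaves (a heavily introgressed group attaches inside the donor's
clade).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import nnls

from .fstats import BlockSpec, FreqTable, f2

logger = logging.getLogger(__name__)


@dataclass
class DriftMatrix:
    populations: list[str]
    d: np.ndarray   # symmetric pairwise f2, zero diagonal
    se: np.ndarray  # matching jackknife SEs

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        n = len(self.populations)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            n_neg = int((self.d < 0).sum() // 2)
            logger.info("f2 matrix: clamped %d negative entries to 0", n_neg)
            self.d = np.maximum(self.d, 0.0)
        np.fill_diagonal(self.d, 0.0)


@dataclass
class PopTree:
    tree: dendropy.Tree
    outgroup: str

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def leaves_under_mrca(self, labels: list[str]) -> set[str]:
        """Leaf labels spanned by the smallest clade containing ``labels``."""
        mrca = self.tree.mrca(taxon_labels=list(labels))
        return {lf.taxon.label for lf in mrca.leaf_iter()}


def f2_matrix(freqs: FreqTable, blocks: BlockSpec = BlockSpec()) -> DriftMatrix:
    """Pairwise f2 drift distances with block-jackknife SEs."""
    pops = list(freqs.populations)
    if len(pops) < 3:
        raise ValueError("need at least 3 populations for a drift matrix")
    n = len(pops)
    d = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = f2(pops[i], pops[j], freqs, blocks)
            d[i, j] = d[j, i] = r.estimate
            se[i, j] = se[j, i] = r.jackknife_se
    return DriftMatrix(pops, d, se)


def _nj_unrooted(dm: DriftMatrix) -> dendropy.Tree:
    # canonical label order makes the result independent of input order
    order = np.argsort(np.asarray(dm.populations, dtype=object))
    labels = [dm.populations[i] for i in order]
    sub = dm.d[np.ix_(order, order)]
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{x:.12g}" for x in sub[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    return pdm.nj_tree()


def build_tree(dm: DriftMatrix, outgroup: str) -> PopTree:
    """Neighbour joining on the drift matrix, rooted on the outgroup edge.

    Negative NJ branch lengths are floored at 0; the root bisects the
    outgroup's edge at its midpoint.
    """
    if outgroup not in dm.populations:
        raise ValueError(f"outgroup {outgroup!r} not among populations")
    if len(dm.populations) < 3:
        raise ValueError("need at least 3 populations")
    tree = _nj_unrooted(dm)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    og = tree.find_node_with_taxon_label(outgroup)
    half = (og.edge.length or 0.0) / 2.0
    tree.reroot_at_edge(og.edge, length1=half, length2=half,
                        update_bipartitions=True)
    tree.is_rooted = True
    return PopTree(tree, outgroup)


def _edge_leaf_sets(tree: dendropy.Tree) -> list[tuple[object, frozenset]]:
    out = []
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue  # root has no parent edge
        leaves = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
        out.append((edge, leaves))
    return out


def variance_explained(
    ptree: PopTree, dm: DriftMatrix
) -> tuple[float, np.ndarray]:
    """Fraction of pairwise-distance variance explained by the tree.

    Branch lengths are refit by non-negative least squares to the observed
    distances under the tree's topology; the statistic is
    1 - SS_residual / SS_total with SS_total about the mean pairwise
    distance.  Also returns the residual matrix (observed - fitted).
    """
    labels = set(dm.populations)
    if set(ptree.leaf_labels) != labels:
        raise ValueError("tree leaves do not match distance-matrix populations")
    pops = dm.populations
    idx = {p: i for i, p in enumerate(pops)}
    edges = _edge_leaf_sets(ptree.tree)
    pairs = [(i, j) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dm.d[i, j] for i, j in pairs])
    for e, (_, below) in enumerate(edges):
        for r, (i, j) in enumerate(pairs):
            if (pops[i] in below) != (pops[j] in below):
                A[r, e] = 1.0
    x, _ = nnls(A, y)
    fitted = A @ x
    resid = y - fitted
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("pairwise distances are constant; variance undefined")
    frac = 1.0 - float((resid**2).sum()) / ss_tot
    resid_mat = np.zeros_like(dm.d)
    for r, (i, j) in enumerate(pairs):
        resid_mat[i, j] = resid_mat[j, i] = resid[r]
    return frac, resid_mat


def classify_group_placement(
    ptree: PopTree, group_a: list[str], group_b: list[str]
) -> str:
    """How two leaf groups relate in the rooted tree.

    Returns ``"separate"`` when the smallest clade containing each group
    contains no leaf of the other, ``"a_within_b"`` when the clade spanning
    group B contains every leaf of A (and not conversely),
    ``"b_within_a"`` for the mirror case, else ``"intermixed"``.
    """
    sa, sb = set(group_a), set(group_b)
    span_a = ptree.leaves_under_mrca(group_a)
    span_b = ptree.leaves_under_mrca(group_b)
    if not (span_a & sb) and not (span_b & sa):
        return "separate"
    a_in_b = sa <= span_b
    b_in_a = sb <= span_a
    if a_in_b and not b_in_a:
        return "a_within_b"
    if b_in_a and not a_in_b:
        return "b_within_a"
    return "intermixed"
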