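"""Distance-based phylogenetics: p-distance, neighbor joining,
column-bootstrap support, subfamily and ortholog-pair calls.

The tree container and Newick serialization come from dendropy; the
p-distance, the Saitou–Nei NJ joins and the bootstrap are implemented
here so the tie rules and the pairwise-deletion behaviour are pinned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .core_io import Alignment, SequenceRecord

logger = logging.getLogger(__name__)

# characters excluded from p-distance comparisons (gap and ambiguity)
MISSING = {"-", "X"}


@dataclass
class DistanceMatrix:
    """Pairwise p-distances with per-pair comparable-site counts."""

    taxa: list[str]
    d: np.ndarray
    valid_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(self.d < 0) or np.any(self.d > 1):
            raise ValueError("p-distances must lie in [0, 1]")


@dataclass
class SubfamilyAssignment:
    assignments: dict[str, str]  # leaf label -> subfamily
    monophyletic: dict[str, bool]  # subfamily -> clade-on-some-rooting flag


def p_distance(alignment: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Fraction of differing sites per sequence pair.

    ``pairwise`` deletion compares each pair over the columns where
    neither member has a gap or ambiguity; ``complete`` restricts all
    pairs to columns free of gaps/ambiguity in every sequence.  A pair
    left with zero comparable sites is an error naming the pair.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    seqs = [r.residues for r in alignment.records]
    taxa = alignment.ids
    n = len(seqs)
    arr = np.array([list(s) for s in seqs])
    ok = ~np.isin(arr, list(MISSING))
    if deletion == "complete":
        keep = ok.all(axis=0)
        arr = arr[:, keep]
        ok = ok[:, keep]
    d = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=int)
    for i in range(n):
        valid[i, i] = ok[i].sum()
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]!r} and {taxa[j]!r}"
                )
            diff = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = diff / m
            valid[i, j] = valid[j, i] = m
    return DistanceMatrix(taxa=list(taxa), d=d, valid_sites=valid)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; ties are
    broken by the smallest (row, column) index pair in the current
    working order.  Negative branch lengths are clamped to zero (the
    raw value is logged).  The returned dendropy tree is unrooted with
    a trifurcating seed node.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for label in dm.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    D = dm.d.astype(float).copy()

    def clamp(v: float, context: str) -> float:
        if v < 0:
            logger.debug("negative branch length %.6g at %s clamped to 0", v, context)
            return 0.0
        return v

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - (r[:, None] + r[None, :])
        # only the upper triangle is scanned: i < j, deterministic ties
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        i, j = min((int(a), int(b)) for a, b in ties)
        vi = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2)), f"join {i},{j}")
        vj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))), f"join {i},{j}")
        new = dendropy.Node()
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = new
        del nodes[j]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.edge.length = clamp((dab + dac - dbc) / 2, "final a")
    b.edge.length = clamp((dab + dbc - dac) / 2, "final b")
    c.edge.length = clamp((dac + dbc - dab) / 2, "final c")
    root = tree.seed_node
    for node in nodes:
        root.add_child(node)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits

def tree_splits(tree: dendropy.Tree, nontrivial_only: bool = True) -> set[frozenset[str]]:
    """Bipartitions of an unrooted tree, each normalized to the side
    not containing the lexicographically smallest leaf label."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = frozenset(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if nontrivial_only and (len(side) < 2 or len(side) > len(leaves) - 2):
            continue
        if 0 < len(side) < len(leaves):
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``replicates`` times; the
    support of an internal branch is the percentage of replicate trees
    containing its bipartition, written as an integer internal-node
    label.  A replicate whose resampled columns leave some pair with
    zero comparable sites is redrawn (counted and logged).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(p_distance(alignment, deletion))
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref, all_set = leaves[0], frozenset(leaves)
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(tree)}
    rng = np.random.default_rng(seed)
    ncol = alignment.length
    redraws = 0
    done = 0
    while done < replicates:
        cols = rng.integers(0, ncol, size=ncol)
        recs = [
            SequenceRecord(
                id=r.id,
                residues="".join(r.residues[c] for c in cols),
                moltype=r.moltype,
                aligned=True,
            )
            for r in alignment.records
        ]
        try:
            rep_dm = p_distance(Alignment(recs), deletion)
        except ValueError:
            redraws += 1
            if redraws > 100 * replicates:
                raise RuntimeError("bootstrap: too many undefined replicates")
            continue
        rep_splits = tree_splits(nj_tree(rep_dm))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
        done += 1
    if redraws:
        logger.info("bootstrap: %d replicates redrawn (undefined distances)", redraws)
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if side in counts:
            node.label = str(round(100 * counts[side] / replicates))
    return tree


# ---------------------------------------------------------------------------
# subfamilies and orthologs

def assign_subfamilies(
    tree: dendropy.Tree, anchors: dict[str, str]
) -> SubfamilyAssignment:
    """Propagate subfamily labels from anchor leaves.

    Each unanchored leaf takes the subfamily of its nearest anchored
    leaf by patristic distance (ties: majority among tied anchors, then
    alphabetical subfamily).  The per-subfamily monophyly flag reports
    whether its leaves form a clade on some rooting of the unrooted
    tree, i.e. whether the leaf set is one side of a bipartition.
    """
    leaf_labels = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = set(anchors) - set(leaf_labels)
    if missing:
        raise ValueError(f"anchor leaves not in tree: {sorted(missing)}")
    pdm = tree.phylogenetic_distance_matrix()
    taxon = {t.label: t for t in tree.taxon_namespace}
    assignments: dict[str, str] = dict(anchors)
    for leaf in leaf_labels:
        if leaf in anchors:
            continue
        dists = [
            (pdm.patristic_distance(taxon[leaf], taxon[a]), a) for a in anchors
        ]
        dmin = min(d for d, _ in dists)
        tied = [anchors[a] for d, a in dists if abs(d - dmin) < 1e-12]
        if len(set(tied)) > 1:
            warnings.warn(
                f"leaf {leaf!r} equidistant to anchors of {sorted(set(tied))}; "
                "majority wins"
            )
        best = max(sorted(set(tied)), key=tied.count)
        assignments[leaf] = best

    splits = tree_splits(tree, nontrivial_only=False)
    all_set = frozenset(leaf_labels)
    ref = min(leaf_labels)
    mono: dict[str, bool] = {}
    for fam in sorted(set(assignments.values())):
        members = frozenset(l for l, f in assignments.items() if f == fam)
        side = all_set - members if ref in members else members
        mono[fam] = (
            len(members) == 1
            or len(members) == len(all_set)
            or side in splits
        )
    return SubfamilyAssignment(assignments=assignments, monophyletic=mono)


def ortholog_pairs(
    tree: dendropy.Tree, species_of: dict[str, str]
) -> list[tuple[str, str]]:
    """Cross-species cherries: two-leaf sister pairs whose members
    belong to different species."""
    if len(set(species_of.values())) < 2:
        raise ValueError("need at least 2 species")
    pairs: list[tuple[str, str]] = []
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        leaf_children = [c for c in children if c.is_leaf()]
        # at the trifurcating seed of an unrooted tree, two leaf
        # children among three total are still adjacent to one node
        is_cherry = len(leaf_children) == 2 and (
            len(children) == 2 or (node is tree.seed_node and len(children) == 3)
        )
        if is_cherry:
            a, b = sorted(c.taxon.label for c in leaf_children)
            if species_of.get(a) != species_of.get(b):
                pairs.append((a, b))
    return sorted(pairs)
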