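"""p-distance, neighbor joining (with additive-matrix recovery),
bootstrap supports, subfamily and ortholog-pair calls."""

import dendropy
import numpy as np
import pytest

from iqfam.core_io import Alignment, SequenceRecord, tree_to_newick, read_newick
from iqfam.phylogeny import (
    DistanceMatrix,
    assign_subfamilies,
    bootstrap_support,
    nj_tree,
    ortholog_pairs,
    p_distance,
    tree_splits,
)
from iqfam.synthetic import simulate_clade_alignment


def aln(*pairs):
    return Alignment([SequenceRecord(i, s, aligned=True) for i, s in pairs])


# ---------------------------------------------------------------------------
# p-distance

def test_p_distance_quarter():
    dm = p_distance(aln(("a", "AAAA"), ("b", "AAAT")))
    assert dm.d[0, 1] == 0.25
    assert dm.valid_sites[0, 1] == 4


def test_p_distance_pairwise_deletion_excludes_gap():
    dm = p_distance(aln(("a", "AA-A"), ("b", "AAAA")), deletion="pairwise")
    assert dm.d[0, 1] == 0.0
    assert dm.valid_sites[0, 1] == 3


def test_p_distance_complete_deletion_drops_column_for_all():
    dm = p_distance(
        aln(("a", "AA-A"), ("b", "AATA"), ("c", "CATA")), deletion="complete"
    )
    # column 3 (gap in a) dropped for every pair
    assert dm.valid_sites[1, 2] == 3


def test_p_distance_matches_recount_oracle():
    rng = np.random.default_rng(9)
    chars = list("ACDEFG-")
    seqs = ["".join(rng.choice(chars, size=100)) for _ in range(5)]
    records = aln(*[(f"s{i}", s) for i, s in enumerate(seqs)])
    dm = p_distance(records, deletion="pairwise")
    for i in range(5):
        for j in range(i + 1, 5):
            diffs = valid = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x in "-X" or y in "-X":
                    continue
                valid += 1
                diffs += x != y
            assert dm.valid_sites[i, j] == valid
            assert dm.d[i, j] == pytest.approx(diffs / valid)


def test_p_distance_no_comparable_sites_names_pair():
    with pytest.raises(ValueError, match="'a'.*'b'"):
        p_distance(aln(("a", "A--"), ("b", "-AA"), ("c", "AAA")))


# ---------------------------------------------------------------------------
# neighbor joining

def test_nj_three_taxa_closed_form():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float) / 10
    dm = DistanceMatrix(["a", "b", "c"], d, np.ones((3, 3), int))
    tree = nj_tree(dm)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx(0.1)
    assert lengths["b"] == pytest.approx(0.1)
    assert lengths["c"] == pytest.approx(0.3)


def random_binary_tree(n_taxa: int, rng) -> dendropy.Tree:
    """Random unrooted binary tree with branch lengths in [0.01, 0.08]."""
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=tns)

    def leaf(i):
        node = dendropy.Node(taxon=tns.get_taxon(f"t{i}"))
        node.edge.length = rng.uniform(0.01, 0.08)
        return node

    for i in range(3):
        tree.seed_node.add_child(leaf(i))
    for i in range(3, n_taxa):
        edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
        edge = edges[rng.integers(len(edges))]
        parent, child = edge.tail_node, edge.head_node
        mid = dendropy.Node()
        split = child.edge.length * rng.uniform(0.2, 0.8)
        parent.remove_child(child)
        child.edge.length -= split
        mid.add_child(child)
        new_leaf = leaf(i)
        mid.add_child(new_leaf)
        parent.add_child(mid)
        mid.edge.length = split
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return DistanceMatrix(taxa, d, np.ones((n, n), int))


@pytest.mark.parametrize("n_taxa", [6, 8, 10])
def test_nj_recovers_additive_tree_exactly(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(3):
        true_tree = random_binary_tree(n_taxa, rng)
        dm = path_length_matrix(true_tree)
        est = nj_tree(dm)
        assert tree_splits(est) == tree_splits(true_tree)
        dm_est = path_length_matrix(est)
        assert np.allclose(dm_est.d, dm.d, atol=1e-9)


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(77)
    true_tree = random_binary_tree(7, rng)
    dm = path_length_matrix(true_tree)
    perm = rng.permutation(7)
    dm_perm = DistanceMatrix(
        [dm.taxa[i] for i in perm], dm.d[np.ix_(perm, perm)], dm.valid_sites[np.ix_(perm, perm)]
    )
    assert tree_splits(nj_tree(dm)) == tree_splits(nj_tree(dm_perm))


def test_nj_tie_break_deterministic():
    # ultrametric 4-taxon matrix with two equally good joins
    d = np.array(
        [
            [0, 0.2, 0.4, 0.4],
            [0.2, 0, 0.4, 0.4],
            [0.4, 0.4, 0, 0.2],
            [0.4, 0.4, 0.2, 0],
        ]
    )
    dm = DistanceMatrix(["a", "b", "c", "d"], d, np.ones((4, 4), int))
    newicks = {tree_to_newick(nj_tree(dm)) for _ in range(5)}
    assert len(newicks) == 1
    assert frozenset({"c", "d"}) in tree_splits(nj_tree(dm), nontrivial_only=False) or frozenset(
        {"a", "b"}
    )


def test_nj_requires_three_taxa():
    dm = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]), np.ones((2, 2), int))
    with pytest.raises(ValueError):
        nj_tree(dm)


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_saturated_clades_get_full_support():
    alignment = simulate_clade_alignment(
        {"A": 3, "B": 3}, length=150, diagnostic_columns=50, noise_rate=0.0, seed=1
    )
    tree = bootstrap_support(alignment, replicates=100, seed=5)
    # the A|B bipartition is the only branch with signal (within-clade
    # sequences are identical, so those branches are arbitrary)
    clade_b = frozenset({"B_1", "B_2", "B_3"})
    supports = {}
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for node in tree.preorder_internal_node_iter():
        if node.label is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if "A_1" in side:
            side = leaves - side
        supports[side] = int(node.label)
    assert supports[clade_b] == 100


def test_bootstrap_single_replicate_supports_binary():
    alignment = simulate_clade_alignment({"A": 3, "B": 3}, length=120, seed=2)
    tree = bootstrap_support(alignment, replicates=1, seed=3)
    supports = [
        int(n.label)
        for n in tree.preorder_internal_node_iter()
        if n.label is not None
    ]
    assert set(supports) <= {0, 100}


def test_bootstrap_seed_reproducibility():
    alignment = simulate_clade_alignment({"A": 4, "B": 3}, length=120, noise_rate=0.05, seed=4)
    t1 = bootstrap_support(alignment, replicates=30, seed=9)
    t2 = bootstrap_support(alignment, replicates=30, seed=9)
    assert tree_to_newick(t1) == tree_to_newick(t2)


# ---------------------------------------------------------------------------
# subfamilies and orthologs

def test_assign_subfamilies_planted_clades():
    alignment = simulate_clade_alignment({"I": 4, "II": 3, "III": 2}, length=240, seed=6)
    tree = nj_tree(p_distance(alignment))
    anchors = {"I_1": "I", "II_1": "II", "III_1": "III"}
    result = assign_subfamilies(tree, anchors)
    for leaf, fam in result.assignments.items():
        assert leaf.startswith(fam + "_")
    assert all(result.monophyletic.values())


def test_assign_subfamilies_single_anchor_covers_all():
    alignment = simulate_clade_alignment({"A": 3, "B": 3}, length=120, seed=8)
    tree = nj_tree(p_distance(alignment))
    result = assign_subfamilies(tree, {"A_1": "only"})
    assert set(result.assignments.values()) == {"only"}


def test_assign_subfamilies_rice_family_sizes():
    # eight-member family tree: three planted clades of 4, 2 and 2
    alignment = simulate_clade_alignment({"I": 4, "II": 2, "III": 2}, length=240, seed=10)
    tree = nj_tree(p_distance(alignment))
    result = assign_subfamilies(tree, {"I_1": "I", "II_1": "II", "III_1": "III"})
    sizes = {
        fam: sum(1 for f in result.assignments.values() if f == fam)
        for fam in ("I", "II", "III")
    }
    assert sizes == {"I": 4, "II": 2, "III": 2}


def test_ortholog_pairs_single_cross_species_cherry():
    tree = read_newick("((r1:1,b1:1):1,(r2:1,r3:1):1);")
    species = {"r1": "rice", "r2": "rice", "r3": "rice", "b1": "brachy"}
    assert ortholog_pairs(tree, species) == [("b1", "r1")]


def test_ortholog_pairs_none_when_no_cross_species_cherry():
    tree = read_newick("((r1:1,r2:1):1,(b1:1,b2:1):1);")
    species = {"r1": "r", "r2": "r", "b1": "b", "b2": "b"}
    assert ortholog_pairs(tree, species) == []


def test_ortholog_pairs_match_cherry_enumeration_oracle():
    rng = np.random.default_rng(55)
    for trial in range(5):
        tree = random_binary_tree(8, rng)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        species = {l: ("sp1" if rng.random() < 0.5 else "sp2") for l in labels}
        if len(set(species.values())) < 2:
            species[labels[0]] = "sp1"
            species[labels[1]] = "sp2"
        # oracle: a cherry is a leaf pair whose patristic path has 2 edges
        pdm = tree.phylogenetic_distance_matrix()
        lookup = {t.label: t for t in tree.taxon_namespace}
        oracle = set()
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if pdm.path_edge_count(lookup[a], lookup[b]) == 2 and species[a] != species[b]:
                    oracle.add((a, b))
        assert set(ortholog_pairs(tree, species)) == oracle
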