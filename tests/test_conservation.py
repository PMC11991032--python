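import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstkit import (
    Alignment,
    compile_pattern,
    consensus_from_logo,
    distance_matrix,
    logo_columns,
    nj_tree,
    p_distance,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _aln(*seqs):
    return Alignment(rows=tuple((f"s{i}", s) for i, s in enumerate(seqs)))


# --- logo statistics ---------------------------------------------------------

def test_fully_conserved_column_is_432_bits():
    (col,) = logo_columns(_aln("R", "R", "R", "R"))
    assert round(col.bits, 2) == 4.32
    assert col.width == 1.0


def test_uniform_column_is_zero_bits():
    (col,) = logo_columns(_aln(*AA))
    assert col.bits == pytest.approx(0.0, abs=1e-12)


def test_half_split_column():
    (col,) = logo_columns(_aln("R", "R", "K", "K"))
    assert col.bits == pytest.approx(math.log2(20) - 1.0, abs=1e-12)


def test_all_gap_column_zero_bits_zero_width():
    cols = logo_columns(_aln("R-", "R-"))
    assert cols[1].bits == 0.0 and cols[1].width == 0.0


def test_gap_scaling_width():
    (col,) = logo_columns(_aln("R", "R", "R", "-"))
    assert col.width == pytest.approx(0.75)
    assert round(col.bits, 2) == 4.32  # gaps do not dilute information


def test_removing_all_gap_row_raises_widths_keeps_bits():
    with_blank = _aln("RYW", "RYW", "---")
    without = _aln("RYW", "RYW")
    a = logo_columns(with_blank)
    b = logo_columns(without)
    for ca, cb in zip(a, b):
        assert ca.bits == pytest.approx(cb.bits)
        assert ca.width < cb.width


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.text(alphabet=AA + "-", min_size=5, max_size=5), min_size=2, max_size=12))
def test_bits_bounded(rows):
    for col in logo_columns(Alignment(rows=tuple((f"s{i}", r) for i, r in enumerate(rows)))):
        assert 0.0 <= col.bits <= math.log2(20) + 1e-12
        assert 0.0 <= col.width <= 1.0


# --- consensus ---------------------------------------------------------------

def test_consensus_of_identical_alignment_is_the_sequence():
    aln = _aln("RYWMH", "RYWMH", "RYWMH")
    assert consensus_from_logo(logo_columns(aln), aln) == "RYWMH"


def test_consensus_collapses_variable_spacers(truth_bundle):
    aln = truth_bundle.aligned_sst
    cons = consensus_from_logo(logo_columns(aln), aln)
    assert cons.startswith("Rx{5,7}YW")
    assert "YH" in cons
    compile_pattern(cons)  # consensus must be re-parsable


def test_consensus_of_random_alignment_is_all_wildcards():
    rng = np.random.default_rng(5)
    rows = ["".join(AA[i] for i in rng.integers(0, 20, size=12)) for _ in range(20)]
    aln = _aln(*rows)
    cols = logo_columns(aln)
    assert all(c.bits < 2.0 for c in cols)  # verified premise
    assert consensus_from_logo(cols, aln) == "x{12}"


# --- distances ---------------------------------------------------------------

def test_p_distance_cases():
    assert p_distance("RYWK", "RYWK") == 0.0
    assert p_distance("RYW-", "RYWA") == 0.0
    assert p_distance("RYWK", "RYWA") == 0.25


def test_p_distance_requires_shared_columns():
    with pytest.raises(ValueError):
        p_distance("RY--", "--WA")


# --- neighbour joining -------------------------------------------------------

def test_nj_two_taxa():
    assert nj_tree(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"]) == "(A:0.2,B:0.2);"


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 3.0, 8.0], [3.0, 0.0, 9.0], [8.0, 9.0, 0.0]])
    assert nj_tree(d, ["A", "B", "C"]) == "(A:1,B:2,C:7);"


def test_nj_four_taxa_recovers_known_tree():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
    d = np.array(
        [
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ]
    )
    import dendropy

    nwk = nj_tree(d, ["A", "B", "C", "D"])
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = ["A", "B", "C", "D"]
    for i in range(4):
        for j in range(i + 1, 4):
            assert pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]) == pytest.approx(
                d[i, j], abs=1e-9
            )
    # AB|CD split present: A and B are siblings
    a = tree.taxon_namespace.get_taxon("A")
    b = tree.taxon_namespace.get_taxon("B")
    mrca = pdm.mrca(a, b)
    assert {leaf.taxon.label for leaf in mrca.leaf_iter()} == {"A", "B"}


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])
    with pytest.raises(ValueError):
        nj_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["A", "B"])


def _random_additive(n, rng):
    import dendropy

    labels = [f"T{i}" for i in range(n)]
    nodes = [f"{l}:{rng.uniform(0.1, 2.0):.6f}" for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    tree = dendropy.Tree.get(data=f"({nodes[0]},{nodes[1]});", schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                d[a, b] = pdm.patristic_distance(taxa[labels[a]], taxa[labels[b]])
    return labels, d


def test_nj_exact_on_random_additive_trees():
    import dendropy

    rng = np.random.default_rng(11)
    for _ in range(15):
        n = int(rng.integers(4, 13))
        labels, d = _random_additive(n, rng)
        tree = dendropy.Tree.get(data=nj_tree(d, labels), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                assert abs(
                    pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]) - d[i, j]
                ) < 1e-9


def test_nj_cross_check_against_scikit_bio():
    """Same additive matrix -> same leaf path-lengths as skbio's NJ."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj
    import dendropy

    rng = np.random.default_rng(3)
    labels, d = _random_additive(7, rng)
    ours = dendropy.Tree.get(data=nj_tree(d, labels), schema="newick")
    theirs = skbio_nj(DistanceMatrix(d, labels))
    pdm = ours.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in ours.taxon_namespace}
    for i in range(7):
        for j in range(i + 1, 7):
            assert pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]) == pytest.approx(
                theirs.find(labels[i]).distance(theirs.find(labels[j])), abs=1e-9
            )


def test_same_family_monophyletic_at_zero_noise(truth_bundle):
    """Family profiles differ in interzone length, so p-distances cluster
    sequences by family in the NJ tree (mirrors family clading)."""
    import dendropy

    aln = truth_bundle.aligned_sst
    sub = Alignment(rows=tuple(aln.rows[:8] + aln.rows[-8:]))  # two family blocks
    labels, d = distance_matrix(sub)
    tree = dendropy.Tree.get(
        data=nj_tree(d, labels), schema="newick", preserve_underscores=True
    )
    group_a = frozenset(l for l in labels if "Bra" in l)
    # unrooted monophyly: some edge bipartition separates the family exactly
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None:
            continue
        leafset = frozenset(
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        )
        splits.add(leafset)
        splits.add(frozenset(labels) - leafset)
    assert group_a in splits
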