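"""Unit and property tests for pairwise sequence-evolution metrics."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from orfunc.seq_evol import (
    AlignmentError,
    CodingSequencePair,
    GranthamTable,
    InternalStopError,
    ResiduePositionSet,
    SaturationError,
    SENSE_CODONS,
    grantham_distance,
    jukes_cantor_correction,
    jukes_cantor_distance,
    neighbor_joining_tree,
    nei_gojobori_omega,
    translate_codon_alignment,
)

# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "nt,expected",
    [
        ("ATG", "M"),
        ("ATGGCT", "MA"),
        ("ATGTTTTAA", "MF"),     # terminal stop stripped
        ("---ATG", "-M"),        # whole-codon gap maps to gap residue
    ],
)
def test_translate_codon_alignment(nt, expected):
    assert translate_codon_alignment(nt) == expected


def test_translate_internal_stop_names_codon_index():
    with pytest.raises(InternalStopError) as err:
        translate_codon_alignment("ATGTAATTT")
    assert err.value.codon_index == 2


@pytest.mark.parametrize("nt", ["AT", "A-GGCT", "ATG-AA"])
def test_translate_rejects_malformed_input(nt):
    with pytest.raises(AlignmentError):
        translate_codon_alignment(nt)


# ---------------------------------------------------------------------------
# Jukes-Cantor
# ---------------------------------------------------------------------------


def test_jc_identical_pair_is_zero(pair_factory):
    pair = pair_factory("ATGGCTTTT" * 34, "ATGGCTTTT" * 34)
    assert jukes_cantor_distance(pair) == 0.0


def test_jc_quarter_mismatch_closed_form(pair_factory):
    # 12 sites, 3 mismatches -> p = 0.25 -> d = -(3/4) ln(1 - 1/3)
    pair = pair_factory("ATGGCTTTTAAA", "ATGGCTTTTTTC")
    d = jukes_cantor_distance(pair)
    assert d == pytest.approx(-0.75 * math.log(1 - 1 / 3), abs=1e-10)
    assert d == pytest.approx(0.3041, abs=5e-5)


def test_jc_saturation_raises():
    with pytest.raises(SaturationError):
        jukes_cantor_correction(3 / 4)


def test_jc_symmetric_and_gap_aware(pair_factory):
    a, b = "ATGGCTTTTAAA", "ATG---TTTTTC"
    d_ab = jukes_cantor_distance(pair_factory(a, b))
    d_ba = jukes_cantor_distance(pair_factory(b, a))
    assert d_ab == d_ba
    # gapped codon excluded: 9 compared sites, 3 mismatches (AAA vs TTC)
    assert d_ab == pytest.approx(jukes_cantor_correction(3 / 9))


@given(st.integers(0, 73))
def test_jc_strictly_increasing_in_mismatch_proportion(k):
    p1, p2 = k / 100, (k + 1) / 100
    assert jukes_cantor_correction(p2) > jukes_cantor_correction(p1)


# ---------------------------------------------------------------------------
# Grantham
# ---------------------------------------------------------------------------


def test_grantham_table_invariants(grantham):
    m = grantham.matrix
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0.0)
    assert (m >= 0).all()
    assert 99.0 <= grantham.mean_heterotypic() <= 101.0


@pytest.mark.parametrize(
    "a,b,published",
    [("S", "L", 145), ("W", "C", 215), ("L", "I", 5), ("R", "L", 102)],
)
def test_grantham_entries_match_published_matrix(grantham, a, b, published):
    # published entries are integer-rounded; the exact-mean-100 scale differs
    # from the original rounded scale by well under 1%
    assert grantham.distance(a, b) == pytest.approx(published, abs=2.0)


def test_grantham_distance_zero_iff_identical(pair_factory, grantham):
    identical = pair_factory("ATGTCTCTG", "ATGTCTCTG")
    assert grantham_distance(identical, table=grantham) == 0.0
    # Ser vs Leu at one position: distance is exactly the table entry
    differing = pair_factory("ATGTCTCTG", "ATGCTGCTG")
    d = grantham_distance(differing, table=grantham)
    assert d == pytest.approx(grantham.distance("S", "L") / 3.0)
    assert d > 0


def test_grantham_position_subset(pair_factory, grantham):
    pair = pair_factory("ATGTCTCTG", "ATGCTGCTG")  # M S/L L
    subset = ResiduePositionSet((1, 3), label="toy")
    assert grantham_distance(pair, subset, grantham) == 0.0
    only_diff = ResiduePositionSet((2,))
    assert grantham_distance(pair, only_diff, grantham) == pytest.approx(
        grantham.distance("S", "L")
    )


def test_grantham_all_gapped_positions_error(pair_factory, grantham):
    pair = pair_factory("---TCT", "ATGTCT")
    with pytest.raises(AlignmentError):
        grantham_distance(pair, ResiduePositionSet((1,)), grantham)


def test_grantham_rebuild_from_modified_weights():
    table = GranthamTable.from_properties(mean_target=50.0)
    assert table.mean_heterotypic() == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# Nei-Gojobori vs the independent brute-force oracle
# ---------------------------------------------------------------------------

from oracles import oracle_diff_counts as _oracle_diff_counts  # noqa: E402
from oracles import oracle_site_count as _oracle_site_count  # noqa: E402


def test_ng86_identical_pair(pair_factory):
    pair = pair_factory("ATGGCTTGC" * 20, "ATGGCTTGC" * 20)
    est = nei_gojobori_omega(pair)
    assert est.Sd == est.Nd == 0.0
    assert est.dN == est.dS == 0.0
    assert not est.omega_defined


def test_ng86_synonymous_only_change(pair_factory):
    # single third-position synonymous change in a 6-codon pair
    pair = pair_factory("ATGGCTTGCCTGAAAGAA", "ATGGCCTGCCTGAAAGAA")
    est = nei_gojobori_omega(pair)
    assert est.Nd == 0.0
    assert est.dN == 0.0
    assert est.dS > 0.0
    assert est.omega_defined and est.omega == 0.0


def test_ng86_nonsynonymous_only_change(pair_factory):
    pair = pair_factory("ATGGCTTGCCTGAAAGAA", "ATGCCTTGCCTGAAAGAA")
    est = nei_gojobori_omega(pair)
    assert est.Sd == 0.0
    assert est.dS == 0.0
    assert not est.omega_defined


def test_ng86_counts_match_oracle_on_toy_pairs(pair_factory):
    """2-3 codon toys incl. a two-nucleotide codon difference vs the enumerator."""
    toys = [
        ("ATGGCT", "ATGTCG"),   # GCT -> TCG differs at 2 positions
        ("ATGTGG", "ATGCGG"),
        ("ATGTTAGCT", "ATGCTCGCT"),
        ("TTATGG", "CTCTGG"),
    ]
    for nt_a, nt_b in toys:
        est = nei_gojobori_omega(pair_factory(nt_a, nt_b))
        codons_a = [nt_a[i : i + 3] for i in range(0, len(nt_a), 3)]
        codons_b = [nt_b[i : i + 3] for i in range(0, len(nt_b), 3)]
        S = sum((_oracle_site_count(a) + _oracle_site_count(b)) / 2
                for a, b in zip(codons_a, codons_b))
        sd = nd = 0.0
        for a, b in zip(codons_a, codons_b):
            s, n = _oracle_diff_counts(a, b)
            sd += s
            nd += n
        assert est.S == pytest.approx(S, abs=1e-12)
        assert est.N == pytest.approx(3 * len(codons_a) - S, abs=1e-12)
        assert est.Sd == pytest.approx(sd, abs=1e-12)
        assert est.Nd == pytest.approx(nd, abs=1e-12)


def test_ng86_site_counts_sum_to_sequence_length(pair_factory, rng):
    codons = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=50)]
    other = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=50)]
    pair = pair_factory("".join(codons), "".join(other))
    est = nei_gojobori_omega(pair)
    assert est.S + est.N == pytest.approx(150.0)


def test_ng86_zero_comparable_codons(pair_factory):
    pair = pair_factory("---", "ATG")
    with pytest.raises(AlignmentError):
        nei_gojobori_omega(pair)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------


def _tree_distances(tree, labels):
    out = {}
    for a, b in itertools.combinations(labels, 2):
        out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def test_nj_two_taxa_single_edge():
    tree = neighbor_joining_tree(["x", "y"], np.array([[0.0, 0.5], [0.5, 0.0]]))
    assert tree.find("x").distance(tree.find("y")) == pytest.approx(0.5)


def test_nj_three_taxa_closed_form():
    # d(a,b)=0.3, d(a,c)=0.4, d(b,c)=0.5 -> la=0.1, lb=0.2, lc=0.3
    dm = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
    tree = neighbor_joining_tree(["a", "b", "c"], dm)
    d = _tree_distances(tree, ["a", "b", "c"])
    assert d[("a", "b")] == pytest.approx(0.3)
    assert d[("a", "c")] == pytest.approx(0.4)
    assert d[("b", "c")] == pytest.approx(0.5)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((a:1,b:2):3,(c:4,d:5)) -> additive distances
    dm = np.array(
        [
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0],
        ],
        dtype=float,
    )
    labels = ["a", "b", "c", "d"]
    tree = neighbor_joining_tree(labels, dm)
    d = _tree_distances(tree, labels)
    for (x, y), expected in {("a", "b"): 3, ("a", "c"): 8, ("a", "d"): 9,
                             ("b", "c"): 9, ("b", "d"): 10, ("c", "d"): 9}.items():
        assert d[(x, y)] == pytest.approx(expected, abs=1e-9)
    newick = str(tree)
    assert newick.strip().endswith(";")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_nj_recovers_random_additive_tree_topology(seed):
    """Path distances on a random additive tree round-trip through NJ."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    labels = [f"t{i}" for i in range(n)]
    # random additive tree: sequential attachment with positive branch lengths
    import networkx as nx

    g = nx.Graph()
    g.add_edge(labels[0], labels[1], weight=float(rng.uniform(0.1, 1.0)))
    internal = 0
    for leaf in labels[2:]:
        u, v = list(g.edges())[int(rng.integers(0, g.number_of_edges()))]
        w = g[u][v]["weight"]
        node = f"i{internal}"
        internal += 1
        split = float(rng.uniform(0.2, 0.8)) * w
        g.remove_edge(u, v)
        g.add_edge(u, node, weight=split)
        g.add_edge(node, v, weight=w - split)
        g.add_edge(node, leaf, weight=float(rng.uniform(0.1, 1.0)))
    dm = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i, j in itertools.combinations(range(n), 2):
        dm[i, j] = dm[j, i] = lengths[labels[i]][labels[j]]
    tree = neighbor_joining_tree(labels, dm)
    d = _tree_distances(tree, labels)
    for i, j in itertools.combinations(range(n), 2):
        assert d[(labels[i], labels[j])] == pytest.approx(dm[i, j], abs=1e-8)


@pytest.mark.parametrize(
    "matrix",
    [np.array([[0, 1.0], [2.0, 0]]), np.array([[0, -1.0], [-1.0, 0]])],
)
def test_nj_rejects_invalid_matrices(matrix):
    with pytest.raises(ValueError):
        neighbor_joining_tree(["a", "b"], matrix)
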