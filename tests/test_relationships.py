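"""Allele-sharing distance, UPGMA, bootstrap, median-joining network."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonotyper import relationships as rel
from clonotyper.core_io import DataError


def test_distance_examples():
    assert rel.allele_sharing_distance(["AA"], ["AA"]) == 0.0
    assert rel.allele_sharing_distance(["AA"], ["TT"]) == 1.0
    assert rel.allele_sharing_distance(["AA"], ["AT"]) == 0.5  # {A,A} n {A,T} shares one
    assert rel.allele_sharing_distance(["AA", "GG"], ["AT", "GG"]) == 0.25


def test_chimeric_token_counts_as_het_union():
    # "CC~CT" -> {C,T}: shares one allele with CC, both with CT
    assert rel.allele_sharing_distance(["CC~CT"], ["CC"]) == 0.5
    assert rel.allele_sharing_distance(["CC~CT"], ["CT"]) == 0.0


def test_distance_requires_same_marker_count():
    with pytest.raises(DataError):
        rel.allele_sharing_distance(["AA"], ["AA", "TT"])


token = st.sampled_from(["AA", "AT", "TT", "AG", "GG", "CC~CT"])


@settings(max_examples=100, deadline=None)
@given(st.lists(token, min_size=1, max_size=8), st.data())
def test_distance_premetric_properties(p, data):
    q = data.draw(st.lists(token, min_size=len(p), max_size=len(p)))
    d = rel.allele_sharing_distance(p, q)
    assert 0.0 <= d <= 1.0
    assert d == rel.allele_sharing_distance(q, p)
    assert rel.allele_sharing_distance(p, p) == 0.0


def test_upgma_three_taxon_hand_computation():
    """d(A,B)=0.2, d(A,C)=d(B,C)=0.6: (A,B) merge at height 0.1, C at 0.3."""
    dm = rel.DistanceMatrix(("A", "B", "C"), np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]))
    root = rel.upgma_tree(dm)
    assert root.height == pytest.approx(0.3)
    (inner,) = [c for c in root.children if not c.is_leaf]
    assert inner.leaves() == {"A", "B"}
    assert inner.height == pytest.approx(0.1)
    assert root.to_newick() == "((A:0.1,B:0.1):0.2,C:0.3)"


def test_upgma_tie_break_is_lexicographic():
    dm = rel.DistanceMatrix(("C", "A", "B"), np.full((3, 3), 0.4) - 0.4 * np.eye(3))
    root = rel.upgma_tree(dm)
    (inner,) = [c for c in root.children if not c.is_leaf]
    assert inner.leaves() == {"A", "B"}


def _random_dm(rng, n):
    v = rng.uniform(0.05, 1.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = tuple(f"t{i}" for i in range(n))
    return rel.DistanceMatrix(labels, v)


def test_upgma_is_ultrametric_on_random_matrices():
    rng = np.random.default_rng(17)
    for _ in range(20):
        root = rel.upgma_tree(_random_dm(rng, int(rng.integers(3, 9))))
        depths = set()

        def walk(node, acc):
            if node.is_leaf:
                depths.add(round(acc + node.height, 9))
            for c in node.children:
                walk(c, acc + (node.height - c.height))

        # leaf depth measured from the root must equal root.height for every leaf
        walk(root, 0.0)
        assert depths == {round(root.height, 9)}


def test_upgma_matches_scipy_average_linkage_heights():
    """Independent cross-check: merge heights agree with scipy's average
    linkage (topology may differ only at ties, which this matrix lacks)."""
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(3)
    dm = _random_dm(rng, 7)
    root = rel.upgma_tree(dm)
    ours = sorted(round(2 * n.height, 9) for n in root.walk() if not n.is_leaf)
    Z = average(squareform(dm.values))
    scipys = sorted(round(h, 9) for h in Z[:, 2])
    assert ours == pytest.approx(scipys)


def test_bootstrap_full_and_deterministic():
    profiles = {"A": ("AA", "GG"), "B": ("TT", "CC"), "C": ("TT", "CT")}
    s1 = rel.bootstrap_support(profiles, n_reps=200, seed=9)
    s2 = rel.bootstrap_support(profiles, n_reps=200, seed=9)
    assert s1 == s2
    assert s1[frozenset({"B", "C"})] == 1.0  # supported at every locus


def test_single_locus_split_support_analytic():
    """A clade supported by one locus in ten recovers at rate 1-(9/10)^10."""
    profiles = {
        "A": ("AA",) + ("GG",) * 9,
        "B": ("TT",) + ("GG",) * 9,
        "C": ("TT",) + ("GG",) * 9,
    }
    support = rel.bootstrap_support(profiles, n_reps=600, seed=4)[frozenset({"B", "C"})]
    assert support == pytest.approx(1 - 0.9**10, abs=0.05)


def test_nj_alternative_produces_all_taxa():
    dm = _random_dm(np.random.default_rng(8), 5)
    newick = rel.nj_newick(dm)
    for lab in dm.labels:
        assert lab in newick


def test_mjn_two_classes_single_edge():
    G = rel.median_joining_network({"A": ("AA", "GG"), "B": ("AT", "GG")})
    assert G.number_of_nodes() == 2 and G.number_of_edges() == 1
    ((u, v, data),) = G.edges(data=True)
    assert data["loci"] == [0]


def test_mjn_star_infers_central_median():
    """Three profiles pairwise differing at disjoint loci around an
    unobserved centre: one degree-3 median appears."""
    profiles = {
        "A": ("AT", "CC", "GG"),
        "B": ("AA", "CT", "GG"),
        "C": ("AA", "CC", "GT"),
    }
    G = rel.median_joining_network(profiles)
    medians = [n for n, d in G.nodes(data=True) if not d["observed"]]
    assert medians == [("AA", "CC", "GG")]
    assert G.degree(medians[0]) == 3
    assert G.number_of_edges() == 3


def test_mjn_panel_properties(panel_data):
    """On the default panel: connected, all observed profiles present, and
    the network contains a minimum spanning tree of the observed profiles."""
    from clonotyper.clonal_panel import group_profiles

    g = group_profiles(panel_data.panel)
    profiles = {c.label: c.profile for c in g.classes}
    freqs = {c.label: len(c.members) for c in g.classes}
    G = rel.median_joining_network(profiles, freqs)
    assert nx.is_connected(G)
    observed = {tuple(p) for p in profiles.values()}
    assert observed <= set(G.nodes)
    assert G.number_of_edges() >= len(observed) - 1
    # frequency attributes carried through
    assert G.nodes[tuple(profiles["B"])]["frequency"] == 31

    # MST containment: build shortest-path-metric over G restricted to
    # observed nodes and compare with the complete-graph MST weight
    complete = nx.Graph()
    for a in observed:
        for b in observed:
            if a < b:
                complete.add_edge(a, b, weight=rel._hamming(a, b))
    mst_weight = sum(d["weight"] for _, _, d in nx.minimum_spanning_tree(complete).edges(data=True))
    for u, v, d in G.edges(data=True):
        d["weight"] = len(d["loci"])
    sub_weight = sum(d["weight"] for _, _, d in nx.minimum_spanning_tree(G).edges(data=True))
    assert sub_weight <= mst_weight


def test_mjn_duplicate_profiles_rejected():
    with pytest.raises(DataError):
        rel.median_joining_network({"A": ("AA",), "B": ("AA",)})
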