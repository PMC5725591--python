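"""Genotype relationships: allele-sharing distance, bootstrapped UPGMA
dendrogram, and a median-joining network.

The distance between two multilocus profiles is

    D = 1 - (proportion of shared alleles),

where per locus the shared proportion is |multiset intersection of the two
diploid allele pairs| / 2, averaged over loci. A composite chimeric token
("CC~CT") contributes the union of its layer alleles, treated as a
heterozygous pair. D is a bounded symmetric premetric (D(x,x)=0); the
triangle inequality is not guaranteed.

UPGMA is implemented directly so that ties are broken deterministically by
joining the lexicographically smallest label pair; node height is half the
merge distance, so the tree is ultrametric by construction. Bootstrap
supports resample loci with replacement. Neighbour-joining is offered as an
alternative through scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core_io import DataError


# ---------------------------------------------------------------------------
# Distances

def token_alleles(token: str) -> tuple[str, ...]:
    """Diploid allele pair of a state token.

    "AT" or "A/T" -> (A, T); chimeric "CC~CT" -> union of layer alleles as a
    het pair (C, T); a one-allele union collapses to a homozygous pair.
    """
    token = token.strip()
    if "~" in token:
        parts = token.split("~")
        union = sorted({a for part in parts for a in token_alleles(part)})
        if len(union) == 1:
            return (union[0], union[0])
        if len(union) == 2:
            return tuple(union)
        raise DataError(f"chimeric token {token!r} implies >2 alleles")
    if "/" in token:
        alleles = token.split("/")
    elif len(token) == 2:
        alleles = list(token)
    else:
        raise DataError(f"cannot parse genotype token {token!r}")
    if len(alleles) != 2:
        raise DataError(f"token {token!r} is not diploid")
    return tuple(sorted(alleles))


def _shared(a: tuple[str, str], b: tuple[str, str]) -> int:
    rest = list(b)
    n = 0
    for allele in a:
        if allele in rest:
            rest.remove(allele)
            n += 1
    return n


def allele_sharing_distance(p: Sequence[str], q: Sequence[str]) -> float:
    """D = 1 - mean over loci of (shared alleles / 2)."""
    if len(p) != len(q):
        raise DataError(f"profiles differ in length ({len(p)} vs {len(q)})")
    if not p:
        raise DataError("empty profiles")
    shared = sum(_shared(token_alleles(x), token_alleles(y)) for x, y in zip(p, q))
    return 1.0 - shared / (2.0 * len(p))


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise DataError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise DataError("distance matrix must be symmetric with zero diagonal")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise DataError("distances must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def profiles_distance_matrix(
    profiles: Mapping[str, Sequence[str]],
    reference_profile: Sequence[str] | None = None,
    reference_label: str = "REF",
) -> DistanceMatrix:
    """Pairwise allele-sharing distances; optionally appends a reference
    profile (e.g. an all-homozygous-reference genotype)."""
    items = list(profiles.items())
    if reference_profile is not None:
        items.append((reference_label, tuple(reference_profile)))
    labels = tuple(lab for lab, _ in items)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = allele_sharing_distance(items[i][1], items[j][1])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class CladogramNode:
    """Rooted ultrametric tree node; ``height`` is distance from the leaves."""

    name: str | None = None
    children: list["CladogramNode"] = field(default_factory=list)
    height: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset({self.name})
        return frozenset().union(*(c.leaves() for c in self.children))

    def walk(self) -> Iterable["CladogramNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, parent_height: float | None = None, percent_support: bool = True) -> str:
        length = "" if parent_height is None else f":{max(parent_height - self.height, 0.0):.6g}"
        if self.is_leaf:
            return f"{self.name}{length}"
        inner = ",".join(sorted(c.to_newick(self.height, percent_support) for c in self.children))
        label = ""
        if self.support is not None:
            label = str(int(round(100 * self.support))) if percent_support else f"{self.support:.3f}"
        return f"({inner}){label}{length}"


def upgma_tree(dm: DistanceMatrix) -> CladogramNode:
    """Average-linkage agglomeration; ties join the lexicographically
    smallest label pair (clusters compared by their smallest leaf name)."""
    if len(dm.labels) < 2:
        raise DataError("UPGMA needs at least two taxa")
    clusters: dict[str, CladogramNode] = {lab: CladogramNode(name=lab) for lab in dm.labels}
    sizes: dict[str, int] = {lab: 1 for lab in dm.labels}
    dist: dict[frozenset[str], float] = {
        frozenset({a, b}): dm.get(a, b) for a, b in combinations(dm.labels, 2)
    }
    # cluster key = lexicographically smallest member leaf, for tie-breaking
    while len(clusters) > 1:
        best = min(
            ((dist[frozenset({a, b})], tuple(sorted((a, b)))) for a, b in combinations(clusters, 2)),
            key=lambda t: (t[0], t[1]),
        )
        d, (a, b) = best
        node = CladogramNode(children=[clusters[a], clusters[b]], height=d / 2.0)
        na, nb = sizes[a], sizes[b]
        for other in clusters:
            if other in (a, b):
                continue
            d_new = (na * dist[frozenset({a, other})] + nb * dist[frozenset({b, other})]) / (na + nb)
            dist[frozenset({a, other})] = d_new  # a < b, so a is the merged cluster's key
        for other in list(clusters):
            dist.pop(frozenset({b, other}), None)
        del clusters[b], sizes[b]
        clusters[a] = node
        sizes[a] = na + nb
    return next(iter(clusters.values()))


def tree_clades(root: CladogramNode) -> set[frozenset[str]]:
    """Leaf sets of all internal nodes except the root (the tested bipartitions)."""
    all_leaves = root.leaves()
    return {
        n.leaves() for n in root.walk() if not n.is_leaf and n.leaves() != all_leaves
    }


def bootstrap_support(
    profiles: Mapping[str, Sequence[str]],
    n_reps: int = 1000,
    seed: int = 0,
    reference_profile: Sequence[str] | None = None,
) -> dict[frozenset[str], float]:
    """Clade support by locus resampling: fraction of replicates whose UPGMA
    tree contains the same leaf set."""
    n_loci = len(next(iter(profiles.values())))
    if n_loci < 2:
        raise DataError("bootstrap needs at least two loci")
    reference_tree = upgma_tree(profiles_distance_matrix(profiles, reference_profile))
    clades = tree_clades(reference_tree)
    counts = {clade: 0 for clade in clades}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, n_loci, size=n_loci)
        resampled = {lab: tuple(prof[i] for i in idx) for lab, prof in profiles.items()}
        ref = tuple(reference_profile[i] for i in idx) if reference_profile is not None else None
        rep_tree = upgma_tree(profiles_distance_matrix(resampled, ref))
        rep_clades = tree_clades(rep_tree)
        for clade in clades:
            if clade in rep_clades:
                counts[clade] += 1
    return {clade: c / n_reps for clade, c in counts.items()}


def attach_supports(root: CladogramNode, supports: Mapping[frozenset[str], float]) -> CladogramNode:
    for node in root.walk():
        if not node.is_leaf:
            node.support = supports.get(node.leaves())
    return root


def nj_newick(dm: DistanceMatrix) -> str:
    """Neighbour-joining alternative (scikit-bio implementation)."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    tree = nj(SkbioDM(dm.values, ids=list(dm.labels)))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Median-joining network

def _hamming(p: tuple[str, ...], q: tuple[str, ...]) -> int:
    return sum(1 for a, b in zip(p, q) if a != b)


def _minimum_spanning_network(nodes: Sequence[tuple[str, ...]]) -> nx.Graph:
    """Relaxed MST (epsilon = 0): process distances in increasing order and,
    level by level, add every edge joining components that were distinct
    before the level started. Contains a minimum spanning tree."""
    G = nx.Graph()
    G.add_nodes_from(nodes)
    if len(nodes) < 2:
        return G
    pairs = sorted(
        ((_hamming(p, q), p, q) for p, q in combinations(nodes, 2)),
        key=lambda t: t[0],
    )
    comp = {node: i for i, node in enumerate(nodes)}
    while pairs:
        d = pairs[0][0]
        level = [t for t in pairs if t[0] == d]
        pairs = pairs[len(level):]
        added = []
        for _, p, q in level:
            if comp[p] != comp[q]:
                G.add_edge(p, q, weight=d)
                added.append((p, q))
        for p, q in added:  # merge components only after the whole level
            cp, cq = comp[p], comp[q]
            if cp != cq:
                for node, c in comp.items():
                    if c == cq:
                        comp[node] = cp
        if len(set(comp.values())) == 1:
            break
    return G


def _quasi_medians(u: tuple[str, ...], v: tuple[str, ...], w: tuple[str, ...], cap: int = 81):
    """Per-locus majority consensus; loci where all three states differ
    contribute each state (quasi-median expansion, capped)."""
    options: list[tuple[str, ...]] = []
    size = 1
    for a, b, c in zip(u, v, w):
        states = [a, b, c]
        majority = [s for s in set(states) if states.count(s) >= 2]
        opts = tuple(majority) if majority else tuple(dict.fromkeys(states))
        options.append(opts)
        size *= len(opts)
        if size > cap:
            return []
    return [m for m in product(*options) if m not in (u, v, w)]


def median_joining_network(
    profiles: Mapping[str, Sequence[str]],
    frequencies: Mapping[str, int] | None = None,
    epsilon: int = 0,
    max_iter: int = 20,
) -> nx.Graph:
    """Median-joining network on multistate profiles (epsilon = 0).

    Iterates: build the relaxed minimum spanning network over the current
    node set under Hamming distance; for every triangle add the quasi-median
    profiles; stop at a fixed point. Unobserved (median) nodes that end with
    degree <= 2 are pruned, since a degree-2 median lies on a path its
    neighbours can span directly. Node attributes: ``label``, ``frequency``
    (0 for medians), ``observed``; edge attribute ``loci`` lists the
    differing markers.
    """
    if epsilon != 0:
        raise NotImplementedError("only epsilon = 0 is supported")
    observed = {tuple(p): lab for lab, p in profiles.items()}
    if len(observed) != len(profiles):
        raise DataError("duplicate profiles across classes")
    nodes: set[tuple[str, ...]] = set(observed)
    for _ in range(max_iter):
        G = _minimum_spanning_network(sorted(nodes))
        new: set[tuple[str, ...]] = set()
        for u, v, w in _triangles(G):
            for m in _quasi_medians(u, v, w):
                if m not in nodes:
                    new.add(m)
        if not new:
            break
        nodes |= new
    # prune medians that did not become junctions
    while True:
        G = _minimum_spanning_network(sorted(nodes))
        prunable = [n for n in G.nodes if n not in observed and G.degree(n) <= 2]
        if not prunable:
            break
        nodes -= set(prunable)
    markers = list(range(len(next(iter(nodes)))))
    freqs = frequencies or {}
    for node in G.nodes:
        lab = observed.get(node)
        G.nodes[node]["label"] = lab if lab is not None else "median"
        G.nodes[node]["observed"] = lab is not None
        G.nodes[node]["frequency"] = int(freqs.get(lab, 1)) if lab is not None else 0
    for u, v in G.edges:
        G.edges[u, v]["loci"] = [i for i in markers if u[i] != v[i]]
    return G


def _triangles(G: nx.Graph):
    seen = set()
    for u, v in G.edges:
        for w in set(G.neighbors(u)) & set(G.neighbors(v)):
            trio = tuple(sorted((u, v, w)))
            if trio not in seen:
                seen.add(trio)
                yield trio


def write_gml(G: nx.Graph, path, marker_names: Sequence[str] | None = None) -> None:
    """GML export with string node ids and locus-name edge labels."""
    H = nx.Graph()
    for i, node in enumerate(sorted(G.nodes)):
        H.add_node(
            "/".join(node),
            label=G.nodes[node]["label"],
            frequency=G.nodes[node]["frequency"],
            observed=int(G.nodes[node]["observed"]),
        )
    for u, v, data in G.edges(data=True):
        loci = data.get("loci", [])
        names = [marker_names[i] for i in loci] if marker_names else [str(i) for i in loci]
        H.add_edge("/".join(u), "/".join(v), loci=",".join(names), weight=len(loci))
    nx.write_gml(H, path)
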