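"""Overlapping module discovery by link-community (edge) clustering.

Edges, not genes, are clustered: adjacent edges (sharing one endpoint)
are scored by the Jaccard similarity of the closed neighbourhoods of
their non-shared endpoints, single-linkage clustered, and the dendrogram
is cut at the height maximizing the partition density D.  Because a gene
can carry edges in several edge communities, genes may belong to multiple
modules — edge sets never overlap, node sets may.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gilnet.rmt_network import GILNetwork

__all__ = [
    "LinkCommunityModule",
    "edge_similarity",
    "partition_density",
    "detect_link_communities",
    "name_modules",
]

Edge = tuple[str, str]


@dataclass
class LinkCommunityModule:
    """A named set of edges (and the genes they induce) from one GIL."""

    module_name: str
    edges: list[Edge]
    gil_id: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        induced = {g for e in self.edges for g in e}
        if not self.genes:
            self.genes = induced
        elif self.genes != induced:
            raise ValueError("module gene set must equal the union of edge endpoints")

    @property
    def size(self) -> int:
        return len(self.genes)


def _closed_neighborhoods(net: GILNetwork) -> dict[str, frozenset]:
    adj = net.neighbors()
    return {v: frozenset(nbrs | {v}) for v, nbrs in adj.items()}


def edge_similarity(net: GILNetwork, e1: Edge, e2: Edge) -> float:
    """Jaccard similarity of two adjacent edges.

    With k the shared node and i, j the non-shared endpoints, and
    n+(x) = {x} union neighbors(x):  S = |n+(i) & n+(j)| / |n+(i) | n+(j)|.
    Only defined for edge pairs sharing exactly one node.
    """
    shared = set(e1) & set(e2)
    if len(shared) != 1:
        raise ValueError("edge similarity is defined only for edges sharing exactly one node")
    (i,) = set(e1) - shared
    (j,) = set(e2) - shared
    nbh = _closed_neighborhoods(net)
    ni, nj = nbh[i], nbh[j]
    return len(ni & nj) / len(ni | nj)


def _community_density(m_c: int, n_c: int) -> float:
    """Per-community term m_c * (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1)); 0 if n_c = 2."""
    if n_c <= 2:
        return 0.0
    return m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))


def partition_density(net: GILNetwork, partition: list[set[Edge]]) -> float:
    """Partition density D of an edge partition of the network.

    D = (2/M) * sum_c m_c (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1));
    1 for clique-like communities, 0 for tree-like or singleton ones.
    """
    if not partition:
        raise ValueError("empty partition")
    M = len(net.edges)
    covered = sum(len(c) for c in partition)
    if covered != M or set().union(*partition) != net.edge_set:
        raise ValueError("partition must cover every edge exactly once")
    total = 0.0
    for community in partition:
        nodes = {g for e in community for g in e}
        total += _community_density(len(community), len(nodes))
    return 2.0 * total / M


class _EdgeClustering:
    """Union-find over edges with incremental partition-density bookkeeping."""

    def __init__(self, edges: list[Edge]):
        self.parent = list(range(len(edges)))
        self.edge_count = [1] * len(edges)
        self.node_sets = [set(e) for e in edges]
        self.density_sum = 0.0  # all singleton clusters contribute 0

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def merge(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if len(self.node_sets[ri]) < len(self.node_sets[rj]):
            ri, rj = rj, ri
        self.density_sum -= _community_density(self.edge_count[ri], len(self.node_sets[ri]))
        self.density_sum -= _community_density(self.edge_count[rj], len(self.node_sets[rj]))
        self.parent[rj] = ri
        self.edge_count[ri] += self.edge_count[rj]
        self.node_sets[ri] |= self.node_sets[rj]
        self.node_sets[rj] = set()
        self.density_sum += _community_density(self.edge_count[ri], len(self.node_sets[ri]))

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return out


def _adjacent_pair_similarities(net: GILNetwork) -> list[tuple[float, int, int]]:
    """(similarity, edge_index_a, edge_index_b) for every adjacent edge pair."""
    edges = net.edges
    nbh = _closed_neighborhoods(net)
    incident: dict[str, list[int]] = {}
    for idx, (a, b, _) in enumerate(edges):
        incident.setdefault(a, []).append(idx)
        incident.setdefault(b, []).append(idx)
    pairs: list[tuple[float, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for k, edge_idx in incident.items():
        for x in range(len(edge_idx)):
            for y in range(x + 1, len(edge_idx)):
                e1, e2 = edge_idx[x], edge_idx[y]
                key = (e1, e2)
                if key in seen:
                    continue  # two edges can share at most one node in a simple graph
                seen.add(key)
                i = edges[e1][0] if edges[e1][1] == k else edges[e1][1]
                j = edges[e2][0] if edges[e2][1] == k else edges[e2][1]
                ni, nj = nbh[i], nbh[j]
                pairs.append((len(ni & nj) / len(ni | nj), e1, e2))
    return pairs


def detect_link_communities(
    net: GILNetwork, min_edges: int = 2, return_profile: bool = False
):
    """Single-linkage edge clustering cut at maximum partition density.

    The sparse list of adjacent-edge-pair similarities is merged in
    descending similarity order (exact single linkage on the line graph;
    non-adjacent pairs are simply never candidates).  After exhausting
    each distinct similarity level the partition density is evaluated;
    the partition with maximum D is returned, ties broken toward the
    finest partition (lowest dendrogram height).  Edge clusters smaller
    than ``min_edges`` are discarded as unclustered.
    """
    edges = net.edges
    if not edges:
        return ([], []) if return_profile else []
    M = len(edges)
    pairs = _adjacent_pair_similarities(net)
    pairs.sort(key=lambda p: -p[0])

    uf = _EdgeClustering([(a, b) for a, b, _ in edges])
    best_density = 0.0  # the all-singletons partition has D = 0
    best_partition = [[i] for i in range(M)]
    profile = [(1.0, 0.0)]  # (similarity level, D) — finest partition first
    pos = 0
    while pos < len(pairs):
        level = pairs[pos][0]
        while pos < len(pairs) and pairs[pos][0] == level:
            uf.merge(pairs[pos][1], pairs[pos][2])
            pos += 1
        density = 2.0 * uf.density_sum / M
        profile.append((level, density))
        if density > best_density:  # strict: ties keep the finer (earlier) cut
            best_density = density
            best_partition = list(uf.clusters().values())

    modules = []
    for cluster in best_partition:
        if len(cluster) < min_edges:
            continue
        mod_edges = sorted((edges[i][0], edges[i][1]) for i in cluster)
        modules.append(LinkCommunityModule("", mod_edges, net.gil_id))
    modules.sort(key=lambda m: (-len(m.edges), min(m.genes)))
    if return_profile:
        return modules, profile
    return modules


def name_modules(
    collection_tag: str, gil_id: str, modules: list[LinkCommunityModule]
) -> list[LinkCommunityModule]:
    """Assign the three-part names {collection}_{gil}_LCMnnnn.

    Modules are ordered deterministically (descending edge count, ties by
    lexicographically smallest gene id) and numbered from 1.
    """
    ordered = sorted(modules, key=lambda m: (-len(m.edges), min(m.genes)))
    named = []
    for i, mod in enumerate(ordered, start=1):
        named.append(
            LinkCommunityModule(
                f"{collection_tag}_{gil_id}_LCM{i:04d}", list(mod.edges), gil_id
            )
        )
    return named
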