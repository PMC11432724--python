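"""Residue interaction networks and allosteric hotspot analysis.

Nodes are residues; an edge joins residues that stay in contact persistently
across the ensemble, weighted by the communication distance

    w_ij = −log R(X_i, X_j),

where R is the generalized correlation of the pair's motions — strongly
correlated residues are "close" in communication terms.  On this graph:

* all-pairs shortest paths and path counts come from a Floyd–Warshall sweep;
* residue betweenness C_b(n_i) = Σ_{j<k} g_jk(i)/g_jk (fraction of shortest
  paths through i, endpoints excluded), standardized to Z-scores; residues
  with Z >= 2 are called allosteric hotspots;
* communities are found by Girvan–Newman edge-betweenness removal, keeping
  the partition of maximal modularity;
* per-node bridgeness G_i = Σ_{J≠I} δ_iJ · l_IJ sums, over foreign
  communities J that node i touches, the effective inter-community distance
  l_IJ = 1 / (#edges between I and J) — a Rao–Stirling-style measure of
  global-bridge character;
* mutation sites are mapped onto hotspots as direct / proximal (< 5 Å) /
  distal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix, PersistenceMatrix

logger = logging.getLogger("alloscan")

__all__ = [
    "ResidueInteractionNetwork",
    "ShortestPathEnsemble",
    "CentralityProfile",
    "CommunityPartition",
    "BridgenessProfile",
    "HotspotMapping",
    "build_network",
    "shortest_paths",
    "betweenness_profile",
    "detect_communities",
    "bridgeness_profile",
    "map_mutations",
]

#: Tolerance on path-length equality when counting co-optimal shortest paths.
PATH_TOL = 1e-9

_R_CLAMP = 1.0 - 1e-12
_WEIGHT_FLOOR = 1e-12


@dataclass
class ResidueInteractionNetwork:
    """Persistence-filtered, GC-weighted residue graph."""

    graph: nx.Graph                # nodes = residue ids, edge attr "weight"
    gc: CorrelationMatrix

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)


def build_network(
    persistence: PersistenceMatrix, gc: CorrelationMatrix
) -> ResidueInteractionNetwork:
    """Assemble the residue interaction network from contacts and correlations.

    Edges are the persistent non-covalent contacts; each edge carries the
    communication distance −log R.  R values at (or numerically above) 1 are
    clamped just below 1 so the weight floors at 1e-12 instead of collapsing
    to zero; pairs with R = 0 would have infinite distance and are dropped
    with a warning.
    """
    if not np.array_equal(persistence.residue_ids, gc.residue_ids):
        raise ValueError("persistence and correlation matrices use different residue ids")
    ids = persistence.residue_ids
    adj = persistence.adjacency
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in ids)
    dropped = 0
    for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
        r = gc.matrix[i, j]
        if r <= 0.0:
            dropped += 1
            continue
        w = max(-np.log(min(r, _R_CLAMP)), _WEIGHT_FLOOR)
        g.add_edge(int(ids[i]), int(ids[j]), weight=float(w), gc=float(r))
    if dropped:
        logger.warning("%d persistent contact(s) had R = 0 and were dropped (infinite distance)", dropped)
    return ResidueInteractionNetwork(graph=g, gc=gc)


# ---------------------------------------------------------------------------
# Shortest paths (Floyd–Warshall with path counting)
# ---------------------------------------------------------------------------

@dataclass
class ShortestPathEnsemble:
    """All-pairs shortest distances and shortest-path multiplicities."""

    nodes: list[int]
    dist: np.ndarray     # (n, n), inf for disconnected pairs
    counts: np.ndarray   # (n, n), number of co-optimal shortest paths


def shortest_paths(network: ResidueInteractionNetwork) -> ShortestPathEnsemble:
    """All-pairs weighted shortest paths by the Floyd–Warshall algorithm.

    Path multiplicities count every co-optimal path (ties resolved within
    1e-9 on total length); disconnected pairs keep infinite distance and a
    count of zero.
    """
    nodes = network.nodes
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    if n < 1:
        raise ValueError("network has no nodes")
    dist = np.full((n, n), np.inf)
    counts = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(counts, 1.0)
    for u, v, data in network.graph.edges(data=True):
        w = data["weight"]
        assert w >= 0.0, "negative edge weight"
        i, j = index[u], index[v]
        dist[i, j] = dist[j, i] = w
        counts[i, j] = counts[j, i] = 1.0

    off_diag = ~np.eye(n, dtype=bool)
    with np.errstate(invalid="ignore"):  # inf - inf comparisons are masked out
        for k in range(n):
            alt = dist[:, k][:, None] + dist[k, :][None, :]
            cnt = counts[:, k][:, None] * counts[k, :][None, :]
            valid = off_diag.copy()
            valid[k, :] = False
            valid[:, k] = False
            shorter = valid & (alt < dist - PATH_TOL)
            equal = valid & ~shorter & np.isfinite(alt) & (np.abs(alt - dist) <= PATH_TOL)
            dist[shorter] = alt[shorter]
            counts[shorter] = cnt[shorter]
            counts[equal] += cnt[equal]
    return ShortestPathEnsemble(nodes=nodes, dist=dist, counts=counts)


# ---------------------------------------------------------------------------
# Betweenness and hotspots
# ---------------------------------------------------------------------------

@dataclass
class CentralityProfile:
    """Per-residue betweenness, Z-scores and the Z >= 2 hotspot set."""

    nodes: list[int]
    betweenness: np.ndarray
    z_scores: np.ndarray
    hotspots: list[int]
    z_threshold: float = 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.nodes,
                "betweenness": self.betweenness,
                "z_score": self.z_scores,
                "hotspot": [v in set(self.hotspots) for v in self.nodes],
            }
        )


def betweenness_profile(
    paths: ShortestPathEnsemble, z_threshold: float = 2.0
) -> CentralityProfile:
    """Betweenness centrality from shortest-path counts, with Z-score hotspots.

    C_b(n_i) sums, over all connected pairs j < k with both distinct from i,
    the fraction of shortest j-k paths passing through i (unnormalized raw
    sums; the Z-scoring makes any scale factor irrelevant).  Pairs in other
    components contribute nothing.  Z-scores standardize the centralities over
    all nodes; if every node has equal centrality all Z are 0 and no hotspot
    is called.
    """
    d, g = paths.dist, paths.counts
    n = len(paths.nodes)
    between = np.zeros(n)
    finite = np.isfinite(d)
    for i in range(n):
        with np.errstate(invalid="ignore"):  # inf - inf pairs are masked by `finite`
            via = d[:, i][:, None] + d[i, :][None, :]
            on_path = finite & (np.abs(via - d) <= PATH_TOL)
        on_path[i, :] = False
        on_path[:, i] = False
        np.fill_diagonal(on_path, False)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(on_path, (g[:, i][:, None] * g[i, :][None, :]) / g, 0.0)
        between[i] = np.triu(frac, k=1).sum()

    sd = between.std()
    if sd == 0.0:
        logger.warning("all nodes have equal centrality; no hotspots called")
        z = np.zeros(n)
        hotspots: list[int] = []
    else:
        z = (between - between.mean()) / sd
        hotspots = [paths.nodes[i] for i in np.flatnonzero(z >= z_threshold)]
    return CentralityProfile(paths.nodes, between, z, hotspots, z_threshold)


# ---------------------------------------------------------------------------
# Communities and bridgeness
# ---------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    """Modularity-optimal Girvan–Newman partition."""

    membership: dict[int, int]     # node -> community id
    modularity: float
    dendrogram: list[list[set[int]]] = field(repr=False, default_factory=list)

    @property
    def communities(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


def detect_communities(
    network: ResidueInteractionNetwork, max_communities: int | None = None
) -> CommunityPartition:
    """Girvan–Newman community detection, keeping the best-modularity level.

    Edges of maximal (weighted-shortest-path) edge betweenness are removed
    iteratively; along the removal dendrogram — including the trivial single
    community — the partition maximizing Newman modularity (on the unweighted
    topology) is returned.  ``max_communities`` truncates the dendrogram for
    large graphs.
    """
    g = network.graph
    if g.number_of_nodes() < 1:
        raise ValueError("empty network")
    levels: list[list[set[int]]] = [[set(c) for c in nx.connected_components(g)]]
    if g.number_of_edges() > 0:

        def heaviest(graph: nx.Graph):
            eb = nx.edge_betweenness_centrality(graph, weight="weight")
            return max(eb, key=eb.get)

        limit = max_communities or g.number_of_nodes()
        for level in nx.community.girvan_newman(g, most_valuable_edge=heaviest):
            levels.append([set(c) for c in level])
            if len(level) >= limit:
                break

    best, best_q = None, -np.inf
    for part in levels:
        q = nx.community.modularity(g, part, weight=None) if g.number_of_edges() else 0.0
        if q > best_q + 1e-12:
            best, best_q = part, q
    membership = {
        node: cid
        for cid, comm in enumerate(sorted(best, key=lambda c: min(c)))
        for node in comm
    }
    return CommunityPartition(membership=membership, modularity=float(best_q), dendrogram=levels)


@dataclass
class BridgenessProfile:
    """Per-node inter-community bridgeness G_i."""

    nodes: list[int]
    bridgeness: np.ndarray
    inter_community_links: dict[tuple[int, int], int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.nodes, "bridgeness": self.bridgeness})


def bridgeness_profile(
    network: ResidueInteractionNetwork, partition: CommunityPartition
) -> BridgenessProfile:
    """Bridgeness G_i = Σ_{J≠I} δ_iJ / (#edges between I and J).

    δ_iJ indicates whether node i (of community I) has at least one edge into
    community J; the effective distance l_IJ is the inverse of the total
    I-J edge count.  Nodes with only intra-community edges score exactly 0.
    """
    g = network.graph
    member = partition.membership
    if set(member) != set(g.nodes):
        raise ValueError("partition does not cover the network's nodes")

    links: dict[tuple[int, int], int] = {}
    for u, v in g.edges:
        cu, cv = member[u], member[v]
        if cu != cv:
            key = (min(cu, cv), max(cu, cv))
            links[key] = links.get(key, 0) + 1

    nodes = network.nodes
    values = np.zeros(len(nodes))
    for idx, node in enumerate(nodes):
        own = member[node]
        touched = {member[nb] for nb in g.neighbors(node)} - {own}
        for other in touched:
            key = (min(own, other), max(own, other))
            values[idx] += 1.0 / links[key]
    return BridgenessProfile(nodes=nodes, bridgeness=values, inter_community_links=links)


# ---------------------------------------------------------------------------
# Mutation-to-hotspot mapping
# ---------------------------------------------------------------------------

@dataclass
class HotspotMapping:
    """Relation of mutation sites to the called allosteric hotspots."""

    table: pd.DataFrame   # columns: site, status, distance, nearest_hotspot

    def status_of(self, site: int) -> str:
        return str(self.table.set_index("site").loc[site, "status"])


def map_mutations(
    sites: list[int],
    profile: CentralityProfile,
    coordinates: dict[int, np.ndarray],
    proximity: float = 5.0,
) -> HotspotMapping:
    """Classify mutation sites as direct hotspots, proximal (< 5 Å) or distal.

    ``coordinates`` maps residue id to the Cα position of a designated
    representative model (conventionally the first model of the state's
    ensemble).  A site directly in the hotspot set maps at distance 0; else
    the minimal Cα distance to any hotspot decides proximal vs distal.
    """
    node_set = set(profile.nodes)
    absent = [s for s in sites if s not in node_set]
    if absent:
        raise ValueError(f"mutation site(s) not in the network: {absent}")
    hotspot_set = set(profile.hotspots)
    rows = []
    for site in sites:
        if site in hotspot_set:
            rows.append({"site": site, "status": "direct_hotspot", "distance": 0.0,
                         "nearest_hotspot": site})
            continue
        if not hotspot_set:
            rows.append({"site": site, "status": "distal", "distance": np.inf,
                         "nearest_hotspot": None})
            continue
        dists = {h: float(np.linalg.norm(coordinates[site] - coordinates[h]))
                 for h in hotspot_set}
        nearest = min(dists, key=dists.get)
        d = dists[nearest]
        status = "proximal" if d < proximity else "distal"
        rows.append({"site": site, "status": status, "distance": d, "nearest_hotspot": nearest})
    return HotspotMapping(table=pd.DataFrame(rows))


def export_graphml(
    network: ResidueInteractionNetwork,
    profile: CentralityProfile | None = None,
    partition: CommunityPartition | None = None,
    bridgeness: BridgenessProfile | None = None,
    path: str | None = None,
):
    """Write the network as GraphML with per-node analysis attributes."""
    g = network.graph.copy()
    if profile is not None:
        hot = set(profile.hotspots)
        for node, b, z in zip(profile.nodes, profile.betweenness, profile.z_scores):
            g.nodes[node]["betweenness"] = float(b)
            g.nodes[node]["z_score"] = float(z)
            g.nodes[node]["hotspot"] = node in hot
    if partition is not None:
        for node, c in partition.membership.items():
            g.nodes[node]["community"] = int(c)
    if bridgeness is not None:
        for node, v in zip(bridgeness.nodes, bridgeness.bridgeness):
            g.nodes[node]["bridgeness"] = float(v)
    if path is not None:
        nx.write_graphml(g, path)
    return g
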