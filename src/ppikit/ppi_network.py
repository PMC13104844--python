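"""Evidence-filtered PPI network construction and recursive Leiden clustering.

The network keeps edges passing both a confidence threshold and an evidence
requirement (literature support or ortholog conservation), prunes
low-degree nodes in a single pass, and extracts the giant component.
Community structure is resolved hierarchically: a fixed-resolution Leiden
partition at the top level, then per-cluster resolution optimization with a
size-preserving label-permutation test deciding whether each split is
retained, recursing one level further.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_network",
    "modularity",
    "leiden_partition",
    "optimize_resolution",
    "permutation_split_test",
    "SplitTest",
    "ClusterNode",
    "recursive_cluster",
    "hypergeometric_enrichment",
    "DEFAULT_RESOLUTION_GRID",
]

DEFAULT_RESOLUTION_GRID = tuple(np.round(np.arange(0.5, 4.0 + 1e-9, 0.1), 1))


def build_network(
    edges: pd.DataFrame,
    ilis_threshold: float = 0.223,
    ortholog_min: int = 4,
    min_degree: int = 2,
    iterative_prune: bool = False,
) -> nx.Graph:
    """Build the evidence-supported network from a scored edge table.

    ``edges`` needs columns ``gene_a``, ``gene_b``, ``ilis_best``,
    ``literature_support`` (bool) and ``ortholog_score`` (int). An edge
    survives iff its score passes the threshold AND it has literature
    support or an ortholog score of at least ``ortholog_min``. Self-edges
    are dropped and duplicate unordered pairs collapsed (max score wins).
    Nodes of degree < ``min_degree`` are then removed — in a single pass by
    default (neighbors whose degree drops are not re-pruned) — and the
    largest connected component is returned.
    """
    if edges.empty:
        raise ValueError("edge list is empty")
    df = edges.copy()
    df = df[df["gene_a"] != df["gene_b"]]
    keep = (df["ilis_best"] >= ilis_threshold) & (
        df["literature_support"].astype(bool) | (df["ortholog_score"] >= ortholog_min)
    )
    df = df[keep]
    if df.empty:
        raise ValueError("no edges pass the confidence/evidence filter")
    pair = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    df = df.assign(_pair=pair).sort_values("ilis_best").drop_duplicates("_pair", keep="last")

    g = nx.Graph()
    for _, r in df.iterrows():
        a, b = r["_pair"]
        g.add_edge(a, b, ilis_best=float(r["ilis_best"]))
    if iterative_prune:
        while True:
            low = [n for n, d in g.degree() if d < min_degree]
            if not low:
                break
            g.remove_nodes_from(low)
    else:
        g.remove_nodes_from([n for n, d in g.degree() if d < min_degree])
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty after degree pruning")
    giant = max(nx.connected_components(g), key=len)
    return g.subgraph(giant).copy()


def modularity(graph: nx.Graph, partition: dict, gamma: float = 1.0) -> float:
    """Configuration-model modularity of a node->community partition.

    ``Q = sum_c [ e_c/m - gamma * (d_c / 2m)^2 ]`` with ``m`` the edge
    count, ``e_c`` the intra-community edge count and ``d_c`` the total
    degree of community ``c``.
    """
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    missing = set(graph.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    intra: dict = {}
    deg: dict = {}
    for u, v in graph.edges():
        cu, cv = partition[u], partition[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0) + 1
    for n, d in graph.degree():
        c = partition[n]
        deg[c] = deg.get(c, 0) + d
    q = 0.0
    for c in deg:
        q += intra.get(c, 0) / m - gamma * (deg[c] / (2 * m)) ** 2
    return q


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges()])
    return g, nodes


def leiden_partition(graph: nx.Graph, resolution: float = 1.0, seed: int = 42) -> dict:
    """Leiden partition under the RB-configuration objective.

    Deterministic for a fixed seed and leidenalg version. Returns a
    node -> community-index dict.
    """
    g, nodes = _to_igraph(graph)
    part = la.find_partition(
        g, la.RBConfigurationVertexPartition, resolution_parameter=resolution, seed=seed
    )
    return {nodes[i]: part.membership[i] for i in range(len(nodes))}


def optimize_resolution(
    graph: nx.Graph,
    r_grid=DEFAULT_RESOLUTION_GRID,
    seed: int = 42,
) -> tuple[float, dict, float]:
    """Scan a resolution grid; keep the partition maximizing plain modularity.

    Modularity is evaluated at gamma = 1 regardless of the resolution used
    to generate the candidate partition. Ties break toward the smallest
    resolution.
    """
    if graph.number_of_nodes() < 2 or graph.number_of_edges() < 1:
        raise ValueError("need at least 2 nodes and 1 edge")
    best = None
    for r in r_grid:
        part = leiden_partition(graph, resolution=float(r), seed=seed)
        q = modularity(graph, part, gamma=1.0)
        if best is None or q > best[2]:
            best = (float(r), part, q)
    return best


@dataclass
class SplitTest:
    accepted: bool
    observed_q: float
    null_q: np.ndarray
    percentile_value: float


def permutation_split_test(
    graph: nx.Graph,
    partition: dict,
    n_shuffle: int = 100,
    percentile: float = 95,
    seed: int | None = None,
) -> SplitTest:
    """Size-preserving label-shuffle null for a candidate split.

    Node-to-community assignments are permuted ``n_shuffle`` times over the
    same community-size multiset; the split is accepted iff the observed
    modularity strictly exceeds the nearest-rank ``percentile``-th order
    statistic of the null modularities. A single-community partition is
    rejected trivially.
    """
    nodes = list(graph.nodes)
    labels = np.array([partition[n] for n in nodes])
    observed = modularity(graph, partition, gamma=1.0)
    if len(set(labels.tolist())) < 2:
        return SplitTest(False, observed, np.array([]), np.nan)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        perm = rng.permutation(labels)
        null[i] = modularity(graph, dict(zip(nodes, perm)), gamma=1.0)
    k = int(np.ceil(percentile / 100 * n_shuffle)) - 1  # nearest-rank order statistic
    cut = float(np.sort(null)[k])
    return SplitTest(observed > cut, observed, null, cut)


@dataclass
class ClusterNode:
    """One node of the cluster hierarchy."""

    id_path: str
    level: str  # "cluster" | "sub" | "subsub"
    members: list
    resolution: float | None = None
    modularity: float | None = None
    perm_percentile: float | None = None
    accepted: bool = False  # whether this node's own split was accepted
    children: list = field(default_factory=list)

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def to_dict(self) -> dict:
        return {
            "id": self.id_path,
            "level": self.level,
            "n_members": len(self.members),
            "members": sorted(map(str, self.members)),
            "resolution": self.resolution,
            "modularity": self.modularity,
            "perm_percentile": self.perm_percentile,
            "accepted": self.accepted,
            "children": [c.to_dict() for c in self.children],
        }


_NEXT_LEVEL = {"cluster": "sub", "sub": "subsub"}


def _try_split(
    graph: nx.Graph,
    node: ClusterNode,
    seed: int,
    min_size: int,
    n_shuffle: int,
    r_grid,
) -> None:
    """Attempt a permutation-validated split of one tree node, recursing."""
    sub = graph.subgraph(node.members)
    if sub.number_of_nodes() < 2 or sub.number_of_edges() < 1:
        return
    r, part, q = optimize_resolution(sub, r_grid=r_grid, seed=seed)
    node.resolution, node.modularity = r, q
    if len(set(part.values())) < 2:
        return
    test = permutation_split_test(sub, part, n_shuffle=n_shuffle, seed=seed)
    node.perm_percentile = test.percentile_value
    if not test.accepted:
        return
    node.accepted = True
    child_level = _NEXT_LEVEL[node.level]
    groups: dict = {}
    for n, c in part.items():
        groups.setdefault(c, []).append(n)
    for i, comm in enumerate(sorted(groups.values(), key=len, reverse=True), start=1):
        child = ClusterNode(id_path=f"{node.id_path}-{i}", level=child_level, members=sorted(comm))
        node.children.append(child)
        if child_level in _NEXT_LEVEL and len(comm) >= min_size:
            _try_split(graph, child, seed, min_size, n_shuffle, r_grid)


def recursive_cluster(
    graph: nx.Graph,
    seed: int = 42,
    resolution: float = 1.1,
    min_size: int = 5,
    n_shuffle: int = 100,
    r_grid=DEFAULT_RESOLUTION_GRID,
) -> ClusterNode:
    """Three-level permutation-validated community hierarchy.

    Level 1 is an unconditional Leiden partition at ``resolution``. Each
    level-1 cluster of at least ``min_size`` genes is then sub-clustered via
    per-cluster resolution optimization and the size-preserving permutation
    test; accepted splits recurse once more under the same criterion.
    Returns the tree root, whose children are the level-1 clusters.
    """
    part = leiden_partition(graph, resolution=resolution, seed=seed)
    root = ClusterNode(
        id_path="root",
        level="root",
        members=sorted(graph.nodes),
        resolution=resolution,
        modularity=modularity(graph, part, gamma=1.0),
        accepted=True,
    )
    groups: dict = {}
    for n, c in part.items():
        groups.setdefault(c, []).append(n)
    for i, comm in enumerate(sorted(groups.values(), key=len, reverse=True), start=1):
        node = ClusterNode(id_path=f"C{i}", level="cluster", members=sorted(comm))
        root.children.append(node)
        if len(comm) >= min_size:
            _try_split(graph, node, seed, min_size, n_shuffle, r_grid)
    return root


def tree_to_json(root: ClusterNode, path) -> None:
    with open(path, "w") as fh:
        json.dump(root.to_dict(), fh, indent=1)


def hypergeometric_enrichment(
    cluster_genes,
    annotation: dict,
    background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with BH correction.

    ``annotation`` maps term -> set of annotated genes. Terms with no
    annotated gene in the background are skipped; within the cluster, BH
    adjustment is applied across all tested terms and terms with adjusted
    p < ``alpha`` are returned, most significant first.
    """
    background = set(background)
    cluster = set(cluster_genes)
    if not cluster <= background:
        raise ValueError("cluster genes must be a subset of the background")
    N, n = len(background), len(cluster)
    rows = []
    for term, genes in annotation.items():
        K = len(set(genes) & background)
        if K == 0:
            continue
        k = len(set(genes) & cluster)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "n_annotated": K, "n_overlap": k, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "n_annotated", "n_overlap", "p", "p_adj"])
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df[df["p_adj"] < alpha].sort_values(["p_adj", "p"]).reset_index(drop=True)
    return df
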