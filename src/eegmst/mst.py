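"""Minimum spanning tree construction on 1−PLI distances and tree metrics.

The MST of the connectivity graph (link distance = 1 − PLI) is the unique
loop-free sub-network connecting all N electrodes with m = N−1 links of
maximal total PLI: a "connectivity backbone". Because every MST has exactly
m links, its topology metrics can be compared across groups and conditions
without the threshold bias that raw weighted networks suffer from.

Metrics
-------
degree          highest node degree (raw and ÷m)
leaf number L   count of degree-1 nodes; 2 ≤ L ≤ N−1
leaf fraction   L ÷ m
diameter d      longest shortest path in hops; d ≤ m − L + 2
eccentricity    per-node longest shortest path; mean and max summaries
BC              betweenness centrality, pair-normalized to [0, 1]; BC_max
T_H             tree hierarchy L / (2·m·BC_max) — balances short diameter
                (efficient communication) against hub overload (high BC_max)
R               degree correlation: Pearson correlation of degrees over
                connected node pairs (assortativity); undefined when all
                link endpoints have equal degree (e.g. a star)
kappa           ⟨k²⟩/⟨k⟩, width of the degree distribution (hub presence)
MST mean        mean PLI weight over the tree's links
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix, epoch_pli_matrices
from .core import EpochedRecording

__all__ = [
    "SpanningTree",
    "TreeMetrics",
    "kruskal_mst",
    "tree_metrics",
    "average_tree_metrics",
    "subject_band_metrics",
    "METRIC_NAMES",
]


@dataclass
class SpanningTree:
    """An N-node, (N−1)-link tree with PLI link weights.

    ``links`` are (i, j, pli_weight) with i < j; the distance convention is
    1 − PLI throughout.
    """

    n_nodes: int
    links: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.links) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} links, got {len(self.links)}"
            )
        g = self.to_networkx()
        if not nx.is_connected(g):
            raise ValueError("links do not form a connected tree")

    @property
    def m(self) -> int:
        """Number of links, always N − 1."""
        return self.n_nodes - 1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.links, weight="pli")
        return g

    def total_distance(self) -> float:
        """Sum of 1 − PLI over the tree's links."""
        return float(sum(1.0 - w for _, _, w in self.links))

    def to_parent_list(self, root: int = 0) -> list[int]:
        """Parent index per node from a rooted traversal (root's parent −1).

        A compact serialization for tree-view rendering: node i hangs under
        ``parents[i]``.
        """
        g = self.to_networkx()
        parents = [-1] * self.n_nodes
        for child, parent in nx.bfs_predecessors(g, root):
            parents[child] = parent
        return parents

    def mean_pli(self) -> float:
        return float(np.mean([w for _, _, w in self.links]))


def kruskal_mst(pli: ConnectivityMatrix | np.ndarray, jitter_seed: int | None = None) -> SpanningTree:
    """Kruskal's algorithm on link distances 1 − PLI.

    Links are sorted by ascending distance and added whenever they join two
    previously unconnected components; the result is the spanning tree of
    minimum total distance, i.e. maximum total PLI. Ties in distance are
    broken lexicographically by (i, j) so the output is deterministic; with
    ``jitter_seed`` a 1e−12-scale reproducible perturbation enforces the
    strict-uniqueness assumption instead.
    """
    values = pli.values if isinstance(pli, ConnectivityMatrix) else np.asarray(pli, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"PLI matrix must be square, got {values.shape}")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("PLI matrix must be symmetric")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")

    iu, ju = np.triu_indices(n, k=1)
    weights = values[iu, ju]
    dist = 1.0 - weights
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        dist = dist + rng.uniform(-0.5e-12, 0.5e-12, size=dist.shape)
    # sort by (distance, i, j); lexsort keys are last-is-primary
    order = np.lexsort((ju, iu, dist))

    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    links: list[tuple[int, int, float]] = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            links.append((i, j, float(weights[idx])))
            if len(links) == n - 1:
                break
    return SpanningTree(n_nodes=n, links=links)


@dataclass
class TreeMetrics:
    """Topology metrics of one spanning tree (see module docstring)."""

    n_nodes: int
    degree_max: float
    degree_max_norm: float
    leaf_number: float
    leaf_fraction: float
    diameter: float
    diameter_norm: float
    eccentricity_mean: float
    eccentricity_mean_norm: float
    eccentricity_max: float
    bc_max: float
    bc_mean: float
    tree_hierarchy: float
    degree_correlation: float | None
    kappa: float
    mst_mean: float

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Metric column order used in pipeline outputs.
METRIC_NAMES = [f.name for f in fields(TreeMetrics) if f.name != "n_nodes"]


def tree_metrics(tree: SpanningTree) -> TreeMetrics:
    """Compute the full MST metric suite for one tree.

    Betweenness centrality uses pair normalization 2/((N−1)(N−2)), so leaves
    score 0 and a star center scores 1. The degree correlation is the
    Pearson correlation over symmetrized link endpoint degree pairs and is
    reported as None (undefined) when endpoint degrees have zero variance.
    Tree hierarchy uses the leaf *number*: T_H = L / (2·m·BC_max), which
    puts a star exactly at 0.5.
    """
    n, m = tree.n_nodes, tree.m
    if n < 3:
        raise ValueError("tree metrics need at least 3 nodes")
    g = tree.to_networkx()

    degrees = np.array([d for _, d in g.degree()], dtype=float)
    leaf_number = int((degrees == 1).sum())
    ecc = nx.eccentricity(g)
    ecc_values = np.array(list(ecc.values()), dtype=float)
    diameter = float(ecc_values.max())
    bc = nx.betweenness_centrality(g, normalized=True)
    bc_values = np.array(list(bc.values()), dtype=float)
    bc_max = float(bc_values.max())

    # degree assortativity: Pearson over degrees of connected node pairs,
    # each link counted in both directions. When every link joins the same
    # unordered degree pair (e.g. hub-leaf in a star) there is no variation
    # across links to correlate and R is undefined; the symmetrized Pearson
    # would return an artifactual -1 there.
    pair_types = {tuple(sorted((degrees[i], degrees[j]))) for i, j, _ in tree.links}
    end_a, end_b = [], []
    for i, j, _ in tree.links:
        end_a += [degrees[i], degrees[j]]
        end_b += [degrees[j], degrees[i]]
    end_a, end_b = np.array(end_a), np.array(end_b)
    if len(pair_types) < 2 or end_a.std() == 0:
        degree_correlation: float | None = None
    else:
        degree_correlation = float(np.corrcoef(end_a, end_b)[0, 1])

    kappa = float((degrees**2).mean() / degrees.mean())
    return TreeMetrics(
        n_nodes=n,
        degree_max=float(degrees.max()),
        degree_max_norm=float(degrees.max() / m),
        leaf_number=float(leaf_number),
        leaf_fraction=leaf_number / m,
        diameter=diameter,
        diameter_norm=diameter / m,
        eccentricity_mean=float(ecc_values.mean()),
        eccentricity_mean_norm=float(ecc_values.mean() / m),
        eccentricity_max=float(ecc_values.max()),
        bc_max=bc_max,
        bc_mean=float(bc_values.mean()),
        tree_hierarchy=leaf_number / (2.0 * m * bc_max),
        degree_correlation=degree_correlation,
        kappa=kappa,
        mst_mean=tree.mean_pli(),
    )


def average_tree_metrics(metrics: list[TreeMetrics]) -> dict[str, float | None]:
    """Arithmetic mean of per-epoch tree metrics.

    Epochs with undefined degree correlation are excluded from the R
    average; ``degree_correlation_n_defined`` reports how many contributed.
    """
    if not metrics:
        raise ValueError("no metrics to average")
    out: dict[str, float | None] = {}
    for name in METRIC_NAMES:
        vals = [getattr(tm, name) for tm in metrics]
        if name == "degree_correlation":
            defined = [v for v in vals if v is not None]
            out[name] = float(np.mean(defined)) if defined else None
            out["degree_correlation_n_defined"] = float(len(defined))
        else:
            out[name] = float(np.mean(vals))
    out["n_nodes"] = float(metrics[0].n_nodes)
    return out


def subject_band_metrics(rec_band: EpochedRecording) -> dict[str, float | None]:
    """Per-epoch MST metrics of a band-filtered recording, averaged over epochs.

    One PLI matrix and one tree per epoch; metrics are averaged
    arithmetically (never a tree of the epoch-averaged matrix).
    """
    mats = epoch_pli_matrices(rec_band)
    return average_tree_metrics([tree_metrics(kruskal_mst(m)) for m in mats])
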