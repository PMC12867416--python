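"""Signed OTU co-occurrence networks from CLR-transformed abundance data.

Associations are Spearman rank correlations; edges are kept when the
Benjamini-Hochberg adjusted p-value is below ``fdr_alpha`` (strict) and
|rho| is at least ``rho_min`` (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "NetworkParams",
    "Edge",
    "CooccurrenceNetwork",
    "TopologyMetrics",
    "spearman_matrix",
    "bh_adjust",
    "build_network",
    "topology",
    "negative_edge_fraction",
    "neighbor_jaccard",
    "presence_jaccard",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class NetworkParams:
    """Edge-selection thresholds. Correlation measure is fixed to Spearman."""

    rho_min: float = 0.3
    fdr_alpha: float = 0.05
    correlation: str = "spearman"

    def __post_init__(self) -> None:
        if not 0 < self.rho_min < 1:
            raise ValueError("rho_min must be in (0, 1)")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.correlation != "spearman":
            raise ValueError("only Spearman correlation is supported")


@dataclass(frozen=True)
class Edge:
    """Undirected signed edge; endpoints stored in sorted order."""

    i: str
    j: str
    rho: float
    q: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-edges are not allowed")
        if self.i > self.j:
            a, b = self.j, self.i
            object.__setattr__(self, "i", a)
            object.__setattr__(self, "j", b)

    @property
    def sign(self) -> str:
        return "+" if self.rho >= 0 else "-"

    @property
    def key(self) -> tuple[str, str]:
        return (self.i, self.j)


@dataclass
class CooccurrenceNetwork:
    """Signed weighted undirected association graph over OTU nodes."""

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    params: NetworkParams = field(default_factory=NetworkParams)
    label: str = ""

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.edges = tuple(self.edges)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node ids")
        keys = set()
        for e in self.edges:
            if e.i not in node_set or e.j not in node_set:
                raise ValueError(f"edge endpoint not in node set: {e.key}")
            if e.key in keys:
                raise ValueError(f"duplicate edge {e.key}")
            keys.add(e.key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_dict(self) -> dict[tuple[str, str], Edge]:
        return {e.key: e for e in self.edges}

    def to_networkx(self) -> nx.Graph:
        """Graph with attributes rho, q, sign and weight = |rho|."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.i, e.j, rho=e.rho, q=e.q, sign=e.sign, weight=abs(e.rho))
        return g


@dataclass(frozen=True)
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    density: float
    mean_degree: float
    mean_degree_centrality: float
    max_degree_centrality: float
    mean_clustering: float
    avg_path_length: float
    negative_edge_fraction: float


# ---------------------------------------------------------------------------
# Correlation and multiplicity
# ---------------------------------------------------------------------------

def spearman_matrix(clr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman correlation with average-rank ties.

    Returns (rho, p) symmetric matrices with unit diagonal.  Pairs
    involving a constant column are NaN in both outputs (undefined, never
    reported as zero).  P-values come from the t-distribution
    approximation on n-2 degrees of freedom; perfect correlations are
    floored at machine epsilon.
    """
    clr = np.asarray(clr, dtype=float)
    n, p = clr.shape
    if n < 4:
        raise ValueError("need at least 4 samples for Spearman correlation")
    ranks = np.apply_along_axis(stats.rankdata, 0, clr)
    sd = ranks.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float).reshape(p, p)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    perfect = np.isclose(np.abs(rho), 1.0)
    pvals[perfect] = _EPS
    pvals[np.isnan(rho)] = np.nan
    np.fill_diagonal(pvals, np.where(constant, np.nan, 0.0))
    return rho, pvals


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(
    clr: np.ndarray,
    otu_ids: Sequence[str],
    params: NetworkParams | None = None,
    label: str = "",
    retain_isolates: bool = False,
) -> CooccurrenceNetwork:
    """Build the thresholded association network from a CLR matrix.

    BH adjustment is applied once across all upper-triangle pairs with a
    defined correlation.  An edge is kept iff q < fdr_alpha and
    |rho| >= rho_min.  Isolated OTUs are dropped unless
    ``retain_isolates``.
    """
    if params is None:
        params = NetworkParams()
    otu_ids = [str(o) for o in otu_ids]
    clr = np.asarray(clr, dtype=float)
    if clr.shape[1] != len(otu_ids):
        raise ValueError("otu_ids length does not match matrix columns")
    if clr.shape[1] < 2:
        raise ValueError("need at least 2 OTUs")
    rho, pvals = spearman_matrix(clr)
    iu, ju = np.triu_indices(len(otu_ids), k=1)
    pair_p = pvals[iu, ju]
    defined = ~np.isnan(pair_p)
    qvals = np.full(pair_p.shape, np.nan)
    if defined.any():
        qvals[defined] = bh_adjust(pair_p[defined])

    edges = []
    for i, j, r, q in zip(iu, ju, rho[iu, ju], qvals):
        if np.isnan(q):
            continue
        if q < params.fdr_alpha and abs(r) >= params.rho_min:
            edges.append(Edge(otu_ids[i], otu_ids[j], float(r), float(q)))
    if retain_isolates:
        nodes = tuple(otu_ids)
    else:
        touched = {n for e in edges for n in e.key}
        nodes = tuple(o for o in otu_ids if o in touched)
    return CooccurrenceNetwork(nodes, tuple(edges), params, label)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def topology(net: CooccurrenceNetwork | nx.Graph) -> TopologyMetrics:
    """Global topology metrics of an undirected simple graph.

    Density is 2E/(N(N-1)); degree centrality is degree/(N-1); clustering
    is the mean local clustering coefficient (degree < 2 contributes 0);
    path length is averaged over pairs in the largest connected component.
    """
    g = net.to_networkx() if isinstance(net, CooccurrenceNetwork) else net
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("topology requires at least 2 nodes")
    m = g.number_of_edges()
    density = 2.0 * m / (n * (n - 1))
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    centrality = degrees / (n - 1)
    clustering = float(np.mean(list(nx.clustering(g).values())))
    components = list(nx.connected_components(g))
    lcc = max(components, key=len)
    if len(lcc) > 1:
        apl = nx.average_shortest_path_length(g.subgraph(lcc))
    else:
        apl = float("nan")
    if isinstance(net, CooccurrenceNetwork) and net.n_edges > 0:
        neg = negative_edge_fraction(net)
    else:
        neg = 0.0
    return TopologyMetrics(
        n_nodes=n,
        n_edges=m,
        density=density,
        mean_degree=float(degrees.mean()),
        mean_degree_centrality=float(centrality.mean()),
        max_degree_centrality=float(centrality.max()),
        mean_clustering=clustering,
        avg_path_length=float(apl),
        negative_edge_fraction=neg,
    )


def negative_edge_fraction(net: CooccurrenceNetwork) -> float:
    """Fraction of edges with negative correlation sign."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    return sum(1 for e in net.edges if e.sign == "-") / net.n_edges


def neighbor_jaccard(
    netA: CooccurrenceNetwork, netB: CooccurrenceNetwork
) -> dict[str, float]:
    """Per-node Jaccard similarity of neighbour sets across two networks.

    Computed for nodes present in both networks; a node whose neighbour
    union is empty scores 0 by convention.
    """
    shared = set(netA.nodes) & set(netB.nodes)
    if not shared:
        raise ValueError("node sets are disjoint")
    ga, gb = netA.to_networkx(), netB.to_networkx()
    out = {}
    for node in sorted(shared):
        na, nb = set(ga.neighbors(node)), set(gb.neighbors(node))
        union = na | nb
        out[node] = len(na & nb) / len(union) if union else 0.0
    return out


def presence_jaccard(
    table_a: "np.ndarray | object", table_b: "np.ndarray | object"
) -> dict[str, float]:
    """Jaccard of sample-presence profiles per OTU (alternative sociality).

    Accepts two OtuTable objects over the same sample universe; compares
    the sets of samples in which each OTU is present.  Exposed as a
    variant without claiming equivalence to the neighbour-set measure.
    """
    shared = set(table_a.otu_ids) & set(table_b.otu_ids)
    if not shared:
        raise ValueError("OTU sets are disjoint")
    out = {}
    a_idx = {o: k for k, o in enumerate(table_a.otu_ids)}
    b_idx = {o: k for k, o in enumerate(table_b.otu_ids)}
    for otu in sorted(shared):
        pa = {s for s, c in zip(table_a.sample_ids, table_a.counts[:, a_idx[otu]]) if c > 0}
        pb = {s for s, c in zip(table_b.sample_ids, table_b.counts[:, b_idx[otu]]) if c > 0}
        union = pa | pb
        out[otu] = len(pa & pb) / len(union) if union else 0.0
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_edge_list(net: CooccurrenceNetwork, path: str | Path) -> None:
    """Write edges as TSV (source, target, rho, q, sign) plus a node list."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("source\ttarget\trho\tq\tsign\n")
        for e in net.edges:
            fh.write(f"{e.i}\t{e.j}\t{e.rho:.10g}\t{e.q:.10g}\t{e.sign}\n")
    node_path = path.with_suffix(".nodes.tsv")
    with open(node_path, "w") as fh:
        fh.write("node\n")
        for node in net.nodes:
            fh.write(f"{node}\n")


def read_edge_list(
    path: str | Path, params: NetworkParams | None = None, label: str = ""
) -> CooccurrenceNetwork:
    path = Path(path)
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["source", "target", "rho", "q"]:
            raise ValueError(f"{path}: unexpected edge-list header {header}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            edges.append(Edge(parts[0], parts[1], float(parts[2]), float(parts[3])))
    node_path = path.with_suffix(".nodes.tsv")
    if node_path.exists():
        with open(node_path) as fh:
            fh.readline()
            nodes = tuple(line.strip() for line in fh if line.strip())
    else:
        nodes = tuple(sorted({n for e in edges for n in e.key}))
    return CooccurrenceNetwork(nodes, tuple(edges), params or NetworkParams(), label)


def write_graphml(net: CooccurrenceNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))
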