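"""Permutation null models for sub-network topology and attack robustness.

The null model draws random node subsets of the same size as the target
from the observed background network and computes metrics on the induced
subgraphs — it does not rewire edges.  Robustness is quantified as the
decay of the largest connected component under node removal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .cooccurrence import CooccurrenceNetwork

__all__ = [
    "MetricNull",
    "NullResult",
    "RobustnessCurve",
    "SUPPORTED_METRICS",
    "subset_permutation_test",
    "robustness_curve",
    "write_null_result",
    "write_robustness_curve",
]

SUPPORTED_METRICS = (
    "density",
    "mean_clustering",
    "mean_degree_centrality",
    "max_degree_centrality",
    "n_edges",
)


@dataclass(frozen=True)
class MetricNull:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_perm: float
    degenerate: bool = False


@dataclass
class NullResult:
    metrics: dict[str, MetricNull]
    n_perm: int
    seed: int | None
    target_size: int


@dataclass
class RobustnessCurve:
    removal_fractions: np.ndarray
    lcc_fractions: np.ndarray
    strategy: str
    auc: float


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return net.to_networkx()


# ---------------------------------------------------------------------------
# Fast induced-subgraph metrics on a dense adjacency matrix
# ---------------------------------------------------------------------------

def _adjacency(g: nx.Graph, order: Sequence) -> np.ndarray:
    idx = {n: k for k, n in enumerate(order)}
    a = np.zeros((len(order), len(order)), dtype=np.float64)
    for u, v in g.edges():
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    return a


def _metrics_from_adjacency(a: np.ndarray, metrics: Sequence[str]) -> dict[str, float]:
    n = a.shape[0]
    deg = a.sum(axis=0)
    m = deg.sum() / 2.0
    out: dict[str, float] = {}
    if "n_edges" in metrics:
        out["n_edges"] = m
    if "density" in metrics:
        out["density"] = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    if "mean_degree_centrality" in metrics:
        out["mean_degree_centrality"] = float(deg.mean() / (n - 1)) if n >= 2 else 0.0
    if "max_degree_centrality" in metrics:
        out["max_degree_centrality"] = float(deg.max() / (n - 1)) if n >= 2 else 0.0
    if "mean_clustering" in metrics:
        # triangles through node i = (A^3)_ii / 2; local CC = tri / C(k, 2)
        tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
        possible = deg * (deg - 1) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            local = np.where(possible > 0, tri / possible, 0.0)
        out["mean_clustering"] = float(local.mean()) if n else 0.0
    return out


# ---------------------------------------------------------------------------

def subset_permutation_test(
    background: CooccurrenceNetwork | nx.Graph,
    target_nodes: Iterable,
    metrics: Sequence[str] = SUPPORTED_METRICS,
    n_perm: int = 1000,
    seed: int | None = None,
) -> NullResult:
    """Compare a node subset's induced topology against random subsets.

    For each of ``n_perm`` permutations, a subset of the same size is
    drawn uniformly without replacement from the background node set, and
    metrics are computed on the induced subgraph.  Z-scores standardise
    the observed value against the null; the two-sided permutation
    p-value is (1 + 2 * min(#null >= obs, #null <= obs)) / (n_perm + 1),
    capped at 1.
    """
    g = _as_graph(background)
    target = sorted(target_nodes, key=str)
    node_order = sorted(g.nodes(), key=str)
    node_set = set(node_order)
    if not set(target) <= node_set:
        missing = sorted(set(target) - node_set, key=str)
        raise ValueError(f"target nodes not in background: {missing[:5]}")
    k = len(target)
    if k < 3:
        raise ValueError("target subset must have at least 3 nodes")
    unknown = set(metrics) - set(SUPPORTED_METRICS)
    if unknown:
        raise ValueError(f"unsupported metrics: {sorted(unknown)}")

    adj = _adjacency(g, node_order)
    idx = {n: i for i, n in enumerate(node_order)}
    t_idx = np.array([idx[n] for n in target])
    observed = _metrics_from_adjacency(adj[np.ix_(t_idx, t_idx)], metrics)

    rng = np.random.default_rng(seed)
    null = {name: np.empty(n_perm) for name in metrics}
    n_nodes = len(node_order)
    for b in range(n_perm):
        pick = rng.choice(n_nodes, size=k, replace=False)
        vals = _metrics_from_adjacency(adj[np.ix_(pick, pick)], metrics)
        for name in metrics:
            null[name][b] = vals[name]

    results: dict[str, MetricNull] = {}
    for name in metrics:
        dist = null[name]
        mu, sd = float(dist.mean()), float(dist.std())
        obs = float(observed[name])
        degenerate = sd == 0.0
        z = 0.0 if degenerate and obs == mu else (
            float("nan") if degenerate else (obs - mu) / sd
        )
        n_ge = int(np.sum(dist >= obs))
        n_le = int(np.sum(dist <= obs))
        p = min(1.0, (1 + 2 * min(n_ge, n_le)) / (n_perm + 1))
        results[name] = MetricNull(obs, mu, sd, z, p, degenerate)
    return NullResult(metrics=results, n_perm=n_perm, seed=seed, target_size=k)


def robustness_curve(
    net: CooccurrenceNetwork | nx.Graph,
    strategy: str = "targeted_degree",
    n_random_reps: int = 20,
    seed: int | None = None,
    adaptive: bool = False,
) -> RobustnessCurve:
    """Largest-connected-component decay under sequential node removal.

    ``targeted_degree`` removes nodes in descending initial degree (static
    order, node-id tie-break); ``random`` averages the curve over
    ``n_random_reps`` seeded shuffles.  ``adaptive`` recomputes degrees
    after each targeted removal.  LCC sizes are relative to the initial
    largest component; the AUC is the trapezoidal area of the curve
    against the fraction of nodes removed.
    """
    g0 = _as_graph(net)
    n = g0.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    initial_lcc = max((len(c) for c in nx.connected_components(g0)), default=0)
    if initial_lcc == 0:
        raise ValueError("network has no connected component")

    def lcc_trajectory(order: Sequence) -> np.ndarray:
        g = g0.copy()
        traj = np.empty(n + 1)
        traj[0] = initial_lcc
        for step, node in enumerate(order, start=1):
            g.remove_node(node)
            if g.number_of_nodes():
                traj[step] = max(len(c) for c in nx.connected_components(g))
            else:
                traj[step] = 0.0
        return traj / initial_lcc

    fractions = np.arange(n + 1) / n
    if strategy == "targeted_degree":
        if adaptive:
            g = g0.copy()
            traj = np.empty(n + 1)
            traj[0] = initial_lcc
            for step in range(1, n + 1):
                node = min(g.nodes(), key=lambda v: (-g.degree(v), str(v)))
                g.remove_node(node)
                if g.number_of_nodes():
                    traj[step] = max(len(c) for c in nx.connected_components(g))
                else:
                    traj[step] = 0.0
            lcc = traj / initial_lcc
        else:
            order = sorted(g0.nodes(), key=lambda v: (-g0.degree(v), str(v)))
            lcc = lcc_trajectory(order)
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        nodes = sorted(g0.nodes(), key=str)
        acc = np.zeros(n + 1)
        for _ in range(n_random_reps):
            order = list(rng.permutation(nodes))
            acc += lcc_trajectory(order)
        lcc = acc / n_random_reps
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    auc = float(np.trapezoid(lcc, fractions))
    return RobustnessCurve(
        removal_fractions=fractions, lcc_fractions=lcc, strategy=strategy, auc=auc
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_null_result(result: NullResult, path: str | Path) -> None:
    payload = {
        "n_perm": result.n_perm,
        "seed": result.seed,
        "target_size": result.target_size,
        "metrics": {
            name: {
                "observed": m.observed,
                "null_mean": m.null_mean,
                "null_sd": m.null_sd,
                "z": m.z,
                "p_perm": m.p_perm,
                "degenerate": m.degenerate,
            }
            for name, m in result.metrics.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_robustness_curve(curve: RobustnessCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fraction_removed\tlcc_fraction\tstrategy\n")
        for f, l in zip(curve.removal_fractions, curve.lcc_fractions):
            fh.write(f"{f:.10g}\t{l:.10g}\t{curve.strategy}\n")
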