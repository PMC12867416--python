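"""Stable cross-condition networks, guild partitioning, Zi-Pi scores,
guild abundance and cross-group bridging sub-networks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .cooccurrence import CooccurrenceNetwork, Edge, NetworkParams
from .core_data import OtuTable, relative_abundance

__all__ = [
    "StableEdge",
    "StableNetwork",
    "GuildPartition",
    "ZiPiScores",
    "stable_network",
    "detect_guilds",
    "modularity",
    "zipi",
    "guild_abundance",
    "bridging_subgraph",
    "write_partition",
    "write_zipi",
]


@dataclass(frozen=True)
class StableEdge:
    i: str
    j: str
    rho_a: float
    rho_b: float

    def __post_init__(self) -> None:
        if self.i > self.j:
            a, b = self.j, self.i
            object.__setattr__(self, "i", a)
            object.__setattr__(self, "j", b)

    @property
    def sign(self) -> str:
        return "+" if self.rho_a >= 0 else "-"

    @property
    def key(self) -> tuple[str, str]:
        return (self.i, self.j)


@dataclass
class StableNetwork:
    """Edges significant with consistent sign in both source networks."""

    nodes: tuple[str, ...]
    edges: tuple[StableEdge, ...]
    label_a: str = ""
    label_b: str = ""

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.edges = tuple(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        """Weight is the mean absolute correlation across both networks."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.i,
                e.j,
                rho_a=e.rho_a,
                rho_b=e.rho_b,
                sign=e.sign,
                weight=(abs(e.rho_a) + abs(e.rho_b)) / 2.0,
            )
        return g


@dataclass
class GuildPartition:
    """Node -> guild assignment; guild ids are contiguous integers from 0."""

    assignment: dict[str, int]
    n_guilds: int
    modularity_q: float
    algorithm: str = "louvain"
    seed: int = 0
    resolution: float = 1.0

    def members(self, guild: int) -> list[str]:
        return sorted(n for n, g in self.assignment.items() if g == guild)

    def guilds(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {g: [] for g in range(self.n_guilds)}
        for n, g in self.assignment.items():
            out[g].append(n)
        return {g: sorted(v) for g, v in out.items()}


@dataclass(frozen=True)
class ZiPiScores:
    """Within-module degree z-score and participation coefficient per node."""

    zi: Mapping[str, float]
    pi: Mapping[str, float]


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return net.to_networkx()


# ---------------------------------------------------------------------------

def stable_network(
    netA: CooccurrenceNetwork,
    netB: CooccurrenceNetwork,
    require_sign_agreement: bool = True,
) -> StableNetwork:
    """Intersect two thresholded networks into the shared stable core.

    An edge survives iff present in both networks and (by default) with
    the same correlation sign; a node survives iff incident to a
    surviving edge.
    """
    if netA.params != netB.params:
        raise ValueError("networks were built with different parameters")
    edges_b = netB.edge_dict()
    kept = []
    for ea in netA.edges:
        eb = edges_b.get(ea.key)
        if eb is None:
            continue
        if require_sign_agreement and ea.sign != eb.sign:
            continue
        kept.append(StableEdge(ea.i, ea.j, ea.rho, eb.rho))
    if not kept:
        raise ValueError("no stable edges: network intersection is empty")
    touched = sorted({n for e in kept for n in e.key})
    return StableNetwork(tuple(touched), tuple(kept), netA.label, netB.label)


def detect_guilds(
    net: StableNetwork | CooccurrenceNetwork | nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    min_size: int = 3,
) -> GuildPartition:
    """Partition a network into guilds by multilevel modularity maximisation.

    Louvain communities on absolute edge weights; guilds smaller than
    ``min_size`` are merged into the neighbouring guild with the largest
    total connecting weight (nearest by id when tied or disconnected).
    Guild ids are renumbered 0..k-1 by decreasing size, ties broken by
    smallest member id.
    """
    g = _as_graph(net)
    if g.number_of_edges() < 1:
        raise ValueError("network has no edges")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    communities = [set(c) for c in communities]

    # Merge undersized guilds into their strongest-attached neighbour guild.
    changed = True
    while changed and len(communities) > 1:
        changed = False
        communities.sort(key=len)
        for idx, comm in enumerate(communities):
            if len(comm) >= min_size:
                continue
            attach = np.zeros(len(communities))
            for node in comm:
                for nbr, data in g[node].items():
                    for k, other in enumerate(communities):
                        if k != idx and nbr in other:
                            attach[k] += data.get("weight", 1.0)
            if attach.max() > 0:
                target = int(np.argmax(attach))
            else:
                # Disconnected small guild: merge into guild with smallest id.
                candidates = [k for k in range(len(communities)) if k != idx]
                target = min(candidates, key=lambda k: min(communities[k]))
            communities[target] |= comm
            del communities[idx]
            changed = True
            break

    communities.sort(key=lambda c: (-len(c), min(c)))
    assignment = {}
    for gid, comm in enumerate(communities):
        for node in sorted(comm):
            assignment[node] = gid
    q = modularity(g, assignment)
    return GuildPartition(
        assignment=assignment,
        n_guilds=len(communities),
        modularity_q=q,
        algorithm="louvain",
        seed=seed,
        resolution=resolution,
    )


def modularity(net, partition: Mapping[str, int]) -> float:
    """Newman-Girvan modularity Q of a node partition, unweighted edges.

    Q = sum_g [ e_g/m - (d_g/2m)^2 ] where e_g is the number of edges
    inside community g and d_g the total degree of its nodes.
    """
    g = _as_graph(net)
    missing = set(g.nodes()) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an empty edge set")
    groups = set(partition[n] for n in g.nodes())
    q = 0.0
    for grp in groups:
        members = {n for n in g.nodes() if partition[n] == grp}
        e_g = sum(1 for u, v in g.edges() if u in members and v in members)
        d_g = sum(d for n, d in g.degree() if n in members)
        q += e_g / m - (d_g / (2.0 * m)) ** 2
    return q


def zipi(net, partition: Mapping[str, int]) -> ZiPiScores:
    """Within-module degree z-score (zi) and participation coefficient (pi).

    zi standardises a node's within-module degree against its module's
    mean and standard deviation (zi = 0 when the sd is 0).  pi is
    1 - sum_g (k_ig / k_i)^2; isolated nodes score 0 on both.
    """
    g = _as_graph(net)
    missing = set(g.nodes()) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    modules: dict[int, list[str]] = {}
    for n in g.nodes():
        modules.setdefault(partition[n], []).append(n)

    within = {}
    for n in g.nodes():
        own = partition[n]
        within[n] = sum(1 for nbr in g.neighbors(n) if partition[nbr] == own)

    zi: dict[str, float] = {}
    for mod, members in modules.items():
        ks = np.array([within[n] for n in members], dtype=float)
        mu, sd = ks.mean(), ks.std()
        for n in members:
            zi[n] = 0.0 if sd == 0 else (within[n] - mu) / sd

    pi: dict[str, float] = {}
    for n in g.nodes():
        k = g.degree(n)
        if k == 0:
            pi[n] = 0.0
            zi[n] = 0.0
            continue
        per_mod: dict[int, int] = {}
        for nbr in g.neighbors(n):
            mod = partition[nbr]
            per_mod[mod] = per_mod.get(mod, 0) + 1
        pi[n] = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
    return ZiPiScores(zi=zi, pi=pi)


def guild_abundance(
    table: OtuTable, partition: GuildPartition, guild: int
) -> dict[str, float]:
    """Per-sample summed relative abundance of a guild's member OTUs."""
    return _guild_abundance(table, partition.members(guild), aggregate="sum")


def guild_abundance_mean(
    table: OtuTable, partition: GuildPartition, guild: int
) -> dict[str, float]:
    """Mean (not sum) of member relative abundances, as an alternative."""
    return _guild_abundance(table, partition.members(guild), aggregate="mean")


def _guild_abundance(
    table: OtuTable, members: Sequence[str], aggregate: str
) -> dict[str, float]:
    if not members:
        raise ValueError("guild has no members")
    idx = []
    for otu in members:
        if otu in table.otu_ids:
            idx.append(table.otu_ids.index(otu))
        else:
            warnings.warn(f"guild member {otu} absent from table; skipped")
    if not idx:
        raise ValueError("no guild member present in the table")
    rel = relative_abundance(table)[:, idx]
    values = rel.sum(axis=1) if aggregate == "sum" else rel.mean(axis=1)
    return dict(zip(table.sample_ids, values.tolist()))


def bridging_subgraph(
    net: CooccurrenceNetwork, setA: set[str], setB: set[str]
) -> CooccurrenceNetwork:
    """Sub-network of edges with one endpoint in each of two disjoint sets.

    An empty result (no cross-group edges) is returned as a network with
    no edges rather than raised as an error.
    """
    setA, setB = set(setA), set(setB)
    if setA & setB:
        raise ValueError(f"node sets overlap: {sorted(setA & setB)[:5]}")
    kept = tuple(
        e
        for e in net.edges
        if (e.i in setA and e.j in setB) or (e.i in setB and e.j in setA)
    )
    touched = {n for e in kept for n in e.key}
    nodes = tuple(n for n in net.nodes if n in touched)
    return CooccurrenceNetwork(nodes, kept, net.params, f"{net.label}:bridging")


def two_set_partition(
    net: CooccurrenceNetwork, setA: set[str], setB: set[str]
) -> dict[str, int]:
    """Induced two-block partition of a bridging subgraph's nodes."""
    return {n: (0 if n in setA else 1) for n in net.nodes}


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_partition(partition: GuildPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tguild_id\n")
        for node in sorted(partition.assignment):
            fh.write(f"{node}\t{partition.assignment[node]}\n")


def write_zipi(scores: ZiPiScores, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tzi\tpi\n")
        for node in sorted(scores.zi):
            fh.write(f"{node}\t{scores.zi[node]:.10g}\t{scores.pi[node]:.10g}\n")


def write_guild_abundance(
    abundances: Mapping[int, Mapping[str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tguild_id\tabundance\n")
        for gid in sorted(abundances):
            for sid, val in abundances[gid].items():
                fh.write(f"{sid}\t{gid}\t{val:.10g}\n")
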