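"""Independent brute-force oracles used by the acceptance suite.

Deliberately naive implementations: average ranks from first principles,
Pearson on ranks by the definition of covariance, and the modularity sum
evaluated edge by edge.  Kept free of any call into the package under
test.
"""

import numpy as np


def _average_ranks(v):
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _pearson(x, y):
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    ) ** 0.5
    return num / den


def brute_force_spearman_matrix(data):
    """All-pairs Spearman via explicit ranks + Pearson definition."""
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    ranks = [_average_ranks(data[:, j]) for j in range(p)]
    rho = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            rho[i, j] = rho[j, i] = _pearson(ranks[i], ranks[j])
    return rho


def direct_modularity(graph, partition):
    """Evaluate Q = sum_g [e_g/m - (d_g/2m)^2] term by term."""
    m = graph.number_of_edges()
    groups = sorted(set(partition.values()))
    q = 0.0
    for grp in groups:
        members = [n for n in graph.nodes() if partition[n] == grp]
        e_g = 0
        for u, v in graph.edges():
            if u in members and v in members:
                e_g += 1
        d_g = 0
        for node in members:
            d_g += graph.degree(node)
        q += e_g / m - (d_g / (2 * m)) ** 2
    return q
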