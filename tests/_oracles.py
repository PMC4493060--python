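"""Independent brute-force oracles used to pin the graph and stats implementations.

Everything here is deliberately naive (explicit loops, exhaustive enumeration)
and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by the classic triple loop."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j] > 0:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        links = sum(
            1 for x in range(k) for y in range(x + 1, k) if a[nb[x], nb[y]] > 0
        )
        c[i] = 2.0 * links / (k * (k - 1))
    return c


def brute_char_path_length(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    n = a.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(i + 1, n) if math.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no finite pair")
    return sum(vals) / len(vals)


def brute_global_efficiency(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    n = a.shape[0]
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            count += 1
            if math.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / count if count else 0.0


def brute_local_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if a[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        total += brute_global_efficiency(sub)
    return total / n


def brute_nodal_efficiency(a: np.ndarray) -> np.ndarray:
    d = floyd_warshall(a)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and math.isfinite(d[i, j]) and d[i, j] > 0:
                s += 1.0 / d[i, j]
        out[i] = s / (n - 1)
    return out


def modularity_of_partition(a: np.ndarray, communities: list[set[int]]) -> float:
    """Newman modularity of a given partition, evaluated straight from the formula."""
    m = a[np.triu_indices(a.shape[0], 1)].sum()
    if m == 0:
        raise ValueError("no edges")
    deg = a.sum(axis=1)
    q = 0.0
    for com in communities:
        nodes = sorted(com)
        inside = sum(
            a[u, v] for x, u in enumerate(nodes) for v in nodes[x + 1 :]
        )
        d_c = sum(deg[u] for u in nodes)
        q += inside / m - (d_c / (2.0 * m)) ** 2
    return q


def set_partitions(items: list[int]):
    """All set partitions, by recursively placing each item in every block."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1 :]
        yield partial + [{first}]


def exhaustive_max_modularity(a: np.ndarray) -> float:
    nodes = list(range(a.shape[0]))
    return max(
        modularity_of_partition(a, part) for part in set_partitions(nodes)
    )


def bh_stepup(pvalues: list[float], q: float) -> list[bool]:
    """Benjamini-Hochberg step-up applied literally to its definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= rank * q / m:
            k_star = rank
    if k_star == 0:
        return [False] * m
    threshold = pvalues[order[k_star - 1]]
    return [p <= threshold for p in pvalues]


def rm_anova_ss(table: np.ndarray) -> tuple[float, int, int]:
    """(F, df1, df2) from the explicit sums-of-squares partition, loop form."""
    s, c = table.shape
    gm = table.mean()
    ss_total = sum((table[i, j] - gm) ** 2 for i in range(s) for j in range(c))
    ss_subj = sum(c * (table[i].mean() - gm) ** 2 for i in range(s))
    ss_cond = sum(s * (table[:, j].mean() - gm) ** 2 for j in range(c))
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = c - 1, (c - 1) * (s - 1)
    return (ss_cond / df1) / (ss_err / df2), df1, df2


def t_sf_by_quadrature(t_val: float, df: int) -> float:
    """Upper-tail Student-t probability by numerical integration of the density."""
    from scipy.integrate import quad

    def pdf(x):
        return (
            math.gamma((df + 1) / 2.0)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))
            * (1.0 + x * x / df) ** (-(df + 1) / 2.0)
        )

    val, _ = quad(pdf, t_val, np.inf)
    return val


def random_binary_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T
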