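"""Degree-preserving null models and targeted-attack robustness.

Maslov-Sneppen rewiring randomizes a binary network by repeated double-edge
swaps, conserving every node's degree exactly.  The small-worldness index
sigma = (Cp/Cp_rand) / (Lp/Lp_rand) is computed against the mean clustering
and path length of an ensemble of such nulls.  Robustness R is the
largest-connected-component area under the targeted-attack curve (nodes
removed in decreasing order of nodal efficiency), normalized by N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import Network
from .errors import UndefinedMetricError
from .metrics import (
    NodalMetrics,
    _binary_clustering_vector,
    _distance_matrix,
    char_path_length,
    clustering,
    nodal_efficiency,
    shortest_paths,
)


@dataclass
class NullSummary:
    Cp_rand: float
    Lp_rand: float
    gamma: float        # Cp / Cp_rand
    lam: float          # Lp / Lp_rand
    sigma: float        # gamma / lam
    n_nulls: int


@dataclass
class RobustnessResult:
    attack_order: np.ndarray   # node indices in removal order
    curve: np.ndarray          # s_k, k = 0..N-1; s_0 = intact largest component
    R: float


def _edges_of(a: np.ndarray) -> list[tuple[int, int]]:
    iu, ju = np.nonzero(np.triu(a, 1))
    return list(zip(iu.tolist(), ju.tolist()))


def _rewire_edge_list(
    edges: list[tuple[int, int]], n_attempts: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Attempt n_attempts double-edge swaps in place on a copy of the edge list."""
    edges = list(edges)
    e = len(edges)
    if e < 2:
        return edges
    eset = set(edges)
    idx = rng.integers(0, e, size=(n_attempts, 2))
    flips = rng.integers(0, 2, size=n_attempts)
    for (i1, i2), flip in zip(idx, flips):
        if i1 == i2:
            continue
        a, b = edges[i1]
        c, d = edges[i2]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in eset or e2 in eset:
            continue
        eset.discard(edges[i1])
        eset.discard(edges[i2])
        eset.add(e1)
        eset.add(e2)
        edges[i1] = e1
        edges[i2] = e2
    return edges


def _adjacency_from_edges(edges: list[tuple[int, int]], n: int) -> np.ndarray:
    a = np.zeros((n, n))
    if edges:
        arr = np.asarray(edges)
        a[arr[:, 0], arr[:, 1]] = 1.0
        a[arr[:, 1], arr[:, 0]] = 1.0
    return a


def maslov_rewire(
    net: Network, swaps_per_edge: float = 10, rng: np.random.Generator | int | None = None
) -> Network:
    """Degree-preserving randomization of a binary network by double-edge swaps.

    swaps_per_edge * E swaps are *attempted*; proposals creating self-loops or
    duplicate edges are rejected, so graphs with no legal swap (e.g. complete
    graphs) are returned unchanged.
    """
    if net.mode != "binary":
        raise ValueError("Maslov-Sneppen rewiring is defined for binary networks")
    rng = np.random.default_rng(rng)
    edges = _edges_of(net.adjacency)
    n_attempts = int(round(swaps_per_edge * len(edges)))
    rewired = _rewire_edge_list(edges, n_attempts, rng)
    return Network(_adjacency_from_edges(rewired, net.n), mode="binary",
                   node_table=net.node_table)


def _binary_cp_lp(a: np.ndarray) -> tuple[float, float]:
    cp = float(_binary_clustering_vector(a).mean())
    d = _distance_matrix(a, "binary")
    iu = np.triu_indices(a.shape[0], 1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise UndefinedMetricError("null network has no reachable pair")
    return cp, float(finite.mean())


def null_ensemble(
    net: Network,
    n_nulls: int = 100,
    swaps_per_edge: float = 10,
    rng: np.random.Generator | int | None = None,
) -> NullSummary:
    """sigma, gamma, lambda against an ensemble of degree-preserving nulls.

    For weighted networks the binary support is rewired and the original edge
    weights are randomly permuted onto the new edges, preserving the degree
    sequence and the weight distribution.
    """
    rng = np.random.default_rng(rng)
    a = net.adjacency
    edges = _edges_of(a)
    if not edges:
        raise UndefinedMetricError("null ensemble undefined for an empty network")
    weighted = net.mode == "weighted"
    if weighted:
        weights = np.array([a[i, j] for i, j in edges])
        cp_real, _ = clustering(net)
        lp_real = char_path_length(shortest_paths(net))
    else:
        cp_real, lp_real = _binary_cp_lp(a)

    n_attempts = int(round(swaps_per_edge * len(edges)))
    cps, lps = np.empty(n_nulls), np.empty(n_nulls)
    for b in range(n_nulls):
        rewired = _rewire_edge_list(edges, n_attempts, rng)
        null_a = _adjacency_from_edges(rewired, net.n)
        if weighted:
            perm = rng.permutation(len(edges))
            for (i, j), w in zip(rewired, weights[perm]):
                null_a[i, j] = null_a[j, i] = w
            null_net = Network(null_a, mode="weighted")
            cps[b], _ = clustering(null_net)
            lps[b] = char_path_length(shortest_paths(null_net))
        else:
            cps[b], lps[b] = _binary_cp_lp(null_a)

    cp_rand, lp_rand = float(cps.mean()), float(lps.mean())
    if cp_rand == 0.0:
        raise UndefinedMetricError(
            "sigma undefined: all rewired null networks are triangle-free (Cp_rand = 0)"
        )
    gamma = cp_real / cp_rand
    lam = lp_real / lp_rand
    return NullSummary(Cp_rand=cp_rand, Lp_rand=lp_rand, gamma=gamma, lam=lam,
                       sigma=gamma / lam, n_nulls=n_nulls)


def _largest_component(a: np.ndarray) -> int:
    if a.shape[0] == 0:
        return 0
    _, labels = connected_components(csr_matrix(a), directed=False)
    return int(np.bincount(labels).max())


def attack_curve(net: Network, nodal: NodalMetrics | None = None,
                 recompute_ranking: bool = False) -> RobustnessResult:
    """Largest-component curve under targeted node removal.

    Nodes are removed in decreasing order of nodal efficiency computed once on
    the intact network (ties broken by ascending node index); with
    recompute_ranking the next victim is re-chosen after every removal.
    """
    n = net.n
    if nodal is None:
        nodal = nodal_efficiency(shortest_paths(net))
    enod = np.asarray(nodal.Enod, dtype=float)
    alive = np.ones(n, dtype=bool)
    curve = np.empty(n)
    order = []
    static_order = np.lexsort((np.arange(n), -enod))
    for k in range(n):
        sub = net.adjacency[np.ix_(alive, alive)]
        curve[k] = max(_largest_component(sub), 0)
        if k == n - 1:
            break
        if recompute_ranking and k > 0:
            sub_net = Network(sub, mode=net.mode)
            sub_enod = nodal_efficiency(shortest_paths(sub_net)).Enod
            alive_idx = np.flatnonzero(alive)
            victim = alive_idx[np.lexsort((alive_idx, -sub_enod))[0]]
        else:
            victim = next(v for v in static_order if alive[v])
        order.append(int(victim))
        alive[victim] = False
    result = RobustnessResult(attack_order=np.array(order, dtype=int), curve=curve, R=0.0)
    result.R = robustness_auc(result)
    return result


def robustness_auc(result: RobustnessResult) -> float:
    """R = (1/N) * sum_k s_k, including the intact network as k = 0."""
    n = result.curve.size
    return float(result.curve.sum() / n)
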