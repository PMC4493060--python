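"""Global and nodal graph-topology metrics.

Binary networks: average degree K, clustering coefficient Cp, characteristic
path length Lp, local efficiency Eloc, global efficiency Eglob, mean physical
edge distance Dp, Newman modularity Q, and per-node nodal efficiency Enod.
The weighted variants follow the Rubinov-Sporns conventions: strength for K,
Onnela clustering for Cp, and shortest paths on edge lengths 1/w for the
efficiency/path family.

Disconnected graphs: Lp averages finite distances only and the reachable
fraction is reported alongside; the efficiency family uses 1/inf = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .connectivity import Network
from .errors import UndefinedMetricError
from .io import NodeTable


@dataclass
class PathStats:
    d: np.ndarray                 # (N, N) shortest-path lengths, inf when unreachable
    reachable_fraction: float     # share of ordered off-diagonal pairs with finite d


@dataclass
class GlobalMetrics:
    K: float
    Cp: float
    Lp: float
    Eloc: float
    Eglob: float
    Dp: float | None
    Q: float
    reachable_fraction: float
    sigma: float | None = None
    gamma: float | None = None
    lam: float | None = None
    R: float | None = None

    def as_dict(self) -> dict:
        out = {"K": self.K, "Cp": self.Cp, "Lp": self.Lp, "Eloc": self.Eloc,
               "Eglob": self.Eglob, "Dp": self.Dp, "Q": self.Q}
        if self.sigma is not None:
            out["sigma"] = self.sigma
        if self.R is not None:
            out["R"] = self.R
        return out


@dataclass
class NodalMetrics:
    Enod: np.ndarray
    degree: np.ndarray


# ---------------------------------------------------------------- degree / strength

def degree_stats(net: Network) -> tuple[float, np.ndarray]:
    """(K, per-node degrees). For weighted networks the degree is node strength."""
    deg = net.adjacency.sum(axis=1)
    return float(deg.mean()), deg


# ---------------------------------------------------------------- clustering

def _binary_clustering_vector(a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # 2 * edges among neighbors of i
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def clustering(net: Network) -> tuple[float, np.ndarray]:
    """(Cp, per-node clustering). Nodes with degree < 2 contribute 0 and are not excluded.

    Weighted networks use the Onnela geometric-mean triangle intensity with
    weights rescaled by the maximum weight; with 0/1 weights this reduces
    exactly to the binary coefficient.
    """
    a = net.adjacency
    if net.mode == "binary":
        c = _binary_clustering_vector(a)
    else:
        g = nx.from_numpy_array(a)
        cd = nx.clustering(g, weight="weight")
        c = np.array([cd[i] for i in range(net.n)], dtype=float)
    return float(c.mean()), c


# ---------------------------------------------------------------- paths and efficiency

def _distance_matrix(a: np.ndarray, mode: str) -> np.ndarray:
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    if mode == "binary":
        return _csgraph_sp(csr_matrix(a), method="D", directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    return _csgraph_sp(csr_matrix(lengths), method="D", directed=False)


def shortest_paths(net: Network) -> PathStats:
    """All-pairs shortest paths: hops for binary, sums of 1/w for weighted."""
    d = _distance_matrix(net.adjacency, net.mode)
    n = net.n
    off = ~np.eye(n, dtype=bool)
    reachable = float(np.isfinite(d[off]).mean()) if n > 1 else 1.0
    return PathStats(d=d, reachable_fraction=reachable)


def char_path_length(paths: PathStats) -> float:
    """Mean shortest-path length over unordered pairs with finite distance."""
    n = paths.d.shape[0]
    iu = np.triu_indices(n, 1)
    vals = paths.d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise UndefinedMetricError("characteristic path length undefined: no reachable pair")
    return float(finite.mean())


def global_efficiency(paths: PathStats) -> float:
    """Mean of 1/d over all unordered pairs, with 1/inf = 0."""
    n = paths.d.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, 1)
    vals = paths.d[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals) & (vals > 0), 1.0 / vals, 0.0)
    return float(inv.mean())


def _subgraph_efficiency(a_sub: np.ndarray, mode: str) -> float:
    d = _distance_matrix(a_sub, mode)
    m = a_sub.shape[0]
    if m < 2:
        return 0.0
    iu = np.triu_indices(m, 1)
    vals = d[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals) & (vals > 0), 1.0 / vals, 0.0)
    return float(inv.mean())


def local_efficiency(net: Network) -> tuple[float, np.ndarray]:
    """Mean over nodes of the global efficiency of each node's neighbor subgraph."""
    a = net.adjacency
    eloc = np.zeros(net.n)
    for i in range(net.n):
        nb = np.flatnonzero(a[i] > 0)
        if nb.size < 2:
            continue
        eloc[i] = _subgraph_efficiency(a[np.ix_(nb, nb)], net.mode)
    return float(eloc.mean()), eloc


def nodal_efficiency(paths: PathStats) -> NodalMetrics:
    """Enod_i = mean over j != i of 1/d_ij, unreachable terms counted as 0."""
    d = paths.d.copy()
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    enod = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(Enod=enod, degree=np.zeros(n))


# ---------------------------------------------------------------- physical distance

def physical_distance(net: Network, node_table: NodeTable | None = None) -> float:
    """Mean Euclidean distance in mm spanned by existing edges (presence only)."""
    table = node_table if node_table is not None else net.node_table
    if table is None:
        raise ValueError("physical_distance requires a node table with coordinates")
    a = net.adjacency
    iu = np.triu_indices(net.n, 1)
    mask = a[iu] > 0
    if not mask.any():
        raise UndefinedMetricError("physical distance undefined: network has no edges")
    coords = table.coords
    dist = np.linalg.norm(coords[iu[0][mask]] - coords[iu[1][mask]], axis=1)
    return float(dist.mean())


# ---------------------------------------------------------------- modularity

def modularity(
    net: Network,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 100,
) -> tuple[float, list[set[int]]]:
    """Best Newman modularity over Louvain restarts; Q >= 0 always.

    The trivial all-in-one partition scores Q = 0, so it is evaluated as a
    floor: the returned partition can never score below it.
    """
    a = net.adjacency
    if not np.any(np.triu(a, 1) > 0):
        raise UndefinedMetricError("modularity undefined: network has no edges")
    rng = np.random.default_rng(rng)
    g = nx.from_numpy_array(a)  # binary edges carry weight 1.0, so one code path serves both modes
    best_q, best_part = 0.0, [set(range(net.n))]
    for _ in range(n_restarts):
        seed = int(rng.integers(0, 2**31 - 1))
        part = nx.community.louvain_communities(g, weight="weight", seed=seed)
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q:
            best_q, best_part = float(q), [set(c) for c in part]
    return best_q, best_part


# ---------------------------------------------------------------- suites

def global_metrics(
    net: Network,
    node_table: NodeTable | None = None,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 100,
) -> tuple[GlobalMetrics, NodalMetrics]:
    """Compute the full metric set (without sigma/R, which need null models)."""
    k, deg = degree_stats(net)
    cp, _ = clustering(net)
    paths = shortest_paths(net)
    lp = char_path_length(paths)
    eglob = global_efficiency(paths)
    eloc, _ = local_efficiency(net)
    table = node_table if node_table is not None else net.node_table
    dp = physical_distance(net, table) if table is not None else None
    q, _ = modularity(net, rng=rng, n_restarts=n_restarts)
    nodal = nodal_efficiency(paths)
    nodal.degree = deg
    gm = GlobalMetrics(K=k, Cp=cp, Lp=lp, Eloc=eloc, Eglob=eglob, Dp=dp, Q=q,
                       reachable_fraction=paths.reachable_fraction)
    return gm, nodal


def weighted_metric_suite(
    net: Network,
    node_table: NodeTable | None = None,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 100,
) -> tuple[GlobalMetrics, NodalMetrics]:
    """Weighted-network metric suite (strength, Onnela Cp, 1/w path lengths)."""
    if net.mode != "weighted":
        raise ValueError("weighted_metric_suite requires a weighted network")
    return global_metrics(net, node_table=node_table, rng=rng, n_restarts=n_restarts)
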