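"""Functional-connectivity network construction.

Pearson correlation across all ROI pairs, edgewise two-sided p-values from the
t-transform t = r * sqrt((T-2)/(1-r^2)) with T-2 degrees of freedom, and
Bonferroni thresholding over the N(N-1)/2 unique pairs to a binary network.
A weighted variant keeps |r| as edge weight on the same edge set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import ShapeMismatchError
from .io import NodeTable, ScanSeries


@dataclass
class CorrelationResult:
    r: np.ndarray            # (N, N) symmetric, unit diagonal
    p: np.ndarray            # (N, N) symmetric two-sided p, diagonal 1
    n_timepoints: int

    def __post_init__(self) -> None:
        r, p = np.asarray(self.r, float), np.asarray(self.p, float)
        if r.shape != p.shape or r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ShapeMismatchError("r and p must be square matrices of equal shape")
        if np.abs(r - r.T).max(initial=0.0) > 1e-12 or np.abs(p - p.T).max(initial=0.0) > 1e-12:
            raise ValueError("r and p must be symmetric")
        if np.any(np.abs(r) > 1 + 1e-12) or np.any((p < 0) | (p > 1)):
            raise ValueError("r must lie in [-1, 1] and p in [0, 1]")

    @property
    def n(self) -> int:
        return self.r.shape[0]


@dataclass
class Network:
    """Symmetric adjacency with zero diagonal, binary or weighted, tied to a node table."""

    adjacency: np.ndarray
    mode: str                            # "binary" | "weighted"
    node_table: NodeTable | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ShapeMismatchError("adjacency must be square")
        if np.abs(a - a.T).max(initial=0.0) > 1e-12:
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal (no self-loops)")
        if self.mode == "binary":
            if not np.all((a == 0) | (a == 1)):
                raise ValueError("binary adjacency entries must be 0 or 1")
        elif self.mode == "weighted":
            if np.any(a < 0):
                raise ValueError("weighted adjacency entries must be >= 0")
        else:
            raise ValueError(f"unknown network mode {self.mode!r}")
        if self.node_table is not None and self.node_table.n != a.shape[0]:
            raise ShapeMismatchError(
                f"adjacency is {a.shape[0]}x{a.shape[0]} but node table has {self.node_table.n} ROIs"
            )
        self.adjacency = a

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


def pearson_matrix(series: ScanSeries) -> CorrelationResult:
    """Full Pearson matrix with edgewise two-sided p-values."""
    x = series.data
    t = x.shape[0]
    if t < 3:
        raise ShapeMismatchError("need at least 3 time points for correlation p-values")
    sd = x.std(axis=0)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(x.mean(axis=0)))
    if np.any(degenerate):
        bad = int(np.flatnonzero(degenerate)[0])
        raise ValueError(f"zero-variance time series at ROI index {bad}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    df = t - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * scipy.stats.t.sf(np.abs(tstat), df))
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 1.0)
    return CorrelationResult(r=r, p=p, n_timepoints=t)


def edge_p_threshold(n: int, alpha: float) -> float:
    """Per-edge Bonferroni threshold: alpha over the N(N-1)/2 unique pairs."""
    return alpha / (n * (n - 1) / 2.0)


def bonferroni_threshold(
    corr: CorrelationResult, alpha: float = 0.05, positive_only: bool = False,
    node_table: NodeTable | None = None,
) -> Network:
    """Binary network: edge present iff p < alpha / (N(N-1)/2) (strict)."""
    thr = edge_p_threshold(corr.n, alpha)
    keep = corr.p < thr
    if positive_only:
        keep &= corr.r > 0
    a = keep.astype(float)
    np.fill_diagonal(a, 0.0)
    return Network(adjacency=a, mode="binary", node_table=node_table)


def weighted_network(
    corr: CorrelationResult, alpha: float = 0.05, positive_only: bool = False,
    node_table: NodeTable | None = None,
) -> Network:
    """Weighted variant: the same edge set, surviving edges weighted by |r|."""
    support = bonferroni_threshold(corr, alpha, positive_only).adjacency
    a = support * np.abs(corr.r)
    np.fill_diagonal(a, 0.0)
    return Network(adjacency=a, mode="weighted", node_table=node_table)
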