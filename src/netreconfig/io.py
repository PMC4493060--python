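"""Readers and writers for node tables, ROI time series, adjacency matrices and reports.

All on-disk formats are tab-separated text with a header line.  The node table
defines the canonical ROI order; every matrix consumer validates its dimension
against the node table and fails fast on mismatch.
"""

from __future__ import annotations


import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ShapeMismatchError

NODE_COLUMNS = ["roi_id", "label", "x", "y", "z", "module"]


@dataclass(frozen=True)
class NodeTable:
    """ROI identifiers, MNI-style coordinates in mm, and module assignment.

    Row order is the single source of truth for column/row order of every
    time-series and adjacency matrix in a study.
    """

    roi_id: np.ndarray      # (N,) int, contiguous 0..N-1
    label: np.ndarray       # (N,) str
    coords: np.ndarray      # (N, 3) float, mm
    module: np.ndarray      # (N,) str

    def __post_init__(self) -> None:
        ids = np.asarray(self.roi_id)
        n = ids.size
        if n < 3:
            raise ParseError(f"node table needs at least 3 rows, got {n}")
        if len(np.unique(ids)) != n:
            raise ParseError("duplicate roi_id in node table")
        if not np.array_equal(np.sort(ids), np.arange(n)):
            raise ParseError("roi_id must be contiguous integers starting at 0")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (n, 3):
            raise ParseError(f"coordinates must be (N, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ParseError("non-finite coordinate in node table")
        if any(len(str(m)) == 0 for m in self.module):
            raise ParseError("empty module label in node table")

    @property
    def n(self) -> int:
        return int(np.asarray(self.roi_id).size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": np.asarray(self.roi_id, dtype=int),
                "label": self.label,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "module": self.module,
            }
        )


@dataclass
class ScanSeries:
    """One subject x condition ROI time-series matrix (rows = time, cols = ROIs)."""

    subject_id: str
    condition: str
    data: np.ndarray        # (T, N) float
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeMismatchError("series data must be a 2-D (time x ROI) matrix")
        if self.data.shape[0] < 3:
            raise ShapeMismatchError(f"series needs at least 3 time points, got {self.data.shape[0]}")
        if not np.all(np.isfinite(self.data)):
            raise ParseError(f"non-finite value in series {self.subject_id}/{self.condition}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def replace(self, data: np.ndarray) -> "ScanSeries":
        return ScanSeries(self.subject_id, self.condition, data, self.tr_seconds)


def read_node_table(path: str | Path) -> NodeTable:
    """Read a node table TSV with columns roi_id, label, x, y, z, module."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "module": str})
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"node table {path} is missing columns: {missing}")
    for c in ("x", "y", "z"):
        if not np.issubdtype(df[c].dtype, np.number):
            raise ParseError(f"non-numeric coordinate column '{c}' in {path}")
    if df["roi_id"].duplicated().any():
        raise ParseError(f"duplicate roi_id in {path}")
    return NodeTable(
        roi_id=df["roi_id"].to_numpy(dtype=int),
        label=df["label"].to_numpy(dtype=object),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        module=df["module"].to_numpy(dtype=object),
    )


def write_node_table(table: NodeTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_series(
    path: str | Path,
    node_table: NodeTable,
    subject_id: str | None = None,
    condition: str | None = None,
    tr_seconds: float = 2.0,
) -> ScanSeries:
    """Read a T x N series TSV (header row = ROI labels).

    subject_id / condition default to the two '_'-separated fields of the
    file stem (the layout ``write_series`` produces).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    data = df.to_numpy(dtype=float)
    if data.shape[1] != node_table.n:
        raise ShapeMismatchError(
            f"series {path} has {data.shape[1]} columns but node table has {node_table.n} ROIs"
        )
    if subject_id is None or condition is None:
        parts = path.stem.split("_")
        if subject_id is None:
            subject_id = parts[0] if parts else "unknown"
        if condition is None:
            condition = parts[1] if len(parts) > 1 else "unknown"
    return ScanSeries(subject_id, condition, data, tr_seconds)


def write_series(series: ScanSeries, path: str | Path, node_table: NodeTable | None = None) -> None:
    if node_table is not None and series.n_rois != node_table.n:
        raise ShapeMismatchError("series column count does not match node table")
    cols = (
        list(node_table.label)
        if node_table is not None
        else [f"roi{j:03d}" for j in range(series.n_rois)]
    )
    pd.DataFrame(series.data, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_adjacency(path: str | Path, node_table: NodeTable | None = None) -> np.ndarray:
    a = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ShapeMismatchError(f"adjacency in {path} is not square: {a.shape}")
    if node_table is not None and a.shape[0] != node_table.n:
        raise ShapeMismatchError(
            f"adjacency is {a.shape[0]}x{a.shape[0]} but node table has {node_table.n} ROIs"
        )
    return a


def write_adjacency(adjacency: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(adjacency, dtype=float)).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.17g"
    )


def read_confounds(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a T x C confound TSV; returns (matrix, column names)."""
    df = pd.read_csv(path, sep="\t")
    data = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ParseError(f"non-finite value in confound file {path}")
    return data, list(df.columns)


def write_report(
    metrics_long: pd.DataFrame,
    summary: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the study report: long-format metrics, a Table-1-style summary, and JSON.

    ``metrics_long`` must have columns (subject, condition, metric, value) with
    one row per subject x condition x metric; ``summary`` has one row per metric
    with per-condition mean/sd and the ANOVA F, dfs and p.
    """
    if len(metrics_long) == 0:
        raise ValueError("empty record set: nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long_path = out_dir / "metrics_long.tsv"
    summary_path = out_dir / "summary.tsv"
    json_path = out_dir / "report.json"
    metrics_long.to_csv(long_path, sep="\t", index=False, float_format="%.17g")
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.17g")
    payload = {
        "records": metrics_long.to_dict(orient="records"),
        "summary": summary.to_dict(orient="records"),
    }
    json_path.write_text(json.dumps(payload, sort_keys=True, indent=1))
    return {"long": long_path, "summary": summary_path, "json": json_path}


def read_report_long(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
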