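"""ROI-level temporal preprocessing.

Fixed stage order: leading-volume discard and truncation -> linear detrend ->
discrete-cosine high-pass -> nuisance regression.  Each stage is idempotent
(projections), and the confound stage is a pass-through when no confound
matrix is supplied, as is the case for synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal

from .errors import RankDeficiencyError, ShapeMismatchError
from .io import ScanSeries


@dataclass
class ConfoundMatrix:
    """T x C nuisance regressors (e.g. 6 motion parameters, WM and CSF signals)."""

    data: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeMismatchError("confound matrix must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite value in confound matrix")
        if len(self.names) != self.data.shape[1]:
            raise ShapeMismatchError("confound names must match column count")


def discard_and_truncate(series: ScanSeries, n_discard: int, n_keep: int) -> ScanSeries:
    """Drop the first n_discard volumes and keep the next n_keep."""
    t = series.n_timepoints
    if t < n_discard + n_keep:
        raise ShapeMismatchError(
            f"series has {t} time points, cannot discard {n_discard} and keep {n_keep}"
        )
    return series.replace(series.data[n_discard : n_discard + n_keep])


def linear_detrend(series: ScanSeries) -> ScanSeries:
    """Remove each column's least-squares line over the time index (mean included)."""
    return series.replace(scipy.signal.detrend(series.data, axis=0, type="linear"))


def dct_basis(t: int, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Unit-norm discrete-cosine regressors with frequency below cutoff_hz.

    The k-th basis function (k >= 1) is cos(pi * k * (2i + 1) / (2T)) with
    frequency k / (2 * T * tr); the count kept is floor(2 * T * tr * cutoff).
    The constant term is returned as the first column.
    """
    n_funcs = int(np.floor(2.0 * t * tr_seconds * cutoff_hz))
    i = np.arange(t)
    cols = [np.full(t, 1.0 / np.sqrt(t))]
    for k in range(1, n_funcs + 1):
        v = np.cos(np.pi * k * (2 * i + 1) / (2.0 * t))
        cols.append(v / np.linalg.norm(v))
    return np.column_stack(cols)


def highpass_filter(series: ScanSeries, cutoff_hz: float, tr_seconds: float | None = None) -> ScanSeries:
    """Project out the span of low-frequency cosine regressors (plus the constant)."""
    tr = series.tr_seconds if tr_seconds is None else tr_seconds
    nyquist = 1.0 / (2.0 * tr)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    basis = dct_basis(series.n_timepoints, tr, cutoff_hz)
    x = series.data
    return series.replace(x - basis @ (basis.T @ x))


def regress_confounds(series: ScanSeries, confounds: ConfoundMatrix | None) -> ScanSeries:
    """Least-squares residual of each ROI column on intercept + confounds."""
    if confounds is None:
        return series
    if confounds.data.shape[0] != series.n_timepoints:
        raise ShapeMismatchError(
            f"confounds have {confounds.data.shape[0]} rows, series has {series.n_timepoints}"
        )
    design = np.column_stack([np.ones(series.n_timepoints), confounds.data])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the columns implicated via QR with column pivoting
        _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = piv[rank:]
        names = ["intercept"] + list(confounds.names)
        offenders = sorted(names[j] for j in bad)
        raise RankDeficiencyError(f"confound design is rank deficient; collinear columns: {offenders}")
    beta, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    return series.replace(series.data - design @ beta)


def preprocess_scan(
    series: ScanSeries,
    n_discard: int = 0,
    n_keep: int | None = None,
    highpass_hz: float | None = None,
    confounds: ConfoundMatrix | None = None,
) -> ScanSeries:
    """Run the full fixed-order stage chain on one scan."""
    if n_discard or n_keep is not None:
        keep = series.n_timepoints - n_discard if n_keep is None else n_keep
        series = discard_and_truncate(series, n_discard, keep)
    series = linear_detrend(series)
    if highpass_hz is not None:
        series = highpass_filter(series, highpass_hz)
    return regress_confounds(series, confounds)
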