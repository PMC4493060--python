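"""Synthetic multi-condition fMRI cohort generator.

Generates subject x condition ROI time series from a modular factor model: the
signal of ROI i in condition level l is

    x_i(t) = a_l * g_{m(i)}(t) + b_l * g(t) + c_l * eps_i(t),

where g_m is the shared factor of i's module, g a global factor, eps_i private
noise, and c_l = sqrt(1 - a_l^2 - b_l^2).  The implied population correlation is
a_l^2 + b_l^2 within a module and b_l^2 between modules, positive semi-definite
by construction.  Both loadings increase with condition level, so coupling --
and disproportionately the between-module coupling -- grows with task demand.
All latent channels follow a stationary AR(1) process to emulate the temporal
autocorrelation of BOLD noise; columns are standardized afterwards, which
leaves Pearson correlations unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .io import NodeTable, ScanSeries

DEFAULT_CONDITIONS = ("RS", "VSW", "VSD")


@dataclass
class SimConfig:
    """Cohort layout and factor-model loadings per condition level."""

    n_subjects: int = 18
    n_rois: int = 160
    n_timepoints: int = 230
    n_modules: int = 6
    condition_levels: tuple[str, ...] = DEFAULT_CONDITIONS
    lambda_within: tuple[float, ...] = (0.45, 0.55, 0.65)
    lambda_global: tuple[float, ...] = (0.05, 0.15, 0.30)
    subject_sd: float = 0.05
    ar1_phi: float = 0.3
    module_center_spread_mm: float = 60.0
    module_sd_mm: float = 12.0
    tr_seconds: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        levels = len(self.condition_levels)
        if len(set(self.condition_levels)) != levels or levels < 1:
            raise ValueError("condition_levels must be distinct and non-empty")
        if len(self.lambda_within) != levels or len(self.lambda_global) != levels:
            raise ValueError("one loading per condition level is required")
        for a, b in zip(self.lambda_within, self.lambda_global):
            if not (0.0 <= a < 1.0 and 0.0 <= b < 1.0):
                raise ValueError("loadings must lie in [0, 1)")
            if a * a + b * b >= 1.0:
                raise ValueError("lambda_within^2 + lambda_global^2 must be < 1")
        if self.n_modules < 1 or self.n_rois < self.n_modules:
            raise ValueError("need n_rois >= n_modules >= 1")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in (-1, 1)")

    @property
    def n_levels(self) -> int:
        return len(self.condition_levels)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("condition_levels", "lambda_within", "lambda_global"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    node_table: NodeTable
    scans: list[ScanSeries]
    truth: dict  # per-subject loadings actually used, per level

    def scan(self, subject_id: str, condition: str) -> ScanSeries:
        for s in self.scans:
            if s.subject_id == subject_id and s.condition == condition:
                return s
        raise KeyError((subject_id, condition))


def module_sizes(cfg: SimConfig) -> list[int]:
    """Module sizes: floor split with the remainder spread over the first modules."""
    base, rem = divmod(cfg.n_rois, cfg.n_modules)
    return [base + (1 if m < rem else 0) for m in range(cfg.n_modules)]


def module_assignment(cfg: SimConfig) -> np.ndarray:
    """Module index (0..n_modules-1) per ROI, in contiguous blocks."""
    return np.repeat(np.arange(cfg.n_modules), module_sizes(cfg))


def make_node_table(cfg: SimConfig, rng: np.random.Generator | None = None) -> NodeTable:
    """Node table with spatially clustered coordinates per module.

    Module centers are rejection-sampled in a cube of half-width
    module_center_spread_mm until all pairwise center distances are at least
    2 * module_sd_mm, so within-module Euclidean distances are stochastically
    smaller than between-module ones.
    """
    rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    spread = cfg.module_center_spread_mm
    min_sep = 2.0 * cfg.module_sd_mm
    centers: list[np.ndarray] = []
    for _ in range(100_000):
        cand = rng.uniform(-spread, spread, size=3)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
        if len(centers) == cfg.n_modules:
            break
    else:
        raise ValueError("could not place well-separated module centers; increase spread")
    assign = module_assignment(cfg)
    coords = np.vstack(
        [centers[m] + rng.normal(0.0, cfg.module_sd_mm, size=3) for m in assign]
    )
    return NodeTable(
        roi_id=np.arange(cfg.n_rois),
        label=np.array([f"ROI{j:03d}" for j in range(cfg.n_rois)], dtype=object),
        coords=coords,
        module=np.array([f"M{m + 1}" for m in assign], dtype=object),
    )


def _effective_loadings(
    cfg: SimConfig, level: int, subject_jitter: tuple[float, float]
) -> tuple[float, float]:
    """Per-subject loadings at one level, clipped so the factor model stays valid."""
    a = float(np.clip(cfg.lambda_within[level] + subject_jitter[0], 0.0, 0.999))
    b = float(np.clip(cfg.lambda_global[level] + subject_jitter[1], 0.0, 0.999))
    norm = a * a + b * b
    if norm >= 1.0:  # shrink radially back inside the unit disc
        scale = np.sqrt(0.999 / norm)
        a *= scale
        b *= scale
    return a, b


def condition_correlation(
    cfg: SimConfig, level: int, subject_jitter: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Population correlation matrix implied by the factor model at one level.

    r = a^2 + b^2 within a module, r = b^2 between modules, 1 on the diagonal.
    """
    if not 0 <= level < cfg.n_levels:
        raise ValueError(f"level {level} out of range")
    a, b = _effective_loadings(cfg, level, subject_jitter)
    assign = module_assignment(cfg)
    same_module = assign[:, None] == assign[None, :]
    r = np.where(same_module, a * a + b * b, b * b)
    np.fill_diagonal(r, 1.0)
    return r


def _ar1(rng: np.random.Generator, phi: float, t: int, k: int) -> np.ndarray:
    """(t, k) matrix of stationary unit-variance AR(1) channels."""
    out = np.empty((t, k))
    out[0] = rng.standard_normal(k)
    innov_sd = np.sqrt(1.0 - phi * phi)
    eta = rng.standard_normal((t - 1, k))
    for i in range(1, t):
        out[i] = phi * out[i - 1] + innov_sd * eta[i - 1]
    return out


def simulate_scan(
    cfg: SimConfig,
    subject_id: str,
    level: int,
    rng: np.random.Generator,
    subject_jitter: tuple[float, float] = (0.0, 0.0),
    n_timepoints: int | None = None,
) -> ScanSeries:
    """Sample one T x N scan from the factor model, then z-score each column."""
    t = cfg.n_timepoints if n_timepoints is None else n_timepoints
    a, b = _effective_loadings(cfg, level, subject_jitter)
    c = np.sqrt(max(0.0, 1.0 - a * a - b * b))
    assign = module_assignment(cfg)
    g_mod = _ar1(rng, cfg.ar1_phi, t, cfg.n_modules)
    g_glob = _ar1(rng, cfg.ar1_phi, t, 1)
    eps = _ar1(rng, cfg.ar1_phi, t, cfg.n_rois)
    x = a * g_mod[:, assign] + b * g_glob + c * eps
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    return ScanSeries(subject_id, cfg.condition_levels[level], x, cfg.tr_seconds)


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Full cohort: per-subject loading jitter drawn once and shared across conditions."""
    root = np.random.SeedSequence(cfg.rng_seed)
    ss_nodes, ss_jitter, ss_scans = root.spawn(3)
    node_table = make_node_table(cfg, np.random.default_rng(ss_nodes))
    jitter_rng = np.random.default_rng(ss_jitter)
    jitters = jitter_rng.normal(0.0, cfg.subject_sd, size=(cfg.n_subjects, 2))
    scan_seeds = ss_scans.spawn(cfg.n_subjects * cfg.n_levels)

    scans: list[ScanSeries] = []
    truth: dict = {"subjects": {}, "config": cfg.to_dict()}
    for s in range(cfg.n_subjects):
        subject_id = f"sub{s + 1:02d}"
        jit = (float(jitters[s, 0]), float(jitters[s, 1]))
        levels_truth = {}
        for l in range(cfg.n_levels):
            rng = np.random.default_rng(scan_seeds[s * cfg.n_levels + l])
            scans.append(simulate_scan(cfg, subject_id, l, rng, jit))
            a, b = _effective_loadings(cfg, l, jit)
            levels_truth[cfg.condition_levels[l]] = {"lambda_within": a, "lambda_global": b}
        truth["subjects"][subject_id] = {"jitter": list(jit), "levels": levels_truth}
    return SyntheticCohort(node_table=node_table, scans=scans, truth=truth)
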