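"""Study-level configuration: thresholds, null-model sizes, preprocessing counts."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class StudyConfig:
    """Analysis knobs for one end-to-end study run.

    alpha_edge is the familywise error level for edgewise Bonferroni
    thresholding; the per-edge threshold is alpha_edge / (N(N-1)/2).
    """

    alpha_edge: float = 0.05
    n_nulls: int = 100
    rewire_factor: int = 10            # double-edge-swap attempts per edge
    n_keep_timepoints: int = 230
    n_discard: int = 10                # leading volumes dropped before analysis
    fdr_q: float = 0.05
    posthoc_alpha: float = 0.05
    rng_seed: int = 0
    weighted_mode: bool = False
    positive_only: bool = False
    highpass_hz: float | None = None   # None disables temporal high-pass
    regress_global_signal: bool = False
    modularity_restarts: int = 100
    compute_sigma: bool = True
    compute_robustness: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_edge < 1.0:
            raise ValueError("alpha_edge must be in (0, 1)")
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.modularity_restarts < 1:
            raise ValueError("modularity_restarts must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig fields: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, sort_keys=True, indent=1))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
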