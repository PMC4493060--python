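"""End-to-end study orchestration: simulate/load -> preprocess -> networks ->
metrics -> group statistics -> report."""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .connectivity import Network, bonferroni_threshold, pearson_matrix, weighted_network
from .errors import NetReconfigError
from .io import (
    NodeTable,
    ScanSeries,
    read_node_table,
    read_series,
    write_report,
)
from .metrics import global_metrics, nodal_efficiency, shortest_paths
from .nulls import attack_curve, null_ensemble
from .preprocess import ConfoundMatrix, preprocess_scan
from .stats import (
    AnovaResult,
    NodalStatsResult,
    PosthocResult,
    nodal_group_analysis,
    posthoc_paired,
    reproducibility_index,
    rm_anova,
)
from .synthetic import SimConfig, SyntheticCohort, simulate_cohort

METRIC_ORDER = ["Cp", "Lp", "Eloc", "Eglob", "sigma", "K", "Dp", "Q", "R"]


def condition_pairs(n_conditions: int) -> list[tuple[int, int]]:
    """Post-hoc pair order: adjacent levels first, then the extremes (for 3 levels)."""
    if n_conditions == 3:
        return [(0, 1), (1, 2), (0, 2)]
    return list(itertools.combinations(range(n_conditions), 2))


@dataclass
class StudyReport:
    """Machine-readable study outcome mirroring a Table-1/Table-2 layout."""

    conditions: list[str]
    metrics: list[str]
    records: pd.DataFrame                    # subject, condition, metric, value
    anova: dict[str, AnovaResult]
    posthoc: dict[str, PosthocResult]
    nodal: NodalStatsResult | None
    provenance: dict

    def metric_table(self, metric: str) -> np.ndarray:
        """(subjects, conditions) value table for one metric."""
        sub = self.records[self.records["metric"] == metric]
        pivot = sub.pivot(index="subject", columns="condition", values="value")
        return pivot[self.conditions].to_numpy()

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        pairs = condition_pairs(len(self.conditions))
        for metric in self.metrics:
            table = self.metric_table(metric)
            a = self.anova[metric]
            row: dict = {"metric": metric}
            for j, cond in enumerate(self.conditions):
                row[f"mean_{cond}"] = table[:, j].mean()
                row[f"sd_{cond}"] = table[:, j].std(ddof=1)
            row.update({"F": a.F, "df1": a.df1, "df2": a.df2, "p": a.p})
            for (i, j) in pairs:
                name = f"{self.conditions[i]}_vs_{self.conditions[j]}"
                pr = self.posthoc[metric].by_pair((i, j))
                row[f"t_{name}"] = pr.t
                row[f"p_adj_{name}"] = pr.p_adj
                row[f"dir_{name}"] = pr.direction
            rows.append(row)
        return pd.DataFrame(rows)

    def outcome_labels(self, alpha: float = 0.05, posthoc_alpha: float = 0.05) -> list[str]:
        """Per-metric ANOVA labels followed by per-pair post-hoc labels.

        ANOVA: "sig"/"ns".  Post-hoc: "na" when the metric's ANOVA is not
        significant, else "up"/"down" for a significant adjusted pair or "ns".
        """
        labels = []
        for metric in self.metrics:
            labels.append("sig" if self.anova[metric].p < alpha else "ns")
        pairs = condition_pairs(len(self.conditions))
        for metric in self.metrics:
            anova_sig = self.anova[metric].p < alpha
            for pair in pairs:
                if not anova_sig:
                    labels.append("na")
                    continue
                pr = self.posthoc[metric].by_pair(pair)
                labels.append(pr.direction if pr.p_adj < posthoc_alpha else "ns")
        return labels

    def to_dict(self) -> dict:
        out = {
            "schema_version": 1,
            "conditions": self.conditions,
            "metrics": self.metrics,
            "records": self.records.to_dict(orient="records"),
            "anova": {
                m: dataclasses.asdict(a) for m, a in self.anova.items()
            },
            "posthoc": {
                m: [dataclasses.asdict(pr) for pr in ph.pairs]
                for m, ph in self.posthoc.items()
            },
            "provenance": self.provenance,
        }
        if self.nodal is not None:
            out["nodal"] = {
                "F": self.nodal.F.tolist(),
                "p": self.nodal.p.tolist(),
                "significant": self.nodal.significant.astype(int).tolist(),
                "fdr_threshold": self.nodal.fdr_threshold,
                "posthoc": {
                    str(node): [dataclasses.asdict(pr) for pr in ph.pairs]
                    for node, ph in self.nodal.posthoc.items()
                },
            }
        return out

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        return json.dumps(self.to_dict(), sort_keys=True, indent=1, default=_default)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        d = json.loads(text)
        records = pd.DataFrame(d["records"])
        anova = {m: AnovaResult(**a) for m, a in d["anova"].items()}
        from .stats import PairResult

        posthoc = {
            m: PosthocResult(pairs=[PairResult(**{**pr, "pair": tuple(pr["pair"])})
                                    for pr in prs])
            for m, prs in d["posthoc"].items()
        }
        nodal = None
        if "nodal" in d:
            nd = d["nodal"]
            nodal = NodalStatsResult(
                F=np.asarray(nd["F"]),
                p=np.asarray(nd["p"]),
                significant=np.asarray(nd["significant"], dtype=bool),
                fdr_threshold=nd["fdr_threshold"],
                posthoc={
                    int(node): PosthocResult(
                        pairs=[PairResult(**{**pr, "pair": tuple(pr["pair"])}) for pr in prs]
                    )
                    for node, prs in nd["posthoc"].items()
                },
            )
        return cls(conditions=d["conditions"], metrics=d["metrics"], records=records,
                   anova=anova, posthoc=posthoc, nodal=nodal, provenance=d["provenance"])


def analyze_scan(
    series: ScanSeries,
    node_table: NodeTable,
    cfg: StudyConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, float], np.ndarray]:
    """Network construction and the full metric set for one preprocessed scan.

    Returns (metric name -> value, nodal efficiency vector).
    """
    corr = pearson_matrix(series)
    if cfg.weighted_mode:
        net = weighted_network(corr, cfg.alpha_edge, cfg.positive_only, node_table)
    else:
        net = bonferroni_threshold(corr, cfg.alpha_edge, cfg.positive_only, node_table)
    gm, nodal = global_metrics(net, node_table=node_table, rng=rng,
                               n_restarts=cfg.modularity_restarts)
    values = gm.as_dict()
    if cfg.compute_sigma:
        if gm.Cp == 0.0:
            # Triangle-free network: gamma = 0 regardless of the null ensemble,
            # so sigma is 0 (not small-world) without sampling nulls.
            values["sigma"] = 0.0
        else:
            summary = null_ensemble(net, n_nulls=cfg.n_nulls,
                                    swaps_per_edge=cfg.rewire_factor, rng=rng)
            values["sigma"] = summary.sigma
    if cfg.compute_robustness:
        values["R"] = attack_curve(net, nodal).R
    return values, nodal.Enod


def _load_cohort(data_dir: str | Path, cfg: StudyConfig) -> SyntheticCohort:
    """Read a data directory: nodes.tsv plus one {subject}_{condition}.tsv per scan."""
    data_dir = Path(data_dir)
    node_table = read_node_table(data_dir / "nodes.tsv")
    scans = []
    for path in sorted(data_dir.glob("*.tsv")):
        if path.name in ("nodes.tsv",):
            continue
        scans.append(read_series(path, node_table))
    if not scans:
        raise NetReconfigError(f"no series files found in {data_dir}")
    return SyntheticCohort(node_table=node_table, scans=scans, truth={})


def run_study(
    study_cfg: StudyConfig,
    sim_cfg: SimConfig | None = None,
    data_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
    confounds: dict[tuple[str, str], ConfoundMatrix] | None = None,
) -> StudyReport:
    """Run the complete study and return (optionally also write) the report.

    Synthetic mode (sim_cfg given): the generator already emits the retained
    number of time points, so no volumes are discarded and no confounds exist.
    Data mode (data_dir given): leading volumes are discarded and the series
    truncated per the study config before detrending.
    """
    if (sim_cfg is None) == (data_dir is None):
        raise ValueError("provide exactly one of sim_cfg or data_dir")
    synthetic = sim_cfg is not None
    cohort = simulate_cohort(sim_cfg) if synthetic else _load_cohort(data_dir, study_cfg)

    conditions = (
        list(sim_cfg.condition_levels)
        if synthetic
        else sorted({s.condition for s in cohort.scans})
    )
    subjects = sorted({s.subject_id for s in cohort.scans})

    root = np.random.SeedSequence(study_cfg.rng_seed)
    scan_seeds = root.spawn(len(cohort.scans))
    rows = []
    enod = np.full((len(subjects), len(conditions), cohort.node_table.n), np.nan)
    for scan, seed in zip(cohort.scans, scan_seeds):
        try:
            pre = preprocess_scan(
                scan,
                n_discard=0 if synthetic else study_cfg.n_discard,
                n_keep=None if synthetic else study_cfg.n_keep_timepoints,
                highpass_hz=study_cfg.highpass_hz,
                confounds=(confounds or {}).get((scan.subject_id, scan.condition)),
            )
            values, enod_vec = analyze_scan(
                pre, cohort.node_table, study_cfg, np.random.default_rng(seed)
            )
        except NetReconfigError as err:
            raise NetReconfigError(
                f"scan {scan.subject_id}/{scan.condition}: {err}"
            ) from err
        si = subjects.index(scan.subject_id)
        ci = conditions.index(scan.condition)
        enod[si, ci] = enod_vec
        for metric, value in values.items():
            rows.append(
                {"subject": scan.subject_id, "condition": scan.condition,
                 "metric": metric, "value": float(value)}
            )
    if np.any(np.isnan(enod)):
        raise NetReconfigError("incomplete design: some subject x condition scan is missing")

    records = pd.DataFrame(rows)
    metrics = [m for m in METRIC_ORDER if m in set(records["metric"])]
    pairs = condition_pairs(len(conditions))
    anova: dict[str, AnovaResult] = {}
    posthoc: dict[str, PosthocResult] = {}
    report = StudyReport(conditions=conditions, metrics=metrics, records=records,
                         anova=anova, posthoc=posthoc, nodal=None, provenance={})
    for metric in metrics:
        table = report.metric_table(metric)
        anova[metric] = rm_anova(table)
        posthoc[metric] = posthoc_paired(table, pairs)
    report.nodal = nodal_group_analysis(enod, q=study_cfg.fdr_q,
                                        posthoc_alpha=study_cfg.posthoc_alpha)
    report.provenance = {
        "package": "netreconfig",
        "version": __version__,
        "study_config": study_cfg.to_dict(),
        "sim_config": sim_cfg.to_dict() if synthetic else None,
        "data_dir": str(data_dir) if data_dir else None,
        "seed": study_cfg.rng_seed,
        "n_scans": len(cohort.scans),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(records, report.summary_frame(), out_dir)
        (out_dir / "study_report.json").write_text(report.to_json())
    return report


@dataclass
class ComparisonResult:
    labels_main: list[str]
    labels_validation: list[str]
    consistent: list[bool]
    index: float   # percent of consistent comparisons


def compare_runs(
    report_a: StudyReport,
    report_b: StudyReport,
    alpha: float = 0.05,
    posthoc_alpha: float = 0.05,
) -> ComparisonResult:
    """Reproducibility of one run against another: ANOVA + post-hoc label agreement."""
    if report_a.metrics != report_b.metrics:
        raise ValueError(
            f"metric sets differ: {report_a.metrics} vs {report_b.metrics}"
        )
    if report_a.conditions != report_b.conditions:
        raise ValueError("condition sets differ between reports")
    la = report_a.outcome_labels(alpha, posthoc_alpha)
    lb = report_b.outcome_labels(alpha, posthoc_alpha)
    index = reproducibility_index(la, lb)
    return ComparisonResult(
        labels_main=la,
        labels_validation=lb,
        consistent=[x == y for x, y in zip(la, lb)],
        index=index,
    )
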