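"""Within-subject group statistics.

One-way repeated-measures ANOVA (no sphericity correction, matching the
uncorrected F(c-1, (c-1)(s-1)) degrees of freedom), post-hoc paired t-tests
with Bonferroni adjustment over the condition pairs, Benjamini-Hochberg FDR
across nodes, and the reproducibility index comparing two analysis runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class PairResult:
    pair: tuple[int, int]
    t: float
    p_raw: float
    p_adj: float
    direction: str        # "up" if the later condition is larger, "down", or "none"
    mean_diff: float


@dataclass
class PosthocResult:
    pairs: list[PairResult]

    def by_pair(self, pair: tuple[int, int]) -> PairResult:
        for pr in self.pairs:
            if pr.pair == pair:
                return pr
        raise KeyError(pair)


@dataclass
class NodalStatsResult:
    F: np.ndarray                      # (N,)
    p: np.ndarray                      # (N,)
    significant: np.ndarray            # (N,) bool, BH-FDR across nodes
    fdr_threshold: float
    posthoc: dict[int, PosthocResult]  # only FDR-surviving nodes


def _as_table(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a subjects x conditions table")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 conditions, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("table must be complete and finite")
    return x


def rm_anova(values) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    SS_total = SS_subjects + SS_conditions + SS_error;
    F = (SS_conditions/df1) / (SS_error/df2), df1 = c-1, df2 = (c-1)(s-1).
    """
    x = _as_table(values)
    s, c = x.shape
    gm = x.mean()
    ss_total = float(((x - gm) ** 2).sum())
    ss_subj = float(c * ((x.mean(axis=1) - gm) ** 2).sum())
    ss_cond = float(s * ((x.mean(axis=0) - gm) ** 2).sum())
    ss_err = max(ss_total - ss_subj - ss_cond, 0.0)
    df1, df2 = c - 1, (c - 1) * (s - 1)
    tiny = 1e-300 + 1e-12 * ss_total
    if ss_cond <= tiny:
        return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0)
    if ss_err <= tiny:
        return AnovaResult(F=float("inf"), df1=df1, df2=df2, p=0.0)
    f = (ss_cond / df1) / (ss_err / df2)
    return AnovaResult(F=float(f), df1=df1, df2=df2, p=float(scipy.stats.f.sf(f, df1, df2)))


def posthoc_paired(values, pairs: list[tuple[int, int]] | None = None) -> PosthocResult:
    """Paired t-tests per condition pair, Bonferroni-adjusted over the pairs tested.

    For pair (i, j) the difference scores are column j minus column i, so a
    positive t ("up") means the later condition is larger.
    """
    x = _as_table(values)
    s, c = x.shape
    if pairs is None:
        pairs = list(itertools.combinations(range(c), 2))
    m = len(pairs)
    results = []
    for (i, j) in pairs:
        d = x[:, j] - x[:, i]
        sd = d.std(ddof=1)
        mean = float(d.mean())
        if sd == 0.0:
            t, p = (0.0, 1.0) if mean == 0.0 else (float("inf") * np.sign(mean), 0.0)
        else:
            t = mean / (sd / np.sqrt(s))
            p = float(2.0 * scipy.stats.t.sf(abs(t), s - 1))
        direction = "none" if mean == 0.0 else ("up" if mean > 0 else "down")
        results.append(
            PairResult(pair=(i, j), t=float(t), p_raw=p, p_adj=min(1.0, m * p),
                       direction=direction, mean_diff=mean)
        )
    return PosthocResult(pairs=results)


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: (rejection mask, p-value threshold used).

    The threshold is the largest rejected p-value, or 0.0 if nothing is rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def nodal_group_analysis(
    enod: np.ndarray, q: float = 0.05, posthoc_alpha: float = 0.05
) -> NodalStatsResult:
    """Per-node RM-ANOVA with BH-FDR across nodes; post-hoc pairs within survivors.

    enod is a (subjects, conditions, nodes) array of nodal efficiencies.
    """
    x = np.asarray(enod, dtype=float)
    if x.ndim != 3:
        raise ValueError("enod must be (subjects, conditions, nodes)")
    s, c, n = x.shape
    if c < 2:
        raise ValueError("need at least 2 conditions for a nodal group analysis")
    fvals, pvals = np.empty(n), np.empty(n)
    for node in range(n):
        res = rm_anova(x[:, :, node])
        fvals[node], pvals[node] = res.F, res.p
    reject, threshold = fdr_bh(pvals, q)
    posthoc = {
        int(node): posthoc_paired(x[:, :, node]) for node in np.flatnonzero(reject)
    }
    return NodalStatsResult(F=fvals, p=pvals, significant=reject,
                            fdr_threshold=threshold, posthoc=posthoc)


def reproducibility_index(main_labels, validation_labels) -> float:
    """Percentage of positions where two outcome-label vectors agree.

    Labels encode significance status and, for significant post-hoc
    comparisons, direction; matching "ns" (or "na") counts as consistent.
    """
    a = list(main_labels)
    b = list(validation_labels)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty label vectors")
    agree = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * agree / len(a)
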