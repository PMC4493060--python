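# netreconfig

Graph-theoretic analysis of how functional brain networks reconfigure under
increasing visual task demand, packaged as a tested, reusable pipeline for
within-subject fMRI designs (e.g. resting state → passive viewing → one-back
decision). Because no recordings ship with the package, a synthetic cohort
generator with a modular factor-model covariance stands in for the fMRI data;
every analysis stage also accepts user-supplied ROI time series as plain TSV.

## Who it is for

Researchers comparing whole-brain network topology across ordered task
conditions in a repeated-measures design: build per-scan connectivity
networks, measure their global/nodal topology against degree-matched null
models, quantify robustness to targeted attack, and test condition effects
subject-wise.

## The model and statistics

For each subject × condition scan (T × N ROI time series, detrended,
optionally high-pass filtered and nuisance-regressed):

1. **Connectivity** — Pearson correlation r_ij for all N(N−1)/2 ROI pairs,
   with two-sided p-values from t = r√((T−2)/(1−r²)) on T−2 df. An edge is
   kept iff p < α / (N(N−1)/2) (Bonferroni, α = 0.05; for N = 160 the
   per-edge threshold is 0.05/12720). The weighted variant keeps |r| on the
   same edge set.
2. **Topology** — average degree K, clustering coefficient C_p,
   characteristic path length L_p (mean over reachable pairs), local and
   global efficiency E_loc, E_glob, nodal efficiency
   E_nod(i) = (1/(N−1)) Σ_{j≠i} 1/d_ij, mean Euclidean edge length D_p (mm),
   and Newman modularity Q from Louvain restarts.
3. **Null models** — Maslov–Sneppen double-edge-swap rewiring preserves the
   degree sequence exactly; small-worldness
   σ = (C_p/C_p^rand)/(L_p/L_p^rand) is computed against the ensemble mean
   of 100 nulls.
4. **Robustness** — nodes are removed in decreasing E_nod order; R is the
   area under the largest-connected-component curve divided by N (so a
   complete N-node graph attains the ceiling (N+1)/2).
5. **Inference** — per metric, one-way repeated-measures ANOVA
   (F(c−1, (c−1)(s−1)), no sphericity correction) with Bonferroni-adjusted
   paired post-hoc t-tests; per node, the same ANOVA with Benjamini–Hochberg
   FDR across nodes; a reproducibility index (percent of agreeing
   significance/direction labels) compares two analysis runs.

## Worked example

A reduced synthetic study (6 subjects, 48 ROIs in 4 modules, 150 time
points, 3 conditions RS/VSW/VSD, 50 nulls):

```python
from netreconfig import StudyConfig, run_study
from netreconfig.synthetic import SimConfig

sim = SimConfig(n_subjects=6, n_rois=48, n_timepoints=150, n_modules=4,
                lambda_within=(0.55, 0.62, 0.70), lambda_global=(0.15, 0.22, 0.30),
                rng_seed=42)
study = StudyConfig(n_nulls=50, modularity_restarts=25, rng_seed=7)
report = run_study(study, sim_cfg=sim)
print(report.summary_frame()[["metric", "mean_RS", "mean_VSW", "mean_VSD", "F", "p"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints

```
metric  mean_RS  mean_VSW  mean_VSD      F     p
    Cp    0.605     0.860     0.975  8.616 0.007
    Lp    1.840     1.404     1.684  1.671 0.236
  Eloc    0.672     0.902     0.981  6.431 0.016
 Eglob    0.183     0.237     0.329  6.792 0.014
 sigma    7.860     6.859     5.780  1.691 0.233
     K    6.278     9.438    11.132 11.160 0.003
    Dp   25.403    25.778    26.420  3.949 0.054
     Q    0.733     0.738     0.735  0.155 0.859
     R    7.993     9.795    11.028  9.225 0.005
```

Each row gives the per-condition group means of one global metric and the
repeated-measures F(2, 10) and p across the three conditions: here the
planted coupling increase is recovered as rising density (K), clustering
(C_p), efficiencies and robustness (R), with σ ≫ 1 (small-world) throughout.
Post-hoc and nodal results live on the same report object:

```python
pr = report.posthoc["Eglob"].by_pair((0, 2))      # RS vs VSD
# t = 2.99, adjusted p = 0.091, direction = up
int(report.nodal.significant.sum())               # 13 of 48 nodes survive FDR
```

The same pipeline runs from the shell:

```bash
netreconfig simulate --out-dir data/            # node table + series TSVs
netreconfig run --config study.yaml --out results/
netreconfig compare results_a/study_report.json results_b/study_report.json
```

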