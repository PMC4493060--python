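# Methods

This note documents the models, conventions and numerical choices behind
`netreconfig`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the package's known limits.

## Synthetic cohort generator

The generator emulates a within-subject fMRI study: `n_subjects` = 18
subjects scanned under `condition_levels` = (RS, VSW, VSD), each scan a
T × N matrix with T = 230 retained volumes, N = 160 ROIs grouped into 6
modules, and TR = 2 s.

Signals follow a modular factor model. With m(i) the module of ROI i and
level-l loadings a_l (`lambda_within`), b_l (`lambda_global`):

    x_i(t) = a_l · g_{m(i)}(t) + b_l · g(t) + c_l · ε_i(t),
    c_l = √(1 − a_l² − b_l²)

All latent channels (module factors, global factor, private noise) are
stationary unit-variance AR(1) processes with φ = 0.3, a coarse stand-in for
BOLD temporal autocorrelation; columns are z-scored afterwards, which leaves
Pearson correlations untouched. The implied population correlation is
a_l² + b_l² within a module and b_l² between modules — positive
semi-definite by construction, so no nearest-PSD repair is ever needed.
Loadings increase with condition level (defaults a = 0.45/0.55/0.65,
b = 0.05/0.15/0.30), planting monotonically rising coupling whose
between-module share grows fastest. Per-subject additive loading jitter
(SD 0.05) is drawn once per subject and shared across that subject's
conditions, matching the repeated-measures design; jittered loadings are
clipped into [0, 0.999] and shrunk radially if a² + b² would reach 1. One
root seed fans out through named `SeedSequence` spawns (node table, jitter,
one stream per scan), so cohorts are bit-reproducible and scans are
independently re-runnable.

Node coordinates are drawn around module centers rejection-sampled in a cube
of half-width 60 mm with pairwise separation ≥ 2 × 12 mm, so within-module
Euclidean distances are stochastically smaller than between-module ones —
enough spatial structure for the wiring-cost metric D_p to be meaningful.

What the generator does *not* emulate: hemodynamic response shapes, task
block structure, scanner drift and motion artifacts, inter-regional
heterogeneity of noise, negative coupling, and subject-specific module
boundaries. Tests passing on this cohort therefore validate the pipeline's
arithmetic and its ability to recover planted covariance differences; they
say nothing about sensitivity to realistic fMRI confounds.

## Preprocessing

Stage order is fixed and logged: leading-volume discard/truncation → linear
detrend → high-pass → nuisance regression. Each stage is a projection, hence
idempotent (verified to 1e−10). The high-pass is a discrete-cosine-basis
projection (basis functions of frequency k/(2·T·TR) below the cutoff, plus
the constant), the SPM-family convention: deterministic and free of filter
edge effects at T = 230. The default cutoff is "off" for synthetic cohorts
(the generator has no drift); 0.01 Hz is the conventional value for real
data. The global signal is not a confound by default; a flag adds it.
Confound regression requires a full-rank design and names the collinear
columns otherwise.

## Network construction

Edgewise p-values use the exact t-transform of the Pearson r on T−2 df.
Thresholding is strict (p < α/m, m = N(N−1)/2 unique pairs) and
sign-agnostic by default — the retention rule is purely statistical; a
`positive_only` flag drops negative edges for users who prefer that
convention. Weighted networks carry |r| on the surviving edge set so that
edge lengths 1/w are well defined; whether a weighted analysis should use
r, |r| or positive r only is a genuinely open convention and |r| is the
documented default.

## Graph metrics

Binary definitions follow the standard complex-network conventions:
C_i = 2E_i/(k_i(k_i−1)) with C_i = 0 for degree < 2 (and the mean taken over
all N nodes, keeping C_p comparable across networks), BFS distances,
L_p = mean distance over reachable pairs with the unreachable fraction
reported alongside, efficiencies with 1/∞ = 0, E_loc as the mean global
efficiency of neighbor-induced subgraphs, and E_nod as the mean inverse
distance to all other nodes. The disconnected-graph convention matters at
Bonferroni stringency, where isolated nodes are common; the efficiency
family is the principled workaround and the L_p convention (finite pairs
only) is declared rather than inferred. Weighted variants: node strength for
K, Onnela geometric-mean triangle intensity for C_p (weights rescaled by the
maximum; reduces exactly to the binary coefficient on 0/1 weights), shortest
paths on lengths 1/w for the path/efficiency family, D_p from edge presence
only.

Modularity Q is maximized by Louvain restarts (default 100, seeded); the
all-in-one partition scores exactly 0 and acts as a floor, so the returned
Q is never negative. On graphs of ≤ 8 nodes the restart scheme reproduces
the exhaustive-partition maximum in tests, bounding the approximation.

## Null models, σ, robustness

Maslov–Sneppen rewiring attempts `swaps_per_edge` × E double-edge swaps
(default 10), rejecting proposals that would create self-loops or duplicate
edges; the degree sequence is conserved exactly, and graphs with no legal
swap (complete graphs) return unchanged. σ uses ensemble means of C_p and
L_p over `n_nulls` = 100 independent rewirings; at these settings the
Monte-Carlo SE of σ is far below between-condition differences. A
triangle-free observed network has C_p = 0, hence γ = 0 and σ = 0 ("not
small-world") without sampling nulls; if the observed network has triangles
but every null is triangle-free, σ is undefined (raised as an error by
`null_ensemble`, treated as +∞ by the acceptance script where only a
minimum is reported).

Robustness uses the static intact-network E_nod ranking (ties broken by
node index); re-ranking after each removal is available but off by default.
R = (Σ_k s_k)/N including the intact network as k = 0, which puts the
complete-graph ceiling at (N+1)/2 — 80.5 for N = 160, just above the
73.9–77.7 range typical of dense task networks, which is what motivated
this normalization among the possible AUC conventions.

## Group statistics

The repeated-measures ANOVA is the explicit within-subject sums-of-squares
partition (SS_total = SS_subjects + SS_conditions + SS_error,
F = MS_cond/MS_err on (c−1, (c−1)(s−1)) df) with no sphericity correction,
matching the uncorrected F(2, 34) layout of an 18 × 3 design; it is pinned
in tests against pingouin and a hand oracle, and F = t² holds for c = 2.
Degenerate tables follow fixed conventions: zero condition variance → F = 0,
p = 1; zero error variance with condition variance → p = 0. Post-hoc paired
t-tests cover all three pairs (RS–VSW, VSW–VSD, RS–VSD), two-tailed,
Bonferroni ×3. Nodal inference runs the same ANOVA per node with BH-FDR
(q = 0.05) across nodes and Bonferroni post-hocs within surviving nodes.
The reproducibility index between two runs compares 9 ANOVA labels
(sig/ns) plus 27 post-hoc labels (up/down/ns, "na" when the metric's ANOVA
is not significant); matching "ns"/"na" counts as consistent, since an
agreement on absence is still an agreement.

## Problem sizes used in the shipped checks

The test suite exercises brute-force oracle equivalence on 200 random graphs
of ≤ 12 nodes (exhaustive modularity on ≤ 8), degree conservation on 100
random graphs, ANOVA calibration on 500 null tables, and planted-effect
recovery on five full default cohorts; the acceptance script analyzes one
full default cohort with 100 nulls per network (~2 minutes single-core).

## Known limitations

- With the default generator loadings, the Bonferroni critical correlation
  at T = 230 (r ≈ 0.30) exceeds the planted resting-state within-module
  correlation (0.205) and the between-module correlation at every level
  (≤ 0.09). Resting-state networks of low-jitter subjects are therefore
  extremely sparse — occasionally triangle-free, scoring σ = 0 — and
  between-module edges are essentially absent at all levels, so modularity Q
  barely responds to condition. Users who want dense, small-world networks
  at every level (and a detectable Q effect) should raise the loadings so
  the implied correlations straddle the critical r; the defaults are kept
  as the package's reference conditions and the behaviour is reported as
  measured.
- The generator's stationary factor model cannot express time-varying
  connectivity within a scan.
- Louvain restarts give a lower bound on max-Q for graphs beyond exhaustive
  size; Q comparisons across conditions share this bias.
- σ for weighted networks permutes observed weights onto rewired supports;
  this preserves degree sequence and weight distribution but not
  weight-degree correlations.
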