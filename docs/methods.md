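# Methods

This note documents the models implemented in `fetoconn`, the numerical
and design choices behind them, what the synthetic-data generator does
and does not emulate, and known limitations.

## Data model

A connectome is a d×d symmetric, non-negative, zero-diagonal weight
matrix over a fixed ordered node set; weights are treated as
dimensionless non-negative reals (in practice they come from
microstructure-informed tractography, e.g. fiber-bundle-capacity
weighting, whose physical units are not standardized). Matrices read
from CSV are symmetrized when the asymmetry is at most 1e-6 (numerical
round-trip noise) and rejected beyond that; the diagonal is forced to
zero because self-connections are undefined here. Connection "length"
defaults to the Euclidean distance between region centroids — a
reproducible stand-in for streamline length; a user-supplied length
matrix can be passed wherever a distance matrix is accepted.

## Graph metrics

Conventions, chosen once and used everywhere:

* **Weight→length:** l = 1/w. Stronger connections are shorter; absent
  edges have infinite length. Shortest paths use Dijkstra on this
  transform.
* **Global efficiency** is the mean over ordered node pairs of the
  inverse shortest-path length (1/∞ = 0, so disconnection is handled
  gracefully); **characteristic path length** is the mean shortest-path
  length and raises on disconnected graphs rather than silently dropping
  infinite pairs.
* **Clustering** is the Onnela geometric-mean formulation with weights
  normalized by the graph maximum; nodes of degree < 2 contribute 0.
  This makes the mean clustering invariant to a common rescaling of all
  weights.
* **Local efficiency** of a node is the global efficiency of the
  subgraph induced on its neighbors (node removed).
* **Small-world index** is (CC/⟨CC_null⟩)/(CPL/⟨CPL_null⟩) against an
  ensemble (default 100) of degree-preserving Maslov–Sneppen rewirings
  (10 attempted swaps per edge) with the original weights shuffled onto
  the rewired edge set; disconnected rewirings are resampled. Graphs too
  dense to admit the requested number of swaps use however many swaps
  succeed — the partially rewired graph is still a valid
  degree-preserving null. With 0 rewiring iterations the null is defined
  as the graph itself (no weight shuffle), so the index self-normalizes
  to exactly 1; this anchors the normalization and is the documented
  degenerate case. Several incompatible small-world definitions exist in
  the literature, so absolute SWI values are comparable only within one
  convention.
* **Betweenness** uses lengths 1/w and is normalized by (d−1)(d−2)/2;
  hub ranking is invariant to the normalization. **Eigenvector
  centrality** is the principal eigenvector of the weight matrix
  (dense symmetric eigendecomposition, oriented non-negative, unit l2
  norm); it requires a connected graph. Hub extraction takes the top-k
  (default 10) nodes by strength, betweenness or eigenvector centrality
  with ties broken by node order, deterministically.

## Template aggregation model

Templates for weeks 22…37 are estimated jointly by minimizing
L_repr + λ_cons·L_cons + λ_dist·L_dist (README for the formulas). Choices:

* **GED convention.** The l1 distance is accumulated over the upper
  triangle — each undirected edge counted once. Counting both triangles
  would double every term, which only rescales the λ's.
* **λ defaults.** λ_cons = λ_dist = 1. The three loss terms are not
  naturally commensurate (L_dist is bounded by 2·ln 2 per pair while the
  GED terms scale with total weight); the defaults keep the optimization
  dominated by representation with consistency as a mild smoother, and
  both weights are exposed in the model interface and the CLI.
* **Histograms.** Connection-length histograms use 20 equal-width bins
  spanning [0, max inter-node distance], fixed for the whole cohort
  before optimization. Hard binning is non-differentiable, so each edge
  splits its weight linearly between the two adjacent bin centers
  (lengths beyond the first/last center clamp to the end bin). Hard
  binning is available as an evaluation-only mode; the two agree exactly
  when every edge length sits on a bin center.
* **Optimization.** Stochastic subgradient descent from per-week
  element-wise-average initialization (week t averages subjects in
  [t−0.5, t+0.5), widening the window in 0.5-week steps if empty). Each
  iteration samples one subject uniformly (seeded) and steps all M
  templates on that subject's representation and distance terms plus
  1/N of the consistency gradient, so one epoch's expected step matches
  the full-loss gradient. The l1 subgradient at zero difference is 0.
  Non-negativity is enforced by projection after every step; symmetry is
  structural (optimization runs in upper-triangle coordinates). The
  JS-divergence gradient uses ∂D_JS/∂q_b = log(2q_b/(p_b+q_b)) with an
  eps = 1e-12 floor inside the logarithm; for bins empty in both
  distributions the one-sided limit log 2 is used.
* **Learning rate and stopping.** The default learning rate is 1e-5 —
  small relative to the weight scale, which the l1 (sign) gradients
  require for stability. The run stops after 200 epochs or when the
  epoch-to-epoch relative change of the full loss falls below 1e-6.
  At these defaults the optimizer is still descending when it stops:
  on the default synthetic study the mean GED between fitted templates
  and the ground-truth field keeps improving with longer runs (about
  32 → 28 at 200 epochs, → 23 at 2000, → 19 at convergence near 7000
  epochs, roughly 35 ms/epoch at d = 30, n = 60). Users who care about
  template fidelity more than runtime should raise `n_epochs`; the
  default keeps the fit in the seconds range.
* **Divergence guards.** A total loss exceeding 10× its initial value,
  or a template collapsing to all-zero (which makes its length
  distribution undefined), aborts with advice to lower the learning
  rate.
* **Baselines.** Consensus thresholding keeps the strongest mean-weight
  edges until the template's binary density matches the group's mean
  density (nearest achievable). Distance-preserved averaging applies the
  same idea within edge-length bins — per bin, the most frequently
  present edges (ties broken by higher mean weight) are kept up to the
  rounded mean per-bin count — so long-range connections are
  proportionally retained. Kept edges take mean weights in both.

## Growth models

The sigmoid f(t) = b + L/(1+exp(−k(t−t0))) has baseline b (units of
weight), amplitude L, rate k (1/week, bounded to [0.01, 10]) and
inflection t0 (weeks, bounded to the observed age range ± 2); the slope
at the inflection is L·k/4. Fitting minimizes squared residuals with a
bounded trust-region least-squares solver and an analytic Jacobian, from
the deterministic start b₀ = min, L₀ = range, k₀ = 1, t₀ = age of the
value nearest midrange. Bounds keep the non-convex fit identified on
subsamples; optimizer failure is reported via a `converged` flag, never
an exception. Adjusted R² uses 4 parameters and is compared against the
1-parameter-slope linear fit (OLS with a two-sided t-test on the slope).
Because "growth rate" can be read either as the curve slope L·k/4 or via
the rate parameter itself, hemispheric comparisons report paired tests on
t0, on L·k/4, and on 1/k separately.

Bootstrap ensembles refit the sigmoid on 1000 seeded draws of 75% of
subjects without replacement, report the mean curve with ±2 SD bands on a
uniform age grid, and summarize t0 over converged fits (non-converged
fits are excluded and counted; under 50% convergence raises a warning
flag). A constant nonzero paired difference makes the paired t statistic
unbounded; it is reported as ±∞ with p = 0 and a `degenerate` flag
rather than hidden.

**Edge-trend retention.** For each of 100 repetitions, 75% of subjects
are drawn without replacement and every edge is tested for a linear age
association; an edge is retained when significant with a consistent sign
in ≥ 95% of repetitions. The significance level inside the resampling is
0.01 (two-sided), matching the level used for the nodal regressions. At
0.05 the repetitions — which share subjects and are therefore strongly
correlated — retain chance edges at about 2 per 1000 (measured on 9360
simulated null edges), defeating the purpose of the retention rule; at
0.01 no null edge was retained in the same simulation while planted
trends are still recovered with sensitivity 1.0. Nodal regression
screens use Bonferroni correction at α = 0.01 across regions.

## Age prediction and split-half reproducibility

GED nearest-neighbor prediction assigns the week of the l1-closest
template, ties to the younger week; errors are |predicted −
round(true age)| because templates exist at integer weeks. The same-age
classifier represents each connectome as its edge-weight vector plus
eight topological descriptors (GE, LE, CPL, CC, SWI, total strength,
mean betweenness, mean eigenvector centrality — the descriptor set is
configurable), summarizes each (subject, template) pair by the l1/l2/l∞
norms of the feature difference, and trains a linear SVM (C = 1,
features standardized on training folds only) to predict same-week
membership; fold assignment is by subject, and a held-out subject's age
is the week of its highest-scoring template. Split-half reproducibility
compares intra-subject GED (same subject, two measurement halves) with
inter-subject GED within each half (Welch t), and computes the
fingerprint rate: the fraction of subjects whose own other-half
connectome is strictly closer than every other subject's, averaged over
both query directions.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume:

* **Geometry.** d/2 mirrored centroids per hemisphere on a brain-sized
  half-ellipsoid (Fibonacci spiral plus small seeded jitter), lobes as
  contiguous sagittal sectors. Real parcellations are not geometrically
  regular; only distances and lobe/hemisphere labels matter downstream.
* **Growth field.** Edge presence decays exponentially with centroid
  distance (60 mm scale, ceiling 0.9), with a nearest-neighbor backbone
  guaranteeing connectivity. Planted trends: by default 162 increasing
  and 12 decreasing edges at d = 88 (the decreasing ones
  interhemispheric), scaled proportionally to the number of node pairs
  for smaller graphs. Trending edges follow sigmoids with b ~ U(0.5, 2),
  L ~ U(2, 5), k ~ U(0.8, 2) and t0 ~ N(28.6, 0.44²) clipped to
  [27.7, 30.5] weeks; left-hemisphere-internal edges get a −0.2-week t0
  offset to exercise the hemispheric comparison. Non-trending present
  edges are constant at their baseline.
* **Noise.** A subject's true connectome deviates from the population
  field by a stable scalar effect (log-normal, sd 0.10) and a stable
  per-edge deviation (log-normal, sd 0.15) — the individual topology
  that makes connectomes fingerprintable. Each measurement then adds
  multiplicative log-normal noise (sd 0.13) and additive Gaussian noise
  (sd 0.05), truncated at zero. Split-half pairs share the stable terms
  and draw the measurement terms independently. The measurement scale
  was calibrated so the synthetic intra/inter-subject GED ratio falls
  near 0.35–0.37, the separation regime in which split-half
  fingerprinting is perfect while intra-subject variability remains
  substantial.
* **Desk scale.** The default study used by the tests and the
  acceptance script is d = 30 nodes, n = 60 subjects, 16 weekly
  templates, 40 increasing / 6 decreasing planted edges — the same
  structure as the full-size configuration (d = 88, n = 198, 162/12) at
  a size where every analysis runs in seconds.

What passing tests on these cohorts do **not** show: robustness to
registration and parcellation error, non-uniform age sampling,
heteroscedastic or spatially correlated measurement noise, motion
artifacts, or any property of real tractography-derived weights beyond
the sigmoid-growth + distance-sparsity + stable-individual-deviation
structure modeled here.

A note on template evaluation at desk scale: with this noise
calibration, gestational-age prediction from templates is nearly
saturated — per-week element-wise averages already predict in-sample
ages to ~0.2 weeks (each subject contributes to its own week's
average), and even the noiseless ground-truth templates do not predict
held-out subjects better than weekly averages, because the residual
error is each subject's own stable deviation, common to all template
sets. The aggregation optimizer's value at this scale is measured
directly instead: fitted templates are consistently closer to the
ground-truth field (lower mean GED) than their initialization, and the
margin grows as the optimizer converges.

## Pipeline and reproducibility

Every stochastic component takes an explicit seed and is bit-reproducible
given it. The pipeline derives per-stage seeds as global seed + fixed
offsets, writes the resolved configuration and a provenance record
(stage, seed, inputs, version) next to each stage's outputs, and never
mutates inputs. The CLI is a thin layer over the library; all results
are machine-readable files.

## Known limitations

* Templates inherit the l1 geometry: the optimizer drives each template
  entry toward a kernel-weighted median of subject weights, which is
  robust to outliers but can under-shrink isolated spurious edges when
  the learning rate × epochs budget is small.
* The small-world index depends on the null-model convention; values
  from other conventions are not directly comparable.
* CPL and eigenvector centrality require connected graphs by design;
  heavily thresholded connectomes may need the error semantics relaxed
  upstream.
* The same-age SVM uses exact integer-week equality for its labels; a
  tolerance window would change the class balance and is not
  implemented.
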