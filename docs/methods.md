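# Methods

## Problem and model

`fpannet` analyses the topology of a small resting-state functional brain
network — by default the 16-region frontal–parietal attention network
(FPAN) — from regional BOLD time series, and compares that topology between
a patient-like and a control-like group.

The analysis has four stages.

1. **Functional connectivity.** For each subject the T × N matrix of
   regional time series yields an N × N Pearson correlation matrix,
   Fisher-transformed (z = atanh r) to stabilize the sampling distribution.
   Negative correlations are set to zero (edge absent) rather than used as
   weights, the usual convention for weighted graph analysis; the diagonal
   is zero. Mean strength is the average z over all N(N−1)/2 pairs,
   *including* pairs whose negative correlation was zeroed — the
   denominator never changes, so strength is comparable across subjects.

2. **Small-world metrics.** The weighted clustering coefficient C is the
   geometric-mean (Onnela) form with weights scaled by the network maximum:
   C_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1)), averaged over
   nodes, with k_i the number of nonzero neighbours and C_i = 0 when
   k_i < 2. The characteristic path length L is the mean shortest-path
   distance over node pairs with edge length 1/w. Both are normalized by
   the ensemble mean over n_random = 100 null networks obtained by randomly
   permuting the nonzero edge weights over the same edge positions
   (topology, hence degree sequence, preserved): γ = C/C_random,
   λ = L/L_random. σ = γ/λ is reported for completeness but drives no
   claim. Ensemble member k uses seed `base_seed + k` so any single null is
   reproducible.

3. **Spanning-tree topology.** The maximum-strength spanning tree is built
   by Kruskal's algorithm: edges sorted by weight descending, each kept
   unless it closes a cycle, until n − 1 edges connect all nodes. Ties are
   broken by (weight descending, smaller node index, smaller partner
   index), which makes the tree deterministic even on degenerate inputs.
   All tree metrics use hop distances (each edge counts 1):

   | metric | definition | star (n=16) | path (n=16) |
   |---|---|---|---|
   | diameter (normalized) | max hop distance / m | 2/15 | 1 |
   | leaf fraction | #degree-1 nodes / m | 1 | 2/15 |
   | kappa | Σk² / Σk | 8.0 | 58/30 |
   | betweenness (per node) | pairs through node / ((n−1)(n−2)/2) | hub 1, leaves 0 | centre 56/105 |
   | tree hierarchy | leaf / (2·m·BC_max) | 0.5 (count) | → 0 |
   | eccentricity | max hop distance from node | mean 31/16 | mean 11.5 |

   with m = n − 1. Betweenness is computed from the component sizes left
   by deleting each node (the pairs straddling two components are exactly
   the pairs routed through it), normalized so a leaf scores exactly 0 and
   a star hub exactly 1. Tree hierarchy is computed in two variants: the
   defining equation uses the leaf *count* (star = 0.5 at every n); a
   leaf-*fraction* variant (count variant ÷ m) is also reported because
   published toolbox outputs of magnitude ~0.02 on 16-node networks
   correspond to that scaling. The group tables use the fraction variant;
   both columns are always written.

4. **Statistics.** Cohort characteristics use pooled-variance two-sample
   t-tests (a Welch option exists); the sign convention is control minus
   patient. Each network metric is tested for a diagnosis effect by ANCOVA
   — OLS of the metric on intercept + gender + verbal IQ + diagnosis
   (TDC = 0, ADHD = 1), F(1, n − 4) for the diagnosis term. Metric–symptom
   association uses partial correlation: both variables residualized on
   the covariates with intercept, Pearson r of the residuals, two-sided p
   from t = r√(df/(1−r²)), df = n − 2 − k. Correlations use the full
   sample (both groups). Multiplicity is controlled by Benjamini–Hochberg
   FDR at q = 0.05 within each results family (the global-metric table,
   the correlation table, and the 16-region nodal table separately).

## Synthetic cohort generator

Real resting-state data are not required for testing: the generator plants
the topology the pipeline is supposed to detect.

* **Backbone covariance.** Given a spanning tree, the population
  correlation matrix has `edge_r_strong` (default 0.6) on tree edges and
  `edge_r_weak` (default 0.1) elsewhere, unit diagonal. This template can
  be non-positive-definite (a star hub cannot correlate 0.6 with 15
  mutually weak leaves), so it is repaired by eigenvalue clipping at 1e−6
  followed by re-standardizing the diagonal. The repair preserves the
  strong > weak ordering (post-repair star edges ≈ 0.42 vs off-edges
  ≈ 0.11), which is what backbone recovery relies on. The repair triggers
  only for genuinely non-positive-definite input, so it is idempotent.
* **Star↔line continuum.** Each subject's covariance is the convex blend
  (1−b)·Σ_star + b·Σ_path. Controls draw b ~ N(0.2, 0.15), patients
  b ~ N(0.8, 0.15), truncated to [0, 1]. The blend is the single ground
  truth parameter: larger b means larger diameter, fewer leaves, lower
  kappa and lower hierarchy of the subject's true backbone.
* **Time series.** T = 166 rows (the usable volume count of a typical
  ~6-minute acquisition after discarding initial volumes) of i.i.d.
  zero-mean multivariate normal draws plus independent white observation
  noise (sd 0.5). No autocorrelation, drift, motion or hemodynamics are
  modelled — passing recovery tests therefore demonstrates sensitivity of
  the metrics to planted covariance topology under white noise, not
  robustness to realistic fMRI artefacts.
* **Covariates and symptom score.** Gender is Bernoulli (controls 0.478,
  patients 0.748 male), verbal IQ Gaussian (112.6 vs 107.1, sd 14),
  mirroring the demographic imbalance such cohorts show; age, handedness
  and performance IQ are matched across groups. The symptom score is
  `baseline_group + 13·b + N(0, 4)` with baselines 43 (control) and 62
  (patient), giving group means near 45.5 and 72.4 and a built-in
  metric–score correlation through b.
* **Determinism.** All randomness flows through one `numpy` Generator
  seeded by the spec; identical specs give bitwise-identical cohorts.

## Numerical choices

* Correlations of magnitude 1 are clipped to 1 − 1e−7 before atanh
  (finite z for duplicated channels), with a warning.
* Disconnected graphs (possible after negative-edge removal) raise an
  error listing the components rather than propagating infinite distances;
  a 16-node FC matrix that disconnects signals an upstream problem.
* Null-ensemble means are computed as the observed value plus an exactly
  summed (math.fsum) mean of centered offsets; this removes summation
  rounding so a weight-constant network has γ = λ = 1 exactly.
* Time-series TSVs round-trip bit-exactly (repr formatting on write,
  round-trip float parsing on read). Recomputed correlation matrices may
  still differ at the last bit across array layouts because BLAS reduction
  order varies; equality guarantees are on values (1e−12), not bits.
* ROI extraction assigns a voxel to a sphere when its center, mapped
  through the image affine, lies within the radius in mm; overlapping
  spheres share voxels.

## Problem sizes used in the checks

Oracle tests enumerate all 1296 labeled trees on 6 nodes (Kruskal
optimality) and all 16807 on 7 nodes (metric extremality), and brute-force
clustering/path-length/betweenness on graphs of ≤ 8 nodes. Calibration uses
200 null cohorts of 30 + 30 subjects at T = 120; planted-effect recovery
uses 50 cohorts of 60 + 60 subjects at T = 166. These sizes give stable
rates (binomial half-width ±3 percentage points at 200 replicates) while
keeping the whole suite under a minute of compute.

## Known limitations

* White observation noise only; no temporal autocorrelation, so effective
  sample sizes are optimistic relative to real BOLD data.
* The negative-edge convention (zeroing) and the 1/w distance map are
  conventions, not estimands; alternative choices (absolute value,
  1 − r distances) would change metric magnitudes.
* Tree metrics on 16 nodes are coarse (diameter takes 14 discrete values);
  group tests treat them as continuous, which the calibration check shows
  is adequate at n ≥ 30 per group but may not be for very small samples.
* The weighted clustering coefficient is one of several weighted
  generalizations (Onnela form used here; Barrat's is a drop-in
  replacement behind the same function).
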