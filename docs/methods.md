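# Methods

This note records the models, conventions and numerical choices behind
tractnet, and what its synthetic-data tests do and do not demonstrate.

## Deterministic tractography

Tensor fields are voxel grids of symmetric 3×3 diffusion tensors (mm²/s)
with a voxel-to-world affine.  Tracking follows the principal eigenvector by
fixed-step Euler integration, bidirectionally from every seed, with the two
half-tracks concatenated.  Choices the literature leaves open and how we
fixed them:

- **Interpolation**: trilinear on the six unique tensor components, with
  eigendecomposition at the interpolated point.  Indices are clamped at the
  grid edge, so positions within the outer half-voxel shell remain usable.
- **Eigenvector sign**: chosen per step to have positive dot product with
  the previous direction.
- **Termination**: FA below `fa_threshold` (default 0.2), turning angle
  above `angle_threshold` (default 40°), mask exit, or total length above
  `max_length` (default 250 mm — a loop guard, configurable).  Seeds whose
  local FA is already below threshold produce no streamline.
- **Seeding**: a regular world-space grid at `seed_grid_spacing` (default
  0.5 mm, "super-resolution" relative to typical 2 mm diffusion voxels).
  Tracking is fully deterministic; no randomness anywhere.

Units: streamline coordinates and lengths in mm; voxel indices 0-based;
label lookup at endpoints is nearest-voxel, with no dilation tolerance.

## Connectome construction

`assign_edges` counts a streamline toward edge (i, j) iff its first and last
points fall in distinct regions i, j of the parcellation; endpoints in
background or in a single region contribute nothing, so the adjacency has a
zero diagonal by construction.  Each traced streamline is counted once; no
geometric deduplication of near-duplicate trajectories is attempted.

Weighting strategies (per-edge, symmetric):

- length-adjusted `w_ij = ½ Σ_{m=1..N_ij} 1/l_m` — the summation runs over
  exactly the N_ij streamlines of the edge; reciprocal lengths compensate
  the higher seed counts of long tracts.
- volume-adjusted `w_ij = 2 N_ij / (V_i + V_j)` with V in mm³ — larger
  regions capture more seeds; dividing by the end-node volume sum removes
  that bias and any global head-size effect (doubling all volumes halves
  all weights, which the tests assert).

## Graph metrics

All weighted metrics operate on `ŵ = w / max(w)` (per network; an empty
network yields all-zero ŵ without error).  Conventions:

- clustering: `C_i = 2 t_i / (k_i (k_i − 1))`; weighted triangles use the
  cube root of the weight product (geometric-mean intensity).  Nodes of
  degree < 2 score 0.
- shortest paths: hop counts (unweighted) or sums of 1/ŵ (weighted);
  disconnected pairs contribute 0 to efficiency and are excluded from the
  characteristic path length average.
- local efficiency: efficiency of the neighbourhood subgraph; the weighted
  form follows the Brain Connectivity Toolbox cube-root convention (paths
  on cube-rooted lengths, pairs weighted by the cube root of the incident
  weights), normalised by `k_i (k_i − 1)`.
- betweenness: fraction of shortest paths through a node over ordered
  source–target pairs, normalised by `(n − 1)(n − 2)` so a path centre
  scores 1.  Some sources print `(n − 1)²`; `strict_print=True` exposes
  that variant.
- small-worldness: `S = (C/C_rand)/(L/L_rand)` with null means over
  `n_null` (default 100) Maslov–Sneppen double-edge-swap randomisations,
  10×|E| swap attempts each, seeded; swaps carry edge weights with the
  moved edges, so the weighted S uses topology-randomised but
  weight-preserving nulls.  Whether the original tooling also preserved
  the weight distribution in its nulls is not documented anywhere we know
  of; carrying weights is the stricter choice.

For binary weights every weighted metric reduces exactly to its unweighted
counterpart; the suite asserts this, plus equality with exhaustive
brute-force oracles on random graphs of up to 8 nodes.

## Multi-threshold scaffold

Topological metrics are confounded by edge count, so all metrics are
evaluated at 40 evenly spaced edge-density levels spanning `(0, d_max]`,
where `d_max` is the minimum native density across subjects — the highest
level at which all subjects can hold exactly the same number of edges.
Unweighted degree, itself an edge-density index, is instead evaluated at 40
edge-weight cut-offs.  These cut-offs come from the "average subject" (the
element-wise mean weight matrix): at each density level, the smallest weight
retained by the average subject is the cut-off.  An alternative reading —
the mean of the retained weights — is available via
`weight_rule="mean_retained"`; neither is asserted as the original tool's
behaviour.  Density thresholding keeps the top `round(level·n(n−1)/2)` edges
by weight with deterministic lexicographic tie-breaks, and the surviving
network is re-normalised before weighted metrics.

AUC_total is the trapezoidal integral of a curve over its threshold axis;
missing values restrict integration to the longest contiguous finite run.

## Group statistics

- **AUC ANCOVA**: OLS of AUC on group + covariates, single-df F test for
  group.  Parametric mode screens full-model residuals by a skew/kurtosis
  rule (|skew| ≤ 1, |excess kurtosis| ≤ 2) replacing visual Q–Q inspection,
  and falls back to log10 for positive, screen-failing data.  Permutation
  mode reports the same F with a Freedman–Lane p-value: residuals of the
  covariates-only model are permuted, added back to the reduced fit, and
  the group F recomputed; p = (b + 1)/(m + 1); all n! permutations are
  enumerated when `n_perm=None`.
- **MTPC**: per-threshold group t from the covariate-adjusted model;
  Freedman–Lane permutations give the null of max |t| across thresholds
  (two-tailed); its 95th percentile is the FWE-adjusted critical value.
  Supra-critical runs of at least `cluster_min = 3` consecutive thresholds
  form clusters; each cluster's AUC_MTPC is the trapezoidal area of |t|
  above the critical value (the area of |t| itself is selectable via
  `cluster_area="full"`), and AUC_crit is the mean area of the analogous
  clusters in the permuted data.  A result is significant iff a cluster's
  area exceeds AUC_crit.  Covariate presets: age + sex always; total
  intracranial volume added under the length-adjusted strategy (whose
  weights carry no head-size correction); pre-morbid IQ added for
  cognition correlations.
- **Partial Spearman**: rank-transform x, y and covariates, remove the
  linear effect of covariate ranks, correlate the residuals;
  df = n − 2 − #covariates; rows missing any variable are dropped per
  correlation (pairwise deletion).  Bonferroni: `p_adj = min(1, p·m)`.

## Synthetic cohorts: what they emulate

The generator produces what the statistics need to be exercised against: a
shared small-world backbone (Watts–Strogatz ring lattice, rewiring 0.1,
ring-distance-decaying lognormal weights — heavy-tailed like streamline
counts), per-subject multiplicative lognormal edge noise (σ = 0.25), and a
two-group structure in which patients (a) lose each lowest-quartile template
edge with probability `weak_edge_deletion_prob` and (b) have weights
attenuated by a factor grading from `weight_attenuation` at the weakest
template edge quadratically (in weight-quantile rank) to 1 at the strongest.

The grading is deliberate: metrics divide weights by the network maximum, so
a uniform multiplicative factor cancels identically and could never produce
a weighted-metric group difference.  Rank-graded attenuation encodes the
clinically observed pattern — weak connections preferentially weakened and
lost, strong ones relatively spared — while remaining visible after
normalisation at every density level; the quadratic profile spreads the
effect across most of the weight range rather than concentrating it in the
weakest tail.  Covariates: age ~ U(51, 84) years, balanced sex, TIV ~
N(1430, 90)·10³ mm³, pre-morbid IQ ~ N(107, 12); cognitive and disease
columns carry plausible clinical scales, with disease measures present for
patients only.  Optional linear covariate effects act multiplicatively on
all log-weights.

What passing tests therefore show: the pipeline recovers injected group
differences of this specific generative form at correct false-positive
rates.  What they do not show: robustness to registration error, motion,
scanner site effects, non-multiplicative noise, or count-based
(heteroscedastic) weight noise — real tractography weights are Poisson-like,
so the relative noise of strong edges is smaller than this generator's
equal-σ model assumes; the equal-σ choice makes the normalising maximum
noisier than real data likely is, and is the main reason detection power
under the default conditions sits near, not above, 90%.

## Problem sizes and calibration checks

Monte-Carlo checks run at desk scale, chosen as the smallest sizes at which
the binomial assertions are meaningful: 200 replicate null cohorts
(25 + 25 subjects, 90 nodes, 1000 permutations) for type-I and FWE
calibration, 50 replicate cohorts for detection power, 100 subjects × 20
rewiring nulls for the small-world regime, exhaustive oracles at n ≤ 8.
Empirically (seed 1): AUC-ANCOVA type-I 0.040, MTPC FWE 0.045 (both inside
the exact binomial 95% interval around 0.05), conjunction-rule null rate
0.005, detection power 0.84–0.92 across seed blocks.

## Known limitations

- No probabilistic tractography, spherical deconvolution, or CSF-partial-
  volume handling; tensors are generated or supplied directly (no raw DWI
  simulation).
- No atlas registration: the parcellation is an input.
- The generator does not model the second-order pattern of patients showing
  slightly higher weighted nodal efficiency; it targets edge count/strength
  effects only.
- MTPC cluster areas depend on the threshold axis units; comparisons are
  scale-invariant only because observed and null areas share the axis.
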