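# Methods

This note documents the models, numerical conventions and design
choices behind `neomux`, and what the synthetic experiments do and do
not establish.

## Analysis model

### Connectome construction

- **FC** (`connectome.build_fc`): Pearson correlation between ROI time
  series; negative correlations enter by absolute value; Fisher
  r-to-z (`atanh`). `|r|` is clipped at `1 − 1e−7` so a perfect
  (anti)correlation maps to a large finite weight (≈ 8.4) instead of
  infinity; the clip cannot reorder non-degenerate ranks. The signed
  Pearson matrix is kept alongside the z-weights because the
  connectivity-strength score is defined on it.
- **SC** (`connectome.build_sc`): per pair, the streamline count
  averaged across the two tracing directions
  (`(forward[i,j] + reverse[j,i])/2`, then symmetrized by averaging
  with the transpose) divided by the average size of the two ROIs.
  ROI-size normalization removes the bias of large regions attracting
  more streamline endpoints.
- **Connectivity strength** (`connectome.strength_score`): mean
  upper-triangle entry of the *unthresholded* weighted connectome —
  strength is deliberately contrasted with topology, which is measured
  on binarized networks. For FC, "removing negative correlations" is
  implemented as zero-replacement of negative Pearson entries
  (default); since removal is ambiguous, `neg_policy` also offers
  `abs` (the FC-construction rule) and `drop` (exclude from the
  average). Strength uses raw `r`, not Fisher z.

### Thresholding

`k = round_half_up(d · n(n−1)/2)` edges are retained at each density
`d` of the default grid 0.05–0.70 in steps of 0.05 (14 levels).
Round-half-up is a fixed convention; the retained count, not the
nominal density, defines the realized density `k/M` exactly, and `k`
is always taken relative to all node pairs so equal densities are
guaranteed across subjects and groups.

- **Proportional** (subject level): rank by weight descending.
- **Consistency** (group level): rank by coefficient of variation
  `CV_e = s_e/μ_e` ascending, with the sample (n−1) standard
  deviation. Edges with zero cross-subject mean get `CV = +∞`
  (structural zeros are worst-ranked, not errors).
- **Tie-breaking**: CV ties break by higher mean, then both schemes
  fall back to lexicographic node-label pair order. This makes
  thresholding a total order, hence deterministic across platforms and
  *nested* along the density grid (the edge set at a lower density is
  a subset of the set at any higher density).

### Graph and multiplex metrics

Distances are unweighted BFS shortest paths. Global efficiency is the
mean inverse distance over ordered pairs with `1/∞ := 0`, so
disconnected pairs contribute zero rather than making the score
undefined. Nodal local efficiency is the global efficiency of the
neighbor-induced subgraph, `0` for nodes of degree < 2 (the common
library convention); local efficiency is the unweighted mean over all
nodes. Both lie in [0, 1] and equal 1 exactly on complete graphs.
Metrics are computed on the whole network and on each hemisphere
subnetwork thresholded independently, mirroring per-hemisphere network
construction.

Edge overlap uses Dice normalization
`2|E_a ∩ E_b|/(|E_a| + |E_b|)`. All compared layers have equal
density by construction, where Dice, Jaccard and min-normalizations
are monotone transforms of one another and Dice reduces to
`|∩|/k` with the printed 0 (disjoint) and 1 (identical) endpoints.
Inter-layer assortativity is the Pearson or Spearman correlation
between the SC and FC degree sequences, paired by node label. A
regular layer (zero degree variance) makes the correlation undefined;
it is reported as missing and excluded listwise downstream — coercing
it to 0 would fabricate a "no coupling" observation.

### Permutation inference (H1)

The empirical statistic is the edge overlap between the FT and PT
consistency networks at one density. Each permutation redraws the
group assignment uniformly at random with the original group sizes and
recomputes the statistic. The test is lower-tailed — a genuine
difference in edge architecture manifests as *low* between-group
overlap — with the add-one estimator
`p = (1 + #{null ≤ empirical}) / (n_perm + 1)`, which never returns 0
and counts the identity relabeling.

**Null degeneracy.** At sparse densities the most consistent edges
survive every relabeling and the null collapses onto a few attainable
overlap values; p-values referred to such a null are misleading. The
diagnostic counts distinct null values and flags the level when there
are fewer than 20 or the null standard deviation is below 1e−6
(`null_degeneracy_check`; both thresholds configurable). Flagged
levels are excluded from the BH family and from the significance
report. Discreteness, not a normality statistic, is the operative
criterion because the failure mode *is* a discrete support. On small
(20-node) synthetic networks the diagnostic typically excludes many
sparse levels; this is the intended behavior, not an error.

BH correction is applied across densities within one modality (the
family actually displayed together); pooling across modalities is a
caller choice.

### Regression (H2/H3, exploratory)

Per (metric, modality, density ≤ 0.5):
`value ~ GA_c * hemisphere` with a subject-level random intercept,
REML estimation (statsmodels MixedLM). GA is centered at the cohort
mean; hemisphere is coded L=0/R=1 as a within-subject factor.
"Density as a nested factor" is operationalized as separate models
per density — matching one-coefficient-per-density reporting — with a
single pooled model deliberately not the default. Densities above 0.5
are excluded because near-saturated networks leave too little
inter-individual variability for the model (the exclusion bound is
configurable). Tukey fences (quartiles by linear interpolation,
type-7; 1.5×IQR) remove outliers per (metric, modality, density,
hemisphere) cell before fitting. Singular or non-converged fits are
reported as rows with `converged=False`, never silently dropped.
p-values are BH-adjusted across densities within each
(metric, modality, term) family.

AUC aggregation is the trapezoidal integral of the metric-versus-
density profile over the full grid (span 0.65), one value per
subject × hemisphere, fed to the same model form once per
(metric, modality). The strength comparison is Welch's
unequal-variance two-tailed t-test — robust to the variance imbalance
a group difference in FC scale itself induces.

The random-effects structure is a random intercept only; a random
hemisphere slope is not identifiable with one observation per
subject × hemisphere per cell.

## Synthetic cohort generator

`simulate.generate_cohort` emulates the inputs the analysis consumes:

- **Backbone**: on `n_nodes = 20` (default) split into L/R
  hemispheres, exactly `round(0.25 · M)` node pairs form the FT
  structural backbone, drawn by weighted sampling with
  within-hemisphere pairs 3× more likely than interhemispheric ones —
  a two-block stochastic structure giving short-range and
  interhemispheric edge classes.
- **PT group effect**: the PT backbone is the FT backbone after
  degree-preserving double-edge swaps touching `rewire_fraction = 0.5`
  of edges. Degrees (hence assortativity baselines) are preserved so
  the planted difference is purely in edge *identity* — the H1
  construct. On very small graphs the swap budget can be exhausted;
  completed swaps are kept and a warning notes the partial rewiring.
- **Counts**: per-pair base rates are log-normal around
  `count_mean = 120` and shared between groups, so generation is group-
  exchangeable when no effect is planted. Directed forward/reverse
  counts are negative binomial with dispersion (size) 2, plus a sparse
  Poisson(0.3) floor of spurious streamlines on all pairs. Dispersion
  is a convention (empirical neonatal count dispersions are not
  available): size 2 keeps backbone edges far more consistent than
  noise edges while giving the cross-subject variability that the
  consistency ranking — and hence a continuous permutation null —
  requires. With near-deterministic counts the null collapses
  (degeneracy) and the lower-tail permutation p becomes unusably
  conservative.
- **GA effect**: within-hemisphere backbone rates are multiplied by
  `1 + ga_eff_slope · (GA − 40)` (slope 0.02/week), an effect on
  weights, not topology, so GA–efficiency associations emerge only
  through thresholding.
- **Time series**: `Σ = c · f · Ŝ + (1 − c) · σ² I` with coupling
  `c = 0.2`, group strength factor `f` (FT 1.0, PT 0.3), and `Ŝ` the
  row-normalized symmetrized SC of that subject. Sampled time series
  (T = 150) therefore produce correlation matrices with negative
  entries, exercising the |r| step. If `Σ` is not positive definite it
  is repaired by diagonal loading and the subject is recorded in the
  cohort log. The scale choices balance two regimes the design
  requires simultaneously: per-edge FC signal weak enough that FC edge
  selection is noise-dominated (so SC rewiring does not leak into the
  FC edge-overlap test), while the strength score — an average over
  all ~190 pairs, with √M-smaller noise — still separates the groups
  at n = 20 per group.
- **Covariates**: FT GA ~ Normal(39.5, 1.2) truncated to [37, 44]
  weeks; PT GA ~ Uniform(23, 36.9); PMA at scan ~ Normal(40.5, 1.8)
  truncated to the term-equivalent window [37, 44] for both groups;
  birth weight grows ≈ 0.19 kg/week of GA.
- **Seeding**: a single integer seed is split via
  `numpy.random.SeedSequence.spawn` into streams for covariates,
  backbone, edge rates, ROI sizes, and one stream per subject, so
  cohorts are bit-reproducible and substructures are independently
  stable.

`SimConfig.exchangeable_null()` encodes the exact null: no rewiring,
equal strength factors *and* zero GA slope. The last condition
matters — GA distributions differ by group, so any nonzero GA→weight
slope breaks group exchangeability even without rewiring.

### What the generator does not emulate

Hemodynamics, motion and scanner artifacts, tractography distance/
gyral biases, atlas geometry, spatial autocorrelation of ROIs, and
realistic count magnitudes. Consequently, passing synthetic
experiments establishes that the *statistical machinery* is correct
and calibrated under the assumed generative structure — not that the
pipeline's operating characteristics transfer quantitatively to real
neonatal data.

## Problem sizes and experiment design

Synthetic experiments run at desk scale chosen as the package's own
study conditions: 20 nodes, 10–20 subjects per group, 150 time
points, 500 permutations per test for replicated experiments (10,000
remains the single-run default), 50–200 replicates per property.
Calibration of the H1 test is checked at density 0.2 — below the
backbone density, in the sparse-but-not-degenerate regime. The
GA-slope recovery check generates metric values from the mixed model's
own generative process (random intercept + planted slope over real
cohort covariates), because a slope planted on SC edge *weights* does
not induce an a-priori-known slope on binarized-network efficiency
after nonlinear thresholding; recovery through the full pipeline is
therefore checked at sign level, and coverage at model level with a
t-quantile Wald interval.

## Known limitations

- The permutation overlap statistic lives on a lattice (multiples of
  1/k); at small n and sparse d the add-one p is conservative even
  when unflagged.
- MixedLM Wald intervals slightly undercover at a few dozen subjects;
  the IQR pre-filter can additionally trim genuine extreme-GA
  observations, attenuating slopes by a small amount.
- Consistency and proportional thresholding of weighted SC matrices
  with many exact zeros can admit zero-weight edges at high densities
  via the deterministic tie rule (a warning is emitted).
- The CLI recomputes connectomes from the cohort directory in each
  subcommand rather than caching intermediates; for the cohort sizes
  targeted here this costs seconds.
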