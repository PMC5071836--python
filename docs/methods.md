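# Methods note

This note records the statistical model behind `olfcluster`, the meaning
and defaults of every tunable parameter, what the synthetic cohort
generator emulates (and deliberately does not), and the numerical choices
made for reproducibility.

## 1. Problem and data model

Each subject contributes three psychophysical olfactory scores:

| score | meaning | scale |
|---|---|---|
| `thr` | odor detection threshold (dilution step still detected; higher = better sensitivity) | 1–16, quarter-step grid |
| `disc` | odor discrimination (correct target pens among 16 triplets) | integer 0–16 |
| `ident` | odor identification (correctly named odors among 16 items) | integer 0–16 |

The working hypothesis is that the joint pattern of the three scores
contains a small number of natural groups that are *not* simply the
anosmia/hyposmia/normosmia bands of the TDI sum (`thr + disc + ident`,
cutoffs 16.5 and 30.5), and that group membership is statistically
associated with — but not determined by — the clinical etiology.

## 2. Pipeline stages, assumptions and parameters

### 2.1 Sex-specific age correction (`preprocess.AgeSexCorrector`)

Assumption: olfactory performance declines approximately linearly with
age, with possibly different slopes per sex. Within each sex stratum,
each score is regressed on age by simple ordinary least squares; the
corrected score is the residual plus the overall (both-sex) subtest mean,
which keeps corrected scores on the familiar clinical scale. A stratum
with fewer than two subjects or constant age degenerates to
mean-centering with a logged warning. The correction is a transformer:
coefficients fitted on one cohort can be applied to another.

### 2.2 Pareto density estimation (`mixture.pde`)

The density of each corrected subtest is estimated by sphere counts: the
estimate at grid point *g* is proportional to the number of data points
within the **Pareto radius** *r* of *g*, normalized to integrate to one.
The Pareto radius is the `q = 0.18` quantile of the pairwise distances of
the sample; for samples larger than `max_points = 2000` a seeded random
subsample of 2,000 points is used for the quantile (the full sample is
always used for the counts). Default evaluation grid: 200 equally spaced
points spanning the data range extended by *r* on both sides.

### 2.3 Two-phase Gaussian mixture fit (`mixture.fit_gmm`)

Each subtest's corrected distribution is modeled as an `m = 3` component
univariate Gaussian mixture (low / mid / high performance modes):

1. **EM phase** — responsibilities computed in log space
   (log-sum-exp), means initialized at sample quantiles, with a
   per-iteration log-likelihood monotonicity assertion and a reseed rule
   for degenerate components (σ floored at 10⁻³ of the sample standard
   deviation). Convergence tolerance `tol = 1e-8`, `max_iter = 500`.
2. **PDE refinement phase** — the mixture density is refined by
   least squares against the PDE curve using an in-package
   Levenberg–Marquardt optimizer with an analytic Jacobian,
   reparameterized so weights stay on the simplex and σ stays positive.
   The best iterate is returned, so the refined fit never has a larger
   sum of squared residuals against the PDE curve than the EM solution.

Components are reported sorted by mean; weights sum to one.

Each subject is then featurized as the 9-vector of Bayesian posterior
component memberships, three per subtest, computed in log space
(`mixture.posterior`, `MixtureFeaturizer`). Each 3-block sums to one.

### 2.4 Emergent self-organizing map (`esom.Esom`)

An *emergent* SOM uses far more neurons than expected clusters so cluster
structure can emerge instead of being imposed. Defaults: toroidal grid of
`rows = 50` × `cols = 80` = 4,000 units (torus: opposite edges joined, no
border effects), weights initialized uniformly within the per-dimension
data range, online training for `epochs = 30` sweeps in per-epoch
shuffled order. Learning rate decays linearly from `lr0 = 0.5` to
`lr1 = 0.05`; the Gaussian neighborhood radius decays linearly from
`radius0 = rows/2` to `radius1 = 1` (a cone kernel is also available).
The mean quantization error is recorded after every epoch.

Height fields on the trained grid:

* **U-matrix** — mean weight-space distance of each unit to its 8
  toroidal Moore neighbors (4-neighbor von Neumann variant available).
* **P-matrix** — number of data points within the Pareto radius of each
  unit's weight vector.
* **U\*-matrix** — `U * clamp((P − mean(P)) / (mean(P) − max(P)) + 1, 0, ∞)`:
  equal to U at mean density, zero at maximum density, amplified in
  sparse regions; a constant P leaves U unchanged.

### 2.5 Cluster extraction (`cluster_stats.cluster_landscape`)

The visual watershed reading of the U\*-landscape is replaced by a
reproducible surrogate: units at or below the
`threshold_quantile = 0.5` quantile of the U\*-heights are valley units;
valleys are toroidally 8-connected components; basins smaller than
`min_basin_units = 5` are merged into the large component with the
nearest mean weight; subjects inherit the cluster of their best matching
unit, and ridge-resident BMUs attach to the nearest valley unit in
weight space. Cluster ids 1..k are ordered by descending subject count.

### 2.6 Association statistics (`cluster_stats`)

* **χ²** — Pearson test of independence on the etiology × cluster
  contingency table (no continuity correction),
  df = (rows − 1)(cols − 1): 16 for the full 9 × 3 design, 14 when the
  Healthy row is excluded. Zero expected cells raise an error.
* **relDiff** — (n_expected − n_observed) / (0.5 (n_expected + n_observed))
  per cell, bounded in [−2, 2]; with the default sign convention
  overrepresented cells are negative (`sign_convention="obs_minus_exp"`
  flips this). Worked values: obs = exp → 0; obs = 3·exp → −1;
  obs = 0 → 2.
* **Spearman ρ** — between discrimination/identification,
  discrimination/threshold and threshold/identification, globally and per
  group (cluster or etiology); groups below `min_group_size = 3` are
  omitted with a warning.

## 3. What the synthetic generator does and does not emulate

`cohort.generate_cohort` emulates the *structure* of a large clinical
database: nine etiologies with realistic relative frequencies (from a
demographic reference table of 10,714 subjects), ages 6–95 (truncated
normal, mean 52.2, SD 17), both sexes, and a latent three-profile model
of olfactory performance:

| profile | thr center (SD) | disc center (SD) | ident center (SD) |
|---|---|---|---|
| good | 13.5 (1.5) | 14 (1.5) | 14 (1.5) |
| abolished | 1 (0.75) | 3 (1.8) | 3 (1.8) |
| reduced | 5 (1.5) | 9 (1.8) | 9 (1.8) |

Threshold centers follow the reported per-cluster medians;
discrimination/identification centers were fixed once as clinically
plausible values for good, absent-to-poor and reduced-but-preserved
performance. Scores are truncated normals shifted by an age slope of
−0.05 score units/year about the age-range midpoint, then clipped and
rounded to the legal grids. Each etiology has its own profile mixture
(e.g. Congenital is 95% abolished, Healthy 90% good, Infectious 70%
reduced), and the planted profile is recorded per subject.

Not emulated: test–retest noise and learning effects, etiology-specific
age distributions, within-profile correlation structure beyond the shared
profile and age effect, missing data, comorbidity, and the exact
real-data cluster shapes. Headline data-dependent statistics of any real
cohort (χ² magnitude, exact correlations, cluster counts) are therefore
not reproduced — only the structural behavior of the method is.

## 4. Numerical choices and reproducibility

The pipeline contract is: identical configuration and seeds produce
byte-identical artifacts. Two choices make this hold exactly:

* **No heap-sensitive numerics on the critical path.** Multithreaded BLAS
  and MINPACK routines can return results that differ in the last bits
  depending on memory alignment. All distance computations use explicit
  `((a − b)²).sum(axis)` reductions rather than matrix products, OLS
  slopes use the closed form, EM updates use elementwise reductions, and
  the PDE refinement uses the in-package Levenberg–Marquardt (normal
  equations via `einsum`) instead of a MINPACK wrapper.
* **Round-off snaps.** Corrected scores and fitted mixture parameters are
  rounded to 10 decimal places before serialization, absorbing benign
  round-off so that serialized artifacts compare equal byte for byte.

All stochastic steps (cohort draws, EM reseeds, PDE subsampling, SOM
initialization and shuffling) flow from explicit integer seeds through
`numpy.random.default_rng`.

## 5. Problem sizes

The package's own test and acceptance runs use a reduced profile chosen
for desk-scale runtimes: 2,000 subjects on a 20 × 30 grid for 30 epochs
(≈10 s; recovers the three planted profiles with adjusted Rand index
≈ 0.97). The full default configuration (10,714 subjects, 50 × 80 grid,
30 epochs) runs in a few minutes on one CPU via
`olfcluster run` or `pipeline.run_pipeline`.

## 6. Limitations

* The watershed surrogate (height-quantile flood fill) is a deterministic
  stand-in for interactive landscape reading; very shallow ridges can
  merge basins that a human would separate, and the quantile threshold is
  a free parameter.
* The 1-D mixture features discard inter-subtest dependence beyond what
  the SOM recovers from the joint 9-vector.
* The generator's profile mixtures per etiology are plausible but
  invented; association strengths measured on synthetic cohorts reflect
  those choices, not clinical reality.
* m = 3 Gaussians per subtest is fixed by design, not selected by an
  information criterion.
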