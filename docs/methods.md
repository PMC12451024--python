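# Methods

## The analysis model

The pipeline treats a subject's white matter network as an undirected,
weighted graph over the 90 regions of the standard anatomical
parcellation (left/right interleaved; `hubnet.atlas` fixes the order).
Two matrices describe it: streamline counts (how many reconstructed
fibers join two regions) and mean FA per connection (a [0, 1] proxy for
microstructural integrity).  All statistics downstream of the matrices
assume the matrices are given; tractography, registration, and atlas
warping are out of scope.

**Backbone.** Individual tractography is noisy, so group analyses are run
on a *backbone*: the set of region pairs whose connection is consistent
across a reference group.  Consistency is tested per pair with a
one-tailed sign test of H₀ "no connection": with m of n subjects showing
a positive count, p = 0.5^m under the classic discard-zeros rule, or the
Binomial(n, ½) upper tail P(X ≥ m) when zeros are counted as failures.
Zero handling in a sign test against a point null is genuinely ambiguous;
the discard-zeros rule is the classic convention and the default, the
zeros-as-failures variant is selectable, and the backbone metadata always
records which was used.  Edges survive at p strictly below α/4005
(Bonferroni over all pairs).  At n = 37 reference subjects the minimal
surviving counts are m = 17 (discard-zeros) and m = 32
(zeros-as-failures).  The reference group defaults to the good readers
(configurable, including "all").

**Sparsity convention.** Reported sparsity is E/N² (retained edges over
the squared region count) — the convention under which 1816 edges on 90
nodes give 22.42%.  Because different reports divide by C(N,2) or
N(N−1), the two per-pair densities are also stored
(`BackboneNetwork.alt_densities`) so any convention can be recovered.

**Nodal degree.** A region's FA-weighted degree for a subject is the sum
of the subject's FA over backbone edges incident to the region.  Backbone
edges absent in a subject (count 0, hence FA 0) contribute zero; nothing
is imputed.  An isolated backbone region scores 0 for everyone.

**Behavioral composites.** Each task is z-scored over the whole sample
with the sample SD (n − 1); PA averages the three accuracy-task z-scores
and RAN averages the three *negated* time z-scores, so positive always
means better than average.  Reader groups come from the reading-history
ratio: strictly above 0.36 is "poor".

**Screening.** For each region, the partial Pearson correlation between
nodal degree and a behavioral measure controls sex, age, and nonverbal
IQ by residualizing both variables on the covariates (with intercept);
p comes from t = r√df/√(1−r²) with df = n − 2 − k, two-tailed.  BH-FDR
is applied across the 90 regions within one behavioral measure (the
family that reproduces published adjusted values; joint correction
across measures would be a caller-side choice).  The Fisher r-to-z
group comparison uses variance 1/(n − 3 − k) per group because the
compared coefficients are partial correlations; k = 0 recovers the
plain version.

**Hierarchical regression.** Blocks enter cumulatively; each step
reports R², ΔR², and adjusted R².  Coefficients, standardized β
(= B·sd(x)/sd(y), the SPSS convention, so binary predictors need no
separate coding decision), and VIF/tolerance come from the final model;
each predictor's entry step is recorded.  A published step-1 coefficient
(e.g. the sex→PA β of a covariate-only model) is reproduced by fitting
that block alone.

**Mediation.** Both regressions (M ~ X + C, Y ~ X + M + C) are ordinary
least squares on, by default, standardized X, M, Y and continuous
covariates (binary covariates stay 0/1), so paths are standardized
coefficients and c = c′ + a·b holds exactly.  Significance of a·b uses a
nonparametric bootstrap resampling whole subject rows (1000 draws), with
the bias-corrected percentile interval: z₀ = Φ⁻¹ of the fraction of
bootstrap estimates below the point estimate (ties weighted ½ so z₀ is
determinate), bounds at percentiles Φ(2z₀ ± z_{(1+level)/2}).  If every
draw falls on one side, z₀ is clamped to ±Φ⁻¹(1 − 1/n_boot) and the
result flagged degenerate.  The direct-effect CI is the plain percentile
interval of c′ from the same draws.  The verdict is "full mediation" iff
the indirect CI excludes 0 while the direct CI covers it, "partial" if
both exclude 0, otherwise "no mediation".

## The synthetic cohort generator

The generator exists because cohorts of this kind are not publicly
deposited; it emulates the *statistical* structure of such a study so the
pipeline is testable, not the physics of diffusion imaging.

Generative model, per cohort (defaults in parentheses):

- A symmetric true-edge mask drawn at the target backbone density (0.22
  of the 4005 pairs), from a sub-seed so tests can recover the ground
  truth (`true_edge_mask`).
- Per subject, each edge present with probability 0.95 (true edges) or
  0.05 (others); present edges get count ~ 1 + Poisson(50) and
  FA = 0.45 + λ·PA_latent·[edge touches the hub] + N(0, 0.10), truncated
  to [0.05, 0.95].  Truncation keeps FA physically plausible; at the
  default effect sizes it shifts the planted correlations only at the
  third decimal.
- The latent phonological trait is standard normal plus a sex shift
  sized so the *standardized* sex→trait coefficient is 0.300 (the raw
  shift is back-computed from the sex split, P(female) = 0.6).
- Observed task scores are affine maps of the trait plus task noise
  (relative SD 0.3), scaled to realistic undergraduate score
  distributions and clipped to the instrument ranges (0–16 tasks, 0–150
  reading).  Clipping matters: the score ceilings attenuate the
  trait–composite correlation, which is why the calibrator simulates the
  observed composite rather than the latent trait.
- Character reading is b·PA_latent + c′·(standardized hub degree) +
  noise with b = 0.604 and c′ = 0, so the planted latent-scale indirect
  effect is 0.56 × 0.604 ≈ 0.338 with no direct path.  Naming times are
  pure noise (no planted RAN association), and age/IQ are narrow normals.
- Reading-history ratios are drawn in bands just below (good) and above
  (poor) the 0.36 threshold, so group labels are *derived* by the
  classifier, never stored.

**Hub calibration.** The FA loading λ that realizes a target hub–trait
partial correlation is found by bisection against a reduced large-n
simulation (n = 50,000 subjects, only the ~20 hub-incident true edges
realized, fixed seed so the objective is smooth).  The reduced model
reproduces every term entering the partial correlation — presence noise,
FA noise and truncation, task noise and score clipping, the sex/age/IQ
partialling.  Unattainable targets (the correlation ceiling set by FA
truncation and composite noise) raise a calibration error.  At the
default design, λ ≈ 0.025 yields a mean recovered partial r of
0.556 ± 0.005 over 400 cohorts of n = 65 — consistent with the 0.56
target once the O(1/n) small-sample bias of r is accounted for.

**What the generator does not emulate.** Spatial structure (edges are
exchangeable given the mask), count–FA dependence beyond co-presence,
scanner/site effects, score discreteness (task scores are continuous
within range), and any group difference in white matter (left at zero:
the emulated design found none surviving FDR).  Passing tests therefore
demonstrate the statistics are implemented correctly and are well
calibrated under this model — not that the pipeline is robust to
real-world artifacts.

## Numerical and design choices

- Strict inequality at the Bonferroni threshold; n_pairs always
  C(n_regions, 2).
- Partial correlations are clipped to [−1, 1] before the t transform;
  |r| = 1 reports p = 0.
- Region-wise screening and ANCOVA are vectorized (one residualization,
  all regions at once); the bootstrap refits both mediation models for
  all draws via batched normal-equation solves, with a pseudoinverse
  fallback for singular resamples.
- BH adjustment: step-up adj_(i) = min_{j≥i}(p_(j)·m/j) capped at 1.
  Note the adjusted values are *not* a fixed point of re-adjustment (the
  m/rank multipliers would apply twice); the meaningful invariants —
  dominance over raw p, monotonicity in the sorted order, and exact
  agreement of thresholded decisions with the classic step-up rule — are
  the ones tested.
- Matrices are written at full float precision so a cohort write/read
  round-trips exactly; result tables print at 6 significant digits.
- Readers validate squareness, NaNs, symmetry (tolerance 1e-8), FA range,
  and count/FA support agreement, naming the subject and cell on failure.

## Problem sizes in the test and acceptance suites

Stochastic checks run at the emulated design size (n = 65, 90 regions):
100 planted replicate cohorts for detection/recovery rates, 60 null
cohorts for FDR calibration, 200 simulated datasets for bootstrap
coverage of a known indirect effect, and 1000 bootstrap draws per
mediation.  The hub-detection rate is compared against the Fisher-z power
of the screening test at the planted effect (≈ 0.92 at r = 0.56, n = 65,
k = 3, per-test level 0.05/90) rather than against an arbitrary round
number, with a binomial consistency band.  The mean recovered indirect
effect over replicate cohorts (~0.30) sits slightly below the latent-scale
product 0.338 because the observed PA composite measures the latent trait
with noise; the coverage check therefore uses datasets where the estimand
is exact.

## Known limitations

- Single-mediator, single-exposure mediation only; no moderated or
  multi-mediator models.
- No permutation or cluster-based inference; no global graph metrics
  (efficiency, small-worldness, modularity).
- The ANCOVA is the linear-model group contrast on each region
  separately; it does not model region covariance.
- The generator plants one hub; multi-hub designs (e.g. two correlated
  hubs splitting a ΔR² block) can be composed by callers but have no
  built-in calibration.
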