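# hubnet

Hub-based white matter network analysis of reading-related skills, for
structural-connectome studies that ask *which brain regions' connectivity
explains individual differences in behavior*.

Diffusion-MRI tractography yields, per subject, a 90×90 region-by-region
connectivity matrix (streamline counts and mean fractional anisotropy, FA,
per connection, over the standard 90-region anatomical parcellation).
`hubnet` implements the full analysis chain that turns a cohort of such
matrices plus a behavioral table into hub-level brain–behavior statistics:

1. **Backbone identification.** For each of the C(90,2) = 4005 region pairs,
   a one-tailed nonparametric sign test of the null "no connection"
   (streamline count = 0) across a reference group; edges with
   p < 0.05/4005 ≈ 1.25×10⁻⁵ (Bonferroni) form a fixed binary backbone.
   Sparsity is reported as E/N² (plus the per-pair alternatives).
2. **FA-weighted nodal degree.** Per subject and region,
   k_i = Σ_j A_ij · FA_ij over backbone edges — the scalar brain measure.
3. **Behavioral composites.** Phonological awareness (PA) = mean of three
   task z-scores; rapid naming (RAN) = mean of three negated time z-scores;
   good/poor reader classification at the 0.36 reading-history threshold.
4. **Group statistics.** χ², pooled/Welch t (from raw data or from printed
   group moments), and region-wise ANCOVA with BH-FDR.
5. **Hub screening.** Covariate-adjusted partial correlations (sex, age,
   nonverbal IQ partialled out; df = n − 2 − k) between nodal degree and
   each behavioral measure, BH-FDR over the 90 regions; Fisher r-to-z
   comparison of hub correlations between groups.
6. **Hierarchical regression.** PA ~ covariates, then + hub degrees; ΔR²
   per step, standardized β, VIF/tolerance collinearity diagnostics.
7. **Mediation.** hub degree → PA → character reading with covariates:
   M = i₁ + aX, Y = i₂ + c′X + bM; indirect effect a·b with a
   bias-corrected bootstrap CI (1000 subject-resamples), and the
   full/partial/no-mediation verdict from the indirect and direct CIs.

Because cohorts of this kind are rarely shareable, the package ships a
**synthetic cohort generator** (`hubnet.simulate`) that plants this exact
structure — a consistent backbone, one hub whose degree tracks a latent
phonological trait at a calibrated partial correlation (default 0.56), a
standardized sex→PA effect of 0.300, and full mediation of the
degree→reading association — so every stage is testable end to end, and
real data can be dropped into the same on-disk layout without code
changes.

## Worked example

```python
from hubnet import (CohortConfig, composite_frame, generate_cohort,
                    identify_backbone, mediate, mediation_report,
                    nodal_strength_table, screen_hubs)

connectomes, records = generate_cohort(CohortConfig(seed=1, hub_loading=0.025))
comp = composite_frame(records)
reference = [c for c, g in zip(connectomes, comp.group) if g == "good"]
strengths = nodal_strength_table(connectomes, identify_backbone(reference))
covs = comp[["sex", "age", "raven_iq"]].to_numpy(float)

hubs = [r for r in screen_hubs(strengths, comp.pa_z.to_numpy(), covs)
        if r.p_adjusted < 0.05]
```

prints (via `examples/04_hub_screening.py`):

```
1 of 90 regions survive BH-FDR at q < 0.05 for PA:
  MTG.L: partial r = 0.598 (df = 60), p = 2.82e-07, FDR-adjusted p = 2.54e-05
```

i.e. the screening recovers exactly the planted hub (left middle temporal
gyrus) at a partial correlation near the planted 0.56.  Mediation on that
hub (`examples/05_regression_and_mediation.py`):

```
  a  (MTG.L -> M)        =  0.5875
  b  (M -> Y | MTG.L)    =  0.5750
  c' (direct effect)      =  0.0604  95% CI [-0.2063, 0.3067] ns
  a*b (indirect effect)   =  0.3379  95% bias-corrected CI [0.1885, 0.5476] *
  verdict: full mediation
```

The indirect effect is significant while the direct path is not: PA fully
mediates the association between the hub's connectivity and reading, as
planted.  The `examples/` directory holds one short script per capability
(simulation, backbone/degree, group statistics, screening, mediation).

A thin CLI wraps the same stages:

```bash
hubnet simulate --out cohort/ --seed 1
hubnet run --manifest cohort/manifest.tsv --behavior cohort/behavior.tsv \
           --out results/ --seed 1
```

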