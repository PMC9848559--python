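# isoweb

Empirical food-web construction from gut contents and bulk stable
isotopes, for freshwater community ecologists. Given per-taxon δ13C/δ15N
tissue profiles and per-gut volumetric diet compositions, the package
estimates the proportional contribution of every candidate resource to
every consumer's diet, assembles the results into a prey × predator
predation matrix, and summarises the web with standard network indices.
A synthetic-community generator with known ground truth makes every
stage testable without field data.

## Method

The pipeline chains five stages:

1. **Gut-content analysis.** For each fish species, every diet item *i*
   gets a frequency of occurrence FOᵢ (fraction of guts containing it)
   and a mean volumetric contribution VOᵢ; the feeding index

       FIᵢ = FOᵢ·VOᵢ / Σⱼ FOⱼ·VOⱼ

   ranks items, and the categories with FIᵢ > 0 restrict the candidate
   source pool for that consumer's mixing model (species with fewer than
   four full guts fall back to a literature-based pool).

2. **Isotope preparation.** Whole-body samples with C:N > 3.5 are
   lipid-normalised (δ13C′ = δ13C − 3.32 + 0.99·C:N); trophic
   enrichment factors are attached per source (generic 0.4 ± 1.3‰ for
   δ13C, taxon-group values for δ15N); isotopically indistinct taxa are
   pooled to a higher taxonomic level when neither isotope separates
   them (Welch t-test / ANOVA, α = 0.05); a missing basal producer can
   be imputed from zooplankton signatures minus one trophic step.

3. **Bayesian mixing model.** A consumer's isotope value on isotope *k*
   is modelled as Normal with

       μₖ(p) = Σᵢ pᵢ qᵢₖ (μᵢₖ + Δᵢₖ) / Σᵢ pᵢ qᵢₖ
       σₖ²(p) = Σᵢ pᵢ² qᵢₖ² (ωᵢₖ² + τᵢₖ²) / (Σᵢ pᵢ qᵢₖ)² + σₖ²

   where p is the diet simplex, q elemental concentrations, μ/ω source
   mean/SD and Δ/τ TEF mean/SD. Priors are Dirichlet(1,…,1) on p and
   half-Normal(0, 10‰) on each residual SD σₖ. Inference is adaptive
   random-walk Metropolis on the additive log-ratio transform
   (30,000 iterations, 10,000 burn-in, 4 chains by default), with
   Gelman–Rubin R̂ convergence checks and a brute-force simplex-grid
   integration oracle for validation.

4. **Feasibility and pruning.** Consumers must sit inside the
   Monte-Carlo simulated mixing polygon (convex hull of TEF-adjusted
   source signatures). Sources whose posterior-median contribution falls
   below 0.25/N are removed one at a time, lowest first, refitting after
   each removal and never removing a source whose loss pushes the
   consumer outside the polygon. Renormalised posterior medians become
   the consumer's predation-matrix column.

5. **Network indices.** From the matrix: S, L, link density L/S,
   directed connectance L/S², basal/intermediate/top fractions, Pianka's
   pairwise niche overlap and Levins' niche breadth B = 1/Σp², plus a
   directed-graph plot with node size scaled by degree and edge width by
   interaction strength.

## Worked example

Simulate a community with known diets, run the full pipeline, and
compare the recovered matrix with the truth:

```
isoweb simulate --seed 11 --out fixture/
isoweb run --input fixture/ --output webs/ --seed 5
```

which prints the indices of the assembled web:

```
 S   L  link_density  connectance  frac_basal  frac_intermediate  frac_top  mean_pianka  mean_niche_breadth
 8  14          1.75      0.21875       0.375                0.0     0.625     0.824744            2.436025
```

Eight taxa (3 basal sources + 5 fish) carry 14 trophic links — 1.75
links per taxon, 21.9 % of all possible directed links realised; the
three sources are the basal fraction, every fish is a top predator, the
fish diets overlap strongly (mean Pianka 0.82) and an average diet is
spread over ≈ 2.4 effective resources. In Python,

```python
from isoweb import diet_recovery_error, run_pipeline, RunConfig
result = run_pipeline(RunConfig(input_dir="fixture", output_dir="webs", seed=5))
print(diet_recovery_error(result.matrix, "fixture/truth.json"))
# 0.0311  — mean absolute error of recovered diet proportions
```

`webs/` then contains the predation matrix CSV, per-consumer posterior
summaries, web indices, the pruning audit inside `manifest.json`, and a
food-web plot.

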