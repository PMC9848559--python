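# Methods

This note documents the models, numerical choices and limitations of
the package; the README gives the usage-level overview.

## The mixing model

Each consumer is modelled independently. With N candidate sources and
K = 2 isotopes (δ13C, δ15N), observation j on isotope k is

    y_jk ~ Normal( μ_k(p), s_k²(p) )
    μ_k(p)  = Σ_i p_i q_ik (μ_ik + Δ_ik) / Σ_i p_i q_ik
    s_k²(p) = Σ_i p_i² q_ik² (ω_ik² + τ_ik²) / (Σ_i p_i q_ik)² + σ_k²

with diet proportions p on the simplex, elemental concentrations q_ik
(all 1.0 in the concentration-independent default; the source-file
dialect carries conc columns, so the dependent form is one flag away),
source signatures μ_ik ± ω_ik, trophic enrichment factors Δ_ik ± τ_ik
and residual SDs σ_k. This is the process-error formulation: source and
TEF spread propagate into the likelihood variance rather than being
latent per-observation draws. Assumptions worth keeping in mind: tissue
equilibrium with the diet, additive TEFs, Normal within-source spread,
and exchangeable consumer observations.

Priors are uninformative — Dirichlet(1,…,1) on p, independent
half-Normal(0, s0 = 10‰) on each σ_k. Gut-content information enters
only by restricting which sources appear in the model, never as an
informative prior; diet proportions therefore remain comparable across
consumers with and without gut data.

### Sampler

Adaptive random-walk Metropolis on the unconstrained parametrisation
(additive log-ratio transform of p with the last source as reference,
log σ_k), including both log-Jacobians. The full-vector Gaussian
proposal scale starts at 0.5 and is rescaled every 100 burn-in
iterations by exp(r − 0.3) (r the batch acceptance rate, clipped to
±0.5), then frozen; the 0.2–0.5 post-adaptation acceptance band is
asserted in the tests. Defaults are 30,000 iterations, 10,000 burn-in,
4 chains, thinning 10, giving 2,000 retained draws per chain. Each chain
draws from `default_rng([seed, chain])`, so runs are reproducible from
the seed alone. Gibbs updates were deliberately not used: at the N ≤ ~15
sources seen in practice, a well-adapted RWM mixes adequately and the
whole sampler stays a page of testable code.

Inside the sampler the likelihood is evaluated from the sufficient
statistics (n, Σy, Σy²) per isotope, making each evaluation O(N); the
public `log_posterior` keeps the plain per-observation form and the test
suite asserts both agree to 1e-10.

### Diagnostics and summaries

Gelman–Rubin R̂ uses the classic between/within form
√(((n−1)/n·W + B/n)/W); parameters above 1.1 are flagged. Posterior
summaries are pooled-chain medians with central 95% intervals; the
medians renormalised to sum to one are what the predation matrix stores
(raw medians are reported alongside, since renormalisation is a
convention, not an inference).

`grid_posterior_oracle` integrates the exact unnormalised posterior on
a simplex lattice (and a σ grid of 40 points on [0.02, 6]‰) for N ≤ 3;
it exists purely as an independent check on the sampler and agrees with
MCMC posterior means to well under 0.02 on toy problems.

## Feasibility and pruning

The mixing polygon test follows the simulated-polygon approach: each of
the (default 1000) Monte-Carlo iterates resamples every source's
TEF-adjusted signature from Normal(μ+Δ, √(ω²+τ²)), forms the convex
hull, and counts each consumer observation as inside (boundary
inclusive). A consumer passes when the mean per-observation inside
probability reaches the 5% acceptance level; a per-mean-point mode is
available, since published applications are ambiguous about which was
used. Degenerate hulls (two sources, collinear draws) degrade to a
distance-to-segment test with a 1.0‰ tolerance — a point can never lie
exactly on a random segment, so a band replaces containment.

Pruning: fit, compute the threshold 0.25/N from the *current* N, and if
any source's posterior median falls below it remove the single lowest
contributor — unless removing it would fail the polygon test, in which
case it is restored, marked protected and the next-lowest tried — then
refit and repeat; the loop refuses to go below two sources. Removal is
strictly one-at-a-time with refitting because the threshold depends on
N and because the polygon constraint must be checkable per step. The
audit trail records medians, thresholds and every action, and replaying
it against the initial pool reproduces the final fit exactly (the
sampler is seed-deterministic).

A caveat the test design surfaced: with two isotopes, any N = 4 problem
has a one-dimensional likelihood ridge (mass can shift between sources
without moving the mixture mean), so a truly absent source is only
driven below the threshold when the geometry bounds its feasible
contribution — in the packaged pruning scenario the planted source sits
far up the δ15N axis, which is exactly the situation the threshold rule
is meant to catch. Pruning outcomes on weakly identified pools should
be read as parsimony decisions, not evidence of absence.

## Network indices

S counts the union of row and column taxa; L counts entries above the
link threshold (default 0: any positive contribution). Connectance is
directed, L/S², the dominant convention for predation matrices with
possible cannibalism; L/[S(S−1)] is available. Basal = no prey,
top = prey but no predators, intermediate = both; isolated nodes
(possible after pruning) count as basal and are listed in the report.
Pianka's overlap is computed over the union prey set (absent = 0) and
averaged over unordered consumer pairs; all-zero diet columns are
excluded with a warning. Niche breadth is Levins' B = 1/Σp² with the
standardised B_A = (B−1)/(N_j−1), undefined for single-prey consumers —
the natural measures when only diet proportions are available.

## Synthetic communities

The generator emulates the data the pipeline consumes: K isotopically
distinct sources, consumers drawn from the forward model above with
known Dirichlet diets, and per-gut compositions noisy around the true
diet. Defaults (chosen once as field-realistic): within-taxon SD 0.7‰,
residual SD 0.5‰, TEFs 0.4 ± 1.3‰ (δ13C) and 3.4 ± 1.0‰ (δ15N, a
fish-consumer value; the prep module's table also carries 2.5 ± 1.0 for
invertebrates and 2.2 ± 1.0 for algal primary consumers), source means
on δ13C in [−32, −18]‰ and δ15N in [0, 12]‰, 20 samples per taxon, 20
guts per consumer, Dirichlet concentration 1.

Source δ13C means are drawn stratified — one source per equal-width bin
of the range — rather than fully independently: the empirical procedure
pools isotopically indistinct taxa before modelling, so distinct
sources are the relevant regime, and stratification guarantees it
without hand-picking seeds. δ15N means are independent uniform.

Guts drop each diet item independently with probability 0.3 (at least
one item always survives), renormalise, and draw the composition from a
Dirichlet with mean equal to the retained diet and concentration
`diet_concentration` per retained item — so frequency of occurrence is
genuinely below one and FO ≠ VO, which the feeding index needs. The
same concentration parameter governs across-consumer diet spread and
within-consumer gut noise; in the infinite limit guts converge to the
true diet.

Randomness: one seeded stream per stage (`default_rng([seed, stage])`,
stage 0 community / 1 isotopes / 2 guts), draws consumed in documented
order, so fixtures are byte-identical across runs and an independent
re-implementation of the recipe reproduces them (asserted in tests).

What the generator does *not* emulate: correlated source signatures,
temporal or spatial variation, tissue-turnover lags, size-structured
diets, gut-content identification error, and non-Normal isotope spread.
Passing recovery tests therefore show the machinery is correct under
its own assumptions, not that field webs are recovered at this
accuracy.

## File dialects and pipeline

Consumer files (`<taxon>.csv`: D13C, D15N), source files (the 11-column
Sources/Mean/SD/TEF/conc dialect, concentrations optional with default
1.0), a species-level diet table (reservoir metadata plus 12 diet
categories of mean volumetric proportions, rows flagged when sums leave
[0.98, 1.02] or replicates fall below 4), and the predation matrix
(prey rows, predator columns). The species-level diet table cannot
yield FO (it stores means only), so the generator also writes a
per-gut long-format file that the GCA stage consumes; Excel workbooks
are supported through a one-way conversion command, CSV being the
canonical dialect. Readers are strict about headers and fail with the
offending column/row; writer/reader pairs round-trip at 1e-9.

`run_pipeline` derives one seed per consumer from the run seed via
`SeedSequence([seed, index])` over the sorted consumer list, runs
GCA-restriction → polygon → fit/prune per consumer, assembles the
matrix, computes indices, draws the plot and writes a manifest (config,
per-consumer seeds, R̂, polygon probabilities, pruning audit) from
which the run can be replayed bit-for-bit.

The diet-category → prey-taxon mapping needed to turn feeding indices
into source pools is inherently a modelling input; a documented default
covering the 12 categories ships with the package (identity mapping on
synthetic communities), and results are sensitive to it.

## Problem sizes in the shipped checks

The test suite and acceptance script keep problems small enough to
re-run routinely: the reference recovery problem (3 sources, truth
p = (0.7, 0.2, 0.1), 30 observations) runs at the full
30,000/10,000/4-chain budget; interval-coverage sweeps use 50 problems
at 4,000 iterations / 2 chains; the end-to-end community is 3 sources ×
5 consumers with 20 samples and 20 guts each, run at 6,000/2,000/4
chains. Observed behaviour at these sizes: recovery medians within
~0.03 of truth, R̂ ≤ 1.05, MCMC-vs-oracle agreement within 0.001, and
end-to-end diet MAE ≈ 0.03.

## Known limitations

- Two isotopes only; N > 3 sources are increasingly prior-dominated
  (the ridge problem above) — as in any mixing-model analysis.
- No hierarchical pooling across consumers, no covariates, no
  informative priors.
- The pooling decision rule ("pool when neither isotope differs
  significantly", config-switchable to the one-isotope variant) treats
  non-significance as equivalence; a proper equivalence test would need
  effect-size bounds the source procedure does not define.
- The unknown-producer node inherits zooplankton SDs unchanged; one
  trophic step of TEF is subtracted from the means (the alternative —
  copying signatures verbatim — is a constructor argument away).
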