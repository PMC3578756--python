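# Methods

## Model

### Forward simulation

`ralesim.simcore` implements a discrete-generation Wright–Fisher
population of `N` diploids (2N haplotypes) with selection, mutation and
recombination each generation:

1. **Fitness.** Each diploid's liability is computed from the current
   genotypes (below) plus a fresh environmental deviate; fitness is
   Gaussian stabilizing selection around the optimum.
2. **Reproduction.** Each of the N offspring draws two parents
   independently with probability proportional to fitness (with
   replacement; selfing permitted). Each parent transmits one gamete.
3. **Gametes.** A gamete starts from one uniformly chosen parental strand,
   switches strands at Poisson(r) crossover breakpoints placed uniformly
   on the unit interval, and then receives Poisson(μ + μ_d) new mutations
   at fresh uniform positions (infinitely-many sites — positions are
   float64 draws, so collisions are astronomically unlikely and are
   asserted against rather than redrawn). Each new mutation is causative
   with probability μ_d/(μ + μ_d); causative effects are
   Exponential(λ), neutral effects are exactly 0.

Mutations carry an explicit class flag in addition to their effect, so
causative-*class* sites remain identifiable in control runs with λ = 0
(where every effect is zero).

All rates are also expressible through the scaled parameters
θ = 4Nμ, θ_d = 4Nμ_d and ρ = 4Nr (`SimParams.from_scaled`), so reduced-N
runs preserve the coalescent-scale mutational input of the full-size model
(N = 20,000, μ = 0.00125, μ_d = 0.1μ, r = 0.00125, i.e. θ = ρ = 100 and
θ_d = 10). Equilibrium runs last 8N generations from a mutation-free
population; for θ-scale quantities this leaves a ~2% equilibration deficit
(E[π] = θ(1 − e^{−4}) ≈ 0.98 θ), well inside replicate noise.

**Fixation handling.** Neutral mutations reaching 2N copies are dropped
(they can never affect a phenotype or a test). Fixed causative mutations
are moved to a *fixed burden* — a constant added to every haplotype effect
sum — and logged; because a constant burden displaces every genotypic
value, the stabilizing-selection optimum is recentered onto the burden by
default (`recenter_optimum=False` disables this). The two bookkeeping
operations are exactly equivalent to keeping the fixed column in the
matrix, so the ≤16-generation lag in recognising a fixation (below) does
not perturb the dynamics beyond the rare optimum update itself.

**Implementation.** Haplotypes are stored copy-on-write: the population is
a vector of references into a pool of haplotype rows, and only gametes
that recombine or mutate allocate new rows, so per-generation work scales
with the number of genetic events rather than with 2N × L. Extinct rows
and extinct/fixed columns are garbage-collected every 16 generations;
snapshots returned to callers are always fully compacted, position-sorted,
and carry verified allele counts. A full-neutral desk replicate
(N = 1000, θ = 100, 8000 generations) runs in under 10 s on one CPU core.

### Phenotype and gene action

`ralesim.phenotype` holds the genotype→phenotype→fitness map described in
the README. `alternative_gene_action` supplies the standard comparison
models computed from the same haplotype sums — additive (E1 + E2),
dominant (max) and recessive (min); these definitions are interpretive
(the comparisons are qualitative), and the AM–GM inequality guarantees
recessive ≤ geometric-mean ≤ additive with equality only at E1 = E2.
Broad-sense heritability is the realized Var(G)/Var(P) of a population
(sample variances, ddof = 1), not an allelic variance decomposition.

## Panels and marker filters

Cases are sampled uniformly without replacement from individuals at or
above the 85th percentile of realized liability; controls from individuals
within 1 population SD of the mean *and below the case threshold* — for
pure-noise (λ = 0) populations the 85th percentile (≈1.036 SD for a
Gaussian) lies so close to the window edge that sampling noise would
otherwise let the strata overlap. Panels keep phased haplotypes (the
simulator knows true phase), derived-allele dosages, and per-marker
metadata including the panel MAF (minor allele defined in the panel, used
by the 5% GWAS filter) and the control MAF (minor allele defined in the
general population, used by chip ascertainment).

A GWAS design keeps panel-MAF ≥ 5% markers; resequencing keeps all.
"Imperfect chips" are drawn by including each candidate marker
(control-population MAF ≥ 0.05) with probability equal to its expected
control heterozygosity 2q(1−q), which flattens the ascertained MAF
distribution on [0.05, 0.5].

## Association tests

**Logistic scan.** Additive logistic regression of status on dosage,
likelihood-ratio tested against the intercept-only model (χ²₁). The 2×3
status-by-dosage table is a sufficient statistic, so the scan fits all
markers simultaneously by a vectorized Newton iteration on the aggregated
tables (steps clipped to ±5, ≤60 iterations): quasi-separated markers
converge in deviance even though the slope diverges. The implementation
agrees with `statsmodels.Logit` to ~10 significant digits on polymorphic
markers (unit-tested); a Wald alternative is deliberately not offered
because the LRT is the robust choice at rare markers. Significance
threshold 10⁻⁸.

**Fisher exact allele test.** Two-sided p from the 2×2 table of
allele × status counts. Because the margins are fixed under label
permutation, the package precomputes, per marker, the two-sided p-value
for every possible derived-in-cases count (exact hypergeometric
enumeration with the conventional (1 + 10⁻⁷) relative tolerance on
pmf ties); permutations then reduce to table lookups. Verified against
`scipy.stats.fisher_exact` and against full enumeration in exact rational
arithmetic.

**ESM.** Given Fisher p-values for the L *unique* markers (identical
dosage columns collapsed to one representative, panel minor-allele count
≥ 4), with Y₁ ≥ Y₂ ≥ … the sorted −log₁₀ p,

    Z_M = Σ_{i=1..min(M,L)} [ Y_i − (−log₁₀ ê_i) ],   ê_i = i/(L+1).

The null expectation ê_i is the mean of the i-th smallest of L uniform
order statistics; this is the one formula in the statistic reconstructed
from a verbal description, and `esm_statistic` accepts the p-vector and M
directly so alternative expectations can be swapped in. M defaults to 50
(25 is appropriate for non-recombining GWAS panels, which rarely have more
unique markers). The statistic is monotone increasing as any included
p-value shrinks and invariant to marker order.

**Madsen–Browning rank-sum ("general genetic" scoring).** Per-marker
weight w_j = sqrt(n q_j(1−q_j)) with q_j = (minor copies in controls + 1)/
(2 n_controls + 2); individual score Σ_j dosage_ij/w_j (minor-allele
dosage); statistic = sum of case midranks. The weight formula follows the
original general-genetic formulation (an external-source reconstruction —
the weights are recomputed from the permuted control set in every
permutation). Redundant markers are *not* collapsed.

**Li–Leal multiple-marker test.** Two-sample Hotelling T² on genotype
scores (−1/0/+1 for minor-allele count 0/1/2) over the K rarest panel
variants by MAF (ties broken by position order; K = 50 at desk scale, up
to 250 at full scale), pooled covariance inverted by a symmetric
pseudoinverse (`scipy.linalg.pinvh`, default spectral cutoff
max(dim)·eps·σ_max). Numerically degenerate permutations yield NaN and the
replicate is recorded without a p-value, as can happen with many rare
markers.

**Permutation significance.** Case/control labels are permuted 1000
times; every label-dependent ingredient (Fisher p-values, rank-sum
weights, pooled covariances) is recomputed per permutation. The observed
statistic is standardized to z = (obs − mean)/sd of the permutation
distribution and converted to a two-tailed Gaussian p (the two-tailed
convention is kept even though a large negative z is not evidence for
association; a one-tailed option exists). Region threshold 10⁻⁶. Under
λ = 0 the z-scores are unit-Gaussian (KS-tested in the acceptance suite).

## Scaling conventions

Two distinct quantities demand two distinct reduced-N conventions:

- **Coalescent-scale quantities** (diversity, SFS, marker counts, panel
  LD): preserving θ, θ_d, ρ suffices. The desk preset uses N = 1000 with
  θ = ρ = 100, θ_d = 10, panels of 150 cases / 150 controls (the upper
  15% of a population of 1000 is exactly 150 individuals), σ_e and σ_s
  unchanged. Desk power numbers are for *ordering and calibration*
  properties of the tests, not the full-scale percentages: with 20× fewer
  samples, absolute power is strongly compressed.
- **Equilibrium genetic variance** (the heritability plateau): the
  variance balances mutational input against selection *and* drift, so
  preserving θ_d alone leaves reduced-N runs drift-dominated (variance far
  above the full-scale plateau), while preserving the per-gamete μ_d alone
  leaves them drift-depleted. `h2_scaled_params` therefore applies the
  standard forward-simulation rescaling: θ_d preserved *and* σ_s shrunk by
  sqrt(N/20000), which keeps the population-scaled selection strength
  N·s invariant (selection enters through 1/σ_s²) and hence both the
  drift- and selection-limited variance regimes. The rescaling becomes
  exact as N approaches full scale; at N = 1000 (rescaling factor 20) a
  residual upward bias of order 10% in the plateau is expected from
  strong-selection artifacts, a known cost of aggressive rescaling.

## What the generator does and does not emulate

The simulator reproduces the full joint distribution of causative and
neutral variation in one gene region under constant population size,
uniform recombination and panmixia. It deliberately omits demographic
change, population structure, recombination hotspots, genotyping error,
covariates and multi-locus (background) genetic variation — the
environmental deviate stands in for all trait variance outside the focal
region. Passing tests therefore demonstrate the statistical machinery and
the model's internal predictions, not robustness of the tests to
stratification or to realistic genome-wide architectures.

## Problem sizes used by the tests and the acceptance script

Chosen as single-workstation sizes: neutral-control diversity uses 30
causative-only replicates (N = 1000, θ_d = 10, λ = 0); heritability uses
20 replicates per λ ∈ {0.075, 0.10} of the Ns-preserving parameterization
at N = 1000; null calibration and power ordering use 50 desk replicates
each (full θ = 100 regions with 150/150 panels, 1000 permutations per
region test); null power of the logistic scan uses 50 desk replicates.
Monte-Carlo standard errors are reported or asserted alongside every such
estimate.

## Known limitations

- Desk-scale absolute power is far below full-scale power (sample-size
  compression); only orderings and null calibrations are meaningful at
  desk scale, and even orderings compress toward zero for the weakest
  tests (the rank-sum and Hotelling tests rarely clear α = 10⁻⁶ at
  desk scale at all).
- The Hotelling T² statistic is poorly calibrated when computed on few
  markers: its permutation distribution is strongly right-skewed, so the
  permutation z-scores of null replicates are visibly non-Gaussian at the
  desk setting K = 50 (they approach Gaussian only for K of order 200+,
  which is the full-scale setting). This is a property of the statistic,
  not of the permutation machinery — the vectorized and single-shot
  computations agree to 8 digits.
- The χ²₁ likelihood-ratio p-value of the single-marker scan is mildly
  anti-conservative in the mid-range (p ≈ 0.1) on small panels with many
  rare markers, while remaining conservative near the origin and in the
  extreme tail that the 10⁻⁸ threshold uses; larger panels push per-cell
  counts into the regime where the asymptotic approximation is safe.
- The ESM order-statistic expectation and the Madsen–Browning weights are
  reconstructions (documented above) rather than transcriptions.
- The optimum-recentering policy after causative fixation is a modelling
  choice; fixation of causative alleles is rare at the default parameters,
  and a flag preserves the alternative (fixed optimum at 0).
- Heritability at reduced N carries the rescaling bias discussed above.
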