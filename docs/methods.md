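# Methods

This note documents the statistical models, conventions and default
parameters behind `phylosdm`, the design choices made where the
procedures admit more than one published convention, what the synthetic
generators do and do not emulate, and known limitations.

## Scope and data model

The package analyses a single non-recombining haploid locus (mtDNA COI)
sampled across populations, plus presence-only occurrence records and
climate raster layers. Sequences arrive pre-aligned; ambiguity codes
other than `N` are rejected at parse time so haplotype identity stays
well-defined (Sanger-quality barcode data). The default missing-data
policy is **complete deletion**: any column containing `-` or `N` is
excluded for all analyses, matching the common practice of analysing a
single cleaned region of fixed length. Pairwise deletion is available
behind a flag; under it, per-pair comparisons skip sites missing in
either sequence and haplotype classes are exact string classes on all
columns. Terminal trimming is left to the user (the mask is built from
whatever alignment is supplied).

Populations with fewer than five samples are listed but excluded from
per-population statistics and from pairwise Φ_ST; they always enter
pooled ("TOTAL") statistics and the retained-diversity forecast, because
those are species-level quantities.

## Diversity statistics

* **Haplotype diversity** Hd = n/(n−1)·(1 − Σpᵢ²) with the Nei (1987,
  eq. 8.12) sampling variance.
* **Nucleotide diversity** π = mean over all C(n,2) pairs of the
  per-site difference proportion; SD from the total variance formula
  (Nei 1987, eq. 10.7), which includes the stochastic (evolutionary)
  variance component — the convention used by DnaSP's reported SDs.
* **Allelic richness** by rarefaction, Ar(g) = Σᵢ [1 − C(n−nᵢ,g)/C(n,g)]
  (terms with n−nᵢ < g contribute 1). Both the *raw* convention
  (Ar(g) ∈ [1, Nh]) and the *minus-one* convention (subtract 1, as in
  CONTRIB) are exposed; the rarefaction size g defaults to the smallest
  included population size. Published tables do not always state (g,
  convention), so both are explicit parameters here.

## Neutrality tests

Tajima's D uses the standard constants a₁…e₂ and is undefined (NaN) at
S = 0. Fu's Fs = ln(S′/(1−S′)) with S′ = Pr(K ≥ k_obs | θ, n) under the
Ewens sampling formula; the signless Stirling numbers |s(n,k)| are
computed by their recursion entirely in log-space with log-sum-exp,
because they overflow fixed-width integers long before the pooled sample
sizes seen in practice (n ≈ 270). θ for Fs is the mean pairwise
difference (θ̂_π), matching the statistic's definition.

P-values come from simulating the null: standard constant-size Kingman
coalescent genealogies without recombination, with
Poisson(θ/2 × branch length) infinite-sites mutations. The D null is
simulated at θ̂_W = S/a₁ and the Fs null at θ̂_π (each statistic is
compared against samples calibrated to its own estimator).
p = Pr(stat_sim ≤ stat_obs); for Fs the conventional significance level
is 0.02 (corresponding to a nominal 5% test). Default 1000 simulations.

Calibration is verified in the test-suite: across 200 constant-size
replicates (n = 20, θ = 5) the D rejection rate at α = 0.05 falls in
the exact binomial acceptance region, and across 200 sudden-expansion
replicates (100-fold growth, expansion age 0.125 coalescent units,
present-day θ = 10 — a recent, strong expansion of the kind that
produces star-like genealogies) the median Fs is negative and over 60%
of replicates are significant at 0.02.

## Mismatch distribution

Observed: the histogram of absolute pairwise differences. Expected
under the sudden-expansion model (population at mutation-scaled size θ₀
grows instantly to θ₁ at mutation time τ before present):

F_i(τ,θ₀,θ₁) = F̂_i(θ₁)·P(i+1, τ(1+θ₁)/θ₁)
  + e^(−τ(1+θ₁)/θ₁) Σ_{j≤i} τ^{i−j}/(i−j)! · F̂_j(θ₀),

where F̂_j(θ) = θʲ/(1+θ)^{j+1} is the equilibrium law and P the
regularised lower incomplete gamma function; probability mass beyond the
observed maximum difference is folded into the last class so expected
frequencies always sum to 1. Parameters are fitted by minimising
SSD = Σ (obs_freq − exp_freq)² with a coarse grid over (τ, θ₀, θ₁−θ₀)
followed by Nelder–Mead refinement; the refined point is only accepted
if it improves on the best grid point, so the reported optimum is never
worse than any grid value.

**Raggedness** uses the convention r = Σ_{i=1}^{d+1}(xᵢ−xᵢ₋₁)² with a
zero-frequency class appended after the last observed class; other
published conventions omit that trailing term. The convention is fixed
and documented here because it changes r in the third decimal.

**Bootstrap p-values**: C(n,2) pairwise differences are redrawn i.i.d.
(multinomially) from the fitted law and the model is refit to each
replicate; p = fraction of replicates with SSD (or r) at least the
observed value. This treats pairs as independent, which they are not
(they share a genealogy), so these p-values are approximate and
somewhat anticonservative relative to full coalescent re-simulation;
they are reported with the seed and replicate count.

## AMOVA and Φ-statistics

Distances default to raw pairwise difference counts — appropriate for
the shallow intraspecific divergence this pipeline targets — with an
optional Jukes–Cantor + gamma correction. Variance components follow
Excoffier, Smouse & Quattro (1992) from nested sums of squared
distances with the unequal-sample-size coefficients; negative
components and negative Φ estimates are retained, not clamped.
Permutation schemes per level: individuals among all populations
(Φ_ST), individuals among populations within groups (Φ_SC), whole
populations among groups (Φ_CT); default 1000 permutations, seeded.

A structural caveat verified in testing: with G = 2 groups of two
populations each, the whole-population permutation null for Φ_CT has
only six distinct assignments, so its attainable p cannot go below
≈ 1/3 regardless of effect size. At least ~8 populations are needed for
that level to resolve p < 0.05 — a property of the permutation scheme
itself, shared with the standard implementations.

Pairwise Φ_ST is the two-population AMOVA estimator with individuals
permuted between the two populations. Regional grouping schemes
(geographic, climatic and road-network partitions of steppe/desert
populations) ship as presets keyed by population id.

## Haplotype network

Minimum-spanning tree over haplotype Hamming distances, built by
Kruskal with lexicographic tie-breaking on (steps, id_a, id_b) so output
is reproducible. Non-tree edges whose weight equals the maximum edge
weight on the tree path between their endpoints are recorded as
equally-minimal alternatives rather than dropped — for shallow mtDNA
data the MST is rarely unique and the ambiguity is part of the result.
Haplotype ids H1, H2, … are assigned by decreasing global frequency
(ties by first occurrence), so "H1" is the most dominant haplotype.

## Maximum-entropy niche model

`MaxEntSDM` fits the Gibbs distribution over background cells that
maximises the penalised presence log-likelihood

ℓ(λ) = mean_presence λ·f(x) − log Σ_bg e^{λ·f(x)} − RM·Σ_j β_j|λ_j|.

Layers are min-max normalised to [0,1] using the pooled background +
presence rows; features are L (identity), Q (squares), P (pairwise
products), H (forward and reverse hinges at evenly spaced knots) and T
(step functions at the same knots), all scaled to [0,1]. β_j follows
the sample-size-dependent class defaults of MaxEnt (L/Q/P interpolated
from 0.65 at m=0 to 0.05 at m=100; hinge 0.5; threshold 2→1), scaled by
the feature's standard deviation over presences divided by √m, with a
small floor so constant-over-presence features stay penalised. The
convex problem is solved by FISTA (proximal gradient with soft
thresholding and backtracking line search); convergence is declared on
relative objective change ≤ tol (default 1e−7, capped at 1000
iterations) and flagged on the fitted model.

Outputs: raw (e^η normalised to sum to 1 over the training background),
logistic p = 1/(1+e^{−(H+η)}) and cloglog, where H is the entropy of
the fitted raw distribution. The **logistic** transform is the default
because the thresholding rule used downstream is defined on the
logistic scale; cloglog is available by flag. Projection clamps
features to the training range and reports the clamp count.

Defaults: 10,000 background cells sampled uniformly without replacement
(seeded); 20 hinge/threshold knots per layer per direction. At the desk
scale used by the test-suite and the acceptance script (60 × 60 grids,
2,000 background cells) 8 knots are used — on grids this size additional
knots only add redundant columns.

**Model selection**: RM ∈ {0.5…4.0 step 0.5} × FC ∈ {L, LQ, H, LQH,
LQHP, LQHPT} (48 candidates), tenfold cross-validation of presences
against the shared background. Per candidate: mean test AUC (Mann–
Whitney rank form), mean AUC_diff = AUC_train − AUC_test, mean OR10
(fraction of test presences below the fold's 10% training threshold),
and AICc = 2k − 2lnL + 2k(k+1)/(n−k−1) with k the nonzero coefficients
of the full-data model and lnL the presence log-likelihood with raw
output renormalised over the full grid (the ENMTools convention); AICc
is flagged undefined when n − k − 1 ≤ 0. Selection takes the lowest
ΔAICc; exact ties break by lower OR10, then lower AUC_diff, then higher
AUC_test — an operationalisation of weighing the overfitting
diagnostics alongside AICc, since published selections do not always
coincide with the literal AICc minimum and the exact tie-break used is
rarely stated. The rule is configurable.

**Threshold**: the 10% training presence value is the ⌈0.1·n⌉-th
smallest training-presence suitability, so at least 90% of training
presences score at or above it; implementations differ subtly at ties,
hence the explicit rule. Binarisation uses suitability ≥ threshold.

## Forecast

Range change = 100·(A_future − A_current)/A_current with cell areas
cosine-latitude weighted. A sampled population persists in a scenario
iff the projected suitability of its containing cell is ≥ the current
model's threshold (the inclusive comparison matches binarisation;
strict inequality is available and differs only on exact ties).
Populations are point-sampled at their cell with no dispersal buffer —
the conservative restricted-dispersal assumption — and a population on
a nodata cell falls back to the nearest valid cell within one cell.
Retained diversity pools all individuals of persisting populations
(including small sites) and recomputes Nh, Hd and π with the same
estimators as the diversity table, so an all-persist scenario
reproduces the pooled values bit-identically. Lost haplotypes are those
whose entire count lies in extirpated populations; the network
annotation flags whether losses are scattered (lost nodes not
predominantly adjacent to other lost nodes) rather than pruning a
clade.

## Synthetic data

The generators emulate the input classes, not any particular dataset:

* **Sequences**: a structured Kingman coalescent with island-model
  migration (per-lineage emigration rate, uniform destination) and
  piecewise-constant population size (sudden expansion by a growth
  factor at a given coalescent time), with finite-sites mutation
  (Poisson θ/2 per unit branch length, uniform site, uniform different
  base). Finite sites — rather than infinite sites — so that S,
  haplotype collapsing and mismatch behaviour feel recurrent mutation
  as real COI data do. The simulator's pair-coalescence times were
  verified against msprime's island model.
* **Rasters**: Gaussian-blurred white-noise fields sharing a common
  component to reach a configurable pairwise correlation (default 0.5;
  0.95 reliably triggers the |r| > 0.8 filter), on a lon/lat grid
  defaulting to 60 × 60 cells of 0.2° over a temperate-arid window.
  Future stacks add per-layer constant deltas plus small smooth noise.
* **Suitability truth**: η = 30z₁ + 24z₂ − 75(z₁−0.5)² − 60(z₂−0.5)² on
  the two leading normalised layers — a coherent climate envelope
  centred at (0.7, 0.7) occupying roughly 8% of each gradient, chosen
  so that a presence sample of a few dozen records carries enough
  signal for a correctly-specified model to discriminate strongly
  (ranking AUC ≈ 0.9), as for a biome-restricted species. Occurrences
  are drawn cell-wise proportional to suitability and jittered within
  the cell.
* A single top-level seed fans out to stage seeds via
  `numpy.random.SeedSequence.spawn`, so stages are independently
  reproducible.
* In fully-synthetic pipeline runs the sampled populations are placed
  at cells spread over the upper suitability range (from near-optimal
  to marginal), because real surveys sample populations at occupied
  sites; without this coupling, synthetic populations would routinely
  sit outside the modelled range and every scenario would extirpate
  everything.

What the generators do **not** emulate: spatial autocorrelation of
sampling effort, observation error in occurrences, selection or
recombination in the sequences, realistic climate downscaling, and any
correlation between a population's genetic makeup and its position on
the suitability surface. Passing tests therefore demonstrate
correctness of the estimators and the pipeline's plumbing under known
truth — not that any real species follows these models.

## Numerical choices

* Ewens/Stirling computations in log-space; normalisation verified to
  1e−10 up to n = 300.
* Raw MaxEnt output normalised over the training background to 1e−8.
* Mismatch SSD optimum never worse than the evaluated grid.
* Degenerate inputs: S = 0 → Tajima's D NaN; k_obs = 1 → Fs +∞
  (flagged); empty persisting set → retained statistics defined as 0;
  all-masked alignments, ragged alignments, off-grid coordinates and
  geometry mismatches raise typed errors distinguishing input from
  computation failures.
* Problem sizes in the test-suite and acceptance script (60 × 60 grids,
  2,000 background cells, 100–1,000 permutations/simulations, 8 knots)
  are the package's desk-scale defaults for fully-synthetic runs;
  field-scale defaults (10,000 background points, 1,000 permutations,
  20 knots) remain the library defaults.

## Known limitations

* Single locus, haploid statistics only; no recombination-aware or
  multi-locus estimators, no Bayesian skyline demography.
* Mismatch bootstrap ignores pair non-independence (above).
* Raster support is ESRI ASCII grid only; projection must be geographic
  lon/lat.
* The MaxEnt implementation follows the published model family but is
  not a bit-for-bit replica of MaxEnt 3.4.4 (different optimiser, knot
  placement and tie handling).
* Statistical-parsimony and median-joining networks, Mantel tests and
  Bayesian clustering are out of scope.
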