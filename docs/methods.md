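# Methods

This note documents the models behind `mtpopgen`, the parameter scalings and
defaults, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Data model and conventions

An analysis starts from an aligned FASTA over {A,C,G,T,-,N} plus a
two-column TSV mapping samples to populations.  Coordinates are 0-based
half-open internally; 1-based ids appear only in reports.  Two sequences are
the same haplotype iff they are identical strings after uppercasing; an N
mismatching a base keeps sequences distinct (conservative — no
ambiguity-merging rule is assumed).  Indel columns count toward haplotype
identity and the segregating-site tally S, but all pairwise *distances* use
pairwise deletion: sites with a gap or N in either sequence are dropped for
that pair.  Alignment columns of dubious homology are removed by
user-supplied mask ranges; the package does not decide which regions are
ambiguous.

Site classification: a column is an indel site if any non-N character is a
gap; every unordered pair of distinct bases observed in a column counts once
as a transition (A↔G, C↔T) or transversion, so multi-state columns can
contribute to both tallies and the three categories can sum to more than S.

## Diversity

Haplotype diversity h = n(1−Σp²)/(n−1) with Nei's sampling variance
V(h) = 2/(n(n−1)) [2(n−2)(Σp³−(Σp²)²) + Σp²−(Σp²)²].  Nucleotide diversity π
is the mean per-site difference proportion over all pairs (p-distance on
pairwise-complete sites); its standard deviation uses the total variance

    V(π) = (n+1)/(3(n−1)L) π + 2(n²+n+3)/(9n(n−1)) π²,

which contains both the sampling and the coalescent (stochastic) term, the
convention of the standard population-genetics packages.  π is deliberately
reported on uncorrected proportions; the Tamura–Nei model enters only the
distance matrices used for structure analyses, matching how such surveys
apply it.  TN93's closed form is implemented directly, with the gamma-rates
variant replacing each −k·ln(w) term by k·α(w^(−1/α)−1); the default shape
α = 0.61 is the control-region estimate carried by the package's reference
configuration.  An invariant-sites fraction can be recorded but does not
rescale distances — there is no standard closed form, and the reference
implementations ignore it as well (documented limitation).

## Neutrality tests

Tajima's D follows the usual constants a₁…e₂; D is undefined (NaN) at S = 0.
Fu's Fs uses the Ewens sampling formula: with θ̂ equal to the mean pairwise
difference count, S′ = Pr(K ≥ K_obs) is computed from unsigned Stirling
numbers of the first kind built in log space (exact to 1e−10 against the
rising-factorial identity up to n = 100), and Fs = ln(S′/(1−S′)).

p-values are one-sided toward negative values — the direction in which
population expansion pulls both statistics.  Each observed dataset is
compared against neutral constant-size coalescent replicates with exactly
the observed S mutations placed multinomially by branch length (the fixed-S
convention of the standard tools).  The default replicate count is 1000 and
a seed is required for reproducibility.  Calibration: over 1000 neutral
datasets (n = 20, θ = 5) the 5 % one-sided tests reject at a rate inside the
binomial 95 % band for both D and Fs (test-suite property).

## Mismatch distribution and sudden expansion

The model population sat at scaled size θ₀, grew instantly to θ₁ at τ units
of mutational time before sampling (τ = 2ut).  The expected
pairwise-difference distribution is

    F_i = F̂_i(θ₁) + exp(−τ(θ₁+1)/θ₁) Σ_{j≤i} τ^j/j! [F̂_{i−j}(θ₀) − F̂_{i−j}(θ₁)],

with F̂ the geometric equilibrium.  At τ = 0 this collapses to the θ₀
equilibrium, and for θ₀ = 0, θ₁ → ∞ to a Poisson(τ) — both verified, along
with agreement with a 10⁵-pair Monte-Carlo oracle of the two-epoch pair
process.  Expected vectors are truncated, never renormalised; tail mass is
the complement of the sum.

Fitting minimises the unweighted SSD over τ∈[0,50], θ₀∈[0,50],
θ₁∈[1e−6, 99999] by L-BFGS-B from ≥10 deterministic seeded starts, always
including the method-of-moments start (τ ≈ mean differences, θ₀ ≈ 0,
θ₁ at the cap).  The 99999 upper bound doubles as the conventional sentinel
reported when θ₁ is unidentifiable; the 1e−6 lower bound keeps the
transient exponent defined (θ₁ = 0 is a measure-zero boundary).  Confidence
intervals and the SSD / raggedness p-values come from a parametric
coalescent bootstrap under the fitted parameters (default 200 replicates,
refitted with 4 starts each).  Raggedness is the sum of squared successive
frequency differences with one zero appended after the last class, so the
degenerate single-class histogram scores 1.0.

Expansion dating uses years = τ/(2u) with u = μ·L·generation time and the
unrounded per-sequence rate (1.9e−7 × 993 per year by default): τ = 8.109
maps to ≈21,500 years, matching the figure this u reproduces where the
rounded u = 1.88e−4 would not.

## AMOVA and Φ statistics

Sums of squares come straight from the squared-distance matrix
(SS_total = Σ_{i<j}δ²/n; within-group sums analogously per group), variance
components from the expected mean squares with the standard unequal-size
coefficients, in one-level and two-level (groups of populations) layouts.
Components may be negative and are never truncated; an all-identical input
is flagged (`defined=False`) rather than propagating NaNs.  Significance:
individuals permuted among populations for Φ_ST (1000 default pairwise,
5000 for the full analysis), whole populations among groups for Φ_CT, with
p = (hits+1)/(perms+1); small problems can enumerate every distinct
assignment exhaustively, in which case p is the exact tail proportion.  The
default distance is squared TN93+Γ(0.61); a p-distance option serves as a
robustness check.  On ≤8 individuals the vectorised components agree to
1e−10 with a plain-loop oracle, and the fixed-difference toy gives Φ_ST = 1
with exact permutation p = 1/3.

## Haplotype network

Kruskal's algorithm over the complete haplotype graph weighted by raw
substitution counts, with deterministic tie-breaking (weight, then
lexicographic id pair).  Every non-tree edge whose weight equals the maximum
edge weight on the tree path between its endpoints is flagged as an
equally-minimal alternative, turning the tree into a minimum spanning
network.  Node metadata carry per-population counts and total frequency for
plotting.  A full median-joining algorithm (median vectors) is out of scope.

## Isolation with migration

Two populations of scaled sizes θ₁, θ₂ split from an ancestor of size θ_A at
time t and exchange migrants at rates m₁, m₂.  All quantities are scaled by
the per-locus mutation rate u: θ = N_e·u, t is in expected substitutions per
locus, m = m_rate/u.  Backward in time each lineage mutates at rate 1, a
pair in deme i coalesces at rate 1/θᵢ, a lineage in deme i migrates at rate
mᵢ, and above t everything is ancestral.  Under this scaling the equilibrium
mean pairwise difference within a deme is 2θ and the Watterson relation is
E[S] = 2θa₁.

The sampler is Metropolis–Hastings over (genealogy, parameters) with
uniform [0, bound] priors; bounds are user-set (initial-run-then-adjust, as
is standard for this model family).  Moves:

1. **Parameter updates** (scale, window slide, and independence draws from
   the prior); only the structured-coalescent prior density changes.
   Updates of t are constrained to the window allowed by the current
   genealogy's migration events and node demes.
2. **Node-time slides** within the window bounded by neighbouring events;
   uniform within finite windows, multiplicative above the root.
3. **Lineage regrafts**: the branch above a random node is detached and its
   migration path and reattachment point re-simulated from the *exact*
   conditional structured-coalescent prior given the remaining genealogy
   (including the paired process above the old root, whose extension's
   migrations are simulated too).  The proposal density then cancels the
   prior exactly and the acceptance ratio is the likelihood ratio alone —
   verified by the regraft acceptance rate being exactly 1 under
   likelihood-off sampling.  This move also regenerates the chosen
   lineage's migration events, covering migration birth/death/move.
4. **Joint rescaling** of t, all node times and all migration times by a
   common factor (Jacobian f^(dof)), which decouples the overall time scale
   from the event-by-event moves.

The likelihood is Felsenstein pruning under HKY with empirical base
frequencies and a fixed κ estimated once from the data by the moment
formula κ ≈ (P/Q)·g_R·g_Y/(g_A·g_G + g_C·g_T); fixing κ (rather than
sampling it) keeps the state space small, and rate heterogeneity is not
modelled inside the IM stage.  Site patterns are compressed once per run;
per-site branch lengths are node-time differences divided by L.

Outputs: marginal histograms on 200 equal bins over each prior (TMRCA on a
data-driven grid), the mode as the midpoint of the maximal bin after 3-bin
moving-average smoothing, the shortest contiguous 95 % HPD span, and
autocorrelation-based ESS (initial-positive-sequence truncation).  Runs that
miss the ESS target (default 500) complete with an explicit warning.
Defaults (50,000 burn-in / 500,000 steps) are library defaults for desk
use; the tests use shorter chains (see below).  Conversions: divergence and
TMRCA years = mode/u·generation time; N_e = θ/u, with a species-level value
dividing further by the mtDNA inheritance scalar 0.25.

Sampler validity is established by prior recovery: with the likelihood
switched off, every parameter's marginal must return its uniform prior
(Kolmogorov–Smirnov p > 0.01 on 5000 heavily thinned samples), which
exercises every move's Hastings ratio jointly.  Parameter recovery: on data
simulated at θ₁ = θ₂ = 10, θ_A = 5, t = 1, m = 0 with 10+10 sequences of
500 sites, the true θs fall inside their 95 % HPDs in ≥80 % of replicate
runs.  For such a recent split the migration posteriors are essentially
flat — a single locus carries almost no information on gene flow, which is
itself the expected behaviour.

## Coalescent simulator

Three scenarios: `constant`, `sudden_expansion` (pairwise coalescence rate
1/θ₁ more recently than τ, 1/θ₀ earlier) and `im_split` (delegated to the
IM machinery).  For the panmictic scenarios node times are in mutational
time, where a branch of duration dt carries Poisson(dt/2) mutations so a
pair separated at depth T differs at Poisson(T) sites — exactly the scaling
in which τ and θ plug into the mismatch formulas; for `im_split` times are
substitutions per locus with mutation rate 1 per lineage.  The
`mutation_scale` attribute converts either unit to expected substitutions
per sequence, which is what exported newick branch lengths and the sequence
evolver use.  Sequence evolution is HKY via the symmetrised
eigendecomposition, with per-site gamma and invariant-sites rate
multipliers normalised to mean 1; the default base composition is the
AT-rich control-region average (A 37.25 %, C 9.57 %, G 7.93 %, T 45.24 %,
renormalised from printed percentages summing to 99.99 %) with κ = 20,
chosen to reproduce the observed ≈6:1 transition:transversion ratio under
these frequencies via the same moment formula the IM stage uses.  Indels
are not simulated; the three indel columns in the reference survey are
incidental to every downstream statistic as implemented.

All randomness flows through a single seeded `numpy` generator; the same
seed reproduces byte-identical outputs.  Monte-Carlo checks: E[S] = θa₁ and
E[π] = θ/L within three standard errors, pair coalescence means for both
panmictic scenarios, the HKY pair-divergence expectation against the matrix
exponential, and the Jukes–Cantor special case.

What the simulator does *not* emulate: indels and alignment ambiguity,
multi-locus data, recombination, selection, site-specific hypermutability,
and sequencing error.  Tests passing on synthetic data therefore validate
the estimators under their own model assumptions, not robustness to those
real-data complications.

## Reference dataset and reproduced figures

The bundled count table (68 haplotypes × 5 localities, column sums
17/21/17/18/20) supports the haplotype-composition results: 12 shared vs 56
(82.4 %) locality-specific haplotypes, and haplotype diversities of 0.99 for
the KW and LD compositions.  The underlying sequences are GenBank
GQ283010–GQ283077 and are not redistributed; pooled Tajima's D (−1.78) and
Fu's Fs are therefore evaluated from the published summary statistics
(n = 93, S = 84, K = 68, mean pairwise differences = π·L), which determine
both statistics exactly.  Note that the same Fs implementation that
reproduces all five per-locality values within rounding yields ≈−70 for the
pooled sample, far below the published −24.85; no θ consistent with any
printed statistic yields that value, so the pooled figure appears to be a
numerical artifact of the original analysis software at n = 93, and this
package reports the value its validated formula produces.

## Problem sizes used by the test suite

The suite favours many small, seeded simulations: neutrality calibration
uses 1000 datasets × 200 null replicates at n = 20; mismatch recovery 200
datasets at the n = 17 survey regime; IM prior recovery a 2+2-tip
configuration thinned to 5000 samples; IM coverage ten 10+10 × 500-site
runs of 45,000 steps.  These sizes were chosen as the smallest at which the
corresponding statistical statements are meaningful; library defaults are
larger.
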