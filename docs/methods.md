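# Methods

This note records the models, conventions and design choices behind
stygopop, in the spirit of a statistical-methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

The observed-data object is a `HaplotypeTable`: distinct haplotype strings
over the substitution-variable alignment columns, with per-deme counts and
the full alignment length L (invariant sites included, so π = k̄/L).
Coordinates are 0-based internally and 1-based in everything written to
disk. The gap character is never a substitution state: columns whose
variation involves a gap are indel sites, reported separately and excluded
from all nucleotide statistics (the "complete deletion" convention of
DnaSP/Arlequin — this is why a dataset can have 82 variable sites but
S = 81). Ambiguity codes other than N are rejected; sequences with N at a
retained variable site are excluded by default or matched when unambiguous.

## Diversity statistics

- Haplotype diversity h = n(1 − Σp²)/(n − 1), sampling variance from Nei
  (1987, eq. 8.12).
- Nucleotide diversity π = k̄/L with k̄ the mean pairwise difference count
  over all n(n−1)/2 sequence pairs; var(π) follows Nei (1987, eq. 10.7),
  which includes the stochastic (evolutionary) term — this reproduces the
  magnitude of the published standard deviations (e.g. 0.0010 ± 0.0008 for
  a 3/3 two-haplotype group of six). The variance of pairwise differences
  uses the sample (n−1) denominator over pairs.
- Tajima's D uses the 1989 coefficient set (a₁…e₂); S = 0 raises an
  undefined-statistic error rather than returning 0.
- Fu's Fs: S′ = P(K ≥ NH | θ = k̄) from the Ewens sampling formula, with
  unsigned Stirling numbers of the first kind computed by the log-space
  recursion |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| (pairwise log-add), exact
  against rational arithmetic for small n and overflow-free at n = 90.
  Fs = ln(S′/(1−S′)); S′ at the boundary returns a signed-infinity sentinel.
- R2: per-site singletons (minor-allele count 1) attributed to the carrier
  sequence; R2 = sqrt(Σᵢ(Uᵢ − k̄/2)²/n)/S. When the two alleles of a site
  each occur once (only possible at n = 2), both carriers are credited —
  the statistic is unchanged by this tie rule.

## AMOVA, Φ_ST and SAMOVA

AMOVA follows Excoffier, Smouse & Quattro (1992): squared intersequence
distances are the pairwise difference counts; sums of squares are formed
from deme-level cross-sums W = CᵀD²C (C the haplotype × deme count matrix),
and the three variance components are solved from the expected mean squares
with the standard unbalanced-design coefficients. A saturated partition
(every deme its own group) collapses to the two-level model with σ_b ≡ 0.
Components may be negative, as usual. Significance: F_CT permutes whole
demes among groups, F_SC permutes individuals among demes within groups.
Pairwise Φ_ST is the two-level special case; a haplotype-identity (0/1
distance) F_ST is available as an option because the distance convention
of the original analysis is not recorded. Permutation p-values of a
discrete statistic are conservative (ties counted against rejection); the
calibration that matters — the rejection rate at the nominal level — is
what the test suite asserts (measured 5.0% at α = 0.05 on null splits),
not strict uniformity of the p-value distribution.

SAMOVA searches contiguous K-partitions of demes, contiguity given by a
Delaunay triangulation of deme coordinates (collinear layouts fall back to
a chain; duplicate coordinates are deterministically jittered with a
warning). The annealing schedule — not specified by the method's original
description — is: initial partitions grown by random BFS from K seeds;
proposal = move one boundary deme to an adjacent group, rejecting moves
that empty or disconnect a group; T₀ set from the median absolute score
change of early proposals so that ~50% would be accepted; geometric
cooling T ← 0.9T with 100 proposals per temperature; a chain stops after
50 temperatures without improving its best F_CT. Ties between runs break
on the lexicographically smallest canonical partition. On ≤10-deme
problems the annealer reproduces the exhaustive contiguous-bipartition
optimum exactly (this is a standing acceptance check). Geographic distance
beyond adjacency is deliberately ignored: the spatial constraint is
contiguity, not distance decay.

## Statistical-parsimony network

The connection limit is the largest step count j whose probability of a
homoplasy-free multi-step connection is at least α = 0.95. We model the j
underlying mutations as falling uniformly and independently over the L
sites, so the connection is parsimonious exactly when all mutations struck
distinct sites: P_j = Π_{i=1}^{j−1}(1 − i/L). This is our own
transparent stand-in for the original 1992 estimator (whose full equations
the package does not transcribe); for L = 1,217 it gives a limit of 11
steps, consistent with the empirical network joining haplogroups separated
by 10 steps. The network is built agglomeratively: pairs are processed in
increasing Hamming-distance order up to the limit; every pair whose
endpoints lay in different components at the start of its distance level
is connected (multi-step connections realized through inferred
intermediate nodes of one step each), so equal-length alternatives survive
as loops and are flagged rather than resolved. Within a level, ties order
by descending haplotype frequency then id — the TCS frequency criterion —
which makes output deterministic. Group separations report both the raw
minimum Hamming distance and the minimum network path length, since a
published "minimum steps" figure could mean either.

## Mismatch distributions and the sudden-expansion model

For a pair of lineages under θ(x) piecewise-constant in mutational time
x = 2ut (θ = θ₁ for x < τ, θ₀ beyond), the difference-count distribution
is the coalescence-time mixture of Poissons. Integrating gives the closed
form implemented in `expected_mismatch`:

F_i = Geo_i(θ₁)·P(i+1, τ(θ₁+1)/θ₁) + e^{−τ/θ₁} Σ_m Pois_{i−m}(τ)·Geo_m(θ₀),

with Geo_i(θ) = θ^i/(θ+1)^{i+1} and P the lower regularized incomplete
gamma function. This is algebraically the classic sudden-expansion
mismatch distribution; the test suite verifies it against direct
quadrature of the defining integral (an independent route), against the
equilibrium limit at τ = 0, and against the pure-Poisson star-burst limit.
θ₀ = 0 is handled as the exact point-mass limit.

Fitting minimizes the SSD between observed relative frequencies and F_i
over the observed class support. The parameterization τ = u², θ₀ = v²,
θ₁ = min(θ₀ + w², 10⁵) enforces positivity and θ₀ ≤ θ₁; θ₁ is capped
because the SSD surface is flat in θ₁ once it is large (the usual
"post-expansion θ effectively infinite" regime). A fixed multistart grid
(τ ∈ {0.1,1,2,5,10} × θ₀ ∈ {0,0.5,2} × θ₁ ∈ {10,100,1000}, plus a
moment-matched start at the histogram mean) is screened by one SSD
evaluation each and the three best starts are polished by Nelder–Mead;
on histograms generated exactly from the model the optimum is recovered
to ~10⁻⁵. The SSD p-value is a parametric bootstrap: coalescent samples
under the fitted history (simulated directly in mutational units, branch
mutation rate 1/2 per unit), each refit from warm starts; p is the
fraction of bootstrap SSDs at or above the observed. Single-class
histograms return the τ = 0 degenerate fit with a warning.

## Neutrality-test p-values and their calibration

Null distributions come from standard constant-size Kingman genealogies.
Two conditionings are provided: fixed-S (exactly S mutations dropped
multinomially by branch length — infinite sites) and fixed-θ (Poisson
mutations at rate θ/2 per coalescent-unit branch length). Fixed-S is the
default; fixed-θ with θ = k̄ is the convention DnaSP applies to Fu's Fs,
and it is what reproduces the published significance of the Cayuco group's
Fs (p ≈ 0.0006 < 0.001 at 10,000 simulations, versus p ≈ 0.01 under
fixed-S). All three tests are one-tailed in the expansion direction
(lower tail). Calibration is checked empirically: over 2,000 neutral
fixed-θ datasets with per-replicate fixed-S nulls, the type-I error at
the 5% level is 4.4–5.0% for D, Fs and R2 (recomputed by
`scripts/acceptance.py`). Summary statistics in these simulations are
computed directly from mutation-labelled branches (frequency-spectrum
identity for k̄, external-branch loads for singletons, hashed root-paths
for haplotype counts), which the suite cross-checks against the explicit
sequence-matrix route.

## Coalescent scenario simulator and ABC

Scenarios are event lists over named populations: backward-in-time merges
(population splits) and founder bottlenecks (size Nf over the Bd
generations preceding the merge — i.e. immediately after the forward-time
founding), with piecewise-constant haploid sizes and an ancestral stem
size beyond the last merge. The built-in sets mirror the study design:
three major-region scenarios (fragmentation; centre origin with dispersal
both ways; east-to-west stepping stone), three eastern-subregion and two
western-subregion scenarios, every dispersal followed by a bottleneck.
Sequences evolve under finite sites with transition bias κ (default 4.75,
the observed TS/TV ratio; multiple hits allowed), and samples collapse to
haplotype tables.

Default priors (used when no study-specific prior table is supplied):
N ~ logU(10², 10⁵) haploid, Nf ~ U(2, 100), Bd ~ U(1, 50) generations,
event times ~ U(10², 10⁵) generations with the declared orderings
(t₂ > t₁ > t₀; ancestral N above derived; central > eastern > western
sizes), μ ~ logU(10⁻⁸, 10⁻⁷) per site per generation; constrained draws
by rejection. Every reference table records a hash of its prior
specification, and rows are seeded as (seed, scenario, row) so tables are
bit-reproducible regardless of chunking.

Model choice standardizes summaries by the reference-table spread,
retains the closest fraction (default 0.10) by Euclidean distance, and
reports both the retained-proportion (rejection) posterior and a
multinomial logistic regression of the scenario indicator on the
summaries with Epanechnikov distance weights, evaluated at the observed
point. The default summary set is the four per-group statistics (number
of haplotypes, segregating sites, mean and variance of pairwise
differences); pairwise Φ_ST and between-group mean differences are an
optional block.

**A structural limitation worth stating plainly:** one non-recombining
locus yields one genealogy per dataset, and the across-genealogy variance
of every summary is large. At fixed parameters the competing major-region
scenarios do shift the summary means (founding the central population
from the east depresses its within-group diversity, a difference the
suite verifies), but across prior-predictive draws the scenario signal is
largely erased: a flexible classifier trained on labelled reference
tables — an upper bound on any ABC procedure's accuracy — barely exceeds
the 1/3 chance level, and the measured max-posterior self-recovery rate
is ~0.33 rather than near 1. Single-locus scenario choice of this kind is
therefore informative only conditionally on where the observed data fall,
not reliably in the marginal sense; posterior probabilities from such
analyses deserve corresponding caution.

## Synthetic study-shaped data

`generate_study_like` simulates the five-group composite stepping-stone
history (A←B←C←E forward, D←E, founder bottlenecks at each dispersal)
with default parameters chosen so the prior-free "study conditions" are
matched at the printed scale: 90 samples in the empirical deme layout
(21 demes, group sizes 6/17/29/23/15), L = 1,217, and — at the default
μ = 1.3×10⁻⁷/site/gen, sizes N_A..N_E = 4k/9k/30k/9k/15k, t₁ = 50k
generations — about 70–95 segregating sites and overall π ≈ 0.012,
bracketing the published S = 81 and π = 0.0100. The generator produces
fewer distinct haplotypes (~35–40) than the empirical 49, because the
default history lacks the recent within-group expansions that stock the
real data with young singleton haplotypes; passing tests on synthetic
data therefore demonstrate pipeline correctness at the right scale of
variation, not that the default history reproduces every empirical
feature. Demes within a group are panmictic in the generator (deme labels
partition samples but carry no extra structure); geography is a noisy
west-east line, not digitized cave coordinates. The truth record written
beside each dataset re-simulates it bit-identically.

## Agreement with the published study values

Statistics that are functions of printed summaries alone are recomputed
directly: Fu's Fs for Bolondrón (−3.580 vs −3.540 published, within the
rounding of the printed π), Fs for Cayuco (−5.679 vs −5.736) and its
coalescent significance (p < 0.001), h and π (with sd) for the fully
determined smallest group. Overall Tajima's D recomputes to −0.785 from
the printed (n, S, π); matching the published −0.841 requires k̄ to
~0.3%, while the printed two-significant-figure π pins it only to ~0.5% —
the exact value needs the underlying alignment. Checks that require the
per-locality haplotype matrix (group-level h/π for the remaining groups,
F_CT = 0.656, the 10-step network separation, the published ABC
posteriors, R2 for Cayuco) are wired to accept a user-supplied haplotype
table in the package's TSV format and are reported as failing, with the
missing input named, until one is provided.

## Problem sizes

The test suite and acceptance script run, by design, at desk scale:
2,000 replicates for calibration and simulator-expectation checks,
100 replicates for τ recovery, 1,500 simulations per scenario and ~100
pseudo-observed datasets for the ABC recovery experiment, 10–100
annealing chains for SAMOVA, and 10,000 coalescent simulations for
single p-values. Full-scale runs (10⁴–10⁶ simulations per scenario,
100 chains per K) use the same code paths through the documented
parameters.
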