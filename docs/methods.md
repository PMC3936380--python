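# Methods

`phylorefugia` implements the statistical core of a single-locus
(chloroplast) phylogeographic study: how haplotype variation is
summarized, how geographic structure is detected and partitioned, how
demographic history is probed, and how explicit refugial hypotheses and
niche-differentiation claims are tested. This note records the models,
the defaults and why they were chosen, the numerical decisions, and the
known limits of what the synthetic experiments demonstrate.

## Coalescent machinery

All genealogy simulation (`refugia_coalescent`) uses the continuous-time
structured coalescent. Demes carry sizes in **gene copies** — the
natural unit for a haploid, uniparentally inherited locus — and a pair
of lineages in a deme of N copies coalesces at rate 1/N per generation
(k lineages: k(k−1)/(2N)), so the expected pairwise coalescence time is
N generations. Waiting times are exact exponentials; there is no
discretization. Demes merge backwards in time at join events; optional
per-lineage migration rates add lineage movement between demes as a
competing exponential event. Time is kept in generations internally and
converted from years only at the interface (`years_to_generations`).

Two refugial presets encode the competing hypotheses tested by the
`refugia_test` machinery:

- **two-refugia**: two demes of size Ne each, isolated since time T,
  with an ancestral deme also of size Ne — long-term persistence in two
  refugia;
- **fragmentation**: one deme of size Ne until T, then two demes of
  Ne/2 — recent fragmentation of a single refugium, conserving the
  total size.

The structural difference between the two hypothesis families is not
fully determined by the descriptions such studies give of their
simulation settings; these presets are one defensible parameterization
and everything (sizes, times, sample layout) is overridable through
`PopulationModel`.

The Slatkin–Maddison statistic *s* (minimum number of deme-state
changes on the genealogy) is computed by Hartigan's generalization of
Fitch parsimony, which is exact for unordered states on trees of any
degree; tests confirm equality with exhaustive enumeration over all
interior labelings on 500 random trees. A scenario is rejected when the
observed *s* falls outside the central 95% (empirical 2.5th–97.5th
percentiles, linear interpolation) of *s* over simulated genealogies; a
one-tailed variant (`tail="lower"`) is available since an observed tree
can realistically only be *more* scattered than a scenario predicts.
Because *s* is integer-valued, the test is conservative when the
simulated distribution is concentrated on few values; calibration
experiments should use configurations whose *s* distribution is spread
(large Ne, recent splits, tens of samples), where the self-rejection
rate measures close to the nominal 5%.

## Synthetic data

`synthetic_data.simulate_sequences` draws a genealogy from the
structured coalescent with demes equal to the geographic groups, then
drops mutations on branches:

- substitutions: Poisson(μ · L · branch-length-in-years) per branch
  under finite-sites Jukes–Cantor (uniform site choice, uniform change
  to one of the other three bases). Finite sites — not infinite sites —
  so that multiple hits and homoplasy exercise the network code the way
  real chloroplast data do.
- indels: an independent Poisson process at 5% of the substitution rate
  producing 1–3 bp gap runs, mimicking the short indel polymorphisms
  typical of plastid spacers. A substitution landing on a gapped site
  re-seats a base; indels dominate the gap pattern.

Tips are assigned to populations by their original (exchangeable)
sample index within each deme, never in tree-traversal order: tree
order places genealogically related tips in the same population and
manufactures spurious structure (measured as an N_ST > G_ST
false-positive rate of ~20% instead of the nominal ~5% under panmixia).

Default design (overridable): 19 populations of 2–14 haploid samples in
two groups, L = 1417 bp, μ = 1.59 × 10⁻⁹ substitutions/site/year,
generation time 34 years, deme sizes of 10,000 gene copies and a split
2.68 Ma ago. The size is the low end of the 10⁴–10⁶ grid used in the
hypothesis tests and, with this μ and generation time, gives per-locus
θ ≈ 1.5 — matching the low nucleotide diversity (π ~ 10⁻⁴–10⁻³)
typical of plastid data at this scale; the split time is the
intermediate-rate divergence estimate for the barrier. Population
coordinates lie on a line with a small alternating latitude offset
(±0.1°) so the Delaunay neighborhood graph used by SAMOVA is well
defined; exactly collinear coordinates fall back to a chain graph.

`simulate_niche_data` draws occurrence and background points from
per-lineage multivariate normal environmental distributions (BIO-style
columns). It emulates the *statistical* structure of
occurrence/background sampling only: no spatial autocorrelation, no
raster geometry, no correlation between geography and environment
beyond what the supplied means/covariances encode. Passing tests on
these data show the estimators and decision rules behave as designed,
not that any particular field dataset would yield the same calls.

## Haplotypes and networks

Collapsing supports the two gap conventions used with plastid
alignments. Under `fifth_state`, identity is exact string equality
('-' a distinct symbol). Under `missing`, sites where either sequence
has a gap are ignored pairwise — a relation that is not transitive, so
samples are assigned greedily in input order to the first haplotype
whose representative matches; the choice is deterministic and
idempotent. Pairwise distances use the matching convention (pairwise
deletion under `missing`).

The statistical-parsimony connection limit is the largest number of
steps j for which the probability of a parsimonious (homoplasy-free)
connection exceeds the confidence level (default 0.95). The probability
is computed from the Jukes–Cantor/Poisson argument: per-site mutation
counts are Poisson with mean λ solved from the observed proportion of
differing sites (JC correction, capped at the 3/4 saturation point), and
a j-step connection is parsimonious when every differing site mutated
exactly once and every identical site not at all:

    P(j) = P(one hit | differ)^j · P(no hit | same)^(L−j).

For L = 1417 at 95% this gives a limit of 12 steps. The test oracle
evaluates the same probability model through explicit truncated Poisson
series rather than closed forms.

Networks are built by a minimum-spanning construction: haplotype pairs
in order of increasing distance, an edge added when it joins two
components and is within the limit, multi-step edges expanded into
chains of anonymous zero-frequency intermediates. When equal-length
alternatives would close a loop, the pair with the higher total
haplotype frequency is kept (a simplified frequency criterion — the
full topology/geography criteria require curator judgment) and the
discarded alternatives are reported.

## Diversity and differentiation

Per-population summaries are Nei's unbiased haplotype diversity
h = n/(n−1)(1 − Σp²) and nucleotide diversity π (mean pairwise
proportion of differing sites, pairwise deletion).

The ordered/unordered framework follows the Pons–Petit unbiased
construction for K populations with unequal sample sizes n_k (harmonic
mean ñ). With x_ki the sample frequencies and d a haplotype distance
matrix (identity 0/1 for the unordered case):

    v_S = ñ/(ñ−1) · (1/K) Σ_k Σ_ij x_ki x_kj d_ij
    v_T = Σ_ij x̄_i x̄_j d_ij + v_S/(Kñ),   x̄ = unweighted mean frequency

The v_S/(Kñ) term removes the sampling-variance bias of the plug-in
total; both estimators were checked for (approximate) unbiasedness by
multinomial simulation. G_ST = 1 − h_S/h_T and N_ST = 1 − v_S/v_T.
Standard errors are delete-one-population jackknives (the analytic
variance formulas could not be verified and the jackknife matches their
intent for a reviewer). Negative estimates are reported as computed and
flagged. The N_ST > G_ST test permutes haplotype identities on the
distance matrix (rows and columns together) — the documented behavior
of this test family; individuals are not reshuffled — with one-sided
p = (#{N_ST* − G_ST ≥ observed} + 1)/(B + 1). Ordered distances default
to parsimony-network step counts where connected, raw mismatches
otherwise.

## AMOVA and SAMOVA

AMOVA follows the Excoffier–Smouse–Quattro construction. Pairwise
difference counts are used directly as squared distances (the standard
convention for haplotype data; TN93-corrected distances — verified to
1e-12 against an independent implementation — are optional). Sums of
squares come from within-unit pair sums divided by unit sizes; variance
components solve the expected-mean-square equations with the
unequal-sample-size coefficients n1, n2, n3; Φ_CT = σ²a/σ²,
Φ_SC = σ²b/(σ²b+σ²c), Φ_ST = (σ²a+σ²b)/σ². Degenerate layouts are
handled explicitly: a single grouping level drops the among-group row,
every-population-its-own-group sets σ²b = 0, zero total variance flags
the indices as undefined. Permutation tests move individuals among
populations (Φ_ST), individuals within groups (Φ_SC), and whole
populations among groups (Φ_CT); the Φ_CT permutation enumerates all
distinct arrangements exhaustively (exact p) when there are fewer than
the requested number.

SAMOVA searches contiguous K-partitions of the Delaunay neighborhood
graph by simulated annealing: random contiguous seeds-and-growth
initialization, single-population moves to adjacent groups that keep
the donor group non-empty and connected, acceptance always for
improvements and with probability exp(ΔΦ_CT/T) otherwise. The initial
temperature is set from the median |ΔΦ_CT| of probe moves so roughly
half of typical worsening moves are accepted, with geometric cooling
(×0.9 over 50 stages of a 1000-step run) and 100 restarts by default.
Φ_CT evaluation is O(P²) via precomputed population-pair sums, making
the search cheap at the study scale. On two-group simulations the
search recovers the exhaustive-search optimum exactly (tested against
full enumeration of contiguous bipartitions).

## Demography

Tajima's D uses the standard constants; its p-value comes from neutral
coalescent simulations conditioned on the observed S (mutations placed
uniformly on branches), one-tailed in the direction of the observed
departure. Fu's Fs is the logit of P(K ≥ k_obs | θ = θ_π) under the
Ewens sampling distribution, computed entirely in log space via the
unsigned-Stirling recurrence (matches exact enumeration to ~1e-15 for
n ≤ 8 and avoids the catastrophic cancellation a naive 1 − S′ incurs in
the extreme tails); its p-value is the fraction of constant-size
coalescent simulations at θ_π with Fs at least as negative.

The mismatch distribution is fit to the sudden-expansion expectation

    F_i(τ, θ0, θ1) = F̂_i(θ1) + e^(−τ(θ1+1)/θ1) Σ_{j≤i} (τ^j/j!) [F̂_{i−j}(θ0) − F̂_{i−j}(θ1)]

(F̂ the equilibrium geometric pmf, evaluated in log space) by bounded
least squares on SSD with three method-of-moments starts and the
parameterization θ1 = θ0 + Δ, Δ ≥ 0, enforcing θ0 ≤ θ1. Goodness of fit
(SSD and Harpending's raggedness, the sum of squared successive
frequency differences) is assessed by parametric bootstrap: datasets
are re-simulated under the fitted expansion (coalescent on the
mutational time axis, rate 1/θ(x) per pair), *re-fit*, and
p = (#{stat ≥ observed} + 1)/(B + 1). Calibration was checked under the
true expansion model (~5% rejection); library and CLI default to 10,000
replicates, tests use 60–1000 for runtime.

## Unit conversions

`rate_scaling` holds the deterministic arithmetic: T = a + s/(1−s) for
generation time (a = age at maturity, s = adult annual survival; 25
years with s = 0.9 or 0.99 gives 34 and 124 years); per-lineage
substitution rate = (d_xy/2)/(2·t_div); IM divergence time in years
= t/(μL); Ne = q/(c·μ·L·g) and Nm = q·m/c with inheritance scalar c
(default 2, i.e. q = 2Nu for a haploid uniparental locus — exposed as a
parameter because the correct scalar depends on the sampler's
convention). All functions are exact; rounding to 1–2 decimals of MYA
happens only in reports. Note that a derivation chain of
0.003785/23.8 per Myr equals 1.59 × 10⁻¹⁰/year, an order of magnitude
below the commonly quoted 1.59 × 10⁻⁹ s/s/y; `RateEstimate` therefore
reports both the per-Myr and per-year values explicitly and leaves the
choice of rate grid to the caller (`MU_GRID` spans 1.0–3.0 × 10⁻⁹).

## Niche divergence and conservatism

The background test scores occurrence and background points on shared
PCA axes (correlation PCA of the pooled occurrence + background rows by
default; covariance PCA by flag; axis signs fixed so the
largest-magnitude loading is positive). Per axis, the observed
|difference of lineage means| is compared to the middle 95% of
background divergence over jackknife replicates, each resampling 75% of
each background set with replacement ("75% of replacement" is
ambiguous; fraction and with/without replacement are parameters).
Above the interval → divergence, below → conservatism, inside →
neither. The decision rule is exposed separately
(`classify_divergence`) and reproduces all seven published axis
classifications from the published observed values and null intervals.

Calibration caveat: with a 95% interval per axis the exact-null
per-axis "neither" rate is ~95%, so a run testing three axes is jointly
clean only ~86% of the time — and because the null interval is a folded
|difference| bounded away from zero while the observed difference
concentrates at zero as occurrence samples grow, very large occurrence
samples make spurious *conservatism* calls increasingly likely. The
test is a heuristic comparison, not a calibrated hypothesis test;
sampling occurrences at a density comparable to the background resample
noise keeps both tails near nominal.

## Problem sizes

The test suite and the acceptance script run everything at the study's
own design scale (≤ 160 samples, ≤ 19 populations) or smaller:
oracle-equivalence checks use 4–10 populations and ≤ 12-node exhaustive
searches; calibration experiments use 50–200 replicate datasets with
200–400 permutations/simulations each, sizes at which the Monte-Carlo
standard error is well inside the asserted bounds.
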