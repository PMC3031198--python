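# Methods

## The inference problem

`codiv` asks whether a set of Y codistributed taxon-pairs — pairs of sister
populations separated by the same putative barrier — diverged simultaneously,
and how much post-divergence gene flow each pair experienced, given
multi-locus DNA sequence alignments from every pair.  Because the joint
likelihood of a multi-taxon, multi-locus isolation-with-migration model is
intractable, inference is by hierarchical approximate Bayesian computation
(ABC): simulate large numbers of data sets from the prior, reduce each to a
summary vector, and treat the prior draws whose summaries fall closest to the
observed summaries as a posterior sample.

## Hierarchical model

Hyper-parameters shared across taxon-pairs:

* Ψ — the number of distinct divergence times among the Y pairs, with a
  discrete-uniform prior on {1, …, Y}.  Ψ = 1 is simultaneous divergence.
* The τ assignment — Ψ times drawn i.i.d. from a uniform prior on
  (τ_lo, τ_hi); a uniformly chosen subset of Ψ pairs receives one distinct
  time each and the remaining Y − Ψ pairs draw from those Ψ times with
  replacement.  By construction every drawn time is used, so the assignment
  has exactly Ψ distinct values.
* Derived summaries: E(τ) = mean of the assignment and the dispersion index
  Ω = Var(τ)/E(τ), with Ω = 0 exactly when Ψ = 1.  Ω uses the population
  variance (denominator Y): any convention is fine for inference, but only
  the population form is exactly zero under simultaneous divergence, and one
  convention must be fixed for reproducibility.
* Z — a categorical indicator over candidate migration models (e.g.
  isolation, Nm ∈ (0,1), Nm ∈ (0,10)), uniform a priori.

Per taxon-pair (all independently uniform): ancestral size θ_A; descendant
sizes at the split θ_A1, θ_A2 (parameterized as uniform fractions of θ_A);
current descendant sizes θ_B1, θ_B2; growth-onset times τ_B1, τ_B2
(parameterized as uniform fractions of τ so that τ_Bi ≤ τ holds by
construction — the model itself gives no explicit prior for these times);
and the symmetric migration rate Nm drawn from the range of the active
migration model.  All θ are per-site population mutation rates (4Nμ).

Per locus: a relative substitution-rate scalar drawn from
Gamma(shape = α, scale = 1/α), so the mean scalar is 1; one α per simulated
data set is drawn from Uniform(1, 20) and shared across its loci, making
rate heterogeneity a data-set-level uncertainty.  A fixed per-locus
inheritance scalar (e.g. 0.25 for mtDNA) multiplies the locus θ.

## Coalescent simulator and units

Each locus genealogy is simulated backward in time under a two-deme
structured coalescent: exponential size change in each descendant deme from
its current size back to its size at the split (piecewise-exponential, with
waiting times drawn by closed-form inversion of the integrated hazard — no
time discretization), symmetric migration until τ, then a single ancestral
deme.  Loci are unlinked; recombination, selection, and indels are not
modelled.

The unit convention is fixed once and pinned by a calibration test: time is
in units of 4·N_ref generations with θ_ref = θ_B1 + θ_B2 (so N_ref is the
sum of current descendant sizes, the scale on which τ is specified).  A deme
of size θ_d has relative size x_d = θ_d/θ_ref, within-deme pair-coalescence
rate 2/x_d, per-lineage backward migration rate 4·Nm/x_d (at the
time-zero size), and mutations accrue at θ_ref·scalars expected
substitutions per site per unit time.  Under this convention a single
population of parameter θ satisfies E[pairwise differences per site] = θ in
the infinite-sites limit, which the test suite verifies by simulation, and
the strong-migration limit of the two demes is a panmictic population of
size θ_B1 + θ_B2 (also verified, against both a panmictic run of the same
engine and msprime).

Finite-sites mutation uses JC, F81 (the default) or HKY.  Rate matrices are
normalized to one expected substitution per site per unit branch distance;
branches are simulated exactly by uniformization (Poisson number of
candidate events at the maximal leaving rate, applied sequentially per site
through the jump chain), so repeat hits accumulate and the per-branch
marginal equals exp(Qd).  A direct chi-square test against the closed-form
transition matrix verifies this.

## Summary statistics

Per locus, three categories of statistic classes are available: pooled and
per-population π, Watterson's θ_W, SD(π − θ_W), Shannon's index on haplotype
frequencies, and Wakeley's within-population correlation s of difference
counts over sequence pairs sharing a member; and between populations π_b,
π_net = π_b − (π_1 + π_2)/2, and Wakeley's interpopulation correlations
s_XY and Ψ_W, which respond to whether deep cross-population coalescences
are shared (isolation) or broken up (migration).

Numerical conventions, chosen once and recorded in the table manifest:

* π and θ_W are per-locus difference counts, not per-site rates; the π_b
  ordering and the moments are scale-consistent either way and counts avoid
  a division convention on filtered alignment lengths.
* SD(π − θ_W) uses the Tajima (1989) moment estimator
  Var = e₁S + e₂S(S−1), a function of (n, S) only — the numerator
  normalization of Tajima's D — since no explicit formula is attached to the
  statistic's verbal definition.
* The exact published algebra of Ψ_W is not reproduced in the source the
  statistic comes from; s_XY is implemented as the Pearson correlation over
  all (symmetrized) cross-population pair-of-pairs sharing one sequence, and
  Ψ_W as the companion intraclass form normalized by the variance of
  difference counts over all cross pairs.  Both are label-symmetric and are
  cross-checked against explicit-loop brute force in the tests.
* Zero-variance (monomorphic) alignments give 0, not a mask, for the
  correlation statistics, keeping the vector layout stable.
* Masking is a pure function of sample sizes (e.g. within-population classes
  need n ≥ 2; s needs n ≥ 3; Ψ_W needs n1+n2 ≥ 3), never of the data, so
  observed and simulated vectors always mask identically.  Masked loci are
  excluded from moment averages.

For one data set the per-locus values form the ragged tensor D (class ×
pair × locus).  D is reduced to D_m by the first k ≤ 4 raw moments across
each pair's loci, and all classes' pair-axes are then permuted jointly into
descending order of the first moment of π_b (stable on ties).  Expected π_b
is exchangeable across pairs and increases with each pair's τ, so this sort
removes the arbitrary input ordering from the Euclidean distance — the
property the sorting experiment quantifies.  Most experiments use the
single class π_b with the first moment only; model choice adds the first
moment of Ψ_W.

## ABC

Reference-table coordinates are scaled to unit sample variance
(zero-variance coordinates are dropped and logged), the observed vector is
scaled identically, and the n_accept rows with smallest Euclidean distance
are accepted (stable ties).  Continuous hyper-parameters are adjusted by
local-linear regression: Epanechnikov weights with bandwidth equal to the
largest accepted distance, weighted least squares of the target on the
summary offsets, adjusted value θ*ᵢ = θᵢ − (Dᵢ − D*)·b, truncated to the
prior support.  A singular design falls back to unadjusted values with a
warning.  Discrete indicators (Z, Ψ) use kernel-weighted multinomial
logistic regression with a ridge penalty of 1e-6 (deterministic behaviour
under quasi-separation) evaluated at zero offset; failure falls back to
weighted accepted frequencies.  Both raw accepted frequencies and
regression-adjusted probabilities are reported, since either may be wanted
downstream; Bayes factors default to the adjusted values.

Point estimates are posterior modes of a Gaussian KDE with Silverman
bandwidth, with boundary reflection when the support is bounded (Ω ≥ 0, so
a posterior concentrated at simultaneous divergence yields a mode at 0
rather than a boundary-biased positive value).  Model-averaged estimation
weights the joint accepted set by P(z)/n_z per model-z row, which is
equivalent to concatenating per-model accepted draws in proportion to their
posterior probabilities.

## Validation harness and problem sizes

PODS (pseudo-observed data sets) are simulated with known hyper-parameters
under the exact sampling configuration of the reference table; RMSE
(posterior modes vs truth across PODS) and RMSPE (accepted draws around the
truth, one per PODS) quantify estimator quality.  The harness reproduces
four designs: π_b-sorting vs configuration order (Y = 5, 10, 20,
simultaneous-divergence PODS), the number-of-loci trend (1–64 loci),
rate-heterogeneity misspecification, and migration-model choice (isolation
vs Nm < 1 vs Nm < 10, with/without Ψ_W, with/without polychotomous
regression).

Prior bounds used by the harness are explicit configuration with defaults
τ ∈ (0, 5), θ ∈ (0.0001, 0.01) per site, size fractions ∈ (0.1, 1) and
growth-time fractions ∈ (0, 1); absolute error levels therefore are
comparable across runs of this package but only in trend with other
implementations whose (unpublished) bounds may differ.

Default experiment sizes are desk-scale so a full validation sweep runs on
one CPU in minutes: reference tables of a few thousand to ~10⁴ rows,
30–50 PODS per condition, 200–500 accepted draws, 5 taxon-pairs with 4–8
loci of 500 bp and five sequences per population (the loci experiment
spans 1–64 loci).  These sizes preserve every qualitative contrast; a
faithful large-scale run (10⁶–3×10⁶ rows, 100 PODS, 16 loci of 1100 bp)
uses the same code paths with larger arguments and is hours of CPU time.

## What the generator does and does not emulate

The simulator produces exactly the data the model assumes: unlinked,
gap-free, recombination-free loci with known population labels and
gamma-distributed rate scalars.  Real data violate several of these
(intragenic recombination, alignment error and missing data, non-equilibrium
base composition, linked loci), so passing validation here demonstrates
correctness of the machinery and internal consistency of the statistical
procedure, not robustness to those violations.  Gapped or ambiguous
alignment columns in observed data are dropped listwise per locus before
statistics are computed, and the simulated locus length matches the
post-filter length.

## Known limitations

* Wakeley's Ψ_W and s_XY follow this package's reconstruction (documented
  above), not the original printed algebra; coordinates would shift under a
  different variant but the architecture and the model-choice contrast do
  not depend on the exact form.
* The simulator uses an internally consistent unit convention; absolute τ
  estimates from other coalescent implementations may differ by a constant
  scale factor.
* Migration rates are constant per lineage over (0, τ) at the time-zero
  deme size; size change during the growth phase does not modulate the
  migration intensity.
* No recombination, gene conversion, selection, or indels; at most two
  descendant populations per taxon-pair.
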