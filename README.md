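# codiv

Hierarchical approximate Bayesian computation (HABC) for testing
**simultaneous divergence and migration across codistributed taxon-pairs**
from multi-locus DNA sequence data.

## The problem

Comparative phylogeography repeatedly asks one question: did a set of Y
sister-population pairs that straddle the same barrier split at the same
time (one geo-climatic event) or at different times?  And did gene flow
continue after the split?  `codiv` answers it with a hierarchical
coalescent model: each taxon-pair y has its own demographic parameters
(ancestral size θ_A, descendant sizes θ_A1→θ_B1 and θ_A2→θ_B2 with
exponential growth, divergence time τ_y, symmetric migration rate Nm),
while hyper-parameters tie the pairs together:

* **Ψ** — the number of distinct divergence times among the Y pairs
  (discrete-uniform prior on 1..Y; Ψ = 1 ⇔ simultaneous divergence),
* **E(τ)** — the mean divergence time, in coalescent units of 4N
  generations (N = sum of current descendant sizes),
* **Ω = Var(τ)/E(τ)** — the dispersion index of divergence times
  (Ω = 0 ⇔ simultaneous divergence),
* **Z** — an indicator over candidate migration models (e.g. isolation,
  Nm ∈ (0,1), Nm ∈ (0,10)).

The likelihood is intractable, so inference is simulation-based: millions
of data sets are simulated from the joint prior under the *exact sampling
configuration* of the observed data (same pairs, loci, sample sizes,
lengths — different numbers of loci of varying length per pair are fine),
each is reduced to a summary vector **D_m**, and the draws whose vectors
fall closest to the observed **D_m\*** (unit-variance Euclidean distance)
form the posterior sample, sharpened by local-linear regression
(continuous hyper-parameters) or polychotomous logistic regression
(Ψ, Z).

Per locus the package computes π, Watterson's θ_W, SD(π − θ_W), Shannon's
haplotype diversity, Wakeley's correlation statistics (s, s_XY, Ψ_W), and
the between-population π_b and π_net.  The per-locus tensor **D** (class ×
pair × locus) is reduced to **D_m** by the first ≤ 4 raw moments across
loci, and the taxon-pair axis is sorted by descending mean π_b — an
exchangeability trick that makes the distance independent of the arbitrary
input ordering of the pairs and substantially tightens estimation of Ω.
Wakeley's Ψ_W, designed to separate migration from isolation, drives the
migration-model choice.

## Worked example

Simulate a pseudo-observed data set of three taxon-pairs (four 500-bp loci
each, four sequences per population) under a *known simultaneous*
divergence history, then infer the hyper-parameters from a fresh
4000-row reference table:

```python
import numpy as np
from codiv import PriorSpec, uniform_config, draw_hyper, simulate_dataset
from codiv.pipeline import build_reference_table, estimate_hyperparameters
from codiv.sumstats import moment_vector

rng = np.random.default_rng(42)
config = uniform_config(n_pairs=3, n_loci=4, n1=4, n2=4, length=500,
                        subst_model="JC")
prior = PriorSpec(tau_range=(0.0, 5.0))

truth = draw_hyper(config, PriorSpec(psi_fixed=1), rng)
observed = moment_vector(simulate_dataset(truth, config, rng))
print(f"true E(tau) = {truth.e_tau:.3f}, true Omega = {truth.omega:.3f}, "
      f"true Psi = {truth.psi}")

table = build_reference_table(config, prior, n_rows=4000, rng=rng)
result = estimate_hyperparameters(table, observed.flatten(), n_accept=300,
                                  tau_range=prior.tau_range)
print(f"posterior mode E(tau) = {result['e_tau_mode']:.3f}")
print(f"posterior mode Omega  = {result['omega_mode']:.3f}")
```

Output:

```
true E(tau) = 3.870, true Omega = 0.000, true Psi = 1
posterior mode E(tau) = 5.000
posterior mode Omega  = 0.000
Pr(Psi = k | D*)      = {1: 0.607, 2: 0.261, 3: 0.132}
B(Psi=1, Psi>1)       = 3.09
```

The Ω mode of 0.0 and the Ψ posterior concentrated on 1 recover the
simultaneous-divergence truth (Bayes factor 3.09 relative to the uniform
prior over Ψ); the E(τ) mode sits at the upper prior bound because the
true mean divergence time (3.87) is deep relative to the τ ∈ (0, 5)
prior, where the mode is only weakly identified from three pairs of four
short loci.

A command-line interface mirrors the library for shell-driven runs:
`codiv obs-stats`, `codiv simulate`, `codiv estimate`,
`codiv validate-model-choice`, `codiv validate-sorting` (see `--help`).
Observed data can be FASTA (population tagged `pop=1|2` in the
description line) or IM-format files; gapped/ambiguous alignment columns
are dropped before analysis.

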