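"""Structured-coalescent simulation of taxon-pair loci with finite-sites mutation.

Demography (per taxon-pair, looking backward in time): two descendant demes
whose sizes change exponentially from their current values (θ_B1, θ_B2) back
to the sizes at the split (θ_A1, θ_A2), reached at the growth-onset times
(τ_B1, τ_B2) and constant earlier; symmetric migration between the demes at
Nm migrants per generation until the divergence time τ; at τ all lineages
merge into a single ancestral deme of constant size θ_A.

Unit convention (used consistently everywhere and pinned by the calibration
test E[π per site] = θ in the single-population limit):

* time is measured in units of 4·N_ref generations, where the reference size
  is the sum of current descendant sizes, θ_ref = θ_B1 + θ_B2 (so τ is on
  the scale the hyper-prior draws it on);
* a deme of per-site size θ_d has relative size x_d = θ_d / θ_ref and
  within-deme coalescence rate 2/x_d per lineage pair per unit time;
* each lineage in deme d migrates backward at rate 4·Nm / x_d per unit time
  (x_d evaluated at the current, time-zero size), for t < τ;
* mutations occur along each lineage at θ_eff = θ_ref · rate_scalar ·
  inheritance_scalar expected substitutions per site per unit time.

Waiting times inside exponential-growth epochs are drawn exactly by
inverting the integrated coalescent hazard in closed form (no time
stepping).  Substitution models (JC, F81, HKY) are applied exactly via their
transition-probability matrices, so multiple hits at a site are implicit
(finite sites).  Loci are unlinked: each gets an independent genealogy.
Intragenic recombination is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .config_io import LocusAlignment, SamplingConfig
from .hyperprior import HyperDraw, LocusParams, TaxonParams

__all__ = [
    "Genealogy",
    "SimulatedDataset",
    "simulate_genealogy",
    "mutate_sequences",
    "simulate_dataset",
    "transition_matrix",
]


@dataclass
class Genealogy:
    """Binary coalescent tree over n1 + n2 tips.

    Tips 0..n1-1 belong to population 1, tips n1..n1+n2-1 to population 2.
    ``parent[i]`` is the parent node of i (-1 for the root) and ``time[i]``
    its height; internal nodes are n..2n-2 in order of creation, so node
    times are non-decreasing along that range.
    """

    parent: np.ndarray
    time: np.ndarray
    n1: int
    n2: int

    @property
    def n_tips(self) -> int:
        return self.n1 + self.n2

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    @property
    def root(self) -> int:
        return len(self.time) - 1

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.time[p] - self.time[node]) if p >= 0 else 0.0

    def total_branch_length(self) -> float:
        p = self.parent
        has_parent = p >= 0
        return float((self.time[p[has_parent]] - self.time[has_parent.nonzero()[0]]).sum())

    def first_cross_population_coalescence(self) -> float:
        """Time of the earliest node whose descendants span both populations.

        Returns ``inf`` when one population is unsampled.
        """
        if self.n1 == 0 or self.n2 == 0:
            return math.inf
        n = self.n_tips
        has_pop1 = np.zeros(2 * n - 1, dtype=bool)
        has_pop2 = np.zeros(2 * n - 1, dtype=bool)
        has_pop1[: self.n1] = True
        has_pop2[self.n1: n] = True
        best = math.inf
        for node in np.argsort(self.time[n:], kind="stable") + n:
            kids = np.nonzero(self.parent == node)[0]
            has_pop1[node] = has_pop1[kids].any()
            has_pop2[node] = has_pop2[kids].any()
            if has_pop1[node] and has_pop2[node]:
                best = min(best, float(self.time[node]))
        return best


@dataclass
class SimulatedDataset:
    """Alignments for every locus of every taxon-pair plus their generating draw."""

    alignments: list[list[LocusAlignment]]  # [pair][locus]
    hyper: HyperDraw | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.alignments)


def _exp_epoch_waiting_time(c: float, x0: float, beta: float, unit_exp: float) -> float:
    """Invert the integrated hazard for rate c / (x0 · e^{β s}).

    Returns the waiting time s solving ∫_0^s c / x(u) du = unit_exp, where
    x(u) = x0·e^{βu}; ``inf`` when the integral never reaches unit_exp.
    """
    if c <= 0:
        return math.inf
    if beta == 0.0:
        return unit_exp * x0 / c
    arg = 1.0 - unit_exp * beta * x0 / c
    if arg <= 0.0:  # only possible for β > 0: hazard integral saturates
        return math.inf
    return -math.log(arg) / beta


class _DemeSize:
    """Backward-time relative size of one descendant deme (piecewise exp)."""

    def __init__(self, theta_b: float, theta_a_split: float, tau_b: float,
                 theta_ref: float):
        self.x_now = theta_b / theta_ref
        self.x_split = theta_a_split / theta_ref
        if tau_b > 0 and theta_b > 0 and theta_a_split > 0:
            self.tau_b = tau_b
            self.beta = math.log(theta_a_split / theta_b) / tau_b
        else:
            # degenerate growth phase: constant at the split-time size (or,
            # if that is zero, at the current size) throughout
            self.tau_b = 0.0
            self.beta = 0.0
            if self.x_split > 0:
                self.x_now = self.x_split
            else:
                self.x_split = self.x_now

    def at(self, t: float) -> tuple[float, float]:
        """Relative size and local exponential rate β at backward time t."""
        if t < self.tau_b:
            return self.x_now * math.exp(self.beta * t), self.beta
        return self.x_split, 0.0


def simulate_genealogy(
    params: TaxonParams,
    n1: int,
    n2: int,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Simulate one locus genealogy under divergence-with-migration-and-growth."""
    rng = np.random.default_rng(rng)
    n = n1 + n2
    if n < 2:
        raise ValueError("need at least two sampled sequences")
    theta_ref = params.theta_b1 + params.theta_b2
    if theta_ref <= 0:
        raise ValueError("current descendant sizes must not both be zero")

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    demes = [list(range(n1)), list(range(n1, n))]
    sizes = [
        _DemeSize(params.theta_b1, params.theta_a1, params.tau_b1, theta_ref),
        _DemeSize(params.theta_b2, params.theta_a2, params.tau_b2, theta_ref),
    ]
    # per-lineage backward migration rates, constant before tau
    mig = [0.0, 0.0]
    if params.nm > 0:
        for d in (0, 1):
            x0 = sizes[d].x_now
            mig[d] = 4.0 * params.nm / x0 if x0 > 0 else 0.0

    tau = params.tau
    next_node = n
    t = 0.0
    n_active = n

    def coalesce(deme_lineages: list[int], when: float) -> None:
        nonlocal next_node, n_active
        k = len(deme_lineages)
        i = int(rng.random() * k)
        j = int(rng.random() * (k - 1))
        if j >= i:
            j += 1
        a, b = deme_lineages[i], deme_lineages[j]
        parent[a] = parent[b] = next_node
        time[next_node] = when
        if i < j:
            i, j = j, i
        deme_lineages.pop(i)
        deme_lineages.pop(j)
        deme_lineages.append(next_node)
        next_node += 1
        n_active -= 1

    # --- two-deme phase (t < tau) -----------------------------------------
    while n_active > 1 and t < tau:
        breaks = [b for b in (sizes[0].tau_b, sizes[1].tau_b, tau) if b > t]
        t_end = min(breaks)
        # candidate waiting times from t within this interval
        best_s, best_kind = math.inf, None
        for d in (0, 1):
            k = len(demes[d])
            if k >= 2:
                x_t, beta = sizes[d].at(t)
                if x_t <= 0:
                    best_s, best_kind = 0.0, ("coal", d)
                    break
                s = _exp_epoch_waiting_time(
                    float(k * (k - 1)), x_t, beta, rng.standard_exponential()
                )
                if s < best_s:
                    best_s, best_kind = s, ("coal", d)
        rate_m = len(demes[0]) * mig[0] + len(demes[1]) * mig[1]
        if rate_m > 0:
            s = rng.standard_exponential() / rate_m
            if s < best_s:
                best_s, best_kind = s, ("mig", None)
        if t + best_s >= t_end:
            t = t_end
            continue
        t += best_s
        kind, d = best_kind
        if kind == "coal":
            coalesce(demes[d], t)
        else:
            w0 = len(demes[0]) * mig[0]
            src = 0 if rng.random() * rate_m < w0 else 1
            idx = int(rng.integers(len(demes[src])))
            demes[1 - src].append(demes[src].pop(idx))

    # --- ancestral phase (t >= tau) ---------------------------------------
    if n_active > 1:
        t = max(t, tau)
        pool = demes[0] + demes[1]
        x_a = params.theta_a / theta_ref
        while len(pool) > 1:
            k = len(pool)
            if x_a > 0:
                t += rng.exponential(x_a / (k * (k - 1)))
            coalesce(pool, t)

    return Genealogy(parent=parent, time=time, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Finite-sites mutation

def transition_matrix(model: str, d: float, base_freqs, kappa: float = 2.0) -> np.ndarray:
    """4x4 substitution probability matrix after d expected substitutions/site.

    The generator is normalized so that one unit of d equals one expected
    substitution per site at stationarity.  JC and F81 use their closed
    forms; HKY uses the matrix exponential of the normalized rate matrix.
    State order is A, C, G, T.
    """
    if d < 0:
        raise ValueError("branch distance must be >= 0")
    pi = np.asarray(base_freqs, dtype=float)
    if pi.shape != (4,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-9:
        raise ValueError("invalid base frequencies")
    if model == "JC":
        e = math.exp(-4.0 * d / 3.0)
        p_same = 0.25 + 0.75 * e
        p_diff = 0.25 - 0.25 * e
        P = np.full((4, 4), p_diff)
        np.fill_diagonal(P, p_same)
        return P
    if model == "F81":
        scale = 1.0 - float(pi @ pi)
        if scale <= 0:  # degenerate frequencies: no substitutions possible
            return np.eye(4)
        e = math.exp(-d / scale)
        return e * np.eye(4) + (1.0 - e) * np.tile(pi, (4, 1))
    if model == "HKY":
        # transitions A<->G and C<->T up-weighted by kappa
        Q = np.tile(pi, (4, 1)).astype(float)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
            Q[i, j] *= kappa
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(pi @ np.diag(Q))
        if mu <= 0:
            return np.eye(4)
        return expm(Q * (d / mu))
    raise ValueError(f"unknown substitution model {model!r}")


def _normalized_generator(model: str, base_freqs, kappa: float) -> np.ndarray:
    """Rate matrix scaled to one expected substitution per site per unit time."""
    pi = np.asarray(base_freqs, dtype=float)
    if model == "JC":
        Q = np.full((4, 4), 1.0 / 3.0)
    elif model == "F81":
        Q = np.tile(pi, (4, 1)).copy()
    elif model == "HKY":
        Q = np.tile(pi, (4, 1)).astype(float)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
            Q[i, j] *= kappa
    else:
        raise ValueError(f"unknown substitution model {model!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        return np.zeros((4, 4))
    return Q / mu


def _jump_chain(Q: np.ndarray) -> tuple[float, np.ndarray]:
    """Uniformization of Q: event rate λ and cumulative jump probabilities.

    Events occur at the state-independent Poisson rate λ = max leaving rate;
    an event in state i jumps according to row i of I + Q/λ (self-jumps
    realize the slower states), which reproduces exp(Qt) exactly.
    """
    lam = float(-np.diag(Q).min())
    if lam <= 0:
        return 0.0, np.eye(4).cumsum(axis=1)
    J = np.eye(4) + Q / lam
    cum = J.cumsum(axis=1)
    cum[:, 3] = 1.0
    return lam, cum


def mutate_sequences(
    genealogy: Genealogy,
    length: int,
    theta_per_site: float,
    locus: LocusParams,
    rng: np.random.Generator | None = None,
    pair_id: str = "",
    locus_id: str = "",
) -> LocusAlignment:
    """Overlay finite-sites mutations on a genealogy and emit the alignment.

    The root sequence is drawn from the stationary base frequencies; each
    branch applies the substitution model's exact transition matrix for
    branch distance θ_eff · branch_length with
    θ_eff = θ_per_site · rate_scalar · inheritance_scalar.
    """
    rng = np.random.default_rng(rng)
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if theta_per_site < 0:
        raise ValueError("theta must be >= 0")
    rate = theta_per_site * locus.rate_scalar * locus.inheritance_scalar
    pi = np.asarray(locus.base_freqs, dtype=float)
    n_nodes = len(genealogy.time)
    seqs = np.empty((n_nodes, length), dtype=np.uint8)

    cum_pi = np.cumsum(pi)
    root = genealogy.root
    seqs[root] = (rng.random(length)[:, None] > cum_pi[:3]).sum(axis=1)

    lam, cum_jump = _jump_chain(
        _normalized_generator(locus.subst_model, pi, locus.kappa)
    )
    # parents strictly precede children in descending node-time order
    order = np.argsort(-genealogy.time, kind="stable")
    for node in order:
        p = genealogy.parent[node]
        if p < 0:
            continue
        d = rate * (genealogy.time[p] - genealogy.time[node])
        seqs[node] = seqs[p]
        if d == 0.0 or lam == 0.0:
            continue
        # exact finite-sites simulation by uniformization: Poisson number of
        # candidate events over the branch, applied sequentially per site so
        # repeat hits accumulate
        n_events = rng.poisson(lam * d * length)
        if n_events == 0:
            continue
        sites = rng.integers(0, length, size=n_events)
        jumps = rng.random(n_events)
        row = seqs[node]
        for site, u in zip(sites, jumps):
            row[site] = np.searchsorted(cum_jump[row[site]], u, side="right")

    n = genealogy.n_tips
    labels = np.r_[np.ones(genealogy.n1, dtype=np.int8),
                   np.full(genealogy.n2, 2, dtype=np.int8)]
    return LocusAlignment(seqs[:n], labels, pair_id=pair_id, locus_id=locus_id)


def simulate_dataset(
    hyper: HyperDraw,
    config: SamplingConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Simulate every locus of every taxon-pair for one hyper-prior draw.

    Loci are unlinked: each gets an independent genealogy under the pair's
    demography (with its τ from the Ψ-assignment) and its own rate scalar.
    """
    rng = np.random.default_rng(rng)
    if len(hyper.taxa) != config.n_pairs or len(hyper.loci) != config.n_pairs:
        raise ValueError("hyper draw and sampling configuration disagree on Y")
    out: list[list[LocusAlignment]] = []
    for y, locus_cfgs in enumerate(config.pairs):
        taxon = hyper.taxa[y]
        if len(hyper.loci[y]) != len(locus_cfgs):
            raise ValueError(f"pair {y}: locus count mismatch")
        theta_ref = taxon.theta_b1 + taxon.theta_b2
        pair_alns = []
        for j, lc in enumerate(locus_cfgs):
            gene = simulate_genealogy(taxon, lc.n1, lc.n2, rng)
            aln = mutate_sequences(
                gene, lc.length, theta_ref, hyper.loci[y][j], rng,
                pair_id=config.pair_names[y],
                locus_id=lc.name or f"locus{j + 1}",
            )
            pair_alns.append(aln)
        out.append(pair_alns)
    return SimulatedDataset(alignments=out, hyper=hyper)


def write_fasta(alignment: LocusAlignment, sink) -> None:
    """Emit a simulated alignment in the package's FASTA dialect (pop= tags)."""
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        for i, (seq, pop) in enumerate(zip(alignment.sequences, alignment.pop_labels)):
            fh.write(f">{alignment.pair_id or 'pair'}_{i + 1} pop={pop}\n{seq}\n")
    finally:
        if own:
            fh.close()
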