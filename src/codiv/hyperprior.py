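"""Draws from the hierarchical prior over divergence histories.

One draw fixes a complete multi-taxon history: a migration-model indicator Z,
the number of distinct divergence times Ψ (discrete-uniform on 1..Y), the
assignment of those Ψ times to the Y taxon-pairs, per-taxon demographic
parameters, and per-locus substitution-rate scalars (gamma distributed with
shape α drawn from its own uniform hyper-prior, mean 1).

The τ-assignment algorithm: Ψ times are drawn i.i.d. from the uniform τ
prior; a uniformly chosen subset of Ψ taxon-pairs receives one distinct time
each, and the remaining Y − Ψ pairs sample from the Ψ times with
replacement.  Every drawn time is therefore used by at least one pair and
the number of distinct values in the assignment equals Ψ exactly (ties among
continuous draws have probability zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config_io import PriorSpec, SamplingConfig

__all__ = [
    "TaxonParams",
    "LocusParams",
    "HyperDraw",
    "draw_psi_and_tau",
    "draw_taxon_params",
    "draw_locus_scalars",
    "draw_model_indicator",
    "draw_hyper",
]


@dataclass(frozen=True)
class TaxonParams:
    """Demographic parameters of one taxon-pair.

    θ values are per-site scaled population sizes (4Nμ); times are in
    coalescent units of 4N generations with N the sum of current descendant
    sizes.  Looking forward in time the ancestral population (θ_A) splits at
    τ into descendants of initial sizes θ_A1, θ_A2 which grow exponentially
    to current sizes θ_B1, θ_B2 starting at times τ_B1, τ_B2; Nm symmetric
    migrants per generation are exchanged between the descendants after the
    split (Nm = 0 under isolation).
    """

    theta_a: float
    theta_a1: float
    theta_a2: float
    theta_b1: float
    theta_b2: float
    tau: float
    tau_b1: float
    tau_b2: float
    nm: float = 0.0

    def __post_init__(self):
        for name in ("theta_a", "theta_a1", "theta_a2", "theta_b1", "theta_b2",
                     "tau", "tau_b1", "tau_b2", "nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_b1 > self.tau or self.tau_b2 > self.tau:
            raise ValueError("growth onset times must not exceed tau")


@dataclass(frozen=True)
class LocusParams:
    """Per-locus mutation parameters (rate scalar plus configured model)."""

    rate_scalar: float
    inheritance_scalar: float = 1.0
    subst_model: str = "F81"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.rate_scalar <= 0:
            raise ValueError("rate_scalar must be > 0")


@dataclass
class HyperDraw:
    """One complete draw from the hierarchical prior."""

    z: int
    model_label: str
    psi: int
    tau_assign: np.ndarray          # length Y, units of 4N generations
    taxa: list[TaxonParams]
    loci: list[list[LocusParams]]   # loci[y][j]
    alpha: float

    @property
    def e_tau(self) -> float:
        return float(np.mean(self.tau_assign))

    @property
    def omega(self) -> float:
        """Dispersion index Var(τ)/E(τ); population variance, 0 when Ψ=1."""
        mean = self.e_tau
        if mean == 0 or np.ptp(self.tau_assign) == 0:
            return 0.0
        return float(np.var(self.tau_assign) / mean)


def draw_psi_and_tau(
    n_pairs: int,
    tau_range: tuple[float, float],
    psi_fixed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Draw Ψ and the length-Y vector of divergence times."""
    rng = np.random.default_rng(rng)
    if n_pairs < 1:
        raise ValueError("need at least one taxon-pair")
    if psi_fixed is not None:
        if not (1 <= psi_fixed <= n_pairs):
            raise ValueError(f"psi_fixed={psi_fixed} outside [1, {n_pairs}]")
        psi = psi_fixed
    else:
        psi = int(rng.integers(1, n_pairs + 1))
    times = rng.uniform(tau_range[0], tau_range[1], size=psi)
    assign = np.empty(n_pairs)
    anchors = rng.choice(n_pairs, size=psi, replace=False)
    assign[anchors] = times
    rest = np.setdiff1d(np.arange(n_pairs), anchors, assume_unique=True)
    if rest.size:
        assign[rest] = times[rng.integers(0, psi, size=rest.size)]
    return psi, assign


def draw_taxon_params(
    prior: PriorSpec,
    tau: float,
    rng: np.random.Generator | None = None,
    migration_model=None,
) -> TaxonParams:
    """Draw one taxon-pair's demographic parameters given its τ."""
    rng = np.random.default_rng(rng)
    theta_a = rng.uniform(*prior.theta_a_range)
    f1, f2 = rng.uniform(*prior.size_fraction_range, size=2)
    theta_b1, theta_b2 = rng.uniform(*prior.theta_b_range, size=2)
    g1, g2 = rng.uniform(*prior.growth_time_fraction_range, size=2)
    if migration_model is None:
        migration_model = prior.migration_models[0]
    nm = (
        0.0
        if migration_model.is_isolation
        else float(rng.uniform(migration_model.nm_lo, migration_model.nm_hi))
    )
    return TaxonParams(
        theta_a=theta_a,
        theta_a1=theta_a * f1,
        theta_a2=theta_a * f2,
        theta_b1=theta_b1,
        theta_b2=theta_b2,
        tau=tau,
        tau_b1=tau * g1,
        tau_b2=tau * g2,
        nm=nm,
    )


def draw_locus_scalars(
    alpha_range: tuple[float, float],
    n_loci: int,
    rate_het_enabled: bool = True,
    fixed_scalars=None,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Draw the gamma shape α and per-locus relative rate scalars.

    Scalars are i.i.d. Gamma(shape=α, scale=1/α), so the mean scalar is 1
    whatever α; larger α means less rate heterogeneity.  With rate
    heterogeneity disabled all scalars are 1; ``fixed_scalars`` (prior
    knowledge of relative rates, e.g. from outgroup comparisons) are used
    verbatim.
    """
    rng = np.random.default_rng(rng)
    if n_loci < 1:
        raise ValueError("need at least one locus")
    alpha = float(rng.uniform(*alpha_range))
    if fixed_scalars is not None:
        scalars = np.asarray(fixed_scalars, dtype=float)
        if scalars.shape != (n_loci,):
            raise ValueError(
                f"fixed_scalars has length {scalars.size}, expected {n_loci}"
            )
        if (scalars <= 0).any():
            raise ValueError("fixed scalars must be > 0")
        return alpha, scalars.copy()
    if not rate_het_enabled:
        return alpha, np.ones(n_loci)
    return alpha, rng.gamma(shape=alpha, scale=1.0 / alpha, size=n_loci)


def draw_model_indicator(migration_models, rng=None) -> int:
    """Pick a candidate migration model uniformly at random."""
    rng = np.random.default_rng(rng)
    models = list(migration_models)
    if not models:
        raise ValueError("no migration models configured")
    return int(rng.integers(0, len(models)))


def draw_hyper(
    config: SamplingConfig,
    prior: PriorSpec,
    rng: np.random.Generator | None = None,
    z: int | None = None,
) -> HyperDraw:
    """One complete draw: model, Ψ/τ assignment, taxa, locus scalars.

    One α is drawn per data set and shared by all its loci (the scalars vary
    per locus); ``z`` can be forced for PODS generation under a known model.
    """
    rng = np.random.default_rng(rng)
    if z is None:
        z = draw_model_indicator(prior.migration_models, rng)
    model = prior.migration_models[z]
    psi, tau_assign = draw_psi_and_tau(
        config.n_pairs, prior.tau_range, prior.psi_fixed, rng
    )
    alpha = float(rng.uniform(*prior.alpha_range))
    # all demographic parameters are drawn before any locus-level scalar so
    # that histories are reproducible across sampling configurations that
    # share a seed but differ in loci (paired validation designs)
    taxa = [
        draw_taxon_params(prior, float(tau_assign[y]), rng, model)
        for y in range(config.n_pairs)
    ]
    loci = []
    for y, locus_cfgs in enumerate(config.pairs):
        fixed = [lc.rate_scalar_fixed for lc in locus_cfgs]
        if any(f is not None for f in fixed):
            scalars = np.array([1.0 if f is None else f for f in fixed])
        elif prior.rate_het_enabled:
            scalars = rng.gamma(shape=alpha, scale=1.0 / alpha,
                                size=len(locus_cfgs))
        else:
            scalars = np.ones(len(locus_cfgs))
        loci.append(
            [
                LocusParams(
                    rate_scalar=float(s),
                    inheritance_scalar=lc.inheritance_scalar,
                    subst_model=lc.subst_model,
                    kappa=lc.kappa,
                    base_freqs=lc.base_freqs,
                )
                for s, lc in zip(scalars, locus_cfgs)
            ]
        )
    return HyperDraw(
        z=z,
        model_label=model.label,
        psi=psi,
        tau_assign=tau_assign,
        taxa=taxa,
        loci=loci,
        alpha=alpha,
    )
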