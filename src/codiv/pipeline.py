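"""Workflow glue: reference-table construction and observed-vector preparation.

The four-step workflow is (1) define the sampling configuration and
hyper-priors, (2) compute the observed moment vector D_m*, (3) simulate the
reference table of prior draws with matching sampling configuration, and
(4) run rejection/regression ABC of the hyper-parameters on the table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abc import (
    LocalLinearABC,
    PolychotomousABC,
    bayes_factor,
    posterior_mode,
)
from .coalsim import simulate_dataset
from .config_io import PriorSpec, ReferenceTable, SamplingConfig
from .hyperprior import draw_hyper
from .sumstats import (
    DEFAULT_CLASSES,
    build_summary_tensor,
    reduce_moments,
    stat_columns,
)

__all__ = [
    "build_reference_table",
    "build_reference_tables",
    "observed_vector",
    "subset_classes",
    "estimate_hyperparameters",
]


def _manifest(config, selection, n_moments, sort_by):
    return {
        "stat_columns": stat_columns(selection, config.n_pairs, n_moments),
        "classes": list(selection),
        "n_moments": n_moments,
        "sort_by": sort_by,
        "n_pairs": config.n_pairs,
        "pi_scale": "per-locus difference counts",
        "omega_variance": "population (denominator Y)",
    }


def build_reference_tables(
    config: SamplingConfig,
    prior: PriorSpec,
    n_rows: int,
    selection=DEFAULT_CLASSES,
    n_moments: int = 1,
    sort_modes=("pi_b",),
    rng=None,
) -> dict[str, ReferenceTable]:
    """Simulate a reference table once; emit one table per sort mode.

    The expensive part (coalescent simulation and per-locus statistics) is
    shared; only the cheap moment reduction is repeated per sort mode.
    """
    rng = np.random.default_rng(rng)
    records = []
    stats = {mode: np.empty((n_rows, len(selection) * config.n_pairs * n_moments))
             for mode in sort_modes}
    for i in range(n_rows):
        hyper = draw_hyper(config, prior, rng)
        dataset = simulate_dataset(hyper, config, rng)
        tensor = build_summary_tensor(dataset, selection)
        for mode in sort_modes:
            stats[mode][i] = reduce_moments(tensor, n_moments, mode).flatten()
        rec = {
            "z": hyper.z,
            "model": hyper.model_label,
            "psi": hyper.psi,
            "e_tau": hyper.e_tau,
            "omega": hyper.omega,
            "alpha": hyper.alpha,
        }
        for y, tau in enumerate(hyper.tau_assign):
            rec[f"tau_{y + 1}"] = float(tau)
        records.append(rec)
    params = pd.DataFrame.from_records(records)
    return {
        mode: ReferenceTable(params.copy(), stats[mode],
                             _manifest(config, selection, n_moments, mode))
        for mode in sort_modes
    }


def build_reference_table(
    config, prior, n_rows, selection=DEFAULT_CLASSES,
    n_moments: int = 1, sort_by: str = "pi_b", rng=None,
) -> ReferenceTable:
    """Simulate ``n_rows`` prior draws and collect (hyper-record, D_m) rows."""
    return build_reference_tables(
        config, prior, n_rows, selection, n_moments, (sort_by,), rng
    )[sort_by]


def observed_vector(
    alignments, config, selection=DEFAULT_CLASSES,
    n_moments: int = 1, sort_by: str = "pi_b",
):
    """Flattened observed D_m* plus the matching column manifest."""
    tensor = build_summary_tensor(alignments, selection)
    if tensor.n_pairs != config.n_pairs:
        raise ValueError("observed data and configuration disagree on Y")
    vec = reduce_moments(tensor, n_moments, sort_by).flatten()
    return vec, _manifest(config, selection, n_moments, sort_by)


def subset_classes(table: ReferenceTable, classes) -> ReferenceTable:
    """Restrict a reference table to a subset of its statistic classes."""
    manifest = table.manifest
    old = list(manifest["classes"])
    missing = [c for c in classes if c not in old]
    if missing:
        raise ValueError(f"classes not in table: {missing}")
    n_pairs = manifest["n_pairs"]
    n_moments = manifest["n_moments"]
    block = n_pairs * n_moments
    cols = []
    for c in classes:
        start = old.index(c) * block
        cols.extend(range(start, start + block))
    new_manifest = dict(manifest)
    new_manifest["classes"] = list(classes)
    new_manifest["stat_columns"] = stat_columns(classes, n_pairs, n_moments)
    return ReferenceTable(table.params, table.stats[:, cols], new_manifest)


def estimate_hyperparameters(
    table: ReferenceTable,
    observed: np.ndarray,
    n_accept: int = 500,
    tau_range=None,
    n_psi_categories: int | None = None,
    prior_model_probs=None,
    ridge: float = 1e-6,
) -> dict:
    """Full posterior summary at one observed vector.

    Returns posterior modes and accepted/adjusted draws for E(τ) and Ω,
    raw and regression-adjusted posteriors over Ψ and the model indicator,
    and the Bayes factor for simultaneous divergence, B(Ψ=1, Ψ>1).
    """
    y_cont = table.params[["e_tau", "omega"]].to_numpy()
    support = [
        (0.0, None if tau_range is None else tau_range[1]),
        (0.0, None),
    ]
    est = LocalLinearABC(n_accept, support=support).fit(table.stats, y_cont)
    post, adjusted = est.adjust(observed)
    out = {
        "accepted": table.params.iloc[post.indices].reset_index(drop=True),
        "distances": post.distances,
        "weights": post.weights,
        "e_tau_adjusted": adjusted[:, 0],
        "omega_adjusted": adjusted[:, 1],
        "e_tau_mode": posterior_mode(adjusted[:, 0], support[0]),
        "omega_mode": posterior_mode(adjusted[:, 1], support[1]),
    }

    psi_all = table.params["psi"].to_numpy()
    n_cat = n_psi_categories or int(psi_all.max())
    psi_est = PolychotomousABC(n_accept, ridge=ridge).fit(table.stats, psi_all)
    psi_probs = psi_est.predict_proba(observed)[0]
    out["psi_categories"] = psi_est.classes_
    out["psi_probs_adjusted"] = psi_probs
    out["psi_probs_raw"] = psi_est.raw_frequencies(observed)
    prior_p1 = 1.0 / n_cat
    p1 = float(psi_probs[psi_est.classes_ == 1][0]) if 1 in psi_est.classes_ else 0.0
    p1_raw = float(out["psi_probs_raw"][psi_est.classes_ == 1][0]) \
        if 1 in psi_est.classes_ else 0.0
    out["bayes_factor_psi1_adjusted"] = bayes_factor(min(p1, 1 - 1e-12), prior_p1) \
        if p1 > 0 else 0.0
    out["bayes_factor_psi1_raw"] = bayes_factor(min(p1_raw, 1 - 1e-12), prior_p1) \
        if p1_raw > 0 else 0.0

    z_all = table.params["z"].to_numpy()
    if np.unique(z_all).size > 1:
        z_est = PolychotomousABC(n_accept, ridge=ridge).fit(table.stats, z_all)
        out["model_categories"] = z_est.classes_
        out["model_probs_adjusted"] = z_est.predict_proba(observed)[0]
        out["model_probs_raw"] = z_est.raw_frequencies(observed)
    return out
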