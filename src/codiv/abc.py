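"""Rejection + regression ABC over reference tables of moment vectors.

The estimators follow the scikit-learn protocol (``fit`` on the reference
table, query at an observed summary vector) and compose with sklearn
tooling:

* :class:`ABCRejection` — scale every coordinate to unit variance across the
  reference table, accept the ``n_accept`` rows closest in Euclidean
  distance to the observation;
* :class:`LocalLinearABC` — rejection followed by Epanechnikov-weighted
  local-linear regression adjustment of continuous hyper-parameters,
  truncated to their prior support;
* :class:`PolychotomousABC` — rejection followed by kernel-weighted
  multinomial logistic regression of a discrete indicator (migration model,
  Ψ) on the summary offsets, evaluated at the observed point.

Module-level functions (`rejection_sample`, `loclinear_adjust`,
`polychotomous_adjust`, `posterior_mode`, `hyper_summaries`,
`bayes_factor`) are thin wrappers over the estimators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PosteriorSample",
    "ABCRejection",
    "LocalLinearABC",
    "PolychotomousABC",
    "standardize",
    "rejection_sample",
    "loclinear_adjust",
    "polychotomous_adjust",
    "posterior_mode",
    "hyper_summaries",
    "bayes_factor",
    "model_average_weights",
]


def standardize(stats: np.ndarray, observed: np.ndarray):
    """Scale reference-table coordinates to unit variance.

    Every coordinate is divided by its standard deviation across the table;
    the observation is scaled by the same factors.  Zero-variance
    coordinates carry no distance information and are dropped (their indices
    are returned for the log).
    """
    stats = np.asarray(stats, dtype=float)
    observed = np.asarray(observed, dtype=float).ravel()
    if stats.ndim != 2 or stats.shape[0] < 1:
        raise ValueError("reference statistics must be a non-empty 2-D array")
    if observed.shape[0] != stats.shape[1]:
        raise ValueError("observed vector length does not match the table")
    if stats.shape[0] < 2:
        raise ValueError("need at least two reference rows")
    sd = stats.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all summary coordinates have zero variance")
    return stats[:, keep] / sd[keep], observed[keep] / sd[keep], keep


def epanechnikov_weights(distances: np.ndarray) -> np.ndarray:
    """Epanechnikov kernel weights with bandwidth = largest distance."""
    d = np.asarray(distances, dtype=float)
    d_max = d.max()
    if d_max == 0:
        return np.ones_like(d)
    return 1.0 - (d / d_max) ** 2


@dataclass
class PosteriorSample:
    """Accepted draws with distances, kernel weights and adjusted values."""

    indices: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    offsets: np.ndarray                  # scaled (D_i - D*) of accepted rows
    adjusted: dict = field(default_factory=dict)
    category_probs: dict = field(default_factory=dict)

    @property
    def n_accept(self) -> int:
        return self.indices.size


class ABCRejection(BaseEstimator):
    """Nearest-neighbour rejection sampling on unit-variance Euclidean distance.

    Parameters
    ----------
    n_accept : int
        Number of reference rows accepted (closest to the observation).
    """

    def __init__(self, n_accept: int = 500):
        self.n_accept = n_accept

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least two rows")
        if not 1 <= self.n_accept <= X.shape[0]:
            raise ValueError("n_accept must be in [1, n_rows]")
        sd = X.std(axis=0, ddof=1)
        self.keep_ = sd > 0
        if not self.keep_.any():
            raise ValueError("all summary coordinates have zero variance")
        self.scale_ = sd[self.keep_]
        self.X_ = X[:, self.keep_] / self.scale_
        self.n_features_in_ = X.shape[1]
        return self

    def sample(self, observed) -> PosteriorSample:
        """Accept the n_accept rows closest to the observed vector."""
        check_is_fitted(self, "X_")
        obs = np.asarray(observed, dtype=float).ravel()
        if obs.shape[0] != self.n_features_in_:
            raise ValueError("observed vector length mismatch")
        obs = obs[self.keep_] / self.scale_
        offsets = self.X_ - obs
        distances = np.sqrt((offsets ** 2).sum(axis=1))
        order = np.argsort(distances, kind="stable")[: self.n_accept]
        d = distances[order]
        return PosteriorSample(
            indices=order,
            distances=d,
            weights=epanechnikov_weights(d),
            offsets=offsets[order],
        )


class LocalLinearABC(BaseEstimator, RegressorMixin):
    """Rejection ABC with local-linear regression adjustment.

    Fits ``y`` (continuous hyper-parameters, shape (n_rows, n_targets)) on
    the reference summaries; :meth:`adjust` returns the accepted values
    shifted along the locally fitted linear trend to the observed point,
    θ*_i = θ_i − (D_i − D*)·b, truncated to ``support`` when given.
    ``predict`` reports the weighted-KDE posterior mode per target.
    """

    def __init__(self, n_accept: int = 500, support=None):
        self.n_accept = n_accept
        self.support = support

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        X = np.asarray(X, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y row counts differ")
        self.rejection_ = ABCRejection(self.n_accept).fit(X)
        self.y_ = y
        self.n_targets_ = y.shape[1]
        return self

    def adjust(self, observed) -> tuple[PosteriorSample, np.ndarray]:
        """Accepted sample plus regression-adjusted target values."""
        check_is_fitted(self, "rejection_")
        post = self.rejection_.sample(observed)
        y_acc = self.y_[post.indices]
        adjusted = _local_linear(post.offsets, y_acc, post.weights)
        if self.support is not None:
            for j, bounds in enumerate(self.support):
                if bounds is None:
                    continue
                lo, hi = bounds
                if lo is not None:
                    adjusted[:, j] = np.maximum(adjusted[:, j], lo)
                if hi is not None:
                    adjusted[:, j] = np.minimum(adjusted[:, j], hi)
        post.adjusted = {j: adjusted[:, j] for j in range(adjusted.shape[1])}
        return post, adjusted

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.n_targets_))
        for i, obs in enumerate(X):
            _, adjusted = self.adjust(obs)
            for j in range(self.n_targets_):
                bounds = None
                if self.support is not None:
                    bounds = self.support[j]
                out[i, j] = posterior_mode(adjusted[:, j], bounds)
        return out[:, 0] if self.n_targets_ == 1 else out


def _local_linear(offsets, y_acc, weights):
    """Weighted least squares of targets on summary offsets; the adjusted
    values subtract the fitted linear trend evaluated at the offsets."""
    n, p = offsets.shape
    design = np.hstack([np.ones((n, 1)), offsets])
    sw = np.sqrt(weights)
    coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y_acc * sw[:, None],
                                       rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "singular local-linear design; returning unadjusted values",
            RuntimeWarning,
        )
        return y_acc.copy()
    slopes = coef[1:, :]
    return y_acc - offsets @ slopes


class PolychotomousABC(BaseEstimator, ClassifierMixin):
    """Rejection ABC with polychotomous (multinomial logistic) regression.

    For a discrete indicator (migration model Z, or Ψ) the accepted
    categories are regressed on the summary offsets with Epanechnikov
    weights and a small ridge penalty (deterministic handling of
    quasi-separation); the returned distribution is the model's prediction
    at the observed point, i.e. at zero offset.  Falls back to the
    kernel-weighted category frequencies if the regression cannot be fitted.
    """

    def __init__(self, n_accept: int = 500, ridge: float = 1e-6,
                 max_iter: int = 200):
        self.n_accept = n_accept
        self.ridge = ridge
        self.max_iter = max_iter

    def fit(self, X, y):
        y = np.asarray(y)
        X = np.asarray(X, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y row counts differ")
        self.rejection_ = ABCRejection(self.n_accept).fit(X)
        self.classes_ = np.unique(y)
        self.y_ = y
        return self

    def predict_proba(self, observed) -> np.ndarray:
        """Posterior category probabilities at the observed point.

        Accepts a single observed summary vector (or a stack of them) and
        returns probabilities over ``classes_``.
        """
        check_is_fitted(self, "rejection_")
        obs2d = np.atleast_2d(np.asarray(observed, dtype=float))
        out = np.empty((obs2d.shape[0], self.classes_.size))
        for i, obs in enumerate(obs2d):
            post = self.rejection_.sample(obs)
            out[i] = self._proba_at(post)
        return out

    def predict(self, observed):
        proba = self.predict_proba(observed)
        return self.classes_[np.argmax(proba, axis=1)]

    def raw_frequencies(self, observed) -> np.ndarray:
        """Unregressed accepted-category frequencies (unit weights)."""
        check_is_fitted(self, "rejection_")
        post = self.rejection_.sample(np.asarray(observed, dtype=float))
        y_acc = self.y_[post.indices]
        return np.array([(y_acc == c).mean() for c in self.classes_])

    def _proba_at(self, post: PosteriorSample) -> np.ndarray:
        y_acc = self.y_[post.indices]
        present = np.unique(y_acc)
        probs = np.zeros(self.classes_.size)
        if present.size == 1:
            probs[self.classes_ == present[0]] = 1.0
            return probs
        weights = post.weights
        positive = weights > 0
        if positive.sum() < present.size + 1 or np.unique(y_acc[positive]).size < 2:
            positive = np.ones_like(positive)
            weights = np.ones_like(weights)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                clf = LogisticRegression(
                    C=1.0 / self.ridge, max_iter=self.max_iter
                ).fit(post.offsets[positive], y_acc[positive],
                      sample_weight=weights[positive])
            p = clf.predict_proba(np.zeros((1, post.offsets.shape[1])))[0]
            for c, pc in zip(clf.classes_, p):
                probs[self.classes_ == c] = pc
            return probs
        except Exception:
            warnings.warn(
                "polychotomous regression failed; using weighted frequencies",
                RuntimeWarning,
            )
            wsum = weights.sum()
            for j, c in enumerate(self.classes_):
                probs[j] = weights[y_acc == c].sum() / wsum
            return probs


# ---------------------------------------------------------------------------
# Functional wrappers

def rejection_sample(stats, observed, n_accept) -> PosteriorSample:
    return ABCRejection(n_accept).fit(stats).sample(observed)


def loclinear_adjust(stats, targets, observed, n_accept, support=None):
    """Adjusted values of continuous targets; returns (sample, adjusted)."""
    est = LocalLinearABC(n_accept, support=support).fit(stats, targets)
    return est.adjust(observed)


def polychotomous_adjust(stats, categories, observed, n_accept, ridge=1e-6):
    """(classes, probabilities at the observed point)."""
    est = PolychotomousABC(n_accept, ridge=ridge).fit(stats, categories)
    return est.classes_, est.predict_proba(observed)[0]


def posterior_mode(values, support=None, weights=None) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) with boundary reflection.

    ``support=(lo, hi)`` reflects the sample about any finite bound before
    density estimation so the mode is not biased away from the boundary
    (e.g. Ω ≥ 0 under simultaneous divergence); either bound may be None.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no values given")
    if values.size == 1 or np.ptp(values) == 0:
        return float(values[0])
    lo, hi = (None, None) if support is None else support
    augmented = [values]
    wparts = [weights] if weights is not None else None
    if lo is not None and math.isfinite(lo):
        augmented.append(2 * lo - values)
        if wparts is not None:
            wparts.append(weights)
    if hi is not None and math.isfinite(hi):
        augmented.append(2 * hi - values)
        if wparts is not None:
            wparts.append(weights)
    sample = np.concatenate(augmented)
    w = np.concatenate(wparts) if wparts is not None else None
    try:
        kde = gaussian_kde(sample, bw_method="silverman", weights=w)
    except np.linalg.LinAlgError:
        return float(np.median(values))
    g_lo, g_hi = values.min(), values.max()
    if lo is not None and math.isfinite(lo):
        g_lo = max(g_lo, lo)
    if hi is not None and math.isfinite(hi):
        g_hi = min(g_hi, hi)
    if g_hi <= g_lo:
        return float(g_lo)
    grid = np.linspace(g_lo, g_hi, 512)
    return float(grid[np.argmax(kde(grid))])


def hyper_summaries(tau_assign):
    """(E(τ), Ω, Ψ) of a divergence-time assignment.

    Ω uses the population variance (denominator Y), so Ω is exactly 0 when
    all τ coincide; Ω is defined as 0 when E(τ) = 0.
    """
    tau = np.asarray(tau_assign, dtype=float)
    if tau.ndim != 1 or tau.size == 0:
        raise ValueError("tau_assign must be a non-empty 1-D vector")
    if (tau < 0).any():
        raise ValueError("divergence times must be >= 0")
    e_tau = float(tau.mean())
    omega = (
        0.0 if e_tau == 0 or np.ptp(tau) == 0 else float(np.var(tau) / e_tau)
    )
    psi = int(np.unique(tau).size)
    return e_tau, omega, psi


def bayes_factor(posterior_p: float, prior_p: float) -> float:
    """Bayes factor from posterior and prior probabilities of a hypothesis.

    B = [p/(1−p)] / [q/(1−q)].  Boundary posterior probabilities signal
    infinite (p = 1) or zero (p = 0) support explicitly.
    """
    if not 0 < prior_p < 1:
        raise ValueError("prior probability must be strictly inside (0, 1)")
    if posterior_p <= 0:
        return 0.0
    if posterior_p >= 1:
        return math.inf
    prior_odds = prior_p / (1 - prior_p)
    return (posterior_p / (1 - posterior_p)) / prior_odds


def model_average_weights(model_labels, model_probs) -> np.ndarray:
    """Per-row weights that realize model-averaged posterior estimation.

    Given accepted rows from several models and posterior model
    probabilities, weighting row i of model z by P(z)/n_z makes the weighted
    accepted set equivalent to concatenating per-model accepted draws in
    proportion to their posterior probabilities.
    """
    labels = np.asarray(model_labels)
    weights = np.zeros(labels.size, dtype=float)
    for z, p in model_probs.items():
        mask = labels == z
        if mask.any() and p > 0:
            weights[mask] = p / mask.sum()
    total = weights.sum()
    if total <= 0:
        raise ValueError("no accepted rows carry posterior model probability")
    return weights / total
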