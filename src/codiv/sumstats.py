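"""Per-locus summary statistics, the tensor D and its moment reduction D_m.

Three categories of per-locus statistic classes are available:

1. whole-sample statistics treating the taxon-pair as one pooled sample
   (``pi.pool``, ``thetaW.pool``, ``sd_pi_thetaW.pool``, ``shannon.pool``,
   ``wakeley_s.pool``);
2. the same statistics on each descendant population sample (suffixes
   ``.1`` / ``.2``);
3. between-population statistics: ``pi_b`` and ``pi_net`` (total and net
   average cross-population pairwise differences) and Wakeley's
   interpopulation correlation coefficients ``wakeley_sxy`` and
   ``wakeley_psiW``, informative for distinguishing migration from
   isolation.

All π and θ_W values are on the per-locus (count) scale.  Statistics
undefined at a locus's sample sizes are masked; the mask is a pure function
of the sampling configuration, so observed and simulated vectors always mask
identically.  Monomorphic (zero-variance) alignments yield 0, not a mask,
for the correlation-type statistics.

For each data set the per-locus values form a ragged tensor D indexed
(statistic class, taxon-pair, locus); D is reduced to D_m by taking the
first raw moments (up to four) of each class across a pair's loci, and the
taxon-pair axis is re-ordered by descending mean ``pi_b``.  Because expected
``pi_b`` is exchangeable across sampling configurations and tracks each
pair's divergence time, this sort makes the Euclidean distance between
moment vectors independent of the arbitrary input order of taxon-pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config_io import LocusAlignment, SamplingConfig

__all__ = [
    "STAT_CLASSES",
    "DEFAULT_CLASSES",
    "SummaryTensor",
    "MomentVector",
    "pairwise_diff_stats",
    "watterson",
    "sd_pi_theta",
    "shannon",
    "wakeley_stats",
    "locus_stats",
    "build_summary_tensor",
    "reduce_moments",
    "stat_columns",
]

STAT_CLASSES = (
    "pi.pool", "pi.1", "pi.2",
    "thetaW.pool", "thetaW.1", "thetaW.2",
    "sd_pi_thetaW.pool", "sd_pi_thetaW.1", "sd_pi_thetaW.2",
    "shannon.pool", "shannon.1", "shannon.2",
    "wakeley_s.pool", "wakeley_s.1", "wakeley_s.2",
    "pi_b", "pi_net", "wakeley_sxy", "wakeley_psiW",
)

DEFAULT_CLASSES = ("pi_b",)


def pairwise_count_matrix(matrix: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pairwise Hamming distances (difference counts)."""
    diff = matrix[:, None, :] != matrix[None, :, :]
    return diff.sum(axis=2)


def _mean_offdiag(block: np.ndarray) -> float:
    n = block.shape[0]
    return float(np.triu(block, 1).sum() * 2.0 / (n * (n - 1)))


def _segregating_sites(matrix: np.ndarray) -> int:
    return int((matrix != matrix[0]).any(axis=0).sum())


def _harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def pairwise_diff_stats(alignment: LocusAlignment):
    """(π_pool, π_1, π_2, π_b, π_net); within-population values are NaN
    when that population has fewer than two sequences."""
    M = alignment.matrix
    if M.shape[0] < 2:
        raise ValueError("need at least two sequences")
    D = pairwise_count_matrix(M)
    idx1 = np.nonzero(alignment.pop_labels == 1)[0]
    idx2 = np.nonzero(alignment.pop_labels == 2)[0]
    pi_pool = _mean_offdiag(D)
    pi_1 = _mean_offdiag(D[np.ix_(idx1, idx1)]) if idx1.size >= 2 else math.nan
    pi_2 = _mean_offdiag(D[np.ix_(idx2, idx2)]) if idx2.size >= 2 else math.nan
    if idx1.size and idx2.size:
        pi_b = float(D[np.ix_(idx1, idx2)].mean())
    else:
        pi_b = math.nan
    pi_net = (
        pi_b - 0.5 * (pi_1 + pi_2)
        if not (math.isnan(pi_1) or math.isnan(pi_2) or math.isnan(pi_b))
        else math.nan
    )
    return pi_pool, pi_1, pi_2, pi_b, pi_net


def watterson(matrix: np.ndarray) -> float:
    """Watterson's estimator S / a_{n-1} on the per-locus scale."""
    n = matrix.shape[0]
    if n < 2:
        return math.nan
    return _segregating_sites(matrix) / _harmonic(n - 1)


def _tajima_coefficients(n: int) -> tuple[float, float]:
    a1 = _harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def sd_pi_theta(matrix: np.ndarray) -> float:
    """Standard deviation of π − θ_W via the Tajima (1989) moment estimator.

    Var(π − θ_W) = e1·S + e2·S·(S−1); a function of the sample size and the
    number of segregating sites only.
    """
    n = matrix.shape[0]
    if n < 2:
        return math.nan
    s = _segregating_sites(matrix)
    if s == 0:
        return 0.0
    e1, e2 = _tajima_coefficients(n)
    return math.sqrt(e1 * s + e2 * s * (s - 1))


def shannon(matrix: np.ndarray) -> float:
    """Shannon diversity −Σ p ln p on whole-haplotype frequencies."""
    if matrix.shape[0] < 1:
        return math.nan
    _, counts = np.unique(matrix, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _pairs_correlation(values_sq_sums, n_points, sum_a, sum_ab, sum_a2):
    """Pearson correlation from symmetrized pairs-of-pairs sufficient stats."""
    if n_points <= 0:
        return math.nan
    mean = sum_a / n_points
    var = sum_a2 / n_points - mean * mean
    if var <= 1e-12:
        return 0.0
    cov = sum_ab / n_points - mean * mean
    return float(cov / var)


def _within_correlation(D: np.ndarray) -> float:
    """Wakeley's s: correlation of difference counts over pairs of sequence
    pairs sharing one member, within one sample."""
    m = D.shape[0]
    if m < 3:
        return math.nan
    r = D.sum(axis=1).astype(float)
    q = (D.astype(float) ** 2).sum(axis=1)
    n_points = m * (m - 1) * (m - 2)  # symmetrized count
    sum_a = (m - 2) * r.sum()
    sum_a2 = (m - 2) * q.sum()
    sum_ab = (r * r - q).sum()
    return _pairs_correlation(None, n_points, sum_a, sum_ab, sum_a2)


def _cross_correlations(C: np.ndarray) -> tuple[float, float]:
    """Wakeley's interpopulation correlation coefficients (s_XY, Ψ_W).

    Both consider cross-population sequence pairs sharing one member.  s_XY
    is the Pearson correlation over all such (symmetrized) pairs-of-pairs.
    Ψ_W is the companion derivation normalized by the variance of the
    difference counts over *all* cross pairs (an intraclass-correlation
    form).  The source derivations are reconstructed from their verbal
    definition; the two coincide for balanced, homoscedastic samples.
    """
    n1, n2 = C.shape
    n_points = n1 * n2 * (n1 + n2 - 2)
    if n_points < 2:
        return math.nan, math.nan
    C = C.astype(float)
    r_rows = C.sum(axis=1)
    q_rows = (C ** 2).sum(axis=1)
    r_cols = C.sum(axis=0)
    q_cols = (C ** 2).sum(axis=0)
    sum_ab = (r_rows ** 2 - q_rows).sum() + (r_cols ** 2 - q_cols).sum()
    sum_a = (n2 - 1) * r_rows.sum() + (n1 - 1) * r_cols.sum()
    sum_a2 = (n2 - 1) * q_rows.sum() + (n1 - 1) * q_cols.sum()
    s_xy = _pairs_correlation(None, n_points, sum_a, sum_ab, sum_a2)
    # intraclass form: center and scale by all cross pairs
    mu = C.mean()
    var_all = (C ** 2).mean() - mu * mu
    if var_all <= 1e-12:
        psi_w = 0.0
    else:
        psi_w = float((sum_ab / n_points - mu * mu) / var_all)
    return s_xy, psi_w


def wakeley_stats(alignment: LocusAlignment):
    """(s_1, s_2, s_pool, s_XY, Ψ_W); NaN where sample sizes are too small."""
    D = pairwise_count_matrix(alignment.matrix)
    idx1 = np.nonzero(alignment.pop_labels == 1)[0]
    idx2 = np.nonzero(alignment.pop_labels == 2)[0]
    s1 = _within_correlation(D[np.ix_(idx1, idx1)])
    s2 = _within_correlation(D[np.ix_(idx2, idx2)])
    s_pool = _within_correlation(D)
    if idx1.size and idx2.size:
        s_xy, psi_w = _cross_correlations(D[np.ix_(idx1, idx2)])
    else:
        s_xy, psi_w = math.nan, math.nan
    return s1, s2, s_pool, s_xy, psi_w


def class_defined(cls: str, n1: int, n2: int) -> bool:
    """Whether a statistic class is defined at the given sample sizes.

    This is the masking rule: a pure function of the sampling configuration,
    never of the data.
    """
    n = n1 + n2
    if cls.endswith(".pool"):
        base = cls[:-5]
        return n >= 3 if base == "wakeley_s" else n >= 2
    if cls.endswith(".1") or cls.endswith(".2"):
        ni = n1 if cls.endswith(".1") else n2
        base = cls[:-2]
        if base == "shannon":
            return ni >= 1
        return ni >= 3 if base == "wakeley_s" else ni >= 2
    if cls == "pi_b":
        return n1 >= 1 and n2 >= 1
    if cls == "pi_net":
        return n1 >= 2 and n2 >= 2
    if cls in ("wakeley_sxy", "wakeley_psiW"):
        return n1 >= 1 and n2 >= 1 and n >= 3
    raise ValueError(f"unknown statistic class {cls!r}")


def locus_stats(alignment: LocusAlignment, selection=DEFAULT_CLASSES) -> dict:
    """Compute the selected statistic classes for one locus.

    Only the work the selection requires is done; undefined statistics are
    returned as NaN (the configuration-level mask).
    """
    sel = set(selection)
    unknown = sel - set(STAT_CLASSES)
    if unknown:
        raise ValueError(f"unknown statistic classes: {sorted(unknown)}")
    out: dict[str, float] = {}
    M = alignment.matrix
    labels = alignment.pop_labels
    idx1 = np.nonzero(labels == 1)[0]
    idx2 = np.nonzero(labels == 2)[0]
    need_dist = sel & {
        "pi.pool", "pi.1", "pi.2", "pi_b", "pi_net",
        "wakeley_s.pool", "wakeley_s.1", "wakeley_s.2",
        "wakeley_sxy", "wakeley_psiW",
    }
    D = pairwise_count_matrix(M) if need_dist else None

    def sub(idx):
        return D[np.ix_(idx, idx)]

    if {"pi.pool", "pi.1", "pi.2", "pi_b", "pi_net"} & sel:
        if "pi.pool" in sel:
            out["pi.pool"] = _mean_offdiag(D)
        pi_1 = _mean_offdiag(sub(idx1)) if idx1.size >= 2 else math.nan
        pi_2 = _mean_offdiag(sub(idx2)) if idx2.size >= 2 else math.nan
        pi_b = (
            float(D[np.ix_(idx1, idx2)].mean())
            if idx1.size and idx2.size else math.nan
        )
        if "pi.1" in sel:
            out["pi.1"] = pi_1
        if "pi.2" in sel:
            out["pi.2"] = pi_2
        if "pi_b" in sel:
            out["pi_b"] = pi_b
        if "pi_net" in sel:
            out["pi_net"] = pi_b - 0.5 * (pi_1 + pi_2)
    for cls, idx in (("thetaW.pool", None), ("thetaW.1", idx1), ("thetaW.2", idx2)):
        if cls in sel:
            sub_m = M if idx is None else M[idx]
            out[cls] = watterson(sub_m)
    for cls, idx in (("sd_pi_thetaW.pool", None), ("sd_pi_thetaW.1", idx1),
                     ("sd_pi_thetaW.2", idx2)):
        if cls in sel:
            sub_m = M if idx is None else M[idx]
            out[cls] = sd_pi_theta(sub_m)
    for cls, idx in (("shannon.pool", None), ("shannon.1", idx1), ("shannon.2", idx2)):
        if cls in sel:
            sub_m = M if idx is None else M[idx]
            out[cls] = shannon(sub_m) if sub_m.shape[0] >= 1 else math.nan
    for cls, idx in (("wakeley_s.pool", None), ("wakeley_s.1", idx1),
                     ("wakeley_s.2", idx2)):
        if cls in sel:
            out[cls] = _within_correlation(D if idx is None else sub(idx))
    if {"wakeley_sxy", "wakeley_psiW"} & sel:
        if idx1.size and idx2.size:
            s_xy, psi_w = _cross_correlations(D[np.ix_(idx1, idx2)])
        else:
            s_xy, psi_w = math.nan, math.nan
        if "wakeley_sxy" in sel:
            out["wakeley_sxy"] = s_xy
        if "wakeley_psiW" in sel:
            out["wakeley_psiW"] = psi_w
    return out


@dataclass
class SummaryTensor:
    """Ragged tensor D: per-pair (n_classes, n_loci) value blocks with mask."""

    classes: tuple[str, ...]
    blocks: list[np.ndarray]   # blocks[y] has shape (n_classes, n_loci_y)

    @property
    def n_pairs(self) -> int:
        return len(self.blocks)


def build_summary_tensor(dataset, selection=DEFAULT_CLASSES) -> SummaryTensor:
    """Fill D for a simulated or observed data set.

    ``dataset`` is either a :class:`codiv.coalsim.SimulatedDataset` or a
    plain list-of-lists of :class:`LocusAlignment` ([pair][locus]).
    """
    alignments = getattr(dataset, "alignments", dataset)
    classes = tuple(selection)
    unknown = set(classes) - set(STAT_CLASSES)
    if unknown:
        raise ValueError(f"unknown statistic classes: {sorted(unknown)}")
    blocks = []
    for pair_alns in alignments:
        block = np.empty((len(classes), len(pair_alns)))
        for j, aln in enumerate(pair_alns):
            stats = locus_stats(aln, classes)
            for i, cls in enumerate(classes):
                block[i, j] = stats[cls]
        blocks.append(block)
    return SummaryTensor(classes=classes, blocks=blocks)


@dataclass
class MomentVector:
    """D_m: raw moments across loci per (class, pair), π_b-sorted on pairs."""

    classes: tuple[str, ...]
    values: np.ndarray          # (n_classes, n_pairs, n_moments)
    permutation: np.ndarray     # original pair index at each sorted position

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)


def reduce_moments(
    tensor: SummaryTensor,
    n_moments: int = 4,
    sort_by: str = "pi_b",
) -> MomentVector:
    """Reduce D to D_m and re-order taxon-pairs.

    Raw moment k of a class for a pair is the mean over that pair's unmasked
    loci of value**k.  With ``sort_by="pi_b"`` the pair axis is permuted
    jointly (all classes together) into descending order of the first moment
    of ``pi_b``, stable on ties; ``sort_by="none"`` keeps the configured
    (e.g. sample-size) order.
    """
    if not 1 <= n_moments <= 4:
        raise ValueError("n_moments must be in 1..4")
    if sort_by not in ("pi_b", "none"):
        raise ValueError("sort_by must be 'pi_b' or 'none'")
    if sort_by == "pi_b" and "pi_b" not in tensor.classes:
        raise ValueError("sorting requires the pi_b class in the tensor")
    n_classes = len(tensor.classes)
    n_pairs = tensor.n_pairs
    values = np.empty((n_classes, n_pairs, n_moments))
    for y, block in enumerate(tensor.blocks):
        for i, cls in enumerate(tensor.classes):
            vals = block[i]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                raise ValueError(
                    f"taxon-pair {y}: no defined loci for class {cls!r}"
                )
            for k in range(n_moments):
                values[i, y, k] = np.mean(vals ** (k + 1))
    if sort_by == "pi_b":
        key = values[tensor.classes.index("pi_b"), :, 0]
        order = np.argsort(-key, kind="stable")
    else:
        order = np.arange(n_pairs)
    return MomentVector(
        classes=tensor.classes,
        values=values[:, order, :],
        permutation=order,
    )


def stat_columns(selection, n_pairs: int, n_moments: int) -> list[str]:
    """Column names of the flattened D_m; a pure function of the layout."""
    return [
        f"{cls}|y{y + 1}|m{k + 1}"
        for cls in selection
        for y in range(n_pairs)
        for k in range(n_moments)
    ]


def moment_vector(
    dataset,
    selection=DEFAULT_CLASSES,
    n_moments: int = 1,
    sort_by: str = "pi_b",
) -> MomentVector:
    """Convenience: tensor + moment reduction in one call."""
    return reduce_moments(
        build_summary_tensor(dataset, selection), n_moments, sort_by
    )
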