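import numpy as np
import pytest

from codiv.config_io import LocusAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alignment(seqs_pop1, seqs_pop2, pair_id="p", locus_id="l"):
    seqs = list(seqs_pop1) + list(seqs_pop2)
    labels = [1] * len(seqs_pop1) + [2] * len(seqs_pop2)
    return LocusAlignment.from_sequences(seqs, labels, pair_id, locus_id)


def random_alignment(rng, n1, n2, length, n_states=4):
    matrix = rng.integers(0, n_states, size=(n1 + n2, length)).astype(np.uint8)
    labels = np.r_[np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)]
    return LocusAlignment(matrix, labels)


# ---------------------------------------------------------------------------
# Brute-force reference implementations (independent of the package's
# vectorized algebra): explicit loops over sequence pairs and
# pairs-of-pairs.

def bf_hamming(a, b):
    return int(sum(x != y for x, y in zip(a, b)))


def bf_pi(rows):
    n = len(rows)
    if n < 2:
        return np.nan
    dists = [bf_hamming(rows[i], rows[j]) for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(dists))


def bf_pi_b(rows1, rows2):
    return float(np.mean([bf_hamming(a, b) for a in rows1 for b in rows2]))


def bf_segregating(rows):
    return sum(1 for col in zip(*rows) if len(set(col)) > 1)


def bf_watterson(rows):
    n = len(rows)
    if n < 2:
        return np.nan
    return bf_segregating(rows) / sum(1.0 / i for i in range(1, n))


def bf_shannon(rows):
    haps = {}
    for r in rows:
        key = tuple(r)
        haps[key] = haps.get(key, 0) + 1
    n = len(rows)
    return -sum((c / n) * np.log(c / n) for c in haps.values())


def _pearson_sym(points):
    """Pearson correlation of a symmetrized list of (a, b) pairs."""
    pts = points + [(b, a) for a, b in points]
    a = np.array([p[0] for p in pts], dtype=float)
    b = np.array([p[1] for p in pts], dtype=float)
    va = a.var()
    if va <= 1e-12:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / va)


def bf_within_s(rows):
    """Correlation of difference counts over within-sample pairs sharing a
    sequence (triple loop)."""
    m = len(rows)
    if m < 3:
        return np.nan
    points = []
    for i in range(m):
        others = [j for j in range(m) if j != i]
        for a_idx in range(len(others)):
            for b_idx in range(a_idx + 1, len(others)):
                j, k = others[a_idx], others[b_idx]
                points.append(
                    (bf_hamming(rows[i], rows[j]), bf_hamming(rows[i], rows[k]))
                )
    return _pearson_sym(points)


def bf_cross_stats(rows1, rows2):
    """(s_XY, psi_W) by explicit loops over cross pairs sharing one member."""
    n1, n2 = len(rows1), len(rows2)
    if n1 * n2 * (n1 + n2 - 2) < 2:
        return np.nan, np.nan
    points = []
    for x in range(n1):
        for y in range(n2):
            for y2 in range(y + 1, n2):
                points.append(
                    (bf_hamming(rows1[x], rows2[y]), bf_hamming(rows1[x], rows2[y2]))
                )
    for y in range(n2):
        for x in range(n1):
            for x2 in range(x + 1, n1):
                points.append(
                    (bf_hamming(rows1[x], rows2[y]), bf_hamming(rows1[x2], rows2[y]))
                )
    s_xy = _pearson_sym(points)
    all_cross = np.array(
        [bf_hamming(a, b) for a in rows1 for b in rows2], dtype=float
    )
    var_all = all_cross.var()
    if var_all <= 1e-12:
        psi = 0.0
    else:
        pts = points + [(b, a) for a, b in points]
        ab = np.mean([a * b for a, b in pts])
        psi = float((ab - all_cross.mean() ** 2) / var_all)
    return s_xy, psi
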