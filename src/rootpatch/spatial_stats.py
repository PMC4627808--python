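"""Spatial statistics for one-dimensional transects.

Distance matrices (Bray-Curtis for species composition, Euclidean for
trait composition and univariate counts), Sturges-rule distance
classes, Mantel correlograms with permutation inference and a
progressive multiple-testing correction, pattern classification
(patchy / autocorrelated / none), and global Moran's I with
inverse-distance weights.

The correlogram convention: for each distance class the Mantel
statistic is the Pearson correlation between the dissimilarity matrix
and the binary class-membership matrix (1 = pair in class), with the
sign flipped so that a *positive* coefficient means pairs within the
class are more *similar* than average.  Classes are tested in order of
increasing distance and the k-th evaluated class' permutation p-value
is corrected by the progressive Holm factor k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceClassSet",
    "Correlogram",
    "MoranResult",
    "bray_curtis",
    "euclidean",
    "sturges_classes",
    "mantel_r",
    "mantel_correlogram",
    "classify_pattern",
    "global_morans_i",
]


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def bray_curtis(cover_matrix) -> np.ndarray:
    """Plot x plot Bray-Curtis dissimilarity on raw percent covers.

    BC(a, b) = sum|a_i - b_i| / sum(a_i + b_i), in [0, 1].
    """
    x = np.asarray(cover_matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("covers must be non-negative")
    if np.any(x.sum(axis=1) <= 0):
        raise ValueError("Bray-Curtis undefined: plot with zero total cover")
    return squareform(pdist(x, metric="braycurtis"))


def euclidean(matrix) -> np.ndarray:
    """Plot x plot Euclidean distance.

    Accepts a 1-D vector (e.g. herbivore counts per core), where it
    reduces to the absolute difference.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.any(~np.isfinite(x)):
        raise ValueError("matrix contains missing values")
    return squareform(pdist(x, metric="euclidean"))


# ---------------------------------------------------------------------------
# Sturges distance classes
# ---------------------------------------------------------------------------

@dataclass
class DistanceClassSet:
    """Distance classes for the pairs of a transect.

    ``boundaries`` has K+1 increasing entries (m); pair (i, j) belongs
    to class k iff boundaries[k] < d_ij <= boundaries[k+1] (first class
    closed at its lower end).  Pairs beyond boundaries[-1] carry label
    -1 and are excluded from correlograms.
    """
    n_classes: int
    boundaries: np.ndarray
    pair_i: np.ndarray          # upper-triangle row indices
    pair_j: np.ndarray          # upper-triangle col indices
    labels: np.ndarray          # class per pair, -1 = beyond last class
    n_pairs: np.ndarray         # pairs per class

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])


def sturges_classes(positions) -> DistanceClassSet:
    """Distance classes by the Sturges rule applied to the pair count.

    K = ceil(1 + log2(n(n-1)/2)); classes of width
    w = (d_max - d_min) / K are centered at d_min + k*w, the first
    truncated at 0.  For a 30-point transect at 0.3 m spacing this
    gives the 10 classes 0-0.72, 0.72-1.56, ..., 7.44-8.28 m, and the
    longest pairs (> 8.28 m) are left out.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.size
    if n < 3:
        raise ValueError("need at least 3 positions")
    i, j = np.triu_indices(n, k=1)
    d = np.abs(pos[i] - pos[j])
    d_min, d_max = d.min(), d.max()
    if d_max == d_min:
        raise ValueError("all pairwise distances equal")
    n_pairs_total = n * (n - 1) // 2
    k = int(np.ceil(1 + np.log2(n_pairs_total)))
    w = (d_max - d_min) / k
    centers = d_min + w * np.arange(k)
    boundaries = np.concatenate([[max(0.0, centers[0] - w / 2)],
                                 centers + w / 2])
    labels = np.full(d.shape, -1, dtype=int)
    for c in range(k):
        lo, hi = boundaries[c], boundaries[c + 1]
        if c == 0:
            in_c = (d >= lo) & (d <= hi)
        else:
            in_c = (d > lo) & (d <= hi)
        labels[in_c] = c
    n_pairs = np.bincount(labels[labels >= 0], minlength=k)
    return DistanceClassSet(k, boundaries, i, j, labels, n_pairs)


# ---------------------------------------------------------------------------
# Mantel machinery
# ---------------------------------------------------------------------------

def mantel_r(d1, d2, mask=None) -> float:
    """Mantel statistic: Pearson r over masked upper-triangle entries.

    ``mask``, if given, is a boolean matrix (or upper-triangle vector)
    selecting the pairs entering the correlation.  Fewer than 3
    selected pairs, or a constant vector on either side, make the
    statistic undefined (NaN).
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("d1 and d2 must be square matrices of equal order")
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    if mask is not None:
        m = np.asarray(mask)
        m = m[iu] if m.ndim == 2 else m
        x, y = x[m], y[m]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class Correlogram:
    """Per-class Mantel coefficients with permutation significance."""
    table: pd.DataFrame         # class, lower, upper, n_pairs, r, p, p_corrected, significant
    alpha: float
    pattern: str = "none"       # patchy | autocorrelated | none

    @property
    def r(self) -> np.ndarray:
        return self.table["r"].to_numpy()

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy()


def _class_r(x: np.ndarray, labels: np.ndarray, include: np.ndarray,
             n_k: np.ndarray) -> np.ndarray:
    """Membership-matrix Mantel r for every class, sign-flipped.

    Closed form of the Pearson correlation between the pair
    dissimilarities ``x`` (restricted to included pairs) and each
    binary class indicator, negated so positive = within-class
    similarity.
    """
    xs = x[include]
    n_tot = xs.size
    sums = np.bincount(labels[include], weights=xs, minlength=n_k.size)
    sx = xs.sum()
    sxx = (xs * xs).sum()
    xbar = sx / n_tot
    ssx = sxx - n_tot * xbar * xbar
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(ssx * n_k * (n_tot - n_k) / n_tot)
        r = (sums - xbar * n_k) / denom
    return -r


def mantel_correlogram(d, classes: DistanceClassSet, n_perm: int = 999,
                       alpha: float = 0.05, seed=None) -> Correlogram:
    """Mantel correlogram of a dissimilarity matrix over distance classes.

    For each class in order of increasing distance: the sign-flipped
    membership Mantel coefficient, a two-sided permutation p-value from
    ``n_perm`` simultaneous row/column permutations of ``d``, and the
    progressive Holm correction (the k-th evaluated class' p times k,
    capped at 1).  Classes with no pairs, or no variance, are skipped.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    rng = np.random.default_rng(seed)
    labels, include = classes.labels, classes.labels >= 0
    n_k = classes.n_pairs.astype(float)
    pi, pj = classes.pair_i, classes.pair_j

    x_obs = dm[pi, pj]
    r_obs = _class_r(x_obs, labels, include, n_k)

    exceed = np.zeros(classes.n_classes)
    valid = np.isfinite(r_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        x_perm = dm[perm[pi], perm[pj]]
        r_perm = _class_r(x_perm, labels, include, n_k)
        with np.errstate(invalid="ignore"):
            exceed += np.where(valid & np.isfinite(r_perm),
                               np.abs(r_perm) >= np.abs(r_obs), 0.0)
    p = np.where(valid, (1.0 + exceed) / (n_perm + 1.0), np.nan)

    # progressive Holm: k-th evaluated class corrected by factor k
    p_corr = np.full_like(p, np.nan)
    rank = 0
    for c in range(classes.n_classes):
        if np.isfinite(p[c]):
            rank += 1
            p_corr[c] = min(1.0, p[c] * rank)

    table = pd.DataFrame({
        "class": np.arange(classes.n_classes),
        "lower": classes.boundaries[:-1],
        "upper": classes.boundaries[1:],
        "n_pairs": classes.n_pairs,
        "r": r_obs,
        "p": p,
        "p_corrected": p_corr,
    })
    table["significant"] = (table["p_corrected"] <= alpha).fillna(False)
    cg = Correlogram(table=table, alpha=alpha)
    cg.pattern = classify_pattern(cg)
    return cg


def classify_pattern(correlogram: Correlogram) -> str:
    """Spatial pattern from a corrected correlogram.

    "autocorrelated": any class significant after correction.
    "patchy": additionally the first (or second) class is significant
    and positive while some later class coefficient is <= 0 —
    similarity at short range decaying to indifference/dissimilarity.
    "none" otherwise.
    """
    t = correlogram.table
    sig = t["significant"].to_numpy()
    r = t["r"].to_numpy()
    if not sig.any():
        return "none"
    head = [k for k in (0, 1) if k < len(sig) and sig[k] and r[k] > 0]
    if head:
        first = head[0]
        later = r[first + 1:]
        if np.any(later[np.isfinite(later)] <= 0):
            return "patchy"
    return "autocorrelated"


# ---------------------------------------------------------------------------
# global Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    i: float
    expectation: float
    p: float


def global_morans_i(values, positions, n_perm: int = 999,
                    seed=None) -> MoranResult:
    """Global Moran's I with inverse-distance weights w_ij = 1/d_ij.

    Two-sided permutation p-value measured as deviation from the null
    expectation E[I] = -1/(n-1).
    """
    z = np.asarray(values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 values")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I undefined for constant values")
    d = np.abs(pos[:, None] - pos[None, :])
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, 1.0 / d, 0.0)
    s0 = w.sum()
    e_i = -1.0 / (n - 1)

    def moran(v):
        dev = v - v.mean()
        return n / s0 * (dev @ w @ dev) / (dev @ dev)

    i_obs = moran(z)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        i_star = moran(rng.permutation(z))
        if abs(i_star - e_i) >= abs(i_obs - e_i):
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MoranResult(i=float(i_obs), expectation=e_i, p=float(p))
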