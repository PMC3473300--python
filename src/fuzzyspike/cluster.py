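"""Automatic cluster-count estimation and fuzzy C-means clustering.

The number of units is estimated without supervision from the histogram
of per-spike l1-norms of the score vectors: the histogram uses the
unbiased-optimal bin width ``W = 3.49 sigma N^(-1/3)``, is thresholded at
the count of the first valley after the mode (suppressing low-amplitude
noise peaks), and the surviving peaks are counted as clusters.  Spikes are
then partitioned by fuzzy C-means with fuzziness ``m = 1.1``, a value soft
enough for graded memberships yet close to the hard (ISODATA) limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

__all__ = [
    "L1Histogram",
    "FCMResult",
    "l1_norm",
    "l1_norms",
    "optimal_bin_width",
    "estimate_cluster_count",
    "fcm",
    "fcm_memberships",
    "mark_outliers",
    "regularized_covariance",
]


def l1_norm(v: np.ndarray) -> float:
    """Sum of absolute components (the vector's 'generalized length')."""
    v = np.asarray(v)
    if v.size == 0:
        raise ValueError("empty vector has no l1-norm")
    return float(np.sum(np.abs(v)))


def l1_norms(scores: np.ndarray) -> np.ndarray:
    """Row-wise l1-norms of a score matrix."""
    return np.sum(np.abs(np.atleast_2d(scores)), axis=1)


def optimal_bin_width(sigma: float, N: int) -> float:
    """Scott's unbiased-optimal histogram bin width ``3.49 sigma N^(-1/3)``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if N < 1:
        raise ValueError("need at least one sample")
    return 3.49 * sigma * N ** (-1.0 / 3.0)


@dataclass
class L1Histogram:
    """The l1-norm histogram with its mode/valley/peak annotation."""

    norms: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray            # raw counts
    smoothed: np.ndarray          # 3-bin moving average used for peak finding
    W: float
    mode_bin: int
    valley_threshold: float
    peak_bins: np.ndarray
    peak_count: int

    def peak_centers(self) -> np.ndarray:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return centers[self.peak_bins]


def _local_peaks(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus yield their leftmost bin."""
    peaks = []
    n = y.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1  # plateau [i, j]
        left = y[i - 1] if i > 0 else -np.inf
        right = y[j + 1] if j + 1 < n else -np.inf
        if y[i] > left and y[i] > right:
            peaks.append(i)
        i = j + 1
    return np.array(peaks, dtype=int)


def _first_valley_after(y: np.ndarray, mode: int) -> int:
    """First local minimum after the mode (last bin if monotone decreasing)."""
    n = y.size
    i = mode + 1
    while i < n - 1:
        if y[i] < y[i - 1] and y[i] <= y[i + 1]:
            return i
        i += 1
    return n - 1


def count_peaks_above_valley(counts: np.ndarray):
    """Apply the mode/valley/peak rule to a histogram's (smoothed) counts.

    The noise threshold is the count of the first local minimum after the
    global mode; the cluster count is the number of local maxima strictly
    above it (minimum 1).  Returns ``(c, mode, valley_threshold, peaks)``.
    """
    y = np.asarray(counts, dtype=np.float64)
    mode = int(np.argmax(y))
    valley = _first_valley_after(y, mode)
    threshold = float(y[valley]) if valley > mode else 0.0
    peaks = _local_peaks(y)
    peaks = peaks[y[peaks] > threshold]
    return max(int(peaks.size), 1), mode, threshold, peaks


def estimate_cluster_count(norms: np.ndarray, smooth: bool = True):
    """Estimate the number of clusters from the l1-norm histogram.

    Returns ``(c, L1Histogram)``.  The histogram is optionally smoothed by
    a 3-bin moving average before peak finding; the noise threshold is the
    count of the first valley after the global mode, and ``c`` is the
    number of local maxima with count strictly above that threshold
    (always at least 1).
    """
    norms = np.asarray(norms, dtype=np.float64)
    if norms.size < 10:
        raise ValueError("need at least 10 norms to build a histogram")
    sigma = float(np.std(norms, ddof=1))
    if sigma == 0:  # degenerate: all norms identical
        hist = L1Histogram(
            norms=norms, bin_edges=np.array([norms[0], norms[0]]),
            counts=np.array([norms.size]), smoothed=np.array([float(norms.size)]),
            W=0.0, mode_bin=0, valley_threshold=0.0,
            peak_bins=np.array([0]), peak_count=1,
        )
        return 1, hist
    W = optimal_bin_width(sigma, norms.size)
    nbins = max(int(np.ceil((norms.max() - norms.min()) / W)), 1)
    counts, edges = np.histogram(norms, bins=nbins, range=(norms.min(), norms.min() + nbins * W))
    y = counts.astype(float)
    if smooth and y.size >= 3:
        y = np.convolve(np.pad(y, 1, mode="edge"), np.ones(3) / 3.0, mode="valid")
    c, mode, threshold, peaks = count_peaks_above_valley(y)
    hist = L1Histogram(
        norms=norms, bin_edges=edges, counts=counts, smoothed=y, W=W,
        mode_bin=mode, valley_threshold=threshold, peak_bins=peaks, peak_count=c,
    )
    return c, hist


@dataclass
class FCMResult:
    """Outcome of fuzzy C-means: memberships, centroids, crisp labels."""

    memberships: np.ndarray       # n x c, rows sum to 1
    centroids: np.ndarray         # c x k
    m: float
    labels: np.ndarray            # argmax memberships
    n_steps: int
    objective: float
    objective_history: np.ndarray
    outlier_flags: np.ndarray | None = None

    @property
    def c(self) -> int:
        return self.centroids.shape[0]


def fcm_memberships(scores: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Membership update: ``u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1))``.

    Computed via per-row normalization by the smallest distance so the
    large exponent at small ``m`` cannot overflow; a point coincident with
    a centroid gets crisp membership there.
    """
    scores = np.atleast_2d(scores)
    d = np.linalg.norm(scores[:, None, :] - centroids[None, :, :], axis=2)
    u = np.zeros(d.shape)
    zero_rows = np.any(d == 0, axis=1)
    if np.any(zero_rows):
        for i in np.flatnonzero(zero_rows):
            u[i, int(np.argmin(d[i]))] = 1.0
    ok = ~zero_rows
    if np.any(ok):
        dk = d[ok]
        r = dk / dk.min(axis=1, keepdims=True)        # >= 1
        w = r ** (-2.0 / (m - 1.0))                   # <= 1, no overflow
        u[ok] = w / w.sum(axis=1, keepdims=True)
    return u


def _farthest_point_init(scores: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    idx = [int(rng.integers(scores.shape[0]))]
    for _ in range(1, c):
        d = np.min(
            np.linalg.norm(scores[:, None, :] - scores[idx][None, :, :], axis=2), axis=1
        )
        idx.append(int(np.argmax(d)))
    return scores[idx].copy()


def init_from_histogram(scores: np.ndarray, hist: L1Histogram) -> np.ndarray:
    """One seed spike per detected histogram peak (nearest-norm spike)."""
    norms = l1_norms(scores)
    centers = hist.peak_centers()
    idx = [int(np.argmin(np.abs(norms - ctr))) for ctr in centers]
    return scores[idx].copy()


def fcm(
    scores: np.ndarray,
    c: int,
    m: float = 1.1,
    tol: float = 1e-5,
    max_iter: int = 300,
    init_centroids: np.ndarray | None = None,
    seed: int = 0,
    n_init: int = 1,
) -> FCMResult:
    """Fuzzy C-means by alternating optimization.

    Memberships and centroids are updated in turn until the largest
    membership change falls below ``tol``; the weighted squared-distance
    objective ``J_m`` is recorded every iteration and is non-increasing.  The
    returned memberships are consistent with the returned centroids.

    With ``n_init > 1`` (and no explicit ``init_centroids``) the algorithm
    restarts from ``n_init`` seeded farthest-point initializations and the
    run with the lowest final objective wins — alternating optimization
    only finds a local optimum, and a single unlucky start can split one
    dense cluster instead of separating two true ones.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    n = scores.shape[0]
    if c < 1:
        raise ValueError("need at least one cluster")
    if c > n:
        raise ValueError(f"cannot form {c} clusters from {n} points")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    if not (m > 1):
        raise ValueError("fuzziness m must exceed 1")

    if init_centroids is None and n_init > 1:
        runs = [
            fcm(scores, c, m=m, tol=tol, max_iter=max_iter, seed=seed + j, n_init=1)
            for j in range(n_init)
        ]
        return min(runs, key=lambda r: r.objective)

    if init_centroids is None:
        centroids = _farthest_point_init(scores, c, np.random.default_rng(seed))
    else:
        centroids = np.array(init_centroids, dtype=np.float64)
        if centroids.shape != (c, scores.shape[1]):
            raise ValueError("init_centroids has wrong shape")

    u = fcm_memberships(scores, centroids, m)
    history = [_objective(scores, centroids, u, m)]
    steps = 1
    for _ in range(max_iter - 1):
        um = u**m
        centroids = (um.T @ scores) / um.sum(axis=0)[:, None]
        u_new = fcm_memberships(scores, centroids, m)
        history.append(_objective(scores, centroids, u_new, m))
        steps += 1
        delta = np.max(np.abs(u_new - u))
        u = u_new
        if delta < tol:
            break
    return FCMResult(
        memberships=u,
        centroids=centroids,
        m=m,
        labels=np.argmax(u, axis=1),
        n_steps=steps,
        objective=history[-1],
        objective_history=np.array(history),
    )


def _objective(scores, centroids, u, m):
    d2 = np.sum((scores[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
    return float(np.sum(u**m * d2))


def regularized_covariance(points: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Covariance around ``center`` with a tiny diagonal ridge.

    Near-singular (or zero) covariances are lifted by ``1e-9 * trace/k``
    on the diagonal so Mahalanobis distances never crash; a fully
    degenerate cluster (all points coincident) gets a minuscule spherical
    covariance, making every member distance zero.
    """
    points = np.atleast_2d(points)
    k = points.shape[1]
    if center is None:
        center = points.mean(axis=0)
    dev = points - center
    cov = dev.T @ dev / max(points.shape[0] - 1, 1)
    tr = np.trace(cov)
    ridge = 1e-9 * (tr / k if tr > 0 else 1.0)
    cov = cov + ridge * np.eye(k)
    # lift further if still ill-conditioned
    while np.linalg.cond(cov) > 1e12:
        ridge *= 10
        cov = cov + ridge * np.eye(k)
    return cov


def mahalanobis_sq(points: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    dev = np.atleast_2d(points) - center
    return np.einsum("ij,ij->i", dev, np.linalg.solve(cov, dev.T).T)


def mark_outliers(
    scores: np.ndarray, result: FCMResult, quantile: float = 0.999
) -> np.ndarray:
    """Flag spikes far from their own cluster centre (Mahalanobis gate).

    A spike is flagged iff its squared Mahalanobis distance to the
    centroid of its crisp cluster exceeds the chi-square quantile with
    ``k`` degrees of freedom.
    """
    scores = np.atleast_2d(scores)
    k = scores.shape[1]
    cut = chi2.ppf(quantile, df=k)
    flags = np.zeros(scores.shape[0], dtype=bool)
    for j in range(result.c):
        members = np.flatnonzero(result.labels == j)
        if members.size == 0:
            continue
        cov = regularized_covariance(scores[members], result.centroids[j])
        d2 = mahalanobis_sq(scores[members], result.centroids[j], cov)
        flags[members] = d2 > cut
    result.outlier_flags = flags
    return flags
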