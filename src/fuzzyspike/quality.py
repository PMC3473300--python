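"""Cluster-quality indices for fuzzy partitions and unit isolation.

Three classical validity indices computed from the membership matrix
alone — partition coefficient (Bezdek), partition entropy (Bezdek) and
proportion exponent (Windham) — plus the L-ratio isolation measure
(Schmitzer-Torbert & Redish): for cluster C,

    L(C) = sum over spikes outside C of  1 - CDF_chi2(k)(D^2 spike,C)
    L_ratio(C) = L(C) / n_C,

a size-normalized count of external spikes that look statistically like
members.  When L_ratio rises above a threshold (default 5, recommended
3-6), the recording has drifted enough that retraining is advised.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, floor

import numpy as np
from scipy.stats import chi2

from .cluster import FCMResult, mahalanobis_sq, regularized_covariance

__all__ = [
    "QualityReport",
    "partition_coefficient",
    "partition_entropy",
    "proportion_exponent",
    "l_ratio",
    "check_drift",
    "compute_quality_report",
]


def _check_memberships(u: np.ndarray) -> np.ndarray:
    u = np.atleast_2d(np.asarray(u, dtype=np.float64))
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        raise ValueError("memberships must lie in [0, 1]")
    if not np.allclose(u.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("membership rows must sum to 1")
    return u


def partition_coefficient(memberships: np.ndarray) -> float:
    """``pc = (1/n) sum u_ij^2``; 1 for a crisp partition, 1/c for uniform."""
    u = _check_memberships(memberships)
    return float(np.sum(u**2) / u.shape[0])


def partition_entropy(memberships: np.ndarray, base: float = np.e) -> float:
    """``pe = -(1/n) sum u_ij log u_ij`` (0 log 0 = 0); 0 iff crisp."""
    u = _check_memberships(memberships)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(u > 0, u * np.log(u), 0.0)
    return float(-terms.sum() / u.shape[0] / np.log(base))


def proportion_exponent(memberships: np.ndarray) -> float:
    """Windham's proportion exponent; larger = crisper, inf if any row is crisp.

    For each row with maximum membership mu (strictly above 1/c),

        P_i = sum_{j=1}^{floor(1/mu)} (-1)^(j+1) C(c, j) (1 - j mu)^(c-1)

    and ``pex = -log2 prod_i P_i`` (additive over rows).
    """
    u = _check_memberships(memberships)
    n, c = u.shape
    mu = u.max(axis=1)
    if np.any(mu <= 1.0 / c + 1e-15):
        raise ValueError("every row's maximum membership must exceed 1/c")
    total = 0.0
    for m_i in mu:
        if m_i >= 1.0:
            return float("inf")
        s = 0.0
        for j in range(1, floor(1.0 / m_i) + 1):
            s += (-1) ** (j + 1) * comb(c, j) * (1.0 - j * m_i) ** (c - 1)
        if s <= 0:
            return float("inf")
        total += -np.log2(s)
    return float(total)


def l_ratio(
    scores: np.ndarray,
    labels: np.ndarray,
    cluster_id: int,
    df: int | None = None,
) -> float:
    """Isolation of one cluster against all other spikes.

    Sums the chi-square upper-tail probabilities of the squared
    Mahalanobis distances (to the cluster's own mean and covariance) of
    every spike *outside* the cluster, divided by the cluster size.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    labels = np.asarray(labels)
    inside = labels == cluster_id
    n_c = int(inside.sum())
    if n_c == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    if df is None:
        df = scores.shape[1]
    outside = scores[~inside]
    if outside.shape[0] == 0:
        return 0.0
    center = scores[inside].mean(axis=0)
    cov = regularized_covariance(scores[inside], center)
    d2 = mahalanobis_sq(outside, center, cov)
    return float(np.sum(chi2.sf(d2, df=df)) / n_c)


@dataclass
class QualityReport:
    """Validity indices of one partition plus per-cluster isolation."""

    pc: float
    pe: float
    pex: float
    l_ratios: dict            # cluster id -> L_ratio
    threshold: float = 5.0
    alarms: dict | None = None

    def __post_init__(self) -> None:
        if self.alarms is None:
            self.alarms = check_drift(self, self.threshold)


def check_drift(report: QualityReport, threshold: float = 5.0) -> dict:
    """Per-cluster drift alarms: alarm iff L_ratio exceeds the threshold."""
    return {j: bool(v > threshold) for j, v in report.l_ratios.items()}


def compute_quality_report(
    scores: np.ndarray, result: FCMResult, threshold: float = 5.0
) -> QualityReport:
    """All quality indices for one clustering result.

    ``pex`` is reported as NaN when undefined (some row's top membership
    does not exceed 1/c, possible for heavily mixed partitions).
    """
    pc = partition_coefficient(result.memberships)
    pe = partition_entropy(result.memberships)
    try:
        pex = proportion_exponent(result.memberships)
    except ValueError:
        pex = float("nan")
    lr = {
        j: l_ratio(scores, result.labels, j)
        for j in range(result.c)
        if np.any(result.labels == j)
    }
    return QualityReport(pc=pc, pe=pe, pex=pex, l_ratios=lr, threshold=threshold)
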