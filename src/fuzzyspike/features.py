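"""Waveform features via singular value decomposition.

Aligned waveforms are row-centred (each spike loses its own mean, removing
DC offsets), factorized as ``X = U S V^T``, and represented by their first
``k`` left-singular-vector coordinates (the principal-component scores).
``k`` is chosen automatically by the scree-test "optimal coordinates"
rule on the variance spectrum.  New spikes never require refactorization:
the low-rank projection ``U_k = X_new V_k S_k^{-1}`` reproduces training
scores exactly and costs one small matrix product per spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SVDModel", "center_rows", "fit_svd", "select_noc", "project_psvd"]


@dataclass
class SVDModel:
    """Full SVD of the centred waveform matrix plus the retained rank ``k``."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    k: int = 1

    @property
    def variance_fraction(self) -> float:
        """Fraction of total variance captured by the first k components."""
        lam = self.S**2
        return float(lam[: self.k].sum() / lam.sum())

    @property
    def V_k(self) -> np.ndarray:
        return self.V[:, : self.k]

    @property
    def S_k_inv(self) -> np.ndarray:
        s = self.S[: self.k]
        if np.any(s == 0):
            raise ValueError("retained singular value is zero; reduce k")
        return 1.0 / s


def center_rows(A: np.ndarray):
    """Remove each row's mean (centering across the second mode).

    Returns ``(X, row_means)`` with ``A == X + row_means[:, None]``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    if A.size == 0:
        raise ValueError("cannot centre an empty matrix")
    means = A.mean(axis=1)
    return A - means[:, None], means


def fit_svd(X: np.ndarray) -> SVDModel:
    """Thin SVD with a deterministic sign convention.

    Each right singular vector is flipped so that its largest-magnitude
    component is positive, making scores and centroids comparable across
    runs and libraries.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 waveforms for SVD")
    if not np.any(X):
        raise ValueError("rank-0 input: all waveforms are identically zero")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    return SVDModel(U=U, S=S, V=V)


def select_noc(S: np.ndarray, squared: bool = True, margin: float = 0.002) -> int:
    """Scree-test optimal-coordinates choice of the number of components.

    Works on the variance spectrum ``lambda_i = s_i^2``.  For each
    position ``i`` the 'optimal coordinate' prediction is the linear
    extrapolation through the next point and the last point of the
    spectrum; a component counts as retained when its eigenvalue exceeds
    that prediction by more than ``margin`` of the total variance (the
    excess of a genuinely structured component over the scree line;
    eigenvalues sitting on a straight or exactly convex-decaying tail have
    excesses near zero).  ``k`` is the number of such components, at
    least 1.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.size < 3:
        raise ValueError("need at least 3 singular values")
    lam = S**2 if squared else S.copy()
    total = lam.sum()
    if total == 0:
        return 1
    p = lam.size
    k = 0
    for i in range(p - 2):
        slope = (lam[p - 1] - lam[i + 1]) / ((p - 1) - (i + 1))
        predicted = lam[i + 1] - slope
        if (lam[i] - predicted) / total > margin:
            k += 1
    return max(k, 1)


def project_psvd(Xnew: np.ndarray, model: SVDModel) -> np.ndarray:
    """Project centred waveforms onto the retained singular basis.

    ``scores = X_new V_k S_k^{-1}``; applied to the training matrix this
    reproduces the first ``k`` columns of ``U`` exactly.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=np.float64))
    if Xnew.shape[1] != model.V.shape[0]:
        raise ValueError(
            f"waveforms have {Xnew.shape[1]} columns, model expects {model.V.shape[0]}"
        )
    return Xnew @ model.V_k * model.S_k_inv
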