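"""Householder reflection of features over the span of the remaining features.

For each column X_j of a standardized feature matrix, the reflection over the
hyperplane spanned by the other columns is

    Y_j = 2 * X_hat_j - X_j,

where X_hat_j is the least-squares fit of X_j on X_{,-j}. The half-difference
Z = (X - Y) / 2 is then the regression residual, which is orthogonal to every
other column, so T = cov(X, Z) is diagonal with T_jj = var(Z_j) > 0 on any
full-rank input. Y, Z and T are the raw material for knockoff construction.

Shrinkage (ridge) priors on the per-column regressions are implemented by
appending p "ghost" rows diag(1/sigma_1, ..., 1/sigma_p): the augmented
least-squares solution for column j equals the ridge solution

    (X_{,-j}' X_{,-j} + diag(1/sigma_k^2)_{k != j})^{-1} X_{,-j}' X_j,

which keeps var(Z_j) bounded away from zero when columns are nearly collinear
and permits p > n.

Computation follows a single QR factorization of the (augmented) matrix: for
each j, deleting column j of R leaves an upper-Hessenberg matrix that at most
p - j Givens rotations re-triangularize; the per-column regression is then a
back-substitution. This is algebraically identical to p separate normal-
equation solves but costs O(p^3) total instead of O(n p^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .matrix import COV_DDOF, FeatureMatrix, sample_cov

__all__ = ["AugmentedMatrix", "ReflectionResult", "augment", "reflect"]

# relative diagonal tolerance below which R is declared rank deficient
_RANK_TOL = 1e-10


@dataclass
class AugmentedMatrix:
    """Feature matrix with p appended ghost rows diag(d_1..d_p), d_k = 1/sigma_k."""

    values: np.ndarray          # (n + p, p)
    ghost_weights: np.ndarray   # length p, the appended diagonal d_k > 0
    source: FeatureMatrix


@dataclass
class ReflectionResult:
    """Reflections Y, residual halves Z = (X - Y)/2 and diagonal T = diag cov(X, Z).

    All covariances are computed on the first n (non-ghost) rows with divisor
    n - 1. Without augmentation cov(X, Z) is exactly diagonal (to numerical
    precision) and T_j = var(Z_j); with augmentation T is *defined* as the
    diagonal and ``max_offdiag`` reports the largest ignored off-diagonal
    magnitude as a diagnostic.
    """

    Y: np.ndarray               # (n, p)
    Z: np.ndarray               # (n, p)
    T: np.ndarray               # length p, positive
    augmented: bool
    cov_convention: str = "n-1"
    max_offdiag: float = 0.0


def augment(X: FeatureMatrix, prior_var: np.ndarray) -> AugmentedMatrix:
    """Append ghost rows implementing ridge penalties 1/sigma_j^2.

    ``prior_var`` holds the per-feature prior variances sigma_j^2 > 0; the
    appended rows are diag(1/sigma_j). With sigma_j^2 = 1/p for all j the
    ghost block is sqrt(p) * I.
    """
    s2 = np.asarray(prior_var, dtype=float)
    if s2.shape != (X.p,):
        raise ValueError(f"expected {X.p} prior variances, got shape {s2.shape}")
    if np.any(~np.isfinite(s2)) or np.any(s2 <= 0):
        raise ValueError("prior variances must be positive and finite")
    d = 1.0 / np.sqrt(s2)
    values = np.vstack([X.values, np.diag(d)])
    return AugmentedMatrix(values=values, ghost_weights=d, source=X)


def _givens(a: float, b: float) -> tuple[float, float]:
    """Rotation (c, s) with [[c, s], [-s, c]] @ [a, b] = [r, 0]."""
    if b == 0.0:
        return 1.0, 0.0
    r = np.hypot(a, b)
    return a / r, b / r


def _reflect_column(R: np.ndarray, j: int) -> np.ndarray:
    """Reflected j-th column of R: 2 * R_{,-j} @ beta_hat - R_j.

    R is p x p upper triangular from the QR of the (augmented) matrix.
    Givens rotations are applied left-to-right on the columns right of the
    removed one; the rotation order does not affect the least-squares
    solution.
    """
    p = R.shape[0]
    U = np.delete(R, j, axis=1).copy()   # p x (p-1), upper Hessenberg below col j
    v = R[:, j].copy()
    for k in range(j, p - 1):
        a, b = U[k, k], U[k + 1, k]
        c, s = _givens(a, b)
        if s != 0.0:
            rows = np.array([k, k + 1])
            G = np.array([[c, s], [-s, c]])
            U[rows, k:] = G @ U[rows, k:]
            v[rows] = G @ v[rows]
    diag = np.abs(np.diag(U[: p - 1, :]))
    scale = np.abs(U).max() or 1.0
    if np.any(diag <= _RANK_TOL * scale):
        raise np.linalg.LinAlgError("triangular system is singular")
    beta = linalg.solve_triangular(U[: p - 1, :], v[: p - 1])
    return 2.0 * np.delete(R, j, axis=1) @ beta - R[:, j]


def reflect(Xa: AugmentedMatrix | FeatureMatrix) -> ReflectionResult:
    """Reflect every column over the span of the others; return Y, Z and T.

    Accepts either a plain standardized :class:`FeatureMatrix` (no shrinkage;
    requires n > p and full rank) or an :class:`AugmentedMatrix` with ghost
    rows (always full rank, works for any n, p >= 2).

    Raises
    ------
    ValueError
        if the matrix is rank deficient (only possible without ghost rows);
        the message suggests enabling augmentation.
    """
    if isinstance(Xa, AugmentedMatrix):
        source = Xa.source
        work = Xa.values
        augmented = True
    else:
        source = Xa
        work = Xa.values
        augmented = False
    n, p = source.values.shape
    if work.shape[0] <= p:
        raise ValueError(
            f"need more rows than features ({work.shape[0]} rows, {p} features); "
            "enable ghost-sample augmentation for wide matrices"
        )

    Q, R = np.linalg.qr(work, mode="reduced")
    if np.any(np.abs(np.diag(R)) <= _RANK_TOL * np.abs(R).max()):
        raise ValueError(
            "feature matrix is rank deficient; enable ghost-sample augmentation "
            "(shrinkage priors) to proceed"
        )

    Rt = np.empty_like(R)
    try:
        for j in range(p):
            Rt[:, j] = _reflect_column(R, j)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "reflection regression is singular; enable ghost-sample augmentation"
        ) from exc

    Y = (Q @ Rt)[:n, :]
    X = source.values
    Z = (X - Y) / 2.0
    C = sample_cov(X, Z)
    T = np.diag(C).copy()
    off = C - np.diag(np.diag(C))
    max_offdiag = float(np.abs(off).max()) if p > 1 else 0.0
    if np.any(T <= 0):
        j = int(np.argmin(T))
        raise ValueError(
            f"non-positive residual covariance T for feature "
            f"{source.feature_names[j]!r}; the matrix is (numerically) rank "
            "deficient — enable ghost-sample augmentation"
        )
    return ReflectionResult(
        Y=Y, Z=Z, T=T, augmented=augmented,
        cov_convention=f"n-{COV_DDOF}", max_offdiag=max_offdiag,
    )
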