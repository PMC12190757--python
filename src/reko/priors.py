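"""Empirical-Bayes shrinkage priors for the reflection regressions.

Each column regression ``X_j = X_{,-j} beta + e`` carries a Gaussian prior
``beta ~ N(0, tau^-1 sigma_j^2 I)``. Integrating beta out, the marginal
likelihood of X_j given X_{,-j} is a normal with covariance
``tau^-1 (sigma_j^2 X_{,-j} X_{,-j}' + I)``; rotating by the eigenvectors of
``X_{,-j} X_{,-j}' = Q D Q'`` diagonalizes it, so with u = Q' X_j and
eigenvalues d the log marginal likelihood, profiled over tau at its ML value,
is (up to an additive constant)

    l(s) = -(m/2) log( sum_i u_i^2 / (s d_i + 1) ) - (1/2) sum_i log(s d_i + 1)

with s = sigma_j^2. Each sigma_j^2 is estimated by bisection on dl/ds over
(1e-6, 1]; the upper bound 1 is a practical cap on the prior variance of a
standardized regression.

A per-feature eigendecomposition of X_{,-j} X_{,-j}' would cost O(n p^3)
overall. Instead the eigenvectors of X X' are shared across j and only the
eigenvalues are downdated: X_{,-j} X_{,-j}' = X X' - x_j x_j', a symmetric
rank-one downdate whose eigenvalues are the roots of the secular equation

    1 - sum_i z_i^2 / (d_i - mu) = 0,     z = Q' x_j,

solved by bisection between interlacing brackets. For n >> p the nonzero
eigenpairs of X X' come cheaply from the p x p Gram matrix X'X; a randomized
SVD provides approximate leading eigenpairs when even that is too large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import FeatureMatrix
from ._rng import substream

__all__ = [
    "PriorEstimate",
    "profile_loglik",
    "estimate_sigma_j",
    "eigen_downdate",
    "rsvd_topk",
    "estimate_priors",
]

SIGMA2_LO = 1e-6   # lower end of the bisection interval
SIGMA2_HI = 1.0    # practical upper bound on sigma_j^2
_DEFAULT_FLAT = None  # sentinel; flat likelihood returns 1/p, filled per call


def profile_loglik(sigma2: float, d: np.ndarray, u2: np.ndarray) -> float:
    """Log marginal likelihood of one column regression, tau profiled out.

    Parameters
    ----------
    sigma2 : prior variance s > 0 at which to evaluate.
    d : nonnegative eigenvalues of X_{,-j} X_{,-j}' (length m <= n).
    u2 : squared rotated response (Q' X_j)**2, same length.

    Returns the value up to an additive constant independent of ``sigma2``.
    """
    d = np.asarray(d, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if d.shape != u2.shape:
        raise ValueError("d and u2 must have the same length")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not np.any(u2 > 0):
        raise ValueError("all rotated responses are zero (degenerate response)")
    m = d.size
    w = sigma2 * d + 1.0
    return float(-(m / 2.0) * np.log(np.sum(u2 / w)) - 0.5 * np.sum(np.log(w)))


def _dloglik(sigma2: float, d: np.ndarray, u2: np.ndarray) -> float:
    """Derivative of :func:`profile_loglik` with respect to sigma2."""
    m = d.size
    w = sigma2 * d + 1.0
    num = np.sum(u2 * d / w**2)
    den = np.sum(u2 / w)
    return float((m / 2.0) * num / den - 0.5 * np.sum(d / w))


def estimate_sigma_j(
    d: np.ndarray,
    u2: np.ndarray,
    tol: float = 1e-6,
) -> tuple[float, str]:
    """Maximize the profiled marginal likelihood over sigma2 in (1e-6, 1].

    Bisection on the derivative of :func:`profile_loglik`. Returns
    ``(sigma2_hat, flag)`` with flag ``"interior"`` for a bracketed root,
    ``"boundary"`` when the derivative has the same sign at both ends (the
    better endpoint is returned), or ``"flat"`` when the likelihood carries
    no information about sigma2 (all d == 0).
    """
    d = np.asarray(d, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if d.shape != u2.shape:
        raise ValueError("d and u2 must have the same length")
    if not np.any(u2 > 0):
        raise ValueError("all rotated responses are zero (degenerate response)")
    if not np.any(d > 0):
        return SIGMA2_HI, "flat"
    lo, hi = SIGMA2_LO, SIGMA2_HI
    g_lo, g_hi = _dloglik(lo, d, u2), _dloglik(hi, d, u2)
    if g_lo <= 0 and g_hi <= 0:
        return lo, "boundary"
    if g_lo >= 0 and g_hi >= 0:
        return hi, "boundary"
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _dloglik(mid, d, u2) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), "interior"


def _secular_downdate(d: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues and rotated responses of ``D - z z'`` for diagonal D.

    Solves the secular equation ``1 - sum_i z_i^2 / (d_i - mu) = 0`` per
    eigenvalue by bisection between the interlacing brackets
    ``d_{i+1} <= mu_i <= d_i`` (``d_m - ||z||^2 <= mu_m`` for the smallest);
    the secular function is strictly decreasing between poles, so each
    bracket holds exactly one root. Coordinates with negligible ``z_i`` are
    deflated (eigenvalue unchanged, eigenvector a coordinate axis).

    Returns ``(mu, u)`` sorted by descending eigenvalue, where
    ``u_i = v_i' z`` is the response ``z`` expressed in the downdated
    eigenbasis, with eigenvectors from the rank-one update formula
    ``v_i propto (D - mu_i I)^{-1} z``.
    """
    m = d.size
    order = np.argsort(d)[::-1]
    d_s, z_s = d[order], z[order]
    z2_s = z_s**2
    znorm2 = float(z2_s.sum())
    scale = max(abs(d_s[0]) if m else 1.0, znorm2, 1.0)
    if znorm2 == 0.0:
        return d_s, z_s
    keep = z2_s > 1e-14 * scale          # deflation: z_i ~ 0 leaves d_i fixed
    dk, zk = d_s[keep], z_s[keep]
    zk2 = zk**2
    mk = dk.size
    if mk == 0:
        return d_s, z_s

    # brackets: (d_{i+1}, d_i) for i < mk-1, (d_last - ||z||^2, d_last) for last
    hi = dk.copy()
    lo = np.empty(mk)
    lo[: mk - 1] = dk[1:]
    lo[mk - 1] = dk[mk - 1] - znorm2
    pad = np.maximum(1e-14 * scale, 1e-12 * (hi - lo))
    a = np.minimum(lo + pad, hi)
    b = np.maximum(hi - pad, lo)

    def f(mu: np.ndarray) -> np.ndarray:
        # secular function, vectorized over all roots at once
        diff = dk[None, :] - mu[:, None]
        diff = np.where(diff == 0.0, 1e-300, diff)
        return 1.0 - (zk2[None, :] / diff).sum(axis=1)

    fa, fb = f(a), f(b)
    lo_b, hi_b = a.copy(), b.copy()
    active = (hi_b - lo_b) > 0
    for _ in range(90):
        if not active.any():
            break
        mid = 0.5 * (lo_b + hi_b)
        fm = f(mid)
        go_up = fm > 0  # f decreases between poles: positive => root above mid
        lo_b = np.where(active & go_up, mid, lo_b)
        hi_b = np.where(active & ~go_up, mid, hi_b)
        active = active & ((hi_b - lo_b) > 1e-16 * scale)
    roots = 0.5 * (lo_b + hi_b)
    # bracket failure (same sign at both nudged ends): the root sits within
    # the nudge of an endpoint; clamp to the better one
    bad = (fa > 0) == (fb > 0)
    if bad.any():
        roots = np.where(bad, np.where(np.abs(fa) < np.abs(fb), a, b), roots)

    # rotated response via the update eigenvector formula v_i ~ (D - mu_i)^-1 z
    diff = dk[None, :] - roots[:, None]
    tiny = 1e-300
    diff = np.where(diff == 0.0, tiny, diff)
    Wv = zk[None, :] / diff
    norms = np.linalg.norm(Wv, axis=1)
    u_roots = (Wv @ zk) / np.where(norms == 0, 1.0, norms)

    mu = np.concatenate([roots, d_s[~keep]])
    u = np.concatenate([u_roots, z_s[~keep]])
    srt = np.argsort(mu)[::-1]
    return mu[srt], u[srt]


def eigen_downdate(
    eigvals: np.ndarray,
    eigvecs: np.ndarray,
    xj: np.ndarray,
) -> np.ndarray:
    """Eigenvalues of ``A - xj xj'`` given the eigendecomposition ``A = Q D Q'``.

    Rotates xj into the eigenbasis (z = Q' xj) and solves the rank-one
    downdate secular equation by bisection between interlacing brackets.
    Returns the downdated eigenvalues in descending order. With exact
    eigenvectors this matches a dense eigendecomposition of the downdated
    matrix; with truncated (approximate) eigenvectors it approximates the
    leading eigenvalues.
    """
    d = np.asarray(eigvals, dtype=float)
    Q = np.asarray(eigvecs, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if Q.shape != (xj.size, d.size):
        raise ValueError("eigvecs must be (len(xj), len(eigvals))")
    z = Q.T @ xj
    mu, _ = _secular_downdate(d, z)
    return mu


def rsvd_topk(
    X: np.ndarray,
    k: int,
    seed: int,
    n_oversample: int = 10,
    n_power: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Approximate top-k eigenpairs of X X' by randomized range finding.

    Gaussian sketch with ``n_oversample`` extra columns and ``n_power``
    power iterations; returns ``(eigvals, eigvecs)`` with eigvals descending.
    ``k`` beyond the rank of X is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    r = min(n, p)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > r:
        warnings.warn(
            f"k={k} exceeds min(n, p)={r}; truncating to {r}", stacklevel=2
        )
        k = r
    rng = substream(seed, "rsvd")
    l = min(k + n_oversample, r)
    G = rng.standard_normal((p, l))
    Y = X @ G
    for _ in range(n_power):
        Y, _ = np.linalg.qr(Y)
        Y = X @ (X.T @ Y)
    Q, _ = np.linalg.qr(Y)
    B = Q.T @ X
    Ub, s, _ = np.linalg.svd(B, full_matrices=False)
    eigvals = s[:k] ** 2
    eigvecs = Q @ Ub[:, :k]
    return eigvals, eigvecs


@dataclass
class PriorEstimate:
    """Per-feature empirical-Bayes prior variances sigma_j^2 in (0, 1]."""

    sigma2: np.ndarray            # length p
    method: str                   # exact | rank-one-update | rsvd
    k_eigenpairs: int
    loglik_at_opt: np.ndarray     # length p
    flags: list[str] = field(default_factory=list)  # per-feature fit flags


def _exact_eigpairs(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All nonzero eigenpairs of X X' via the cheaper Gram matrix side."""
    n, p = X.shape
    if p <= n:
        lam, V = np.linalg.eigh(X.T @ X)
        lam = np.maximum(lam, 0.0)
        order = np.argsort(lam)[::-1]
        lam, V = lam[order], V[:, order]
        pos = lam > 1e-12 * max(lam[0], 1.0)
        lam, V = lam[pos], V[:, pos]
        U = X @ V / np.sqrt(lam)
        return lam, U
    lam, U = np.linalg.eigh(X @ X.T)
    order = np.argsort(lam)[::-1]
    return np.maximum(lam[order], 0.0), U[:, order]


def estimate_priors(
    X: FeatureMatrix,
    mode: str = "rank-one-update",
    k: int | None = None,
    seed: int = 0,
    tol: float = 1e-6,
) -> PriorEstimate:
    """Empirical-Bayes sigma_j^2 for every feature of a standardized matrix.

    Modes
    -----
    ``exact``
        dense eigendecomposition of X_{,-j} X_{,-j}' for every j; the slow
        reference, quadratic-to-cubic per feature.
    ``rank-one-update`` (default)
        one eigendecomposition of X X', then per-j rank-one eigenvalue
        downdates with shared eigenvectors.
    ``rsvd``
        like rank-one-update but with randomized top-k eigenpairs,
        k defaulting to min(200, n, p).

    Features whose likelihood is flat in sigma2 receive the default 1/p
    (flag ``"flat"``); boundary solutions are flagged ``"boundary"``.
    """
    if mode not in {"exact", "rank-one-update", "rsvd"}:
        raise ValueError(f"unknown mode {mode!r}")
    V = X.values
    n, p = V.shape
    if k is None:
        k = min(200, n, p)
    sigma2 = np.empty(p)
    loglik = np.empty(p)
    flags: list[str] = []

    if mode == "exact":
        for j in range(p):
            Xm = np.delete(V, j, axis=1)
            lam, U = np.linalg.eigh(Xm @ Xm.T)
            d = np.maximum(lam, 0.0)
            u2 = (U.T @ V[:, j]) ** 2
            sigma2[j], flag = _fit_one(d, u2, p, tol)
            flags.append(flag)
            loglik[j] = profile_loglik(sigma2[j], d, u2)
        return PriorEstimate(sigma2, "exact", min(n, p), loglik, flags)

    if mode == "rank-one-update":
        d0, U = _exact_eigpairs(V)
        k_used = d0.size
    else:
        d0, U = rsvd_topk(V, k, seed)
        k_used = d0.size

    for j in range(p):
        xj = V[:, j]
        z = U.T @ xj
        dd, u = _secular_downdate(d0, z)
        dd = np.maximum(dd, 0.0)
        u2 = u**2
        # energy of x_j outside the retained eigenspace acts as extra
        # zero-eigenvalue coordinates; total coordinate count stays n
        rest = max(0.0, float(xj @ xj - (z**2).sum()))
        m_rest = n - dd.size
        if m_rest > 0:
            d_full = np.concatenate([dd, np.zeros(m_rest)])
            u2_full = np.concatenate([u2, [rest], np.zeros(m_rest - 1)])
        else:
            d_full, u2_full = dd, u2
        sigma2[j], flag = _fit_one(d_full, u2_full, p, tol)
        flags.append(flag)
        loglik[j] = profile_loglik(sigma2[j], d_full, u2_full)
    return PriorEstimate(sigma2, mode, k_used, loglik, flags)


def _fit_one(d: np.ndarray, u2: np.ndarray, p: int, tol: float) -> tuple[float, str]:
    s, flag = estimate_sigma_j(d, u2, tol)
    if flag == "flat":
        return 1.0 / p, "flat"   # the natural default prior variance
    return s, flag
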