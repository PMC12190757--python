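"""Knockoff construction from reflections.

Valid knockoffs must reproduce the second-moment structure

    cov([X, Xt]) = [[Sigma, Sigma - S], [Sigma - S, Sigma]]

for a diagonal S >= 0 with 2S - S Sigma^-1 S >= 0. Reflection knockoffs take
S = alpha * T with T = diag cov(X, Z) from the Householder reflection and the
largest admissible scalar alpha. Writing C = cov(Z T^-1/2) = Q Lambda Q', the
conditional covariance of the knockoff given X is

    2 alpha T - alpha^2 cov(Z) = T^1/2 Q (2 alpha I - alpha^2 Lambda) Q' T^1/2,

which is PSD iff alpha <= 2 / Lambda_1. The estimate alpha_hat = min(1, 2/Lambda_1)
needs no optimization. Knockoffs are sampled as

    Xt = X - alpha_hat Z + U B Q' T^1/2,   B = diag sqrt(2 alpha_hat - alpha_hat^2 Lambda_j),

with U either i.i.d. standard normal columns (Model-X flavored; the default)
or an orthonormal basis of the null space of [X, 1] scaled to unit sample
variance, which makes the second-moment identities exact in sample.

The equicorrelated second-order Model-X construction is provided as the
baseline comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .matrix import COV_DDOF, FeatureMatrix, sample_cov
from .reflection import ReflectionResult
from ._rng import substream

__all__ = [
    "KnockoffFactorization",
    "compute_alpha",
    "construct_knockoffs",
    "modelx_knockoffs",
    "second_moment_check",
]


@dataclass
class KnockoffFactorization:
    """Spectral pieces of the reflection-knockoff conditional covariance."""

    alpha_hat: float          # min(1, 2/Lambda_1)
    alpha_unclipped: float    # 2/Lambda_1 before the cap at 1
    lam: np.ndarray           # eigenvalues Lambda of C = cov(Z T^-1/2), descending
    Q: np.ndarray             # p x p orthonormal eigenvectors, columns match lam
    S: np.ndarray             # length p, alpha_hat * T
    B: np.ndarray             # length p, sqrt(max(0, 2 alpha - alpha^2 Lambda_j))
    T: np.ndarray             # length p, carried along for sampling
    noise_mode: str = "gaussian"


def compute_alpha(R: ReflectionResult) -> KnockoffFactorization:
    """Estimate alpha_hat and factor the knockoff noise covariance.

    Forms C = cov(Z T^-1/2), eigendecomposes its symmetrized version, and
    sets alpha_hat = min(1, 2/Lambda_1); S = alpha_hat * T. Entries of
    2 alpha - alpha^2 Lambda_j that are negative only by floating-point
    noise are clipped at zero before the square root.
    """
    T = np.asarray(R.T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("all T_j must be positive; rerun reflection with augmentation")
    scale = 1.0 / np.sqrt(T)
    C = sample_cov(R.Z * scale[None, :])
    C = (C + C.T) / 2.0
    p = C.shape[0]
    offdiag = C - np.diag(np.diag(C))
    if np.abs(offdiag).max() <= 1e-12:
        # numerically diagonal C (uncorrelated features): the eigenbasis is
        # degenerate, so fix Q = I rather than an arbitrary rotation
        lam, Q = np.diag(C).copy(), np.eye(p)
    else:
        lam, Q = np.linalg.eigh(C)
        order = np.argsort(lam)[::-1]
        lam, Q = lam[order], Q[:, order]
    lam1 = float(lam.max())
    if lam1 <= 0:
        raise ValueError("leading eigenvalue of cov(Z T^-1/2) is not positive")
    alpha_un = 2.0 / lam1
    alpha = min(1.0, alpha_un)
    B2 = 2.0 * alpha - alpha**2 * lam
    B = np.sqrt(np.clip(B2, 0.0, None))
    return KnockoffFactorization(
        alpha_hat=alpha,
        alpha_unclipped=alpha_un,
        lam=lam,
        Q=Q,
        S=alpha * T,
        B=B,
        T=T,
    )


def _nullspace_noise(X: np.ndarray, p: int) -> np.ndarray:
    """p orthonormal directions orthogonal to col(X) and the constant vector.

    Columns are exactly centered and mutually orthonormal, then scaled by
    sqrt(n - 1) so each has unit sample variance; this makes the knockoff
    second moments exact in sample (not just in expectation).
    """
    n = X.shape[0]
    if n < 2 * p + 1:
        raise ValueError(
            f"null-space noise needs n >= 2p + 1 (got n={n}, p={p}); "
            "use gaussian noise mode instead"
        )
    A = np.hstack([X, np.ones((n, 1))])
    ns = linalg.null_space(A.T)
    if ns.shape[1] < p:
        raise ValueError(
            "null space of [X, 1] has fewer than p directions; "
            "use gaussian noise mode instead"
        )
    return ns[:, :p] * np.sqrt(n - COV_DDOF)


def construct_knockoffs(
    X: FeatureMatrix,
    R: ReflectionResult,
    F: KnockoffFactorization,
    noise_mode: str = "gaussian",
    seed: int = 0,
    copy_index: int = 0,
) -> np.ndarray:
    """Sample one knockoff copy Xt = X - alpha Z + U B Q' T^1/2.

    ``gaussian`` noise draws U with i.i.d. standard normal columns (seeded;
    ``copy_index`` distinguishes multiple copies). ``nullspace`` noise uses
    an orthonormal basis of the complement of span([X, 1]), which requires
    n >= 2p + 1 and reproduces the knockoff covariance identities exactly.
    """
    if noise_mode not in {"gaussian", "nullspace"}:
        raise ValueError(f"unknown noise mode {noise_mode!r}")
    V = X.values
    n, p = V.shape
    if noise_mode == "gaussian":
        rng = substream(seed, "knockoff-noise", copy_index)
        U = rng.standard_normal((n, p))
    else:
        U = _nullspace_noise(V, p)
    F.noise_mode = noise_mode
    noise = (U * F.B[None, :]) @ F.Q.T * np.sqrt(F.T)[None, :]
    return V - F.alpha_hat * R.Z + noise


def modelx_knockoffs(
    X: FeatureMatrix,
    seed: int = 0,
    shrink: bool = True,
    copy_index: int = 0,
) -> np.ndarray:
    """Second-order Gaussian knockoffs with equicorrelated S.

    Estimates the feature correlation matrix (Ledoit-Wolf shrunk when
    ``shrink``), sets S = min(1, 2 lambda_min) I, and samples from the
    conditional Gaussian Xt | X = X (I - Sigma^-1 S) + N C with
    C'C = 2S - S Sigma^-1 S.
    """
    V = X.values
    n, p = V.shape
    if p < 2:
        raise ValueError("need p >= 2")
    if shrink:
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf(assume_centered=True).fit(V).covariance_
        dd = np.sqrt(np.diag(cov))
        Sigma = cov / np.outer(dd, dd)
    else:
        Sigma = sample_cov(V)
    lam, W = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    if lam.min() <= 1e-10:
        raise ValueError(
            "feature covariance is singular; enable shrinkage (shrink=True)"
        )
    s = min(1.0, 2.0 * float(lam.min()))
    # mean: X (I - Sigma^-1 s) ; noise covariance: 2 s I - s^2 Sigma^-1
    Sig_inv = (W / lam) @ W.T
    mean = V - s * (V @ Sig_inv)
    noise_eig = np.clip(2.0 * s - s**2 / lam, 0.0, None)
    Chalf = (W * np.sqrt(noise_eig)) @ W.T
    rng = substream(seed, "modelx-noise", copy_index)
    N = rng.standard_normal((n, p))
    return mean + N @ Chalf


def second_moment_check(
    X: np.ndarray | FeatureMatrix,
    Xt: np.ndarray,
    S: np.ndarray,
) -> dict[str, float]:
    """Max absolute deviations of cov([X, Xt]) from the knockoff targets.

    Targets: cov(Xt) = cov(X); cov(X_j, Xt_k) = cov(X_j, X_k) for j != k;
    cov(X_j, Xt_j) = var(X_j) - S_j.
    """
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    Xt = np.asarray(Xt, dtype=float)
    if V.shape != Xt.shape:
        raise ValueError("X and knockoff shapes differ")
    S = np.asarray(S, dtype=float)
    Sig = sample_cov(V)
    cov_tt = sample_cov(Xt)
    cov_xt = sample_cov(V, Xt)
    dev_tt = float(np.abs(cov_tt - Sig).max())
    cross_target = Sig - np.diag(S)
    off = cov_xt - cross_target
    dev_diag = float(np.abs(np.diag(off)).max())
    off_no_diag = off - np.diag(np.diag(off))
    dev_off = float(np.abs(off_no_diag).max()) if V.shape[1] > 1 else 0.0
    return {
        "knockoff_cov": dev_tt,
        "cross_cov_offdiag": dev_off,
        "cross_cov_diag": dev_diag,
        "max": max(dev_tt, dev_off, dev_diag),
    }
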