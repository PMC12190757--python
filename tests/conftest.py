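"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's computational paths:
reflections are recomputed from per-column normal equations, thresholds by a
plain loop over candidates, and posterior inclusion probabilities by exact
enumeration of all models.
"""

from itertools import product

import numpy as np
import pytest

from reko import FeatureMatrix, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def orthogonal_design(n: int, p: int, seed: int = 0) -> FeatureMatrix:
    """Standardized matrix with exactly orthogonal, exactly centered columns."""
    rng = np.random.default_rng(seed)
    G = np.hstack([np.ones((n, 1)), rng.standard_normal((n, p))])
    Q, _ = np.linalg.qr(G)
    V = Q[:, 1:] * np.sqrt(n - 1)  # orthogonal to 1 => centered; unit variance
    return FeatureMatrix(V, [f"f{j + 1}" for j in range(p)])


def correlated_pair(n: int, r: float, seed: int = 0) -> FeatureMatrix:
    """Two standardized columns with *exact* sample correlation r."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    a -= a.mean()
    a /= a.std(ddof=1)
    b = rng.standard_normal(n)
    b -= b.mean()
    b -= a * (a @ b) / (a @ a)
    b /= b.std(ddof=1)
    x2 = r * a + np.sqrt(1 - r**2) * b
    return FeatureMatrix(np.column_stack([a, x2]), ["x1", "x2"])


def reflect_oracle(V: np.ndarray, ridge: np.ndarray | None = None) -> np.ndarray:
    """Per-column normal-equations reflection: Y_j = 2 fit_j - X_j.

    ``ridge`` gives per-feature penalties 1/sigma_k^2 added to the Gram
    diagonal of the retained covariates (the ghost-row model).
    """
    n, p = V.shape
    Y = np.empty_like(V)
    for j in range(p):
        Xm = np.delete(V, j, axis=1)
        G = Xm.T @ Xm
        if ridge is not None:
            G = G + np.diag(np.delete(ridge, j))
        beta = np.linalg.solve(G, Xm.T @ V[:, j])
        Y[:, j] = 2 * Xm @ beta - V[:, j]
    return Y


def threshold_oracle(W: np.ndarray, q: float, variant: str) -> float:
    """Brute-force scan of Eq.-style candidate thresholds."""
    offset = 1 if variant == "knockoff_plus" else 0
    best = np.inf
    for t in sorted(set(np.abs(W[W != 0]))):
        neg = int(np.sum(W <= -t))
        pos = int(np.sum(W >= t))
        if (neg + offset) / max(pos, 1) <= q:
            best = t
            break
    return best


def exact_pips(W: np.ndarray, y: np.ndarray, pi0: float, v: float) -> np.ndarray:
    """Posterior inclusion probabilities by enumeration of all 2^K models.

    Conjugate spike-and-slab with slab N(0, v sigma2) and Jeffreys prior on
    sigma2; the per-model marginal likelihood is available in closed form,
    so the PIPs are exact. Feasible only for small K.
    """
    n, K = W.shape
    yc = y - y.mean()
    yy = yc @ yc
    lo = np.log(pi0) - np.log1p(-pi0)
    logws, gammas = [], []
    for bits in product([0, 1], repeat=K):
        g = np.array(bits, bool)
        k = int(g.sum())
        if k == 0:
            lm = -(n / 2) * np.log(yy)
        else:
            Wg = W[:, g]
            A = np.eye(k) + v * (Wg.T @ Wg)
            _, ld = np.linalg.slogdet(A)
            Wy = Wg.T @ yc
            S = yy - v * Wy @ np.linalg.solve(A, Wy)
            lm = -0.5 * ld - (n / 2) * np.log(S)
        logws.append(lm + k * lo)
        gammas.append(g)
    logws = np.array(logws)
    w = np.exp(logws - logws.max())
    w /= w.sum()
    return w @ np.array(gammas)
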