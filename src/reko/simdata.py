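"""Synthetic data generation and the power / realized-FDR benchmark harness.

Feature matrices are multivariate Gaussian with independent, AR(1) or
block-equicorrelated covariance (or loaded from a user matrix), then
standardized. Phenotypes are linear: a uniformly drawn causal subset gets
standard-normal effect sizes, and the noise variance is set so the proportion
of variance explained (PVE) by the causal predictor matches a target.

The benchmark loop generates replicates, builds M knockoff copies per method,
computes knockoff statistics, aggregate-selects at each nominal FDR level q,
and pools true/false positives over replicates:

    power = pooled TP / pooled causal count
    realized FDR = pooled FP / max(pooled selections, 1)

with binomial Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from .matrix import FeatureMatrix, standardize
from .reflection import augment, reflect
from .sampler import compute_alpha, construct_knockoffs, modelx_knockoffs
from .filter import KnockoffStatsSet, aggregate_select, knockoff_stats, lasso_importance
from .priors import estimate_priors
from ._rng import substream

__all__ = [
    "SimulationConfig",
    "BenchmarkResult",
    "gen_features",
    "gen_phenotype",
    "trim_features",
    "evaluate",
    "run_benchmark",
    "make_reko_stats",
]


@dataclass
class SimulationConfig:
    """Study conditions for one benchmark run."""

    n: int = 800
    p: int = 150
    structure: str = "ar1"            # independent | ar1 | block | from_matrix
    rho: float = 0.5
    block_size: int = 10
    matrix_path: str | None = None
    n_causal: int = 20
    pve: float = 0.5
    q_grid: tuple[float, ...] = (0.1,)
    replicates: int = 100
    copies: int = 3                    # knockoff copies M aggregated per replicate
    methods: tuple[str, ...] = ("reko",)
    variant: str = "knockoff_plus"
    priors: str = "eb"                 # eb | fixed (sigma2 = 1/p)
    noise_mode: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pve < 1:
            raise ValueError("pve must be in (0, 1)")
        if self.n_causal > self.p:
            raise ValueError("n_causal cannot exceed p")


@dataclass
class BenchmarkResult:
    """Pooled power / realized FDR per (method, q)."""

    table: pd.DataFrame
    config: SimulationConfig | None = None


def _covariance(p: int, structure: str, rho: float, block_size: int) -> np.ndarray:
    if structure == "independent":
        return np.eye(p)
    if structure == "ar1":
        if not -1 < rho < 1:
            raise ValueError("ar1 correlation must be in (-1, 1)")
        idx = np.arange(p)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if structure == "block":
        if not -1 < rho < 1:
            raise ValueError("block correlation must be in (-1, 1)")
        Sig = np.eye(p)
        for start in range(0, p, block_size):
            stop = min(start + block_size, p)
            Sig[start:stop, start:stop] = rho
        np.fill_diagonal(Sig, 1.0)
        return Sig
    raise ValueError(f"unknown structure {structure!r}")


def gen_features(
    n: int,
    p: int,
    structure: str = "ar1",
    seed: int = 0,
    rho: float = 0.5,
    block_size: int = 10,
    matrix_path: str | None = None,
) -> FeatureMatrix:
    """Gaussian features with the requested covariance, standardized.

    ``from_matrix`` loads a delimited matrix from ``matrix_path`` and
    standardizes it (header row of feature names expected).
    """
    if structure == "from_matrix":
        if matrix_path is None:
            raise ValueError("from_matrix requires matrix_path")
        from .io import read_matrix

        return read_matrix(matrix_path)
    Sig = _covariance(p, structure, rho, block_size)
    rng = substream(seed, "features")
    L = np.linalg.cholesky(Sig + 1e-12 * np.eye(p))
    raw = rng.standard_normal((n, p)) @ L.T
    return standardize(raw)


def gen_phenotype(
    X: FeatureMatrix,
    n_causal: int,
    pve: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear phenotype with standard-normal effects rescaled to a target PVE.

    A causal set of size ``n_causal`` is drawn uniformly; effects are i.i.d.
    standard normal; Gaussian noise variance is var(X beta) (1 - pve) / pve,
    so the realized proportion of variance explained matches ``pve`` in
    expectation. Returns ``(y, causal_indices, beta_full)``.
    """
    if not 0 < pve < 1:
        raise ValueError("pve must be strictly inside (0, 1)")
    if not 1 <= n_causal <= X.p:
        raise ValueError("need 1 <= n_causal <= p")
    rng = substream(seed, "phenotype")
    causal = np.sort(rng.choice(X.p, size=n_causal, replace=False))
    beta = np.zeros(X.p)
    beta[causal] = rng.standard_normal(n_causal)
    g = X.values @ beta
    var_g = float(np.var(g, ddof=1))
    if var_g == 0:
        var_g = 1e-12
    noise_var = var_g * (1.0 - pve) / pve
    y = g + rng.normal(scale=np.sqrt(noise_var), size=X.n)
    return y, causal, beta


def trim_features(
    X: FeatureMatrix,
    marginal_assoc: np.ndarray | None = None,
    r_max: float = 0.9,
    mode: str = "assoc",
    seed: int = 0,
) -> np.ndarray:
    """Greedily drop one of each feature pair correlated beyond ``r_max``.

    Pairs are visited in order of decreasing |correlation|; ``assoc`` mode
    drops the member with the weaker marginal association, ``random`` mode
    drops one uniformly (seeded). Returns the sorted indices of kept
    features; the kept submatrix has max off-diagonal |correlation| <= r_max.
    """
    if not 0 < r_max < 1:
        raise ValueError("r_max must be in (0, 1)")
    if mode not in {"assoc", "random"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "assoc":
        if marginal_assoc is None:
            raise ValueError("assoc mode needs marginal association strengths")
        assoc = np.abs(np.asarray(marginal_assoc, float))
        if assoc.size != X.p:
            raise ValueError("one association value per feature required")
    rng = substream(seed, "trim")
    C = np.corrcoef(X.values, rowvar=False)
    iu, ju = np.triu_indices(X.p, k=1)
    r = np.abs(C[iu, ju])
    hot = r > r_max
    order = np.argsort(-r[hot])
    pairs = list(zip(iu[hot][order], ju[hot][order]))
    removed: set[int] = set()
    for a, b in pairs:
        if a in removed or b in removed:
            continue
        if mode == "assoc":
            drop = a if assoc[a] < assoc[b] else b
        else:
            drop = a if rng.random() < 0.5 else b
        removed.add(int(drop))
    return np.array(sorted(set(range(X.p)) - removed), dtype=int)


def evaluate(
    selections: Sequence[np.ndarray],
    causal_sets: Sequence[np.ndarray],
) -> dict[str, float]:
    """Pooled power and realized FDR over replicates.

    power = pooled TP / pooled causal count;
    realized FDR = pooled FP / max(pooled selection count, 1).
    Standard errors use the binomial approximation at the pooled rates.
    """
    if len(selections) != len(causal_sets):
        raise ValueError("selections and causal sets must align per replicate")
    tp = fp = n_causal = n_sel = 0
    for sel, causal in zip(selections, causal_sets):
        sel = np.asarray(sel)
        causal = set(np.asarray(causal).tolist())
        hits = sum(1 for j in sel if int(j) in causal)
        tp += hits
        fp += sel.size - hits
        n_causal += len(causal)
        n_sel += sel.size
    power = tp / n_causal if n_causal else 0.0
    fdr = fp / max(n_sel, 1)
    se_power = float(np.sqrt(power * (1 - power) / n_causal)) if n_causal else 0.0
    se_fdr = float(np.sqrt(fdr * (1 - fdr) / max(n_sel, 1)))
    return {
        "power": power,
        "realized_fdr": fdr,
        "tp": tp,
        "fp": fp,
        "n_causal": n_causal,
        "n_selected": n_sel,
        "se_power": se_power,
        "se_fdr": se_fdr,
    }


def make_reko_stats(
    X: FeatureMatrix,
    y: np.ndarray,
    M: int,
    seed: int,
    priors: str = "eb",
    noise_mode: str = "gaussian",
) -> KnockoffStatsSet:
    """M reflection-knockoff lasso statistic sets for one dataset.

    The reflection and its spectral factorization are deterministic given X,
    so only the knockoff noise and the lasso fit vary across the M copies.
    """
    if priors == "eb":
        pe = estimate_priors(X, mode="rank-one-update", seed=seed)
        sigma2 = pe.sigma2
    elif priors == "fixed":
        sigma2 = np.full(X.p, 1.0 / X.p)
    else:
        raise ValueError(f"unknown priors {priors!r}")
    R = reflect(augment(X, sigma2))
    F = compute_alpha(R)
    W = np.empty((M, X.p))
    for m in range(M):
        Xt = construct_knockoffs(X, R, F, noise_mode=noise_mode, seed=seed,
                                 copy_index=m)
        imp = lasso_importance(X.values, Xt, y, seed=seed * 1000 + m)
        W[m] = knockoff_stats(imp)
    return KnockoffStatsSet(W=W, importance_kind="beta")


def _make_modelx_stats(X: FeatureMatrix, y: np.ndarray, M: int, seed: int) -> KnockoffStatsSet:
    W = np.empty((M, X.p))
    for m in range(M):
        Xt = modelx_knockoffs(X, seed=seed, copy_index=m)
        imp = lasso_importance(X.values, Xt, y, seed=seed * 1000 + m)
        W[m] = knockoff_stats(imp)
    return KnockoffStatsSet(W=W, importance_kind="beta")


def run_benchmark(config: SimulationConfig, log: bool = False) -> BenchmarkResult:
    """Run the full simulation loop and pool power / realized FDR.

    Fully seeded: replicate r derives every stream from (config.seed, r).
    Returns a tidy table with one row per (method, q).
    """
    records: dict[tuple[str, float], dict[str, list]] = {
        (m, q): {"sel": [], "causal": []}
        for m in config.methods
        for q in config.q_grid
    }
    for r in range(config.replicates):
        rep_seed = int(substream(config.seed, "replicate", r).integers(2**31 - 1))
        X = gen_features(
            config.n, config.p, config.structure, seed=rep_seed,
            rho=config.rho, block_size=config.block_size,
            matrix_path=config.matrix_path,
        )
        y, causal, _ = gen_phenotype(X, config.n_causal, config.pve, seed=rep_seed)
        for method in config.methods:
            if method == "reko":
                stats = make_reko_stats(
                    X, y, config.copies, rep_seed,
                    priors=config.priors, noise_mode=config.noise_mode,
                )
            elif method == "modelx":
                stats = _make_modelx_stats(X, y, config.copies, rep_seed)
            else:
                raise ValueError(f"unknown method {method!r}")
            for q in config.q_grid:
                sel = aggregate_select(stats, q, config.variant)
                records[(method, q)]["sel"].append(sel.selected)
                records[(method, q)]["causal"].append(causal)
        if log:
            print(f"replicate {r + 1}/{config.replicates} done")
    rows = []
    for (method, q), rec in records.items():
        stats = evaluate(rec["sel"], rec["causal"])
        rows.append({"method": method, "q": q, **stats})
    table = pd.DataFrame(rows).sort_values(["method", "q"]).reset_index(drop=True)
    return BenchmarkResult(table=table, config=config)
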