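"""Knockoff statistics, thresholding and multi-copy aggregation.

A knockoff statistic W_j = importance(X_j) - importance(Xt_j) is symmetric
about zero for null features, which is what makes the data-dependent
threshold

    T = min { t : #{j : W_j <= -t} / max(#{j : W_j >= t}, 1) <= q }

(over candidate t in the nonzero |W_j|) control the FDR at nominal level q;
the ``knockoff_plus`` variant adds 1 to the numerator and carries the exact
finite-sample guarantee.

Two importance measures are provided: the magnitude of cross-validated
lasso coefficients (frequentist) and posterior inclusion probabilities from
a spike-and-slab Gibbs sampler (Bayesian). Both fit the original features
and their knockoffs jointly.

Because knockoffs are random, M independently constructed copies yield M
identically distributed statistic vectors W^(1..M). Aggregation concatenates
them to estimate the threshold (a larger, more stable empirical null) and
selects features whose per-feature average W-bar_j clears it; averaging
preserves the null symmetry, so FDR control is retained. The combined filter
intersects the selections of two importance measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = [
    "KnockoffStatsSet",
    "SelectionResult",
    "lasso_importance",
    "pip_importance",
    "knockoff_stats",
    "knockoff_threshold",
    "aggregate_select",
    "combined_filter",
]


@dataclass
class KnockoffStatsSet:
    """M identically generated knockoff-statistic vectors for p features."""

    W: np.ndarray                 # (M, p)
    importance_kind: str = "beta"  # beta | pip

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))

    @property
    def M(self) -> int:
        return self.W.shape[0]

    @property
    def p(self) -> int:
        return self.W.shape[1]

    @property
    def W_bar(self) -> np.ndarray:
        """Per-feature average statistic across the M copies."""
        return self.W.mean(axis=0)

    @property
    def W_cat(self) -> np.ndarray:
        """Concatenation of all M copies (order irrelevant for thresholding)."""
        return self.W.ravel()


@dataclass
class SelectionResult:
    """Outcome of thresholding: selected feature indices at nominal level q."""

    threshold: float              # +inf means nothing selected
    selected: np.ndarray          # sorted integer indices
    q: float
    variant: str                  # knockoff | knockoff_plus
    aggregated: bool = False
    n_features: int = 0
    parents: list[str] = field(default_factory=list)


def _check_xy(X: np.ndarray, Xt: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    X = np.asarray(X, float)
    Xt = np.asarray(Xt, float)
    y = np.asarray(y, float).ravel()
    if X.shape != Xt.shape:
        raise ValueError("X and knockoff matrices must share a shape")
    if y.size != X.shape[0]:
        raise ValueError("phenotype length must equal the sample count")
    if np.std(y) == 0:
        raise ValueError("phenotype has zero variance")
    return X, Xt, y


def lasso_importance(
    X: np.ndarray,
    Xt: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    cv: int = 5,
    n_alphas: int = 50,
    alpha: float | None = None,
    l1_ratio: float = 0.95,
) -> np.ndarray:
    """|penalized regression coefficient| of each original and knockoff column.

    Fits an L1-dominated elastic-net regression of the centered phenotype on
    the 2p columns of [X, Xt]; the small ridge component (``l1_ratio`` < 1)
    makes the solution unique, so duplicated or perfectly exchangeable
    columns split their credit symmetrically instead of one of them
    arbitrarily absorbing it. The column order is randomly permuted per seed
    so that solver path order cannot systematically favor originals over
    knockoffs. The penalty is chosen by K-fold cross-validation unless a
    fixed ``alpha`` is supplied. Returns a length-2p nonnegative vector
    ordered (originals 1..p, knockoffs 1..p).
    """
    from sklearn.linear_model import ElasticNet, ElasticNetCV

    X, Xt, y = _check_xy(X, Xt, y)
    p = X.shape[1]
    design = np.hstack([X, Xt])
    rng = substream(seed, "lasso-interleave")
    perm = rng.permutation(2 * p)
    if alpha is None:
        model = ElasticNetCV(
            l1_ratio=l1_ratio,
            cv=cv,
            alphas=n_alphas,
            max_iter=3000,
            random_state=int(substream(seed, "lasso-cv").integers(2**31 - 1)),
        )
    else:
        model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=3000)
    model.fit(design[:, perm], y - y.mean())
    coef = np.empty(2 * p)
    coef[perm] = model.coef_
    return np.abs(coef)


def pip_importance(
    X: np.ndarray,
    Xt: np.ndarray,
    y: np.ndarray,
    mcmc: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Posterior inclusion probabilities from a spike-and-slab Gibbs sampler.

    Bayesian variable selection over the joint design [X, Xt]:
    y = W gamma*beta + e with e ~ N(0, sigma2 I), beta_j | gamma_j=1 ~
    N(0, slab_var * sigma2), gamma_j ~ Bernoulli(pi0). Single-site Gibbs
    updates of (gamma_j, beta_j) with sigma2 resampled each sweep. Returns
    the length-2p vector of posterior inclusion frequencies. Deterministic
    given the seed.

    ``mcmc`` keys (defaults): iters (2000), burnin (500), pi0 (1/p),
    slab_var (1.0).
    """
    X, Xt, y = _check_xy(X, Xt, y)
    n, p = X.shape
    opts = {"iters": 2000, "burnin": 500, "pi0": 1.0 / p, "slab_var": 1.0}
    if mcmc:
        opts.update(mcmc)
    iters, burnin = int(opts["iters"]), int(opts["burnin"])
    pi0, v = float(opts["pi0"]), float(opts["slab_var"])
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    if not 0 < pi0 < 1:
        raise ValueError("pi0 must be in (0, 1)")

    rng = substream(seed, "gibbs")
    W = np.hstack([X, Xt])
    yc = y - y.mean()
    k = 2 * p
    col_ss = (W**2).sum(axis=0)
    gamma = np.zeros(k, dtype=bool)
    beta = np.zeros(k)
    resid = yc.copy()
    sigma2 = float(np.var(yc)) or 1.0
    log_prior_odds = np.log(pi0) - np.log1p(-pi0)
    incl = np.zeros(k)

    for it in range(iters):
        order = rng.permutation(k)
        for j in order:
            wj = W[:, j]
            r_j = resid + wj * beta[j] if gamma[j] else resid
            prec = col_ss[j] / sigma2 + 1.0 / (v * sigma2)
            mu = (wj @ r_j) / sigma2 / prec
            # log Bayes factor for inclusion with beta integrated out
            log_bf = 0.5 * (mu**2 * prec) - 0.5 * np.log(v * sigma2 * prec)
            logit = log_prior_odds + log_bf
            include = rng.random() < 1.0 / (1.0 + np.exp(-logit))
            if include:
                b = mu + rng.standard_normal() / np.sqrt(prec)
                resid = r_j - wj * b
                beta[j], gamma[j] = b, True
            else:
                resid = r_j
                beta[j], gamma[j] = 0.0, False
        # Metropolized swap moves: exchange an included column with an
        # excluded one (betas integrated out conditional on the rest), so
        # the chain mixes across near-collinear features that share credit
        inc = np.flatnonzero(gamma)
        exc = np.flatnonzero(~gamma)
        for _ in range(max(1, inc.size)):
            if inc.size == 0 or exc.size == 0:
                break
            j = int(inc[rng.integers(inc.size)])
            kk = int(exc[rng.integers(exc.size)])
            r0 = resid + W[:, j] * beta[j]
            lf = {}
            for c in (j, kk):
                prec_c = col_ss[c] / sigma2 + 1.0 / (v * sigma2)
                mu_c = (W[:, c] @ r0) / sigma2 / prec_c
                lf[c] = 0.5 * mu_c**2 * prec_c - 0.5 * np.log(v * sigma2 * prec_c), mu_c, prec_c
            if np.log(rng.random()) < lf[kk][0] - lf[j][0]:
                _, mu_k, prec_k = lf[kk]
                b_new = mu_k + rng.standard_normal() / np.sqrt(prec_k)
                beta[j], gamma[j] = 0.0, False
                beta[kk], gamma[kk] = b_new, True
                resid = r0 - W[:, kk] * b_new
                inc = np.flatnonzero(gamma)
                exc = np.flatnonzero(~gamma)
        # conjugate update of the noise variance (Jeffreys prior)
        shape = 0.5 * (n + gamma.sum())
        rate = 0.5 * (resid @ resid + (beta[gamma] ** 2).sum() / v)
        sigma2 = float(rate / rng.gamma(shape, 1.0)) if rate > 0 else sigma2
        if it >= burnin:
            incl += gamma
    return incl / (iters - burnin)


def knockoff_stats(importance: np.ndarray) -> np.ndarray:
    """Difference statistic W_j = importance_j - importance_{knockoff j}.

    ``importance`` has length 2p ordered (originals, knockoffs).
    """
    imp = np.asarray(importance, dtype=float).ravel()
    if imp.size % 2:
        raise ValueError(f"importance length {imp.size} is not 2p")
    p = imp.size // 2
    return imp[:p] - imp[p:]


def knockoff_threshold(W: np.ndarray, q: float, variant: str = "knockoff") -> float:
    """Data-dependent selection threshold at nominal FDR level q.

    Scans candidate thresholds t over the nonzero |W_j| and returns the
    smallest t with  (#{W_j <= -t} + offset) / max(#{W_j >= t}, 1) <= q,
    offset 0 for ``knockoff`` and 1 for ``knockoff_plus``. Returns +inf
    (select nothing) when no candidate qualifies or W is empty/all zero.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if variant not in {"knockoff", "knockoff_plus"}:
        raise ValueError(f"unknown variant {variant!r}")
    W = np.asarray(W, dtype=float).ravel()
    candidates = np.unique(np.abs(W[W != 0]))
    if candidates.size == 0:
        import warnings

        warnings.warn("empty or all-zero knockoff statistics; nothing selectable",
                      stacklevel=2)
        return np.inf
    offset = 1.0 if variant == "knockoff_plus" else 0.0
    # vectorized counts over all candidates at once
    neg = (W[None, :] <= -candidates[:, None]).sum(axis=1)
    pos = (W[None, :] >= candidates[:, None]).sum(axis=1)
    ratio = (neg + offset) / np.maximum(pos, 1)
    ok = np.flatnonzero(ratio <= q)
    return float(candidates[ok[0]]) if ok.size else np.inf


def aggregate_select(
    stats: KnockoffStatsSet,
    q: float,
    variant: str = "knockoff",
) -> SelectionResult:
    """Threshold on the concatenated statistics, select on the averages.

    The threshold T_cat is computed from the pooled vector of all M*p
    statistics; feature j is selected when its average statistic W-bar_j
    >= T_cat. With M = 1 this is exactly the single-copy filter.
    """
    if stats.M < 1:
        raise ValueError("need at least one knockoff-statistic set")
    t_cat = knockoff_threshold(stats.W_cat, q, variant)
    # roundoff guard: averaging M identical copies can perturb W_bar by an
    # ulp, which must not flip a selection sitting exactly at the threshold
    tol = 1e-12 * max(1.0, abs(t_cat)) if np.isfinite(t_cat) else 0.0
    selected = np.flatnonzero(stats.W_bar >= t_cat - tol)
    return SelectionResult(
        threshold=t_cat,
        selected=selected,
        q=q,
        variant=variant,
        aggregated=stats.M > 1,
        n_features=stats.p,
    )


def combined_filter(selA: SelectionResult, selB: SelectionResult) -> SelectionResult:
    """Intersection filter: a feature is selected iff both filters select it."""
    if selA.n_features != selB.n_features:
        raise ValueError("selections come from different feature universes")
    if selA.q != selB.q:
        raise ValueError("selections use different nominal FDR levels")
    both = np.intersect1d(selA.selected, selB.selected)
    return SelectionResult(
        threshold=np.nan,
        selected=both,
        q=selA.q,
        variant=selA.variant,
        aggregated=selA.aggregated or selB.aggregated,
        n_features=selA.n_features,
        parents=[selA.variant, selB.variant],
    )
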