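"""Combine frequentist and Bayesian importance measures.

Runs the knockoff filter twice on the same data — once with penalized
regression coefficients (Beta) and once with posterior inclusion
probabilities (PIP) from a spike-and-slab sampler — and intersects the two
selections. The combined filter trades a little power for a tighter grip on
false discoveries, which matters when features are highly correlated.
"""

import numpy as np

from reko import (
    KnockoffStatsSet,
    aggregate_select,
    augment,
    combined_filter,
    compute_alpha,
    construct_knockoffs,
    estimate_priors,
    gen_features,
    gen_phenotype,
    knockoff_stats,
    lasso_importance,
    pip_importance,
    reflect,
)

n, p, M, q = 300, 40, 3, 0.15
X = gen_features(n=n, p=p, structure="block", rho=0.7, block_size=5, seed=11)
y, causal, _ = gen_phenotype(X, n_causal=5, pve=0.5, seed=11)

pe = estimate_priors(X, seed=11)
R = reflect(augment(X, pe.sigma2))
F = compute_alpha(R)

W_beta = np.empty((M, p))
W_pip = np.empty((M, p))
for m in range(M):
    Xt = construct_knockoffs(X, R, F, seed=11, copy_index=m)
    W_beta[m] = knockoff_stats(lasso_importance(X.values, Xt, y, seed=100 + m))
    W_pip[m] = knockoff_stats(
        pip_importance(X.values, Xt, y, mcmc={"iters": 1500, "burnin": 500},
                       seed=200 + m)
    )

sel_beta = aggregate_select(KnockoffStatsSet(W_beta, "beta"), q)
sel_pip = aggregate_select(KnockoffStatsSet(W_pip, "pip"), q)
both = combined_filter(sel_beta, sel_pip)

truth = set(causal.tolist())
for name, sel in [("Beta", sel_beta), ("PIP", sel_pip), ("combined", both)]:
    got = set(sel.selected.tolist())
    print(f"{name:9s} selected {len(got):2d}  "
          f"(true {len(got & truth)}, false {len(got - truth)})")
print(f"causal features: {sorted(truth)}")
print("a feature passes the combined filter only if both importance "
      "measures rank it above its own knockoff")
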