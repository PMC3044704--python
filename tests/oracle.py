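"""Independent brute-force posterior for tiny Bayes C problems.

Enumerates all 2^K indicator configurations with the SNP effects
integrated out analytically (Gaussian marginal likelihood per
configuration) and sums configuration weights to obtain exact marginal
inclusion probabilities and posterior mean effects.  Used as the oracle
the Gibbs sampler must match; it shares no code with the sampler.
Variances are held fixed (no variance updates) so the comparison is
exact up to Monte-Carlo error.
"""

import itertools

import numpy as np
from scipy import stats


def enumerate_posterior(y, Z, pi, sigma_u2, sigma_e2):
    """Exact inclusion probabilities and effect means by enumeration.

    Returns (incl_prob[K], effect_mean[K]) under the model
    y ~ N(Z_delta u, sigma_e2 I), u ~ N(0, sigma_u2 I), with each
    delta_j independently 1 with prior probability 1 - pi.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, k = Z.shape
    log_weights = []
    configs = list(itertools.product([0, 1], repeat=k))
    cond_means = []
    for delta in configs:
        idx = [j for j in range(k) if delta[j]]
        cov = sigma_e2 * np.eye(n)
        if idx:
            zd = Z[:, idx]
            cov = cov + sigma_u2 * (zd @ zd.T)
        ll = stats.multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        n_in = len(idx)
        prior = n_in * np.log(1 - pi) + (k - n_in) * np.log(pi) if 0 < pi < 1 else (
            0.0 if (pi == 0 and n_in == k) or (pi == 1 and n_in == 0) else -np.inf
        )
        log_weights.append(ll + prior)
        # E[u | delta, y] for included effects (ridge solution)
        mean_u = np.zeros(k)
        if idx:
            zd = Z[:, idx]
            a = zd.T @ zd + (sigma_e2 / sigma_u2) * np.eye(len(idx))
            mean_u[idx] = np.linalg.solve(a, zd.T @ y)
        cond_means.append(mean_u)

    log_weights = np.array(log_weights)
    w = np.exp(log_weights - log_weights.max())
    w /= w.sum()
    incl = np.zeros(k)
    eff = np.zeros(k)
    for wt, delta, mu in zip(w, configs, cond_means):
        incl += wt * np.asarray(delta, dtype=float)
        eff += wt * mu
    return incl, eff
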