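"""Numba kernel for the Bayes C Gibbs sampler.

One kernel runs the whole chain: systematic scan over fixed effects,
then every locus (joint indicator/effect update from the marginal
two-component likelihood), then the two variance components.  The
maintained residual is re-derived from scratch every ``check_every``
iterations; the largest deviation seen is returned as a diagnostic and
the residual is refreshed to stop drift.

Random-number consumption is fixed per scan position (one uniform and
one normal per locus, drawn whether or not the locus enters the model),
so a run is reproducible from its seed and column permutations combined
with a matching ``scan_order`` reproduce the identical chain.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_kernel(
    y,
    xt,  # (p, n) fixed-effect columns, row-contiguous; p may be 0
    zt,  # (K, n) SNP dosage columns, row-contiguous
    pi,
    v_u,
    s2_u,
    v_e,
    s2_e,
    chain_length,
    burn_in,
    thin,
    seed,
    update_variances,
    sigma_u2,
    sigma_e2,
    check_every,
    scan_order,
):
    np.random.seed(seed)
    n = y.shape[0]
    p = xt.shape[0]
    k = zt.shape[0]

    n_kept = 0
    for t in range(burn_in, chain_length):
        if (t - burn_in) % thin == 0:
            n_kept += 1

    b = np.zeros(p)
    u = np.zeros(k)
    delta = np.zeros(k, dtype=np.uint8)
    r = y.copy()

    xtx = np.empty(p)
    for q in range(p):
        s = 0.0
        for i in range(n):
            s += xt[q, i] * xt[q, i]
        xtx[q] = s
    ztz = np.empty(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            s += zt[j, i] * zt[j, i]
        ztz[j] = s

    if pi >= 1.0:
        log_prior_odds = -np.inf
    elif pi <= 0.0:
        log_prior_odds = np.inf
    else:
        log_prior_odds = np.log((1.0 - pi) / pi)

    model_freq = np.zeros(k)
    effect_sum = np.zeros(k)
    b_sum = np.zeros(p)
    var_u_trace = np.empty(n_kept)
    var_e_trace = np.empty(n_kept)
    incl_trace = np.empty(n_kept, dtype=np.int64)
    delta_trace = np.zeros((n_kept, k), dtype=np.uint8)

    resid_max_dev = 0.0
    err_locus = -1
    kept = 0

    for t in range(chain_length):
        # --- fixed effects, flat prior ---
        for q in range(p):
            if xtx[q] <= 0.0:
                continue
            bq = b[q]
            rhs = 0.0
            for i in range(n):
                rhs += xt[q, i] * (r[i] + xt[q, i] * bq)
            mean = rhs / xtx[q]
            new_b = mean + np.random.standard_normal() * np.sqrt(sigma_e2 / xtx[q])
            diff = bq - new_b
            for i in range(n):
                r[i] += xt[q, i] * diff
            b[q] = new_b

        # --- loci: joint (delta_j, u_j) update ---
        for s_i in range(k):
            j = scan_order[s_i]
            uj = u[j]
            if delta[j] == 1:
                for i in range(n):
                    r[i] += zt[j, i] * uj
            rhs = 0.0
            for i in range(n):
                rhs += zt[j, i] * r[i]
            c = ztz[j] / sigma_e2 + 1.0 / sigma_u2
            log_bf = -0.5 * np.log(c * sigma_u2) + 0.5 * rhs * rhs / (
                sigma_e2 * sigma_e2 * c
            )
            if not np.isfinite(log_bf):
                err_locus = j
                break
            lo = log_bf + log_prior_odds
            if lo > 35.0:
                prob = 1.0
            elif lo < -35.0:
                prob = 0.0
            else:
                prob = 1.0 / (1.0 + np.exp(-lo))
            u_draw = np.random.random()
            z_draw = np.random.standard_normal()
            if u_draw < prob:
                new_u = rhs / (sigma_e2 * c) + z_draw / np.sqrt(c)
                delta[j] = 1
                u[j] = new_u
                for i in range(n):
                    r[i] -= zt[j, i] * new_u
            else:
                delta[j] = 0
                u[j] = 0.0
        if err_locus >= 0:
            break

        # --- variance components, scaled inverse chi-square ---
        if update_variances:
            k_in = 0
            ssu = 0.0
            for j in range(k):
                if delta[j] == 1:
                    k_in += 1
                    ssu += u[j] * u[j]
            sigma_u2 = (v_u * s2_u + ssu) / np.random.chisquare(v_u + k_in)
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            sigma_e2 = (v_e * s2_e + sse) / np.random.chisquare(v_e + n)

        # --- residual identity check / refresh ---
        if check_every > 0 and (t + 1) % check_every == 0:
            dev = 0.0
            for i in range(n):
                ri = y[i]
                for q in range(p):
                    ri -= xt[q, i] * b[q]
                for j in range(k):
                    if delta[j] == 1:
                        ri -= zt[j, i] * u[j]
                d = abs(r[i] - ri)
                if d > dev:
                    dev = d
                r[i] = ri
            if dev > resid_max_dev:
                resid_max_dev = dev

        # --- accumulate post burn-in ---
        if t >= burn_in and (t - burn_in) % thin == 0:
            n_in = 0
            for j in range(k):
                delta_trace[kept, j] = delta[j]
                if delta[j] == 1:
                    n_in += 1
                    model_freq[j] += 1.0
                    effect_sum[j] += u[j]
            for q in range(p):
                b_sum[q] += b[q]
            var_u_trace[kept] = sigma_u2
            var_e_trace[kept] = sigma_e2
            incl_trace[kept] = n_in
            kept += 1

    if n_kept > 0:
        model_freq /= n_kept
        effect_sum /= n_kept
        b_sum /= n_kept
    return (
        model_freq,
        effect_sum,
        b_sum,
        var_u_trace,
        var_e_trace,
        incl_trace,
        delta_trace,
        resid_max_dev,
        err_locus,
    )
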