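"""Numba-compiled Gibbs samplers for whole-genome marker regression.

All three samplers share the residual-update scheme: a running residual
r = y - mu - X b is maintained and each marker effect is updated from its
scalar full conditional.  Variances use scaled-inverse-chi-square updates
(draws via chisquare).  RNG is numba's internal NumPy-compatible state,
seeded once per call, so chains are reproducible for a fixed seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_scaled_inv_chi2(df, ssq):
    return ssq / np.random.chisquare(df)


@njit(cache=True)
def _sample_inv_gauss(mu, lam):
    # Michael, Schucany & Haas (1976) transformation
    nu = np.random.standard_normal()
    yv = nu * nu
    x = mu + (mu * mu * yv) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * yv + mu * mu * yv * yv
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def bayes_a_sampler(X, y, niter, burnin, thin, df_b, scale_b, df_e, scale_e,
                    seed):
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.empty(p)
    for j in range(p):
        xtx[j] = np.dot(X[:, j], X[:, j])
    b = np.zeros(p)
    var_b = np.full(p, scale_b)
    mu = np.mean(y)
    se2 = np.var(y) * 0.5 + 1e-8
    r = y - mu
    n_keep = (niter - burnin + thin - 1) // thin
    b_mean = np.zeros(p)
    mu_mean = 0.0
    se2_chain = np.empty(n_keep)
    vg_chain = np.empty(n_keep)
    kept = 0
    for it in range(niter):
        # intercept
        r += mu
        mu = np.mean(r) + np.random.standard_normal() * np.sqrt(se2 / n)
        r -= mu
        # marker effects + per-marker variances (scaled-t prior)
        for j in range(p):
            if xtx[j] == 0.0:
                continue
            rhs = np.dot(X[:, j], r) + xtx[j] * b[j]
            cj = xtx[j] + se2 / var_b[j]
            bnew = rhs / cj + np.random.standard_normal() * np.sqrt(se2 / cj)
            r += X[:, j] * (b[j] - bnew)
            b[j] = bnew
            var_b[j] = _sample_scaled_inv_chi2(
                df_b + 1.0, df_b * scale_b + b[j] * b[j]
            )
        sse = np.dot(r, r)
        se2 = _sample_scaled_inv_chi2(df_e + n, df_e * scale_e + sse)
        if not np.isfinite(se2):
            return b_mean, mu_mean, se2_chain, vg_chain, np.zeros(p), it + 1
        if it >= burnin and (it - burnin) % thin == 0:
            b_mean += b
            mu_mean += mu
            gv = np.dot(X, b)
            se2_chain[kept] = se2
            vg_chain[kept] = np.var(gv)
            kept += 1
    b_mean /= kept
    mu_mean /= kept
    return b_mean, mu_mean, se2_chain, vg_chain, np.ones(p), 0


@njit(cache=True)
def bayes_b_sampler(X, y, niter, burnin, thin, df_b, scale_b, df_e, scale_e,
                    pi_zero, estimate_pi, seed):
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.empty(p)
    for j in range(p):
        xtx[j] = np.dot(X[:, j], X[:, j])
    b = np.zeros(p)
    delta = np.ones(p, dtype=np.int64)
    var_b = np.full(p, scale_b)
    mu = np.mean(y)
    se2 = np.var(y) * 0.5 + 1e-8
    r = y - mu
    log_prior_in = np.log(1.0 - pi_zero)
    log_prior_out = np.log(pi_zero)
    rate_s = 1.1 / scale_b          # Gamma hyper-prior centered on the init
    n_keep = (niter - burnin + thin - 1) // thin
    b_mean = np.zeros(p)
    incl = np.zeros(p)
    mu_mean = 0.0
    se2_chain = np.empty(n_keep)
    vg_chain = np.empty(n_keep)
    kept = 0
    for it in range(niter):
        r += mu
        mu = np.mean(r) + np.random.standard_normal() * np.sqrt(se2 / n)
        r -= mu
        for j in range(p):
            if xtx[j] == 0.0:
                continue
            # residual with marker j removed
            rhs = np.dot(X[:, j], r) + xtx[j] * b[j]
            # slab vs spike odds with b_j integrated out given var_b[j]
            cj = xtx[j] + se2 / var_b[j]
            log_odds = (
                log_prior_in
                - log_prior_out
                + 0.5 * (np.log(se2 / var_b[j]) - np.log(cj))
                + 0.5 * rhs * rhs / (se2 * cj)
            )
            prob_in = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < prob_in:
                bnew = rhs / cj + np.random.standard_normal() * np.sqrt(se2 / cj)
                delta[j] = 1
            else:
                bnew = 0.0
                delta[j] = 0
            r += X[:, j] * (b[j] - bnew)
            b[j] = bnew
            var_b[j] = _sample_scaled_inv_chi2(
                df_b + delta[j], df_b * scale_b + b[j] * b[j]
            )
        if estimate_pi:
            # pi_zero | delta ~ Beta with a uniform prior on the
            # inclusion fraction
            n_in = 0
            for j in range(p):
                n_in += delta[j]
            a = 1.0 + p - n_in
            c = 1.0 + n_in
            ga = np.random.gamma(a, 1.0)
            gc = np.random.gamma(c, 1.0)
            pz = ga / (ga + gc)
            if pz < 1e-6:
                pz = 1e-6
            if pz > 1.0 - 1e-6:
                pz = 1.0 - 1e-6
            log_prior_in = np.log(1.0 - pz)
            log_prior_out = np.log(pz)
            # slab scale | var_b: conjugate Gamma update so the effect-size
            # scale decouples from the initial inclusion guess
            inv_sum = 0.0
            for j in range(p):
                inv_sum += 1.0 / var_b[j]
            scale_b = np.random.gamma(
                1.1 + 0.5 * df_b * p, 1.0 / (rate_s + 0.5 * df_b * inv_sum)
            )
        sse = np.dot(r, r)
        se2 = _sample_scaled_inv_chi2(df_e + n, df_e * scale_e + sse)
        if not np.isfinite(se2):
            return b_mean, mu_mean, se2_chain, vg_chain, incl, it + 1
        if it >= burnin and (it - burnin) % thin == 0:
            b_mean += b
            mu_mean += mu
            incl += delta
            gv = np.dot(X, b)
            se2_chain[kept] = se2
            vg_chain[kept] = np.var(gv)
            kept += 1
    b_mean /= kept
    mu_mean /= kept
    incl /= kept
    return b_mean, mu_mean, se2_chain, vg_chain, incl, 0


@njit(cache=True)
def bayes_l_sampler(X, y, niter, burnin, thin, df_e, scale_e, lam2_shape,
                    lam2_rate, seed):
    # Park & Casella parametrization: b_j ~ N(0, tau2_j * se2),
    # tau2_j ~ Exp(lam2/2), lam2 ~ Gamma(shape, rate)
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.empty(p)
    for j in range(p):
        xtx[j] = np.dot(X[:, j], X[:, j])
    b = np.zeros(p)
    tau2 = np.ones(p)
    lam2 = lam2_shape / lam2_rate
    mu = np.mean(y)
    se2 = np.var(y) * 0.5 + 1e-8
    r = y - mu
    n_keep = (niter - burnin + thin - 1) // thin
    b_mean = np.zeros(p)
    mu_mean = 0.0
    se2_chain = np.empty(n_keep)
    vg_chain = np.empty(n_keep)
    lam_chain = np.empty(n_keep)
    kept = 0
    for it in range(niter):
        r += mu
        mu = np.mean(r) + np.random.standard_normal() * np.sqrt(se2 / n)
        r -= mu
        for j in range(p):
            if xtx[j] == 0.0:
                continue
            rhs = np.dot(X[:, j], r) + xtx[j] * b[j]
            cj = xtx[j] + 1.0 / tau2[j]
            bnew = rhs / cj + np.random.standard_normal() * np.sqrt(se2 / cj)
            r += X[:, j] * (b[j] - bnew)
            b[j] = bnew
            # 1/tau2_j | b_j, lam2, se2 ~ InvGauss
            babs = abs(b[j])
            if babs < 1e-10:
                babs = 1e-10
            inv_tau2 = _sample_inv_gauss(np.sqrt(lam2 * se2) / babs, lam2)
            tau2[j] = 1.0 / inv_tau2
        # lam2 | tau2
        lam2 = np.random.gamma(lam2_shape + p,
                               1.0 / (lam2_rate + 0.5 * np.sum(tau2)))
        sse = np.dot(r, r)
        ssb = 0.0
        for j in range(p):
            ssb += b[j] * b[j] / tau2[j]
        se2 = _sample_scaled_inv_chi2(df_e + n + p, df_e * scale_e + sse + ssb)
        if not np.isfinite(se2):
            return b_mean, mu_mean, se2_chain, vg_chain, lam_chain, it + 1
        if it >= burnin and (it - burnin) % thin == 0:
            b_mean += b
            mu_mean += mu
            gv = np.dot(X, b)
            se2_chain[kept] = se2
            vg_chain[kept] = np.var(gv)
            lam_chain[kept] = np.sqrt(lam2)
            kept += 1
    b_mean /= kept
    mu_mean /= kept
    return b_mean, mu_mean, se2_chain, vg_chain, lam_chain, 0
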