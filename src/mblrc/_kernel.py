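"""JIT-compiled Metropolis-within-Gibbs core for the multilevel model.

One call runs one chain.  Block structure:

* plant-level curve parameters — scalar random-walk Metropolis per
  (plant, parameter), proposed for all plants at once per parameter
  (plants are conditionally independent given genotype means/precisions);
* genotype means — scalar Metropolis per (genotype, parameter), plus a
  joint "shift" move that translates a genotype mean together with all its
  plants' values (breaks the random-walk coupling between levels that
  otherwise makes hierarchical means mix slowly);
* genotype precisions — Metropolis on the log scale (the truncated-normal
  normalising constants depend on the precision, so the gamma conditional
  is not conjugate);
* observation precision — exact conjugate gamma Gibbs draw.

Proposal scales adapt in batches during burn-in toward a target acceptance
rate and are frozen afterwards, preserving detailed balance for the
retained draws.
"""

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_THETA_EPS = 1e-6
_BATCH = 50


@njit(cache=True)
def _nrh(a_max, alpha, r_d, theta, par):
    """Scalar non-rectangular hyperbola mean (smaller quadratic root)."""
    if theta < _THETA_EPS:
        return alpha * par * a_max / (alpha * par + a_max) - r_d
    s = alpha * par + a_max
    disc = s * s - 4.0 * theta * alpha * par * a_max
    if disc < 0.0:
        disc = 0.0
    return (s - math.sqrt(disc)) / (2.0 * theta) - r_d


@njit(cache=True)
def _ltnorm(x, m, sd, lo, hi):
    """Truncated-normal log density on [lo, hi] (x assumed inside)."""
    z = (x - m) / sd
    zlo = (lo - m) / (sd * _SQRT2)
    zhi = (hi - m) / (sd * _SQRT2)
    mass = 0.5 * (math.erf(zhi) - math.erf(zlo))
    if mass <= 0.0:
        return -np.inf
    return -0.5 * z * z - _LOG_SQRT_2PI - math.log(sd) - math.log(mass)


@njit(cache=True)
def run_chain(
    par,
    a_n,
    plant_idx,
    plant_geno,
    prior_mean,
    prior_sd,
    lo,
    hi,
    gam_shape,
    gam_rate,
    plant0,
    geno0,
    tau0,
    obstau0,
    upd_plant,
    upd_geno,
    upd_tau,
    upd_obstau,
    n_adapt,
    n_keep,
    thin,
    target_accept,
    seed,
):
    np.random.seed(seed)
    N = par.shape[0]
    P = plant0.shape[0]
    G = geno0.shape[0]
    K = 4 * P + 4 * G + 4 + 1

    plant = plant0.copy()
    geno = geno0.copy()
    tau = tau0.copy()
    tau_obs = obstau0

    # current NRH means per observation
    mu = np.empty(N)
    for i in range(N):
        p = plant_idx[i]
        mu[i] = _nrh(plant[p, 0], plant[p, 1], plant[p, 2], plant[p, 3], par[i])

    # observation indices grouped by genotype (counting sort) so the joint
    # shift move touches only its genotype's observations
    geno_obs_count = np.zeros(G, dtype=np.int64)
    for i in range(N):
        geno_obs_count[plant_geno[plant_idx[i]]] += 1
    geno_obs_start = np.zeros(G + 1, dtype=np.int64)
    for g in range(G):
        geno_obs_start[g + 1] = geno_obs_start[g] + geno_obs_count[g]
    obs_by_geno = np.empty(N, dtype=np.int64)
    fill = geno_obs_start[:G].copy()
    for i in range(N):
        g = plant_geno[plant_idx[i]]
        obs_by_geno[fill[g]] = i
        fill[g] += 1

    # proposal step sizes
    step_plant = np.empty((P, 4))
    step_geno = np.empty((G, 4))
    step_shift = np.empty((G, 4))
    for j in range(4):
        base = 0.02 * (hi[j] - lo[j])
        for p in range(P):
            step_plant[p, j] = base
        for g in range(G):
            step_geno[g, j] = base
            step_shift[g, j] = base
    step_tau = np.full(4, 0.4)

    # adaptation batch counters
    acc_plant = np.zeros((P, 4))
    acc_geno = np.zeros((G, 4))
    acc_shift = np.zeros((G, 4))
    acc_tau = np.zeros(4)
    batch_no = 0

    # post-adaptation acceptance bookkeeping
    post_acc = 0.0
    post_prop = 0.0

    out = np.empty((n_keep, K))
    prop = np.empty(P)
    mu_prop = np.empty(N)
    logacc = np.empty(P)
    ok = np.empty(P, dtype=np.bool_)
    accepted = np.empty(P, dtype=np.bool_)

    total = n_adapt + n_keep * thin
    for t in range(total):
        adapting = t < n_adapt

        # --- plant-level parameters, one parameter slot at a time ---
        for j in range(4):
            if not upd_plant[j]:
                continue
            sd_j = 1.0 / math.sqrt(tau[j])
            for p in range(P):
                prop[p] = plant[p, j] + step_plant[p, j] * np.random.normal()
                if lo[j] <= prop[p] <= hi[j]:
                    ok[p] = True
                    g = plant_geno[p]
                    logacc[p] = _ltnorm(
                        prop[p], geno[g, j], sd_j, lo[j], hi[j]
                    ) - _ltnorm(plant[p, j], geno[g, j], sd_j, lo[j], hi[j])
                else:
                    ok[p] = False
                    logacc[p] = -np.inf
            for i in range(N):
                p = plant_idx[i]
                if not ok[p]:
                    continue
                a0 = plant[p, 0]
                a1 = plant[p, 1]
                a2 = plant[p, 2]
                a3 = plant[p, 3]
                if j == 0:
                    a0 = prop[p]
                elif j == 1:
                    a1 = prop[p]
                elif j == 2:
                    a2 = prop[p]
                else:
                    a3 = prop[p]
                m_new = _nrh(a0, a1, a2, a3, par[i])
                d_cur = a_n[i] - mu[i]
                d_new = a_n[i] - m_new
                logacc[p] += -0.5 * tau_obs * (d_new * d_new - d_cur * d_cur)
                mu_prop[i] = m_new
            for p in range(P):
                if ok[p] and math.log(np.random.random()) < logacc[p]:
                    plant[p, j] = prop[p]
                    accepted[p] = True
                    acc_plant[p, j] += 1.0
                    if not adapting:
                        post_acc += 1.0
                else:
                    accepted[p] = False
                if not adapting:
                    post_prop += 1.0
            for i in range(N):
                if accepted[plant_idx[i]]:
                    mu[i] = mu_prop[i]

        # --- genotype means ---
        if upd_geno:
            for j in range(4):
                sd_j = 1.0 / math.sqrt(tau[j])
                for g in range(G):
                    m = geno[g, j]
                    mp = m + step_geno[g, j] * np.random.normal()
                    if not adapting:
                        post_prop += 1.0
                    if not (lo[j] <= mp <= hi[j]):
                        continue
                    d = _ltnorm(
                        mp, prior_mean[j], prior_sd[j], lo[j], hi[j]
                    ) - _ltnorm(m, prior_mean[j], prior_sd[j], lo[j], hi[j])
                    for p in range(P):
                        if plant_geno[p] == g:
                            d += _ltnorm(
                                plant[p, j], mp, sd_j, lo[j], hi[j]
                            ) - _ltnorm(plant[p, j], m, sd_j, lo[j], hi[j])
                    if math.log(np.random.random()) < d:
                        geno[g, j] = mp
                        acc_geno[g, j] += 1.0
                        if not adapting:
                            post_acc += 1.0

        # --- joint shift: genotype mean and its plants move together ---
        if upd_geno:
            for j in range(4):
                if not upd_plant[j]:
                    continue
                sd_j = 1.0 / math.sqrt(tau[j])
                for g in range(G):
                    delta = step_shift[g, j] * np.random.normal()
                    mp = geno[g, j] + delta
                    if not adapting:
                        post_prop += 1.0
                    if not (lo[j] <= mp <= hi[j]):
                        continue
                    ok_shift = True
                    for p in range(P):
                        if plant_geno[p] == g:
                            xv = plant[p, j] + delta
                            if not (lo[j] <= xv <= hi[j]):
                                ok_shift = False
                                break
                    if not ok_shift:
                        continue
                    d = _ltnorm(
                        mp, prior_mean[j], prior_sd[j], lo[j], hi[j]
                    ) - _ltnorm(geno[g, j], prior_mean[j], prior_sd[j], lo[j], hi[j])
                    for p in range(P):
                        if plant_geno[p] == g:
                            d += _ltnorm(
                                plant[p, j] + delta, mp, sd_j, lo[j], hi[j]
                            ) - _ltnorm(plant[p, j], geno[g, j], sd_j, lo[j], hi[j])
                    for idx in range(geno_obs_start[g], geno_obs_start[g + 1]):
                        i = obs_by_geno[idx]
                        p = plant_idx[i]
                        a0 = plant[p, 0]
                        a1 = plant[p, 1]
                        a2 = plant[p, 2]
                        a3 = plant[p, 3]
                        if j == 0:
                            a0 += delta
                        elif j == 1:
                            a1 += delta
                        elif j == 2:
                            a2 += delta
                        else:
                            a3 += delta
                        m_new = _nrh(a0, a1, a2, a3, par[i])
                        d_cur = a_n[i] - mu[i]
                        d_new = a_n[i] - m_new
                        d += -0.5 * tau_obs * (d_new * d_new - d_cur * d_cur)
                        mu_prop[i] = m_new
                    if math.log(np.random.random()) < d:
                        geno[g, j] = mp
                        for p in range(P):
                            if plant_geno[p] == g:
                                plant[p, j] += delta
                        for idx in range(geno_obs_start[g], geno_obs_start[g + 1]):
                            i = obs_by_geno[idx]
                            mu[i] = mu_prop[i]
                        acc_shift[g, j] += 1.0
                        if not adapting:
                            post_acc += 1.0

        # --- genotype precisions (log-scale Metropolis) ---
        if upd_tau:
            for j in range(4):
                lt = math.log(tau[j])
                ltp = lt + step_tau[j] * np.random.normal()
                taup = math.exp(ltp)
                if not adapting:
                    post_prop += 1.0
                if taup <= 0.0 or not np.isfinite(taup):
                    continue
                sd_cur = 1.0 / math.sqrt(tau[j])
                sd_new = 1.0 / math.sqrt(taup)
                # gamma prior with log-scale Jacobian: shape*log(tau) - rate*tau
                d = gam_shape * (ltp - lt) - gam_rate * (taup - tau[j])
                for p in range(P):
                    g = plant_geno[p]
                    d += _ltnorm(
                        plant[p, j], geno[g, j], sd_new, lo[j], hi[j]
                    ) - _ltnorm(plant[p, j], geno[g, j], sd_cur, lo[j], hi[j])
                if math.log(np.random.random()) < d:
                    tau[j] = taup
                    acc_tau[j] += 1.0
                    if not adapting:
                        post_acc += 1.0

        # --- observation precision (conjugate gamma Gibbs) ---
        if upd_obstau:
            ssr = 0.0
            for i in range(N):
                r = a_n[i] - mu[i]
                ssr += r * r
            tau_obs = np.random.gamma(
                gam_shape + 0.5 * N, 1.0 / (gam_rate + 0.5 * ssr)
            )

        # --- batch adaptation of proposal scales ---
        if adapting and (t + 1) % _BATCH == 0:
            batch_no += 1
            adj = min(0.5, 1.0 / math.sqrt(batch_no))
            for j in range(4):
                if upd_plant[j]:
                    for p in range(P):
                        rate = acc_plant[p, j] / _BATCH
                        if rate > target_accept:
                            step_plant[p, j] *= math.exp(adj)
                        else:
                            step_plant[p, j] *= math.exp(-adj)
                        acc_plant[p, j] = 0.0
                if upd_geno:
                    for g in range(G):
                        rate = acc_geno[g, j] / _BATCH
                        if rate > target_accept:
                            step_geno[g, j] *= math.exp(adj)
                        else:
                            step_geno[g, j] *= math.exp(-adj)
                        acc_geno[g, j] = 0.0
                        if upd_plant[j]:
                            rate = acc_shift[g, j] / _BATCH
                            if rate > target_accept:
                                step_shift[g, j] *= math.exp(adj)
                            else:
                                step_shift[g, j] *= math.exp(-adj)
                            acc_shift[g, j] = 0.0
                if upd_tau:
                    rate = acc_tau[j] / _BATCH
                    if rate > target_accept:
                        step_tau[j] *= math.exp(adj)
                    else:
                        step_tau[j] *= math.exp(-adj)
                    acc_tau[j] = 0.0

        # --- retain ---
        if t >= n_adapt and (t - n_adapt) % thin == 0:
            row = (t - n_adapt) // thin
            k = 0
            for p in range(P):
                for j in range(4):
                    out[row, k] = plant[p, j]
                    k += 1
            for g in range(G):
                for j in range(4):
                    out[row, k] = geno[g, j]
                    k += 1
            for j in range(4):
                out[row, k] = tau[j]
                k += 1
            out[row, k] = tau_obs

    rate_post = post_acc / post_prop if post_prop > 0 else np.nan
    return out, rate_post
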