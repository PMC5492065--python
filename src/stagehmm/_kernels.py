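"""Numba-compiled inner loops: kernel assembly and the forward recursion.

These functions work on flat arrays so they can be jitted; the public,
validated API lives in `states`, `covariates`, and `likelihood`.  Parameter
conventions (stage ordering, intercept layout, shared growth slopes) mirror
`stagehmm.covariates.ParameterLayout`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STAGES = 7
N_STATES = 15
ABSORBING = 14

# Per-destination source stages of the growth mask (padded with -1): egg
# from egg; each instar from itself and up to two stages below; pupa from
# I5 and itself.  Captured as a compile-time constant by the forward pass,
# which exploits the kernel's structural sparsity.
_GROWTH_SOURCES = np.array(
    [
        [0, -1, -1],   # egg
        [0, 1, -1],    # I1
        [1, 2, -1],    # I2
        [1, 2, 3],     # I3
        [2, 3, 4],     # I4
        [3, 4, 5],     # I5
        [5, 6, -1],    # pupa
    ],
    dtype=np.int64,
)


@njit(cache=True)
def _sigmoid(z):
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


@njit(cache=True)
def build_px_stack(
    b0,            # (G,) instar survival intercepts
    b1,            # (G,) slopes, or length-0 when the form is constant
    group_of,      # (5,) int64, survival-group index of I1..I5
    a0,            # (7,) growth intercepts
    a1,            # (4,) shared growth slopes, or length-0
    egg_survival,
    egg_hatch,
    pupation,
    x_surv,        # (C,) survival covariate per class
    x_grow,        # (C,) growth covariate per class
    death_mult,    # (C,) multiplier on per-step death probability
    partition_by_growth,  # bool: dying mass partitioned by the growth kernel
):
    """Build one 15x15 column-stochastic kernel per covariate class."""
    C = x_surv.shape[0]
    out = np.zeros((C, N_STATES, N_STATES))
    phi = np.empty(N_STAGES)
    psi = np.zeros((N_STAGES, N_STAGES))
    for c in range(C):
        xs = x_surv[c]
        xg = x_grow[c]
        phi[0] = egg_survival
        for i in range(5):
            z = b0[group_of[i]]
            if b1.shape[0] > 0:
                z += b1[group_of[i]] * xs
            phi[1 + i] = _sigmoid(z)
        phi[6] = 1.0
        mult = death_mult[c]
        if mult != 1.0:
            for i in range(N_STAGES):
                d = (1.0 - phi[i]) * mult
                if d > 1.0:
                    d = 1.0
                phi[i] = 1.0 - d

        for j in range(N_STAGES):
            for i in range(N_STAGES):
                psi[j, i] = 0.0
        psi[0, 0] = 1.0 - egg_hatch
        psi[1, 0] = egg_hatch
        for i in range(1, 4):  # I1..I3: stasis, +1, +2
            z1 = a0[2 * (i - 1)]
            z2 = a0[2 * (i - 1) + 1]
            if a1.shape[0] > 0:
                z1 += a1[i - 1] * xg
                z2 += a1[i - 1] * xg
            m = z1 if z1 > z2 else z2
            if m < 0.0:
                m = 0.0
            e0 = np.exp(-m)
            e1 = np.exp(z1 - m)
            e2 = np.exp(z2 - m)
            s = e0 + e1 + e2
            psi[i, i] = e0 / s
            psi[i + 1, i] = e1 / s
            psi[i + 2, i] = e2 / s
        z1 = a0[6]  # I4: stasis, I5
        if a1.shape[0] > 0:
            z1 += a1[3] * xg
        m = z1 if z1 > 0.0 else 0.0
        e0 = np.exp(-m)
        e1 = np.exp(z1 - m)
        s = e0 + e1
        psi[4, 4] = e0 / s
        psi[5, 4] = e1 / s
        psi[5, 5] = 1.0 - pupation
        psi[6, 5] = pupation
        psi[6, 6] = 1.0

        for i in range(N_STAGES):
            for j in range(N_STAGES):
                if psi[j, i] > 0.0:
                    out[c, j, i] = phi[i] * psi[j, i]
                    if partition_by_growth:
                        out[c, N_STAGES + j, i] = (1.0 - phi[i]) * psi[j, i]
            if not partition_by_growth:
                out[c, N_STAGES + i, i] = 1.0 - phi[i]
            out[c, ABSORBING, N_STAGES + i] = 1.0
        out[c, ABSORBING, ABSORBING] = 1.0
    return out


@njit(cache=True)
def build_po(p_live, p_dead):
    """15x15 observation kernel; p_live/p_dead are per-stage length 7."""
    po = np.zeros((N_STATES, N_STATES))
    for i in range(N_STAGES):
        po[0, i] = 1.0 - p_live[i]
        po[1 + i, i] = p_live[i]
        po[0, N_STAGES + i] = 1.0 - p_dead[i]
        po[1 + N_STAGES + i, N_STAGES + i] = p_dead[i]
    po[0, ABSORBING] = 1.0
    return po


@njit(cache=True)
def logpost_and_deviance(
    z,                      # unconstrained parameter vector (layout order)
    prob_idx, coef_idx,     # index arrays by parameter kind
    coef_var,               # prior variance of linear coefficients
    beta_idx, beta_a, beta_b,   # informative beta priors (3 entries)
    n_groups, has_b1, has_a1,
    group_of, x_surv, x_grow, death_mult, partition,
    cats, first_occ, first_state, n_occ, cls_idx,
):
    """Unconstrained-scale log posterior (with logit Jacobians) and deviance.

    Prior normalization constants are dropped (they cancel in Metropolis
    ratios); the deviance is exact.  Layout order must match
    `stagehmm.covariates.ParameterLayout`.
    """
    x = z.copy()
    for ii in range(prob_idx.shape[0]):
        x[prob_idx[ii]] = _sigmoid(x[prob_idx[ii]])
    pos = 0
    b0 = x[pos : pos + n_groups]; pos += n_groups
    if has_b1:
        b1 = x[pos : pos + n_groups]; pos += n_groups
    else:
        b1 = np.empty(0)
    a0 = x[pos : pos + 7]; pos += 7
    if has_a1:
        a1 = x[pos : pos + 4]; pos += 4
    else:
        a1 = np.empty(0)
    p_live = np.empty(N_STAGES)
    for i in range(6):
        p_live[i] = x[pos + i]
    p_live[6] = 0.0  # pupae leave the plant and are never seen
    pos += 6
    p_dead = np.zeros(N_STAGES)
    for i in range(5):
        p_dead[1 + i] = x[pos + i]
    pos += 5
    egg_surv = x[pos]
    hatch = x[pos + 1]
    pup = x[pos + 2]
    px = build_px_stack(
        b0, b1, group_of, a0, a1, egg_surv, hatch, pup,
        x_surv, x_grow, death_mult, partition,
    )
    po = build_po(p_live, p_dead)
    ll = forward_loglik_packed(cats, first_occ, first_state, n_occ, cls_idx, px, po)
    if not np.isfinite(ll):
        return -np.inf, np.inf
    lp = ll
    for ii in range(coef_idx.shape[0]):
        lp -= 0.5 * x[coef_idx[ii]] ** 2 / coef_var
    for ii in range(prob_idx.shape[0]):
        p = x[prob_idx[ii]]
        if p <= 0.0 or p >= 1.0:
            return -np.inf, np.inf
        lp += np.log(p) + np.log1p(-p)
    for ii in range(beta_idx.shape[0]):
        p = x[beta_idx[ii]]
        lp += (beta_a[ii] - 1.0) * np.log(p) + (beta_b[ii] - 1.0) * np.log1p(-p)
    return lp, -2.0 * ll


@njit(cache=True)
def metropolis_scalar_chain(
    z0, burn_in, samples, target_accept, rng,
    prob_idx, coef_idx, coef_var, beta_idx, beta_a, beta_b,
    n_groups, has_b1, has_a1,
    group_of, x_surv, x_grow, death_mult, partition,
    cats, first_occ, first_state, n_occ, cls_idx,
):
    """Single-site adaptive random-walk Metropolis over the full parameter
    vector, with Robbins-Monro proposal-scale tuning and a running-variance
    proposal per coordinate, both frozen when burn-in ends.  Returns
    (unconstrained draws, per-draw deviance, per-coordinate acceptance)."""
    d = z0.shape[0]
    z = z0.copy()
    lp, aux = logpost_and_deviance(
        z, prob_idx, coef_idx, coef_var, beta_idx, beta_a, beta_b,
        n_groups, has_b1, has_a1, group_of, x_surv, x_grow, death_mult,
        partition, cats, first_occ, first_state, n_occ, cls_idx,
    )
    log_scale = np.zeros(d)
    mean = z.copy()
    var = np.full(d, 0.01)
    prop_sd = np.sqrt(2.38**2 * var + 1e-9)
    acc = np.zeros(d)
    tries = np.zeros(d)
    draws = np.empty((samples, d))
    aux_out = np.empty(samples)
    for it in range(burn_in + samples):
        adapting = it < burn_in
        for j in range(d):
            zj_old = z[j]
            z[j] = zj_old + np.exp(log_scale[j]) * prop_sd[j] * rng.standard_normal()
            lp_new, aux_new = logpost_and_deviance(
                z, prob_idx, coef_idx, coef_var, beta_idx, beta_a, beta_b,
                n_groups, has_b1, has_a1, group_of, x_surv, x_grow, death_mult,
                partition, cats, first_occ, first_state, n_occ, cls_idx,
            )
            tries[j] += 1.0
            if np.isfinite(lp_new):
                diff = lp_new - lp
                ap = np.exp(diff) if diff < 0.0 else 1.0
            else:
                ap = 0.0
            if rng.random() < ap:
                lp = lp_new
                aux = aux_new
                acc[j] += 1.0
            else:
                z[j] = zj_old
            if adapting:
                log_scale[j] += (ap - target_accept) / (1.0 + it) ** 0.6
        if adapting:
            g = 1.0 / (2.0 + it) ** 0.6
            for j in range(d):
                delta = z[j] - mean[j]
                mean[j] += g * delta
                var[j] += g * (delta * delta - var[j])
            if (it + 1) % 50 == 0 or it == burn_in - 1:
                for j in range(d):
                    prop_sd[j] = np.sqrt(2.38**2 * var[j] + 1e-9)
        else:
            draws[it - burn_in] = z
            aux_out[it - burn_in] = aux
    for j in range(d):
        if tries[j] > 0.0:
            acc[j] /= tries[j]
    return draws, aux_out, acc


@njit(cache=True)
def forward_loglik_packed(cats, first_occ, first_state, n_occ, cls_idx, px, po):
    """Total log-likelihood of all encounter histories by the scaled forward pass.

    ``cats[k, t]`` is the observed category of individual ``k`` at occasion
    ``t``; ``cls_idx[k, t]`` indexes the covariate class of the transition
    into occasion ``t``; ``px`` stacks one kernel per class.  Each history is
    conditioned on the (live) state at first detection.  Returns -inf when
    any history is impossible under the kernels.
    """
    n = cats.shape[0]
    total = 0.0
    alpha = np.empty(N_STATES)
    tmp = np.empty(N_STATES)
    for k in range(n):
        for s in range(N_STATES):
            alpha[s] = 0.0
        alpha[first_state[k]] = 1.0
        logscale = 0.0
        for t in range(first_occ[k] + 1, n_occ[k]):
            c = cls_idx[k, t]
            # Sparse product: live and newly-dead destinations draw only
            # from their growth-mask sources; the absorbing state collects
            # the whole dead space.
            for j in range(N_STAGES):
                acc_live = 0.0
                acc_dead = 0.0
                for m in range(3):
                    i = _GROWTH_SOURCES[j, m]
                    if i < 0:
                        break
                    acc_live += px[c, j, i] * alpha[i]
                    acc_dead += px[c, N_STAGES + j, i] * alpha[i]
                tmp[j] = acc_live
                tmp[N_STAGES + j] = acc_dead
            acc = alpha[ABSORBING]
            for i in range(N_STAGES, ABSORBING):
                acc += alpha[i]
            tmp[ABSORBING] = acc
            cat = cats[k, t]
            ssum = 0.0
            for s in range(N_STATES):
                a = tmp[s] * po[cat, s]
                alpha[s] = a
                ssum += a
            if ssum <= 0.0:
                return -np.inf
            logscale += np.log(ssum)
            inv = 1.0 / ssum
            for s in range(N_STATES):
                alpha[s] *= inv
        total += logscale
    return total
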