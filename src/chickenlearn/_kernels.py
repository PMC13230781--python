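"""Compiled likelihood and sampler kernels.

Model coding shared with the Python reference path:
``fam`` 0 = reward state, 1 = belief state; ``params5`` is the fixed-layout
natural-scale vector ``[alpha_h, alpha_l, beta, kappa, theta]`` (inactive
slots zero).  Choices: 1 = Swerve, 0 = Go straight; opponent index
0 = HCO, 1 = LCO.
"""

import math

import numpy as np
from numba import njit

EPS = 1e-6
SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _phi(x):
    return 0.5 * (1.0 + math.erf(x / SQRT2))


@njit(cache=True)
def _log_bernoulli(x, choice):
    # log P(choice) under P(swerve) = sigmoid(x), numerically stable
    if choice == 1:
        if x >= 0.0:
            return -math.log1p(math.exp(-x))
        return x - math.log1p(math.exp(x))
    if x >= 0.0:
        return -x - math.log1p(math.exp(-x))
    return -math.log1p(math.exp(x))


@njit(cache=True)
def _session_ll(params5, fam, frozen, has_kappa, choices, oppc, oppi, rew, T, A, B, rscale):
    ah = params5[0]
    al = params5[1]
    beta = params5[2]
    kappa = params5[3]
    theta = params5[4]
    v = np.zeros((2, 2))
    p = np.empty(2)
    p[0] = 0.5
    p[1] = 0.5
    total = 0.0
    for t in range(T):
        o = oppi[t]
        if fam == 0:
            ev = v[o, 1] - v[o, 0]
        else:
            ev = A + B * p[o]
        x = beta * ev + theta
        c = choices[t]
        total += _log_bernoulli(x, c)
        if frozen == 0:
            a = ah if o == 0 else al
            if fam == 0:
                r = rew[t] / rscale
                v[o, c] += a * (r - v[o, c])
            else:
                O = oppc[t]
                if has_kappa == 1:
                    pc = p[o]
                    if pc < EPS:
                        pc = EPS
                    elif pc > 1.0 - EPS:
                        pc = 1.0 - EPS
                    bsafe = beta if beta > EPS else EPS
                    q = (math.log(pc / (1.0 - pc)) / bsafe - A) / B
                    pn = p[o] + a * (O - p[o]) + kappa * (c - q)
                    if pn < EPS:
                        pn = EPS
                    elif pn > 1.0 - EPS:
                        pn = 1.0 - EPS
                    p[o] = pn
                else:
                    p[o] = p[o] + a * (O - p[o])
    return total


@njit(cache=True)
def _session_pointwise(
    params5, fam, frozen, has_kappa, choices, oppc, oppi, rew, T, A, B, rscale, out
):
    ah = params5[0]
    al = params5[1]
    beta = params5[2]
    kappa = params5[3]
    theta = params5[4]
    v = np.zeros((2, 2))
    p = np.empty(2)
    p[0] = 0.5
    p[1] = 0.5
    for t in range(T):
        o = oppi[t]
        if fam == 0:
            ev = v[o, 1] - v[o, 0]
        else:
            ev = A + B * p[o]
        x = beta * ev + theta
        c = choices[t]
        out[t] = _log_bernoulli(x, c)
        if frozen == 0:
            a = ah if o == 0 else al
            if fam == 0:
                r = rew[t] / rscale
                v[o, c] += a * (r - v[o, c])
            else:
                O = oppc[t]
                if has_kappa == 1:
                    pc = p[o]
                    if pc < EPS:
                        pc = EPS
                    elif pc > 1.0 - EPS:
                        pc = 1.0 - EPS
                    bsafe = beta if beta > EPS else EPS
                    q = (math.log(pc / (1.0 - pc)) / bsafe - A) / B
                    pn = p[o] + a * (O - p[o]) + kappa * (c - q)
                    if pn < EPS:
                        pn = EPS
                    elif pn > 1.0 - EPS:
                        pn = 1.0 - EPS
                    p[o] = pn
                else:
                    p[o] = p[o] + a * (O - p[o])


@njit(cache=True)
def _nat5(mu, ls, zrow, slots, lo, hi, ident, tie):
    """Natural-scale params5 for one subject from hyper + latent coords."""
    params5 = np.zeros(5)
    for k in range(slots.size):
        raw = mu[k] + math.exp(ls[k]) * zrow[k]
        if ident[k] == 1:
            val = raw
        else:
            val = lo[k] + (hi[k] - lo[k]) * _phi(raw)
        params5[slots[k]] = val
    if tie == 1:
        params5[1] = params5[0]
    return params5


@njit(cache=True)
def _subject_ll(
    mu, ls, z, i, slots, lo, hi, ident, tie, fam, frozen, has_kappa,
    choices, oppc, oppi, rew, tlen, A, B, rscale,
):
    params5 = _nat5(mu, ls, z[i], slots, lo, hi, ident, tie)
    return _session_ll(
        params5, fam, frozen, has_kappa, choices[i], oppc[i], oppi[i], rew[i],
        tlen[i], A, B, rscale,
    )


@njit(cache=True)
def _cond(
    kind, k, i, mu, ls, z, slots, lo, hi, ident, tie, fam, frozen, has_kappa,
    choices, oppc, oppi, rew, tlen, A, B, rscale, mu_scale, sig_scale,
):
    """Log conditional density of one coordinate at the array's current value.

    kind 0: hyper mean mu[k]; kind 1: log of hyper sd ls[k]; kind 2: latent
    z[i, k].  Constant terms w.r.t. the coordinate are irrelevant for slice
    sampling and partly dropped.
    """
    N = z.shape[0]
    if kind == 2:
        lp = -0.5 * z[i, k] * z[i, k]
        lp += _subject_ll(
            mu, ls, z, i, slots, lo, hi, ident, tie, fam, frozen, has_kappa,
            choices, oppc, oppi, rew, tlen, A, B, rscale,
        )
        return lp
    if kind == 0:
        val = mu[k]
        lp = -0.5 * (val / mu_scale[k]) * (val / mu_scale[k])
    else:
        sig = math.exp(ls[k])
        # half-Cauchy(0, sig_scale) density plus log-scale Jacobian
        lp = -math.log(1.0 + (sig / sig_scale[k]) * (sig / sig_scale[k])) + ls[k]
    for j in range(N):
        lp += _subject_ll(
            mu, ls, z, j, slots, lo, hi, ident, tie, fam, frozen, has_kappa,
            choices, oppc, oppi, rew, tlen, A, B, rscale,
        )
    return lp


@njit(cache=True)
def _set_coord(kind, k, i, val, mu, ls, z):
    if kind == 0:
        mu[k] = val
    elif kind == 1:
        ls[k] = val
    else:
        z[i, k] = val


@njit(cache=True)
def _get_coord(kind, k, i, mu, ls, z):
    if kind == 0:
        return mu[k]
    if kind == 1:
        return ls[k]
    return z[i, k]


@njit(cache=True)
def _slice_coord(
    kind, k, i, w, mu, ls, z, slots, lo, hi, ident, tie, fam, frozen, has_kappa,
    choices, oppc, oppi, rew, tlen, A, B, rscale, mu_scale, sig_scale,
):
    """Univariate slice sampling update of one coordinate (Neal 2003)."""
    x0 = _get_coord(kind, k, i, mu, ls, z)
    f0 = _cond(
        kind, k, i, mu, ls, z, slots, lo, hi, ident, tie, fam, frozen, has_kappa,
        choices, oppc, oppi, rew, tlen, A, B, rscale, mu_scale, sig_scale,
    )
    y = f0 + math.log(np.random.random())
    L = x0 - w * np.random.random()
    R = L + w
    for _ in range(20):
        _set_coord(kind, k, i, L, mu, ls, z)
        if (
            _cond(
                kind, k, i, mu, ls, z, slots, lo, hi, ident, tie, fam, frozen,
                has_kappa, choices, oppc, oppi, rew, tlen, A, B, rscale,
                mu_scale, sig_scale,
            )
            <= y
        ):
            break
        L -= w
    for _ in range(20):
        _set_coord(kind, k, i, R, mu, ls, z)
        if (
            _cond(
                kind, k, i, mu, ls, z, slots, lo, hi, ident, tie, fam, frozen,
                has_kappa, choices, oppc, oppi, rew, tlen, A, B, rscale,
                mu_scale, sig_scale,
            )
            <= y
        ):
            break
        R += w
    for _ in range(100):
        x1 = L + np.random.random() * (R - L)
        _set_coord(kind, k, i, x1, mu, ls, z)
        f1 = _cond(
            kind, k, i, mu, ls, z, slots, lo, hi, ident, tie, fam, frozen,
            has_kappa, choices, oppc, oppi, rew, tlen, A, B, rscale,
            mu_scale, sig_scale,
        )
        if f1 >= y:
            return
        if x1 < x0:
            L = x1
        else:
            R = x1
    _set_coord(kind, k, i, x0, mu, ls, z)  # pathological shrinkage: keep x0


@njit(cache=True)
def run_chain(
    seed, n_warmup, n_keep, slots, lo, hi, ident, tie, fam, frozen, has_kappa,
    choices, oppc, oppi, rew, tlen, A, B, rscale, mu_scale, sig_scale,
):
    """One MCMC chain of slice-within-Gibbs sweeps.

    Returns retained draws of the hyper means, log hyper sds and latent
    standard-normal offsets.
    """
    np.random.seed(seed)
    K = slots.size
    N = choices.shape[0]
    mu = np.empty(K)
    ls = np.empty(K)
    z = np.empty((N, K))
    for k in range(K):
        mu[k] = np.random.normal(0.0, 1.0)
        ls[k] = math.log(0.5) + np.random.normal(0.0, 0.3)
        for i in range(N):
            z[i, k] = np.random.normal(0.0, 0.5)
    mu_d = np.empty((n_keep, K))
    ls_d = np.empty((n_keep, K))
    z_d = np.empty((n_keep, N, K))
    w = 2.0
    for it in range(n_warmup + n_keep):
        for k in range(K):
            _slice_coord(
                0, k, 0, w, mu, ls, z, slots, lo, hi, ident, tie, fam, frozen,
                has_kappa, choices, oppc, oppi, rew, tlen, A, B, rscale,
                mu_scale, sig_scale,
            )
            _slice_coord(
                1, k, 0, w, mu, ls, z, slots, lo, hi, ident, tie, fam, frozen,
                has_kappa, choices, oppc, oppi, rew, tlen, A, B, rscale,
                mu_scale, sig_scale,
            )
            for i in range(N):
                _slice_coord(
                    2, k, i, w, mu, ls, z, slots, lo, hi, ident, tie, fam,
                    frozen, has_kappa, choices, oppc, oppi, rew, tlen, A, B,
                    rscale, mu_scale, sig_scale,
                )
        if it >= n_warmup:
            j = it - n_warmup
            mu_d[j] = mu
            ls_d[j] = ls
            z_d[j] = z
    return mu_d, ls_d, z_d


@njit(cache=True)
def pointwise_all(
    mu_d, ls_d, z_d, slots, lo, hi, ident, tie, fam, frozen, has_kappa,
    choices, oppc, oppi, rew, tlen, A, B, rscale,
):
    """Pointwise log-likelihood for every retained draw, subject and trial."""
    n_draws = mu_d.shape[0]
    N = choices.shape[0]
    Tmax = choices.shape[1]
    out = np.zeros((n_draws, N, Tmax))
    for d in range(n_draws):
        for i in range(N):
            params5 = _nat5(mu_d[d], ls_d[d], z_d[d, i], slots, lo, hi, ident, tie)
            _session_pointwise(
                params5, fam, frozen, has_kappa, choices[i], oppc[i], oppi[i],
                rew[i], tlen[i], A, B, rscale, out[d, i],
            )
    return out
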