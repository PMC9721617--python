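"""Numba-compiled inner loops for trial-sequence likelihoods.

Everything here works on 0-based integer arrays (first_state, action, planet)
and *native-space* parameter vectors; transforms happen outside.  Two model
families share one code path each:

* family 0 — deterministic last-outcome learner (M1; stickiness via rho/pi):
  params = [omega, gamma, eta, rho, pi]
* family 1 — dual-system TD learner (M2; M3 ties alpha1 == alpha2):
  params = [omega, eta, alpha1, alpha2, lam]

The Python-level mirror of these recursions lives in ``twostep.agents``; the
two are asserted equal in the test-suite.
"""

import math

import numpy as np
from numba import njit

FAMILY_DET = 0
FAMILY_TD = 1


@njit(cache=True)
def _trial_logp(qmf, q2, tmap, params, family, s, a, prev_a, prev_stim):
    """log P(action a | values) and both choice values for state s."""
    q0 = 0.0
    q1 = 0.0
    if family == FAMILY_DET:
        omega = params[0]
        eta = params[2]
        rho = params[3]
        pi = params[4]
        q0 = omega * q2[tmap[s, 0]] + (1.0 - omega) * qmf[s, 0]
        q1 = omega * q2[tmap[s, 1]] + (1.0 - omega) * qmf[s, 1]
        if prev_a >= 0:
            if prev_a == 0:
                q0 += rho
            else:
                q1 += rho
            if prev_stim == 2 * s + 0:
                q0 += pi
            elif prev_stim == 2 * s + 1:
                q1 += pi
    else:
        omega = params[0]
        eta = params[1]
        q0 = omega * q2[tmap[s, 0]] + (1.0 - omega) * qmf[s, 0]
        q1 = omega * q2[tmap[s, 1]] + (1.0 - omega) * qmf[s, 1]
    x0 = eta * q0
    x1 = eta * q1
    m = x0 if x0 > x1 else x1
    lse = m + np.log(np.exp(x0 - m) + np.exp(x1 - m))
    if a == 0:
        return x0 - lse, q0, q1
    return x1 - lse, q0, q1


@njit(cache=True)
def _trial_update(qmf, q2, tmap, params, family, s, a, p, r):
    if family == FAMILY_DET:
        gamma = params[1]
        keep = 1.0 - gamma
        for ss in range(2):
            for aa in range(2):
                if ss == s and aa == a:
                    qmf[ss, aa] = r
                else:
                    qmf[ss, aa] *= keep
        q2[p] = r
    else:
        alpha1 = params[2]
        alpha2 = params[3]
        lam = params[4]
        d1 = q2[p] - qmf[s, a]
        qmf[s, a] += alpha1 * d1
        d2 = r - q2[p]
        q2[p] += alpha2 * d2
        qmf[s, a] += lam * alpha1 * d2


@njit(cache=True)
def session_loglik(params, family, fs, act, planet, reward, tmap):
    """Sequential log-likelihood of one session of observed choices."""
    qmf = np.zeros((2, 2))
    q2 = np.zeros(2)
    prev_a = -1
    prev_stim = -1
    total = 0.0
    for t in range(fs.shape[0]):
        s = fs[t]
        a = act[t]
        lp, _, _ = _trial_logp(qmf, q2, tmap, params, family, s, a, prev_a, prev_stim)
        total += lp
        _trial_update(qmf, q2, tmap, params, family, s, a, planet[t], reward[t])
        prev_a = a
        prev_stim = 2 * s + a
    return total


@njit(cache=True)
def segment_logliks(P, family, fs, act, planet, reward, offsets, tmap):
    """Log-likelihood of each segment (one subject-session per row of P)."""
    n = P.shape[0]
    out = np.empty(n)
    for i in range(n):
        lo = offsets[i]
        hi = offsets[i + 1]
        out[i] = session_loglik(
            P[i], family, fs[lo:hi], act[lo:hi], planet[lo:hi], reward[lo:hi], tmap
        )
    return out


@njit(cache=True)
def pointwise_logliks(P, family, fs, act, planet, reward, offsets, tmap, out):
    """Per-trial log-likelihoods.

    ``P`` has one row per (draw, segment) laid out draw-major; ``out`` is
    (n_draws, n_trials_total).  Row d*nseg + i of P holds draw d's native
    parameters for segment i.
    """
    nseg = offsets.shape[0] - 1
    ndraws = P.shape[0] // nseg
    for d in range(ndraws):
        for i in range(nseg):
            params = P[d * nseg + i]
            lo = offsets[i]
            hi = offsets[i + 1]
            qmf = np.zeros((2, 2))
            q2 = np.zeros(2)
            prev_a = -1
            prev_stim = -1
            for t in range(lo, hi):
                s = fs[t]
                a = act[t]
                lp, _, _ = _trial_logp(
                    qmf, q2, tmap, params, family, s, a, prev_a, prev_stim
                )
                out[d, t] = lp
                _trial_update(qmf, q2, tmap, params, family, s, a,
                              planet[t], reward[t])
                prev_a = a
                prev_stim = 2 * s + a
    return out


@njit(cache=True)
def predictive_accuracy(P, family, fs, act, planet, reward, offsets, tmap, modal):
    """Mean predictive accuracy per segment, averaged over draws.

    ``modal=True``: credit 1 when argmax-value action matches the observed
    one, 0.5 on exact value ties.  ``modal=False``: credit the model
    probability of the observed action.
    """
    nseg = offsets.shape[0] - 1
    ndraws = P.shape[0] // nseg
    acc = np.zeros(nseg)
    for d in range(ndraws):
        for i in range(nseg):
            params = P[d * nseg + i]
            lo = offsets[i]
            hi = offsets[i + 1]
            qmf = np.zeros((2, 2))
            q2 = np.zeros(2)
            prev_a = -1
            prev_stim = -1
            seg_acc = 0.0
            for t in range(lo, hi):
                s = fs[t]
                a = act[t]
                lp, q0, q1 = _trial_logp(
                    qmf, q2, tmap, params, family, s, a, prev_a, prev_stim
                )
                if modal:
                    if q0 == q1:
                        seg_acc += 0.5
                    elif (q1 > q0) == (a == 1):
                        seg_acc += 1.0
                else:
                    seg_acc += np.exp(lp)
                _trial_update(qmf, q2, tmap, params, family, s, a,
                              planet[t], reward[t])
                prev_a = a
                prev_stim = 2 * s + a
            acc[i] += seg_acc / (hi - lo)
    return acc / ndraws


@njit(cache=True)
def simulate_session(params, family, fs_seq, walk_rewards, tmap, uniforms):
    """Generate actions for one session; mirrors ``session_loglik``.

    ``walk_rewards`` is (2, n_trials); ``uniforms`` pre-drawn U(0,1) values.
    Returns (actions, planets, rewards).
    """
    n = fs_seq.shape[0]
    actions = np.empty(n, dtype=np.int64)
    planets = np.empty(n, dtype=np.int64)
    rewards = np.empty(n)
    qmf = np.zeros((2, 2))
    q2 = np.zeros(2)
    prev_a = -1
    prev_stim = -1
    for t in range(n):
        s = fs_seq[t]
        lp0, _, _ = _trial_logp(qmf, q2, tmap, params, family, s, 0, prev_a, prev_stim)
        p0 = np.exp(lp0)
        a = 0 if uniforms[t] < p0 else 1
        p = tmap[s, a]
        r = walk_rewards[p, t]
        actions[t] = a
        planets[t] = p
        rewards[t] = r
        _trial_update(qmf, q2, tmap, params, family, s, a, p, r)
        prev_a = a
        prev_stim = 2 * s + a
    return actions, planets, rewards


@njit(cache=True)
def cpc_chol(y, dim):
    """Lower Cholesky factor of a correlation matrix from CPC vector y."""
    L = np.zeros((dim, dim))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, dim):
        rem = 1.0
        for j in range(i):
            z = np.tanh(y[idx])
            L[i, j] = z * np.sqrt(rem)
            rem *= 1.0 - z * z
            idx += 1
        L[i, i] = np.sqrt(rem)
    return L


@njit(cache=True)
def cov_slice_logp(u, dim, C, n, lkj_eta, sd_prior_kind=0, sd_prior_scale=1.0):
    """Conditional log density of (log sigma, CPC) given residual scatter C.

    u stacks [log_sigma (dim), y (dim*(dim-1)//2)].  Returns the sum of the
    MVN likelihood of the n residual rows, the SD prior (with log Jacobian;
    kind 0 = HalfNormal(scale), kind 1 = HalfCauchy(scale)) and the
    LKJ(eta) prior in CPC space.
    """
    log_sigma = u[:dim]
    y = u[dim:]
    L = cpc_chol(y, dim)
    # scale rows: L_S = diag(sigma) @ L
    logdet = 0.0
    for d in range(dim):
        s = np.exp(log_sigma[d])
        for j in range(d + 1):
            L[d, j] *= s
        logdet += log_sigma[d] + np.log(L[d, d] / s)
    # X = L^{-1} C  (forward substitution), Z = L^{-1}
    X = C.copy()
    Z = np.eye(dim)
    for col in range(dim):
        for i in range(dim):
            acc_x = X[i, col]
            acc_z = Z[i, col]
            for j in range(i):
                acc_x -= L[i, j] * X[j, col]
                acc_z -= L[i, j] * Z[j, col]
            X[i, col] = acc_x / L[i, i]
            Z[i, col] = acc_z / L[i, i]
    tr = 0.0
    for i in range(dim):
        for j in range(dim):
            tr += X[i, j] * Z[i, j]
    lp = -0.5 * tr - n * logdet
    for d in range(dim):
        s = np.exp(log_sigma[d])
        if sd_prior_kind == 0:
            lp += -0.5 * (s / sd_prior_scale) ** 2 + log_sigma[d]
        else:
            lp += -np.log(1.0 + (s / sd_prior_scale) ** 2) + log_sigma[d]
    idx = 0
    for i in range(1, dim):
        for j in range(i):
            b = lkj_eta + 0.5 * (dim - 2 - j)
            lp += b * (-2.0 * np.log(np.cosh(y[idx])))
            idx += 1
    return lp


@njit(cache=True)
def _to_native_scalar(x, kind):
    # kind: 0 = probit (standard-normal CDF), 1 = exp, 2 = identity
    if kind == 0:
        return 0.5 * math.erfc(-x * 0.7071067811865476)
    if kind == 1:
        if x > 700.0:
            x = 700.0
        return math.exp(x)
    return x


@njit(cache=True)
def fill_session_params(latents_row, kinds, is_m3, session, params):
    """Native kernel parameter vector for one subject-session."""
    k = kinds.shape[0]
    for j in range(5):
        params[j] = 0.0
    for j in range(k):
        x = latents_row[j]
        if session == 2:
            x += latents_row[k + j]
        params[j] = _to_native_scalar(x, kinds[j])
    if is_m3:
        params[4] = params[3]   # lambda into slot 4
        params[3] = params[2]   # alpha2 := alpha
    return params


@njit(cache=True)
def latents_logliks(latents, kinds, family, is_m3, fs, act, planet, reward,
                    offsets, seg_subject, seg_session, tmap):
    """Per-subject total log-likelihood from estimation-space latents.

    Transforms happen inside so one call covers a whole Gibbs move.
    """
    n = latents.shape[0]
    out = np.zeros(n)
    params = np.zeros(5)
    for i in range(offsets.shape[0] - 1):
        si = seg_subject[i]
        fill_session_params(latents[si], kinds, is_m3, seg_session[i], params)
        lo = offsets[i]
        hi = offsets[i + 1]
        out[si] += session_loglik(params, family, fs[lo:hi], act[lo:hi],
                                  planet[lo:hi], reward[lo:hi], tmap)
    return out
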