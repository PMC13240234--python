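"""Numba-compiled forward/Viterbi recursions for the 2-state HMM and HSMM.

The HSMM is run as a dwell-expanded HMM: each behavioral phase is
unrolled into M sub-states that count elapsed dwell, with discrete
hazard h[s, j] = P(D_s = j+1 | D_s >= j+1) governing phase exits.  The
expansion's transition structure is sparse (each sub-state reaches only
its successor and the opposite phase's entry sub-state), so one forward
step costs O(M), not O(M^2).  For segments shorter than M the truncated
recursion is exact.

All forward passes use per-step normalization (scaling) and return the
predictive phase probabilities P(S_t | obs_{1..t-1}) needed for
one-step-ahead pseudo-residuals.
"""

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=False)
def hmm_forward(logB, gamma, delta):
    """Scaled forward pass for a 2-state HMM.

    Parameters: logB (T, 2) log emission densities, gamma (2, 2)
    row-stochastic transition matrix, delta (2,) initial distribution.
    Returns (loglik, pred) with pred[t] = P(S_t | obs before t).
    """
    T = logB.shape[0]
    pred = np.empty((T, 2))
    p0, p1 = delta[0], delta[1]
    loglik = 0.0
    for t in range(T):
        pred[t, 0] = p0
        pred[t, 1] = p1
        bmax = logB[t, 0] if logB[t, 0] > logB[t, 1] else logB[t, 1]
        a0 = p0 * np.exp(logB[t, 0] - bmax)
        a1 = p1 * np.exp(logB[t, 1] - bmax)
        c = a0 + a1
        if c <= 0.0 or not np.isfinite(c):
            return NEG_INF, pred  # forward mass annihilated: impossible params
        loglik += np.log(c) + bmax
        a0 /= c
        a1 /= c
        p0 = a0 * gamma[0, 0] + a1 * gamma[1, 0]
        p1 = a0 * gamma[0, 1] + a1 * gamma[1, 1]
    return loglik, pred


@njit(cache=False)
def hmm_viterbi(logB, log_gamma, log_delta):
    """Most-probable state path for a 2-state HMM; ties resolve to state 0."""
    T = logB.shape[0]
    bp = np.zeros((T, 2), dtype=np.int32)
    v0 = log_delta[0] + logB[0, 0]
    v1 = log_delta[1] + logB[0, 1]
    for t in range(1, T):
        n0a = v0 + log_gamma[0, 0]
        n0b = v1 + log_gamma[1, 0]
        if n0b > n0a:
            bp[t, 0] = 1
            n0 = n0b
        else:
            n0 = n0a
        n1a = v0 + log_gamma[0, 1]
        n1b = v1 + log_gamma[1, 1]
        if n1b > n1a:
            bp[t, 1] = 1
            n1 = n1b
        else:
            n1 = n1a
        v0 = n0 + logB[t, 0]
        v1 = n1 + logB[t, 1]
    path = np.zeros(T, dtype=np.int32)
    path[T - 1] = 0 if v0 >= v1 else 1
    for t in range(T - 1, 0, -1):
        path[t - 1] = bp[t, path[t]]
    return path


@njit(cache=False)
def hsmm_forward(logB, hazard, init):
    """Scaled forward pass for the dwell-expanded 2-phase HSMM.

    Parameters: logB (T, 2) log emissions, hazard (2, M) discrete dwell
    hazards, init (2, M) initial mass over (phase, elapsed dwell age) —
    typically the stationary equilibrium, since a segment is an
    arbitrary cut of a continuous walk.  Returns (loglik, pred) with
    pred[t] = predictive phase probabilities.
    """
    T = logB.shape[0]
    M = hazard.shape[1]
    pred = np.empty((T, 2))
    pi = init.copy()
    alpha = np.zeros((2, M))
    loglik = 0.0
    for t in range(T):
        s0 = 0.0
        s1 = 0.0
        for j in range(M):
            s0 += pi[0, j]
            s1 += pi[1, j]
        pred[t, 0] = s0
        pred[t, 1] = s1
        bmax = logB[t, 0] if logB[t, 0] > logB[t, 1] else logB[t, 1]
        b0 = np.exp(logB[t, 0] - bmax)
        b1 = np.exp(logB[t, 1] - bmax)
        c = 0.0
        for j in range(M):
            alpha[0, j] = pi[0, j] * b0
            alpha[1, j] = pi[1, j] * b1
            c += alpha[0, j] + alpha[1, j]
        if c <= 0.0 or not np.isfinite(c):
            return NEG_INF, pred  # forward mass annihilated: impossible params
        loglik += np.log(c) + bmax
        for j in range(M):
            alpha[0, j] /= c
            alpha[1, j] /= c
        # propagate: exit with hazard, else advance dwell counter
        leave0 = 0.0
        leave1 = 0.0
        for j in range(M):
            leave0 += alpha[0, j] * hazard[0, j]
            leave1 += alpha[1, j] * hazard[1, j]
        for j in range(M - 1, 0, -1):
            pi[0, j] = alpha[0, j - 1] * (1.0 - hazard[0, j - 1])
            pi[1, j] = alpha[1, j - 1] * (1.0 - hazard[1, j - 1])
        # the last sub-state absorbs the tail of the dwell distribution
        pi[0, M - 1] += alpha[0, M - 1] * (1.0 - hazard[0, M - 1])
        pi[1, M - 1] += alpha[1, M - 1] * (1.0 - hazard[1, M - 1])
        pi[0, 0] = leave1
        pi[1, 0] = leave0
    return loglik, pred


@njit(cache=False)
def hsmm_viterbi(logB, hazard, init):
    """Most-probable phase path for the dwell-expanded HSMM.

    Runs Viterbi on the (2, M) expanded state space (initialized from
    the (2, M) ``init`` mass) and collapses the decoded sub-states back
    to phase labels; ties resolve to phase 0.
    """
    T = logB.shape[0]
    M = hazard.shape[1]
    log_h = np.empty((2, M))
    log_1mh = np.empty((2, M))
    for s in range(2):
        for j in range(M):
            h = hazard[s, j]
            log_h[s, j] = np.log(h) if h > 0.0 else NEG_INF
            log_1mh[s, j] = np.log(1.0 - h) if h < 1.0 else NEG_INF
    V = np.full((2, M), NEG_INF)
    newV = np.full((2, M), NEG_INF)
    for s in range(2):
        for j in range(M):
            if init[s, j] > 0.0:
                V[s, j] = np.log(init[s, j]) + logB[0, s]
    entry_bp = np.zeros((T, 2), dtype=np.int32)  # exiting sub-state of the other phase
    stay_last = np.zeros((T, 2), dtype=np.int32)  # 1 if (s, M-1) self-looped
    for t in range(1, T):
        for s in range(2):
            o = 1 - s
            best = NEG_INF
            bj = 0
            for j in range(M):
                v = V[o, j] + log_h[o, j]
                if v > best:
                    best = v
                    bj = j
            newV[s, 0] = best + logB[t, s]
            entry_bp[t, s] = bj
            for j in range(1, M):
                newV[s, j] = V[s, j - 1] + log_1mh[s, j - 1] + logB[t, s]
            alt = V[s, M - 1] + log_1mh[s, M - 1] + logB[t, s]
            if alt > newV[s, M - 1]:
                newV[s, M - 1] = alt
                stay_last[t, s] = 1
            else:
                stay_last[t, s] = 0
        for s in range(2):
            for j in range(M):
                V[s, j] = newV[s, j]
    # terminal argmax; scanning phase 0 first breaks ties toward it
    bs, bjj = 0, 0
    best = NEG_INF
    for s in range(2):
        for j in range(M):
            if V[s, j] > best:
                best = V[s, j]
                bs, bjj = s, j
    path = np.zeros(T, dtype=np.int32)
    s, j = bs, bjj
    for t in range(T - 1, -1, -1):
        path[t] = s
        if t == 0:
            break
        if j == 0:
            jprev = entry_bp[t, s]
            s = 1 - s
            j = jprev
        elif j == M - 1 and stay_last[t, s] == 1:
            j = M - 1
        else:
            j = j - 1
    return path
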