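"""Numba-jitted dynamic-programming kernels.

These are internal numerical cores; the public, documented surfaces are in
``foldengine`` and ``consensus``. All tables use half-open interval indexing:
``Q[i, j]`` covers positions ``i .. j-1`` so that ``Q[i, i]`` is the empty
segment. Pair tables ``Qb[i, j]`` refer to the closed pair (i, j).

Partition-function tables are computed with a per-position rescaling factor
(the caller divides pair weights by c**2 and scales unpaired positions by
1/c) so that very stable long sequences do not overflow float64.
"""

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True)
def inside_kernel(w: np.ndarray, u: float, sigma: float, min_h: int):
    """Inside partition function.

    w: (N, N) scaled Boltzmann weight of pair (i, j) (0 where not allowed),
    u: scaled weight of one unpaired position, sigma: stack bonus applied
    when a pair sits directly inside another. Returns (Q, Qb).
    """
    N = w.shape[0]
    Q = np.zeros((N + 1, N + 1))
    Qb = np.zeros((N, N))
    for i in range(N + 1):
        Q[i, i] = 1.0
    for s in range(1, N + 1):  # segment length
        for i in range(N - s + 1):
            j = i + s - 1  # closed right end
            # pair table for (i, j)
            if s >= min_h + 2 and w[i, j] > 0.0:
                inner = Q[i + 1, j]
                if s >= min_h + 4 and Qb[i + 1, j - 1] > 0.0:
                    inner += (sigma - 1.0) * Qb[i + 1, j - 1]
                Qb[i, j] = w[i, j] * inner
            # segment table for [i, j]
            acc = u * Q[i + 1, j + 1]
            for k in range(i + min_h + 1, j + 1):
                if Qb[i, k] > 0.0:
                    acc += Qb[i, k] * Q[k + 1, j + 1]
            Q[i, j + 1] = acc
    return Q, Qb


@njit(cache=True)
def outside_kernel(w: np.ndarray, sigma: float, min_h: int,
                   Q: np.ndarray, Qb: np.ndarray):
    """Outside values and pair probabilities given the inside tables.

    Returns P with P[i, j] = Pr(pair (i, j)), symmetric.
    """
    N = w.shape[0]
    Ob = np.zeros((N, N))
    P = np.zeros((N, N))
    Qtot = Q[0, N]
    for s in range(N, min_h + 1, -1):  # pair span, decreasing
        for i in range(N - s + 1):
            j = i + s - 1
            if Qb[i, j] <= 0.0:
                continue
            acc = Q[0, i] * Q[j + 1, N]
            for p in range(i):
                left = Q[p + 1, i]
                if left <= 0.0:
                    continue
                for q in range(j + 1, N):
                    if Qb[p, q] <= 0.0 or Ob[p, q] <= 0.0:
                        continue
                    term = Ob[p, q] * w[p, q] * left * Q[j + 1, q]
                    if p == i - 1 and q == j + 1:
                        term *= sigma
                    acc += term
            Ob[i, j] = acc
            pij = Qb[i, j] * acc / Qtot
            P[i, j] = pij
            P[j, i] = pij
    return P


@njit(cache=True)
def mea_kernel(P: np.ndarray, Po: np.ndarray, gamma: float, min_h: int):
    """Maximum-expected-accuracy DP.

    Maximizes sum over pairs of 2*gamma*P(i,j) plus sum over unpaired of
    Po(i). Ties prefer leaving i unpaired, then the smaller partner k.
    choice[i, j] = -1 for "i unpaired", else the partner k.
    """
    N = P.shape[0]
    M = np.zeros((N + 1, N + 1))
    choice = np.full((N + 1, N + 1), -1, dtype=np.int64)
    for s in range(1, N + 1):
        for i in range(N - s + 1):
            j = i + s  # half-open right end
            best = Po[i] + M[i + 1, j]
            bk = -1
            for k in range(i + min_h + 1, j):
                if P[i, k] <= 0.0:
                    continue
                val = 2.0 * gamma * P[i, k] + M[i + 1, k] + M[k + 1, j]
                if val > best + 1e-12:
                    best = val
                    bk = k
            M[i, j] = best
            choice[i, j] = bk
    return M, choice


@njit(cache=True)
def nw_profile(S: np.ndarray) -> np.ndarray:
    """Global profile-profile alignment maximizing summed posterior match
    probability, gaps free. Returns the traceback choice matrix:
    0 = diagonal (match columns), 1 = consume a column of A, 2 = of B.
    Ties prefer diagonal, then consuming A."""
    La, Lb = S.shape
    M = np.zeros((La + 1, Lb + 1))
    choice = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    for x in range(1, La + 1):
        choice[x, 0] = 1
    for y in range(1, Lb + 1):
        choice[0, y] = 2
    for x in range(1, La + 1):
        for y in range(1, Lb + 1):
            best = M[x - 1, y - 1] + S[x - 1, y - 1]
            c = 0
            if M[x - 1, y] > best + 1e-12:
                best = M[x - 1, y]
                c = 1
            if M[x, y - 1] > best + 1e-12:
                best = M[x, y - 1]
                c = 2
            M[x, y] = best
            choice[x, y] = c
    return choice


@njit(cache=True)
def hmm_forward_backward(ls: np.ndarray, log_mm: float, log_mg: float,
                         log_gm: float, log_gg: float):
    """Posterior match probabilities of a 3-state pair HMM in log space.

    ls[i, k]: log emission odds of aligning m_i with n_k. States: 0 match,
    1 insert-in-m (consumes i), 2 insert-in-n (consumes k); no direct
    transition between the two insert states. Start and end are folded in
    as the match state. Returns (pi, logZ).
    """
    Lm, Ln = ls.shape
    a = np.full((Lm + 1, Ln + 1, 3), NEG_INF)
    b = np.full((Lm + 1, Ln + 1, 3), NEG_INF)
    a[0, 0, 0] = 0.0
    for i in range(Lm + 1):
        for k in range(Ln + 1):
            if i > 0 and k > 0:
                am = np.logaddexp(a[i - 1, k - 1, 0] + log_mm,
                                  np.logaddexp(a[i - 1, k - 1, 1] + log_gm,
                                               a[i - 1, k - 1, 2] + log_gm))
                a[i, k, 0] = am + ls[i - 1, k - 1]
            if i > 0:
                a[i, k, 1] = np.logaddexp(a[i - 1, k, 0] + log_mg,
                                          a[i - 1, k, 1] + log_gg)
            if k > 0:
                a[i, k, 2] = np.logaddexp(a[i, k - 1, 0] + log_mg,
                                          a[i, k - 1, 2] + log_gg)
    logZ = np.logaddexp(a[Lm, Ln, 0],
                        np.logaddexp(a[Lm, Ln, 1], a[Lm, Ln, 2]))
    b[Lm, Ln, 0] = 0.0
    b[Lm, Ln, 1] = 0.0
    b[Lm, Ln, 2] = 0.0
    for i in range(Lm, -1, -1):
        for k in range(Ln, -1, -1):
            if i == Lm and k == Ln:
                continue
            bm = NEG_INF
            bx = NEG_INF
            by = NEG_INF
            if i < Lm and k < Ln:
                e = ls[i, k] + b[i + 1, k + 1, 0]
                bm = np.logaddexp(bm, log_mm + e)
                bx = np.logaddexp(bx, log_gm + e)
                by = np.logaddexp(by, log_gm + e)
            if i < Lm:
                bm = np.logaddexp(bm, log_mg + b[i + 1, k, 1])
                bx = np.logaddexp(bx, log_gg + b[i + 1, k, 1])
            if k < Ln:
                bm = np.logaddexp(bm, log_mg + b[i, k + 1, 2])
                by = np.logaddexp(by, log_gg + b[i, k + 1, 2])
            b[i, k, 0] = bm
            b[i, k, 1] = bx
            b[i, k, 2] = by
    pi = np.zeros((Lm, Ln))
    for i in range(1, Lm + 1):
        for k in range(1, Ln + 1):
            v = a[i, k, 0] + b[i, k, 0] - logZ
            if v > -60.0:
                pi[i - 1, k - 1] = np.exp(v)
    return pi, logZ
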