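"""Independent brute-force / first-principles oracles used by the tests.

Everything here is deliberately naive and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy.optimize import minimize


def svr_primal_qp(X, y, C=1.0, eps=0.1):
    """Solve the primal epsilon-SVR as an explicit slack-variable convex
    program with SLSQP.  Variables: w (p), b, xi (n), xi* (n)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    def obj(v):
        w = v[:p]
        return 0.5 * w @ w + C * np.sum(v[p + 1:])

    def jac(v):
        g = np.zeros_like(v)
        g[:p] = v[:p]
        g[p + 1:] = C
        return g

    cons = []
    for i in range(n):
        def above(v, i=i):
            return eps + v[p + 1 + i] - (y[i] - (X[i] @ v[:p] + v[p]))

        def below(v, i=i):
            return eps + v[p + 1 + n + i] + (y[i] - (X[i] @ v[:p] + v[p]))

        cons.append({"type": "ineq", "fun": above})
        cons.append({"type": "ineq", "fun": below})
    bounds = [(None, None)] * (p + 1) + [(0, None)] * (2 * n)
    v0 = np.zeros(p + 1 + 2 * n)
    v0[p] = y.mean()
    res = minimize(
        obj, v0, jac=jac, method="SLSQP", bounds=bounds, constraints=cons,
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    assert res.success, res.message
    return res.x[:p], float(res.x[p])


def bh_stepup_bruteforce(pvalues, alpha):
    """Benjamini-Hochberg rejections by literal step-up over sorted p's.

    Comparisons are done in exact rational arithmetic so that boundary
    cases (p exactly on a cutoff) are decided without rounding error.
    """
    p = [Fraction(v) for v in np.asarray(pvalues, dtype=float)]
    alpha = Fraction(alpha)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= Fraction(k, m) * alpha:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def bh_qvalues_bruteforce(pvalues):
    """q_i = smallest alpha at which i is rejected by the step-up rule,
    found by scanning every candidate cutoff m * p_(k) / k (exact
    rational arithmetic throughout)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    candidates = sorted(
        min(Fraction(m, k) * Fraction(pk), Fraction(1))
        for k in range(1, m + 1) for pk in p
    ) + [Fraction(1)]
    q = np.ones(m)
    for i in range(m):
        for a in candidates:
            if bh_stepup_bruteforce(p, a)[i]:
                q[i] = float(a)
                break
    return q


def kendall_tau_b_bruteforce(x, y):
    """Tau-b from exhaustive concordant/discordant/tie pair counts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nc = nd = tx = ty = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            nc += 1
        else:
            nd += 1
    n0 = len(x) * (len(x) - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom


def pooled_ttest_bruteforce(a, b):
    """Student's pooled-variance t from the closed form."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def scrub_keep_bruteforce(fd, threshold, n_before, n_after):
    """Keep-set by literal set construction of the censoring windows."""
    n = len(fd)
    dropped = set()
    for s in range(n):
        if fd[s] > threshold:
            for t in range(s - n_before, s + n_after + 1):
                if 0 <= t < n:
                    dropped.add(t)
    return np.array([t not in dropped for t in range(n)])


def expected_censored_fraction(n_frames, spike_prob, n_before, n_after,
                               n_sim, seed):
    """Monte-Carlo expectation of the censored fraction when spike frames
    are Bernoulli(spike_prob) (frame 0 never spikes) and each spike censors
    the window [s - n_before, s + n_after] clamped to the run."""
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_sim):
        spikes = rng.random(n_frames) < spike_prob
        spikes[0] = False
        dropped = np.zeros(n_frames, dtype=bool)
        for s in np.flatnonzero(spikes):
            dropped[max(0, s - n_before):min(n_frames, s + n_after + 1)] = True
        total += dropped.mean()
    return total / n_sim
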