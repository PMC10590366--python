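"""Independent brute-force oracles used to validate the HMM machinery.

These deliberately avoid the package's vectorised/factorised code paths:
emissions are computed by explicit nested sums over every genotype
configuration, and chain posteriors / best paths by enumerating all state
paths.
"""

from math import comb

import numpy as np


def binom_pmf(k, n, p):
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def lik(counts, g, eps):
    r, a = counts
    n = r + a
    if n == 0:
        return 1.0
    p = (eps, 0.5, 1 - eps)[g]
    return binom_pmf(a, n, p)


def elik(counts, g, eps, ado):
    if g != 1:
        return lik(counts, g, eps)
    return (
        (1 - ado) * lik(counts, 1, eps)
        + ado / 2 * lik(counts, 0, eps)
        + ado / 2 * lik(counts, 2, eps)
    )


def hw(g, q):
    return ((1 - q) ** 2, 2 * q * (1 - q), q * q)[g]


TRANSMIT = {0: [(0, 1.0)], 1: [(0, 0.5), (1, 0.5)], 2: [(1, 1.0)]}


def child_emission_oracle(cm, cf, cc, ce, q, eps, ado):
    """Exhaustive genotype-configuration sum, child-reference mode."""
    out = np.zeros(4)
    states = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for gm in range(3):
        for gf in range(3):
            w0 = hw(gm, q) * hw(gf, q) * lik(cm, gm, eps) * lik(cf, gf, eps)
            for tm, wm in TRANSMIT[gm]:
                for tf, wf in TRANSMIT[gf]:
                    wc = w0 * wm * wf * lik(cc, tm + tf, eps)
                    for si, (im, ip) in enumerate(states):
                        em = tm if im == 0 else gm - tm
                        ef = tf if ip == 0 else gf - tf
                        out[si] += wc * elik(ce, em + ef, eps, ado)
    return out


def grandparent_emission_oracle(cg1, cg2, cpar, cother, ce, q, eps, ado):
    """Exhaustive genotype-configuration sum, one grandparent-phased side.

    ``cg1``/``cg2`` may be None for an unsequenced grandparent (prior only).
    """
    l1 = (lambda g: 1.0) if cg1 is None else (lambda g: lik(cg1, g, eps))
    l2 = (lambda g: 1.0) if cg2 is None else (lambda g: lik(cg2, g, eps))
    out = np.zeros(2)
    for g1 in range(3):
        for g2 in range(3):
            w12 = hw(g1, q) * l1(g1) * hw(g2, q) * l2(g2)
            for a1, w1 in TRANSMIT[g1]:
                for a2, w2 in TRANSMIT[g2]:
                    wp = w12 * w1 * w2 * lik(cpar, a1 + a2, eps)
                    for go in range(3):
                        wo = hw(go, q) * lik(cother, go, eps)
                        for t, wt in TRANSMIT[go]:
                            w = wp * wo * wt
                            out[0] += w * elik(ce, a1 + t, eps, ado)
                            out[1] += w * elik(ce, a2 + t, eps, ado)
    return out


def enumerate_chain(emissions, transitions):
    """Marginals and best path by explicit enumeration of all state paths.

    Path probabilities start from the uniform initial distribution. The best
    path resolves ties to the lexicographically first path, matching the
    production Viterbi tie-break.
    """
    emissions = np.asarray(emissions, dtype=float)
    T, S = emissions.shape
    grids = np.meshgrid(*[np.arange(S)] * T, indexing="ij")
    paths = np.stack([g.ravel() for g in grids], axis=1)  # lexicographic order
    p = np.full(len(paths), 1.0 / S)
    for t in range(T):
        p = p * emissions[t, paths[:, t]]
        if t > 0:
            p = p * transitions[t - 1, paths[:, t - 1], paths[:, t]]
    marg = np.zeros((T, S))
    for t in range(T):
        for s in range(S):
            marg[t, s] = p[paths[:, t] == s].sum()
    marg /= marg.sum(axis=1, keepdims=True)
    best = paths[int(np.argmax(p))]
    return marg, best
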