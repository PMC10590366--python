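"""Generic forward-backward and Viterbi routines on heterogeneous chains.

Emissions are plain (unnormalised) per-site likelihoods, one row per site;
transitions are per-gap stochastic matrices (one fewer than sites). The
forward-backward pass is computed in scaled linear space (per-site
renormalisation), which is stable for chains of hundreds of thousands of
sites; Viterbi runs in log space with deterministic first-state tie-breaks.
"""

from __future__ import annotations

import numpy as np


def _check(emissions: np.ndarray, transitions: np.ndarray):
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be (n_sites, n_states) with n_sites >= 1")
    n, s = emissions.shape
    transitions = np.asarray(transitions, dtype=float)
    if n == 1:
        transitions = transitions.reshape(0, s, s)
    if transitions.shape != (n - 1, s, s):
        raise ValueError(
            f"transitions shape {transitions.shape} incompatible with emissions {emissions.shape}"
        )
    if (emissions < 0).any():
        raise ValueError("emissions must be non-negative")
    return emissions, transitions


def _scale_rows(emissions: np.ndarray) -> np.ndarray:
    m = emissions.max(axis=1, keepdims=True)
    if (m == 0).any():
        raise ValueError("emission row with all-zero likelihood")
    return emissions / m


def forward_backward(emissions, transitions, initial=None):
    """Posterior state probabilities per site.

    Returns (posteriors, loglik) where posteriors has the shape of
    ``emissions`` and each row sums to 1. ``initial`` defaults to the uniform
    distribution. loglik is the log-likelihood of the observation sequence
    (computed before per-row emission scaling is undone, i.e. exact).
    """
    emissions, transitions = _check(emissions, transitions)
    n, s = emissions.shape
    row_max = emissions.max(axis=1)
    if (row_max == 0).any():
        raise ValueError("emission row with all-zero likelihood")
    em = emissions / row_max[:, None]
    init = np.full(s, 1.0 / s) if initial is None else np.asarray(initial, dtype=float)

    alpha = np.empty((n, s))
    c = np.empty(n)
    a = init * em[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ transitions[t - 1]) * em[t]
        c[t] = a.sum()
        if c[t] <= 0:
            raise ValueError(f"zero forward mass at site {t}")
        alpha[t] = a / c[t]

    beta = np.empty((n, s))
    beta[n - 1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (transitions[t] @ (em[t + 1] * beta[t + 1])) / c[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + np.log(row_max).sum())
    return post, loglik


def viterbi(emissions, transitions, initial=None) -> np.ndarray:
    """Most probable state path; ties resolve to the lowest state index."""
    emissions, transitions = _check(emissions, transitions)
    n, s = emissions.shape
    with np.errstate(divide="ignore"):
        log_em = np.log(_scale_rows(emissions))
        log_tr = np.log(transitions)
        log_init = (
            np.full(s, -np.log(s)) if initial is None else np.log(np.asarray(initial, dtype=float))
        )

    delta = log_init + log_em[0]
    psi = np.empty((n, s), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + log_tr[t - 1]
        psi[t] = scores.argmax(axis=0)  # first max wins on ties
        delta = scores[psi[t], np.arange(s)] + log_em[t]

    path = np.empty(n, dtype=np.int64)
    path[n - 1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path
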