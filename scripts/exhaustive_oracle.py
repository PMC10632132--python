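"""Exhaustive hidden-state path maximization, independent of the
package's Viterbi implementation.

Scores every state sequence over {balanced} + {(deviation, polarity)}
explicitly under the detector's transition/emission model and returns
the maximum joint log-probability (binomial coefficients included).
Exponential in the number of markers; meant for tiny instances only.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def _log_binom_pmf(k, n, p):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(p) + (n - k) * np.log(1 - p)
    )


def exhaustive_best_logp(k, n, s, bdev_grid, p_event, p_switch) -> float:
    k = np.asarray(k)
    n = np.asarray(n)
    s = np.asarray(s)
    bdev_grid = np.asarray(bdev_grid, dtype=float)
    G = len(bdev_grid)
    S = 2 * G + 1
    m = len(k)

    E = np.empty((S, m))
    E[0] = _log_binom_pmf(k, n, 0.5)
    for g, b in enumerate(bdev_grid):
        up = np.where(s > 0, 0.5 + b, 0.5 - b)
        E[1 + 2 * g] = _log_binom_pmf(k, n, up)
        E[2 + 2 * g] = _log_binom_pmf(k, n, 1.0 - up)

    T = np.full((S, S), -np.inf)
    T[0, 0] = np.log1p(-p_event)
    T[0, 1:] = np.log(p_event / (2 * G))
    for g in range(G):
        jp, jm = 1 + 2 * g, 2 + 2 * g
        T[jp, 0] = T[jm, 0] = np.log(p_event)
        T[jp, jm] = T[jm, jp] = np.log(p_switch)
        T[jp, jp] = T[jm, jm] = np.log(1.0 - p_event - p_switch)
    pi = T[0].copy()

    scores = pi + E[:, 0]
    last = np.arange(S)
    for i in range(1, m):
        scores = (scores[:, None] + T[last] + E[None, :, i]).ravel()
        last = np.tile(np.arange(S), len(scores) // S)
    return float(scores.max())
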