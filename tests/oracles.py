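"""Independent oracles used by the test suite.

Each oracle recomputes an expected value by a route independent of the
implementation it checks: explicit allele counting in a finite cell
mixture, full enumeration of hidden-state paths, and enumeration of all
2^n sign-test outcomes.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.special import gammaln


def cell_mixture_baf(etype: str, cf: float, n_cells: int = 1_000_000):
    """Allele fraction and mean copy number from explicit copy counting.

    A mixture of ``n_cells`` cells, ``round(cf * n_cells)`` of them
    carrying the event, the rest diploid (one copy of allele A on
    haplotype 1, one of allele B).  Haplotype 1 is duplicated (gain,
    CN-LOH) or lost (loss).  Returns (|BAF_A - 1/2|, mean copy number).
    """
    n_mut = round(cf * n_cells)
    n_wt = n_cells - n_mut
    a_mut, b_mut = {"gain": (2, 1), "loss": (0, 1), "cnloh": (2, 0)}[etype]
    total_a = n_wt * 1 + n_mut * a_mut
    total_b = n_wt * 1 + n_mut * b_mut
    total = total_a + total_b
    return abs(total_a / total - 0.5), total / n_cells


def log_binom_pmf(k, n, p: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(p) + (n - k) * np.log(1 - p)
    )


def exhaustive_best_path(k, n, s, bdev_grid, p_event, p_switch):
    """Brute-force maximum-joint-probability hidden-state path.

    Holds the score of *every* state sequence over {null} + {(b, pol)}
    explicitly (S^m paths) under the detector's transition/emission
    model, binomial coefficients included.  Returns (best log-prob,
    best path array, number of ties within 1e-9 of the maximum).
    Exponential in the number of markers: use only on tiny instances.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    s = np.asarray(s)
    bdev_grid = np.asarray(bdev_grid, dtype=float)
    G = len(bdev_grid)
    S = 2 * G + 1
    m = len(k)

    # emissions E[state, marker]
    E = np.empty((S, m))
    E[0] = log_binom_pmf(k, n, 0.5)
    for g, b in enumerate(bdev_grid):
        up = np.where(s > 0, 0.5 + b, 0.5 - b)
        E[1 + 2 * g] = [log_binom_pmf(k[i], n[i], up[i]) for i in range(m)]
        E[2 + 2 * g] = [log_binom_pmf(k[i], n[i], 1.0 - up[i]) for i in range(m)]

    T = np.full((S, S), -np.inf)
    T[0, 0] = np.log1p(-p_event)
    T[0, 1:] = np.log(p_event / (2 * G))
    for g in range(G):
        jp, jm = 1 + 2 * g, 2 + 2 * g
        T[jp, 0] = T[jm, 0] = np.log(p_event)
        T[jp, jm] = T[jm, jp] = np.log(p_switch)
        T[jp, jp] = T[jm, jm] = np.log(1.0 - p_event - p_switch)
    pi = T[0].copy()  # start as if preceded by a balanced state

    # scores of all S^i prefixes, earlier markers as most-significant digits
    scores = pi + E[:, 0]  # shape (S,)
    last = np.arange(S)
    for i in range(1, m):
        scores = (scores[:, None] + T[last][:, :] + E[None, :, i]).ravel()
        last = np.tile(np.arange(S), len(scores) // S)
    best_idx = int(np.argmax(scores))
    best_logp = float(scores[best_idx])
    ties = int(np.sum(scores >= best_logp - 1e-9))
    digits = []
    idx = best_idx
    for _ in range(m):
        digits.append(idx % S)
        idx //= S
    return best_logp, np.array(digits[::-1]), ties


def nonnull_runs(path) -> list[tuple[int, int]]:
    """Half-open (start, end) marker-index runs of non-null states."""
    path = np.asarray(path)
    nonnull = (path != 0).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], nonnull, [0]))))
    return [tuple(e) for e in edges.reshape(-1, 2)]


def exact_two_sided_sign_p(k: int, n: int) -> float:
    """Two-sided sign-test p-value by enumerating all 2^n outcomes.

    Each of the 2^n equiprobable carrier-indicator sequences is included
    iff its count statistic is no more likely than the observed count
    (minimum-likelihood two-sided convention)."""
    p_obs = comb(n, k)  # likelihood of the observed count, up to 2^-n
    included = 0
    for bits in itertools.product((0, 1), repeat=n):
        kk = sum(bits)
        if comb(n, kk) <= p_obs:
            included += 1
    return included / 2**n
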