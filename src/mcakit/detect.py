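"""Haplotype-phase detection of allelic imbalance.

The detector works on phased heterozygous sites only (no total-coverage
term): at marker *i* with alt-allele depth ``k_i`` out of ``n_i`` reads
and phase sign ``s_i`` (+1 when the alternate allele is on haplotype 1),
a clonal imbalance that over-represents haplotype 1 by a BAF deviation
``b`` shifts the alt-read probability to ``1/2 + s_i * b``.

A hidden Markov model captures this: a balanced null state emits
``k ~ Binomial(n, 1/2)``; for each deviation ``b`` on a grid there are
two imbalance states of opposite polarity emitting
``k ~ Binomial(n, 1/2 +/- s*b)``.  Polarity flips inside an event model
phase-switch errors.  The Viterbi path defines candidate segments;
each segment's deviation is then re-estimated by grid search with a
polarity re-fit, and scored with a base-10 log-odds (LOD) against the
balanced null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .samples import SampleGenome

__all__ = [
    "PhasedSignal",
    "DetectorParams",
    "RawSegment",
    "build_signal",
    "hmm_segment",
    "lod_score",
    "merge_adjacent",
    "detect_sample",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class PhasedSignal:
    """Per-chromosome arrays of the detector's sufficient statistics."""

    chrom: str
    pos: np.ndarray  # int64, 1-based, strictly increasing
    s: np.ndarray  # int8, +1 if alt allele on haplotype 1 else -1
    k: np.ndarray  # int64, alt-allele depth
    n: np.ndarray  # int64, total depth

    def __len__(self) -> int:
        return len(self.pos)

    def slice(self, i0: int, i1: int) -> "PhasedSignal":
        """Half-open marker-index slice."""
        return PhasedSignal(
            self.chrom, self.pos[i0:i1], self.s[i0:i1], self.k[i0:i1], self.n[i0:i1]
        )


def default_bdev_grid() -> np.ndarray:
    return np.geomspace(0.001, 0.25, 30)


@dataclass(frozen=True)
class DetectorParams:
    """HMM parameters.

    ``p_event`` is the per-marker prior of entering (or leaving) an
    imbalanced state; ``p_switch`` the per-marker polarity-flip rate,
    which should match the phase-switch error rate of the input
    haplotypes (default 1e-3).  The switch rate bounds detectable clones:
    hard-path decoding can track polarity only while the per-marker
    signal information (~2 n b^2 nats at depth n, deviation b) exceeds
    the switch entropy rate, so small deviations need clean phasing.
    ``min_lod`` and ``min_hets`` are the downstream call thresholds,
    carried here for convenience.
    """

    bdev_grid: np.ndarray = field(default_factory=default_bdev_grid)
    p_event: float = 1e-4
    p_switch: float = 1e-3
    min_lod: float = 5.0
    min_hets: int = 2000

    def __post_init__(self) -> None:
        grid = np.asarray(self.bdev_grid, dtype=float)
        if len(grid) == 0:
            raise ValueError("bdev grid must be non-empty")
        if np.any(np.diff(grid) <= 0) or grid[0] <= 0 or grid[-1] >= 0.5:
            raise ValueError("bdev grid must be strictly increasing within (0, 0.5)")
        object.__setattr__(self, "bdev_grid", grid)
        for p in (self.p_event, self.p_switch):
            if not 0.0 < p < 1.0:
                raise ValueError("transition probabilities must be in (0, 1)")
        if self.p_event + self.p_switch >= 1.0:
            raise ValueError("p_event + p_switch must be < 1")


@dataclass(frozen=True)
class RawSegment:
    """A maximal run of non-null Viterbi states on one chromosome."""

    chrom: str
    start_pos: int
    end_pos: int
    first_marker: int  # index into the chromosome's PhasedSignal
    last_marker: int  # inclusive
    n_hets: int
    bdev_hat: float
    lod: float
    polarity_frac: float  # fraction of markers assigned polarity +


def build_signal(sample: SampleGenome) -> dict[str, PhasedSignal]:
    """One PhasedSignal per chromosome, in the sample's chromosome order."""
    out: dict[str, PhasedSignal] = {}
    for chrom, tab in sample.iter_chromosomes():
        k = tab["ad_alt"].to_numpy().astype(np.int64)
        n = k + tab["ad_ref"].to_numpy().astype(np.int64)
        if np.any(n == 0):
            raise ValueError(f"zero-depth marker on {chrom}; filter before detection")
        s = np.where(tab["hap1_alt"].to_numpy() == 1, 1, -1).astype(np.int8)
        out[chrom] = PhasedSignal(chrom, tab["pos"].to_numpy().astype(np.int64), s, k, n)
    return out


# ---------------------------------------------------------------------------
# Viterbi kernel.  State layout: 0 = balanced null; for grid index g,
# state 1+2g has polarity + (haplotype 1 elevated), state 2+2g polarity -.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _viterbi(k, n, s, la, lb, ln_stay_null, ln_enter, ln_exit, ln_flip, ln_stay_ev):
    m = k.shape[0]
    G = la.shape[0]
    ln_half = math.log(0.5)

    v = np.empty(2 * G)
    nv = np.empty(2 * G)
    bp = np.empty((m, 2 * G), np.int8)  # 0=from null, 1=stay, 2=from twin
    bp_null = np.empty(m, np.int32)  # 0=from null, else predecessor state j+1

    v_null = ln_stay_null + n[0] * ln_half
    for g in range(G):
        if s[0] > 0:
            ep = k[0] * la[g] + (n[0] - k[0]) * lb[g]
            em = k[0] * lb[g] + (n[0] - k[0]) * la[g]
        else:
            ep = k[0] * lb[g] + (n[0] - k[0]) * la[g]
            em = k[0] * la[g] + (n[0] - k[0]) * lb[g]
        v[2 * g] = ln_enter + ep
        v[2 * g + 1] = ln_enter + em
        bp[0, 2 * g] = 0
        bp[0, 2 * g + 1] = 0
    bp_null[0] = 0

    for i in range(1, m):
        best_j = 0
        best_v = v[0]
        for j in range(1, 2 * G):
            if v[j] > best_v:
                best_v = v[j]
                best_j = j
        stay = v_null + ln_stay_null
        exit_ = best_v + ln_exit
        if stay >= exit_:
            nv_null = stay + n[i] * ln_half
            bp_null[i] = 0
        else:
            nv_null = exit_ + n[i] * ln_half
            bp_null[i] = best_j + 1

        enter = v_null + ln_enter
        ki = k[i]
        nki = n[i] - k[i]
        for g in range(G):
            if s[i] > 0:
                ep = ki * la[g] + nki * lb[g]
                em = ki * lb[g] + nki * la[g]
            else:
                ep = ki * lb[g] + nki * la[g]
                em = ki * la[g] + nki * lb[g]
            jp = 2 * g
            jm = 2 * g + 1
            best = enter
            code = 0
            cand = v[jp] + ln_stay_ev
            if cand > best:
                best = cand
                code = 1
            cand = v[jm] + ln_flip
            if cand > best:
                best = cand
                code = 2
            nv[jp] = best + ep
            bp[i, jp] = code

            best = enter
            code = 0
            cand = v[jm] + ln_stay_ev
            if cand > best:
                best = cand
                code = 1
            cand = v[jp] + ln_flip
            if cand > best:
                best = cand
                code = 2
            nv[jm] = best + em
            bp[i, jm] = code

        v_null = nv_null
        for j in range(2 * G):
            v[j] = nv[j]

    # backtrack
    path = np.empty(m, np.int32)
    best_state = 0
    best_v = v_null
    best_logp = v_null
    for j in range(2 * G):
        if v[j] > best_v:
            best_v = v[j]
            best_state = j + 1
    best_logp = best_v
    state = best_state
    for i in range(m - 1, -1, -1):
        path[i] = state
        if i == 0:
            break
        if state == 0:
            state = bp_null[i]
        else:
            j = state - 1
            code = bp[i, j]
            if code == 0:
                state = 0
            elif code == 2:
                state = (j ^ 1) + 1  # twin polarity, same grid point
            # code == 1: stay
    return path, best_logp


@njit(cache=True)
def _polarity_viterbi(k, n, s, b, ln_flip, ln_stay):
    """2-state polarity Viterbi at fixed deviation b.

    Returns (joint log-prob incl. switch penalties, polarity path +/-1).
    """
    m = k.shape[0]
    la = math.log(0.5 + b)
    lb = math.log(0.5 - b)
    ln_init = math.log(0.5)
    bp = np.empty((m, 2), np.int8)
    vp = 0.0
    vm = 0.0
    for i in range(m):
        ki = k[i]
        nki = n[i] - k[i]
        if s[i] > 0:
            ep = ki * la + nki * lb
            em = ki * lb + nki * la
        else:
            ep = ki * lb + nki * la
            em = ki * la + nki * lb
        if i == 0:
            nvp = ln_init + ep
            nvm = ln_init + em
            bp[0, 0] = 0
            bp[0, 1] = 1
        else:
            a = vp + ln_stay
            c = vm + ln_flip
            if a >= c:
                nvp = a + ep
                bp[i, 0] = 0
            else:
                nvp = c + ep
                bp[i, 0] = 1
            a = vm + ln_stay
            c = vp + ln_flip
            if a >= c:
                nvm = a + em
                bp[i, 1] = 1
            else:
                nvm = c + em
                bp[i, 1] = 0
        vp = nvp
        vm = nvm

    pol = np.empty(m, np.int8)
    state = 0 if vp >= vm else 1
    best = vp if vp >= vm else vm
    for i in range(m - 1, -1, -1):
        pol[i] = 1 if state == 0 else -1
        state = bp[i, state]
    return best, pol


def lod_score(
    signal: PhasedSignal, bdev: float, polarity: np.ndarray
) -> float:
    """Base-10 log likelihood ratio of the polarity-resolved imbalance
    model versus the balanced Binomial(n, 1/2) null; additive over markers."""
    if bdev < 0:
        raise ValueError("bdev must be non-negative")
    if bdev == 0:
        return 0.0
    p = 0.5 + signal.s.astype(np.float64) * np.asarray(polarity, dtype=np.float64) * bdev
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("bdev too large for the given polarity")
    k = signal.k.astype(np.float64)
    n = signal.n.astype(np.float64)
    return float(
        np.sum(k * np.log10(p / 0.5) + (n - k) * np.log10((1.0 - p) / 0.5))
    )


def _refit_segment(
    signal: PhasedSignal, params: DetectorParams
) -> tuple[float, float, np.ndarray]:
    """Grid search for the segment deviation with a polarity re-fit.

    Returns (bdev_hat, lod, polarity path).  The grid picks the polarity
    path and brackets the deviation; a bounded 1-D maximum-likelihood
    step then refines the deviation continuously within the bracket (the
    grid alone would quantise cell fractions too coarsely).  The LOD is
    the emission-only log10 ratio along the fitted polarity path.
    """
    from scipy.optimize import minimize_scalar

    ln_flip = math.log(params.p_switch)
    ln_stay = math.log1p(-params.p_switch)
    best = -np.inf
    best_b = params.bdev_grid[0]
    best_pol = np.ones(len(signal), dtype=np.int8)
    for b in params.bdev_grid:
        score, pol = _polarity_viterbi(signal.k, signal.n, signal.s, b, ln_flip, ln_stay)
        if score > best:
            best = score
            best_b = float(b)
            best_pol = pol

    # continuous refinement at fixed polarity, bracketed by the grid mesh
    t = signal.s.astype(np.float64) * best_pol.astype(np.float64)
    k = signal.k.astype(np.float64)
    nk = signal.n.astype(np.float64) - k

    def nll(b: float) -> float:
        p = 0.5 + t * b
        return -float(np.sum(k * np.log(p) + nk * np.log(1.0 - p)))

    lo = best_b / 1.6
    hi = min(0.499, best_b * 1.6)
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    if res.success and res.fun <= nll(best_b):
        best_b = float(res.x)
        # one polarity re-fit at the refined deviation
        _, best_pol = _polarity_viterbi(
            signal.k, signal.n, signal.s, best_b, ln_flip, ln_stay
        )
    lod = lod_score(signal, best_b, best_pol)
    return best_b, lod, best_pol


def hmm_segment(signal: PhasedSignal, params: DetectorParams) -> list[RawSegment]:
    """Viterbi segmentation of one chromosome's phased signal."""
    if len(signal) == 0:
        return []
    G = len(params.bdev_grid)
    la = np.log(0.5 + params.bdev_grid)
    lb = np.log(0.5 - params.bdev_grid)
    ln_stay_null = math.log1p(-params.p_event)
    ln_enter = math.log(params.p_event / (2 * G))
    ln_exit = math.log(params.p_event)
    ln_flip = math.log(params.p_switch)
    ln_stay_ev = math.log(1.0 - params.p_event - params.p_switch)

    path, _ = _viterbi(
        signal.k, signal.n, signal.s, la, lb,
        ln_stay_null, ln_enter, ln_exit, ln_flip, ln_stay_ev,
    )
    return _segments_from_path(signal, path, params)


def _segments_from_path(
    signal: PhasedSignal, path: np.ndarray, params: DetectorParams
) -> list[RawSegment]:
    nonnull = path != 0
    if not nonnull.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], nonnull.view(np.int8), [0]))))
    segments = []
    for i0, i1 in edges.reshape(-1, 2):  # half-open [i0, i1)
        sl = signal.slice(i0, i1)
        bdev_hat, lod, pol = _refit_segment(sl, params)
        segments.append(
            RawSegment(
                chrom=signal.chrom,
                start_pos=int(signal.pos[i0]),
                end_pos=int(signal.pos[i1 - 1]),
                first_marker=int(i0),
                last_marker=int(i1 - 1),
                n_hets=int(i1 - i0),
                bdev_hat=bdev_hat,
                lod=lod,
                polarity_frac=float(np.mean(pol == 1)),
            )
        )
    return segments


def viterbi_path(signal: PhasedSignal, params: DetectorParams) -> tuple[np.ndarray, float]:
    """The raw Viterbi state path and its joint log-probability.

    State 0 is the balanced null; state ``1 + 2g`` is deviation
    ``bdev_grid[g]`` with haplotype 1 elevated, ``2 + 2g`` the opposite
    polarity.  Exposed for oracle cross-checks.
    """
    G = len(params.bdev_grid)
    la = np.log(0.5 + params.bdev_grid)
    lb = np.log(0.5 - params.bdev_grid)
    path, logp = _viterbi(
        signal.k, signal.n, signal.s, la, lb,
        math.log1p(-params.p_event),
        math.log(params.p_event / (2 * G)),
        math.log(params.p_event),
        math.log(params.p_switch),
        math.log(1.0 - params.p_event - params.p_switch),
    )
    # add the emission constants (binomial coefficients) dropped in the kernel
    from scipy.special import gammaln

    k, n = signal.k, signal.n
    logp += float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
    return path, logp


def merge_adjacent(
    signal: PhasedSignal,
    segments: list[RawSegment],
    params: DetectorParams,
    max_gap_markers: int = 0,
) -> list[RawSegment]:
    """Merge neighbouring segments separated by at most ``max_gap_markers``
    balanced markers when their deviations are compatible (ratio < 2);
    the merged segment is re-fit and re-scored on the concatenated slice."""
    if not segments:
        return []
    segments = sorted(segments, key=lambda sg: sg.first_marker)
    for a, b in zip(segments, segments[1:]):
        if b.first_marker <= a.last_marker:
            raise ValueError("segments overlap")
    merged = [segments[0]]
    for seg in segments[1:]:
        prev = merged[-1]
        gap = seg.first_marker - prev.last_marker - 1
        lo, hi = sorted((prev.bdev_hat, seg.bdev_hat))
        compatible = lo > 0 and hi / lo < 2.0
        if gap <= max_gap_markers and compatible:
            sl = signal.slice(prev.first_marker, seg.last_marker + 1)
            bdev_hat, lod, pol = _refit_segment(sl, params)
            merged[-1] = RawSegment(
                chrom=signal.chrom,
                start_pos=prev.start_pos,
                end_pos=seg.end_pos,
                first_marker=prev.first_marker,
                last_marker=seg.last_marker,
                n_hets=seg.last_marker - prev.first_marker + 1,
                bdev_hat=bdev_hat,
                lod=lod,
                polarity_frac=float(np.mean(pol == 1)),
            )
        else:
            merged.append(seg)
    return merged


def detect_sample(
    sample: SampleGenome,
    params: DetectorParams | None = None,
    max_gap_markers: int = 0,
) -> list[RawSegment]:
    """Run detection across a sample's chromosomes.

    chrX is analysed in females only; male and unknown-sex chrX tracks
    are skipped.
    """
    params = params or DetectorParams()
    segments: list[RawSegment] = []
    for chrom, signal in build_signal(sample).items():
        if chrom == "chrX" and sample.meta.sex != "female":
            continue
        segs = hmm_segment(signal, params)
        if max_gap_markers > 0:
            segs = merge_adjacent(signal, segs, params, max_gap_markers)
        segments.extend(segs)
    return segments
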