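"""Synthetic phased-genotype cohorts with ground-truth clonal events.

The generator emulates the statistical structure the detector relies on:
per-sample tracks of phased heterozygous sites at ~38x whole-genome
depth, clonal gains / losses / copy-neutral LOH at specified cell
fractions, Markov phase-switch errors, group-specific heterozygosity
distributions, and binary CHIP carrier labels with a configurable
CHIP-mCA odds ratio for co-occurrence testing.

The signal model is a two-population cell mixture: a fraction ``cf`` of
cells carry the event and the rest are diploid.  Allele-copy counting in
that mixture fixes both the expected B-allele-frequency deviation
(:func:`expected_bdev`) and the expected relative coverage on the
diploid=2 scale (:func:`expected_relcov`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .samples import (
    EVENT_TYPES,
    GRCH38_LENGTHS,
    SampleGenome,
    SampleMeta,
    TruthEvent,
)

__all__ = [
    "GroupConfig",
    "CohortConfig",
    "expected_bdev",
    "expected_relcov",
    "simulate_sample",
    "simulate_cohort",
]


def expected_bdev(etype: str, cf: float) -> float:
    """Expected |BAF - 1/2| for an event of type ``etype`` at cell fraction ``cf``.

    Counting allele copies in a mixture of diploid cells and clone cells:

    * CN-LOH: clone cells carry 2 copies of the duplicated-haplotype allele
      and 0 of the other, total copy number 2 -> deviation ``cf / 2``.
    * loss: clone cells carry 1 copy (retained haplotype only), total
      copy number ``2 - cf`` -> deviation ``cf / (2 (2 - cf))``.
    * gain: duplicated allele at ``1 + cf`` copies out of ``2 + cf``
      -> deviation ``cf / (2 (2 + cf))``.
    """
    _check_event(etype, cf)
    if etype == "cnloh":
        return cf / 2.0
    if etype == "loss":
        return cf / (2.0 * (2.0 - cf))
    return cf / (2.0 * (2.0 + cf))


def expected_relcov(etype: str, cf: float) -> float:
    """Expected relative coverage (diploid = 2) for an event at cell fraction ``cf``."""
    _check_event(etype, cf)
    if etype == "cnloh":
        return 2.0
    if etype == "loss":
        return 2.0 - cf
    return 2.0 + cf


def _check_event(etype: str, cf: float) -> None:
    if etype not in EVENT_TYPES:
        raise ValueError(f"unknown event type {etype!r}")
    if not 0.0 <= cf <= 1.0:
        raise ValueError("cell fraction must be in [0, 1]")
    if etype == "gain" and cf >= 1.0:
        raise ValueError("gain requires cf < 1")


@dataclass(frozen=True)
class GroupConfig:
    """Per-ancestry-group simulation settings.

    ``het_mean``/``het_sd`` parameterise a (truncated) normal for the
    per-sample count of heterozygous markers; with ``het_sd == 0`` every
    sample gets exactly ``het_mean`` markers.  Alternatively a
    ``het_quantiles`` table (probability -> count) overrides the normal.
    """

    n_samples: int
    het_mean: float = 925_935.0
    het_sd: float = 0.0
    female_fraction: float = 0.5
    het_quantiles: tuple[tuple[float, float], ...] | None = None


@dataclass(frozen=True)
class CohortConfig:
    """Everything the cohort generator needs, in one place.

    Defaults reflect blood-derived ~38x whole-genome sequencing: Poisson
    read depth around ``mean_depth``, statistical-phasing switch errors at
    ``phase_switch_rate`` per heterozygous marker (default 1e-3, the
    ~0.1% switch-error rate typical of large-reference-panel statistical
    phasing), and event cell fractions drawn log-uniformly on
    [0.005, 0.5] so that sub-percent clones are exercised.
    """

    groups: Mapping[str, GroupConfig]
    genome: Mapping[str, int] = field(default_factory=lambda: dict(GRCH38_LENGTHS))
    mean_depth: float = 38.0
    depth_dispersion: float = 0.0  # extra NB dispersion; 0 = pure Poisson
    phase_switch_rate: float = 1e-3
    event_prevalence: float = 0.05
    event_type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"gain": 0.25, "loss": 0.25, "cnloh": 0.5}
    )
    cf_min: float = 0.005
    cf_max: float = 0.5
    event_frac_min: float = 0.1  # event span as fraction of chromosome length
    event_frac_max: float = 1.0
    cnv_mask_per_chrom: int = 0
    cnv_mask_len_bp: int = 50_000
    chip_prevalence: float = 0.04
    chip_mca_odds_ratio: float = 1.0
    chip_genes: tuple[str, ...] = ("DNMT3A", "TET2", "ASXL1", "JAK2", "TP53")
    age_range: tuple[float, float] = (40.0, 90.0)

    def __post_init__(self) -> None:
        for p in (self.phase_switch_rate, self.event_prevalence, self.chip_prevalence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if not 0 < self.cf_min <= self.cf_max <= 1:
            raise ValueError("cf range must satisfy 0 < cf_min <= cf_max <= 1")


def simulate_sample(
    meta: SampleMeta,
    config: CohortConfig,
    truth_events: Sequence[TruthEvent] = (),
    seed: int | np.random.SeedSequence | None = None,
    n_markers: int | None = None,
) -> SampleGenome:
    """Simulate one sample's phased heterozygous-marker track.

    Markers are placed uniformly per chromosome (total count ``n_markers``
    split proportionally to chromosome length).  Inside an event the
    alt-allele depth is Binomial(n, 1/2 + s*d) where ``d`` is the signed
    expected BAF deviation of the event and ``s`` encodes which haplotype
    carries the alt allele; total depth is Poisson with mean scaled by
    ``expected_relcov / 2``.  Phase-switch errors flip the *reported*
    allele order downstream of Markov switch points at the configured
    per-marker rate; the underlying read counts follow the true phase.

    Males and unknown-sex samples carry no chrX heterozygous track.
    """
    if seed is None:
        raise ValueError("a seed is required; the generator must be reproducible")
    rng = np.random.default_rng(seed)
    if n_markers is None:
        n_markers = _draw_het_count(rng, config.groups[meta.group])

    genome = {
        c: length
        for c, length in config.genome.items()
        if c != "chrX" or meta.sex == "female"
    }
    _validate_events(truth_events, genome)

    total_len = sum(genome.values())
    chroms, tables = [], []
    remaining = n_markers
    items = list(genome.items())
    for i, (chrom, length) in enumerate(items):
        if i == len(items) - 1:
            m = remaining
        else:
            m = int(round(n_markers * length / total_len))
            m = min(m, remaining)
        remaining -= m
        if m == 0:
            continue
        pos = np.sort(rng.choice(length, size=m, replace=False)) + 1
        chrom_events = [e for e in truth_events if e.chrom == chrom]
        tab = _simulate_chrom(rng, chrom, pos, chrom_events, config)
        chroms.append(chrom)
        tables.append(tab)

    if tables:
        markers = pd.concat(tables, ignore_index=True)
    else:
        markers = pd.DataFrame(
            {"chrom": [], "pos": [], "hap1_alt": [], "ad_ref": [], "ad_alt": []}
        ).astype({"pos": np.int64, "hap1_alt": np.int8, "ad_ref": np.int32, "ad_alt": np.int32})
    return SampleGenome(meta, markers)


def _simulate_chrom(
    rng: np.random.Generator,
    chrom: str,
    pos: np.ndarray,
    events: Sequence[TruthEvent],
    config: CohortConfig,
) -> pd.DataFrame:
    m = len(pos)
    hap1_alt_true = rng.integers(0, 2, size=m).astype(np.int8)
    s_true = np.where(hap1_alt_true == 1, 1.0, -1.0)

    # signed deviation of the haplotype-1 allele frequency per marker
    hap1_delta = np.zeros(m)
    relcov = np.full(m, 2.0)
    for ev in events:
        inside = (pos >= ev.start) & (pos <= ev.end)
        d = expected_bdev(ev.etype, ev.cf)
        up_hap = 3 - ev.affected_hap if ev.etype == "loss" else ev.affected_hap
        hap1_delta[inside] = d if up_hap == 1 else -d
        relcov[inside] = expected_relcov(ev.etype, ev.cf)

    lam = config.mean_depth * relcov / 2.0
    if config.depth_dispersion > 0:
        # Gamma-Poisson mixture: adds variance lam^2 * dispersion
        shape = 1.0 / config.depth_dispersion
        lam = rng.gamma(shape, lam / shape)
    n = rng.poisson(lam).astype(np.int64)
    p_alt = np.clip(0.5 + s_true * hap1_delta, 0.0, 1.0)
    k = rng.binomial(n, p_alt)

    # Markov phase-switch errors: reported hap order flips downstream of
    # each switch point, mimicking statistical-phasing switch structure.
    if config.phase_switch_rate > 0 and m > 0:
        switches = rng.random(m) < config.phase_switch_rate
        flipped = np.cumsum(switches) % 2 == 1
        hap1_alt_obs = np.where(flipped, 1 - hap1_alt_true, hap1_alt_true).astype(np.int8)
    else:
        hap1_alt_obs = hap1_alt_true

    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "hap1_alt": hap1_alt_obs,
            "ad_ref": (n - k).astype(np.int32),
            "ad_alt": k.astype(np.int32),
        }
    )


def _draw_het_count(rng: np.random.Generator, gcfg: GroupConfig) -> int:
    if gcfg.het_quantiles is not None:
        probs, counts = zip(*sorted(gcfg.het_quantiles))
        u = rng.random()
        return max(1, int(round(float(np.interp(u, probs, counts)))))
    if gcfg.het_sd == 0:
        return int(round(gcfg.het_mean))
    return max(1, int(round(rng.normal(gcfg.het_mean, gcfg.het_sd))))


def _validate_events(events: Sequence[TruthEvent], genome: Mapping[str, int]) -> None:
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        if ev.chrom not in genome:
            raise ValueError(f"event on {ev.chrom} outside the simulated genome")
        if ev.end > genome[ev.chrom]:
            raise ValueError(f"event end {ev.end} beyond {ev.chrom} length")
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping truth events on {chrom}")


def simulate_cohort(
    config: CohortConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[list[SampleGenome], pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-group cohort.

    Returns ``(samples, truth_table, metadata_table)``.  The truth table
    records every injected event (sample_id, chrom, start, end, etype,
    cf, affected_hap); the metadata table carries sample_id, sex, age,
    group, study, chip carrier status and gene labels.

    CHIP carrier labels are drawn with a configurable 2x2 odds ratio
    against mCA carrier status so co-occurrence tests can be exercised
    under the null (OR = 1) or an enriched alternative.
    """
    if seed is None:
        raise ValueError("a seed is required; the generator must be reproducible")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    master = np.random.default_rng(ss.spawn(1)[0])

    plans: list[tuple[SampleMeta, list[TruthEvent]]] = []
    truth_rows = []
    for group, gcfg in config.groups.items():
        if gcfg.n_samples <= 0:
            raise ValueError(f"group {group!r} has no samples")
        for i in range(gcfg.n_samples):
            sid = f"{group}_{i:05d}"
            sex = "female" if master.random() < gcfg.female_fraction else "male"
            age = master.uniform(*config.age_range)
            events = _draw_events(master, config, sex)
            meta = SampleMeta(sample_id=sid, sex=sex, age=age, group=group, study=group)
            plans.append((meta, events))
            for ev in events:
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "chrom": ev.chrom,
                        "start": ev.start,
                        "end": ev.end,
                        "etype": ev.etype,
                        "cf": ev.cf,
                        "affected_hap": ev.affected_hap,
                    }
                )

    # CHIP labels with the configured CHIP-mCA odds ratio
    has_mca = np.array([len(ev) > 0 for _, ev in plans])
    chip = _assign_chip(master, has_mca, config)
    metas = []
    for (meta, _), carrier in zip(plans, chip):
        genes = (
            frozenset({config.chip_genes[master.integers(len(config.chip_genes))]})
            if carrier
            else frozenset()
        )
        metas.append(SampleMeta(meta.sample_id, meta.sex, meta.age, meta.group, meta.study, genes))
    plans = [(m, ev) for m, (_, ev) in zip(metas, plans)]

    child_seeds = ss.spawn(len(plans))
    samples = [
        simulate_sample(meta, config, events, seed=child)
        for (meta, events), child in zip(plans, child_seeds)
    ]

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "start", "end", "etype", "cf", "affected_hap"],
    )
    metadata = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "sex": [m.sex for m in metas],
            "age": [m.age for m in metas],
            "group": [m.group for m in metas],
            "study": [m.study for m in metas],
            "chip_genes": [",".join(sorted(m.chip_genes)) for m in metas],
        }
    )
    return samples, truth, metadata


def _draw_events(
    rng: np.random.Generator, config: CohortConfig, sex: str
) -> list[TruthEvent]:
    if rng.random() >= config.event_prevalence:
        return []
    types, weights = zip(*config.event_type_weights.items())
    w = np.asarray(weights, dtype=float)
    etype = rng.choice(types, p=w / w.sum())
    autosomes = [c for c in config.genome if c != "chrX" or sex == "female"]
    chrom = autosomes[rng.integers(len(autosomes))]
    length = config.genome[chrom]
    cf = float(
        np.exp(rng.uniform(np.log(config.cf_min), np.log(config.cf_max)))
    )
    span = int(length * rng.uniform(config.event_frac_min, config.event_frac_max))
    span = max(span, 1)
    start = int(rng.integers(1, length - span + 2))
    return [
        TruthEvent(
            chrom=chrom,
            start=start,
            end=start + span - 1,
            etype=str(etype),
            cf=cf,
            affected_hap=int(rng.integers(1, 3)),
        )
    ]


def _assign_chip(
    rng: np.random.Generator, has_mca: np.ndarray, config: CohortConfig
) -> np.ndarray:
    """Draw CHIP carrier flags with a target CHIP-mCA odds ratio.

    Solves for P(CHIP | mCA) and P(CHIP | no mCA) such that the marginal
    CHIP prevalence matches ``chip_prevalence`` and the 2x2 odds ratio
    equals ``chip_mca_odds_ratio``.
    """
    p_c = config.chip_prevalence
    psi = config.chip_mca_odds_ratio
    p_m = has_mca.mean() if len(has_mca) else 0.0
    if p_c == 0.0:
        return np.zeros(len(has_mca), dtype=bool)
    if psi == 1.0 or p_m in (0.0, 1.0):
        p1 = p0 = p_c
    else:
        def marginal(p0: float) -> float:
            p1 = psi * p0 / (1.0 - p0 + psi * p0)
            return p_m * p1 + (1.0 - p_m) * p0 - p_c

        p0 = brentq(marginal, 1e-12, 1.0 - 1e-12)
        p1 = psi * p0 / (1.0 - p0 + psi * p0)
    probs = np.where(has_mca, p1, p0)
    return rng.random(len(has_mca)) < probs


def random_cnv_mask(
    config: CohortConfig, seed: int | np.random.SeedSequence
) -> dict[str, np.ndarray]:
    """Draw a germline-CNV mask: per chromosome, ``cnv_mask_per_chrom``
    uniformly placed intervals of ``cnv_mask_len_bp`` (0-based half-open)."""
    rng = np.random.default_rng(seed)
    mask: dict[str, np.ndarray] = {}
    for chrom, length in config.genome.items():
        k = config.cnv_mask_per_chrom
        if k == 0:
            mask[chrom] = np.empty((0, 2), dtype=np.int64)
            continue
        starts = np.sort(rng.integers(0, max(1, length - config.cnv_mask_len_bp), size=k))
        mask[chrom] = np.column_stack([starts, starts + config.cnv_mask_len_bp])
    return mask
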