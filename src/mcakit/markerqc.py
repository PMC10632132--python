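"""Marker selection ahead of detection.

Three rules produce the detector's input track:

1. drop heterozygous markers with population minor-allele frequency
   below 1% or with fewer than five reads supporting either allele;
2. drop markers inside germline copy-number-variant mask intervals;
3. thin to at most one marker per 1,000 bp window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .samples import SampleGenome

__all__ = ["SiteFilterConfig", "filter_markers", "thin_markers", "qc_pipeline"]


@dataclass(frozen=True)
class SiteFilterConfig:
    min_maf: float = 0.01
    min_allele_depth: int = 5
    thin_window_bp: int = 1000
    #: per-chromosome (start, end) intervals, 0-based half-open (BED convention)
    cnv_mask: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.thin_window_bp <= 0:
            raise ValueError("thin_window_bp must be positive")


def filter_markers(
    sample: SampleGenome,
    af_lookup: Mapping[tuple[str, int], float] | None,
    config: SiteFilterConfig,
) -> SampleGenome:
    """Apply the MAF, allele-depth and CNV-mask rules; order preserved.

    ``af_lookup`` maps (chrom, pos) to the population alternate-allele
    frequency; the minor-allele frequency is ``min(af, 1 - af)``.  Markers
    with no AF entry are removed (conservative).  Pass ``None`` to skip
    the MAF rule entirely (all markers treated as common).
    """
    tab = sample.markers
    keep = (tab["ad_ref"].to_numpy() >= config.min_allele_depth) & (
        tab["ad_alt"].to_numpy() >= config.min_allele_depth
    )

    if af_lookup is not None:
        chroms = tab["chrom"].to_numpy()
        poss = tab["pos"].to_numpy()
        maf = np.full(len(tab), -1.0)
        for i, (c, p) in enumerate(zip(chroms, poss)):
            af = af_lookup.get((c, int(p)))
            if af is not None:
                maf[i] = min(af, 1.0 - af)
        keep &= maf >= config.min_maf

    if config.cnv_mask:
        keep &= ~_in_mask(tab, config.cnv_mask)

    return sample.replace_markers(tab[keep])


def _in_mask(tab: pd.DataFrame, mask: Mapping[str, np.ndarray]) -> np.ndarray:
    """1-based marker positions against 0-based half-open intervals:
    position p is masked iff start < p <= end."""
    hit = np.zeros(len(tab), dtype=bool)
    for chrom, sub in tab.groupby("chrom", sort=False):
        intervals = mask.get(chrom)
        if intervals is None or len(intervals) == 0:
            continue
        pos = sub["pos"].to_numpy()
        for start, end in np.asarray(intervals).reshape(-1, 2):
            hit[sub.index[(pos > start) & (pos <= end)]] = True
    return hit


def thin_markers(sample: SampleGenome, window_bp: int | None = None,
                 config: SiteFilterConfig | None = None) -> SampleGenome:
    """Greedy left-to-right thinning: keep a marker iff it is at least
    ``window_bp`` from the last kept marker on the same chromosome.

    Consequently any half-open window of width ``window_bp`` holds at most
    one kept marker; ties at exactly ``window_bp`` are kept.
    """
    if window_bp is None:
        window_bp = (config or SiteFilterConfig()).thin_window_bp
    tab = sample.markers
    keep = np.zeros(len(tab), dtype=bool)
    for _, sub in tab.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        last = -np.inf
        for idx, p in zip(sub.index, pos):
            if p - last >= window_bp:
                keep[idx] = True
                last = p
    return sample.replace_markers(tab[keep])


def qc_pipeline(
    sample: SampleGenome,
    af_lookup: Mapping[tuple[str, int], float] | None,
    config: SiteFilterConfig,
) -> tuple[SampleGenome, dict[str, int]]:
    """Run both QC stages; returns the filtered sample and a removal log."""
    n0 = sample.n_markers
    filtered = filter_markers(sample, af_lookup, config)
    n1 = filtered.n_markers
    thinned = thin_markers(filtered, config.thin_window_bp)
    n2 = thinned.n_markers
    log = {
        "input": n0,
        "removed_site_filters": n0 - n1,
        "removed_thinning": n1 - n2,
        "retained": n2,
    }
    return thinned, log
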