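"""Core in-memory containers for phased heterozygous-marker tracks.

The unit of analysis is a single sample's genome-wide track of phased
heterozygous sites.  Each site carries the phased allele order (which
allele sits on haplotype 1) and per-allele read depths, which together
give both the B-allele frequency (BAF = alt depth / total depth) and its
phase polarity — the raw signal for haplotype-based detection of mosaic
chromosomal alterations (mCAs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

#: GRCh38 chromosome lengths (chr1-22, chrX), used as default simulation bounds.
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
    "chrX": 156_040_895,
}

#: Column order of the marker table carried by :class:`SampleGenome`.
MARKER_COLUMNS = ["chrom", "pos", "hap1_alt", "ad_ref", "ad_alt"]

SEXES = ("female", "male", "unknown")
EVENT_TYPES = ("gain", "loss", "cnloh")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata used by filters and downstream statistics."""

    sample_id: str
    sex: str = "unknown"
    age: float = 0.0
    group: str = "NA"
    study: str = "NA"
    chip_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth clonal event injected by the simulator.

    ``affected_hap`` is the haplotype duplicated (gain, CN-LOH) or lost
    (loss); ``cf`` is the fraction of cells carrying the event.
    """

    chrom: str
    start: int
    end: int
    etype: str
    cf: float
    affected_hap: int = 1

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"etype must be one of {EVENT_TYPES}, got {self.etype!r}")
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if not 0.0 < self.cf <= 1.0:
            raise ValueError("cell fraction must be in (0, 1]")
        if self.etype == "gain" and self.cf >= 1.0:
            raise ValueError("a full-fraction gain is a germline trisomy, not mosaic")
        if self.affected_hap not in (1, 2):
            raise ValueError("affected_hap must be 1 or 2")


class SampleGenome:
    """A sample's phased heterozygous-marker track plus metadata.

    Markers live in a single pandas DataFrame with columns
    ``chrom, pos, hap1_alt, ad_ref, ad_alt`` sorted by (chrom, pos);
    ``hap1_alt`` is 1 when the alternate allele is on haplotype 1
    (phased genotype ``1|0``) and 0 for ``0|1``.
    """

    def __init__(self, meta: SampleMeta, markers: pd.DataFrame):
        missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        markers = markers[MARKER_COLUMNS].reset_index(drop=True).astype(
            {"pos": np.int64, "hap1_alt": np.int8, "ad_ref": np.int32, "ad_alt": np.int32}
        )
        if (markers["ad_ref"] < 0).any() or (markers["ad_alt"] < 0).any():
            raise ValueError("allele depths must be non-negative")
        for _, pos in _iter_chrom_positions(markers):
            if np.any(np.diff(pos) <= 0):
                raise ValueError("markers must be strictly sorted by position")
        self.meta = meta
        self.markers = markers

    @property
    def sample_id(self) -> str:
        return self.meta.sample_id

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]

    def iter_chromosomes(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for chrom, tab in self.markers.groupby("chrom", sort=False):
            yield chrom, tab

    def depth(self) -> np.ndarray:
        """Total read depth per marker (``ad_ref + ad_alt``)."""
        return (self.markers["ad_ref"] + self.markers["ad_alt"]).to_numpy()

    def baf(self) -> np.ndarray:
        """B-allele frequency per marker."""
        d = self.depth().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.markers["ad_alt"].to_numpy() / d, np.nan)

    def phased_baf_deviation(self) -> np.ndarray:
        """Signed deviation (BAF - 1/2) polarised by the phased allele order.

        Positive values mean the haplotype-1 allele is over-represented.
        """
        s = np.where(self.markers["hap1_alt"].to_numpy() == 1, 1.0, -1.0)
        return s * (self.baf() - 0.5)

    def replace_markers(self, markers: pd.DataFrame) -> "SampleGenome":
        return SampleGenome(self.meta, markers)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SampleGenome({self.sample_id!r}, {self.n_markers} markers, "
            f"{len(self.chromosomes())} chromosomes)"
        )


def _iter_chrom_positions(markers: pd.DataFrame):
    for chrom, tab in markers.groupby("chrom", sort=False):
        yield chrom, tab["pos"].to_numpy()
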