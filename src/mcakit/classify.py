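"""Typing of raw segments into mCA calls, cell fractions, and call filters.

Event typing rests on relative coverage (diploid = 2): a clone at cell
fraction ``f`` shifts a segment's coverage to ``2 + f`` (gain), ``2 - f``
(loss) or leaves it at 2 (CN-LOH).  Given a type, the BAF deviation ``b``
inverts to the cell fraction:

    CN-LOH:  f = 2 b
    loss:    f = 4 b / (1 + 2 b)
    gain:    f = 4 b / (1 - 2 b)

Final calls must pass five filters: >=2,000 informative markers, LOD >=5,
no chrX calls in samples of unknown sex, relative coverage <=2.9, and not
(BAF deviation >0.16 with relative coverage >2.5) — the last two exclude
putative germline duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .detect import RawSegment
from .samples import SampleGenome, SampleMeta

__all__ = [
    "SegmentCall",
    "CallFilterConfig",
    "relative_coverage",
    "classify_event",
    "cell_fraction",
    "apply_call_filters",
    "cf_stratum",
    "classify_lineage",
    "classify_segments",
    "calls_to_frame",
]


@dataclass(frozen=True)
class SegmentCall:
    """A typed mCA call with cell-fraction estimate."""

    sample_id: str
    sex: str
    chrom: str
    start_pos: int
    end_pos: int
    n_hets: int
    bdev: float
    lod: float
    relcov: float
    relcov_se: float
    etype: str  # gain | loss | cnloh | undetermined
    cf: float | None
    cf_stratum: str | None  # high | low (cf >= 0.03 is high)
    lineage: str = "unlabeled"

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass(frozen=True)
class CallFilterConfig:
    """The five post-hoc call filters, with thresholds as printed rules:
    calls are *excluded* when n_hets < min_hets, lod < min_lod, chrX with
    unknown sex, relcov > max_relcov, or (bdev > bdev_dup and relcov >
    relcov_dup)."""

    min_hets: int = 2000
    min_lod: float = 5.0
    max_relcov: float = 2.9
    bdev_dup: float = 0.16
    relcov_dup: float = 2.5
    require_known_sex_for_chrX: bool = True

    def __post_init__(self) -> None:
        if min(self.min_hets, self.min_lod, self.max_relcov, self.bdev_dup, self.relcov_dup) <= 0:
            raise ValueError("filter thresholds must be positive")


def baseline_depth(
    sample: SampleGenome,
    segments: list[RawSegment] = (),
    trim: float = 0.1,
    min_outside: int = 100,
) -> float:
    """Genome-wide per-marker depth baseline: 10%-trimmed mean of total
    depth over markers outside any called segment (robust to the events
    themselves).  If fewer than ``min_outside`` markers remain outside
    the segments, all markers are used instead — a tiny remainder gives
    a noisier baseline than a whole-genome average that includes the
    (typically small) called territory."""
    depth = sample.depth().astype(float)
    if len(segments):
        outside = np.ones(len(depth), dtype=bool)
        chroms = sample.markers["chrom"].to_numpy()
        pos = sample.markers["pos"].to_numpy()
        for seg in segments:
            outside &= ~((chroms == seg.chrom) & (pos >= seg.start_pos) & (pos <= seg.end_pos))
        if outside.sum() >= min_outside:
            depth = depth[outside]
    if len(depth) == 0 or np.all(depth == 0):
        raise ValueError("cannot form a depth baseline: no usable markers")
    return float(trim_mean(depth, trim))


def relative_coverage(
    sample: SampleGenome,
    segment: RawSegment,
    baseline: float | None = None,
    trim: float = 0.1,
) -> tuple[float, float]:
    """Relative coverage of a segment on the diploid=2 scale, with a
    standard error from the per-marker depth variance.

    The in-segment depth summary uses the same trimmed mean as the
    baseline so the (small) trimming bias of a skewed depth distribution
    cancels in the ratio."""
    if baseline is None:
        baseline = baseline_depth(sample, [segment], trim=trim)
    if baseline <= 0:
        raise ValueError("baseline depth must be positive")
    tab = sample.chrom_table(segment.chrom)
    inside = (tab["pos"] >= segment.start_pos) & (tab["pos"] <= segment.end_pos)
    d = (tab.loc[inside, "ad_ref"] + tab.loc[inside, "ad_alt"]).to_numpy(dtype=float)
    if len(d) == 0:
        raise ValueError("segment contains no markers")
    relcov = 2.0 * trim_mean(d, trim) / baseline
    se = 2.0 * d.std(ddof=1) / (baseline * np.sqrt(len(d))) if len(d) > 1 else np.inf
    return float(relcov), float(se)


def classify_event(
    bdev: float,
    relcov: float,
    relcov_se: float,
    length_bp: float,
    z: float = 3.0,
    min_len_bp: float = 1_000_000,
) -> str:
    """Type a segment from its relative coverage.

    Coverage significantly above 2 (z-score) -> gain, below -> loss;
    coverage consistent with 2 on a segment of at least ``min_len_bp``
    -> CN-LOH.  Short copy-neutral segments stay undetermined: below
    ~1 Mb the coverage signal cannot separate the three classes.
    """
    if bdev < 0:
        raise ValueError("bdev must be non-negative")
    if relcov - 2.0 > z * relcov_se:
        return "gain"
    if 2.0 - relcov > z * relcov_se:
        return "loss"
    if length_bp >= min_len_bp:
        return "cnloh"
    return "undetermined"


def cell_fraction(etype: str, bdev: float) -> float:
    """Invert the cell-mixture BAF-deviation model to a cell fraction."""
    if bdev < 0:
        raise ValueError("bdev must be non-negative")
    if etype == "cnloh":
        return 2.0 * bdev
    if etype == "loss":
        return 4.0 * bdev / (1.0 + 2.0 * bdev)
    if etype == "gain":
        if bdev >= 0.5:
            raise ValueError("gain requires bdev < 0.5")
        return 4.0 * bdev / (1.0 - 2.0 * bdev)
    raise ValueError(f"cell fraction undefined for event type {etype!r}")


def cf_stratum(cf: float) -> str:
    """High cell-fraction stratum at CF >= 0.03, else low."""
    if cf is None or not np.isfinite(cf):
        raise ValueError("cell fraction undefined")
    return "high" if cf >= 0.03 else "low"


def apply_call_filters(
    calls: list[SegmentCall],
    config: CallFilterConfig | None = None,
) -> list[SegmentCall]:
    """Retain calls passing all five exclusion rules (a pure conjunction,
    so application order cannot matter)."""
    config = config or CallFilterConfig()
    kept = []
    for c in calls:
        if c.n_hets < config.min_hets:
            continue
        if c.lod < config.min_lod:
            continue
        if (
            config.require_known_sex_for_chrX
            and c.chrom == "chrX"
            and c.sex == "unknown"
        ):
            continue
        if c.relcov > config.max_relcov:
            continue
        if c.bdev > config.bdev_dup and c.relcov > config.relcov_dup:
            continue
        kept.append(c)
    return kept


def classify_lineage(call: SegmentCall, region_table: pd.DataFrame | None) -> str:
    """Lineage lookup against a user-supplied region table.

    The table maps chromosome-arm regions and event types to a lineage
    (columns: chrom, start, end, etype, lineage); the row with the
    longest overlap wins, 'unlabeled' when nothing matches.
    """
    if region_table is None or len(region_table) == 0:
        return "unlabeled"
    required = {"chrom", "start", "end", "etype", "lineage"}
    if not required.issubset(region_table.columns):
        raise ValueError(f"region table needs columns {sorted(required)}")
    rows = region_table[
        (region_table["chrom"] == call.chrom) & (region_table["etype"] == call.etype)
    ]
    best, best_ov = "unlabeled", 0
    for _, row in rows.iterrows():
        ov = min(call.end_pos, int(row["end"])) - max(call.start_pos, int(row["start"])) + 1
        if ov > best_ov:
            best_ov = ov
            best = str(row["lineage"])
    return best


def classify_segments(
    sample: SampleGenome,
    segments: list[RawSegment],
    region_table: pd.DataFrame | None = None,
    z: float = 3.0,
    min_len_bp: float = 1_000_000,
) -> list[SegmentCall]:
    """Attach relative coverage, type, cell fraction and stratum to raw
    segments (no filtering)."""
    if not segments:
        return []
    base = baseline_depth(sample, segments)
    calls = []
    for seg in segments:
        relcov, se = relative_coverage(sample, seg, baseline=base)
        length = seg.end_pos - seg.start_pos + 1
        etype = classify_event(seg.bdev_hat, relcov, se, length, z=z, min_len_bp=min_len_bp)
        if etype == "undetermined":
            cf = None
            stratum = None
        else:
            cf = cell_fraction(etype, seg.bdev_hat)
            stratum = cf_stratum(cf)
        call = SegmentCall(
            sample_id=sample.sample_id,
            sex=sample.meta.sex,
            chrom=seg.chrom,
            start_pos=seg.start_pos,
            end_pos=seg.end_pos,
            n_hets=seg.n_hets,
            bdev=seg.bdev_hat,
            lod=seg.lod,
            relcov=relcov,
            relcov_se=se,
            etype=etype,
            cf=cf,
            cf_stratum=stratum,
        )
        if region_table is not None:
            call = replace(call, lineage=classify_lineage(call, region_table))
        calls.append(call)
    return calls


def calls_to_frame(calls: list[SegmentCall]) -> pd.DataFrame:
    """Final call table (one row per call) in the export column layout."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "computed_gender": [c.sex for c in calls],
            "chrom": [c.chrom for c in calls],
            "beg_pos": [c.start_pos for c in calls],
            "end_pos": [c.end_pos for c in calls],
            "n_hets": [c.n_hets for c in calls],
            "bdev": [c.bdev for c in calls],
            "rel_cov": [c.relcov for c in calls],
            "lod_baf_phase": [c.lod for c in calls],
            "type": [c.etype for c in calls],
            "cf": [np.nan if c.cf is None else c.cf for c in calls],
            "cf_stratum": [c.cf_stratum or "" for c in calls],
            "lineage": [c.lineage for c in calls],
        }
    )
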