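"""Heterozygosity-equalising downsampling across groups.

Detection power scales with the number of heterozygous sites, so groups
with higher heterozygosity call more events at a given clone size.  To
compare rates fairly, each sample's heterozygous-marker count is mapped
through its own (group, sex) stratum's empirical quantile function onto
the target group's quantile function, and markers are removed uniformly
at random genome-wide until the mapped count is reached.  A sample at
its stratum's 50th percentile therefore ends up exactly at the target
stratum's 50th percentile.  Samples already at or below their mapped
target are left untouched (markers are only ever removed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .samples import SampleGenome

__all__ = [
    "EmpiricalQuantiles",
    "QuantileMap",
    "build_quantile_map",
    "target_count",
    "downsample_sample",
    "equalize_cohort",
    "equalized_rerun",
]


@dataclass(frozen=True)
class EmpiricalQuantiles:
    """Empirical quantile function with mid-rank plotting positions.

    Order statistic i (1-based) of n sits at probability (i - 0.5) / n;
    linear interpolation in between, clamped at the extremes.
    """

    values: np.ndarray  # sorted

    @classmethod
    def from_counts(cls, counts) -> "EmpiricalQuantiles":
        counts = np.sort(np.asarray(counts, dtype=float))
        if len(counts) == 0:
            raise ValueError("empty stratum")
        return cls(counts)

    @property
    def _probs(self) -> np.ndarray:
        n = len(self.values)
        return (np.arange(1, n + 1) - 0.5) / n

    def quantile(self, p) -> np.ndarray | float:
        """Q(p) for p in [0, 1]."""
        p = np.clip(p, 0.0, 1.0)
        return np.interp(p, self._probs, self.values)

    def inverse(self, x) -> np.ndarray | float:
        """Q^{-1}(x): the plotting position of count x, clamped to [0, 1]."""
        return np.interp(x, self.values, self._probs, left=0.0, right=1.0)


@dataclass(frozen=True)
class QuantileMap:
    """Per-(group, sex) quantile functions plus the target group label."""

    strata: dict[tuple[str, str], EmpiricalQuantiles]
    target_group: str

    def map_count(self, group: str, sex: str, count: int) -> int:
        source = self.strata[(group, sex)]
        target = self.strata[(self.target_group, sex)]
        return target_count(count, source, target)


def build_quantile_map(
    metadata: pd.DataFrame, het_counts: pd.Series | dict, target_group: str
) -> QuantileMap:
    """Empirical quantile functions of per-sample heterozygous-marker
    counts, separately per (group, sex)."""
    if isinstance(het_counts, dict):
        het_counts = pd.Series(het_counts)
    counts = metadata.set_index("sample_id").assign(
        het=het_counts.reindex(metadata["sample_id"]).to_numpy()
    )
    if counts["het"].isna().any():
        missing = counts.index[counts["het"].isna()].tolist()
        raise ValueError(f"missing het counts for samples: {missing[:5]}")
    strata = {
        (group, sex): EmpiricalQuantiles.from_counts(sub["het"])
        for (group, sex), sub in counts.groupby(["group", "sex"])
    }
    for sex in {s for (_, s) in strata}:
        if (target_group, sex) not in strata:
            raise ValueError(f"target group {target_group!r} has no {sex} stratum")
    return QuantileMap(strata, target_group)


def target_count(
    sample_count: int, source_q: EmpiricalQuantiles, target_q: EmpiricalQuantiles
) -> int:
    """Quantile-match a marker count from the source to the target
    distribution; never upsample."""
    if sample_count <= 0:
        raise ValueError("sample count must be positive")
    p = float(source_q.inverse(sample_count))
    mapped = int(round(float(target_q.quantile(p))))
    return min(mapped, sample_count)


def downsample_sample(
    sample: SampleGenome, target: int, seed: int | np.random.SeedSequence
) -> SampleGenome:
    """Remove markers uniformly at random genome-wide until exactly
    ``target`` remain; marker order is preserved."""
    if target < 0:
        raise ValueError("target must be non-negative")
    n = sample.n_markers
    if target >= n:
        return sample
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=target, replace=False))
    return sample.replace_markers(sample.markers.iloc[keep])


def equalize_cohort(
    samples: list[SampleGenome],
    metadata: pd.DataFrame,
    qmap: QuantileMap,
    seed: int,
) -> tuple[list[SampleGenome], pd.DataFrame]:
    """Downsample every sample per the quantile map.

    Returns the new cohort and a mapping table
    (sample_id, before, target, after)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(samples))
    out, rows = [], []
    for sample, child in zip(samples, children):
        tgt = qmap.map_count(sample.meta.group, sample.meta.sex, sample.n_markers)
        ds = downsample_sample(sample, tgt, child)
        out.append(ds)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "before": sample.n_markers,
                "target": tgt,
                "after": ds.n_markers,
            }
        )
    return out, pd.DataFrame(rows)


def equalized_rerun(
    samples: list[SampleGenome],
    metadata: pd.DataFrame,
    qmap: QuantileMap,
    seed: int,
    detector_params=None,
    filter_config=None,
):
    """Re-run the full detection + classification pipeline before and
    after heterozygosity equalisation.

    Returns ``(calls_before, calls_after, mapping)`` where the call sets
    are final (filtered) call DataFrames.  Detection is re-run from the
    downsampled marker track; QC is assumed already applied to the input
    and is not repeated on the surviving subset.
    """
    from .pipeline import call_cohort

    before = call_cohort(samples, detector_params, filter_config)
    equalized, mapping = equalize_cohort(samples, metadata, qmap, seed)
    after = call_cohort(equalized, detector_params, filter_config)
    return before, after, mapping


def group_call_counts(calls: pd.DataFrame, metadata: pd.DataFrame) -> pd.Series:
    """Number of final calls per group."""
    groups = metadata.set_index("sample_id")["group"]
    if len(calls) == 0:
        return groups.groupby(groups).count() * 0
    return (
        calls.assign(group=calls["sample_id"].map(groups))
        .groupby("group")["sample_id"]
        .count()
        .reindex(groups.unique(), fill_value=0)
    )
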