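"""End-to-end convenience wrappers: QC -> detect -> classify -> filter."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .classify import (
    CallFilterConfig,
    apply_call_filters,
    calls_to_frame,
    classify_segments,
)
from .detect import DetectorParams, detect_sample
from .markerqc import SiteFilterConfig, qc_pipeline
from .samples import SampleGenome


def call_sample(
    sample: SampleGenome,
    detector_params: DetectorParams | None = None,
    filter_config: CallFilterConfig | None = None,
    region_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Detect, classify and filter mCA calls for one QC'd sample."""
    segments = detect_sample(sample, detector_params)
    calls = classify_segments(sample, segments, region_table)
    calls = apply_call_filters(calls, filter_config)
    return calls_to_frame(calls)


def call_cohort(
    samples: Iterable[SampleGenome],
    detector_params: DetectorParams | None = None,
    filter_config: CallFilterConfig | None = None,
    region_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Final call table for a cohort (concatenated per-sample calls)."""
    frames = [
        call_sample(s, detector_params, filter_config, region_table) for s in samples
    ]
    nonempty = [f for f in frames if len(f)]
    if not nonempty:
        return calls_to_frame([])
    return pd.concat(nonempty, ignore_index=True)


def qc_cohort(
    samples: Iterable[SampleGenome],
    af_lookup: Mapping[tuple[str, int], float] | None,
    config: SiteFilterConfig | None = None,
) -> tuple[list[SampleGenome], pd.DataFrame]:
    """Apply marker QC to every sample; returns samples plus a QC log table."""
    config = config or SiteFilterConfig()
    out, logs = [], []
    for s in samples:
        qs, log = qc_pipeline(s, af_lookup, config)
        out.append(qs)
        logs.append({"sample_id": s.sample_id, **log})
    return out, pd.DataFrame(logs)
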