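import numpy as np
import pandas as pd
import pytest

from mcakit import CohortConfig, GroupConfig, simulate_sample
from mcakit.samples import SampleGenome, SampleMeta, TruthEvent


@pytest.fixture
def small_config():
    """Two-chromosome desk-scale genome at the study's 38x depth."""
    return CohortConfig(
        groups={"G": GroupConfig(n_samples=1, het_mean=10_000)},
        genome={"chr1": 50_000_000, "chr2": 50_000_000},
    )


@pytest.fixture
def cnloh_sample(small_config):
    """One sample with a CN-LOH clone at cf=0.2 on half of chr1."""
    ev = TruthEvent("chr1", 1, 25_000_000, "cnloh", 0.2, affected_hap=1)
    meta = SampleMeta("s_cnloh", "female", 60.0, "G", "G")
    sample = simulate_sample(meta, small_config, [ev], seed=7, n_markers=20_000)
    return sample, ev


def make_sample(markers: pd.DataFrame, sex: str = "female", sample_id: str = "t") -> SampleGenome:
    meta = SampleMeta(sample_id, sex=sex)
    markers = markers.copy()
    for col, default in (("hap1_alt", 1), ("ad_ref", 19), ("ad_alt", 19)):
        if col not in markers.columns:
            markers[col] = default
    if "chrom" not in markers.columns:
        markers["chrom"] = "chr1"
    return SampleGenome(meta, markers)


@pytest.fixture
def marker_frame():
    """Hand-built 6-marker track on two chromosomes."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4 + ["chr2"] * 2,
            "pos": [100, 900, 1500, 5000, 100, 2000],
            "hap1_alt": [1, 0, 1, 0, 1, 1],
            "ad_ref": [19, 19, 4, 19, 19, 19],
            "ad_alt": [19, 30, 30, 19, 19, 19],
        }
    )
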