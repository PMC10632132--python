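"""Reading and writing the pipeline's file formats.

Per-sample VCF (phased GT, AD, DP), truth/call BED (0-based half-open),
metadata TSV, allele-frequency TSV and the final call TSV.  VCF output is
written as spec-conformant text (optionally gzipped); reading goes
through cyvcf2.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .samples import SampleGenome, SampleMeta

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Per-allele read depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
"""


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_sample_vcf(sample: SampleGenome, path: str | Path) -> None:
    """Write one sample's marker track as a single-sample VCF.

    Alleles are placeholders (A/C): only the phased allele order and the
    per-allele depths carry signal.  GT is ``1|0`` when the alternate
    allele is on haplotype 1, else ``0|1``.
    """
    with _open_text(path, "w") as fh:
        fh.write(VCF_HEADER)
        contigs = dict.fromkeys(sample.markers["chrom"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample.sample_id}\n"
        )
        tab = sample.markers
        gt = np.where(tab["hap1_alt"].to_numpy() == 1, "1|0", "0|1")
        dp = (tab["ad_ref"] + tab["ad_alt"]).to_numpy()
        for chrom, pos, g, r, a, d in zip(
            tab["chrom"], tab["pos"], gt, tab["ad_ref"], tab["ad_alt"], dp
        ):
            fh.write(f"{chrom}\t{pos}\t.\tA\tC\t.\tPASS\t.\tGT:AD:DP\t{g}:{r},{a}:{d}\n")


def read_sample_vcf(path: str | Path, meta: SampleMeta | None = None) -> SampleGenome:
    """Read a single-sample VCF with phased GT and AD into a SampleGenome."""
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"expected a single-sample VCF, found {len(vcf.samples)} samples")
    sid = vcf.samples[0]
    rows = {"chrom": [], "pos": [], "hap1_alt": [], "ad_ref": [], "ad_alt": []}
    for v in vcf:
        g = v.genotypes[0]
        if len(g) != 3 or not g[2]:
            raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}")
        if g[0] == g[1]:
            continue  # homozygous: not a usable marker
        ad = v.format("AD")[0]
        rows["chrom"].append(v.CHROM)
        rows["pos"].append(v.POS)
        rows["hap1_alt"].append(1 if g[0] == 1 else 0)
        rows["ad_ref"].append(int(ad[0]))
        rows["ad_alt"].append(int(ad[1]))
    vcf.close()
    markers = pd.DataFrame(rows).astype(
        {"pos": np.int64, "hap1_alt": np.int8, "ad_ref": np.int32, "ad_alt": np.int32}
    )
    if meta is None:
        meta = SampleMeta(sample_id=sid)
    return SampleGenome(meta, markers)


def write_cohort_vcf(cohort: Iterable[SampleGenome], outdir: str | Path, gzip_out: bool = False) -> list[Path]:
    """Write one VCF per sample under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".vcf.gz" if gzip_out else ".vcf"
    paths = []
    for sample in cohort:
        p = outdir / f"{sample.sample_id}{suffix}"
        write_sample_vcf(sample, p)
        paths.append(p)
    return paths


def write_truth_bed(truth: pd.DataFrame, path: str | Path) -> None:
    """Write truth events as BED (0-based half-open) with name/score columns.

    Expects columns chrom, start, end (1-based inclusive), etype, cf and
    optionally sample_id.
    """
    t = truth.sort_values(["chrom", "start"], kind="stable")
    with _open_text(path, "w") as fh:
        for _, row in t.iterrows():
            name = f"{row.get('sample_id', '.')}:{row['etype']}"
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{name}\t{row['cf']:.6g}\n"
            )


def read_bed_mask(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED file into per-chromosome (start, end) interval arrays
    (0-based half-open, as stored)."""
    mask: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path, "r") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            mask.setdefault(chrom, []).append((int(start), int(end)))
    return {
        c: np.array(sorted(iv), dtype=np.int64).reshape(-1, 2)
        for c, iv in mask.items()
    }


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "chip_genes" in meta.columns:
        meta["chip_genes"] = meta["chip_genes"].fillna("")
    return meta


def read_af_tsv(path: str | Path) -> dict[tuple[str, int], float]:
    """Read an allele-frequency TSV (chrom, pos, ref, alt, af) into a lookup."""
    af = pd.read_csv(path, sep="\t")
    return {(str(c), int(p)): float(a) for c, p, a in zip(af["chrom"], af["pos"], af["af"])}


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})


def write_calls_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """Export final calls as BED (0-based half-open)."""
    with _open_text(path, "w") as fh:
        for _, row in calls.sort_values(["chrom", "beg_pos"], kind="stable").iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['beg_pos']) - 1}\t{int(row['end_pos'])}\t"
                f"{row['sample_id']}:{row['type']}\n"
            )


def mask_from_config(mask: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {c: np.asarray(iv, dtype=np.int64).reshape(-1, 2) for c, iv in mask.items()}
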