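"""Downstream statistics on mCA call sets.

Covers CHIP-mCA co-occurrence (2x2 Wald tests with a 0.5 continuity
correction and Bonferroni adjustment), the allelic-shift sign test on
CN-LOH duplicated haplotypes, matched case-control construction, plain
logistic association, and prevalence summaries with Wilson intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest, norm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "ContingencyResult",
    "build_carrier_tables",
    "cooccurrence_test",
    "cooccurrence_matrix",
    "bonferroni",
    "allelic_shift_test",
    "match_controls",
    "logistic_assoc",
    "prevalence_summary",
]


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 association output: cross-ratio OR with Wald (log-scale) SE."""

    or_hat: float
    log_or_se: float
    p_wald: float
    corrected: bool  # True when 0.5 was added to all four cells
    n11: float
    n10: float
    n01: float
    n00: float


def cooccurrence_test(n11: int, n10: int, n01: int, n00: int) -> ContingencyResult:
    """Wald test for a 2x2 carrier table.

    If any cell is zero, 0.5 is added to *all four* cells before the
    odds ratio and its standard error are formed.  The two-sided p-value
    is the normal tail probability of log(OR)/SE.
    """
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if np.all(cells == 0):
        raise ValueError("all-zero contingency table")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_hat = (a * d) / (b * c)
    se = float(np.sqrt((1.0 / cells).sum()))
    z = np.log(or_hat) / se
    p = float(2.0 * norm.sf(abs(z)))
    return ContingencyResult(float(or_hat), se, p, corrected, a, b, c, d)


def bonferroni(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni adjustment over the family of evaluated tests."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    adj = np.minimum(1.0, m * p)
    return pd.DataFrame({"p": p, "p_adj": adj, "significant": adj < alpha, "m": m})


def build_carrier_tables(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    cytobands: pd.DataFrame,
    min_carriers: int = 10,
) -> pd.DataFrame:
    """Binary samples-x-categories carrier matrix.

    mCA categories are keyed by (chromosome, arm, event type): a call is
    a carrier of every arm category it overlaps, so one sample can sit
    in several categories.  CHIP categories come from the metadata's
    ``chip_genes`` labels.  Categories with fewer than ``min_carriers``
    carriers are dropped.

    ``cytobands`` needs columns chrom, arm, start, end (1-based
    inclusive arm spans).
    """
    required = {"chrom", "arm", "start", "end"}
    if cytobands is None or not required.issubset(cytobands.columns):
        raise ValueError(f"cytoband table needs columns {sorted(required)}")
    samples = metadata["sample_id"].tolist()
    table = pd.DataFrame(index=samples, dtype=bool)

    if len(calls):
        for _, call in calls.iterrows():
            arms = cytobands[cytobands["chrom"] == call["chrom"]]
            for _, armrow in arms.iterrows():
                if call["beg_pos"] <= armrow["end"] and call["end_pos"] >= armrow["start"]:
                    cat = f"mca:{armrow['chrom']}{armrow['arm']}:{call['type']}"
                    if cat not in table.columns:
                        table[cat] = False
                    table.loc[call["sample_id"], cat] = True

    for sid, genes in zip(metadata["sample_id"], metadata["chip_genes"]):
        if isinstance(genes, frozenset) or isinstance(genes, set):
            labels = genes
        else:
            labels = {g for g in str(genes).split(",") if g and g != "nan"}
        for gene in labels:
            cat = f"chip:{gene}"
            if cat not in table.columns:
                table[cat] = False
            table.loc[sid, cat] = True

    keep = [c for c in table.columns if table[c].sum() >= min_carriers]
    return table[keep].fillna(False).astype(bool)


def cooccurrence_matrix(
    carriers: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """All CHIP-category x mCA-category 2x2 Wald tests with Bonferroni
    flags over the evaluated pairs."""
    chip_cats = [c for c in carriers.columns if c.startswith("chip:")]
    mca_cats = [c for c in carriers.columns if c.startswith("mca:")]
    rows = []
    for cc in chip_cats:
        for mc in mca_cats:
            x = carriers[cc].to_numpy()
            y = carriers[mc].to_numpy()
            res = cooccurrence_test(
                int(np.sum(x & y)),
                int(np.sum(x & ~y)),
                int(np.sum(~x & y)),
                int(np.sum(~x & ~y)),
            )
            rows.append(
                {
                    "chip_category": cc,
                    "mca_category": mc,
                    "or": res.or_hat,
                    "log_or_se": res.log_or_se,
                    "p": res.p_wald,
                    "corrected": res.corrected,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        adj = bonferroni(out["p"], alpha=alpha)
        out["p_adj"] = adj["p_adj"]
        out["significant"] = adj["significant"]
        out["m_tests"] = adj["m"]
    return out


def allelic_shift_test(on_duplicated: np.ndarray | list) -> tuple[int, int, float]:
    """Exact two-sided sign test for allelic shift.

    ``on_duplicated`` is, per informative carrier (heterozygous for the
    variant with an overlapping CN-LOH call of known affected haplotype),
    an indicator that the tested allele lies on the duplicated haplotype.
    Returns (k, n, two-sided exact binomial p against 1/2), using the
    minimum-likelihood convention for two-sidedness.
    """
    x = np.asarray(on_duplicated, dtype=bool)
    n = len(x)
    if n < 1:
        raise ValueError("need at least one informative carrier")
    k = int(x.sum())
    p = binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return k, n, float(p)


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    keys: tuple[str, ...] = ("study", "sequencing_phase", "sex"),
    age_col: str = "age",
    age_tol: float = 2.0,
    ratio: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Matched case-control construction at a 1:``ratio`` target.

    Controls must match each case exactly on ``keys`` and on age within
    ``age_tol`` years; each control is used at most once.  Cases are
    processed in ascending sample_id order and draw their controls
    uniformly at random from the eligible remainder (deterministic given
    the seed).  Cases with fewer than ``ratio`` eligible controls keep
    all available, with a warning.
    """
    overlap = set(cases["sample_id"]) & set(pool["sample_id"])
    if overlap:
        raise ValueError(f"case/control pool overlap: {sorted(overlap)[:5]}")
    keys = tuple(k for k in keys if k in cases.columns and k in pool.columns)
    rng = np.random.default_rng(seed)
    pool = pool.sort_values("sample_id").reset_index(drop=True)
    used = np.zeros(len(pool), dtype=bool)
    rows = []
    for _, case in cases.sort_values("sample_id").iterrows():
        ok = ~used
        for key in keys:
            ok &= (pool[key] == case[key]).to_numpy()
        if age_col in cases.columns and age_col in pool.columns:
            ok &= (np.abs(pool[age_col].to_numpy() - case[age_col]) <= age_tol)
        idx = np.flatnonzero(ok)
        if len(idx) == 0:
            warnings.warn(f"no eligible controls for case {case['sample_id']}")
            continue
        take = min(ratio, len(idx))
        if take < ratio:
            warnings.warn(
                f"case {case['sample_id']}: only {take} of {ratio} controls available"
            )
        chosen = np.sort(rng.choice(idx, size=take, replace=False))
        used[chosen] = True
        for i in chosen:
            rows.append({"case_id": case["sample_id"], "control_id": pool.loc[i, "sample_id"]})
    return pd.DataFrame(rows, columns=["case_id", "control_id"])


def logistic_assoc(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> dict:
    """Maximum-likelihood logistic regression of binary ``y`` on ``x``.

    Returns the odds ratio for ``x`` with a two-sided Wald p-value, or a
    separation flag (and no estimate) when the likelihood is unbounded.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    design = x.reshape(-1, 1)
    if covariates is not None and np.size(covariates):
        design = np.column_stack([design, covariates])
    design = sm.add_constant(design, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            return {"separation": True, "or": np.nan, "p": np.nan}
    beta = fit.params[1]
    if not np.isfinite(fit.bse[1]) or abs(beta) > 30:
        return {"separation": True, "or": np.nan, "p": np.nan}
    return {
        "separation": False,
        "or": float(np.exp(beta)),
        "beta": float(beta),
        "se": float(fit.bse[1]),
        "p": float(fit.pvalues[1]),
    }


def linear_assoc(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> dict:
    """Ordinary least-squares association for quantitative traits."""
    y = np.asarray(y, dtype=float)
    design = np.asarray(x, dtype=float).reshape(-1, 1)
    if covariates is not None and np.size(covariates):
        design = np.column_stack([design, covariates])
    design = sm.add_constant(design, has_constant="add")
    fit = sm.OLS(y, design).fit()
    return {"beta": float(fit.params[1]), "se": float(fit.bse[1]), "p": float(fit.pvalues[1])}


def prevalence_summary(
    carrier: pd.Series | np.ndarray,
    metadata: pd.DataFrame,
    age_bins: list[float],
    by: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Carrier fraction per age bin (and per ``by`` stratum) with Wilson
    95% confidence intervals; empty bins are omitted."""
    meta = metadata.copy()
    meta["carrier"] = np.asarray(carrier, dtype=bool)
    meta["age_bin"] = pd.cut(meta["age"], bins=age_bins, include_lowest=True)
    rows = []
    group_cols = ["age_bin", *by]
    for key, sub in meta.groupby(group_cols, observed=True):
        n = len(sub)
        if n == 0:
            continue
        k = int(sub["carrier"].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update({"n": n, "carriers": k, "fraction": k / n, "ci_low": lo, "ci_high": hi})
        rows.append(row)
    return pd.DataFrame(rows)


def carrier_fraction(n_carriers: int, n_samples: int) -> dict:
    """Overall carrier percentage with a Wilson 95% interval."""
    if n_samples <= 0 or n_carriers < 0 or n_carriers > n_samples:
        raise ValueError("invalid counts")
    lo, hi = proportion_confint(n_carriers, n_samples, alpha=0.05, method="wilson")
    return {
        "fraction": n_carriers / n_samples,
        "percent": 100.0 * n_carriers / n_samples,
        "ci_low": lo,
        "ci_high": hi,
    }
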