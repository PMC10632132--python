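"""Downstream statistics: co-occurrence, allelic shift, matching,
logistic association, prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from mcakit import (
    allelic_shift_test,
    bonferroni,
    build_carrier_tables,
    carrier_fraction,
    cooccurrence_matrix,
    cooccurrence_test,
    logistic_assoc,
    match_controls,
    prevalence_summary,
)

from oracles import exact_two_sided_sign_p


class TestCooccurrence:
    def test_cross_ratio_closed_form(self):
        res = cooccurrence_test(10, 90, 10, 890)
        assert res.or_hat == pytest.approx(10 * 890 / (90 * 10), abs=1e-12)
        assert not res.corrected
        want_se = np.sqrt(1 / 10 + 1 / 90 + 1 / 10 + 1 / 890)
        assert res.log_or_se == pytest.approx(want_se, abs=1e-12)

    def test_half_added_to_all_cells_on_zero(self):
        res = cooccurrence_test(0, 10, 10, 100)
        assert res.corrected
        assert (res.n11, res.n10, res.n01, res.n00) == (0.5, 10.5, 10.5, 100.5)
        assert res.or_hat == pytest.approx(0.5 * 100.5 / (10.5 * 10.5), abs=1e-12)

    def test_symmetric_table_null(self):
        res = cooccurrence_test(5, 5, 5, 5)
        assert res.or_hat == 1.0
        assert res.p_wald == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_test(0, 0, 0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 200)] * 4))
    def test_row_column_swap_inverts_or(self, cells):
        """Swapping both margins maps OR -> 1/OR and leaves p unchanged."""
        n11, n10, n01, n00 = cells
        if n11 + n10 + n01 + n00 == 0:
            return
        a = cooccurrence_test(n11, n10, n01, n00)
        b = cooccurrence_test(n00, n01, n10, n11)  # swap rows AND columns
        c = cooccurrence_test(n10, n11, n00, n01)  # swap columns only
        assert b.or_hat == pytest.approx(a.or_hat, rel=1e-12)
        assert c.or_hat == pytest.approx(1.0 / a.or_hat, rel=1e-12)
        assert c.p_wald == pytest.approx(a.p_wald, abs=1e-12)

    def test_type_one_error_near_nominal_under_null(self):
        """1,000 independent-null 2x2 tables: Wald rejection rate at
        alpha=0.05 stays near nominal (binomial band)."""
        rng = np.random.default_rng(55)
        n = 2000
        rej = 0
        for _ in range(1000):
            x = rng.random(n) < 0.1
            y = rng.random(n) < 0.1
            res = cooccurrence_test(
                int(np.sum(x & y)), int(np.sum(x & ~y)), int(np.sum(~x & y)), int(np.sum(~x & ~y))
            )
            rej += res.p_wald < 0.05
        # 3 sigma band around 50/1000
        assert abs(rej - 50) <= 3 * np.sqrt(1000 * 0.05 * 0.95) + 1


class TestBonferroni:
    def test_adjustment_and_clamping(self):
        out = bonferroni([0.01, 0.9])
        assert out["p_adj"].tolist() == [0.02, 1.0]
        out5 = bonferroni([0.01] * 5)
        assert out5["p_adj"].iloc[0] == pytest.approx(0.05)
        assert (out5["m"] == 5).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])
        with pytest.raises(ValueError):
            bonferroni([])


class TestCarrierTables:
    def _fixtures(self):
        calls = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)] + ["s0"],
                "chrom": ["chr1"] * 12 + ["chr2"],
                "beg_pos": [1] * 13,
                "end_pos": [40_000_000] * 12 + [30_000_000],
                "type": ["cnloh"] * 12 + ["loss"],
            }
        )
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(30)],
                "chip_genes": ["DNMT3A"] * 11 + [""] * 19,
            }
        )
        cyto = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "arm": ["p", "q", "p"],
                "start": [1, 50_000_001, 1],
                "end": [50_000_000, 100_000_000, 50_000_000],
            }
        )
        return calls, meta, cyto

    def test_min_carrier_threshold(self):
        calls, meta, cyto = self._fixtures()
        table = build_carrier_tables(calls, meta, cyto, min_carriers=10)
        assert "mca:chr1p:cnloh" in table.columns  # 12 carriers
        assert "mca:chr2p:loss" not in table.columns  # 1 carrier
        assert "chip:DNMT3A" in table.columns  # 11 carriers
        table13 = build_carrier_tables(calls, meta, cyto, min_carriers=13)
        assert "mca:chr1p:cnloh" not in table13.columns

    def test_multi_arm_call_joins_both_categories(self):
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(12)], "chip_genes": [""] * 12})
        calls = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "chrom": ["chr1"] * 12,
                "beg_pos": [40_000_000] * 12,
                "end_pos": [60_000_000] * 12,  # spans the p/q boundary
                "type": ["gain"] * 12,
            }
        )
        cyto = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "arm": ["p", "q"],
                "start": [1, 50_000_001],
                "end": [50_000_000, 100_000_000],
            }
        )
        table = build_carrier_tables(calls, meta, cyto, min_carriers=10)
        assert {"mca:chr1p:gain", "mca:chr1q:gain"} <= set(table.columns)
        assert table.loc["s0"].sum() == 2

    def test_empty_callset(self):
        _, meta, cyto = self._fixtures()
        table = build_carrier_tables(meta.iloc[:0].assign(chrom=[], beg_pos=[], end_pos=[], type=[]), meta, cyto)
        assert not any(c.startswith("mca:") for c in table.columns)

    def test_matrix_pipeline(self):
        calls, meta, cyto = self._fixtures()
        table = build_carrier_tables(calls, meta, cyto, min_carriers=10)
        out = cooccurrence_matrix(table)
        assert len(out) == 1
        assert (out["m_tests"] == 1).all()


class TestAllelicShift:
    def test_all_carriers_shifted(self):
        """7 of 7 carriers with the tested allele on the duplicated
        haplotype: p = 2 * (1/2)^7."""
        k, n, p = allelic_shift_test([True] * 7)
        assert (k, n) == (7, 7)
        assert p == pytest.approx(2 * 0.5**7, abs=1e-12)

    def test_balanced_gives_one(self):
        _, _, p = allelic_shift_test([True] * 5 + [False] * 5)
        assert p == pytest.approx(1.0)

    def test_single_carrier_two_sided(self):
        _, _, p = allelic_shift_test([False])
        assert p == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            allelic_shift_test([])

    @pytest.mark.parametrize("n", [1, 2, 5, 8, 12])
    def test_matches_exhaustive_enumeration(self, n):
        for k in range(n + 1):
            _, _, p = allelic_shift_test([True] * k + [False] * (n - k))
            assert p == pytest.approx(exact_two_sided_sign_p(k, n), abs=1e-12)


class TestMatchControls:
    def _pool(self, n=200, seed=1):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "sample_id": [f"p{i:04d}" for i in range(n)],
                "study": rng.choice(["S1", "S2"], n),
                "sequencing_phase": rng.choice(["ph1", "ph2"], n),
                "sex": rng.choice(["female", "male"], n),
                "age": rng.uniform(40, 80, n).round(1),
            }
        )

    def test_exact_ratio_when_pool_is_rich(self):
        pool = self._pool(2000)
        cases = pool.iloc[:3].copy()
        cases["sample_id"] = ["c1", "c2", "c3"]
        out = match_controls(cases, pool, seed=4)
        assert (out.groupby("case_id").size() == 10).all()

    def test_matching_keys_respected(self):
        pool = self._pool(2000)
        cases = pool.iloc[:5].copy()
        cases["sample_id"] = [f"c{i}" for i in range(5)]
        out = match_controls(cases, pool, seed=5)
        pool_ix = pool.set_index("sample_id")
        cases_ix = cases.set_index("sample_id")
        for _, row in out.iterrows():
            case, ctrl = cases_ix.loc[row["case_id"]], pool_ix.loc[row["control_id"]]
            assert case["study"] == ctrl["study"]
            assert case["sequencing_phase"] == ctrl["sequencing_phase"]
            assert case["sex"] == ctrl["sex"]
            assert abs(case["age"] - ctrl["age"]) <= 2.0

    def test_no_control_reuse_between_competing_cases(self):
        pool = pd.DataFrame(
            {
                "sample_id": [f"p{i}" for i in range(10)],
                "study": ["S"] * 10,
                "sequencing_phase": ["ph"] * 10,
                "sex": ["female"] * 10,
                "age": [50.0] * 10,
            }
        )
        cases = pd.DataFrame(
            {
                "sample_id": ["c1", "c2"],
                "study": ["S", "S"],
                "sequencing_phase": ["ph", "ph"],
                "sex": ["female", "female"],
                "age": [50.0, 50.0],
            }
        )
        with pytest.warns(UserWarning):
            out = match_controls(cases, pool, seed=6)
        assert len(out) == 10  # split without reuse
        assert out["control_id"].is_unique

    def test_empty_pool_warns(self):
        cases = self._pool(2).assign(sample_id=["c1", "c2"])
        pool = self._pool(5, seed=9)
        pool["study"] = "OTHER"
        with pytest.warns(UserWarning):
            out = match_controls(cases, pool, seed=7)
        assert len(out) == 0

    def test_stable_under_pool_permutation(self):
        pool = self._pool(2000)
        cases = pool.iloc[:2].copy()
        cases["sample_id"] = ["c1", "c2"]
        a = match_controls(cases, pool, seed=11)
        b = match_controls(cases, pool.sample(frac=1.0, random_state=3), seed=11)
        assert sorted(a["control_id"]) == sorted(b["control_id"])


class TestLogisticAssoc:
    def test_separation_flagged(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        res = logistic_assoc(y, y.astype(float))
        assert res["separation"]

    def test_saturated_fit_equals_cross_ratio(self):
        """Covariate-free logistic OR equals the 2x2 cross-ratio."""
        n11, n10, n01, n00 = 30, 70, 20, 880
        x = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
        y = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)])
        res = logistic_assoc(y, x)
        assert not res["separation"]
        assert res["or"] == pytest.approx(n11 * n00 / (n10 * n01), rel=1e-6)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(77)
        rej = 0
        reps = 400
        for _ in range(reps):
            x = rng.random(2000) < 0.3
            y = rng.random(2000) < 0.1
            res = logistic_assoc(y.astype(float), x.astype(float))
            rej += (not res["separation"]) and res["p"] < 0.05
        assert abs(rej / reps - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps) + 0.005

    def test_recovers_configured_odds_ratio(self):
        rng = np.random.default_rng(13)
        n = 50_000
        x = (rng.random(n) < 0.3).astype(float)
        logit = -2.5 + np.log(3.0) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        res = logistic_assoc(y, x)
        assert res["or"] == pytest.approx(3.0, rel=0.1)


class TestPrevalence:
    def test_overall_carrier_percentage(self):
        out = carrier_fraction(3017, 67_390)
        assert out["percent"] == pytest.approx(4.47, abs=0.01)
        assert out["ci_low"] < out["fraction"] < out["ci_high"]

    def test_binned_summary_and_zero_bin(self):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(100)],
                "age": np.repeat([45, 55, 65, 75], 25),
                "sex": ["female", "male"] * 50,
            }
        )
        carrier = np.zeros(100, dtype=bool)
        carrier[:5] = True  # all in the 40-50 bin
        out = prevalence_summary(carrier, meta, [40, 50, 60, 70, 80])
        young = out[out["age_bin"].apply(lambda b: 45 in b)]
        assert young["carriers"].sum() == 5
        zero = out[out["carriers"] == 0]
        assert (zero["ci_low"] == 0).all()

    def test_wilson_interval_inside_clopper_pearson(self):
        k, n = 5, 50
        from statsmodels.stats.proportion import proportion_confint

        w_lo, w_hi = proportion_confint(k, n, method="wilson")
        cp_lo = beta_dist.ppf(0.025, k, n - k + 1)
        cp_hi = beta_dist.ppf(0.975, k + 1, n - k)
        assert cp_lo <= w_lo and w_hi <= cp_hi
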