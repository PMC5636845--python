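"""Mixed-model correlation, error metrics, growth and montage comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from neonatal_ema.evaluation import (
    compare_montages,
    error_metrics,
    evaluate_ema_table,
    fit_lmm,
    growth_analysis,
    paired_signed_rank,
)


def simulated_repeated_measures(rng, n_infants=30, n_rec=3,
                                intercept_sd=7.0, resid_sd=10.0, slope=1.0):
    rows = []
    for i in range(n_infants):
        u = rng.normal(0, intercept_sd)
        for r in range(n_rec):
            pma = rng.uniform(170, 260)
            ema = slope * pma + u + rng.normal(0, resid_sd)
            rows.append({"infant_id": f"i{i:02d}", "recording_id": f"i{i:02d}_r{r}",
                         "pma_days": pma, "ema_days": ema})
    return pd.DataFrame(rows)


class TestLMM:
    def test_perfect_agreement(self):
        pma = np.tile(np.array([180.0, 210.0, 240.0]), 4)
        infants = np.repeat([f"i{k}" for k in range(4)], 3)
        out = fit_lmm(pma, pma, infants)
        assert out["adjusted_r"] == pytest.approx(1.0, abs=1e-6)
        assert out["slope"] == pytest.approx(1.0, abs=1e-6)

    def test_per_infant_offsets_absorbed(self):
        pma = np.tile(np.array([180.0, 210.0, 240.0]), 4)
        infants = np.repeat([f"i{k}" for k in range(4)], 3)
        offsets = np.repeat([-12.0, -4.0, 5.0, 11.0], 3)
        out = fit_lmm(pma + offsets, pma, infants)
        assert out["adjusted_r"] == pytest.approx(1.0, abs=1e-3)
        assert out["slope"] == pytest.approx(1.0, abs=1e-6)

    def test_adjusted_r_invariant_to_infant_constants(self, rng):
        df = simulated_repeated_measures(rng, n_infants=20)
        base = fit_lmm(df["ema_days"], df["pma_days"], df["infant_id"])
        shifts = {f"i{k:02d}": rng.normal(0, 10) for k in range(20)}
        shifted = df["ema_days"] + df["infant_id"].map(shifts)
        alt = fit_lmm(shifted, df["pma_days"], df["infant_id"])
        assert alt["adjusted_r"] == pytest.approx(base["adjusted_r"], abs=0.02)

    def test_recovers_simulated_variance_structure(self, rng):
        df = simulated_repeated_measures(rng, n_infants=30, n_rec=3)
        out = fit_lmm(df["ema_days"], df["pma_days"], df["infant_id"])
        lo, hi = out["slope_ci"]
        assert lo < 1.0 < hi
        # analytic adjusted r for this design: var(pma)/(var(pma)+resid^2)
        pma = df["pma_days"].to_numpy()
        expected = np.sqrt(np.var(pma) / (np.var(pma) + 10.0**2))
        assert out["adjusted_r"] == pytest.approx(expected, abs=0.05)

    def test_singular_fit_falls_back(self, rng):
        # zero between-infant variance triggers the OLS fallback path
        pma = np.tile(np.array([180.0, 210.0, 240.0]), 3)
        infants = np.repeat(["a", "b", "c"], 3)
        ema = pma + rng.normal(0, 0.5, 9)
        out = fit_lmm(ema, pma, infants)
        assert out["adjusted_r"] > 0.99


class TestErrorMetrics:
    def test_perfect_prediction(self):
        out = error_metrics(np.array([200.0, 220.0]), np.array([200.0, 220.0]))
        assert out["mse"] == 0.0 and out["bias"] == 0.0
        assert out["pct_within_1wk"] == 100.0

    def test_hand_computed_case(self):
        # errors +7 and -7
        out = error_metrics(np.array([207.0, 193.0]), np.array([200.0, 200.0]))
        assert out["mse"] == pytest.approx(49.0)
        assert out["bias"] == pytest.approx(0.0)
        assert out["sd"] == pytest.approx(np.sqrt(2) * 7, rel=1e-6)
        assert out["pct_within_1wk"] == 100.0

    def test_week_thresholds(self):
        # the 14-day bound is inclusive; beyond it a recording no longer
        # counts as within two weeks
        out = error_metrics(np.array([200.0, 214.0]), np.array([200.0, 200.0]))
        assert out["pct_within_1wk"] == 50.0
        assert out["pct_within_2wk"] == 100.0
        out = error_metrics(np.array([200.0, 215.0]), np.array([200.0, 200.0]))
        assert out["pct_within_2wk"] == 50.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            error_metrics(np.zeros(3), np.zeros(4))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce(self, seed):
        # oracle: naive Python loops over the definitions
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        pma = rng.uniform(168, 266, n)
        ema = pma + rng.normal(0, 12, n)
        out = error_metrics(ema, pma)
        errs = [e - p for e, p in zip(ema, pma)]
        assert out["mse"] == pytest.approx(sum(x * x for x in errs) / n)
        assert out["bias"] == pytest.approx(sum(errs) / n)
        assert out["se_percent"] == pytest.approx(
            100 * sum(abs(x) for x in errs) / n / (sum(pma) / n)
        )
        assert out["pct_within_2wk"] == pytest.approx(
            100 * sum(abs(x) <= 14 for x in errs) / n
        )


class TestGrowth:
    def table(self, series):
        rows = []
        for infant, recs in series.items():
            for k, (pma, ema) in enumerate(recs):
                rows.append({"infant_id": infant, "recording_id": f"{infant}_r{k}",
                             "pma_days": pma, "ema_days": ema})
        return pd.DataFrame(rows)

    def test_all_increasing(self):
        out = growth_analysis(
            self.table({"a": [(180, 180.0), (200, 195.0), (220, 210.0)]})
        )
        assert out["n_increasing_first_last"] == 1
        assert out["n_increasing_pairs"] == 2 and out["n_deviant_pairs"] == 0

    def test_deviant_pair_attributed_to_outlier(self):
        out = growth_analysis(
            self.table({"a": [(180, 180.0), (200, 200.0), (220, 190.0)]})
        )
        assert out["n_deviant_pairs"] == 1
        assert out["n_deviant_pairs_outlier_attributed"] == 1
        assert out["outlier_recordings"] == ["a_r2"]

    def test_single_recording_infant_counted_separately(self):
        out = growth_analysis(
            self.table({"a": [(180, 181.0), (210, 212.0)], "b": [(200, 204.0)]})
        )
        assert out["n_infants_serial"] == 1
        assert out["n_single_recording"] == 1

    def test_pair_counts_partition(self, rng):
        df = simulated_repeated_measures(rng, n_infants=15)
        out = growth_analysis(df)
        assert out["n_increasing_pairs"] + out["n_deviant_pairs"] == out["n_pairs"]


class TestSignedRank:
    def test_identical_samples_p_one(self):
        stat, p = paired_signed_rank(np.arange(10.0), np.arange(10.0))
        assert p == 1.0

    def test_constant_shift_significant(self):
        x = np.arange(10.0)
        _, p = paired_signed_rank(x + 1.0, x)
        assert p < 0.05

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_statistic_matches_bruteforce(self, seed):
        # oracle: rank |d| (average ranks on ties), statistic = min of the
        # positive- and negative-rank sums over nonzero differences
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0.3, 1, n)
        d = x - y
        nz = d[d != 0]
        ranks = sstats.rankdata(np.abs(nz))
        w_pos = ranks[nz > 0].sum()
        w_neg = ranks[nz < 0].sum()
        stat, _ = paired_signed_rank(x, y)
        assert stat == pytest.approx(min(w_pos, w_neg))


class TestCompareMontages:
    def test_identical_variant_p_one(self, rng):
        df = simulated_repeated_measures(rng, n_infants=10)
        out = compare_montages({"8ch": df, "copy": df.copy()}, reference="8ch")
        assert set(out["montage"]) == {"8ch", "copy"}
        assert np.allclose(out["p_value"], 1.0)

    def test_uniformly_worse_variant_detected(self, rng):
        df = simulated_repeated_measures(rng, n_infants=10)
        worse = df.copy()
        # inflate every error by a constant day -> every squared error rises
        worse["ema_days"] += np.where(
            worse["ema_days"] >= worse["pma_days"], 3.0, -3.0
        )
        out = compare_montages({"8ch": df, "worse": worse}, reference="8ch")
        p = out.loc[out["montage"] == "worse", "p_value"].iloc[0]
        assert p < 0.05

    def test_report_fields(self, rng):
        df = simulated_repeated_measures(rng, n_infants=8)
        out = compare_montages({"8ch": df}, reference="8ch")
        report = evaluate_ema_table(df)
        assert out["mse_days2"].iloc[0] == pytest.approx(report.mse_days2)
        assert report.pct_within_1wk <= report.pct_within_2wk
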