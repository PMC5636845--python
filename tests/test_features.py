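"""Envelope, rEEG, band powers, SAT statistics, synchrony and assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neonatal_ema.features import (
    FEATURE_COLUMNS,
    FEATURE_NAMES,
    activation_synchrony_index,
    band_powers,
    envelope,
    extract_features,
    reeg,
    sat_stats,
)
from neonatal_ema.pipeline import PipelineConfig, annotate_epoch, process_epoch
from neonatal_ema.preprocessing import BIPOLAR_LABELS, BipolarEpoch
from neonatal_ema.sat_detection import SATAnnotation

FS = 64.0


def make_epoch(data, fs=FS, pma=210):
    return BipolarEpoch(
        channel_labels=list(BIPOLAR_LABELS),
        fs=fs,
        data=data,
        start_offset_s=0.0,
        recording_id="r0",
        infant_id="i0",
        pma_days=pma,
    )


class TestEnvelope:
    def test_unit_sine_envelope_is_one(self):
        t = np.arange(int(60 * FS)) / FS
        env = envelope(np.sin(2 * np.pi * 10 * t))
        core = env[int(5 * FS) : -int(5 * FS)]
        assert np.allclose(core, 1.0, atol=0.02)

    def test_zero_signal(self):
        assert np.allclose(envelope(np.zeros(1000)), 0.0)

    def test_tracks_slow_modulator(self):
        t = np.arange(int(120 * FS)) / FS
        a = 2.0 + np.sin(2 * np.pi * 0.05 * t)
        env = envelope(a * np.sin(2 * np.pi * 10 * t))
        core = slice(int(10 * FS), -int(10 * FS))
        assert np.max(np.abs(env[core] - a[core]) / a[core]) < 0.05


class TestREEG:
    def test_constant_signal_zero(self):
        assert np.allclose(reeg(np.ones(int(60 * FS))), 0.0)

    def test_sine_peak_to_peak(self):
        t = np.arange(int(60 * FS)) / FS
        vals = reeg(np.sin(2 * np.pi * 2 * t))
        assert np.allclose(vals, 2.0, atol=0.01)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_windows(self, seed):
        # oracle: explicit per-window max - min
        rng = np.random.default_rng(seed)
        n = int(rng.integers(128, 2048))
        x = rng.standard_normal(n) * rng.uniform(1, 100)
        vals = reeg(x, fs=FS, win_s=2.0)
        w = int(2.0 * FS)
        expected = [
            x[i * w : (i + 1) * w].max() - x[i * w : (i + 1) * w].min()
            for i in range(n // w)
        ]
        assert np.array_equal(vals, np.asarray(expected))


class TestBandPowers:
    def test_alpha_tone_concentrates(self):
        t = np.arange(int(120 * FS)) / FS
        bp = band_powers(np.sin(2 * np.pi * 10 * t))
        assert bp["rel_alpha"] > 0.99

    def test_delta_tone_concentrates(self):
        t = np.arange(int(120 * FS)) / FS
        bp = band_powers(np.sin(2 * np.pi * 1 * t))
        assert bp["rel_delta"] > 0.99

    def test_equal_power_tones_split(self):
        t = np.arange(int(240 * FS)) / FS
        x = np.sin(2 * np.pi * 1 * t) + np.sin(2 * np.pi * 20 * t)
        bp = band_powers(x)
        assert bp["rel_delta"] == pytest.approx(0.5, abs=0.02)
        assert bp["rel_beta"] == pytest.approx(0.5, abs=0.02)

    def test_relative_powers_sum_to_one(self, rng):
        x = rng.standard_normal(int(300 * FS))
        bp = band_powers(x)
        total = sum(bp[f"rel_{b}"] for b in ("delta", "theta", "alpha", "beta"))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_zero_signal_flagged_missing(self):
        bp = band_powers(np.zeros(int(120 * FS)))
        assert bp["power_total"] == 0.0
        assert np.isnan(bp["rel_delta"])


class TestSatStats:
    def test_rate_normalisation(self):
        iv = np.array([[i * 60.0, i * 60.0 + 2.0] for i in range(60)])
        out = sat_stats(iv, 3600.0)
        assert out["sats_per_hour"] == pytest.approx(60.0)

    def test_uniform_gaps(self):
        iv = np.array([[i * 10.0, i * 10.0 + 2.0] for i in range(50)])
        out = sat_stats(iv, 500.0)
        for k in ("isi_p5", "isi_p50", "isi_p95", "isi_rms"):
            assert out[k] == pytest.approx(8.0)

    def test_mixed_gaps_rms(self):
        # gaps 4, 8, 12 -> rms = sqrt((16+64+144)/3)
        onsets = np.cumsum([0, 2 + 4, 2 + 8, 2 + 12, 2 + 4, 2 + 8, 2 + 12])
        iv = np.column_stack([onsets, onsets + 2.0])
        out = sat_stats(iv, 100.0)
        assert out["isi_rms"] == pytest.approx(np.sqrt((16 + 64 + 144) / 3))

    def test_single_sat_isi_missing(self):
        out = sat_stats(np.array([[5.0, 9.0]]), 3600.0)
        assert out["sats_per_hour"] == pytest.approx(1.0)
        assert np.isnan(out["isi_rms"])

    def test_blocks_do_not_bridge_gaps(self):
        # two mask blocks: ISI must not be computed across the block boundary
        blocks = [np.array([[0.0, 2.0], [10.0, 12.0]]),
                  np.array([[500.0, 502.0], [510.0, 512.0]])]
        out = sat_stats(blocks, 40.0)
        assert out["isi_p50"] == pytest.approx(8.0)
        assert out["sats_per_hour"] == pytest.approx(4 * 3600 / 40.0)


class TestASI:
    def asi_for(self, left_iv, right_iv, dur=1000.0):
        per = {
            "Fp1-T3": left_iv, "Fp2-T4": right_iv,
        }
        return activation_synchrony_index(
            per, dur, pairs=(("Fp1-T3", "Fp2-T4"),)
        )

    def test_identical_streams(self):
        iv = np.array([[i * 4.0, i * 4.0 + 1.0] for i in range(250)])
        # activity fraction 0.25 -> CR = 1/0.25
        assert self.asi_for(iv, iv) == pytest.approx(4.0, rel=0.01)

    def test_independent_streams(self, rng):
        # per-second independent Bernoulli activity on both sides
        n = 20000
        a = rng.random(n) < 0.3
        b = rng.random(n) < 0.3
        iv_a = np.array([[t, t + 1.0] for t in np.flatnonzero(a)])
        iv_b = np.array([[t, t + 1.0] for t in np.flatnonzero(b)])
        asi = self.asi_for(iv_a, iv_b, dur=float(n))
        assert asi == pytest.approx(1.0, abs=0.05)

    def test_antiphase_streams(self):
        a = np.array([[i * 8.0, i * 8.0 + 2.0] for i in range(100)])
        b = a + 4.0
        assert self.asi_for(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_zero_marginal_dropped(self):
        iv = np.array([[0.0, 10.0]])
        empty = np.empty((0, 2))
        assert np.isnan(self.asi_for(iv, empty))


def synthetic_annotated_epoch(rng, n_s=600):
    """A bursty epoch with its annotation, for assembly-level tests."""
    n = int(n_s * FS)
    data = rng.standard_normal((8, n))
    for on in range(5, n_s - 5, 10):
        sl = slice(int(on * FS), int((on + 3) * FS))
        data[:, sl] *= 40.0
    epoch = make_epoch(data)
    ann = annotate_epoch(epoch, PipelineConfig(epoch_len_s=float(n_s)))
    return epoch, ann


class TestExtractFeatures:
    def test_full_mask_equals_full_segment(self, rng):
        epoch, ann = synthetic_annotated_epoch(rng)
        mask = np.ones(int(epoch.duration_s), dtype=bool)
        row = extract_features(epoch, ann, mask)
        for name in FEATURE_NAMES:
            full, low = row[f"{name}_full"], row[f"{name}_lowsat"]
            if np.isnan(full):
                assert np.isnan(low)
            else:
                assert full == pytest.approx(low, rel=1e-9)

    def test_identical_channels_median_identity(self, rng):
        epoch, ann = synthetic_annotated_epoch(rng)
        epoch.data[:] = epoch.data[0]
        ann = annotate_epoch(epoch, PipelineConfig(epoch_len_s=epoch.duration_s))
        mask = np.ones(int(epoch.duration_s), dtype=bool)
        row = extract_features(epoch, ann, mask)
        from neonatal_ema.features import band_powers as bp

        single = bp(epoch.data[0])
        assert row["rel_delta_full"] == pytest.approx(single["rel_delta"])

    def test_feature_vector_complete(self, rng):
        epoch, ann = synthetic_annotated_epoch(rng)
        mask = np.ones(int(epoch.duration_s), dtype=bool)
        row = extract_features(epoch, ann, mask)
        assert set(FEATURE_COLUMNS) <= set(row)
        assert len(FEATURE_COLUMNS) == 46

    def test_percentile_ordering(self, rng):
        epoch, ann = synthetic_annotated_epoch(rng)
        mask = np.ones(int(epoch.duration_s), dtype=bool)
        row = extract_features(epoch, ann, mask)
        for seg in ("full", "lowsat"):
            assert row[f"reeg_p5_{seg}"] <= row[f"reeg_p50_{seg}"]
            assert row[f"reeg_p50_{seg}"] <= row[f"reeg_p95_{seg}"]
            assert row[f"env_p50_{seg}"] <= row[f"env_p95_{seg}"]
            assert row[f"sat_dur_p5_{seg}"] <= row[f"sat_dur_p95_{seg}"]

    def test_amplitude_equivariance(self, rng):
        # scaling the signal scales amplitude features by k, absolute powers
        # by k^2, and leaves relative powers and the synchrony index alone
        epoch, ann = synthetic_annotated_epoch(rng)
        mask = np.ones(int(epoch.duration_s), dtype=bool)
        row1 = extract_features(epoch, ann, mask)
        k = 3.0
        scaled = make_epoch(epoch.data * k)
        ann2 = SATAnnotation(
            channels=ann.channels, consensus=ann.consensus,
            epoch_len_s=ann.epoch_len_s,
        )
        row2 = extract_features(scaled, ann2, mask)
        for f in ("env_p50", "env_p95", "reeg_p5", "reeg_p50", "reeg_p95"):
            assert row2[f + "_full"] == pytest.approx(k * row1[f + "_full"], rel=1e-6)
        for f in ("power_total", "power_delta", "power_beta"):
            assert row2[f + "_full"] == pytest.approx(
                k**2 * row1[f + "_full"], rel=1e-6
            )
        for f in ("rel_delta", "rel_beta", "asi"):
            assert row2[f + "_full"] == pytest.approx(row1[f + "_full"], rel=1e-6)

    def test_generator_burst_count_recovered(self, rng):
        # end-to-end: the SATs-per-hour feature on a clean generated epoch
        # matches the generator's schedule
        from neonatal_ema.pipeline import process_recording
        from neonatal_ema.synthetic import CohortConfig, generate_recording

        cfg = CohortConfig(duration_s=600.0)
        rec, truth = generate_recording("i0", "r0", 200, cfg,
                                        np.random.default_rng(5))
        rows = process_recording(rec, PipelineConfig(epoch_len_s=600.0))
        assert len(rows) == 1
        expected = len(truth.events_union) * 3600 / 600.0
        assert rows[0]["sats_per_hour_full"] == pytest.approx(expected, rel=0.1)
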