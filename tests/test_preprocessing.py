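"""Outlier handling, gap repair, the inclusion gate, floatingline
estimation and acceleration counting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fhrva.preprocessing import (
    FHRRecord,
    count_accelerations,
    detect_outliers,
    estimate_floatingline,
    extract_fhrv,
    longest_valid_span,
    preprocess_record,
    quality_gate,
    repair_gaps,
)
from fhrva.synthetic_ctg import ArtifactSpec, GeneratorConfig, generate_record

from .oracles import peak_count

FS = 4.0


class TestDetectOutliers:
    def test_constant_plausible_signal_is_clean(self):
        mask = detect_outliers(np.full(100, 140.0), FS)
        assert not mask.any()

    def test_single_spike_flags_only_that_index(self):
        x = np.full(100, 140.0)
        x[40] = 300.0
        mask = detect_outliers(x, FS)
        assert mask[40] and mask.sum() == 1

    def test_step_beyond_jump_limit_is_flagged(self):
        x = np.concatenate([np.full(50, 140.0), np.full(50, 180.0)])
        mask = detect_outliers(x, FS)
        assert mask[50] and mask.sum() == 1

    def test_missing_samples_are_not_outliers(self):
        x = np.full(50, 140.0)
        x[10:14] = np.nan
        assert not detect_outliers(x, FS).any()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_outliers(np.array([]), FS)


class TestRepairGaps:
    def test_identity_without_flags(self):
        x = 140 + np.sin(np.arange(200) / 7.0)
        out = repair_gaps(x, np.zeros(200, bool), FS)
        np.testing.assert_array_equal(out, x)

    def test_short_gap_linear_interpolation(self):
        # 2-s gap (8 samples at 4 Hz) between 140 and 144.
        x = np.concatenate([np.full(20, 140.0), np.full(8, np.nan), np.full(20, 144.0)])
        out = repair_gaps(x, np.zeros(x.size, bool), FS)
        expected = 140 + 4 * np.arange(1, 9) / 9
        np.testing.assert_allclose(out[20:28], expected)
        assert np.isfinite(out).all()

    def test_long_gap_stays_missing(self):
        x = np.concatenate([np.full(40, 140.0), np.full(40, np.nan), np.full(40, 144.0)])
        out = repair_gaps(x, np.zeros(x.size, bool), FS)  # 10-s gap > 3 s
        assert np.isnan(out[40:80]).all()

    def test_edge_gap_left_missing(self):
        x = np.concatenate([np.full(4, np.nan), np.full(40, 140.0)])
        out = repair_gaps(x, np.zeros(x.size, bool), FS)
        assert np.isnan(out[:4]).all()

    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        x = 140 + rng.standard_normal(160)
        x[rng.random(160) < 0.1] = np.nan
        mask = rng.random(160) < 0.05
        once = repair_gaps(x, mask, FS)
        twice = repair_gaps(once, np.zeros(160, bool), FS)
        np.testing.assert_array_equal(once, twice)


class TestQualityGate:
    def _record(self, fhr, **kw):
        return FHRRecord(record_id="r", fhr=fhr, sampling_rate=FS, **kw)

    def test_clean_record_included(self):
        rec = self._record(np.full(int(30 * 60 * FS), 140.0))
        rep = quality_gate(rec, np.zeros(rec.fhr.size, bool))
        assert rep.included and rep.reasons == []

    def test_prolonged_signal_loss_excludes(self):
        x = np.full(int(30 * 60 * FS), 140.0)
        x[: int(0.35 * x.size)] = np.nan
        rep = quality_gate(self._record(x), np.zeros(x.size, bool))
        assert not rep.included
        assert any("signal loss" in r for r in rep.reasons)

    def test_short_record_excluded_for_duration(self):
        rec = self._record(np.full(int(15 * 60 * FS), 140.0))
        rep = quality_gate(rec, np.zeros(rec.fhr.size, bool))
        assert not rep.included
        assert any("duration" in r for r in rep.reasons)

    def test_outlier_fraction_excludes(self):
        n = int(30 * 60 * FS)
        rec = self._record(np.full(n, 140.0))
        mask = np.zeros(n, bool)
        mask[: int(0.06 * n)] = True
        rep = quality_gate(rec, mask)
        assert not rep.included

    def test_visual_flag_excludes(self):
        rec = self._record(np.full(int(30 * 60 * FS), 140.0), visually_flagged=True)
        rep = quality_gate(rec, np.zeros(rec.fhr.size, bool))
        assert not rep.included


class TestFloatingline:
    def test_constant_trace_gives_constant_line(self):
        x = np.full(int(1200 * FS), 140.0)
        fl = estimate_floatingline(x, FS)
        np.testing.assert_allclose(fl, 140.0, atol=1e-8)

    def test_tracks_slow_component_of_mixture(self):
        t = np.arange(int(1500 * FS)) / FS
        slow = 140 + 6 * np.sin(2 * np.pi * t / 300.0)
        fast = 2 * np.sin(2 * np.pi * t / 4.0)
        fl = estimate_floatingline(slow + fast, FS)
        assert np.corrcoef(fl, slow)[0, 1] > 0.99

    def test_passband_gain_at_60s_period(self):
        t = np.arange(int(1800 * FS)) / FS
        x = 140 + 8 * np.sin(2 * np.pi * t / 60.0)
        fl = estimate_floatingline(x, FS)
        core = slice(int(60 * FS), -int(60 * FS))  # ignore edge transients
        gain = np.std(fl[core]) / np.std(x[core])
        assert gain >= 0.9

    def test_stopband_gain_at_10s_period(self):
        t = np.arange(int(1800 * FS)) / FS
        x = 140 + 8 * np.sin(2 * np.pi * t / 10.0)
        fl = estimate_floatingline(x, FS)
        assert np.std(fl) / np.std(x) <= 0.1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="smoothing support"):
            estimate_floatingline(np.full(100, 140.0), FS)

    def test_rmse_vs_generator_truth_on_drift_dominated_records(self):
        # Drift-dominated configuration: the estimate should track the true
        # floatingline to within 10% of the drift amplitude.
        for seed in (0, 1, 2):
            cfg = GeneratorConfig(
                seed=seed,
                drift_amplitude_bpm=8.0,
                band_powers={"vlf": 0.0, "lf": 1.5, "hf": 1.0},
                artifact_spec=ArtifactSpec(0.0, 0, 0.0),
            )
            rec, truth = generate_record(cfg)
            fl = estimate_floatingline(rec.fhr, rec.sampling_rate)
            rmse = np.sqrt(np.mean((fl - truth.floatingline_true) ** 2))
            assert rmse < 0.1 * cfg.drift_amplitude_bpm

    def test_pure_slow_drift_leaves_tiny_residual(self):
        t = np.arange(int(1800 * FS)) / FS
        amp = 10.0
        x = 140 + amp * np.sin(2 * np.pi * t / 600.0)
        fl = estimate_floatingline(x, FS)
        sig = extract_fhrv(x, fl, FS)
        assert np.std(sig.fhrv) < 0.01 * amp


class TestExtractFHRV:
    def test_identical_inputs_give_zero(self):
        x = np.full(50, 140.0)
        sig = extract_fhrv(x, x, FS)
        np.testing.assert_array_equal(sig.fhrv, 0.0)

    def test_additive_shift(self):
        fl = 140 + np.sin(np.arange(100) / 9.0)
        sig = extract_fhrv(fl + 5, fl, FS)
        np.testing.assert_allclose(sig.fhrv, 5.0)

    def test_reconstruction_identity(self, rng):
        fl = 140 + rng.standard_normal(300)
        x = fl + rng.standard_normal(300)
        sig = extract_fhrv(x, fl, FS)
        np.testing.assert_array_equal(sig.fhrv + sig.floatingline, sig.fhr_clean)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_fhrv(np.zeros(10), np.zeros(11), FS)


class TestCountAccelerations:
    def test_flat_trace_counts_zero(self):
        x = np.full(1000, 140.0)
        assert count_accelerations(x, x, FS) == 0

    def test_subthreshold_bump_not_counted(self):
        base = np.full(2000, 140.0)
        x = base.copy()
        x[800 : 800 + int(20 * FS)] += 10.0  # 10 bpm for 20 s: below 15 bpm
        assert count_accelerations(x, base, FS) == 0

    def test_short_bump_not_counted(self):
        base = np.full(2000, 140.0)
        x = base.copy()
        x[800 : 800 + int(10 * FS)] += 20.0  # 20 bpm but only 10 s
        assert count_accelerations(x, base, FS) == 0

    def test_nearby_intervals_merge(self):
        base = np.full(4000, 140.0)
        x = base.copy()
        x[800 : 800 + int(10 * FS)] += 20.0
        x[800 + int(13 * FS) : 800 + int(23 * FS)] += 20.0  # 3-s gap: merges
        assert count_accelerations(x, base, FS) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_generator_truth_without_artifacts(self, seed):
        cfg = GeneratorConfig(seed=seed, artifact_spec=ArtifactSpec(0.0, 0, 0.0))
        rec, truth = generate_record(cfg)
        fl = estimate_floatingline(rec.fhr, rec.sampling_rate)
        assert count_accelerations(rec.fhr, fl, rec.sampling_rate) == truth.accel_count
        # and the independent scan oracle agrees on the true baseline
        assert peak_count(truth.clean_signal, truth.floatingline_true, FS) == truth.accel_count


class TestPreprocessRecord:
    def test_longest_valid_span(self):
        x = np.concatenate([np.full(10, 1.0), [np.nan], np.full(30, 2.0), [np.nan], np.full(5, 3.0)])
        span = longest_valid_span(x)
        assert (span.start, span.stop) == (11, 41)

    def test_full_preprocessing_of_generated_record(self):
        rec, _ = generate_record(GeneratorConfig(seed=9))
        sig, report = preprocess_record(rec)
        assert report.included and sig is not None
        np.testing.assert_allclose(sig.fhrv + sig.floatingline, sig.fhr_clean, atol=1e-12)
        assert np.isfinite(sig.fhr_clean).all()

    def test_gate_reproducible_and_order_independent(self):
        records = [generate_record(GeneratorConfig(seed=s))[0] for s in range(6)]
        first = [preprocess_record(r)[1].included for r in records]
        second = [preprocess_record(r)[1].included for r in reversed(records)]
        assert first == list(reversed(second))
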