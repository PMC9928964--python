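"""Filters, the four artifact detectors, interpolation, and QC rules."""

from __future__ import annotations

import numpy as np
import pytest

from earsleep.io_core import DATA_CHANNELS, RawRecording
from earsleep.preprocess import (
    PreprocessConfig,
    apply_filters,
    detect_amplitude,
    detect_hf_noise,
    detect_periodic_spikes,
    detect_transient_spikes,
    preprocess_recording,
    remove_and_interpolate,
)
from earsleep.synthetic import ArtifactSpec, CAT_TO_INT, simulate_night


def _rec_from(x, fs=250.0):
    return RawRecording(fs=fs, channels={c: x.copy() for c in DATA_CHANNELS})


class TestApplyFilters:
    fs = 250.0
    t = np.arange(int(60 * 250)) / 250.0

    def test_power_line_suppressed(self):
        x = 100 * np.sin(2 * np.pi * 50 * self.t)
        out = apply_filters(_rec_from(x)).channels["EL1"]
        # steady-state response: skip the filter's edge transients
        core = slice(int(5 * self.fs), -int(5 * self.fs))
        assert np.sqrt(np.mean(out[core] ** 2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_dc_offset_removed(self):
        out = apply_filters(_rec_from(np.full(len(self.t), 100.0))).channels["EL1"]
        assert abs(out.mean()) < 1.0

    def test_passband_preserved(self):
        x = np.sin(2 * np.pi * 10 * self.t)
        out = apply_filters(_rec_from(x)).channels["EL1"]
        assert abs(np.sqrt(np.mean(out**2)) / np.sqrt(np.mean(x**2)) - 1) < 0.05

    def test_notch_impossible_at_low_fs(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError, match="notch"):
            apply_filters(_rec_from(x, fs=180.0))


class TestAmplitudeDetector:
    def test_strict_350_threshold(self):
        x = np.array([0.0, 351.0, -400.0, 350.0])
        np.testing.assert_array_equal(
            detect_amplitude(x), [False, True, True, False]
        )

    def test_all_zero(self):
        assert not detect_amplitude(np.zeros(100)).any()

    def test_scaling_monotonicity(self, rng):
        for _ in range(20):
            x = 300 * rng.standard_normal(500)
            assert detect_amplitude(2 * x).sum() >= detect_amplitude(x).sum()


class TestInterpolation:
    def test_linear_ramp_reconstructed_exactly(self):
        x = np.linspace(0, 10, 50)
        mask = np.zeros(50, dtype=bool)
        mask[20:23] = True
        np.testing.assert_allclose(remove_and_interpolate(x, mask), x, atol=1e-12)

    def test_empty_mask_identity(self):
        x = np.random.default_rng(0).standard_normal(100)
        out = remove_and_interpolate(x, np.zeros(100, dtype=bool))
        np.testing.assert_array_equal(out, x)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError, match="all-masked"):
            remove_and_interpolate(np.zeros(10), np.ones(10, dtype=bool))

    def test_smooth_signal_repair_accuracy(self):
        """Spikes removed from a 2 Hz sinusoid leave <5% amplitude RMSE
        on the repaired samples."""
        fs = 250.0
        t = np.arange(int(10 * fs)) / fs
        clean = 100 * np.sin(2 * np.pi * 2 * t)
        x = clean.copy()
        mask = np.zeros(len(x), dtype=bool)
        rng = np.random.default_rng(3)
        for _ in range(10):
            i = int(rng.integers(100, len(x) - 100))
            x[i : i + 10] += 300.0
            mask[i : i + 10] = True
        repaired = remove_and_interpolate(x, mask)
        rmse = np.sqrt(np.mean((repaired[mask] - clean[mask]) ** 2))
        assert rmse < 5.0  # 5% of the 100 uV amplitude


class TestTransientSpikes:
    fs = 250.0

    def test_injected_spikes_found(self, rng):
        n = int(120 * self.fs)
        x = 20 * rng.standard_normal(n)
        onsets = np.linspace(1000, n - 1000, 10).astype(int)
        w = int(0.04 * self.fs)
        for i in onsets:
            x[i : i + w] += 300.0
        mask = detect_transient_spikes(x, self.fs)
        hits = sum(mask[i : i + w].any() for i in onsets)
        assert hits >= 9

    def test_sinusoid_clean(self):
        t = np.arange(int(30 * self.fs)) / self.fs
        assert not detect_transient_spikes(50 * np.sin(2 * np.pi * 5 * t), self.fs).any()

    def test_long_segments_left_to_other_detectors(self, rng):
        n = int(120 * self.fs)
        x = 20 * rng.standard_normal(n)
        a, b = int(30 * self.fs), int(90 * self.fs)
        x[a:b] += 200 * rng.standard_normal(b - a)  # 60 s, not a spike
        mask = detect_transient_spikes(x, self.fs)
        # runs longer than the spike limit are not claimed (only their
        # brief onset/offset edges may be)
        assert mask[a:b].mean() < 0.1


class TestPeriodicSpikes:
    fs = 250.0

    def test_train_detected(self, rng):
        n = int(60 * self.fs)
        x = 15 * rng.standard_normal(n)
        period = 50
        onsets = np.arange(2000, 2000 + 50 * period, period)
        for i in onsets:
            x[i : i + 2] += 150.0
        mask = detect_periodic_spikes(x, self.fs)
        hits = sum(mask[i : i + 2].any() for i in onsets)
        assert hits >= 0.95 * len(onsets)

    def test_clean_noise_low_false_positives(self, rng):
        x = 15 * rng.standard_normal(int(120 * self.fs))
        assert detect_periodic_spikes(x, self.fs).mean() < 0.005

    def test_wrong_period_not_grouped(self, rng):
        x = 15 * rng.standard_normal(int(20 * self.fs))
        for i in (1000, 1070, 1140):  # 70-sample gaps, not 50
            x[i : i + 2] += 150.0
        assert not detect_periodic_spikes(x, self.fs).any()


class TestHfNoise:
    fs = 250.0

    def _with_hf(self, dur_s, rng):
        rec, _ = simulate_night(8, seed=int(rng.integers(2**31)))  # 4 min
        x = rec.channels["ER1"].copy()
        from earsleep.synthetic import _band_noise

        a = int(60 * self.fs)
        b = a + int(dur_s * self.fs)
        base = np.sqrt(np.mean(x**2))
        x[a:b] += 10 * base * _band_noise(b - a, self.fs, 40, 100, rng)
        return x, a, b

    def test_long_segment_marked(self, rng):
        x, a, b = self._with_hf(60, rng)
        mask = detect_hf_noise(x, self.fs)
        assert mask[a:b].mean() >= 0.90

    def test_short_burst_ignored(self, rng):
        x, a, b = self._with_hf(10, rng)
        assert not detect_hf_noise(x, self.fs)[a:b].any()

    def test_clean_n3_unmarked(self):
        from earsleep.io_core import Hypnogram
        from earsleep.synthetic import synthesize_recording

        rec = synthesize_recording(Hypnogram(labels=("N3",) * 8), seed=5)
        assert detect_hf_noise(rec.channels["EL2"], rec.fs).mean() < 0.01


class TestFullPipeline:
    def test_clean_night_accepted(self, short_cfg):
        rec, _ = simulate_night(20, seed=11, artifacts=None)
        _, mask, validity, qc = preprocess_recording(rec, short_cfg)
        assert qc.accepted
        assert qc.overall_noisy_fraction < 0.02

    def test_heavy_hf_night_rejected(self, short_cfg):
        rec, _ = simulate_night(20, seed=12, artifacts=None)
        from earsleep.synthetic import _band_noise

        rng = np.random.default_rng(0)
        n = rec.n_samples
        cut = int(0.45 * n)
        for c in DATA_CHANNELS:
            base = np.sqrt(np.mean(rec.channels[c] ** 2))
            rec.channels[c][:cut] += 10 * base * _band_noise(cut, rec.fs, 40, 100, rng)
        _, _, _, qc = preprocess_recording(rec, short_cfg)
        assert not qc.accepted
        assert "noisy" in qc.reason

    def test_short_recording_rejected_by_default_rule(self):
        rec, _ = simulate_night(480, seed=13)  # 4 h
        _, _, _, qc = preprocess_recording(rec)  # default config: 5 h rule
        assert not qc.accepted
        assert "5 h" in qc.reason

    def test_detectors_nearly_idempotent_after_repair(self, short_cfg):
        rec, _ = simulate_night(10, seed=14, artifacts=ArtifactSpec())
        clean, mask, _, _ = preprocess_recording(rec, short_cfg)
        # re-running on the repaired output marks almost nothing new
        _, mask2, _, qc2 = preprocess_recording(clean, short_cfg)
        new_frac = np.mean(
            [
                ((mask2.codes[c] != 0) & (mask.codes[c] == 0)).mean()
                for c in DATA_CHANNELS
            ]
        )
        assert new_frac < 0.01

    def test_precedence_periodic_wins(self, rng):
        """A sample claimed by the periodic detector keeps that label even
        where the transient detector would also fire."""
        rec, _ = simulate_night(10, seed=15)
        spec = ArtifactSpec(
            periodic_channel_prob=1.0,
            periodic_bouts_per_hour=30.0,
            transient_rate_per_min=0.0,
            hf_segments_per_recording=0.0,
            excursion_rate_per_hour=0.0,
        )
        from earsleep.synthetic import inject_artifacts

        dirty, gt = inject_artifacts(rec, spec, seed=3)
        _, mask, _, _ = preprocess_recording(dirty, PreprocessConfig(min_duration_h=0.0))
        for c in DATA_CHANNELS:
            truth = gt.artifact_mask[c] == CAT_TO_INT["device_periodic"]
            if truth.sum() == 0:
                continue
            got = mask.codes[c][truth]
            marked = got != 0
            # among detected truth samples, the periodic label dominates
            if marked.sum():
                assert (
                    got[marked] == CAT_TO_INT["device_periodic"]
                ).mean() > 0.9
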