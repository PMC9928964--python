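"""Generator contracts: hypnogram statistics, stage spectra, artifact
injection with exact masks, and reproducibility."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

from earsleep.io_core import DATA_CHANNELS, Hypnogram, STAGES
from earsleep.synthetic import (
    ArtifactSpec,
    CAT_TO_INT,
    StageSpectrumSpec,
    StageTransitionModel,
    default_transition_model,
    generate_hypnogram,
    inject_artifacts,
    simulate_night,
    synthesize_recording,
)


class TestGenerateHypnogram:
    def test_empty(self):
        assert len(generate_hypnogram(0, seed=0)) == 0

    def test_identity_matrix_freezes_stage(self):
        model = StageTransitionModel(P=np.eye(5), initial="W")
        h = generate_hypnogram(50, model, seed=1)
        assert set(h.labels) == {"W"}

    def test_non_stochastic_matrix_rejected(self):
        P = np.full((5, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            StageTransitionModel(P=P)

    def test_stationary_distribution_reached(self):
        """Across independent chains, mean stage frequencies match the
        stationary distribution within 3 standard errors."""
        model = default_transition_model()
        pi = model.stationary()
        n_chains, n_epochs = 24, 1500
        freqs = np.zeros((n_chains, 5))
        for i in range(n_chains):
            h = generate_hypnogram(n_epochs, model, seed=100 + i)
            codes = h.to_int()
            for k in range(5):
                freqs[i, k] = np.mean(codes == k)
        mean = freqs.mean(axis=0)
        sem = freqs.std(axis=0, ddof=1) / np.sqrt(n_chains)
        assert np.all(np.abs(mean - pi) <= 3 * sem + 1e-3), (mean, pi, sem)

    def test_stationary_fractions_roughly_adult_sleep(self):
        pi = default_transition_model().stationary()
        targets = dict(zip(STAGES, [0.10, 0.10, 0.45, 0.15, 0.20]))
        for k, s in enumerate(STAGES):
            assert abs(pi[k] - targets[s]) < 0.08, (s, pi[k])


class TestSynthesizeRecording:
    def test_n3_is_delta_dominated(self):
        h = Hypnogram(labels=("N3",) * 10)
        rec = synthesize_recording(h, seed=3)
        for c in DATA_CHANNELS:
            f, psd = sps.welch(rec.channels[c], fs=rec.fs, nperseg=int(4 * rec.fs))
            delta = psd[(f >= 0.5) & (f < 4)].sum()
            alpha = psd[(f >= 8) & (f < 12)].sum()
            assert delta / alpha > 5, c

    def test_zero_spec_gives_silence(self):
        spec = StageSpectrumSpec(
            weights={s: {b: 0.0 for b in ("delta", "theta", "alpha", "sigma", "beta")} for s in STAGES},
            noise_uv=0.0,
            spindle_rate_per_min=0.0,
            rem_deflection_rate_per_min=0.0,
        )
        rec = synthesize_recording(Hypnogram(labels=("N2",) * 3), spec, seed=0)
        for c in DATA_CHANNELS:
            assert np.allclose(rec.channels[c], 0.0)

    def test_same_seed_bit_identical(self):
        h = generate_hypnogram(5, seed=9)
        a = synthesize_recording(h, seed=11)
        b = synthesize_recording(h, seed=11)
        for c in DATA_CHANNELS:
            np.testing.assert_array_equal(a.channels[c], b.channels[c])

    def test_empty_hypnogram_empty_recording(self):
        rec = synthesize_recording(Hypnogram(labels=()), seed=0)
        assert rec.n_samples == 0

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            synthesize_recording(Hypnogram(labels=("W",)), fs=50, seed=0)

    def test_cross_ear_derivation_retains_stage_signal(self):
        """R - L must keep the stage-dependent source (opposite-polarity
        projection), not cancel it."""
        h = Hypnogram(labels=("N3",) * 5)
        rec = synthesize_recording(h, seed=4)
        diff = rec.channels["ER1"] - rec.channels["EL1"]
        f, psd = sps.welch(diff, fs=rec.fs, nperseg=int(4 * rec.fs))
        delta = psd[(f >= 0.5) & (f < 4)].sum()
        beta = psd[(f >= 16) & (f < 40)].sum()
        assert delta / beta > 5


class TestInjectArtifacts:
    def test_zero_rates_identity(self):
        rec, _ = simulate_night(3, seed=5)
        spec = ArtifactSpec(
            periodic_channel_prob=0.0,
            periodic_bouts_per_hour=0.0,
            transient_rate_per_min=0.0,
            hf_segments_per_recording=0.0,
            excursion_rate_per_hour=0.0,
        )
        dirty, gt = inject_artifacts(rec, spec, seed=0)
        for c in DATA_CHANNELS:
            np.testing.assert_array_equal(dirty.channels[c], rec.channels[c])
            assert gt.artifact_mask[c].sum() == 0

    def test_periodic_grid_is_exact(self):
        """A 10 s bout at 200 ms period and 250 Hz puts 50 onsets exactly
        50 samples apart."""
        rec, _ = simulate_night(2, seed=6)  # 60 s
        spec = ArtifactSpec(
            periodic_channel_prob=1.0,
            periodic_bouts_per_hour=60.0,
            periodic_duty_s=10.0,
            transient_rate_per_min=0.0,
            hf_segments_per_recording=0.0,
            excursion_rate_per_hour=0.0,
        )
        dirty, gt = inject_artifacts(rec, spec, seed=1)
        code = CAT_TO_INT["device_periodic"]
        found_grid = False
        for c in DATA_CHANNELS:
            m = gt.artifact_mask[c] == code
            if not m.any():
                continue
            onsets = np.where(np.diff(np.concatenate([[0], m.astype(int)])) == 1)[0]
            gaps = np.diff(onsets)
            # onsets within one bout are exactly period*fs = 50 apart
            assert np.all((gaps == 50) | (gaps > 50)), gaps
            if np.sum(gaps == 50) >= 40:
                found_grid = True
        assert found_grid

    def test_excursions_marked_as_amplitude(self):
        rec, _ = simulate_night(2, seed=7)
        spec = ArtifactSpec(
            periodic_channel_prob=0.0,
            periodic_bouts_per_hour=0.0,
            transient_rate_per_min=0.0,
            hf_segments_per_recording=0.0,
            excursion_rate_per_hour=120.0,
            excursion_amp_uv=400.0,
        )
        dirty, gt = inject_artifacts(rec, spec, seed=2)
        code = CAT_TO_INT["amplitude"]
        total = sum((gt.artifact_mask[c] == code).sum() for c in DATA_CHANNELS)
        assert total > 0
        for c in DATA_CHANNELS:
            marked = gt.artifact_mask[c] == code
            if marked.any():
                assert np.abs(dirty.channels[c][marked]).max() > 350

    def test_mask_counts_match_by_construction(self):
        rec, gt = simulate_night(4, seed=8, artifacts=ArtifactSpec())
        for c in DATA_CHANNELS:
            assert len(gt.artifact_mask[c]) == rec.n_samples

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="30 s"):
            ArtifactSpec(hf_segment_s=20.0)
        with pytest.raises(ValueError, match="350"):
            ArtifactSpec(excursion_amp_uv=300.0)


class TestReproducibilityAndSeparability:
    def test_simulate_night_bit_reproducible(self):
        a_rec, a_gt = simulate_night(5, seed=77, artifacts=ArtifactSpec())
        b_rec, b_gt = simulate_night(5, seed=77, artifacts=ArtifactSpec())
        assert a_gt.hypnogram.labels == b_gt.hypnogram.labels
        for c in DATA_CHANNELS:
            np.testing.assert_array_equal(a_rec.channels[c], b_rec.channels[c])
            np.testing.assert_array_equal(a_gt.artifact_mask[c], b_gt.artifact_mask[c])

    def test_stages_linearly_separable_from_band_powers(self):
        """A linear model on relative band powers of clean epochs should
        reach 90% five-class accuracy — the floor the staging forest
        builds on."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        rng = np.random.default_rng(0)
        # balanced stage draws, one epoch each
        X, y = [], []
        fs = 250.0
        for k, stage in enumerate(STAGES):
            h = Hypnogram(labels=(stage,) * 12)
            rec = synthesize_recording(h, seed=int(rng.integers(2**31)), fs=fs)
            x = rec.channels["ER1"]
            spe = int(30 * fs)
            for i in range(12):
                seg = x[i * spe : (i + 1) * spe]
                f, psd = sps.welch(seg, fs=fs, nperseg=int(2 * fs))
                bands = [(0.5, 4), (4, 8), (8, 12), (11, 16), (16, 40)]
                bp = np.array([psd[(f >= lo) & (f < hi)].sum() for lo, hi in bands])
                X.append(bp / bp.sum())
                y.append(k)
        score = cross_val_score(
            LogisticRegression(max_iter=2000), np.array(X), np.array(y), cv=4
        ).mean()
        assert score >= 0.90, score
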