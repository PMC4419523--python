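"""EEG front-end stages: filtering, baseline, alpha-IMF selection, Morlet,
binarization, and the leakage guards of the full pipeline."""

import numpy as np
import pytest

from memhnn.codes import FeatureCode
from memhnn.csp import bit_thresholds
from memhnn.eeg import (
    EEGDataset,
    FeatureConfig,
    bandpass,
    baseline_correct,
    binarize,
    morlet_tf,
    select_alpha_imf,
)
from memhnn.memd import IMFSet, memd

FS = 250.0


def tone(freq, n=2000, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestBandpass:
    def test_passband_tone_preserved(self):
        x = tone(10.0)
        y = bandpass(x, FS)
        core = slice(250, -250)  # trim filter edges
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_tone_suppressed(self):
        x = tone(2.0)
        y = bandpass(x, FS)
        assert np.abs(y[250:-250]).max() < 0.1

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(bandpass(np.zeros((3, 1000)), FS), 0.0)

    def test_zero_phase_no_lag(self):
        x = tone(15.0)
        y = bandpass(x, FS)
        lag = np.argmax(np.correlate(y[500:1500], x[500:1500], "full")) - 999
        assert lag == 0

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            bandpass(tone(10.0), FS, low=8.0, high=130.0)


class TestBaselineCorrect:
    def test_constant_offset_removed_everywhere(self):
        x = np.full((2, 500), 7.0)
        y = baseline_correct(x, (0, 100))
        np.testing.assert_allclose(y, 0.0)

    def test_zero_mean_baseline_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 500))
        x -= x[:, 100:200].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(baseline_correct(x, (100, 200)), x)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 500))
        np.testing.assert_allclose(
            baseline_correct(x + 7.0, (0, 100)), baseline_correct(x, (0, 100))
        )

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(np.zeros((2, 100)), (50, 50))


class TestSelectAlphaIMF:
    def test_picks_the_10hz_mode_of_a_mixture(self):
        x = np.stack([tone(10.0) + tone(3.0), 0.9 * tone(10.0) - tone(3.0)])
        s = memd(x)
        k = select_alpha_imf(s, FS)
        from scipy.signal import periodogram

        f, p = periodogram(s.imfs[k], fs=FS, axis=-1)
        assert f[p.sum(axis=0).argmax()] == pytest.approx(10.0, abs=0.5)

    def test_single_imf_returns_zero(self):
        s = IMFSet(imfs=np.random.default_rng(0).standard_normal((1, 2, 300)),
                   residual=np.zeros((2, 300)))
        assert select_alpha_imf(s, FS) == 0

    def test_tie_resolves_to_lowest_index(self):
        imf = np.stack([tone(10.0, 500)[None].repeat(2, 0)] * 2)
        s = IMFSet(imfs=imf, residual=np.zeros((2, 500)))
        assert select_alpha_imf(s, FS) == 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            select_alpha_imf(IMFSet(np.empty((0, 2, 10)), np.zeros((2, 10))), FS)


class TestMorlet:
    def test_ridge_at_tone_frequency(self):
        x = tone(10.0)
        p = morlet_tf(x, FS, [10.0, 20.0])
        core = slice(500, 1500)
        assert p[0, core].mean() > 10 * p[1, core].mean()

    def test_zero_signal_zero_map(self):
        np.testing.assert_allclose(morlet_tf(np.zeros(1000), FS, [10.0]), 0.0)

    def test_quadratic_amplitude_scaling(self):
        x = tone(12.0)
        p1 = morlet_tf(x, FS, [12.0])
        p2 = morlet_tf(2 * x, FS, [12.0])
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-10)

    def test_frequencies_validated(self):
        with pytest.raises(ValueError):
            morlet_tf(tone(10.0), FS, [200.0])


class TestBinarize:
    def test_strict_inequality_at_threshold(self):
        code = binarize(np.array([0.5, 1.0]), np.array([0.5, 0.5]))
        assert code.bits[0] == 0 and code.bits[1] == 1

    def test_output_always_32_bits(self):
        for n_feats in (6, 18, 30):
            code = binarize(np.ones(n_feats), np.zeros(n_feats))
            assert len(code) == 32
            assert sum(code.bits) == n_feats  # padding stays zero

    def test_too_many_features_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.ones(40), np.zeros(40))

    def test_unfitted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.ones(6), np.zeros(5))


class TestBitThresholds:
    def test_cluster_midpoint_separates_bimodal_feature(self):
        rng = np.random.default_rng(0)
        col = np.concatenate([rng.normal(-1, 0.1, 20), rng.normal(-4, 0.1, 40)])
        thr = bit_thresholds(col[:, None])[0]
        assert -4 < thr < -1  # between the modes, despite the 1:2 imbalance
        assert np.median(col) < thr or np.median(col) > -1.2  # median sits in a mode

    def test_median_method_matches_numpy(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((50, 4))
        np.testing.assert_allclose(
            bit_thresholds(F, method="median"), np.median(F, axis=0)
        )


class TestPipeline:
    def test_counts_and_labels(self, eeg_codes):
        train, test, log = eeg_codes
        # the split is sized 65/15; identical codes collapse with a logged count
        assert len(train) + log["duplicates_train"] == 65
        assert len(test) + log["duplicates_test"] == 15
        assert len({c.bits for c in train}) == len(train)
        assert all(c.label in "aiu" for c in train + test)
        assert all(len(c) == 32 for c in train + test)

    def test_no_leakage_test_indices_disjoint(self, eeg_codes):
        _, _, log = eeg_codes
        assert not set(log["train_indices"]) & set(log["test_indices"])

    def test_filters_and_thresholds_independent_of_test_split(self):
        """Fitting on a dataset whose test trials were replaced by noise
        must leave the CSP filters and thresholds bit-identical."""
        from dataclasses import replace as dc_replace

        from memhnn.eeg import _stratified_split, extract_pipeline
        from memhnn.synth import EEGGenConfig, gen_eeg

        ds = gen_eeg(EEGGenConfig(seed=5, n_channels=12, trials_per_class=6))
        cfg = FeatureConfig(
            seed=0, n_train=12, n_test=6, n_csp_filters=6, na_noise_channels=0
        )
        _, test_idx = _stratified_split(ds.labels, cfg.n_train, cfg.n_test, cfg.seed)
        scrambled = ds.trials.copy()
        rng = np.random.default_rng(99)
        for i in test_idx:
            scrambled[i] = rng.standard_normal(scrambled[i].shape)
        ds2 = dc_replace(ds, trials=scrambled)
        _, _, log_a = extract_pipeline(ds, cfg)
        _, _, log_b = extract_pipeline(ds2, cfg)
        np.testing.assert_allclose(log_a["thresholds"], log_b["thresholds"])
        for ma, mb in zip(log_a["csp_models"], log_b["csp_models"]):
            np.testing.assert_allclose(ma.filters, mb.filters)

    def test_alpha_imf_selection_is_logged_per_trial(self, eeg_codes, eeg_dataset):
        _, _, log = eeg_codes
        assert len(log["alpha_imf_index"]) == eeg_dataset.n_trials


def test_dataset_text_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    ds = EEGDataset(
        trials=rng.standard_normal((3, 4, 100)),
        fs=250.0,
        labels=["a", "i", "u"],
        baseline_window=(10, 30),
        task_window=(50, 100),
    )
    ds.write_text(tmp_path / "d")
    back = EEGDataset.read_text(tmp_path / "d")
    np.testing.assert_allclose(back.trials, ds.trials, atol=1e-5)
    assert back.labels == ds.labels
    assert back.baseline_window == ds.baseline_window
    assert back.fs == ds.fs
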