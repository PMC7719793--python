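import numpy as np
import pytest

from smmtransfer import (EpochArray, FeatureConfig, Hyperparams, Standardizer,
                         band_power_matrix, bandpass, fit, fit_spatial_filters,
                         load_trial_csv_dir, predict, save_trial_csv_dir, synth_eeg)


@pytest.fixture
def cfg():
    return FeatureConfig(n_spatial_filters=2, n_windows=5)


def _sine_epochs(freq: float, sfreq: float = 250.0, seconds: float = 2.5):
    t = np.arange(0, seconds, 1.0 / sfreq)
    sig = np.sin(2 * np.pi * freq * t)
    return EpochArray(np.tile(sig, (2, 1, 1)), sfreq), sig


class TestBandpass:
    def test_in_band_tone_passes(self, cfg):
        ep, sig = _sine_epochs(15.0)
        out = bandpass(ep, cfg)
        ratio = np.sqrt(np.mean(out.data[0, 0] ** 2)) / np.sqrt(np.mean(sig ** 2))
        assert abs(ratio - 1.0) < 0.05

    def test_stop_band_tone_blocked(self, cfg):
        ep, sig = _sine_epochs(2.0)
        out = bandpass(ep, cfg)
        ratio = np.sqrt(np.mean(out.data[0, 0] ** 2)) / np.sqrt(np.mean(sig ** 2))
        assert ratio < 0.05

    def test_zero_signal_maps_to_zero(self, cfg):
        ep = EpochArray(np.zeros((1, 2, 500)), 250.0)
        assert np.allclose(bandpass(ep, cfg).data, 0.0)

    def test_band_above_nyquist_rejected(self):
        ep = EpochArray(np.zeros((1, 1, 100)), 50.0)
        with pytest.raises(ValueError):
            bandpass(ep, FeatureConfig(band=(8.0, 30.0)))


class TestSpatialFilters:
    def test_variance_contrast_concentrates_on_channel(self):
        # two classes differing only in channel-0 variance: the most
        # discriminative filter must load almost entirely on channel 0
        g = np.random.default_rng(0)
        n, s = 60, 500
        data = g.standard_normal((n, 2, s))
        labels = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        data[labels > 0, 0] *= 3.0
        ep = EpochArray(data, 250.0)
        W = fit_spatial_filters(ep, labels, 2)
        # one end of the eigenvalue spectrum must isolate channel 0
        conc = [(W[0, k] / np.linalg.norm(W[:, k])) ** 2 for k in range(2)]
        assert max(conc) > 0.9

    def test_identical_covariances_chance_eigenvalues(self):
        g = np.random.default_rng(1)
        data = g.standard_normal((40, 3, 400))
        labels = np.r_[np.ones(20), -np.ones(20)]
        ep = EpochArray(data, 250.0)
        import scipy.linalg
        from smmtransfer.features import _trial_covariances
        covs = _trial_covariances(ep.data, 1e-6)
        C1 = covs[labels > 0].mean(0)
        C2 = covs[labels < 0].mean(0)
        evals = scipy.linalg.eigh(C1, C1 + C2, eigvals_only=True)
        assert np.all(np.abs(evals - 0.5) < 0.05)

    def test_permutation_equivariance_up_to_sign(self):
        g = np.random.default_rng(2)
        data = g.standard_normal((40, 3, 300))
        labels = np.r_[np.ones(20), -np.ones(20)]
        data[labels > 0, 1] *= 2.0
        W1 = fit_spatial_filters(EpochArray(data, 250.0), labels, 2)
        perm = [2, 0, 1]
        W2 = fit_spatial_filters(EpochArray(data[:, perm], 250.0), labels, 2)
        for k in range(2):
            a, b = W1[perm, k], W2[:, k]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos > 0.999

    def test_single_class_rejected(self):
        ep = EpochArray(np.zeros((4, 2, 100)), 250.0)
        with pytest.raises(ValueError):
            fit_spatial_filters(ep, np.ones(4), 2)


class TestBandPower:
    def test_variance_scaling_shows_in_first_row(self, cfg):
        # doubling the amplitude of the first filter's source quadruples
        # its variance: the class-mean log-power gap in row 0 is log(4)
        g = np.random.default_rng(3)
        n, s = 200, 500
        data = g.standard_normal((n, 2, s))
        labels = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        data[labels > 0, 0] *= 2.0
        ep = EpochArray(data, 250.0)
        filters = np.eye(2)
        ds = band_power_matrix(ep, filters, cfg, labels)
        X, y = ds.labeled()
        gap = X[y > 0].mean(0) - X[y < 0].mean(0)
        assert np.all(np.abs(gap[0] - np.log(4)) < 0.15)
        assert np.all(np.abs(gap[1]) < 0.1)

    def test_single_window_gives_column_vectors(self):
        ep = EpochArray(np.random.default_rng(0).standard_normal((3, 2, 100)), 250.0)
        ds = band_power_matrix(ep, np.eye(2), FeatureConfig(n_spatial_filters=2,
                                                            n_windows=1))
        assert (ds.p, ds.q) == (2, 1)

    def test_constant_signal_hits_log_floor(self):
        from smmtransfer.features import LOG_FLOOR
        ep = EpochArray(np.ones((1, 2, 100)), 250.0)
        ds = band_power_matrix(ep, np.eye(2), FeatureConfig(n_spatial_filters=2,
                                                            n_windows=2))
        assert np.allclose(ds.trials[0].values, np.log(LOG_FLOOR))

    def test_too_short_segments_rejected(self):
        ep = EpochArray(np.zeros((1, 2, 40)), 250.0)
        with pytest.raises(ValueError):
            band_power_matrix(ep, np.eye(2), FeatureConfig(n_spatial_filters=2,
                                                           n_windows=5))


class TestEndToEnd:
    def test_planted_erd_classified_above_chance(self, cfg):
        # bandpass -> CSP -> band power -> SMM on synthetic ERD data
        ep, labels = synth_eeg(n_trials=200, n_channels=3, effect_size=0.3, seed=0)
        filt = bandpass(ep, cfg)
        tr, te = np.arange(0, 200, 2), np.arange(1, 200, 2)
        W = fit_spatial_filters(EpochArray(filt.data[tr], ep.sfreq), labels[tr], 2)
        d_tr = band_power_matrix(EpochArray(filt.data[tr], ep.sfreq), W, cfg, labels[tr])
        d_te = band_power_matrix(EpochArray(filt.data[te], ep.sfreq), W, cfg, labels[te])
        std = Standardizer().fit(d_tr)
        model = fit(std.transform(d_tr), Hyperparams(C=1.0, tau=0.1))
        Xte, yte = std.transform(d_te).labeled()
        assert np.mean(predict(model, Xte) == yte) > 0.8

    def test_feature_pipeline_deterministic(self, cfg):
        ep, labels = synth_eeg(n_trials=20, n_channels=3, seed=5)
        f1 = bandpass(ep, cfg)
        f2 = bandpass(ep, cfg)
        np.testing.assert_array_equal(f1.data, f2.data)
        W1 = fit_spatial_filters(f1, labels, 2)
        W2 = fit_spatial_filters(f2, labels, 2)
        np.testing.assert_array_equal(W1, W2)


class TestCSVRoundtrip:
    def test_save_load_preserves_trials_and_labels(self, tmp_path):
        g = np.random.default_rng(0)
        from smmtransfer import MatrixDataset
        data = MatrixDataset.from_arrays(g.standard_normal((5, 3, 4)),
                                         np.array([1, -1, 1, -1, 1.0]))
        save_trial_csv_dir(data, tmp_path / "d")
        back = load_trial_csv_dir(tmp_path / "d")
        X1, y1 = data.labeled()
        X2, y2 = back.labeled()
        np.testing.assert_allclose(X2, X1, atol=1e-12)
        np.testing.assert_array_equal(y2, y1)
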