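"""Feature oracles: closed-form OLS on ramps, Parseval for Welch, band powers."""

import numpy as np
import pytest

from mrcpdetect.epochs import Epoch
from mrcpdetect.features import (DEFAULT_BANDS, BandDefinition, band_power,
                                 feature_matrix, spectral_features,
                                 temporal_features, welch_psd)

FS = 500.0
N = 1000


def make_epoch(samples, path="temporal", label="movement"):
    return Epoch(np.asarray(samples, float), label, "f60", 0.0, path, FS)


def ols_line(t, x):
    """Independent closed-form OLS oracle (normal equations)."""
    A = np.vstack([t, np.ones_like(t)]).T
    beta, *_ = np.linalg.lstsq(A, x, rcond=None)
    return beta


class TestTemporalFeatures:
    def test_constant_epoch(self):
        fv = temporal_features(make_epoch(np.full(N, -3.0)), "executed")
        assert tuple(fv.names) == ("t_max_negativity", "mean_amplitude",
                                   "slope_full", "intercept_full",
                                   "slope_last", "intercept_last")
        np.testing.assert_allclose(fv.values, [0.0, -3.0, 0.0, -3.0, 0.0, -3.0],
                                   atol=1e-9)

    def test_linear_ramp_executed_matches_closed_form(self):
        t = np.arange(N) / FS
        x = -5.0 * t                       # 0 -> -10 µV over [0, 2) s
        fv = temporal_features(make_epoch(x), "executed")
        sl_full, ic_full = ols_line(t, x)
        sl_last, ic_last = ols_line(t[-250:], x[-250:])
        np.testing.assert_allclose(
            fv.values,
            [t[-1], x.mean(), sl_full, ic_full, sl_last, ic_last],
            rtol=1e-9, atol=1e-9)
        assert fv.values[2] == pytest.approx(-5.0, abs=1e-9)

    def test_linear_ramp_imagery(self):
        t = np.arange(N) / FS
        x = -5.0 * t
        fv = temporal_features(make_epoch(x), "imagery")
        assert len(fv.values) == 5
        # mean of the ramp over the final 0.5 s on the discrete grid
        assert fv.values[-1] == pytest.approx(x[-250:].mean())
        assert fv.values[-1] == pytest.approx(-8.75, abs=0.01)

    def test_min_tie_broken_to_earliest(self):
        x = np.zeros(N)
        x[[100, 400]] = -1.0
        fv = temporal_features(make_epoch(x), "executed")
        assert fv.values[0] == pytest.approx(100 / FS)

    def test_regression_until_max_negativity_switch(self):
        t = np.arange(N) / FS
        x = np.where(t < 1.0, -10.0 * t, -10.0 + 12.0 * (t - 1.0))
        fv = temporal_features(make_epoch(x), "executed",
                               regression_until="max_negativity")
        i_min = int(np.argmin(x))
        sl, _ = ols_line(t[:i_min + 1], x[:i_min + 1])
        assert fv.values[2] == pytest.approx(sl, rel=1e-9)

    def test_wrong_path_rejected(self):
        with pytest.raises(ValueError):
            temporal_features(make_epoch(np.zeros(N), path="spectral"))

    def test_scaling_and_reversal_properties(self, rng):
        x = rng.standard_normal(N)
        base = temporal_features(make_epoch(x), "executed").values
        scaled = temporal_features(make_epoch(3.0 * x), "executed").values
        assert scaled[0] == base[0]                       # latency unchanged
        np.testing.assert_allclose(scaled[1:], 3.0 * base[1:], rtol=1e-9)
        rev = temporal_features(make_epoch(x[::-1]), "executed").values
        assert rev[2] == pytest.approx(-base[2], rel=1e-6)  # slope flips
        assert rev[1] == pytest.approx(base[1])             # mean preserved


class TestWelch:
    def test_zero_epoch_zero_psd(self):
        _, p = welch_psd(np.zeros(N), FS)
        assert np.all(p == 0.0)

    def test_white_noise_parseval(self, rng):
        # integrated PSD ~ variance; cross-checked with an independent
        # unwindowed periodogram oracle
        x = rng.standard_normal(50 * int(FS))
        f, p = welch_psd(x, FS)
        total = np.trapezoid(p, f)
        assert total == pytest.approx(x.var(), rel=0.10)
        spec = np.abs(np.fft.rfft(x)) ** 2 / (len(x) * FS)
        oracle = 2 * spec.sum() * FS / len(x)  # one-sided integrated power
        assert total == pytest.approx(oracle, rel=0.10)

    def test_sinusoid_peak_location(self):
        t = np.arange(N) / FS
        f, p = welch_psd(np.sin(2 * np.pi * 10 * t), FS)
        assert f[int(np.argmax(p))] == pytest.approx(10.0)

    def test_segment_too_long_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), FS, seg_len=500)


class TestBandPower:
    def test_flat_psd_every_band(self):
        f = np.arange(0.0, 251.0)
        p = np.full_like(f, 2.5)
        for band in DEFAULT_BANDS:
            assert band_power(f, p, band) == pytest.approx(2.5)

    def test_single_bin_hits_one_band(self):
        f = np.arange(0.0, 251.0)
        p = np.zeros_like(f)
        p[10] = 4.0
        powers = [band_power(f, p, b) for b in DEFAULT_BANDS]
        assert powers[2] > 0              # 10 Hz -> alpha (8-13)
        assert powers[0] == powers[1] == powers[3] == powers[4] == 0

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            band_power(np.array([0.0, 50.0]), np.array([1.0, 1.0]),
                       BandDefinition("alpha", 8, 13))

    def test_union_band_between_members(self, rng):
        f = np.arange(0.0, 251.0)
        p = rng.uniform(0.5, 2.0, f.shape)
        a = band_power(f, p, BandDefinition("a", 4, 8))
        b = band_power(f, p, BandDefinition("b", 8, 13))
        u = band_power(f, p, BandDefinition("u", 4, 13))
        assert min(a, b) <= u <= max(a, b)


class TestSpectralFeatures:
    def test_zero_epoch(self):
        fv = spectral_features(make_epoch(np.zeros(N), path="spectral"))
        np.testing.assert_array_equal(fv.values, np.zeros(5))
        assert fv.names == ("delta", "theta", "alpha", "beta", "gamma")

    def test_sinusoid_dominates_alpha_band(self):
        t = np.arange(N) / FS
        fv = spectral_features(make_epoch(np.sin(2 * np.pi * 10 * t),
                                          path="spectral"))
        alpha = fv.values[2]
        for j in (0, 1, 3, 4):
            assert alpha > 10 * fv.values[j]

    def test_white_noise_roughly_flat(self, rng):
        vals = np.mean([spectral_features(
            make_epoch(rng.standard_normal(N), path="spectral")).values
            for _ in range(200)], axis=0)
        assert vals.max() / vals.min() < 1.5

    def test_amplitude_scaling_squares_power(self, rng):
        x = rng.standard_normal(N)
        base = spectral_features(make_epoch(x, path="spectral")).values
        scaled = spectral_features(make_epoch(2.0 * x, path="spectral")).values
        np.testing.assert_allclose(scaled, 4.0 * base, rtol=1e-9)

    def test_mrcp_raises_delta_band(self, real_recording, real_surrogate,
                                    real_onsets):
        from mrcpdetect.epochs import extract_epochs
        tasks = [real_recording.task_labels[i]
                 for i in real_onsets.trial_indices]
        eps = extract_epochs(real_surrogate, real_onsets.onsets, tasks,
                             "spectral")
        X, y = feature_matrix(eps, "spectral")
        assert X[y == 1, 0].mean() > 2 * X[y == 0, 0].mean()
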