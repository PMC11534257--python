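"""Feature definitions, map geometry, and fusion semantics."""

import numpy as np
import pytest

from fatiguefuse.features import (
    ACC_FEATURE_NAMES,
    FeatureConfig,
    amplitude_histogram,
    ar_coefficients,
    basic_time_features,
    build_acc_map,
    build_semg_map,
    fuse_feature_maps,
    mav_slope,
    mdwt_marginals,
    semg_feature_names,
    spectral_features,
    threshold_counts,
)

FS = 2000.0


class TestBasicTimeFeatures:
    def test_waveform_length_example(self):
        assert basic_time_features([0, 1, 3, 2])["WL"] == 4.0

    def test_rms_example(self):
        out = basic_time_features([1, 2, 2, 1])
        assert out["RMS"] == pytest.approx(np.sqrt(10 / 4), abs=1e-12)

    def test_constant_signal(self):
        out = basic_time_features([-3.0, -3.0, -3.0])
        assert out["RMS"] == 3.0 and out["VAR"] == 0.0 and out["WL"] == 0.0
        assert out["MAV"] == 3.0 and out["MEAN"] == -3.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            basic_time_features([1.0])


class TestThresholdCounts:
    def test_zero_crossings(self):
        assert threshold_counts([1, -1, 1, -1])["ZC"] == 3

    def test_willison_amplitude(self):
        assert threshold_counts([0, 2, 0], eps_wamp=1.5)["WAMP"] == 2

    def test_slope_sign_changes(self):
        assert threshold_counts([0, 1, 0, 1])["SSC"] == 2

    def test_thresholds_suppress_counts(self):
        x = [0.1, -0.1, 0.1, -0.1]
        assert threshold_counts(x, eps_zc=0.5)["ZC"] == 0
        assert threshold_counts(x, eps_wamp=0.5)["WAMP"] == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            threshold_counts([1.0, 2.0])


class TestMavSlope:
    def test_two_segment_difference(self):
        assert mav_slope([1, 1, 3, 3])[0] == pytest.approx(2.0)

    def test_antisymmetry(self):
        assert mav_slope([3, 3, 1, 1])[0] == pytest.approx(-2.0)

    def test_constant_signal(self):
        assert mav_slope([2.0] * 10)[0] == 0.0

    def test_multi_segment_length(self):
        assert mav_slope(np.arange(12.0), n_seg=4).shape == (3,)

    def test_nseg_below_two_rejected(self):
        with pytest.raises(ValueError):
            mav_slope([1, 2, 3], n_seg=1)


class TestSpectralFeatures:
    def test_pure_tone_mnf(self):
        t = np.arange(20000) / FS
        out = spectral_features(np.sin(2 * np.pi * 50 * t), FS)
        assert out["MNF"] == pytest.approx(50.0, abs=1.0)
        assert out["PSR"] >= 0.95

    def test_flat_band_noise_mnf_near_band_midpoint(self):
        from scipy import signal as sps

        sos = sps.butter(8, [20, 500], btype="bandpass", fs=FS, output="sos")
        mnfs = []
        for seed in range(50):
            x = sps.sosfiltfilt(sos, np.random.default_rng(seed).standard_normal(20000))
            mnfs.append(spectral_features(x, FS)["MNF"])
        assert np.mean(mnfs) == pytest.approx(260.0, abs=15.0)

    def test_zero_signal_flagged(self):
        with pytest.warns(UserWarning, match="zero-power"):
            out = spectral_features(np.zeros(512), FS)
        assert out == {"MNF": 0.0, "PSR": 0.0}


class TestWaveletMarginals:
    def test_exactly_eight_values(self):
        assert mdwt_marginals(np.random.default_rng(0).standard_normal(2000)).shape == (8,)

    def test_zero_signal(self):
        assert np.all(mdwt_marginals(np.zeros(2000)) == 0.0)

    def test_constant_annihilated_by_details(self):
        c, n = 7.0, 2048
        marg = mdwt_marginals(np.full(n, c))
        assert np.all(marg[1:] <= 1e-8 * c * n)  # vanishing moment

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            mdwt_marginals(np.zeros(64), levels=7)


class TestAmplitudeHistogram:
    def test_length_and_normalization(self):
        h = amplitude_histogram(np.random.default_rng(1).standard_normal(5000))
        assert h.shape == (20,)
        assert float(np.sum(h)) == pytest.approx(1.0, abs=1e-12)

    def test_negation_reverses_bins(self):
        x = np.random.default_rng(2).standard_normal(5000)
        x -= x.mean()
        np.testing.assert_allclose(
            amplitude_histogram(x), amplitude_histogram(-x)[::-1], atol=1e-12
        )

    def test_outliers_clipped_into_end_bins(self):
        x = np.concatenate([np.random.default_rng(3).standard_normal(1000), [50.0]])
        h = amplitude_histogram(x)
        assert float(np.sum(h)) == pytest.approx(1.0, abs=1e-12)


class TestArCoefficients:
    def test_recovers_ar1_pole(self):
        rng = np.random.default_rng(1)
        x = np.zeros(20000)
        eps = rng.standard_normal(20000)
        for i in range(1, 20000):
            x[i] = 0.9 * x[i - 1] + eps[i]
        coefs = ar_coefficients(x, order=5)
        assert coefs.shape == (5,)
        assert coefs[0] == pytest.approx(0.9, abs=0.05)

    def test_white_noise_coefs_near_zero(self):
        x = np.random.default_rng(4).standard_normal(20000)
        assert np.all(np.abs(ar_coefficients(x)) < 0.05)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ar_coefficients(np.full(1000, 2.0))


class TestMapBuilders:
    def test_semg_map_geometry(self, semg_epoch):
        fmap = build_semg_map(semg_epoch)
        assert fmap.shape == (6, 42)
        assert len(set(fmap.columns)) == 42

    def test_semg_map_matches_independent_recomputation(self, semg_epoch):
        """Each row equals the features recomputed one by one (oracle)."""
        config = FeatureConfig()
        fmap = build_semg_map(semg_epoch, config)
        ch = semg_epoch.samples[2]
        frame = fmap.to_frame().iloc[2]
        basic = basic_time_features(ch)
        counts = threshold_counts(ch, eps_wamp=0.1 * float(np.std(ch)))
        spec = spectral_features(ch, FS)
        assert frame["RMS"] == pytest.approx(basic["RMS"], rel=1e-12)
        assert frame["WL"] == pytest.approx(basic["WL"], rel=1e-12)
        assert frame["MAV"] == pytest.approx(basic["MAV"], rel=1e-12)
        assert frame["ZC"] == counts["ZC"] and frame["WAMP"] == counts["WAMP"]
        assert frame["MNF"] == pytest.approx(spec["MNF"], rel=1e-12)
        assert frame["MAVS"] == pytest.approx(mav_slope(ch)[0], rel=1e-12)
        np.testing.assert_allclose(
            frame[["mDWT_cA7"] + [f"mDWT_cD{k}" for k in range(7, 0, -1)]].to_numpy(),
            mdwt_marginals(ch),
        )
        np.testing.assert_allclose(
            frame[[f"ARC_{i+1}" for i in range(5)]].to_numpy(), ar_coefficients(ch)
        )

    def test_identical_channels_give_identical_rows(self, semg_epoch):
        x = np.tile(semg_epoch.samples[0], (6, 1))
        fmap = build_semg_map(x)
        for row in fmap.values[1:]:
            np.testing.assert_array_equal(row, fmap.values[0])

    def test_acc_map_geometry(self, acc_epoch):
        fmap = build_acc_map(acc_epoch)
        assert fmap.shape == (18, 6)
        assert fmap.columns == ACC_FEATURE_NAMES

    def test_acc_constant_channel_row(self):
        x = np.full((18, 200), 3.0)
        x[0] = -2.0
        fmap = build_acc_map(x)
        np.testing.assert_allclose(fmap.values[0], [-2.0, 0.0, 2.0, 0.0, 2.0, 0.0])
        np.testing.assert_allclose(fmap.values[1], [3.0, 0.0, 3.0, 0.0, 3.0, 0.0])

    def test_acc_zero_channel_row(self):
        fmap = build_acc_map(np.zeros((18, 200)))
        assert np.all(fmap.values == 0.0)

    def test_wrong_channel_count_rejected(self, semg_epoch):
        with pytest.raises(ValueError, match="channel"):
            build_semg_map(semg_epoch.samples[:5])
        with pytest.raises(ValueError, match="channel"):
            build_acc_map(np.zeros((6, 200)))


class TestFusion:
    def test_fused_geometry_and_content(self, semg_epoch, acc_epoch):
        semg_map = build_semg_map(semg_epoch)
        acc_map = build_acc_map(acc_epoch)
        fused = fuse_feature_maps(semg_map, acc_map)
        assert fused.shape == (6, 60)
        np.testing.assert_array_equal(fused.values[:, :42], semg_map.values)
        for i in range(6):
            for j in range(18):
                assert fused.values[i, 42 + j] == acc_map.values[j, i]

    def test_shape_mismatch_rejected(self, semg_epoch, acc_epoch):
        semg_map = build_semg_map(semg_epoch)
        acc_map = build_acc_map(acc_epoch)
        with pytest.raises(ValueError):
            fuse_feature_maps(acc_map, semg_map)


class TestScaleBehavior:
    """Amplitude-scaling contracts of the suite."""

    def test_linear_features_scale_linearly(self, semg_epoch):
        ch = semg_epoch.samples[0]
        a, b = basic_time_features(ch), basic_time_features(2.5 * ch)
        for key in ("RMS", "MAV", "WL"):
            assert b[key] == pytest.approx(2.5 * a[key], rel=1e-9)
        assert mav_slope(2.5 * ch)[0] == pytest.approx(2.5 * mav_slope(ch)[0], rel=1e-9)

    def test_scale_invariant_features(self, semg_epoch):
        ch = semg_epoch.samples[0]
        s1, s2 = spectral_features(ch, FS), spectral_features(4.0 * ch, FS)
        assert s2["MNF"] == pytest.approx(s1["MNF"], rel=1e-9)
        assert s2["PSR"] == pytest.approx(s1["PSR"], rel=1e-9)
        assert threshold_counts(4.0 * ch)["ZC"] == threshold_counts(ch)["ZC"]
        np.testing.assert_allclose(
            amplitude_histogram(4.0 * ch), amplitude_histogram(ch), atol=1e-12
        )

    def test_feature_name_order_is_documented_constant(self):
        names = semg_feature_names()
        assert len(names) == 42
        assert names[0] == "mDWT_cA7" and names[8] == "HIST_01"
        assert names[28:35] == ["RMS", "ZC", "SSC", "WL", "MAV", "MAVS", "WAMP"]
        assert names[-2:] == ["MNF", "PSR"]
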