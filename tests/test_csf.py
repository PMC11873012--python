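import numpy as np
import pytest
from scipy import stats

from ratvision.csf import (
    CSFCurve,
    GratingSpec,
    PsychometricCurve,
    compute_csf,
    contrast_threshold,
    detection_probability,
    fit_csf,
    make_grating,
    patch_contrasts,
    peak_frequency,
    psychometric_curve,
    rat_csf_standin,
    train_detection_observer,
)
from ratvision.geometry import NoiseBlurParams, ViewingGeometry


class TestMakeGrating:
    def test_zero_contrast_is_uniform_gray(self, geom):
        img = make_grating(GratingSpec(nu=0.1, contrast=0.0), geom)
        np.testing.assert_allclose(img, 0.5)

    def test_full_contrast_spans_unit_range(self, geom):
        img = make_grating(GratingSpec(nu=0.2, contrast=1.0), geom)
        assert img.min() == pytest.approx(0.0, abs=0.01)
        assert img.max() == pytest.approx(1.0, abs=0.01)

    def test_spatial_period(self, geom):
        # nu = 0.5 cyc/deg at ppd 2.333 -> period ~ 4.67 px
        img = make_grating(GratingSpec(nu=0.5, contrast=1.0), geom)
        row = img[0] - 0.5
        spectrum = np.abs(np.fft.rfft(row))
        peak_cycles = np.argmax(spectrum[1:]) + 1
        period = geom.res_w / peak_cycles
        assert period == pytest.approx(geom.ppd / 0.5, rel=0.05)

    def test_above_nyquist_rejected(self, geom):
        with pytest.raises(ValueError, match="Nyquist"):
            make_grating(GratingSpec(nu=2.0, contrast=0.5), geom)


class TestPatchContrasts:
    def test_uniform_image_zero(self):
        assert np.all(patch_contrasts(np.full((224, 224), 0.5), 28) == 0)

    def test_feature_count(self):
        feats = patch_contrasts(np.random.default_rng(0).random((224, 224)), 28)
        assert feats.shape == (64,)

    def test_two_level_tiles(self):
        img = np.tile(np.array([[0.4, 0.6]]), (28, 28 * 4))[:28, : 28 * 2]
        feats = patch_contrasts(img, 28)
        np.testing.assert_allclose(feats, 0.1, atol=1e-12)

    def test_oversize_patch_rejected(self):
        with pytest.raises(ValueError):
            patch_contrasts(np.zeros((16, 16)), 32)


class TestContrastThreshold:
    def test_log_interpolation(self):
        curve = PsychometricCurve([0.1, 0.4], [0.2, 0.8], [0, 0])
        assert contrast_threshold(curve) == pytest.approx(0.2, rel=1e-6)

    def test_always_above_criterion(self):
        curve = PsychometricCurve([0.01, 0.1, 1.0], [0.95, 0.9, 0.99], [0, 0, 0])
        assert contrast_threshold(curve) == 0.01

    def test_never_reaches_criterion(self):
        curve = PsychometricCurve([0.01, 0.1, 1.0], [0.1, 0.2, 0.4], [0, 0, 0])
        assert contrast_threshold(curve) == np.inf

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            contrast_threshold(PsychometricCurve([], [], []))


@pytest.fixture(scope="module")
def small_geom():
    """Coarse display for fast detector runs (same degrees-per-pixel)."""
    return ViewingGeometry(res_w=112, res_h=112, ppd=224.0 / 96.0)


@pytest.fixture(scope="module")
def easy_detector(small_geom):
    rng = np.random.default_rng(0)
    return train_detection_observer(
        0.2, NoiseBlurParams(0.0, 0.02), 28, 400, rng, geom=small_geom
    )


class TestDetectionObserver:
    def test_easy_contrast_detected(self, easy_detector):
        rng = np.random.default_rng(1)
        p, _ = detection_probability(easy_detector, 1.0, 200, 1, rng)
        assert p >= 0.99

    def test_monotone_in_contrast(self, easy_detector):
        rng = np.random.default_rng(2)
        curve = psychometric_curve(easy_detector, n_trials=100, n_reps=1, rng=rng)
        rho = stats.spearmanr(curve.contrasts, curve.p_detect).statistic
        assert rho > 0

    def test_zero_contrast_near_false_alarm_rate(self, easy_detector):
        rng = np.random.default_rng(3)
        p, _ = detection_probability(easy_detector, 0.0, 400, 1, rng)
        assert abs(p - easy_detector.fa_rate) < 0.1

    def test_deterministic_given_seed(self, small_geom):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            det = train_detection_observer(
                0.2, NoiseBlurParams(0.5, 0.1), 28, 200, rng, geom=small_geom
            )
            imgs = det.bank.sample(np.full(50, 0.3), 0.1, rng, det.noise_pool)
            outs.append(det.detect(imgs))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_shuffled_labels_give_chance(self, small_geom):
        """A linear readout of patch contrasts with permuted labels is at chance."""
        from sklearn.svm import LinearSVC

        rng = np.random.default_rng(4)
        det = train_detection_observer(
            0.2, NoiseBlurParams(0.0, 0.1), 28, 600, rng, geom=small_geom
        )
        imgs = det.bank.sample(np.full(2000, 0.8), 0.1, rng, det.noise_pool)
        X = patch_contrasts(imgs, 28)
        y = rng.integers(0, 2, size=2000)  # labels independent of the images
        svm = LinearSVC(C=1.0, tol=1e-4, random_state=0).fit(X[:1000], y[:1000])
        acc = (svm.predict(X[1000:]) == y[1000:]).mean()
        assert abs(acc - 0.5) < 0.05


class TestCSF:
    def test_reciprocal_and_zero_rules(self):
        # direct check of the sensitivity = 1/threshold convention
        curve = PsychometricCurve([0.1, 0.4], [0.2, 0.8], [0, 0])
        assert 1.0 / contrast_threshold(curve) == pytest.approx(5.0, rel=1e-6)

    def test_extreme_blur_kills_high_frequencies(self, small_geom):
        rng = np.random.default_rng(5)
        csf = compute_csf(
            NoiseBlurParams(8.0, 0.1), 28, np.array([0.1, 1.0]),
            rng=rng, geom=small_geom, n_per_class=300, n_trials=60, n_reps=1,
        )
        assert csf.sensitivity[1] == 0.0

    def test_sensitivity_non_increasing_in_noise(self, small_geom):
        rng = np.random.default_rng(9)
        sens = []
        for sn in (0.05, 0.2, 0.45):
            csf = compute_csf(
                NoiseBlurParams(1.0, sn), 28, np.array([0.2]),
                rng=rng, geom=small_geom, n_per_class=400, n_trials=100, n_reps=2,
            )
            sens.append(csf.sensitivity[0])
        # allow a little sampling error on each threshold estimate
        assert sens[1] <= sens[0] * 1.1
        assert sens[2] <= sens[1] * 1.1

    def test_single_cell_fit(self, small_geom):
        rng = np.random.default_rng(6)
        target = rat_csf_standin(np.array([0.1, 0.3]))
        fit = fit_csf(
            target, [1.0], [0.2], [28], rng, geom=small_geom,
            n_per_class=200, n_trials=40, n_reps=1,
        )
        assert (fit.sigma_blur, fit.sigma_noise, fit.patch_size) == (1.0, 0.2, 28)
        assert fit.landscape.min() == fit.l1


class TestRatCSFStandin:
    def test_peak_location(self):
        nus = np.geomspace(0.03, 1.2, 200)
        curve = rat_csf_standin(nus)
        assert curve.nus[np.argmax(curve.sensitivity)] == pytest.approx(0.1, rel=0.02)

    def test_zeros_at_band_edges(self):
        curve = rat_csf_standin(np.array([0.04, 0.1, 1.0]))
        assert curve.sensitivity[0] == 0.0
        assert curve.sensitivity[2] == 0.0
        assert curve.sensitivity[1] == pytest.approx(20.0)

    def test_unimodal_on_log_axis(self):
        curve = rat_csf_standin(np.geomspace(0.04, 1.0, 50))
        s = curve.sensitivity
        k = int(np.argmax(s))
        assert np.all(np.diff(s[: k + 1]) >= 0) and np.all(np.diff(s[k:]) <= 0)


class TestPeakFrequency:
    def test_parabolic_curve_recovered(self):
        nus = np.geomspace(0.04, 1.0, 9)
        s = 20 - 30 * (np.log10(nus) - np.log10(0.12)) ** 2
        peak = peak_frequency(CSFCurve(nus, np.clip(s, 0, None)))
        assert peak == pytest.approx(0.12, rel=0.05)

    def test_degenerate_curve_falls_back_to_argmax(self):
        curve = CSFCurve(np.array([0.05, 0.1, 0.2]), np.array([0.0, 3.0, 0.0]))
        assert peak_frequency(curve) == 0.1
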