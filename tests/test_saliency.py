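import numpy as np
import pytest

from ratvision.saliency import (
    BubbleMaskSpec,
    IdealObserver,
    MaskedTrialSet,
    apply_mask,
    area_matched_threshold,
    bubble_sigma_px,
    bubbles_saliency,
    ideal_observer_classify,
    make_bubble_mask,
    permutation_significance_bubbles,
    permutation_significance_tripod,
    top_area_region,
    tripod_saliency,
    FWHM_PER_SIGMA,
)


class TestBubbleMasks:
    def test_no_bubbles_no_transparency(self, rng):
        spec = BubbleMaskSpec(n_bubbles=0)
        assert np.all(make_bubble_mask(spec, (64, 64), rng) == 0.0)

    def test_values_clipped_to_unit_interval(self, rng):
        spec = BubbleMaskSpec(n_bubbles=200, sigma_px=6.0)
        m = make_bubble_mask(spec, (64, 64), rng)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_coverage_increases_with_bubble_count(self):
        rng = np.random.default_rng(3)
        means = []
        for nb in (10, 30, 50, 70, 90):
            masks = make_bubble_mask(
                BubbleMaskSpec(n_bubbles=nb), (224, 224), rng, n_masks=200
            )
            means.append(masks.mean())
        assert np.all(np.diff(means) > 0)

    def test_single_bubble_fwhm_matches_two_degrees(self, geom):
        spec = BubbleMaskSpec(n_bubbles=1, sigma_px=bubble_sigma_px(2.0, geom.ppd),
                              region_fraction=0.01)
        rng = np.random.default_rng(0)
        m = make_bubble_mask(spec, (224, 224), rng)
        # estimate sigma from the rendered profile's second moment
        yy, xx = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
        total = m.sum()
        cy = (m * yy).sum() / total
        cx = (m * xx).sum() / total
        var = (m * ((yy - cy) ** 2 + (xx - cx) ** 2)).sum() / total / 2.0
        fwhm = FWHM_PER_SIGMA * np.sqrt(var)
        assert fwhm == pytest.approx(2.0 * geom.ppd, rel=0.05)

    def test_centers_confined_to_central_region(self):
        rng = np.random.default_rng(1)
        spec = BubbleMaskSpec(n_bubbles=40, region_fraction=0.5)
        masks = make_bubble_mask(spec, (128, 128), rng, n_masks=50)
        border = np.concatenate(
            [masks[:, :20, :].ravel(), masks[:, -20:, :].ravel(),
             masks[:, :, :20].ravel(), masks[:, :, -20:].ravel()]
        )
        assert border.max() < 0.5  # only Gaussian tails reach the border


class TestApplyMask:
    def test_transparent_and_opaque(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(apply_mask(img, np.ones_like(img)), img)
        assert np.all(apply_mask(img, np.zeros_like(img)) == 0.0)

    def test_alpha_blend_value(self):
        assert apply_mask(np.array([[0.8]]), np.array([[0.5]]))[0, 0] == pytest.approx(0.4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_mask(np.zeros((4, 4)), np.zeros((5, 5)))


class TestBubblesSaliency:
    def test_all_correct_gives_one_on_covered_pixels(self, rng):
        masks = make_bubble_mask(BubbleMaskSpec(), (64, 64), rng, n_masks=20)
        S = bubbles_saliency(MaskedTrialSet(masks, np.ones(20)))
        covered = np.isfinite(S)
        np.testing.assert_allclose(S[covered], 1.0)

    def test_all_wrong_gives_zero(self, rng):
        masks = make_bubble_mask(BubbleMaskSpec(), (64, 64), rng, n_masks=20)
        S = bubbles_saliency(MaskedTrialSet(masks, np.zeros(20)))
        covered = np.isfinite(S)
        np.testing.assert_allclose(S[covered], 0.0)

    def test_two_trial_hand_example(self):
        masks = np.array([[[1.0]], [[0.5]]])
        S = bubbles_saliency(MaskedTrialSet(masks, np.array([1, 0])))
        assert S[0, 0] == pytest.approx(1.0 / 1.5)

    def test_duplication_invariance(self, rng):
        masks = make_bubble_mask(BubbleMaskSpec(), (32, 32), rng, n_masks=30)
        labels = rng.integers(0, 2, 30)
        S1 = bubbles_saliency(MaskedTrialSet(masks, labels))
        S2 = bubbles_saliency(
            MaskedTrialSet(np.concatenate([masks, masks]), np.concatenate([labels] * 2))
        )
        # identical up to float32 accumulation order
        np.testing.assert_allclose(S1, S2, rtol=1e-4, atol=1e-6, equal_nan=True)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            bubbles_saliency(MaskedTrialSet(np.zeros((0, 4, 4)), np.zeros(0)))


class TestBubblesPermutationTest:
    def test_single_label_rejected(self, rng):
        masks = make_bubble_mask(BubbleMaskSpec(), (32, 32), rng, n_masks=10)
        with pytest.raises(ValueError):
            permutation_significance_bubbles(MaskedTrialSet(masks, np.ones(10)), 50, rng=rng)

    def test_disjoint_significance_masks(self, rng):
        masks = make_bubble_mask(BubbleMaskSpec(), (64, 64), rng, n_masks=120)
        labels = rng.integers(0, 2, 120)
        smap = permutation_significance_bubbles(
            MaskedTrialSet(masks, labels), 200, 0.05, rng
        )
        assert not np.any(smap.sig_salient & smap.sig_antisalient)


class TestAreaMatchedThreshold:
    @pytest.fixture(scope="class")
    def random_trials(self):
        rng = np.random.default_rng(4)
        masks = make_bubble_mask(BubbleMaskSpec(), (64, 64), rng, n_masks=200)
        labels = rng.integers(0, 2, 200)
        smap, null = permutation_significance_bubbles(
            MaskedTrialSet(masks, labels), 400, 0.05, rng, return_null=True
        )
        return smap, null

    def test_zero_target_gives_empty_region(self, random_trials):
        smap, null = random_trials
        out = area_matched_threshold(smap.S, null, 0)
        assert out.sig_salient.sum() == 0

    def test_recovers_nominal_threshold_area(self, random_trials):
        smap, null = random_trials
        target = int(smap.sig_salient.sum())
        out = area_matched_threshold(smap.S, null, target)
        assert abs(int(out.sig_salient.sum()) - target) <= 1
        assert out.p_threshold == pytest.approx(0.05, abs=0.02)

    def test_area_met_within_one_pixel(self, random_trials):
        smap, null = random_trials
        out = area_matched_threshold(smap.S, null, 150)
        assert abs(int(out.sig_salient.sum()) - 150) <= 1

    def test_unreachable_target_reports_range(self, random_trials):
        smap, null = random_trials
        with pytest.raises(ValueError, match="achievable range"):
            area_matched_threshold(smap.S, null, smap.S.size)

    def test_top_area_region_size(self, random_trials):
        smap, null = random_trials
        region = top_area_region(smap.S, null, 40)
        assert region.sum() == 40


class TestIdealObserver:
    @pytest.fixture(scope="class")
    def observer(self):
        rng = np.random.default_rng(5)
        templates = rng.random((6, 16, 16))
        labels = np.array([0, 0, 0, 1, 1, 1])
        return IdealObserver(templates, labels)

    def test_own_template_recovered(self, observer):
        assert ideal_observer_classify(observer.templates[4], observer) == 1

    def test_exact_tie_breaks_to_lower_index(self):
        t = np.stack([np.ones((4, 4)), np.ones((4, 4))])
        obs = IdealObserver(t, np.array([7, 3]))
        assert ideal_observer_classify(np.ones((4, 4)), obs) == 7

    def test_occluded_inputs_match_brute_force(self, observer, rng):
        for _ in range(20):
            img = observer.templates[rng.integers(6)].copy()
            img[:, : rng.integers(4, 12)] = 0.0
            scores = [float(np.dot(t.ravel(), img.ravel())) for t in observer.templates]
            expected = observer.labels[int(np.argmax(scores))]
            assert ideal_observer_classify(img, observer) == expected

    def test_shape_mismatch_rejected(self, observer):
        with pytest.raises(ValueError):
            ideal_observer_classify(np.zeros((3, 3)), observer)


class TestTripodSaliency:
    def test_singleton_classes(self):
        t1 = np.full((8, 8), 0.9)
        t0 = np.full((8, 8), 0.2)
        S = tripod_saliency(MaskedTrialSet(np.stack([t1, t0]), np.array([1, 0])))
        np.testing.assert_allclose(S, t1 - t0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tripod_saliency(MaskedTrialSet(np.zeros((3, 4, 4)), np.ones(3)))

    def test_independent_choices_give_null_map(self):
        rng = np.random.default_rng(6)
        imgs = rng.random((600, 16, 16))
        r = rng.integers(0, 2, 600)
        S = tripod_saliency(MaskedTrialSet(imgs, r))
        n1, n0 = r.sum(), (1 - r).sum()
        se = np.sqrt(1.0 / 12.0) * np.sqrt(1 / n1 + 1 / n0)
        assert np.abs(S).max() < 5 * se  # no pixel wildly off the null


class TestTripodPermutationTest:
    def test_zero_variance_pixels_left_nonsignificant(self):
        rng = np.random.default_rng(7)
        imgs = rng.random((100, 8, 8))
        imgs[:, 0, 0] = 0.7  # constant pixel -> zero null variance
        r = rng.integers(0, 2, 100)
        smap = permutation_significance_tripod(MaskedTrialSet(imgs, r), 50, 0.05, rng)
        assert not smap.sig_salient[0, 0] and not smap.sig_antisalient[0, 0]

    def test_disjoint_masks(self):
        rng = np.random.default_rng(8)
        imgs = rng.random((200, 12, 12))
        r = rng.integers(0, 2, 200)
        smap = permutation_significance_tripod(MaskedTrialSet(imgs, r), 60, 0.05, rng)
        assert not np.any(smap.sig_salient & smap.sig_antisalient)
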