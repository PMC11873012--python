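import numpy as np
import pandas as pd
import pytest

from ratvision.networks import SyntheticDeepNet
from ratvision.readout import (
    AccuracyMatrix,
    compare_l1,
    compare_pearson,
    evaluate,
    extrema_histogram,
    pixel_baseline,
    train_readout,
    zscore,
)


def _matrix(values, rows=("a", "b"), cols=(1, 2)):
    idx = pd.MultiIndex.from_product([rows, cols], names=["r", "c"])
    return AccuracyMatrix(pd.Series(np.asarray(values, float).ravel(), index=idx))


class TestZscore:
    def test_closed_form(self):
        train = np.array([[1.0], [2.0], [3.0]])
        z, _, kept = zscore(train)
        np.testing.assert_allclose(z.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert list(kept) == [0]

    def test_constant_column_dropped(self):
        train = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        z, _, kept = zscore(train)
        assert z.shape[1] == 1 and list(kept) == [0]

    def test_test_set_uses_train_statistics(self):
        train = np.array([[0.0], [2.0]])
        _, zt, _ = zscore(train, np.array([[1.0]]))
        assert zt[0, 0] == pytest.approx(0.0)

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.ones((4, 3)))


class TestTrainReadout:
    def test_separable_clusters(self, rng):
        n = 500
        x0 = rng.normal(-3.0, 1.0, size=(n, 10))
        x1 = rng.normal(3.0, 1.0, size=(n, 10))
        X = np.vstack([x0, x1])
        y = np.repeat([0, 1], n)
        svm = train_readout(X[::2], y[::2])
        assert (svm.predict(X[1::2]) == y[1::2]).mean() >= 0.99

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(4000, 10))
        y = rng.integers(0, 2, size=4000)
        svm = train_readout(X[:2000], y[:2000])
        acc = (svm.predict(X[2000:]) == y[2000:]).mean()
        assert abs(acc - 0.5) < 0.03

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_readout(rng.normal(size=(10, 3)), np.zeros(10))


class TestEvaluate:
    def _conds(self, n):
        return pd.DataFrame({"size": np.tile([10, 20], n // 2), "az": 0})

    def test_perfect_classifier(self, rng):
        X = np.vstack([rng.normal(-4, 0.1, (20, 3)), rng.normal(4, 0.1, (20, 3))])
        y = np.repeat([0, 1], 20)
        svm = train_readout(X, y)
        acc = evaluate(svm, X, y, self._conds(40))
        assert np.all(acc.values == 1.0)

    def test_overall_is_trial_weighted_mean(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        svm = train_readout(X, y)
        conds = self._conds(40)
        acc = evaluate(svm, X, y, conds)
        counts = conds.groupby(["size", "az"]).size()
        expected = (svm.predict(X) == y).mean()
        assert acc.overall(counts) == pytest.approx(expected)


class TestComparisons:
    def test_l1_identity_offset_symmetry(self):
        a = _matrix([[0.5, 0.6], [0.7, 0.8]])
        b = _matrix([[0.6, 0.7], [0.8, 0.9]])
        assert compare_l1(a, a) == 0.0
        assert compare_l1(a, b) == pytest.approx(0.1)
        assert compare_l1(a, b) == compare_l1(b, a)

    def test_pearson_affine_invariance(self):
        a = _matrix([[0.5, 0.6], [0.7, 0.8]])
        b = AccuracyMatrix(0.5 * a.cells + 0.1)
        neg = AccuracyMatrix(1.0 - a.cells)
        assert compare_pearson(a, a) == pytest.approx(1.0)
        assert compare_pearson(a, b) == pytest.approx(1.0)
        assert compare_pearson(a, neg) == pytest.approx(-1.0)

    def test_pearson_hand_computed_example(self):
        # 3x3 pattern; r computed by hand from sums:
        # x=(.1..9), y=(.2,.1,.4,.3,.6,.5,.8,.7,.9) -> r = 0.9333333
        idx = pd.MultiIndex.from_product([[0, 1, 2], [0, 1, 2]])
        x = AccuracyMatrix(pd.Series(np.arange(0.1, 1.0, 0.1), index=idx))
        y = AccuracyMatrix(
            pd.Series([0.2, 0.1, 0.4, 0.3, 0.6, 0.5, 0.8, 0.7, 0.9], index=idx)
        )
        assert compare_pearson(x, y) == pytest.approx(14.0 / 15.0, abs=1e-9)

    def test_constant_pattern_rejected(self):
        a = _matrix([[0.5, 0.5], [0.5, 0.5]])
        b = _matrix([[0.5, 0.6], [0.7, 0.8]])
        with pytest.raises(ValueError):
            compare_pearson(a, b)

    def test_mismatched_cells_rejected(self):
        a = _matrix([[0.5, 0.6], [0.7, 0.8]])
        b = _matrix([[0.5, 0.6], [0.7, 0.8]], rows=("a", "z"))
        with pytest.raises(ValueError):
            compare_l1(a, b)


class TestExtremaHistogram:
    def test_single_curve_unique_min(self):
        curve = np.array([[5, 4, 1, 2, 3, 4, 5, 6, 7]], dtype=float)
        hist = extrema_histogram(curve, "min")
        assert hist[2] == 1 and hist.sum() == 1

    def test_conservation_over_runs_and_scales(self, rng):
        curves = rng.random((25, 16))
        assert extrema_histogram(curves, "max").sum() == 25

    def test_tie_breaks_toward_shallower_layer(self):
        curve = np.array([[3.0, 1.0, 2.0, 1.0]])
        assert extrema_histogram(curve, "min")[1] == 1


class TestPixelBaseline:
    def test_luminance_difference_easily_read(self, rng):
        bright = np.clip(rng.random((50, 16, 16)) + 0.5, 0, 1)
        dark = rng.random((50, 16, 16)) * 0.4
        X = np.concatenate([bright, dark])
        y = np.repeat([0, 1], 50)
        conds = pd.DataFrame({"view": np.zeros(100, dtype=int)})
        acc = pixel_baseline(X, y, X, y, conds)
        assert acc.overall() > 0.9

    def test_identical_stimuli_at_chance(self, rng):
        X = np.tile(rng.random((1, 12, 12)), (200, 1, 1))
        X = X + rng.normal(0, 1e-3, X.shape)  # break exact degeneracy
        y = rng.integers(0, 2, 200)
        conds = pd.DataFrame({"view": np.zeros(200, dtype=int)})
        acc = pixel_baseline(X[:100], y[:100], X[100:], y[100:], conds)
        assert abs(acc.overall() - 0.5) < 0.15

    def test_output_contract(self, rng):
        X = rng.random((40, 8, 8))
        y = rng.integers(0, 2, 40)
        conds = pd.DataFrame({"size": np.tile([1, 2], 20)})
        acc = pixel_baseline(X, y, X, y, conds)
        assert isinstance(acc, AccuracyMatrix)
        assert set(acc.cells.index) == {1, 2}


class TestDepthTrend:
    def test_pearson_against_smooth_reference_increases_with_depth(self, rng):
        """Linear decodability of identity rises with layer SNR, so the match
        to a smooth reference accuracy pattern improves with depth."""
        net = SyntheticDeepNet(input_dim=64, n_units=120, depth=6,
                               snr=np.geomspace(0.02, 1.5, 6), seed=1)
        # two "objects" at graded difficulty levels
        levels = np.linspace(0.3, 1.5, 4)
        proto = rng.normal(size=(2, 64))
        def draw(n):
            labels = rng.integers(0, 2, n)
            lv = rng.integers(0, len(levels), n)
            X = proto[labels] * levels[lv, None] + rng.normal(size=(n, 64))
            return X, labels, pd.DataFrame({"level": levels[lv]})
        Xtr, ytr, _ = draw(600)
        Xte, yte, conds = draw(600)
        reference = AccuracyMatrix(
            pd.Series(np.linspace(0.55, 0.95, 4), index=pd.Index(levels, name="level"))
        )
        rs = []
        for l in range(1, 7):
            ztr, zte, _ = zscore(net.forward(Xtr, l), net.forward(Xte, l))
            svm = train_readout(ztr, ytr)
            acc = evaluate(svm, zte, yte, conds)
            rs.append(compare_pearson(reference, acc))
        from scipy import stats as sstats

        rho = sstats.spearmanr(np.arange(6), rs).statistic
        assert rho > 0

    def test_no_leakage_train_vs_test(self, rng):
        net = SyntheticDeepNet(input_dim=32, n_units=64, depth=3, seed=2)
        proto = rng.normal(size=(2, 32))
        ytr = rng.integers(0, 2, 300)
        yte = rng.integers(0, 2, 300)
        Xtr = proto[ytr] + rng.normal(size=(300, 32)) * 2.0
        Xte = proto[yte] + rng.normal(size=(300, 32)) * 2.0
        ztr, zte, _ = zscore(net.forward(Xtr, 3), net.forward(Xte, 3))
        svm = train_readout(ztr, ytr)
        assert (svm.predict(ztr) == ytr).mean() >= (svm.predict(zte) == yte).mean()
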