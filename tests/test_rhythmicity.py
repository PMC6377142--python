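import numpy as np
import pytest

from dyde.data_model import AnalysisConfig, ExpressionDataset, detrend
from dyde.rhythmicity import (
    LogisticModel,
    PseudoSine,
    RhythmFeatures,
    classify,
    compute_features,
    compute_features_with_fit,
    fit_pseudo_sine,
    periodogram,
    pseudo_sine_eval,
    rhythm_screen,
    train_classifier,
)
from dyde.synthetic import make_labeled_series


class TestPseudoSineEval:
    def test_zero_at_origin(self):
        for p1, p2 in ((12, 36), (20, 28), (24, 24)):
            p = PseudoSine(A=1.0, phi1=0.0, p1=p1, p2=p2)
            assert pseudo_sine_eval(p, np.array([0.0]))[0] == pytest.approx(0.0)

    def test_degenerate_pure_sinusoid(self):
        t = np.linspace(0, 96, 200)
        p = PseudoSine(A=2.0, phi1=0.0, p1=24.0, p2=24.0)
        np.testing.assert_allclose(pseudo_sine_eval(p, t), 2 * np.sin(2 * np.pi * t / 24),
                                   atol=1e-12)

    def test_junction_continuity_branch_formulas(self):
        # evaluate both branch formulas exactly at t = p1/2
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.uniform(0.1, 3.0)
            phi = rng.uniform(0, 2 * np.pi)
            p1 = rng.uniform(12, 36)
            p2 = rng.uniform(12, 36)
            first = A * np.sin(2 * np.pi / p1 * (p1 / 2) + phi)
            second = A * np.sin(2 * np.pi / p2 * (p1 / 2 - p1 / 2 + p2 / 2) + phi)
            assert abs(first - second) < 1e-12

    def test_periodic_with_mean_period(self):
        p = PseudoSine(A=1.3, phi1=0.7, p1=20.0, p2=28.0)
        t = np.linspace(0, 24, 97)
        np.testing.assert_allclose(pseudo_sine_eval(p, t),
                                   pseudo_sine_eval(p, t + p.period), atol=1e-9)

    def test_invalid_periods(self):
        with pytest.raises(ValueError):
            PseudoSine(A=1.0, phi1=0.0, p1=-1.0, p2=24.0)

    def test_period_definition(self):
        p = PseudoSine(A=1.0, phi1=0.0, p1=20.0, p2=28.0)
        assert p.period == (20.0 + 28.0) / 2.0


class TestFitPseudoSine:
    def test_grid_round_trip(self, cfg):
        t = np.arange(0.0, 48.1, 4.0)
        gen = pseudo_sine_eval(PseudoSine(A=1.0, phi1=0.0, p1=20.0, p2=28.0), t)
        fit = fit_pseudo_sine(gen, t, cfg)
        assert fit.params.p1 == pytest.approx(20.0)
        assert fit.params.p2 == pytest.approx(28.0)
        assert fit.params.period == pytest.approx(24.0)
        assert fit.l2_error < 1e-6

    def test_pure_sinusoid_gets_equal_periods(self, cfg, times12):
        y = 3.0 * np.sin(2 * np.pi * times12 / 24.0 + 0.5)
        fit = fit_pseudo_sine(y, times12, cfg)
        assert fit.params.p1 == pytest.approx(24.0)
        assert fit.params.p2 == pytest.approx(24.0)
        assert fit.l2_error < 1e-6

    def test_all_zero_series(self, cfg, times12):
        fit = fit_pseudo_sine(np.zeros(12), times12, cfg)
        assert fit.params.A == 0.0
        assert fit.l2_error == 0.0

    def test_too_few_points(self, cfg):
        with pytest.raises(ValueError, match=">=6"):
            fit_pseudo_sine(np.ones(5), 4.0 * np.arange(5), cfg)

    def test_period_within_search_range(self, cfg, times12):
        rng = np.random.default_rng(4)
        for _ in range(10):
            fit = fit_pseudo_sine(rng.normal(size=12), times12, cfg)
            lo, hi = cfg.period_range
            assert lo <= fit.params.p1 <= hi
            assert lo <= fit.params.p2 <= hi
            assert fit.params.period == pytest.approx((fit.params.p1 + fit.params.p2) / 2)

    def test_beats_best_pure_sinusoid(self, cfg, times12):
        # the pure-sinusoid fit is the p1 == p2 diagonal of the search grid
        rng = np.random.default_rng(9)
        series = rng.normal(size=12)
        fit = fit_pseudo_sine(series, times12, cfg)
        s = detrend(series, times12)
        best_pure = np.inf
        for p in np.arange(12.0, 36.01, 0.2):
            w = 2 * np.pi / p
            X = np.column_stack([np.sin(w * times12), np.cos(w * times12),
                                 np.ones(12), times12])
            resid = s - X @ np.linalg.lstsq(X, s, rcond=None)[0]
            best_pure = min(best_pure, float(np.linalg.norm(resid)))
        assert fit.l2_error <= best_pure + 1e-9

    def test_noiseless_period_bias_below_grid_step(self, cfg):
        t = np.arange(0.0, 48.1, 4.0)
        rng = np.random.default_rng(12)
        for _ in range(5):
            p_true = rng.uniform(20, 28)
            y = pseudo_sine_eval(PseudoSine(1.0, 0.3, p_true, p_true), t)
            fit = fit_pseudo_sine(y, t, cfg)
            assert abs(fit.params.period - p_true) <= cfg.grid_step_hours


class TestComputeFeatures:
    def test_pure_tone_band_ratio(self, cfg, times12):
        y = np.sin(2 * np.pi * times12 / 24.0)
        reps = np.stack([y, y])
        f = compute_features(reps, times12, cfg)
        assert f.x1 == pytest.approx(f.x2)
        # independent oracle: explicit DFT of the detrended windowed tone
        yd = detrend(y, times12)
        k = np.arange(1, cfg.n_fft // 2 + 1)
        dft = np.array([np.sum(yd * np.exp(-2j * np.pi * kk * np.arange(12) / cfg.n_fft))
                        for kk in k])
        power = np.abs(dft) ** 2
        periods = cfg.n_fft * 4.0 / k
        expected = power[(periods >= 18) & (periods <= 32)].sum() / power.sum()
        assert f.x1 == pytest.approx(expected, abs=1e-9)
        # leakage from the short rectangular window caps the ratio below 1,
        # but an in-band tone must still sit far above the flat-spectrum level
        flat = np.mean((periods >= 18) & (periods <= 32))
        assert f.x1 > 3 * flat
        assert f.x3 == pytest.approx(0.0, abs=1e-9)
        assert f.x4 == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_band_ratio_matches_flat_spectrum(self, cfg, times12):
        # expected ratio for a flat spectrum = fraction of bins in the band
        freqs = np.fft.rfftfreq(cfg.n_fft, d=4.0)[1:]
        periods = 1.0 / freqs
        expected = np.mean((periods >= 18.0) & (periods <= 32.0))
        ratios = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            f = compute_features(rng.normal(size=(1, 12)), times12, cfg)
            ratios.append(f.x1)
        assert abs(np.mean(ratios) - expected) < 0.05

    def test_best_replicate_selection(self, cfg, times12):
        clean = pseudo_sine_eval(PseudoSine(1.0, 0.0, 22.0, 26.0), times12)
        noise = np.random.default_rng(1).normal(size=12)
        _, _, b_idx = compute_features_with_fit(np.stack([noise, clean]), times12, cfg)
        assert b_idx == 1

    def test_zero_variance_series_no_nan(self, cfg, times12):
        f = compute_features(np.zeros((2, 12)), times12, cfg)
        assert f.x1 == 0.0 and f.x5 == 0.0
        assert np.all(np.isfinite(f.as_array()))

    def test_single_replicate_b_equals_a(self, cfg, times12):
        y = np.sin(2 * np.pi * times12 / 24.0)
        f = compute_features(y[None, :], times12, cfg)
        assert f.x1 == pytest.approx(f.x2)
        assert f.x3 == pytest.approx(f.x4)

    def test_periodogram_band_limits_inclusive(self, cfg):
        freqs, power = periodogram(np.ones(12), 4.0, cfg.n_fft)
        assert freqs.size == power.size == cfg.n_fft // 2


def _separable_features(n, rng):
    feats, labels = [], []
    for i in range(n):
        rhythmic = i % 2 == 0
        x1 = rng.normal(1.0 if rhythmic else 0.2, 0.02)
        rest = rng.normal(0.5, 0.1, size=7)
        feats.append(RhythmFeatures(x1, *rest))
        labels.append(rhythmic)
    return feats, labels


class TestClassifier:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(0)
        feats, labels = _separable_features(60, rng)
        model = train_classifier(feats, labels)
        preds = [model.probability(f.as_array()) > 0.5 for f in feats]
        assert preds == labels

    def test_label_swap_negates_weights(self):
        rng = np.random.default_rng(1)
        feats, labels = _separable_features(60, rng)
        m1 = train_classifier(feats, labels)
        m2 = train_classifier(feats, [not l for l in labels])
        np.testing.assert_allclose(m1.weights, -m2.weights, atol=1e-6)
        assert m1.intercept == pytest.approx(-m2.intercept, abs=1e-6)

    def test_boundary_probability_is_half(self):
        rng = np.random.default_rng(2)
        feats, labels = _separable_features(60, rng)
        model = train_classifier(feats, labels)
        # walk along x1 to the decision boundary, keeping other features at
        # their standardized zero
        x = model.feat_mean.copy()
        # decision = b0 + w1 * z1 => z1* = -b0/w1
        z1 = -model.intercept / model.weights[0]
        x[0] = model.feat_mean[0] + z1 * model.feat_sd[0]
        assert model.probability(x) == pytest.approx(0.5, abs=1e-9)

    def test_single_class_error(self):
        rng = np.random.default_rng(3)
        feats, _ = _separable_features(10, rng)
        with pytest.raises(ValueError):
            train_classifier(feats, [True] * 10)

    def test_probability_invariant_to_affine_feature_rescaling(self):
        rng = np.random.default_rng(4)
        feats, labels = _separable_features(60, rng)
        X = np.vstack([f.as_array() for f in feats])
        scale = rng.uniform(0.5, 3.0, size=8)
        shift = rng.normal(size=8)
        X2 = X * scale + shift
        m1 = train_classifier(X, labels)
        m2 = train_classifier(X2, labels)
        for i in range(10):
            p1 = m1.probability(X[i])
            p2 = m2.probability(X2[i])
            assert p1 == pytest.approx(p2, abs=1e-6)

    def test_classify_boundary_and_extremes(self, cfg, times12):
        fit = fit_pseudo_sine(np.sin(2 * np.pi * times12 / 24), times12, cfg)
        feats = RhythmFeatures(*([0.5] * 8))
        neutral = LogisticModel(0.0, np.zeros(8), np.full(8, 0.5), np.ones(8))
        call = classify(neutral, feats, fit)
        assert call.probability == pytest.approx(0.5)
        assert not call.is_rhythmic  # sigma == 0.5 -> arrhythmic
        sure = LogisticModel(50.0, np.zeros(8), np.full(8, 0.5), np.ones(8))
        assert classify(sure, feats, fit).is_rhythmic
        assert classify(sure, feats, fit).probability > 0.999999
        assert call.period == fit.params.period

    def test_dimension_mismatch(self):
        model = LogisticModel(0.0, np.zeros(8), np.zeros(8), np.ones(8))
        with pytest.raises(ValueError, match="mismatch"):
            model.probability(np.zeros(5))

    def test_held_out_accuracy_small(self, cfg):
        train_s, train_l, t = make_labeled_series(40, 40, cfg, seed=10)
        model = train_classifier([compute_features(s, t, cfg) for s in train_s], train_l)
        test_s, test_l, _ = make_labeled_series(50, 50, cfg, seed=11)
        hits = 0
        for s, lab in zip(test_s, test_l):
            f, fit_a, _ = compute_features_with_fit(s, t, cfg)
            hits += classify(model, f, fit_a).is_rhythmic == lab
        assert hits / 100 >= 0.95

    def test_model_json_round_trip(self, tmp_path):
        model = LogisticModel(1.5, np.arange(8.0), np.zeros(8), np.ones(8))
        p = tmp_path / "model.json"
        model.to_json(p)
        m2 = LogisticModel.from_json(p)
        assert m2.intercept == model.intercept
        np.testing.assert_array_equal(m2.weights, model.weights)


class TestRhythmScreen:
    def _trained_model(self, cfg):
        s, l, t = make_labeled_series(40, 40, cfg, seed=21)
        return train_classifier([compute_features(x, t, cfg) for x in s], l), t

    def test_generated_ground_truth(self, cfg):
        model, t = self._trained_model(cfg)
        series, labels, _ = make_labeled_series(10, 10, cfg, seed=22)
        values = np.stack(series)
        ds = ExpressionDataset(tuple(f"g{i}" for i in range(20)), t, values)
        calls = rhythm_screen(ds, model, cfg)
        assert list(calls["is_rhythmic"]) == list(labels)

    def test_empty_dataset(self, cfg, times12):
        model = LogisticModel(0.0, np.zeros(8), np.zeros(8), np.ones(8))
        ds = ExpressionDataset((), times12, np.zeros((0, 2, 12)))
        calls = rhythm_screen(ds, model, cfg)
        assert len(calls) == 0
        assert "prob" in calls.columns

    def test_failures_flagged_not_raised(self, cfg, times12):
        model = LogisticModel(0.0, np.zeros(8), np.zeros(8), np.ones(8))
        # constant gene breaks nothing; screen must return a row per gene
        v = np.zeros((2, 2, 12))
        v[1] = np.random.default_rng(0).normal(size=(2, 12))
        ds = ExpressionDataset(("flat", "noisy"), times12, v)
        calls = rhythm_screen(ds, model, cfg)
        assert len(calls) == 2
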