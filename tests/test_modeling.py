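"""Resampling, classifiers, AUC evaluation, calibration, threshold screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.naive_bayes import GaussianNB

from ctgml.modeling import (EvaluationSpec,
                            LogisticOddsRatio, MixedNaiveBayes,
                            PrevalenceResampler, ResamplingSpec, auc,
                            evaluate_loo, evaluate_repeated, hosmer_lemeshow,
                            threshold_screen)
from ctgml.screening import candidate_features, univariable_blr


def _xy(table):
    X = candidate_features(table).drop(columns=["bmi"])
    return X, table["outcome"].to_numpy()


class TestPrevalenceResampler:
    def test_oversample_hits_target_on_default_split(self, default_cohort):
        X, y = _xy(default_cohort)
        train = np.r_[np.where(y == 0)[0][:276], np.where(y == 1)[0][:8]]
        Xr, yr = PrevalenceResampler(random_state=0).fit_resample(
            X.iloc[train], y[train])
        assert 0.29 <= yr.mean() <= 0.31

    def test_majority_untouched_under_oversampling(self, small_cohort):
        X, y = _xy(small_cohort)
        Xr, yr = PrevalenceResampler(random_state=1).fit_resample(X, y)
        assert (yr == 0).sum() == (y == 0).sum()
        pd.testing.assert_frame_equal(Xr.loc[X.index[y == 0]], X[y == 0])

    def test_minority_count_relation(self, small_cohort):
        X, y = _xy(small_cohort)
        _, yr = PrevalenceResampler(random_state=2).fit_resample(X, y)
        assert (yr == 1).sum() == round(0.3 / 0.7 * (y == 0).sum())

    def test_zero_jitter_gives_exact_copies(self, small_cohort):
        X, y = _xy(small_cohort)
        Xr, yr = PrevalenceResampler(jitter_fraction=0.0,
                                     random_state=3).fit_resample(X, y)
        originals = X[y == 1].drop_duplicates()
        synth = Xr[yr == 1]
        merged = synth.merge(originals, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_jitter_perturbs_continuous_only(self, small_cohort):
        X, y = _xy(small_cohort)
        Xr, yr = PrevalenceResampler(jitter_fraction=0.1,
                                     random_state=4).fit_resample(X, y)
        synth = Xr.loc[[i for i in Xr.index if "*" in str(i)]]
        # integer-valued binary column must remain exactly 0/1
        assert set(np.unique(synth["prolonged_dec"])) <= {0.0, 1.0}

    def test_already_at_target_unchanged(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=100)})
        y = np.r_[np.ones(30), np.zeros(70)]
        _, yr = PrevalenceResampler(random_state=5).fit_resample(X, y)
        assert abs(yr.mean() - 0.3) <= 0.011

    def test_undersample_and_hybrid(self, small_cohort):
        X, y = _xy(small_cohort)
        _, yu = PrevalenceResampler("undersample",
                                    random_state=6).fit_resample(X, y)
        assert abs(yu.mean() - 0.3) <= 0.011
        assert (yu == 1).sum() == (y == 1).sum()
        Xh, yh = PrevalenceResampler("hybrid", random_state=7).fit_resample(X, y)
        assert abs(yh.mean() - 0.3) <= 0.011
        assert len(yh) == len(y)

    def test_single_class_raises(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            PrevalenceResampler().fit_resample(X, np.zeros(10))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ResamplingSpec(method="smote")
        with pytest.raises(ValueError):
            ResamplingSpec(target_prevalence=1.5)


class TestLogisticOddsRatio:
    def test_single_binary_predictor_matches_univariable(self):
        x = np.r_[np.ones(41), np.zeros(461), np.ones(6), np.zeros(9)]
        y = np.r_[np.zeros(502), np.ones(15)]
        model = LogisticOddsRatio().fit(pd.DataFrame({"x": x}), y)
        ref = univariable_blr(x, y)
        assert model.odds_ratios_["x"] == pytest.approx(ref.or_point, rel=1e-6)
        assert model.pvalues_["x"] == pytest.approx(ref.p_value, abs=1e-8)

    def test_coefficient_recovery_and_ci_coverage(self):
        # Wald 95% CIs on data simulated from known coefficients should
        # cover the truth in at least 93% of replicates.
        beta = np.array([-2.0, 0.8, -0.5, 0.3])
        n, reps = 5000, 200
        covered = np.zeros(3)
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            X = rng.normal(size=(n, 3))
            eta = beta[0] + X @ beta[1:]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            m = LogisticOddsRatio().fit(
                pd.DataFrame(X, columns=list("abc")), y)
            lo = np.log(m.conf_int_["ci_low"].to_numpy())
            hi = np.log(m.conf_int_["ci_high"].to_numpy())
            covered += (lo <= beta[1:]) & (beta[1:] <= hi)
        assert (covered / reps >= 0.93).all()

    def test_null_coefficients_shrink_with_n(self):
        med = {}
        for n in (500, 2000, 8000):
            vals = []
            for rep in range(20):
                rng = np.random.default_rng(100 + rep)
                X = pd.DataFrame({"a": rng.normal(size=n)})
                y = (rng.random(n) < 0.3).astype(float)
                vals.append(abs(LogisticOddsRatio().fit(X, y).params_["a"]))
            med[n] = np.median(vals)
        assert med[8000] < med[500]

    def test_separation_flagged_not_raised(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = X["x"].to_numpy()
        m = LogisticOddsRatio().fit(X, y)
        assert m.separated_
        assert not np.isfinite(m.conf_int_.to_numpy()).all()
        assert np.all(np.isfinite(m.predict_proba(X)))

    def test_score_at_cut_is_positive(self):
        X = pd.DataFrame({"x": [0.0, 1.0] * 20})
        y = np.r_[np.zeros(20), np.ones(20)]
        m = LogisticOddsRatio(cut=0.5).fit(X, y)
        scores = m.predict_proba(X)[:, 1]
        labels = m.predict(X)
        assert np.array_equal(labels, (scores >= 0.5).astype(int))

    def test_monotone_in_positive_coefficient_feature(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-2 * x))).astype(float)
        m = LogisticOddsRatio().fit(pd.DataFrame({"x": x}), y)
        grid = pd.DataFrame({"x": np.linspace(-3, 3, 50)})
        scores = m.predict_proba(grid)[:, 1]
        assert np.all(np.diff(scores) >= 0)

    def test_missing_variable_raises(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = (rng.random(40) < 0.5).astype(float)
        m = LogisticOddsRatio().fit(X, y)
        with pytest.raises(ValueError):
            m.predict_proba(pd.DataFrame({"z": [1.0]}))


class TestMixedNaiveBayes:
    def test_identical_conditionals_posterior_equals_prior(self, rng):
        x = np.tile(rng.normal(size=30), 2)
        y = np.r_[np.zeros(30), np.ones(30)]
        m = MixedNaiveBayes().fit(pd.DataFrame({"x": x}), y)
        post = m.predict_proba(pd.DataFrame({"x": rng.normal(size=5)}))
        assert np.allclose(post[:, 1], 0.5, atol=1e-12)

    def test_micro_example_matches_hand_computation(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 4.0, 6.0],
                          "y": [0.0, 1.0, 1.0, 3.0]})
        labels = np.array([0, 0, 1, 1])
        m = MixedNaiveBayes().fit(X, labels)
        point = pd.DataFrame({"x": [3.0], "y": [1.0]})
        # hand computation: priors 1/2; class 0: x~N(1.5, 0.25), y~N(0.5,
        # 0.25); class 1: x~N(5, 1), y~N(2, 1); posterior by direct product
        like0 = 0.5 * sps.norm.pdf(3.0, 1.5, 0.5) * sps.norm.pdf(1.0, 0.5, 0.5)
        like1 = 0.5 * sps.norm.pdf(3.0, 5.0, 1.0) * sps.norm.pdf(1.0, 2.0, 1.0)
        expected = like1 / (like0 + like1)
        assert m.predict_proba(point)[0, 1] == pytest.approx(expected,
                                                             abs=1e-10)

    def test_posteriors_sum_to_one(self, small_cohort):
        X, y = _xy(small_cohort)
        cols = ["maternal_age", "gestational_age", "prolonged_dec"]
        m = MixedNaiveBayes().fit(X[cols], y)
        post = m.predict_proba(X[cols])
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_matches_sklearn_gaussian_nb_on_continuous(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = (rng.random(120) < 0.4).astype(int)
        ours = MixedNaiveBayes().fit(X, y).predict_proba(X)
        ref = GaussianNB().fit(X.to_numpy(), y).predict_proba(X.to_numpy())
        assert np.allclose(ours, ref, atol=1e-6)

    def test_categorical_add_one_smoothing(self):
        X = pd.DataFrame({"g": ["a", "a", "b", "a"]})
        y = np.array([0, 0, 1, 1])
        m = MixedNaiveBayes(categorical=("g",)).fit(X, y)
        # class 1 saw {b, a}; P(b|1) = (1+1)/(2+2), P(a|1) = (1+1)/(2+2)
        assert m.tables_["g"][1]["b"] == pytest.approx(0.5)
        assert m.tables_["g"][0]["b"] == pytest.approx(1 / 4)

    def test_zero_variance_floored_with_warning(self):
        X = pd.DataFrame({"x": [1.0, 1.0, 2.0, 3.0]})
        y = np.array([0, 0, 1, 1])
        with pytest.warns(RuntimeWarning):
            m = MixedNaiveBayes().fit(X, y)
        assert np.isfinite(m.predict_proba(X)).all()


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 100.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 10, [0, 1] * 5) == 50.0

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.random(n), 1)  # ties likely
            labels = (rng.random(n) < 0.4).astype(int)
            if len(np.unique(labels)) < 2:
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = 100.0 * wins / (len(pos) * len(neg))
            assert auc(scores, labels) == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.3).astype(int)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert auc(scores, labels) == pytest.approx(
            auc(np.exp(5 * scores), labels))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class _SpyModel(BaseEstimator):
    """Constant-score model recording train/test row ids per repetition.

    The log is a class attribute: ``sklearn.clone`` deep-copies
    constructor params, so instance state would not survive cloning.
    """

    log: list = []

    def fit(self, X, y):
        self._train_ids = {str(i).split("*")[0] for i in X.index}
        return self

    def predict_proba(self, X):
        type(self).log.append((self._train_ids, set(map(str, X.index))))
        return np.column_stack([np.full(len(X), 0.5), np.full(len(X), 0.5)])


class TestEvaluateRepeated:
    def test_oracle_feature_gives_perfect_auc(self, small_cohort):
        X, y = _xy(small_cohort)
        X = X.assign(oracle=y.astype(float))
        summary = evaluate_repeated(
            X[["oracle"]], y, LogisticOddsRatio(),
            EvaluationSpec(n_repetitions=20), ResamplingSpec(), seed=0)
        assert summary.mean_auc == 100.0
        assert summary.ci_high - summary.ci_low == 0.0

    def test_null_feature_auc_near_chance(self, small_cohort):
        X, y = _xy(small_cohort)
        rng = np.random.default_rng(99)
        X = X.assign(noise=rng.normal(size=len(X)))
        summary = evaluate_repeated(
            X[["noise"]], y, LogisticOddsRatio(),
            EvaluationSpec(n_repetitions=1000), ResamplingSpec(), seed=1)
        assert 45.0 <= summary.mean_auc <= 55.0

    def test_seeded_determinism(self, small_cohort):
        X, y = _xy(small_cohort)
        kwargs = dict(eval_spec=EvaluationSpec(n_repetitions=5),
                      resampling=ResamplingSpec(), seed=7)
        a = evaluate_repeated(X[["maternal_age"]], y, LogisticOddsRatio(),
                              **kwargs)
        b = evaluate_repeated(X[["maternal_age"]], y, LogisticOddsRatio(),
                              **kwargs)
        assert np.array_equal(a.aucs, b.aucs)
        assert (a.mean_auc, a.ci_low, a.ci_high) == \
            (b.mean_auc, b.ci_low, b.ci_high)

    def test_no_train_test_leakage_under_resampling(self, small_cohort):
        X, y = _xy(small_cohort)
        _SpyModel.log = []
        evaluate_repeated(X, y, _SpyModel(),
                          EvaluationSpec(n_repetitions=10),
                          ResamplingSpec(), seed=3)
        assert len(_SpyModel.log) == 10
        for train_ids, test_ids in _SpyModel.log:
            assert train_ids.isdisjoint(test_ids)

    def test_summary_invariants(self, small_cohort):
        X, y = _xy(small_cohort)
        s = evaluate_repeated(X[["gestational_age"]], y, MixedNaiveBayes(),
                              EvaluationSpec(n_repetitions=25),
                              ResamplingSpec(), seed=5)
        assert 0.0 <= s.ci_low <= s.mean_auc <= s.ci_high <= 100.0


class TestEvaluateLoo:
    def test_oracle_feature_gives_perfect_auc(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(15), np.ones(5)].astype(int)
        X = pd.DataFrame({"oracle": y + 0.0,
                          "noise": rng.normal(size=20)})
        s = evaluate_loo(X[["oracle"]], y, LogisticOddsRatio(), seed=0)
        assert s.mean_auc == 100.0

    def test_equals_explicit_refits(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(size=20)})
        y = (rng.random(20) < 1 / (1 + np.exp(-X["x"]))).astype(int)
        y.iloc[:2] = [0, 1]  # ensure both classes
        s = evaluate_loo(X, y.to_numpy(), LogisticOddsRatio(), seed=1)
        for i in range(20):
            mask = np.ones(20, dtype=bool)
            mask[i] = False
            m = LogisticOddsRatio().fit(X[mask], y.to_numpy()[mask])
            assert s.aucs[i] == m.predict_proba(X.iloc[[i]])[0, 1]

    def test_bootstrap_ci_deterministic(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=30)})
        y = (rng.random(30) < 0.4).astype(int)
        y[:2] = [0, 1]
        a = evaluate_loo(X, y, LogisticOddsRatio(), seed=9)
        b = evaluate_loo(X, y, LogisticOddsRatio(), seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestHosmerLemeshow:
    def test_type_one_error_rate(self):
        # under a correctly specified fitted logistic model the decile
        # test with g-2 degrees of freedom should reject at roughly its
        # nominal 5% level (the df correction presumes estimated scores)
        rejections = 0
        n_seeds = 500
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=2000)
            y = (rng.random(2000) < 1 / (1 + np.exp(-(x - 0.5)))).astype(int)
            m = LogisticOddsRatio().fit(pd.DataFrame({"x": x}), y)
            scores = m.predict_proba(pd.DataFrame({"x": x}))[:, 1]
            _, p = hosmer_lemeshow(scores, y)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.08

    def test_perfectly_calibrated_constant_scores(self):
        rng = np.random.default_rng(0)
        scores = np.full(4000, 0.5) + rng.normal(0, 1e-6, 4000)
        y = np.r_[np.zeros(2000), np.ones(2000)].astype(int)
        stat, p = hosmer_lemeshow(scores, y)
        assert stat < 20  # ~chi2 under perfect calibration, not extreme
        assert stat >= 0.0

    def test_degenerate_binning_raises(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.full(100, 0.5), np.r_[np.zeros(50), np.ones(50)])


class TestThresholdScreen:
    def test_published_confusion_counts(self):
        # 13 of 15 positives at or above threshold, all 502 negatives below
        values = np.r_[np.full(502, 4.0), np.full(13, 8.8), [5.0, 5.5]]
        labels = np.r_[np.zeros(502), np.ones(15)]
        sens, spec, counts = threshold_screen(values, labels, 6.0)
        assert counts == {"tp": 13, "fn": 2, "tn": 502, "fp": 0}
        assert sens == pytest.approx(86.6667, abs=1e-3)
        assert round(sens) == 87
        assert spec == 100.0

    def test_threshold_below_minimum(self):
        sens, spec, _ = threshold_screen([1.0, 2.0, 3.0], [0, 1, 1], 0.5)
        assert sens == 100.0
        assert spec == 0.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            threshold_screen([1.0, 2.0], [1, 1], 1.5)
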