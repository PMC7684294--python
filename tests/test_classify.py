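"""ROC measures, single-interval cutoffs, logistic IRLS, CV, binomial test."""

import warnings

import numpy as np
import pytest
from scipy import stats

from painsig import classify, synthdata as sd
from painsig.classify import (
    SeparationWarning,
    SingleIntervalClassifier,
    NetworkSimilarityClassifier,
    apply_classifier,
    binomial_test_two_sided,
    binormal_roc,
    crossval_classifier,
    empirical_auroc,
    fit_logistic,
    network_feature_matrix,
    network_features,
    proportion_se,
    single_interval_classify,
    stability_assessment,
)
from conftest import two_study_config


def _brute_force_auroc(scores, labels):
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestEmpiricalAUROC:
    def test_perfect_separation(self):
        assert empirical_auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_shuffled_labels_near_half(self, rng):
        scores = rng.standard_normal(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(empirical_auroc(scores, labels) - 0.5) < 0.03

    def test_matches_pair_counting_with_ties(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 6, size=30).astype(float)  # many ties
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            assert np.isclose(
                empirical_auroc(scores, labels), _brute_force_auroc(scores, labels)
            )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_auroc([1.0, 2.0], [1, 1])


class TestBinormalROC:
    def test_equal_means_auc_half(self, rng):
        x = rng.standard_normal(50)
        roc = binormal_roc(np.concatenate([x, x]), [0] * 50 + [1] * 50)
        assert np.isclose(roc.auc, 0.5)

    def test_closed_form_consistent_with_printed_pair(self):
        """Under equal variances AUC = Phi(d_a/sqrt(2)); for d_a = 2.13
        that is 0.934, matching the printed AUROC of 0.93."""
        auc = stats.norm.cdf(2.13 / np.sqrt(2))
        assert abs(auc - 0.93) < 0.005
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0, 1, 2000), rng.normal(2.13, 1, 2000)])
        labels = np.array([0] * 2000 + [1] * 2000)
        roc = binormal_roc(scores, labels)
        assert abs(roc.auc - auc) < 0.03
        assert abs(roc.d_a - 2.13) < 0.1

    def test_empirical_matches_binormal_on_gaussians(self, rng):
        n = 100_000
        scores = np.concatenate([rng.normal(0, 1, n), rng.normal(1.0, 1.5, n)])
        labels = np.array([0] * n + [1] * n)
        assert abs(empirical_auroc(scores, labels) - binormal_roc(scores, labels).auc) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            binormal_roc([1.0, 1.0, 0.0, 2.0], [1, 1, 0, 0])

    def test_curve_monotone(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 2, 50)])
        roc = binormal_roc(scores, [0] * 50 + [1] * 50)
        fpr = np.linspace(0.01, 0.99, 50)
        tpr = roc.tpr_at(fpr)
        assert np.all(np.diff(tpr) > 0)


class TestSingleInterval:
    def test_separable_toy_case(self):
        rep = single_interval_classify([1.0, 2.0, 3.0], [0, 1, 1])
        assert 1.0 < rep.cutoff < 2.0
        assert rep.accuracy == 1.0

    def test_printed_accuracy_se(self):
        assert round(proportion_se(0.86, 270) * 100, 1) == 2.1

    def test_cutoff_beats_every_other_midpoint(self, rng):
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, 200).astype(bool)
        rep = single_interval_classify(scores, labels)
        uniq = np.unique(scores)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            acc = np.mean((scores > c) == labels)
            assert acc <= rep.accuracy + 1e-12

    def test_estimator_api(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(2, 1, 40)])
        y = np.array(["nopain"] * 40 + ["pain"] * 40)
        clf = SingleIntervalClassifier().fit(scores, y)
        assert set(clf.predict([10.0])) == {"pain"}
        assert clf.report_.accuracy >= 0.5
        assert np.isclose(
            clf.report_.balanced_accuracy,
            (clf.report_.sensitivity + clf.report_.specificity) / 2,
        )


class TestLogisticIRLS:
    def test_matches_statsmodels_mle(self, rng):
        import statsmodels.api as sm

        X = rng.standard_normal((200, 3))
        beta_true = np.array([0.3, -0.5, 0.8])
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.2 + X @ beta_true)))).astype(float)
        m = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            np.concatenate([[m.intercept], m.coef]), ref.params, atol=1e-6
        )
        np.testing.assert_allclose(m.se, ref.bse[1:], rtol=1e-4)

    def test_parameter_recovery_large_n(self, rng):
        X = rng.standard_normal((5000, 2))
        beta_true = np.array([0.7, -1.1])
        y = (rng.random(5000) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        m = fit_logistic(X, y)
        assert np.all(np.abs(m.coef - beta_true) < 3 * m.se)

    def test_type_one_error_controlled(self, rng):
        hits = 0
        trials = 40
        for _ in range(trials):
            X = rng.standard_normal((500, 2))
            y = rng.integers(0, 2, 500).astype(float)
            m = fit_logistic(X, y)
            hits += int((m.pvalues < 0.05).any())
        # two chances per trial; expect <= ~10% of coefficients significant
        assert hits / (2 * trials) <= 0.10

    def test_deterministic_fit(self, rng):
        X = rng.standard_normal((50, 2))
        y = (X[:, 0] + rng.standard_normal(50) > 0).astype(float)
        m1, m2 = fit_logistic(X, y), fit_logistic(X, y)
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_separation_flagged_not_fatal(self):
        X = np.linspace(-2, 2, 40)[:, None]
        y = (X[:, 0] > 0).astype(float)
        with pytest.warns(SeparationWarning):
            m = fit_logistic(X, y)
        assert m.separation and np.isfinite(m.coef).all()
        assert m.coef[0] > 0

    def test_estimator_wrapper(self, rng):
        X = rng.standard_normal((120, 2))
        y = np.where(X[:, 0] + 0.5 * rng.standard_normal(120) > 0, "somatic", "visceral")
        clf = NetworkSimilarityClassifier().fit(X, y)
        assert clf.predict_proba(X).shape == (120, 2)
        acc = (clf.predict(X) == y).mean()
        assert acc > 0.7
        assert clf.get_params()["threshold"] == 0.5


class TestNetworkFeatures:
    def test_loaded_parcel_gets_largest_z(self, atlas, rng):
        from painsig.imgcore import BrainVolume

        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            data = r.standard_normal(atlas.mask.shape)
            data[atlas.parcels[1].data] += 1.0
            z = network_features(BrainVolume(data), atlas)
            wins += np.argmax(z) == 1
        assert wins >= 95

    def test_pure_noise_small_z(self):
        from painsig.imgcore import BrainVolume

        big = sd.make_atlas((24, 24, 24), 7, seed=4)  # ~10^4 mask voxels
        r = np.random.default_rng(5)
        z = network_features(BrainVolume(r.standard_normal((24, 24, 24))), big)
        assert np.all(np.abs(z) < 0.05)

    def test_parcel_indicator_map_is_degenerate(self, atlas):
        from painsig.imgcore import BrainVolume

        data = atlas.parcels[0].data.astype(float)
        with pytest.raises(ValueError, match="infinite"):
            network_features(BrainVolume(data), atlas)


def _training_features(seed, **kw):
    cfg = two_study_config(seed, **kw)
    cohort = sd.simulate_cohort(cfg)
    feats = network_feature_matrix(cohort.all_maps, cohort.atlas)
    labels = (cohort.metadata["modality"] == "somatic").to_numpy(float)
    return feats, labels, cohort


class TestCrossValidation:
    def test_same_seed_identical(self):
        feats, labels, _ = _training_features(50)
        a = crossval_classifier(feats, labels, seed=3)
        b = crossval_classifier(feats, labels, seed=3)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.model.coef, b.model.coef)

    def test_separable_cohort_high_auroc(self):
        """Quick 5-replicate smoke check; the full 20-replicate condition
        (mean AUROC > 0.85) runs in the acceptance suite."""
        aurocs = []
        for rep in range(5):
            feats, labels, _ = _training_features(60 + rep)
            aurocs.append(crossval_classifier(feats, labels, seed=rep).report.auroc)
        assert np.mean(aurocs) > 0.8

    def test_shuffled_labels_chance(self):
        rng = np.random.default_rng(1)
        aurocs = []
        for rep in range(5):
            feats, labels, _ = _training_features(70 + rep)
            aurocs.append(
                crossval_classifier(feats, rng.permutation(labels), seed=rep).report.auroc
            )
        assert 0.35 < np.mean(aurocs) < 0.65

    def test_no_label_leakage(self):
        """A held-out subject's prediction must not depend on its own
        label: refitting the same training fold with that subject's label
        flipped leaves its predicted probability unchanged."""
        feats, labels, _ = _training_features(80)
        cv = crossval_classifier(feats, labels, k=5, seed=0)
        fold0 = cv.fold_assignments == 0
        train = ~fold0
        flipped = labels.copy()
        j = np.flatnonzero(fold0)[0]
        flipped[j] = 1 - flipped[j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            m = fit_logistic(feats[train], flipped[train])
        np.testing.assert_allclose(
            m.predict_proba(feats[fold0]), cv.probabilities[fold0], atol=1e-10
        )

    def test_k_below_two_rejected(self):
        feats, labels, _ = _training_features(90)
        with pytest.raises(ValueError):
            crossval_classifier(feats, labels, k=1)


class TestStability:
    def test_separable_data_stable_coefficients(self):
        feats, labels, _ = _training_features(100, n_visceral=30, n_somatic=60)
        sd_err, coef_corr = stability_assessment(feats, labels, n_iter=20, k=10, seed=0)
        assert coef_corr > 0.95
        assert sd_err < 0.15

    def test_single_iteration_rejected(self):
        feats, labels, _ = _training_features(101)
        with pytest.raises(ValueError):
            stability_assessment(feats, labels, n_iter=1)


class TestApplyClassifier:
    @pytest.mark.parametrize(
        "k,n,se_pct", [(29, 30, 3.28), (13, 15, 8.78), (10, 15, 12.17)]
    )
    def test_printed_proportion_ses(self, k, n, se_pct):
        assert round(proportion_se(k / n, n) * 100, 2) == se_pct

    def test_degenerate_proportion_zero_se(self):
        assert proportion_se(0.0, 12) == 0.0

    def test_feature_contract_enforced(self):
        feats, labels, _ = _training_features(110)
        cv = crossval_classifier(feats, labels, seed=1)
        with pytest.raises(ValueError, match="feature contract"):
            apply_classifier(cv.model, feats[:, :5])

    def test_model_json_round_trip(self):
        feats, labels, _ = _training_features(111)
        cv = crossval_classifier(feats, labels, seed=1)
        back = classify.LogisticModel.from_json(cv.model.to_json())
        np.testing.assert_allclose(back.coef, cv.model.coef)
        np.testing.assert_allclose(
            back.predict_proba(feats[:3]), cv.model.predict_proba(feats[:3])
        )


class TestBinomialTest:
    def test_printed_vulvar_case(self):
        assert round(binomial_test_two_sided(13, 15, 0.6249), 3) == 0.083

    def test_closed_form_all_successes_fair_coin(self):
        assert np.isclose(binomial_test_two_sided(15, 15, 0.5), 2 * 0.5**15)

    def test_mode_of_null_capped_at_one(self):
        k_mode = int(np.floor(16 * 0.5))
        assert binomial_test_two_sided(k_mode, 15, 0.5) == pytest.approx(1.0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            binomial_test_two_sided(16, 15, 0.5)
        with pytest.raises(ValueError):
            binomial_test_two_sided(3, 15, 1.0)
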