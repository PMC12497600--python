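"""Statistical layer: metric suite, t comparisons, ROC, model fits,
variable selection and the decision tree."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from pttsleep import stats, synth

REPORTED_2VAR_COEFS = {"intercept": -4.40943, "odi3": 0.56794, "pttrs": 0.09504}


class TestConfusionMetrics:
    def test_perfect_diagonal(self):
        m = stats.confusion_metrics(40, 0, 0, 25)
        assert m.accuracy == m.sensitivity == m.specificity == 1.0
        assert m.kappa == pytest.approx(1.0)
        assert m.mcnemar_p is None

    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_matches_per_record_counting_oracle(self, tn, fp, fn, tp):
        if tn + fp + fn + tp == 0:
            return
        m = stats.confusion_metrics(tn, fp, fn, tp)
        # oracle: rebuild label vectors and count directly (no-disorder = 1)
        y_true = np.array([1] * (tn + fp) + [0] * (fn + tp))
        y_pred = np.array([1] * tn + [0] * fp + [1] * fn + [0] * tp)
        assert m.accuracy == pytest.approx(np.mean(y_true == y_pred))
        if tn + fp:
            assert m.sensitivity == pytest.approx(
                np.mean(y_pred[y_true == 1] == 1))
        if fn + tp:
            assert m.specificity == pytest.approx(
                np.mean(y_pred[y_true == 0] == 0))
        if len(np.unique(y_true)) == 2 and len(np.unique(y_pred)) == 2:
            assert m.kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12)
        assert m.detection_prevalence >= m.detection_rate

    def test_positive_class_convention_swap(self):
        m = stats.confusion_metrics(372, 35, 72, 143, positive_class="disorder")
        assert m.sensitivity == pytest.approx(143 / 215)
        assert m.specificity == pytest.approx(372 / 407)

    def test_zero_denominator_reported_as_missing(self):
        m = stats.confusion_metrics(0, 0, 10, 20)
        assert m.sensitivity is None
        assert m.balanced_accuracy is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            stats.confusion_metrics(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            stats.confusion_metrics(0, 0, 0, 0)


class TestGroupSummaryT:
    def test_identical_groups_give_zero(self):
        r = stats.group_summary_t(50, 10.0, 2.0, 50, 10.0, 2.0)
        assert r.difference == 0 and r.t == 0

    def test_pooled_se_and_df(self):
        r = stats.group_summary_t(413, 82.86, 38.0, 216, 67.73, 32.1)
        assert r.df == 627
        assert r.se == pytest.approx(3.029, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.group_summary_t(1, 0, 1, 50, 0, 1)
        with pytest.raises(ValueError):
            stats.group_summary_t(10, 0, 0.0, 50, 0, 1)


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        auc, _ = stats.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.random(2000)
        labels = np.repeat([0, 1], 1000)
        auc, _ = stats.roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_equals_pairwise_concordance_oracle(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, _ = stats.roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                        for a in pos for b in neg])
        assert auc == pytest.approx(conc, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(size=300) > 0).astype(int)
        a1, _ = stats.roc_auc(scores, labels)
        a2, _ = stats.roc_auc(np.exp(2 * scores) + 7, labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            stats.roc_auc([0.1, 0.9], [1, 1])


class TestLogistic:
    def test_recovers_known_coefficients(self):
        tot = hit = 0
        for seed in range(10):
            df = synth.simulate_logistic_cohort(629, REPORTED_2VAR_COEFS, seed=seed,
                                                noise_variables=False)
            m = stats.fit_logistic(df, ["odi3", "pttrs"])
            for name, true in REPORTED_2VAR_COEFS.items():
                row = "intercept" if name == "intercept" else name
                tot += 1
                hit += abs(m.table.loc[row, "coef"] - true) \
                    <= 2 * m.table.loc[row, "se"]
        assert hit / tot >= 0.85

    def test_constant_covariate_has_no_effect(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": np.zeros(200),
                           "disorder": rng.integers(0, 2, 200)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = stats.fit_logistic(df, ["x"])
        assert abs(m.table.loc["x", "coef"]) < 1e-8

    def test_perfect_separation_warns(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)],
                           "disorder": np.r_[np.zeros(50), np.ones(50)].astype(int)})
        with pytest.warns(stats.SeparationWarning):
            stats.fit_logistic(df, ["x"])


class TestMultinomial:
    @staticmethod
    def _simulated_score_table(n, seed, b1, b2):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({v: rng.normal(0, 1, n)
                          for v in stats.MULTINOMIAL_VARIABLES})
        lp1 = b1["intercept"] + sum(b1[v] * X[v]
                                    for v in stats.MULTINOMIAL_VARIABLES)
        lp2 = b2["intercept"] + sum(b2[v] * X[v]
                                    for v in stats.MULTINOMIAL_VARIABLES)
        P = np.column_stack([np.ones(n), np.exp(lp1), np.exp(lp2)])
        P /= P.sum(1, keepdims=True)
        u = rng.random(n)
        cum = P.cumsum(1)
        X["score3"] = np.array([3, 1, 2])[(u[:, None] < cum).argmax(1)]
        return X

    def test_recovery_and_null_covariate_calibration(self):
        b1 = dict(intercept=0.5, pttrs=-0.4, sex=0.2, mean_nadir=0.0,
                  age_months=0.3, oximetry_score=0.0, weight=0.1,
                  height=0.0, odi4=-0.2)
        b2 = dict(intercept=-0.2, pttrs=0.3, sex=-0.1, mean_nadir=0.2,
                  age_months=0.0, oximetry_score=0.1, weight=0.0,
                  height=-0.3, odi4=0.2)
        tot = hit = null_tot = null_ok = 0
        for seed in (1, 2):
            X = self._simulated_score_table(5000, seed, b1, b2)
            m = stats.fit_multinomial(X, outcome="score3", reference=3)
            for eq, b in (("1 vs 3", b1), ("2 vs 3", b2)):
                sub = m.table[m.table.equation == eq]
                for v in ["intercept"] + stats.MULTINOMIAL_VARIABLES:
                    tot += 1
                    hit += abs(sub.loc[v, "coef"] - b[v]) <= 2 * sub.loc[v, "se"]
                    if b[v] == 0.0 and v != "intercept":
                        null_tot += 1
                        null_ok += abs(sub.loc[v, "z"]) < 1.96
        assert hit / tot >= 0.85
        assert null_ok / null_tot >= 0.5

    def test_class_probabilities_sum_to_one(self):
        X = self._simulated_score_table(
            300, 3,
            dict.fromkeys(["intercept"] + stats.MULTINOMIAL_VARIABLES, 0.1),
            dict.fromkeys(["intercept"] + stats.MULTINOMIAL_VARIABLES, -0.1))
        m = stats.fit_multinomial(X, outcome="score3", reference=3)
        proba = m.predict(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_requires_three_levels(self):
        df = pd.DataFrame({v: np.random.default_rng(0).normal(size=50)
                           for v in stats.MULTINOMIAL_VARIABLES})
        df["score3"] = [1, 2] * 25
        with pytest.raises(ValueError, match="3 levels"):
            stats.fit_multinomial(df, outcome="score3")


class TestSelection:
    def test_alpha_one_keeps_all_variables(self):
        df = synth.simulate_features(300, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.select_variables(df, alpha=1.0)
        assert set(res.selected) == set(synth.MODEL_VARIABLES)

    def test_invariant_to_column_order(self):
        df = synth.simulate_features(400, seed=3)
        shuffled = df[list(df.columns[::-1])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = stats.select_variables(df)
            b = stats.select_variables(shuffled)
        assert set(a.selected) == set(b.selected)
        assert set(a.top2_variables) == set(b.top2_variables)

    def test_pure_noise_survives_screen_rarely(self):
        few = 0
        for seed in range(6):
            df = synth.simulate_logistic_cohort(
                400, {"intercept": -0.5}, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.select_variables(df)
            few += len(res.selected) <= 1
        assert few >= 4

    def test_informative_pair_selected(self):
        ok = 0
        for seed in range(8):
            df = synth.simulate_logistic_cohort(629, REPORTED_2VAR_COEFS, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.select_variables(df)
            ok += set(res.top2_variables) == {"odi3", "pttrs"}
        assert ok >= 7


class TestTree:
    @staticmethod
    def _rule_cohort(n, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({v: rng.normal(0, 1, n)
                           for v in synth.MODEL_VARIABLES})
        df["odi3"] = rng.gamma(2, 3, n)
        df["pttrs"] = rng.normal(18, 7, n)
        df["disorder"] = ((df.odi3 > 7) | (df.pttrs > 20)).astype(int)
        return df

    def test_learns_an_exact_threshold_rule(self):
        df = self._rule_cohort(1500, 0)
        m = stats.fit_tree(df, ["odi3", "pttrs"], seed=0)
        assert m.extra["test_accuracy"] >= 0.95

    def test_deterministic_for_fixed_seed(self):
        df = self._rule_cohort(600, 1)
        a = stats.fit_tree(df, ["odi3", "pttrs"], seed=7)
        b = stats.fit_tree(df, ["odi3", "pttrs"], seed=7)
        assert a.metrics.to_dict() == b.metrics.to_dict()
        assert np.array_equal(a.table["coef"], b.table["coef"])

    def test_single_class_training_set_errors(self):
        df = self._rule_cohort(100, 2)
        df["disorder"] = 0
        with pytest.raises(ValueError):
            stats.fit_tree(df, ["odi3", "pttrs"], seed=0)

    def test_tree_and_logistic_concordant_on_cohort(self):
        df = synth.simulate_features(629, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logit = stats.fit_logistic(df, stats.TWO_VARIABLES)
        acc_logit = stats.metrics_from_predictions(
            df["disorder"], (logit.predict(df) >= 0.5)).accuracy
        tree = stats.fit_tree(df, stats.TWO_VARIABLES, seed=0)
        assert abs(tree.extra["test_accuracy"] - acc_logit) <= 0.05


def test_kappa_zero_when_predictions_independent(rng):
    kappas = []
    for _ in range(40):
        y = rng.integers(0, 2, 400)
        pred = rng.integers(0, 2, 400)
        m = stats.metrics_from_predictions(y, pred)
        kappas.append(m.kappa)
    assert np.mean(kappas) == pytest.approx(0.0, abs=0.02)
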