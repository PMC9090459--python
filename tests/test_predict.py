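"""Statistical layer: logistic IRLS, ROC/AUC, cut-offs, diagnostics, calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from csfdyn import (
    CohortSimConfig,
    LogisticOutcomeModel,
    auc_ci,
    confusion_metrics,
    correlate,
    dichotomize_mrs,
    evaluate_models,
    evaluation_table,
    fit_logistic,
    generate_cohort,
    hosmer_lemeshow,
    metrics_from_rates,
    roc_auc,
    univariate_screen,
    youden_cutoff,
)
from csfdyn.errors import SeparationWarning
from csfdyn.predict import bootstrap_auc_ci, round_half_up


def brute_force_auc(scores, labels):
    """All-pairs concordance with ties counted 1/2 (independent oracle)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def assert_youden_equal(got, expected):
    """Same threshold; sensitivity/specificity equal to floating rounding."""
    assert got[0] == expected[0]
    assert got[1] == pytest.approx(expected[1], abs=1e-12)
    assert got[2] == pytest.approx(expected[2], abs=1e-12)


def exhaustive_youden(scores, labels):
    """Best (J, sens, spec) over every observed threshold, by direct counting."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    best = None
    for thr in np.unique(s):
        pred = s >= thr
        sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
        spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
        j = sens + spec - 1
        key = (j, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    return best[1:]


class TestDichotomize:
    @pytest.mark.parametrize("mrs,expected", [(0, 1), (2, 1), (3, 0), (6, 0)])
    def test_drl_threshold(self, mrs, expected):
        assert dichotomize_mrs(mrs) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_mrs(7)


class TestLogistic:
    def test_matches_reference_mle(self, rng):
        """IRLS coefficients and SEs equal the statsmodels Newton MLE."""
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(300, 2))
        eta = 0.3 + X @ np.array([0.5, -1.0])
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        m = LogisticOutcomeModel().fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(np.r_[m.intercept_, m.coef_], ref.params, atol=1e-8)
        assert np.allclose(np.r_[m.intercept_se_, m.coef_se_], ref.bse, atol=1e-8)

    def test_deviance_monotone_across_iterations(self, rng):
        for _ in range(5):
            X = rng.normal(size=(80, 3))
            y = rng.binomial(1, 0.5, size=80)
            m = LogisticOutcomeModel().fit(X, y)
            assert np.all(np.diff(m.deviances_) <= 1e-10)

    def test_null_predictor_has_small_z(self, rng):
        X = rng.normal(size=(2000, 1))
        y = rng.binomial(1, 0.5, size=2000)
        m = LogisticOutcomeModel().fit(X, y)
        assert abs(m.coef_[0]) < 2 * m.coef_se_[0]

    def test_separation_warned(self):
        X = np.r_[np.zeros(10), np.ones(10)].reshape(-1, 1)
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        with pytest.warns(SeparationWarning):
            m = LogisticOutcomeModel().fit(X, y)
        assert m.separation_

    def test_singular_design_rejected(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        y = (x > 0).astype(int)
        with pytest.raises(np.linalg.LinAlgError):
            LogisticOutcomeModel().fit(X, y)

    def test_predict_proba_shapes_and_classes(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.binomial(1, 0.5, size=40)
        m = LogisticOutcomeModel().fit(X, y)
        proba = m.predict_proba(X)
        assert proba.shape == (40, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(m.predict(X)) <= set(m.classes_)


class TestScreen:
    def test_strong_predictor_retained_constant_flagged(self, cohort2000):
        cohort, _ = cohort2000
        df = cohort.head(300).copy()
        df["flatline"] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = univariate_screen(df, ["drap2max_pct", "flatline", "age_years"])
        assert out.loc["drap2max_pct", "retained"]
        assert out.loc["flatline", "flag"] == "zero-variance"
        assert not out.loc["flatline", "retained"]

    def test_permuted_predictor_wald_matches_lr_and_is_null(self, rng):
        """Wald p on a permuted predictor tracks the likelihood-ratio p and
        exceeds the screening threshold in the vast majority of permutations."""
        cohort, _ = generate_cohort(CohortSimConfig(n=200, seed=4))
        y = cohort["drl"].to_numpy(int)
        x = cohort["drap1max_pct"].to_numpy(float)
        pbar = y.mean()
        null_dev = -2 * (
            y.sum() * np.log(pbar) + (y.size - y.sum()) * np.log(1 - pbar)
        )
        n_ok = 0
        for _ in range(100):
            xp = rng.permutation(x)
            m = LogisticOutcomeModel().fit(xp[:, None], y)
            wald_p = m.wald_pvalues()[0]
            lr_p = stats.chi2.sf(null_dev - m.deviances_[-1], 1)
            assert abs(wald_p - lr_p) < 0.01
            n_ok += wald_p >= 0.10
        assert n_ok >= 85


class TestRoc:
    def test_four_score_fixture(self):
        auc, curve = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75
        assert_youden_equal(
            youden_cutoff(curve), exhaustive_youden([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        )
        assert youden_cutoff(curve)[0] == 0.35

    def test_perfect_and_degenerate_cases(self):
        auc, curve = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        _, sens, spec = youden_cutoff(curve)
        assert sens == 1.0 and spec == 1.0
        auc_tied, _ = roc_auc(np.ones(10), [0] * 5 + [1] * 5)
        assert auc_tied == 0.5
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.round(rng.normal(size=50), 2), size=n)
            labels = rng.binomial(1, 0.5, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, curve = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert_youden_equal(youden_cutoff(curve), exhaustive_youden(scores, labels))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=60)
        labels = r.binomial(1, 0.5, size=60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(scores / 2), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestAucCI:
    def test_null_fixture_ci_contains_half(self, rng):
        scores = rng.normal(size=400)
        labels = np.r_[np.zeros(200, int), np.ones(200, int)]
        lo, hi, p, _ = auc_ci(scores, labels)
        assert lo <= 0.5 <= hi
        assert p > 0.05

    def test_perfect_separation_ci_high(self, rng):
        scores = np.r_[rng.normal(0, 1, 50), rng.normal(10, 1, 50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        lo, hi, p, _ = auc_ci(scores, labels)
        assert lo >= 0.9
        assert hi <= 1.0
        assert p < 1e-6

    def test_delong_variance_close_to_bootstrap(self, rng):
        scores = np.r_[rng.normal(0, 1, 100), rng.normal(0.8, 1, 100)]
        labels = np.r_[np.zeros(100, int), np.ones(100, int)]
        *_, se = auc_ci(scores, labels)
        _, _, boot_var = bootstrap_auc_ci(scores, labels, n_boot=2000, seed=5)
        assert se**2 == pytest.approx(boot_var, rel=0.20)


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ((34, 4, 14, 18), (89.5, 56.3, 70.8, 81.8)),
            ((29, 9, 8, 24), (76.3, 75.0, 78.4, 72.7)),
            ((31, 7, 3, 29), (81.6, 90.6, 91.2, 80.6)),
            ((10, 0, 0, 10), (100.0, 100.0, 100.0, 100.0)),
        ],
    )
    def test_confusion_metrics_reproduce_reported_rates(self, matrix, expected):
        got = tuple(round_half_up(v) for v in confusion_metrics(*matrix))
        assert got == expected

    def test_degenerate_matrix_errors_and_nan_fields(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)
        sens, spec, ppv, npv = confusion_metrics(5, 5, 0, 0)
        assert np.isnan(spec)  # no negatives observed
        assert npv == 0.0 and sens == 50.0

    def test_bayes_rates_match_reported_predictive_values(self):
        ppv, npv = metrics_from_rates(0.8947, 0.5625, 38 / 70)
        assert round_half_up(100 * ppv) == 70.8
        assert round_half_up(100 * npv) == 81.8
        ppv, npv = metrics_from_rates(0.8158, 0.9062, 38 / 70)
        assert round_half_up(100 * ppv) == 91.2
        assert round_half_up(100 * npv) == 80.6
        assert metrics_from_rates(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_matrix_and_rate_paths_agree(self):
        """Metrics from a reconstructed matrix equal the Bayes identities."""
        for sens, spec in ((0.8947, 0.5625), (0.7632, 0.75), (0.8158, 0.9062)):
            tp = round(sens * 38)
            tn = round(spec * 32)
            _, _, ppv_m, npv_m = confusion_metrics(tp, 38 - tp, 32 - tn, tn)
            ppv_r, npv_r = metrics_from_rates(tp / 38, tn / 32, 38 / 70)
            assert ppv_m == pytest.approx(100 * ppv_r, abs=1e-9)
            assert npv_m == pytest.approx(100 * npv_r, abs=1e-9)


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_give_zero(self):
        p = np.repeat([0.2, 0.5, 0.8], 10)
        y = np.concatenate(
            [np.r_[np.ones(2), np.zeros(8)],
             np.r_[np.ones(5), np.zeros(5)],
             np.r_[np.ones(8), np.zeros(2)]]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p_val = hosmer_lemeshow(p, y, g=3)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p_val == pytest.approx(1.0)

    def test_three_group_hand_fixture(self):
        """E = (2, 5, 8), O = (3, 5, 7) over groups of 10 gives 1/1.6 + 1/1.6."""
        p = np.repeat([0.2, 0.5, 0.8], 10)
        y = np.concatenate(
            [np.r_[np.ones(3), np.zeros(7)],
             np.r_[np.ones(5), np.zeros(5)],
             np.r_[np.ones(7), np.zeros(3)]]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, _ = hosmer_lemeshow(p, y, g=3)
        assert stat == pytest.approx(1.25, abs=1e-12)

    def test_invariant_to_within_group_permutation(self, rng):
        p = rng.uniform(0.05, 0.95, size=200)
        y = rng.binomial(1, p)
        stat1, _ = hosmer_lemeshow(p, y, g=10)
        order = np.argsort(p, kind="stable")
        # permute subjects within each decile block
        perm = order.copy()
        for g0 in range(0, 200, 20):
            perm[g0:g0 + 20] = rng.permutation(perm[g0:g0 + 20])
        stat2, _ = hosmer_lemeshow(p[perm], y[perm], g=10)
        assert stat2 == pytest.approx(stat1, abs=1e-9)

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.linspace(0.1, 0.9, 10), np.zeros(10), g=10)


class TestCorrelate:
    def test_linear_relation_gives_unity(self, rng):
        x = rng.normal(size=100)
        r, p, method = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_permuted_values_near_zero(self, rng):
        x = rng.normal(size=200)
        y = rng.permutation(rng.normal(size=200))
        r, _, _ = correlate(x, y)
        assert abs(r) < 0.15

    def test_heavy_tailed_input_switches_to_spearman(self, rng):
        x = rng.standard_cauchy(100)
        y = 0.5 * x + rng.normal(size=100)
        *_, method = correlate(x, y)
        assert method == "spearman"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10))


class TestEvaluateModels:
    def test_five_rows_in_fixed_order(self, cohort2000):
        cohort, _ = cohort2000
        evals = evaluate_models(cohort.head(400))
        assert [e.name for e in evals] == [
            "rout_only", "drap1", "drap2", "drap1_plus_drap2", "total_index",
        ]
        table = evaluation_table(evals)
        assert table.shape[0] == 5
        assert (table["error"] == "").all()

    def test_combined_model_dominates_singles(self, cohort2000):
        cohort, _ = cohort2000
        evals = {e.name: e for e in evaluate_models(cohort)}
        best_single = max(
            evals["rout_only"].auc, evals["drap1"].auc, evals["drap2"].auc
        )
        assert evals["total_index"].auc >= best_single - 0.02

    def test_null_cohort_cis_contain_half(self):
        cohort, _ = generate_cohort(
            CohortSimConfig(n=2000, seed=9, beta=(0.0, 0.0, 0.0, 0.0))
        )
        for e in evaluate_models(cohort):
            assert e.auc_ci_low <= 0.5 <= e.auc_ci_high

    def test_outcome_derived_from_mrs_when_missing(self, cohort2000):
        cohort, _ = cohort2000
        sub = cohort.head(200).drop(columns=["drl"])
        evals = evaluate_models(sub)
        assert all(e.error == "" for e in evals)
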