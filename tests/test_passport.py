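import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from epopassport.passport import (
    AdaptivePassport,
    MarkerComponents,
    estimate_components,
    evaluate_profile,
    loo_screen,
    predictive_limits,
    profile_percentile_score,
    roc_auc,
)


COMP = MarkerComponents("m", mu=1.0, sigma2_within=0.14, sigma2_between=0.20)


class TestEstimateComponents:
    def test_hand_computed_anova(self):
        comp = estimate_components({"A": [0, 2], "B": [4, 6]})
        assert comp.mu == pytest.approx(3.0)
        assert comp.sigma2_within == pytest.approx(2.0)
        assert comp.sigma2_between == pytest.approx(7.0)

    def test_constant_equal_subjects_give_zero_variances(self):
        comp = estimate_components({"A": [5, 5, 5], "B": [5, 5], "C": [5, 5]})
        assert (comp.mu, comp.sigma2_within, comp.sigma2_between) == (5.0, 0.0, 0.0)
        assert not comp.clipped

    def test_negative_between_component_clipped_and_flagged(self):
        # group means closer together than within-noise predicts
        comp = estimate_components({"A": [0, 10], "B": [1, 9], "C": [2, 8]})
        assert comp.sigma2_between == 0.0
        assert comp.clipped

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            estimate_components({"A": [1, 2, 3]})

    def test_parameter_recovery_on_simulated_subjects(self):
        rng = np.random.default_rng(5)
        w_true, b_true = 0.14, 0.20
        within, between = [], []
        for _ in range(6):
            groups = {
                f"S{i}": 1.0 + rng.normal(0, np.sqrt(b_true)) + rng.normal(0, np.sqrt(w_true), 13)
                for i in range(200)
            }
            comp = estimate_components(groups)
            within.append(comp.sigma2_within)
            between.append(comp.sigma2_between)
        assert np.mean(within) == pytest.approx(w_true, rel=0.10)
        assert np.mean(between) == pytest.approx(b_true, rel=0.10)


class TestPredictiveLimits:
    def test_prior_predictive_closed_form(self):
        lo, hi = predictive_limits(COMP, (), 0.99)
        z = stats.norm.ppf(0.995)
        half = z * np.sqrt(0.20 + 0.14)
        assert (lo, hi) == pytest.approx((1.0 - half, 1.0 + half))

    def test_no_between_variance_ignores_history(self):
        comp = MarkerComponents("m", mu=2.0, sigma2_within=0.5, sigma2_between=0.0)
        z = stats.norm.ppf(0.995)
        for hist in [(), (0.0,), (5.0, 5.0, 5.0)]:
            lo, hi = predictive_limits(comp, hist, 0.99)
            assert (lo, hi) == pytest.approx((2.0 - z * np.sqrt(0.5), 2.0 + z * np.sqrt(0.5)))

    def test_specificity_level_validated(self):
        with pytest.raises(ValueError):
            predictive_limits(COMP, (), 0.4)

    @pytest.mark.parametrize("history", [(), (1.4,), (0.2, 0.9, 1.7), (2.0,) * 6])
    def test_interval_mass_matches_monte_carlo_oracle(self, history):
        """Brute-force posterior-predictive oracle: sample the subject
        set-point from the prior, weight by the history likelihood, and
        check the interval holds the configured mass."""
        level = 0.99
        lo, hi = predictive_limits(COMP, history, level)
        rng = np.random.default_rng(11)
        n = 1_000_000
        theta = rng.normal(COMP.mu, np.sqrt(COMP.sigma2_between), n)
        logw = np.zeros(n)
        for h in history:
            logw += stats.norm.logpdf(h, theta, np.sqrt(COMP.sigma2_within))
        w = np.exp(logw - logw.max())
        x = rng.normal(theta, np.sqrt(COMP.sigma2_within))
        mass = np.sum(w * ((x >= lo) & (x <= hi))) / w.sum()
        assert mass == pytest.approx(level, abs=0.005)

    def test_width_shrinks_with_history_when_individualisable(self):
        widths = []
        for n in range(6):
            lo, hi = predictive_limits(COMP, (1.2,) * n, 0.99)
            widths.append(hi - lo)
        assert all(b <= a + 1e-12 for a, b in zip(widths, widths[1:]))

    def test_long_history_converges_to_subject_mean(self):
        """Shrinkage endpoint: the centre approaches the subject's own
        mean and the width 2 z sqrt(sigma2_within)."""
        rng = np.random.default_rng(2)
        theta = COMP.mu + 1.1
        profile = rng.normal(theta, np.sqrt(COMP.sigma2_within), 500)
        lo, hi = predictive_limits(COMP, profile, 0.99)
        z = stats.norm.ppf(0.995)
        assert (lo + hi) / 2 == pytest.approx(theta, abs=0.08)
        assert hi - lo == pytest.approx(2 * z * np.sqrt(COMP.sigma2_within), rel=0.02)


class TestEvaluateProfile:
    def test_profile_at_mu_never_atypical(self):
        atyp, limits = evaluate_profile([1.0] * 13, COMP, 0.99)
        assert atyp == []
        assert all(lo < 1.0 < hi for lo, hi in limits)

    def test_gross_outlier_flagged_first(self):
        x = COMP.mu + 10 * np.sqrt(COMP.sigma2_between + COMP.sigma2_within)
        atyp, _ = evaluate_profile([x], COMP, 0.99)
        assert atyp == [0]

    @pytest.mark.parametrize("level", [0.99, 0.95])
    def test_sequential_coverage_matches_specificity(self, level):
        """Model-generated profiles with true components: the fraction
        of observations inside their sequential limits converges to the
        configured specificity."""
        rng = np.random.default_rng(17)
        n_subj, n_obs = 800, 13
        inside = total = 0
        theta = rng.normal(COMP.mu, np.sqrt(COMP.sigma2_between), n_subj)
        obs = rng.normal(theta[:, None], np.sqrt(COMP.sigma2_within), (n_subj, n_obs))
        for prof in obs:
            atyp, _ = evaluate_profile(prof, COMP, level)
            inside += n_obs - len(atyp)
            total += n_obs
        assert inside / total == pytest.approx(level, abs=0.005)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            evaluate_profile([1.0, np.nan], COMP)


class TestProfilePercentileScore:
    def test_median_profile_scores_zero(self):
        assert profile_percentile_score([COMP.mu], COMP) == pytest.approx(0.0, abs=1e-12)

    def test_extreme_percentile_scores_high(self):
        x = stats.norm.ppf(0.995, COMP.mu, np.sqrt(COMP.sigma2_between + COMP.sigma2_within))
        assert profile_percentile_score([x], COMP) >= 0.99 - 1e-9

    def test_monotone_under_added_extreme_observation(self):
        rng = np.random.default_rng(0)
        prof = list(rng.normal(COMP.mu, 0.3, 6))
        s1 = profile_percentile_score(prof, COMP)
        s2 = profile_percentile_score(prof + [COMP.mu + 5.0], COMP)
        assert s2 >= s1


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0

    def test_toy_set_with_one_swap(self):
        assert roc_auc([0.9, 0.4, 0.8, 0.3], [True, True, False, False]) == 0.75

    def test_null_expectation_half(self):
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(200):
            scores = rng.random(20)
            labels = rng.permutation([True] * 10 + [False] * 10)
            aucs.append(roc_auc(scores, labels))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.random(60), 1)  # force ties
        labels = rng.random(60) > 0.5
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])


def _simulate_profiles(rng, n_subj, n_obs, comp, effect=None):
    theta = rng.normal(comp.mu, np.sqrt(comp.sigma2_between), n_subj)
    obs = rng.normal(theta[:, None], np.sqrt(comp.sigma2_within), (n_subj, n_obs))
    if effect is not None:
        obs = obs + np.asarray(effect)[None, :]
    return {f"S{i:02d}": obs[i] for i in range(n_subj)}


class TestLooScreen:
    def test_null_equivalent_doped_sensitivity_matches_null_flag_rate(self):
        """Doped profiles drawn from the clean-generating process: the
        'sensitivity' should match the null at-least-one-atypical rate,
        roughly 1 - 0.99^13 ~ 12%."""
        rng = np.random.default_rng(23)
        placebo = _simulate_profiles(rng, 50, 13, COMP)
        doped = _simulate_profiles(rng, 300, 13, COMP)
        result = loo_screen(placebo, doped, 0.99)
        null_rate = 100 * (1 - 0.99**13)
        assert result.sensitivity == pytest.approx(null_rate, abs=8)

    def test_power_on_published_scale_effects(self):
        """The published response amplitude (+0.9/-0.9 log2 swings
        against sigma2_within ~ 0.14) is detected in most doped
        subjects at cohort scale."""
        effect = [0, 0, 0, 0, 0.9, 0.9, 0.9, 0.9, 0, 0, -0.9, -0.9, -0.9]
        rng = np.random.default_rng(31)
        sens = []
        for _ in range(20):
            placebo = _simulate_profiles(rng, 14, 13, COMP)
            doped = _simulate_profiles(rng, 14, 13, COMP, effect)
            sens.append(loo_screen(placebo, doped, 0.99).sensitivity)
        assert np.mean(sens) >= 80
        assert np.mean([loo_screen(
            _simulate_profiles(np.random.default_rng(100 + i), 14, 13, COMP),
            _simulate_profiles(np.random.default_rng(200 + i), 14, 13, COMP, effect),
            0.99).roc_area for i in range(5)]) > 0.8

    def test_empty_doped_set_gives_sentinel_not_zero(self):
        rng = np.random.default_rng(1)
        placebo = _simulate_profiles(rng, 6, 13, COMP)
        result = loo_screen(placebo, {}, 0.99)
        assert result.sensitivity is None
        assert result.roc_area is None
        assert 0 <= result.specificity <= 100

    def test_requires_three_placebo_subjects(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            loo_screen(_simulate_profiles(rng, 2, 13, COMP), {}, 0.99)

    def test_loo_specificity_not_above_full_data_in_expectation(self):
        """Leave-one-out guards against overfitting: evaluating each
        clean subject with components fit on everyone (including
        themselves) flags no more subjects than LOO does."""
        rng = np.random.default_rng(41)
        loo_flags = full_flags = 0
        for _ in range(60):
            placebo = _simulate_profiles(rng, 8, 13, COMP)
            res = loo_screen(placebo, {}, 0.99)
            loo_flags += sum(r.flagged for r in res.placebo.values())
            full = estimate_components(placebo)
            for prof in placebo.values():
                atyp, _ = evaluate_profile(prof, full, 0.99)
                full_flags += bool(atyp)
        assert loo_flags >= full_flags


class TestAdaptivePassportEstimator:
    def test_sklearn_protocol(self):
        est = AdaptivePassport(specificity_level=0.95)
        est2 = clone(est)
        assert est2.get_params() == {"specificity_level": 0.95, "sequential": True}
        est2.set_params(sequential=False)
        assert est2.sequential is False

    def test_fit_predict_score_shapes(self):
        rng = np.random.default_rng(3)
        X = np.array(list(_simulate_profiles(rng, 20, 13, COMP).values()))
        est = AdaptivePassport().fit(X)
        assert est.sigma2_within_ == pytest.approx(0.14, rel=0.5)
        flags = est.predict(X)
        scores = est.score_samples(X)
        assert flags.shape == (20,) and flags.dtype == bool
        assert scores.shape == (20,) and ((0 <= scores) & (scores <= 1)).all()

    def test_nan_handled_as_missing_observations(self):
        rng = np.random.default_rng(3)
        X = np.array(list(_simulate_profiles(rng, 10, 13, COMP).values()))
        X[0, 5] = np.nan
        est = AdaptivePassport().fit(X)
        assert np.isfinite(est.mu_)
        assert est.predict(X).shape == (10,)

    def test_batch_mode_uses_prior_predictive_throughout(self):
        comp_est = AdaptivePassport(sequential=False)
        rng = np.random.default_rng(6)
        X = np.array(list(_simulate_profiles(rng, 10, 13, COMP).values()))
        comp_est.fit(X)
        limits = comp_est.limits(X[0])
        assert all(l == pytest.approx(limits[0]) for l in limits)


def test_between_exceeds_within_on_published_components():
    """Data simulated from the published per-gene components reproduces
    the qualitative finding that between-subject variability exceeds
    within-subject variability on average."""
    from epopassport.report import load_table3_fixture

    rng = np.random.default_rng(8)
    fixture = load_table3_fixture()
    est_w, est_b = [], []
    for row in fixture.rows:
        if row.kind != "transcript":
            continue
        comp_true = MarkerComponents(row.marker, row.mean, row.sigma2_within, row.sigma2_between)
        profiles = _simulate_profiles(rng, 14, 13, comp_true)
        est = estimate_components(profiles, row.marker)
        est_w.append(est.sigma2_within)
        est_b.append(est.sigma2_between)
    assert np.mean(est_b) > np.mean(est_w)
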