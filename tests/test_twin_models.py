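"""Biometric model fitting, ICC, AIC/LRT conventions and model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from twinconn.synthetic import (TwinCohortSpec, VarianceComponentsSpec,
                                simulate_twin_phenotypes)
from twinconn.twin_models import (TwinPairObservation, compare_group_moments,
                                  fit_biometric_model, fit_saturated, heritability,
                                  intraclass_correlation, likelihood_ratio_test,
                                  model_aic, pairs_from_table, select_model,
                                  _moments, _LN_2PI)


def anova_icc(pairs):
    """One-way random-effects ICC(1) oracle for pairs (k = 2)."""
    y = np.array([[p.y1, p.y2] for p in pairs], dtype=float)
    n, k = y.shape
    grand = y.mean()
    msb = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / n
    return (msb - msw) / (msb + (k - 1) * msw)


class TestIntraclassCorrelation:
    def test_identical_twins_give_r_one(self):
        pairs = [TwinPairObservation(f"p{i}", "MZ", v, v) for i, v in enumerate([1., 2., 5.])]
        assert intraclass_correlation(pairs) == pytest.approx(1.0)

    def test_hand_computed_double_entry(self):
        # {(1,2),(2,1)} double-entered -> {(1,2),(2,1),(2,1),(1,2)} -> r = -1
        pairs = [TwinPairObservation("a", "MZ", 1.0, 2.0),
                 TwinPairObservation("b", "MZ", 2.0, 1.0),
                 TwinPairObservation("c", "MZ", 1.0, 2.0)]
        a = np.array([1, 2, 1, 2, 1, 2])
        b = np.array([2, 1, 2, 1, 2, 1])
        expected = np.corrcoef(a, b)[0, 1]
        assert intraclass_correlation(pairs) == pytest.approx(expected)

    def test_order_invariance(self, pair_factory):
        pairs = pair_factory(0.5, 50, "MZ", seed=3)
        flipped = [TwinPairObservation(p.pair_id, p.zygosity, p.y2, p.y1) for p in pairs]
        assert intraclass_correlation(pairs) == pytest.approx(
            intraclass_correlation(flipped), abs=1e-12)

    def test_matches_anova_oracle(self, pair_factory):
        pairs = pair_factory(0.52, 5000, "MZ", seed=11)
        assert intraclass_correlation(pairs) == pytest.approx(anova_icc(pairs), abs=0.005)

    def test_needs_three_pairs(self):
        pairs = [TwinPairObservation("a", "MZ", 1.0, 2.0)]
        with pytest.raises(ValueError, match="3 pairs"):
            intraclass_correlation(pairs)

    def test_zero_variance_rejected(self):
        pairs = [TwinPairObservation(f"p{i}", "DZ", 1.0, 1.0) for i in range(4)]
        with pytest.raises(ValueError, match="variance"):
            intraclass_correlation(pairs)


class TestModelAic:
    @pytest.mark.parametrize("m2ll, n, k, expected", [
        (1388.18, 274, 4, 848.18),   # full ADE fit
        (1388.18, 274, 3, 846.18),   # nested AE fit
        (1379.74, 274, 10, 851.74),  # saturated reference
    ])
    def test_df_convention_worked_examples(self, m2ll, n, k, expected):
        assert model_aic(m2ll, n, k) == pytest.approx(expected, abs=1e-9)

    def test_classic_convention(self):
        assert model_aic(100.0, 50, 3, convention="classic") == pytest.approx(106.0)

    def test_invalid_param_count(self):
        with pytest.raises(ValueError):
            model_aic(10.0, 5, 5)
        with pytest.raises(ValueError):
            model_aic(10.0, 5, 0)


class TestBiometricFit:
    def test_ae_parameter_recovery(self, ae_pairs_large):
        fit = fit_biometric_model(ae_pairs_large, "AE")
        assert fit.converged
        assert 0.55 <= fit.components.a2 <= 0.65
        assert 0.35 <= fit.components.e2 <= 0.45

    def test_null_recovery_under_e_only(self):
        spec = TwinCohortSpec(n_mz=2000, n_dz=2000,
                              components=VarianceComponentsSpec(e2=1.0), seed=3)
        pairs = pairs_from_table(simulate_twin_phenotypes(spec))
        fit = fit_biometric_model(pairs, "ADE")
        assert fit.components.a2 + fit.components.d2 < 0.05

    def test_ade_boundary_equals_ae(self, pair_factory):
        # r_MZ < 2 r_DZ: dominance estimate collapses to the boundary
        pairs = pair_factory(0.6, 1000, "MZ", 4) + pair_factory(0.45, 1000, "DZ", 5)
        ade = fit_biometric_model(pairs, "ADE")
        ae = fit_biometric_model(pairs, "AE")
        assert ade.components.d2 < 1e-3
        assert abs(ade.minus2ll - ae.minus2ll) < 1e-4

    def test_components_standardized_and_nonnegative(self, small_pairs):
        for model in ("ADE", "ACE", "AE", "CE", "DE", "E"):
            c = fit_biometric_model(small_pairs, model).components
            assert c.a2 + c.d2 + c.c2 + c.e2 == pytest.approx(1.0, abs=1e-9)
            assert min(c.sigma2_a, c.sigma2_d, c.sigma2_c, c.sigma2_e) >= 0.0

    def test_structured_never_beats_saturated(self, small_pairs):
        sat = fit_saturated(small_pairs)
        for model in ("ADE", "ACE"):
            fit = fit_biometric_model(small_pairs, model)
            assert fit.minus2ll >= sat.minus2ll - 1e-6

    def test_dropping_component_never_decreases_m2ll(self, small_pairs):
        ade = fit_biometric_model(small_pairs, "ADE")
        ae = fit_biometric_model(small_pairs, "AE")
        e = fit_biometric_model(small_pairs, "E")
        assert ae.minus2ll >= ade.minus2ll - 1e-8
        assert e.minus2ll >= ae.minus2ll - 1e-8

    def test_ml_agrees_with_moment_estimator_at_large_n(self):
        spec = TwinCohortSpec(n_mz=20000, n_dz=20000,
                              components=VarianceComponentsSpec(a2=0.52, e2=0.48), seed=1)
        pairs = pairs_from_table(simulate_twin_phenotypes(spec))
        fit = fit_biometric_model(pairs, "AE")
        r_mz = intraclass_correlation(pairs, "MZ")
        assert fit.components.a2 == pytest.approx(r_mz, abs=0.01)

    def test_ace_with_dominance_data_underestimates_h2(self, pair_factory):
        # r_MZ > 2 r_DZ: ACE drives c2 to its boundary and h2 below ADE's
        pairs = pair_factory(0.7, 1000, "MZ", 8) + pair_factory(0.25, 1000, "DZ", 9)
        ace = fit_biometric_model(pairs, "ACE")
        ade = fit_biometric_model(pairs, "ADE")
        assert ace.components.c2 < 1e-3
        assert ace.components.h2 < ade.components.h2

    def test_requires_both_zygosities(self, pair_factory):
        with pytest.raises(ValueError, match="zygosity"):
            fit_biometric_model(pair_factory(0.5, 10, "MZ", 1), "AE")

    def test_aic_identity_holds(self, small_pairs):
        fit = fit_biometric_model(small_pairs, "AE")
        assert fit.aic == pytest.approx(
            fit.minus2ll - 2 * (fit.n_obs - fit.n_params), abs=1e-9)
        assert fit.n_obs == 2 * len(small_pairs)


class TestSaturated:
    def test_closed_form_matches_numeric_optimizer(self, small_pairs):
        sat = fit_saturated(small_pairs)
        st_ = _moments(small_pairs)

        def neg2ll(x):
            total = 0.0
            for k, zyg in enumerate(("MZ", "DZ")):
                m = st_.by_zyg(zyg)
                mu1, mu2, lv1, lv2, z = x[5 * k:5 * k + 5]
                v1, v2 = math.exp(lv1), math.exp(lv2)
                c = math.tanh(z) * math.sqrt(v1 * v2)
                det = v1 * v2 - c * c
                s11 = m.ss11 - 2 * mu1 * m.sum1 + m.n * mu1 * mu1
                s22 = m.ss22 - 2 * mu2 * m.sum2 + m.n * mu2 * mu2
                s12 = m.ss12 - mu1 * m.sum2 - mu2 * m.sum1 + m.n * mu1 * mu2
                quad = (v2 * s11 - 2 * c * s12 + v1 * s22) / det
                total += 2 * m.n * _LN_2PI + m.n * math.log(det) + quad
            return total

        res = optimize.minimize(
            neg2ll, np.array([0, 0, 0, 0, 0, 0.3, 0.3, 0.2, 0.2, 0.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 40000, "maxfev": 40000})
        assert sat.minus2ll == pytest.approx(res.fun, abs=1e-6)

    def test_parameter_count_is_ten(self, small_pairs):
        assert fit_saturated(small_pairs).n_params == 10

    def test_saturated_not_above_structured(self, ae_pairs_large):
        sat = fit_saturated(ae_pairs_large)
        ade = fit_biometric_model(ae_pairs_large, "ADE")
        assert sat.minus2ll <= ade.minus2ll + 1e-6


class TestLikelihoodRatio:
    def test_zero_delta_gives_p_one(self, small_pairs):
        ae = fit_biometric_model(small_pairs, "AE")
        ade = fit_biometric_model(small_pairs, "ADE")
        cmp_ = likelihood_ratio_test(ae, ade)
        if cmp_.delta_minus2ll < 1e-6:
            assert cmp_.p_value == pytest.approx(1.0, abs=1e-4)

    def test_chi2_tail_worked_value(self):
        # delta 8.44 on 6 df: the printed saturated-vs-ADE comparison
        assert stats.chi2.sf(8.44, 6) == pytest.approx(0.2076, abs=1e-3)

    def test_extreme_statistic(self):
        assert stats.chi2.sf(100.0, 1) < 1e-20

    def test_mismatched_data_rejected(self, small_pairs, pair_factory):
        other = pair_factory(0.5, 30, "MZ", 1) + pair_factory(0.2, 30, "DZ", 2)
        f1 = fit_biometric_model(small_pairs, "AE")
        f2 = fit_biometric_model(other, "ADE")
        with pytest.raises(ValueError, match="different data"):
            likelihood_ratio_test(f1, f2)


class TestHeritability:
    def test_e_only_model_gives_zero(self, small_pairs):
        fit = fit_biometric_model(small_pairs, "E")
        est = heritability(fit)
        assert est.h2 == 0.0 and est.ci_low == 0.0 and est.ci_high == 0.0

    def test_profile_endpoints_on_chi2_cutoff(self, ae_pairs_large):
        from twinconn.twin_models import _profile_m2ll
        fit = fit_biometric_model(ae_pairs_large, "AE")
        est = heritability(fit)
        for endpoint in (est.ci_low, est.ci_high):
            assert 0.0 < endpoint < 1.0
            rise = _profile_m2ll("AE", fit._stats, endpoint) - fit.minus2ll
            assert rise == pytest.approx(3.841, abs=0.01)

    def test_saturated_fit_rejected(self, small_pairs):
        with pytest.raises(ValueError, match="saturated"):
            heritability(fit_saturated(small_pairs))

    def test_ci_brackets_estimate(self, ae_pairs_large):
        fit = fit_biometric_model(ae_pairs_large, "ADE")
        est = heritability(fit)
        assert est.ci_low <= est.h2 <= est.ci_high


class TestModelSelection:
    def test_lowest_aic_wins(self, small_pairs):
        fits = [fit_biometric_model(small_pairs, m) for m in ("ADE", "AE", "E")]
        fits.append(fit_saturated(small_pairs))
        sel = select_model(fits)
        structured = [f for f in fits if f.model != "saturated"]
        best_aic = min(f.aic for f in structured)
        assert sel.best.aic == pytest.approx(best_aic)
        assert set(sel.table["model"]) == {"ADE", "AE", "E"}
        assert sel.table["p_vs_saturated"].notna().all()

    def test_tie_broken_toward_fewer_parameters(self, small_pairs):
        ade = fit_biometric_model(small_pairs, "ADE")
        ae = fit_biometric_model(small_pairs, "AE")
        ae_tied = type(ae)(model="AE", mean=ae.mean, components=ae.components,
                           minus2ll=ae.minus2ll, n_params=3, n_obs=ae.n_obs,
                           aic=ade.aic, converged=True, _stats=ae._stats)
        sel = select_model([ade, ae_tied])
        assert sel.best.model == "AE"

    def test_single_fit_returned_unchanged(self, small_pairs):
        fit = fit_biometric_model(small_pairs, "AE")
        assert select_model([fit]).best is fit


class TestGroupMoments:
    def test_identical_groups_give_p_one(self, pair_factory):
        pairs = pair_factory(0.4, 50, "MZ", 1)
        as_dz = [TwinPairObservation(p.pair_id, "DZ", p.y1, p.y2) for p in pairs]
        res = compare_group_moments(pairs, as_dz)
        assert res.p_mean == pytest.approx(1.0, abs=1e-9)
        assert res.p_var == pytest.approx(1.0, abs=1e-9)

    def test_mean_shift_detected_variance_preserved(self, pair_factory):
        mz = pair_factory(0.3, 200, "MZ", 21)
        dz = pair_factory(0.3, 200, "DZ", 22, mean=5.0)
        res = compare_group_moments(mz, dz)
        assert res.p_mean < 1e-10
        assert res.p_var > 0.05

    def test_scale_difference_detected(self, pair_factory):
        mz = pair_factory(0.3, 500, "MZ", 3)
        dz = pair_factory(0.3, 500, "DZ", 4, var=4.0)
        assert compare_group_moments(mz, dz).p_var < 1e-6


@settings(max_examples=25, deadline=None)
@given(st.floats(0.0, 0.8), st.integers(0, 1000))
def test_icc_bounded_for_random_cohorts(r, seed):
    """Double-entry ICC always lies in [-1, 1]."""
    pairs = make_pairs_prop(r, seed)
    val = intraclass_correlation(pairs)
    assert -1.0 <= val <= 1.0


def make_pairs_prop(r, seed):
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    y = rng.multivariate_normal([0, 0], cov, size=10)
    return [TwinPairObservation(f"p{i}", "MZ", y[i, 0], y[i, 1]) for i in range(10)]
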