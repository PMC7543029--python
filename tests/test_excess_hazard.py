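import numpy as np
import pandas as pd
import pytest

from mmisurv.excess_hazard import (
    EffectSpec,
    FittedModel,
    ModelSpec,
    fit,
    log_likelihood,
    prepare_patients,
)
from mmisurv import synthetic_registry as synth

from conftest import flat_table, manual_model, patients_frame


# -- hazard evaluation closed forms -----------------------------------------


def test_constant_baseline_hazard():
    m = manual_model([np.log(0.2)], baseline_df=0)
    pat = patients_frame([1.0], 1)
    for t in (0.1, 1.0, 4.7):
        assert m.excess_hazard(pat, t)[0, 0] == pytest.approx(0.2, rel=1e-12)


def test_proportional_linear_effect_closed_form():
    # beta=0.5 on x=2 over constant baseline 0.2 -> 0.2 * e^1
    m = manual_model(
        [np.log(0.2), 0.5],
        baseline_df=0,
        effects=(EffectSpec("x"),),
        x=np.r_[np.full(20, 2.0), np.full(20, -2.0)],  # mean-zero coding
    )
    pat = patients_frame([1.0], 1, x=2.0)
    assert m.excess_hazard(pat, 3.0)[0, 0] == pytest.approx(0.2 * np.e, rel=1e-12)


def test_time_dependent_effect_pivots_at_one_year():
    m = manual_model(
        [np.log(0.2), 0.3],
        baseline_df=0,
        effects=(EffectSpec("x", time_dependent=True),),
        x=np.r_[np.full(20, 1.0), np.full(20, -1.0)],
    )
    pat = patients_frame([1.0], 1, x=1.0)
    assert m.excess_hazard(pat, 1.0)[0, 0] == pytest.approx(0.2, rel=1e-12)
    assert m.excess_hazard(pat, 2.0)[0, 0] == pytest.approx(0.2 * 2**0.3, rel=1e-12)


def test_hazard_requires_positive_time():
    m = manual_model([np.log(0.2)], baseline_df=0)
    with pytest.raises(ValueError, match="positive"):
        m.excess_hazard(patients_frame([1.0], 1), 0.0)


# -- cumulative hazard -------------------------------------------------------


def test_cumulative_constant_hazard_matches_closed_form():
    m = manual_model([np.log(0.2)], baseline_df=0)
    pat = patients_frame([1.0], 1)
    assert m.cumulative_excess_hazard(pat, 5.0)[0, 0] == pytest.approx(1.0, abs=1e-10)
    assert m.cumulative_excess_hazard(pat, 1e-12)[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_cumulative_weibull_closed_form():
    # lambda_E = 0.45 t^0.5 = 0.3 * 1.5 * t^0.5; Lambda(2) = 0.3 * 2^1.5
    m = manual_model([np.log(0.45), 0.5], baseline_df=1)
    pat = patients_frame([1.0], 1)
    got = m.cumulative_excess_hazard(pat, 2.0)[0, 0]
    # the sqrt integrand is not polynomial: 20-node quadrature is ~1e-5 exact
    assert got == pytest.approx(0.3 * 2**1.5, rel=1e-4)


# -- likelihood ---------------------------------------------------------------


def test_loglik_one_death_closed_form():
    table = flat_table(0.1)
    data = patients_frame([1.0], 1)
    spec = ModelSpec(baseline_df=0)
    val = log_likelihood(spec, [np.log(0.2)], data, table)
    assert val == pytest.approx(np.log(0.3) - 0.2, abs=1e-9)


def test_loglik_one_censored_closed_form():
    data = patients_frame([2.0], 0)
    val = log_likelihood(ModelSpec(baseline_df=0), [np.log(0.2)], data, None)
    assert val == pytest.approx(-0.4, abs=1e-10)


def test_loglik_reduces_to_classical_parametric_form():
    """With lambda_P = 0 the likelihood is the standard exponential one."""
    rng = np.random.default_rng(4)
    t = rng.exponential(3.0, 60)
    d = (t < 4.0).astype(int)
    t = np.minimum(t, 4.0)
    data = patients_frame(t, d)
    lam = 0.31
    ours = log_likelihood(ModelSpec(baseline_df=0), [np.log(lam)], data, None)
    classical = d.sum() * np.log(lam) - lam * t.sum()
    assert ours == pytest.approx(classical, rel=1e-10)


# -- fitting ------------------------------------------------------------------


def test_exponential_mle_closed_form():
    rng = np.random.default_rng(11)
    t = np.minimum(rng.exponential(2.0, 300), 5.0)
    d = (t < 5.0).astype(int)
    data = patients_frame(t, d)
    m = fit(ModelSpec(baseline_df=0), data, None)
    assert np.exp(m.params[0]) == pytest.approx(d.sum() / t.sum(), rel=1e-6)
    # closed-form AIC of the exponential fit
    dd, tt = d.sum(), t.sum()
    assert m.aic == pytest.approx(-2 * (dd * np.log(dd / tt) - dd) + 2, rel=1e-9)


def test_fit_rejects_zero_events():
    data = patients_frame([1.0, 2.0, 3.0, 4.0], 0)
    with pytest.raises(ValueError, match="zero events"):
        fit(ModelSpec(baseline_df=0), data, None)


def test_information_criteria_identities(colon_cohort, life_table):
    patients, _, _ = colon_cohort
    m = fit(ModelSpec(baseline_df=3, effects=(EffectSpec("age"),)), patients, life_table)
    assert m.aic == pytest.approx(-2 * m.log_likelihood + 2 * m.n_params, abs=1e-12)
    assert m.bic == pytest.approx(
        -2 * m.log_likelihood + m.n_params * np.log(m.n_events), abs=1e-12
    )
    # covariance symmetric positive semi-definite
    np.testing.assert_allclose(m.covariance, m.covariance.T, atol=1e-12)
    assert np.linalg.eigvalsh(m.covariance).min() >= -1e-10


def test_parameter_recovery_within_wald_interval(life_table):
    scenario = synth.Scenario(
        n=2000,
        seed=25,
        baseline_rate=0.25,
        baseline_shape=0.8,
        year_range=(2005, 2010),
        censor_date=2016.0,
        effects=(synth.TrueEffect("age", beta=0.5, center=70.0, scale=10.0),),
    )
    patients, _ = synth.simulate_cohort(scenario, life_table)
    m = fit(ModelSpec(baseline_df=3, effects=(EffectSpec("age"),)), patients, life_table)
    tab = m.param_table().set_index("name")
    est, se = tab.loc["age", "estimate"], tab.loc["age", "se"]
    assert abs(est - 0.05) < 2 * se  # 0.5 per decade = 0.05 per year


def test_loglik_invariant_to_affine_covariate_recoding(colon_cohort, life_table):
    # recode a pure covariate copy so the life-table keys (age) are untouched
    patients, _, _ = colon_cohort
    patients = patients.assign(x=patients["age"])
    m1 = fit(ModelSpec(baseline_df=3, effects=(EffectSpec("x"),)), patients, life_table)
    recoded = patients.assign(x=2.0 * patients["x"] + 5.0)
    m2 = fit(ModelSpec(baseline_df=3, effects=(EffectSpec("x"),)), recoded, life_table)
    assert m1.log_likelihood == pytest.approx(m2.log_likelihood, abs=1e-4)
    i = m1.param_names.index("x")
    assert m2.params[i] == pytest.approx(m1.params[i] / 2.0, rel=1e-3)


def test_rank_deficient_design_names_columns(colon_cohort, life_table):
    patients, _, _ = colon_cohort
    patients = patients.assign(age2=patients["age"])
    spec = ModelSpec(baseline_df=3, effects=(EffectSpec("age"), EffectSpec("age2")))
    from mmisurv.excess_hazard import DesignRankError

    with pytest.raises(DesignRankError, match="age"):
        fit(spec, patients, life_table)


# -- prediction ---------------------------------------------------------------


def test_predict_constant_hazard_survival():
    m = manual_model([np.log(0.2)], baseline_df=0)
    pat = patients_frame([1.0], 1)
    curve, pred = m.predict_net_survival(pat, [5.0])
    assert curve.survival[0] == pytest.approx(np.exp(-1.0), rel=1e-9)


def test_cohort_curve_of_identical_patients_equals_individual():
    m = manual_model([np.log(0.2)], baseline_df=0)
    pats = patients_frame([1.0, 1.0, 1.0], 1)
    curve, pred = m.predict_net_survival(pats, [1.0, 3.0])
    np.testing.assert_allclose(curve.survival, pred.survival[0])


def test_cohort_curve_is_convex_combination(colon_cohort, life_table):
    patients, _, _ = colon_cohort
    m = fit(ModelSpec(baseline_df=3, effects=(EffectSpec("age"),)), patients, life_table)
    grid = [0.5, 2.0, 5.0]
    curve, pred = m.predict_net_survival(patients.head(40), grid)
    assert np.all(curve.survival <= pred.survival.max(axis=0) + 1e-12)
    assert np.all(curve.survival >= pred.survival.min(axis=0) - 1e-12)


def test_delta_method_variances_nonnegative(colon_cohort, life_table):
    patients, _, _ = colon_cohort
    m = fit(ModelSpec(baseline_df=3, effects=(EffectSpec("age"),)), patients, life_table)
    pred = m.predict(patients.head(10), [1.0, 5.0], with_variance=True)
    assert np.all(pred.hazard_variance >= 0)
    assert np.all(pred.cumhaz_variance >= 0)


def test_quadrature_stable_under_refinement(colon_cohort, life_table):
    """20-node cumulative hazards agree with a 60-node refinement."""
    patients, _, _ = colon_cohort
    m = fit(ModelSpec(baseline_df=3, effects=(EffectSpec("age"),)), patients, life_table)
    from scipy.special import roots_legendre

    pat = patients.head(5)
    cum20 = m.cumulative_excess_hazard(pat, 5.0)[:, 0]
    xf, xtd = m.design.covariate_matrices(pat)
    g0, gamma, bf, btd = m.design.split_params(m.params)
    x60, w60 = roots_legendre(60)
    u = 5.0 / 2 * (x60 + 1)
    w = 5.0 / 2 * w60
    b = m.design.baseline_columns(np.log(u))
    eta = (g0 + b @ gamma)[None, :] + (xf @ bf)[:, None]
    cum60 = np.exp(eta) @ w
    np.testing.assert_allclose(cum20, cum60, rtol=5e-3)


# -- serialization ------------------------------------------------------------


def test_fitted_model_round_trip(tmp_path, colon_cohort, life_table):
    patients, _, _ = colon_cohort
    spec = ModelSpec(
        baseline_df=3,
        effects=(EffectSpec("age", form="spline"), EffectSpec("dep", form="categorical")),
    )
    m = fit(spec, patients, life_table)
    p = tmp_path / "model.json"
    m.save(p)
    back = FittedModel.load(p)
    pat = patients.head(7)
    np.testing.assert_allclose(
        back.excess_hazard(pat, [1.0, 4.0]), m.excess_hazard(pat, [1.0, 4.0]), rtol=1e-12
    )
    assert back.aic == pytest.approx(m.aic)


def test_baseline_scale_override(colon_cohort, life_table):
    """The baseline spline can act on t itself instead of log t."""
    patients, _, _ = colon_cohort
    spec_t = ModelSpec(baseline_df=3, effects=(EffectSpec("age"),), baseline_scale="identity")
    spec_log = ModelSpec(baseline_df=3, effects=(EffectSpec("age"),))
    m_t = fit(spec_t, patients, life_table)
    m_log = fit(spec_log, patients, life_table)
    assert "@t" in spec_t.canonical and "@t" not in spec_log.canonical
    assert m_t.design.baseline_basis.scale == "identity"
    # both parameterisations should describe similar survival at 5 years
    s_t, _ = m_t.predict_net_survival(patients.head(50), [5.0])
    s_log, _ = m_log.predict_net_survival(patients.head(50), [5.0])
    assert abs(s_t.survival[0] - s_log.survival[0]) < 0.05


def test_prepare_patients_shifts_same_day_events():
    df = patients_frame([0.0, 2.0], 1)
    out = prepare_patients(df)
    assert out["time"].iloc[0] == pytest.approx(1 / 365.25)
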