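import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy import stats

from mmisurv import synthetic_registry as synth
from mmisurv.life_tables import PopulationPaths


def test_same_seed_identical_output(life_table):
    sc = synth.colon_like(n=400, seed=5)
    a_pat, a_truth = synth.simulate_cohort(sc, life_table)
    b_pat, b_truth = synth.simulate_cohort(sc, life_table)
    pd.testing.assert_frame_equal(a_pat, b_pat)
    pd.testing.assert_frame_equal(a_truth, b_truth)
    c_pat, _ = synth.simulate_cohort(sc, life_table, seed=6)
    assert not a_pat["time"].equals(c_pat["time"])


def test_zero_excess_matches_expected_survival(life_table):
    """With no excess hazard, observed all-cause survival is S_P."""
    sc = synth.Scenario(
        n=5000, seed=7, baseline_rate=0.0, year_range=(2005, 2010), censor_date=2016.0
    )
    pat, _ = synth.simulate_cohort(sc, life_table)
    km = KaplanMeierFitter().fit(pat["time"], pat["status"])
    s5 = float(km.survival_function_at_times(5.0).iloc[0])
    paths = PopulationPaths(
        life_table,
        pat["age"].to_numpy(),
        pat["diag_date"].to_numpy(),
        pat["sex"].to_numpy(),
        pat["dep"].astype(str).to_numpy(),
        np.full(len(pat), 5.001),
    )
    sp5 = np.exp(-paths.cumhaz_at(np.full(len(pat), 5.0))).mean()
    mc_se = np.sqrt(sp5 * (1 - sp5) / len(pat))
    assert abs(s5 - sp5) < 2 * mc_se + 1e-3


def test_true_net_survival_closed_forms():
    sc = synth.Scenario(n=10, baseline_rate=0.2, year_range=(2005, 2010), censor_date=2016.0)
    cov = pd.DataFrame({"age": [70.0], "dep": [3], "year": [2008]})
    assert synth.true_net_survival(sc, cov, 5.0)[0] == pytest.approx(np.exp(-1.0))
    assert synth.true_net_survival(sc, cov, 0.0)[0] == 1.0
    # Weibull: shape 1.5, rate chosen so Lambda(2) = 0.3 * 2^1.5
    rate = 0.3 * 2**1.5 / 2**1.5
    sc_w = synth.Scenario(
        n=10, baseline_rate=rate, baseline_shape=1.5, year_range=(2005, 2010), censor_date=2016.0
    )
    assert synth.true_net_survival(sc_w, cov, 2.0)[0] == pytest.approx(
        np.exp(-0.3 * 2**1.5), rel=1e-12
    )


def test_censoring_date_validation():
    with pytest.raises(ValueError, match="censoring date"):
        synth.Scenario(n=10, year_range=(2005, 2010), censor_date=2005.0)


def test_observed_time_never_exceeds_censoring(life_table):
    sc = synth.lung_like(n=500, seed=3)
    pat, truth = synth.simulate_cohort(sc, life_table)
    t_cens = sc.censor_date - pat["diag_date"]
    assert np.all(pat["time"] <= t_cens + 1e-12)
    assert set(truth["cause"]) <= {"excess", "population", "censor"}
    assert (pat["status"] == (truth["cause"] != "censor").astype(int)).all()


def test_event_time_inversion_matches_thinning_sampler(life_table):
    """Inversion vs an independent accept-reject (thinning) sampler."""
    sc = synth.Scenario(
        n=2000,
        seed=13,
        baseline_rate=0.3,
        baseline_shape=1.3,  # increasing hazard: bounded on (0, T]
        effects=(synth.TrueEffect("age", beta=0.2, center=70.0, scale=10.0),),
        year_range=(2005, 2010),
        censor_date=2030.0,
        age_sd=0.01,  # essentially one covariate pattern
    )
    pat, truth = synth.simulate_cohort(sc, None)
    horizon = 8.0
    inv_times = pat.loc[(pat["status"] == 1) & (pat["time"] < horizon), "time"].to_numpy()

    rng = np.random.default_rng(7)
    lam = lambda t: 0.3 * 1.3 * t**0.3  # age ~ 70 -> effect ~ 0
    lam_max = lam(horizon)
    thinned = []
    for _ in range(2000):
        t, accepted = 0.0, None
        while t < horizon:
            t += rng.exponential(1.0 / lam_max)
            if t < horizon and rng.uniform() < lam(t) / lam_max:
                accepted = t
                break
        if accepted is not None:
            thinned.append(accepted)
    stat = stats.ks_2samp(inv_times, np.asarray(thinned))
    assert stat.pvalue > 0.01


def test_synthetic_life_table_gompertz_values():
    table = synth.make_synthetic_life_table(
        a=1e-5, b=0.1, strata_multipliers={"only": 1.0}, calendar_trend=0.0,
        age_range=(40, 99), year_range=(2000, 2005),
    )
    got = table.rate_at(70, 2003, "male", "only")[0]
    assert got == pytest.approx(1e-5 * np.exp(7.0), rel=1e-12)
    # zero trend -> identical columns across years
    assert np.allclose(table.rates[..., 0], table.rates[..., -1])


def test_stratum_multiplier_is_exact_ratio():
    table = synth.make_synthetic_life_table(
        strata_multipliers={"a": 1.0, "b": 1.3}, age_range=(40, 90), year_range=(2000, 2002)
    )
    ra = table.rates[:, 0]
    rb = table.rates[:, 1]
    np.testing.assert_allclose(rb / ra, 1.3, rtol=1e-12)


def test_life_table_cap_errors():
    with pytest.raises(ValueError, match="hard cap"):
        synth.make_synthetic_life_table(a=1e-3, b=0.12)
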