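import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmisurv.excess_hazard import ModelSpec
from mmisurv.model_averaging import (
    average_predictions,
    evidence_ratio,
    unconditional_variance,
    xic_weights,
)
from mmisurv.model_selection import ModelSet

from conftest import manual_model, patients_frame


def test_single_model_weight_is_one():
    assert xic_weights(np.array([123.4])).tolist() == [1.0]


def test_two_model_weights_closed_form():
    w = xic_weights(np.array([100.0, 102.0]))
    expected = np.array([1.0, np.exp(-1.0)]) / (1.0 + np.exp(-1.0))
    np.testing.assert_allclose(w, expected, rtol=1e-12)
    np.testing.assert_allclose(w, [0.7311, 0.2689], atol=5e-5)


def test_equal_models_share_weight_equally():
    for k in (2, 5, 9):
        np.testing.assert_allclose(xic_weights(np.full(k, 87.0)), np.full(k, 1.0 / k))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=50.0), min_size=1, max_size=6),
    st.floats(min_value=-1e3, max_value=1e3),
)
def test_weights_sum_to_one_and_shift_invariant(deltas, shift):
    c = np.asarray(deltas) + 1000.0
    w = xic_weights(c)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(w, xic_weights(c + shift), rtol=1e-9)
    assert np.argmax(w) == np.argmin(c)


def test_evidence_ratio_constants():
    """exp(Delta/2) = 2.7, 7.4, 54.6 for Delta = 2, 4, 8 (to one decimal)."""
    for delta, expected in ((2.0, 2.7), (4.0, 7.4), (8.0, 54.6)):
        e = evidence_ratio(np.array([100.0, 100.0 + delta]), 0, 1)
        assert round(e, 1) == expected
    assert evidence_ratio(np.array([100.0, 104.0]), 0, 0) == 1.0


def test_evidence_ratio_multiplicative():
    c = np.array([10.0, 13.0, 17.5])
    e = lambda m, n: evidence_ratio(c, m, n)
    assert e(0, 1) * e(1, 2) == pytest.approx(e(0, 2), rel=1e-12)


# -- unconditional variance ---------------------------------------------------


def test_variance_collapses_to_common_variance():
    v = unconditional_variance([0.4, 0.6], [1.0, 1.0], [0.09, 0.09])
    assert v == pytest.approx(0.09, rel=1e-12)


def test_variance_pure_between_spread():
    d = 0.35
    v = unconditional_variance([0.5, 0.5], [1.0 + d, 1.0 - d], [0.0, 0.0])
    assert v == pytest.approx(d**2, rel=1e-12)


def test_variance_three_model_direct_formula():
    w = np.array([0.5, 0.3, 0.2])
    est = np.array([1.0, 1.2, 0.8])
    var = np.array([0.01, 0.02, 0.04])
    avg = np.sum(w * est)
    oracle = np.sum(w * np.sqrt(var + (est - avg) ** 2)) ** 2
    assert unconditional_variance(w, est, var) == pytest.approx(oracle, rel=1e-12)
    # lower bound: never below the zero-between version
    assert unconditional_variance(w, est, var) >= np.sum(w * np.sqrt(var)) ** 2


def test_negative_variance_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        unconditional_variance([1.0], [1.0], [-0.1])


# -- averaging of predictions -------------------------------------------------


def _two_constant_models(rate_a=0.2, rate_b=0.4):
    a = manual_model([np.log(rate_a)], baseline_df=0, seed=1)
    b = manual_model([np.log(rate_b)], baseline_df=0, seed=2)
    from mmisurv.excess_hazard import EffectSpec

    b.spec = ModelSpec(baseline_df=0, effects=())
    a.spec = ModelSpec(baseline_df=1, effects=())  # distinct canonical only
    a.log_likelihood = b.log_likelihood = -50.0
    a.n_params = b.n_params = 1  # equal AIC -> equal weights
    return a, b


def test_single_model_average_is_identity(colon_cohort):
    m = manual_model([np.log(0.2)], baseline_df=0)
    ms = ModelSet(models=[m], criterion="aic")
    pats = patients_frame([1.0, 2.0], 1)
    avg = average_predictions(ms, pats, [1.0, 5.0])
    np.testing.assert_allclose(avg.hazard, m.excess_hazard(pats, [1.0, 5.0]), rtol=1e-12)
    np.testing.assert_allclose(
        avg.survival, np.exp(-m.cumulative_excess_hazard(pats, [1.0, 5.0])), rtol=1e-12
    )


def test_equal_weight_hazards_average_arithmetically():
    a, b = _two_constant_models(0.1, 0.3)
    ms = ModelSet(models=[a, b], criterion="aic")
    pats = patients_frame([1.0], 1)
    avg = average_predictions(ms, pats, [2.0])
    assert avg.hazard[0, 0] == pytest.approx(0.2, rel=1e-9)


def test_survival_averages_on_cumulative_hazard_scale():
    """S_MA = exp(-sum w Lambda), not sum w exp(-Lambda): 0.2231 not 0.2518."""
    a, b = _two_constant_models(0.2, 0.4)  # Lambda(5) = 1 and 2
    ms = ModelSet(models=[a, b], criterion="aic")
    avg = average_predictions(ms, patients_frame([1.0], 1), [5.0])
    assert avg.survival[0, 0] == pytest.approx(np.exp(-1.5), abs=1e-6)
    assert avg.survival[0, 0] == pytest.approx(0.2231, abs=2e-4)
    assert abs(avg.survival[0, 0] - 0.2518) > 0.02


def test_grid_must_be_positive():
    m = manual_model([np.log(0.2)], baseline_df=0)
    ms = ModelSet(models=[m], criterion="aic")
    with pytest.raises(ValueError, match="positive"):
        average_predictions(ms, patients_frame([1.0], 1), [0.0, 1.0])
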