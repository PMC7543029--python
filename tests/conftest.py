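import numpy as np
import pandas as pd
import pytest

from mmisurv import synthetic_registry as synth
from mmisurv.excess_hazard import FittedModel, ModelDesign, ModelSpec, fit
from mmisurv.life_tables import LifeTable


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return synth.make_synthetic_life_table()


@pytest.fixture(scope="session")
def colon_cohort(life_table):
    """A moderate-lethality cohort with complete 5-year follow-up."""
    scenario = synth.colon_like(n=800, seed=9, censor_date=2016.0)
    patients, truth = synth.simulate_cohort(scenario, life_table)
    return patients, truth, scenario


def flat_table(rate: float, years=(1980, 2030), ages=(0, 109)) -> LifeTable:
    """Life table with one constant hazard everywhere (all sexes/quintiles)."""
    ages_arr = np.arange(ages[0], ages[1] + 1)
    years_arr = np.arange(years[0], years[1] + 1)
    sexes = ("female", "male")
    strata = tuple(str(q) for q in range(1, 6)) + ("all",)
    rates = np.full((len(sexes), len(strata), len(ages_arr), len(years_arr)), rate)
    return LifeTable(ages=ages_arr, years=years_arr, sexes=sexes, strata=strata, rates=rates)


def manual_model(params, baseline_df=0, effects=(), x=None, n_fit=40, seed=0) -> FittedModel:
    """A FittedModel with hand-set parameters.

    The design is built from a small synthetic frame whose continuous
    covariates have exact zero mean, so centering does not shift the
    requested parameter values.
    """
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "age": 70.0,
            "sex": "male",
            "dep": 3,
            "year": 2008,
            "time": rng.uniform(0.5, 6.0, n_fit),
            "status": 1,
        }
    )
    if x is not None:
        data["x"] = np.asarray(x, dtype=float)[: len(data)] if np.ndim(x) else float(x)
        data["x"] -= data["x"].mean()
    spec = ModelSpec(baseline_df=baseline_df, effects=tuple(effects))
    design = ModelDesign(spec, data)
    params = np.asarray(params, dtype=float)
    assert params.size == design.n_params
    return FittedModel(
        spec=spec,
        design=design,
        params=params,
        covariance=np.eye(params.size) * 1e-4,
        log_likelihood=0.0,
        n_params=params.size,
        n_events=int(data["status"].sum()),
        n_obs=len(data),
    )


def patients_frame(time, status, **cols) -> pd.DataFrame:
    time = np.atleast_1d(np.asarray(time, dtype=float))
    df = pd.DataFrame(
        {
            "age": cols.pop("age", 70.0),
            "sex": cols.pop("sex", "male"),
            "dep": cols.pop("dep", 3),
            "year": cols.pop("year", 2008),
            "time": time,
            "status": np.broadcast_to(status, time.shape).astype(int),
        }
    )
    for k, v in cols.items():
        df[k] = v
    return df
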