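"""Registry-like synthetic cohorts with a known true excess hazard.

Each scenario draws patient covariates (age at diagnosis, deprivation
quintile, diagnosis year), a cancer death time from a closed-form true
excess hazard, an other-cause death time from a population life table, and
applies administrative censoring at a fixed calendar cut-off.  Because the
same life table drives both the simulation of other-cause deaths and the
later estimation, the core assumption of the relative-survival setting —
that background mortality is well approximated by the population hazard —
holds exactly by construction; a multiplicative misspecification factor can
break it deliberately for robustness experiments.

The true excess hazard is a Weibull-form baseline with log-linear covariate
effects, optionally time-dependent via a ``log t`` multiplier:

    lambda_E(t, x) = lambda0 * kappa * t^(kappa-1) * exp(ps(x)) * t^(s(x)),

with ``ps(x)`` the proportional and ``s(x)`` the time-dependent linear
predictor.  Its cumulative hazard is closed form, so cancer death times are
drawn by exact inversion and the true net survival of any covariate pattern
is available analytically for evaluation.

All scenario numerics are package choices emulating three qualitative
regimes of cancer lethality and trend (lung-, colon- and breast-like); they
are not registry estimates.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .life_tables import LifeTable, PopulationPaths

__all__ = [
    "TrueEffect",
    "Scenario",
    "simulate_cohort",
    "true_net_survival",
    "true_cumulative_excess_hazard",
    "make_synthetic_life_table",
    "lung_like",
    "colon_like",
    "breast_like",
    "with_time_dependent_age",
]


@dataclass(frozen=True)
class TrueEffect:
    """A log-linear covariate effect in the generating excess hazard.

    The covariate enters as ``g(x) = (x - center) / scale``; with
    ``time_dependent=True`` the contribution is ``beta * g(x) * log t``.
    """

    variable: str
    beta: float
    center: float = 0.0
    scale: float = 1.0
    time_dependent: bool = False


@dataclass(frozen=True)
class Scenario:
    """A complete data-generating configuration."""

    n: int
    seed: int = 0
    sex: str = "male"
    age_mean: float = 70.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (15.0, 99.0)
    dep_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    year_range: tuple[int, int] = (2005, 2010)
    censor_date: float = 2011.0
    baseline_rate: float = 0.25      # lambda0: cumulative hazard scale
    baseline_shape: float = 1.0      # kappa: Weibull shape (1 = exponential)
    effects: tuple[TrueEffect, ...] = ()
    misspecification: float = 1.0    # multiplies the other-cause hazard when simulating
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if abs(sum(self.dep_probs) - 1.0) > 1e-9:
            raise ValueError("deprivation probabilities must sum to 1")
        if self.censor_date < self.year_range[1] + 1:
            raise ValueError(
                "administrative censoring date must cover the full final diagnosis year "
                f"(censor_date={self.censor_date}, last year={self.year_range[1]}); "
                "otherwise some patients would have no follow-up"
            )
        if self.baseline_rate < 0 or self.baseline_shape <= 0:
            raise ValueError("baseline must have rate >= 0 and shape > 0")


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream so adding a draw does not shift the others."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _predictors(scenario: Scenario, covariates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    n = len(covariates)
    ps = np.zeros(n)
    s = np.zeros(n)
    for e in scenario.effects:
        g = (covariates[e.variable].to_numpy(dtype=float) - e.center) / e.scale
        if e.time_dependent:
            s += e.beta * g
        else:
            ps += e.beta * g
    return ps, s


def true_cumulative_excess_hazard(scenario: Scenario, covariates: pd.DataFrame, t) -> np.ndarray:
    """Closed-form Lambda_E(t) per patient; shape (n,) or (n, n_times)."""
    ps, s = _predictors(scenario, covariates)
    kappa = scenario.baseline_shape
    p = kappa + s
    if np.any(p <= 0):
        raise ValueError("time-dependent effects too negative: hazard not integrable at 0")
    t = np.asarray(t, dtype=float)
    scalar_grid = t.ndim == 0 or t.shape == ps.shape
    coef = scenario.baseline_rate * kappa * np.exp(ps) / p
    if scalar_grid:
        return coef * t**p
    return coef[:, None] * t[None, :] ** p[:, None]


def true_net_survival(scenario: Scenario, covariates: pd.DataFrame, t) -> np.ndarray:
    """True net survival ``exp(-Lambda_E,true(t))``; S(0) = 1."""
    return np.exp(-true_cumulative_excess_hazard(scenario, covariates, t))


def _invert_excess(scenario: Scenario, covariates: pd.DataFrame, e: np.ndarray) -> np.ndarray:
    """Exact inversion of Lambda_E(t) = e for the Weibull-form true hazard."""
    ps, s = _predictors(scenario, covariates)
    kappa = scenario.baseline_shape
    p = kappa + s
    coef = scenario.baseline_rate * kappa * np.exp(ps) / p
    with np.errstate(divide="ignore"):
        return np.where(coef > 0, (e / np.where(coef > 0, coef, 1.0)) ** (1.0 / p), np.inf)


def simulate_cohort(
    scenario: Scenario, table: LifeTable | None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns ``(patients, truth_sidecar)``.

    The patients frame has columns ``age, sex, dep, year, diag_date, time,
    status``; the sidecar carries the latent cause of exit and the true
    1-year and 5-year net survival of each patient.  Observed status is 1
    for death from either cause before administrative censoring.
    """
    seed = scenario.seed if seed is None else seed
    n = scenario.n
    rng_age = _stream(seed, "age")
    rng_dep = _stream(seed, "dep")
    rng_year = _stream(seed, "year")
    rng_u = _stream(seed, "within-year")
    rng_exc = _stream(seed, "excess")
    rng_pop = _stream(seed, "population")

    lo, hi = scenario.age_range
    age = rng_age.normal(scenario.age_mean, scenario.age_sd, size=n)
    bad = (age < lo) | (age > hi)
    while bad.any():  # truncated normal by resampling
        age[bad] = rng_age.normal(scenario.age_mean, scenario.age_sd, size=int(bad.sum()))
        bad = (age < lo) | (age > hi)
    dep = rng_dep.choice(np.arange(1, 6), size=n, p=np.asarray(scenario.dep_probs))
    year = rng_year.integers(scenario.year_range[0], scenario.year_range[1] + 1, size=n)
    diag_date = year + rng_u.uniform(0.0, 1.0, size=n)

    cov = pd.DataFrame(
        {"age": age, "sex": scenario.sex, "dep": dep, "year": year, "diag_date": diag_date}
    )
    t_cens = scenario.censor_date - diag_date
    if np.any(t_cens <= 0):
        raise ValueError("some diagnosis dates fall after the censoring date")

    t_exc = _invert_excess(scenario, cov, -np.log(rng_exc.uniform(size=n)))

    if table is not None:
        paths = PopulationPaths(
            table, age, diag_date, np.repeat(scenario.sex, n), dep.astype(str), t_cens + 1e-9
        )
        e_pop = -np.log(rng_pop.uniform(size=n)) / scenario.misspecification
        t_pop = paths.invert(e_pop)
    else:
        t_pop = np.full(n, np.inf)

    t_obs = np.minimum(np.minimum(t_exc, t_pop), t_cens)
    cause = np.where(
        t_obs >= t_cens, "censor", np.where(t_exc <= t_pop, "excess", "population")
    )
    status = (cause != "censor").astype(int)
    t_obs = np.maximum(t_obs, 1.0 / 365.25)

    patients = cov.assign(time=t_obs, status=status)
    truth = pd.DataFrame(
        {
            "cause": cause,
            "true_s1": true_net_survival(scenario, cov, 1.0),
            "true_s5": true_net_survival(scenario, cov, 5.0),
        }
    )
    return patients, truth


# ---------------------------------------------------------------------------
# synthetic life tables
# ---------------------------------------------------------------------------


def make_synthetic_life_table(
    a: float = 1e-5,
    b: float = 0.095,
    age_range: tuple[int, int] = (15, 99),
    year_range: tuple[int, int] = (1990, 2016),
    sexes: tuple[str, ...] = ("male", "female"),
    strata_multipliers: dict | None = None,
    calendar_trend: float = -0.005,
    warn_above: float = 0.5,
    cap: float = 1.5,
) -> LifeTable:
    """Gompertz-like background mortality: ``rate = a exp(b age)`` per cell,
    scaled per stratum and drifting over calendar time by
    ``exp(calendar_trend * (year - year0))``.
    """
    if strata_multipliers is None:
        strata_multipliers = {str(q): 0.85 + 0.075 * q for q in range(1, 6)}
    ages = np.arange(age_range[0], age_range[1] + 1)
    years = np.arange(year_range[0], year_range[1] + 1)
    strata = tuple(sorted(strata_multipliers))
    mult = np.asarray([strata_multipliers[s] for s in strata])
    base = a * np.exp(b * ages)
    trend = np.exp(calendar_trend * (years - years[0]))
    rates = (
        np.ones((len(sexes), 1, 1, 1))
        * mult[None, :, None, None]
        * base[None, None, :, None]
        * trend[None, None, None, :]
    )
    top = float(rates.max())
    if top > cap:
        raise ValueError(f"synthetic life-table rate {top:.3g}/year exceeds the hard cap {cap}")
    if top > warn_above:
        warnings.warn(f"synthetic life-table rate reaches {top:.3g}/year", stacklevel=2)
    return LifeTable(ages=ages, years=years, sexes=tuple(sexes), strata=strata, rates=rates)


# ---------------------------------------------------------------------------
# scenario presets: three qualitative lethality/trend regimes
# ---------------------------------------------------------------------------


def _preset(label, **kw) -> Scenario:
    return Scenario(label=label, **kw)


def lung_like(n: int = 3000, seed: int = 0, **overrides) -> Scenario:
    """High lethality, early-peaking excess hazard (5-y net survival ~ 0.12)."""
    kw = dict(
        n=n,
        seed=seed,
        sex="male",
        age_mean=71.0,
        age_sd=9.0,
        dep_probs=(0.18, 0.19, 0.20, 0.21, 0.22),
        year_range=(2005, 2010),
        censor_date=2011.0,
        baseline_rate=0.65,
        baseline_shape=0.75,
        effects=(
            TrueEffect("age", beta=0.22, center=70.0, scale=10.0),
            TrueEffect("dep", beta=0.08, center=3.0),
            TrueEffect("year", beta=-0.015, center=2008.0),
        ),
    )
    kw.update(overrides)
    return _preset("lung-like", **kw)


def colon_like(n: int = 3000, seed: int = 0, **overrides) -> Scenario:
    """Moderate lethality and trend (5-y net survival ~ 0.5)."""
    kw = dict(
        n=n,
        seed=seed,
        sex="male",
        age_mean=70.0,
        age_sd=10.0,
        dep_probs=(0.2, 0.2, 0.2, 0.2, 0.2),
        year_range=(2005, 2010),
        censor_date=2011.0,
        baseline_rate=0.25,
        baseline_shape=0.8,
        effects=(
            TrueEffect("age", beta=0.20, center=70.0, scale=10.0),
            TrueEffect("dep", beta=0.10, center=3.0),
            TrueEffect("year", beta=-0.045, center=2008.0),
        ),
    )
    kw.update(overrides)
    return _preset("colon-like", **kw)


def breast_like(n: int = 3000, seed: int = 0, **overrides) -> Scenario:
    """Low lethality, steady improvement (5-y net survival ~ 0.8)."""
    kw = dict(
        n=n,
        seed=seed,
        sex="female",
        age_mean=62.0,
        age_sd=12.0,
        dep_probs=(0.21, 0.2, 0.2, 0.2, 0.19),
        year_range=(2005, 2010),
        censor_date=2011.0,
        baseline_rate=0.04,
        baseline_shape=1.1,
        effects=(
            TrueEffect("age", beta=0.12, center=62.0, scale=10.0),
            TrueEffect("dep", beta=0.05, center=3.0),
            TrueEffect("year", beta=-0.025, center=2008.0),
        ),
    )
    kw.update(overrides)
    return _preset("breast-like", **kw)


def selection_scenario(n: int = 3000, seed: int = 0, time_dependent_age: bool = False) -> Scenario:
    """Conditions for studying selection behaviour: complete 5-year
    follow-up (no calendar truncation of recent diagnoses) and two strongly
    identified covariate effects (age, deprivation).

    Under calendar truncation a covariate like the diagnosis year becomes
    nearly collinear with ``log t`` inside the risk sets, so its proportional
    and time-dependent forms fit almost identically and no selection
    procedure can separate them; these conditions avoid that degeneracy so
    that consistency of the search itself is what is being exercised.
    """
    effects: tuple[TrueEffect, ...]
    if time_dependent_age:
        effects = (
            TrueEffect("age", beta=0.12, center=70.0, scale=10.0, time_dependent=True),
            TrueEffect("dep", beta=0.10, center=3.0),
        )
    else:
        effects = (
            TrueEffect("age", beta=0.20, center=70.0, scale=10.0),
            TrueEffect("dep", beta=0.10, center=3.0),
        )
    return Scenario(
        n=n,
        seed=seed,
        sex="male",
        age_mean=70.0,
        age_sd=10.0,
        year_range=(2005, 2010),
        censor_date=2016.0,
        baseline_rate=0.25,
        baseline_shape=0.8,
        effects=effects,
        label="selection" + ("+td-age" if time_dependent_age else ""),
    )


def with_time_dependent_age(scenario: Scenario, beta_td: float = 0.12) -> Scenario:
    """Replace the age effect with a time-dependent one (``beta g(age) log t``).

    The replacement keeps the generating hazard inside the fitted model
    space, where a time-dependent effect is the ``log t`` form of the same
    single coefficient.  ``beta_td`` must keep ``kappa + beta_td * g(age)``
    positive over the age range so the hazard stays integrable at 0.
    """
    effects = tuple(e for e in scenario.effects if e.variable != "age") + (
        TrueEffect("age", beta=beta_td, center=70.0, scale=10.0, time_dependent=True),
    )
    out = replace(scenario, effects=effects, label=scenario.label + "+td-age")
    worst = min(
        scenario.baseline_shape + beta_td * (scenario.age_range[0] - 70.0) / 10.0,
        scenario.baseline_shape + beta_td * (scenario.age_range[1] - 70.0) / 10.0,
    )
    if worst <= 0:
        raise ValueError("beta_td too large: hazard not integrable at extreme ages")
    return out
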