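"""Flexible parametric excess hazard models.

The observed mortality hazard of a cancer cohort is decomposed as
``lambda(t, x) = lambda_E(t, x) + lambda_P(a+t, y+t, z)``: an excess hazard
attributable to the cancer plus the background population hazard from a life
table.  The log excess hazard is modelled as

    log lambda_E(t, x) = s0(log t) + sum_k  b_k(t) * g_k(x_k)

where ``s0`` is a restricted cubic spline in log time (the baseline), each
covariate enters linearly, through a restricted cubic spline, or as factor
dummies, and a time-dependent effect multiplies the covariate code by
``log t``.  Pairwise interactions are products of the (linear or dummy) main
codes, optionally time-dependent as well.

Models are fitted by maximising the full-likelihood of the relative-survival
setting,

    L = sum_i [ delta_i * log(lambda_P_i(t_i) + lambda_E_i(t_i)) - Lambda_E_i(t_i) ],

with the cumulative excess hazard evaluated by Gauss-Legendre quadrature.
The observed information (negative Hessian of L) supplies the parameter
covariance; AIC and BIC use ``-2L + 2p`` and ``-2L + p log d`` with ``d`` the
number of events.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import roots_legendre

from .curves import NetSurvivalCurve
from .life_tables import DAYS_PER_YEAR, LifeTable
from .spline_basis import SplineBasis, evaluate_basis, place_knots

__all__ = [
    "EffectSpec",
    "InteractionSpec",
    "ModelSpec",
    "FittedModel",
    "PatientRecord",
    "ModelPrediction",
    "ConvergenceError",
    "DesignRankError",
    "fit",
    "log_likelihood",
    "diagnosis_dates",
    "prepare_patients",
]

GAUSS_NODES = 20
_NODES, _WEIGHTS = roots_legendre(GAUSS_NODES)
_ETA_MAX = 30.0  # caps exp() in the hazard during optimisation


class ConvergenceError(RuntimeError):
    """The likelihood optimiser failed to converge."""


class DesignRankError(ValueError):
    """The model design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """Functional form of one covariate's effect on the log excess hazard.

    ``form`` is ``"linear"`` or ``"spline"`` for continuous variables and
    ``"categorical"`` for factors; ``time_dependent=True`` multiplies the
    covariate code by ``log t``.
    """

    variable: str
    form: str = "linear"
    df: int = 3
    time_dependent: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("linear", "spline", "categorical"):
            raise ValueError(f"unknown effect form {self.form!r}")

    @property
    def label(self) -> str:
        base = {"linear": "lin", "spline": f"rcs{self.df}", "categorical": "cat"}[self.form]
        return f"{self.variable}:{base}:{'TD' if self.time_dependent else 'PH'}"


@dataclass(frozen=True)
class InteractionSpec:
    """A pairwise interaction between two main-effect variables."""

    variables: tuple[str, str]
    time_dependent: bool = False

    def __post_init__(self) -> None:
        if len(self.variables) != 2 or self.variables[0] == self.variables[1]:
            raise ValueError("an interaction needs two distinct variables")

    @property
    def label(self) -> str:
        a, b = self.variables
        return f"{a}*{b}:{'TD' if self.time_dependent else 'PH'}"


@dataclass(frozen=True)
class ModelSpec:
    """Baseline flexibility plus the list of covariate effects.

    ``baseline_scale`` chooses whether the baseline spline acts on ``log t``
    (the default, matching the established flexible-parametric fitting
    tools) or on ``t`` itself.
    """

    baseline_df: int = 3
    effects: tuple[EffectSpec, ...] = ()
    interactions: tuple[InteractionSpec, ...] = ()
    baseline_scale: str = "log"

    def __post_init__(self) -> None:
        names = [e.variable for e in self.effects]
        if len(names) != len(set(names)):
            raise ValueError("duplicate variables in effects")
        for ia in self.interactions:
            for v in ia.variables:
                if v not in names:
                    raise ValueError(
                        f"interaction {ia.label} requires main effect for {v!r} (hierarchy)"
                    )
        labels = [ia.label for ia in self.interactions]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate interactions")
        if self.baseline_df < 0:
            raise ValueError("baseline_df must be >= 0")
        if self.baseline_scale not in ("log", "identity"):
            raise ValueError("baseline_scale must be 'log' or 'identity'")

    def effect_for(self, variable: str) -> EffectSpec:
        for e in self.effects:
            if e.variable == variable:
                return e
        raise KeyError(variable)

    @property
    def canonical(self) -> str:
        eff = " + ".join(e.label for e in sorted(self.effects, key=lambda e: e.variable))
        ints = " + ".join(ia.label for ia in sorted(self.interactions, key=lambda i: i.label))
        parts = [f"b{self.baseline_df}" + ("@t" if self.baseline_scale == "identity" else "")]
        if eff:
            parts.append(eff)
        if ints:
            parts.append(ints)
        return " | ".join(parts)


@dataclass
class PatientRecord:
    """One subject: covariates, follow-up and vital status."""

    age_at_diagnosis: float
    sex: str
    deprivation_quintile: int
    year_of_diagnosis: int
    follow_up_time: float
    vital_status: int
    diag_date: float | None = None
    stage: str | None = None
    emergency: int | None = None
    performance_status: int | None = None

    def __post_init__(self) -> None:
        if self.follow_up_time <= 0:
            raise ValueError("follow-up time must be positive")
        if self.vital_status not in (0, 1):
            raise ValueError("vital status must be 0 or 1")
        if not 1 <= int(self.deprivation_quintile) <= 5:
            raise ValueError("deprivation quintile must be in 1..5")


def patients_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "age": r.age_at_diagnosis,
                "sex": r.sex,
                "dep": r.deprivation_quintile,
                "year": r.year_of_diagnosis,
                "time": r.follow_up_time,
                "status": r.vital_status,
                **({"diag_date": r.diag_date} if r.diag_date is not None else {}),
            }
        )
    return pd.DataFrame(rows)


def diagnosis_dates(data: pd.DataFrame) -> np.ndarray:
    """Decimal diagnosis dates; mid-year when only the year is recorded."""
    if "diag_date" in data.columns:
        return data["diag_date"].to_numpy(dtype=float)
    return data["year"].to_numpy(dtype=float) + 0.5

def prepare_patients(data: pd.DataFrame) -> pd.DataFrame:
    """Validate follow-up and shift same-day events to one day (1/365.25 y)."""
    data = data.copy()
    t = data["time"].to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    shift = t <= 0
    if shift.any():
        t = np.where(shift, 1.0 / DAYS_PER_YEAR, t)
        data["time"] = t
    status = data["status"].to_numpy()
    if not np.isin(status, (0, 1)).all():
        raise ValueError("vital status must be 0/1")
    return data


# ---------------------------------------------------------------------------
# covariate coding
# ---------------------------------------------------------------------------


@dataclass
class _ContinuousCoder:
    center: float
    basis: SplineBasis | None = None  # None => linear
    col_means: tuple[float, ...] = ()

    def columns(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.basis is None:
            return (x - self.center)[:, None]
        b = evaluate_basis(self.basis, x)
        return b - np.asarray(self.col_means)[None, :]

    def linear_column(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center)[:, None]

    def names(self, var: str) -> list[str]:
        if self.basis is None:
            return [var]
        return [f"{var}:rcs{j + 1}" for j in range(self.basis.dimension)]


@dataclass
class _CategoricalCoder:
    levels: tuple

    def columns(self, x) -> np.ndarray:
        x = np.asarray(x)
        out = np.zeros((x.size, len(self.levels) - 1))
        for j, lev in enumerate(self.levels[1:]):
            out[:, j] = x == lev
        return out

    linear_column = columns

    def names(self, var: str) -> list[str]:
        return [f"{var}={lev}" for lev in self.levels[1:]]


def _build_coders(spec: ModelSpec, data: pd.DataFrame) -> dict:
    coders = {}
    for e in spec.effects:
        x = data[e.variable]
        if e.form == "categorical":
            coders[e.variable] = _CategoricalCoder(levels=tuple(sorted(pd.unique(x))))
        else:
            if not pd.api.types.is_numeric_dtype(x):
                raise ValueError(
                    f"{e.form} form requires a continuous variable, but {e.variable!r} is not numeric"
                )
            xv = x.to_numpy(dtype=float)
            if e.form == "spline":
                basis = place_knots_raw(xv, df=e.df)
                means = evaluate_basis(basis, xv).mean(axis=0)
                coders[e.variable] = _ContinuousCoder(
                    center=float(xv.mean()), basis=basis, col_means=tuple(means)
                )
            else:
                coders[e.variable] = _ContinuousCoder(center=float(xv.mean()))
    return coders


def place_knots_raw(values: np.ndarray, df: int) -> SplineBasis:
    """Tertile-rule knots on the identity scale for covariate splines."""
    v = np.asarray(values, dtype=float)
    shifted = v - v.min() + 1.0  # place_knots requires positive input
    b = place_knots(shifted, df=df, scale="identity")
    off = v.min() - 1.0
    return SplineBasis(
        internal_knots=tuple(k + off for k in b.internal_knots),
        boundary_knots=(b.boundary_knots[0] + off, b.boundary_knots[1] + off),
        scale="identity",
    )


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


class ModelDesign:
    """Maps a spec + reference data onto numeric design matrices."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        t = data["time"].to_numpy(dtype=float)
        d = data["status"].to_numpy(dtype=int)
        events = t[d == 1]
        if spec.baseline_df >= 1:
            self.baseline_basis: SplineBasis | None = place_knots(
                events, df=spec.baseline_df, scale=spec.baseline_scale
            )
        else:
            self.baseline_basis = None
        self.coders = _build_coders(spec, data)
        self.fixed_names: list[str] = []
        self.td_names: list[str] = []
        for e in spec.effects:
            names = self.coders[e.variable].names(e.variable)
            (self.td_names if e.time_dependent else self.fixed_names).extend(names)
        for ia in spec.interactions:
            a, b = ia.variables
            for na in self._ia_names(a):
                for nb in self._ia_names(b):
                    name = f"{na}*{nb}"
                    (self.td_names if ia.time_dependent else self.fixed_names).append(name)

    def _ia_names(self, var: str) -> list[str]:
        coder = self.coders[var]
        if isinstance(coder, _CategoricalCoder):
            return coder.names(var)
        return [var]

    @property
    def n_baseline(self) -> int:
        return 0 if self.baseline_basis is None else self.baseline_basis.dimension

    @property
    def n_params(self) -> int:
        return 1 + self.n_baseline + len(self.fixed_names) + len(self.td_names)

    @property
    def param_names(self) -> list[str]:
        base = ["baseline:const"] + [
            f"baseline:rcs{j + 1}" for j in range(self.n_baseline)
        ]
        return base + self.fixed_names + [f"{n}:logt" for n in self.td_names]

    def covariate_matrices(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Time-fixed and time-dependent covariate codes for ``data``."""
        n = len(data)
        fixed_cols, td_cols = [], []
        for e in self.spec.effects:
            cols = self.coders[e.variable].columns(data[e.variable].to_numpy())
            (td_cols if e.time_dependent else fixed_cols).append(cols)
        for ia in self.spec.interactions:
            a, b = ia.variables
            ca = self.coders[a].linear_column(data[a].to_numpy())
            cb = self.coders[b].linear_column(data[b].to_numpy())
            prod = (ca[:, :, None] * cb[:, None, :]).reshape(n, -1)
            (td_cols if ia.time_dependent else fixed_cols).append(prod)
        xf = np.hstack(fixed_cols) if fixed_cols else np.empty((n, 0))
        xtd = np.hstack(td_cols) if td_cols else np.empty((n, 0))
        return xf, xtd

    def baseline_columns(self, log_t: np.ndarray) -> np.ndarray:
        """Basis columns from *log-time* values (assumes the default scale)."""
        if self.baseline_basis is None:
            return np.empty((np.asarray(log_t).size, 0))
        return evaluate_basis(self.baseline_basis, np.ravel(log_t))

    def baseline_columns_t(self, t: np.ndarray) -> np.ndarray:
        """Basis columns from follow-up times, on the spec's working scale."""
        t = np.ravel(np.asarray(t, dtype=float))
        if self.baseline_basis is None:
            return np.empty((t.size, 0))
        v = np.log(t) if self.baseline_basis.scale == "log" else t
        return evaluate_basis(self.baseline_basis, v)

    def split_params(self, theta: np.ndarray):
        nb = self.n_baseline
        nf = len(self.fixed_names)
        g0 = theta[0]
        gamma = theta[1 : 1 + nb]
        bf = theta[1 + nb : 1 + nb + nf]
        btd = theta[1 + nb + nf :]
        return g0, gamma, bf, btd


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


class _LikelihoodData:
    """Precomputed quantities for repeated likelihood evaluation."""

    def __init__(self, design: ModelDesign, data: pd.DataFrame, table: LifeTable | None,
                 stratum_col: str = "dep"):
        self.t = data["time"].to_numpy(dtype=float)
        if np.any(self.t <= 0):
            raise ValueError("all follow-up times must be positive (use prepare_patients)")
        self.delta = data["status"].to_numpy(dtype=int)
        self.logt = np.log(self.t)
        self.xf, self.xtd = design.covariate_matrices(data)
        self.b_event = design.baseline_columns_t(self.t)
        # per-patient quadrature nodes on (0, t_i]
        half = self.t[:, None] / 2.0
        self.u = half * (_NODES[None, :] + 1.0)
        self.w = half * _WEIGHTS[None, :]
        self.logu = np.log(self.u)
        n, k = self.u.shape
        self.b_quad = design.baseline_columns_t(self.u.ravel()).reshape(n, k, -1)
        if table is None:
            self.lam_p = np.zeros(n)
        else:
            age = data["age"].to_numpy(dtype=float)
            date = diagnosis_dates(data)
            sex = data["sex"].to_numpy() if "sex" in data.columns else np.repeat("all", n)
            strat = (
                data[stratum_col].to_numpy()
                if stratum_col in data.columns
                else np.repeat("all", n)
            )
            self.lam_p = np.asarray(
                table.rate_at(age + self.t, date + self.t, sex, strat), dtype=float
            )
        self.design = design

    def _eta(self, theta):
        g0, gamma, bf, btd = self.design.split_params(theta)
        lp_f = self.xf @ bf if bf.size else 0.0
        lp_td = self.xtd @ btd if btd.size else 0.0
        eta_ev = g0 + (self.b_event @ gamma if gamma.size else 0.0)
        eta_ev = eta_ev + lp_f + lp_td * self.logt
        eta_q = g0 + (self.b_quad @ gamma if gamma.size else 0.0)
        eta_q = eta_q + np.asarray(lp_f)[..., None] + np.asarray(lp_td)[..., None] * self.logu
        return eta_ev, eta_q, lp_f, lp_td

    def loglik(self, theta) -> float:
        eta_ev, eta_q, _, _ = self._eta(theta)
        lam_e = np.exp(np.minimum(eta_ev, _ETA_MAX))
        lam_q = np.exp(np.minimum(eta_q, _ETA_MAX))
        cum = np.sum(self.w * lam_q, axis=1)
        with np.errstate(divide="ignore"):
            ev = self.delta * np.log(self.lam_p + lam_e)
        return float(np.sum(ev - cum))

    def score(self, theta) -> np.ndarray:
        eta_ev, eta_q, _, _ = self._eta(theta)
        lam_e = np.exp(np.minimum(eta_ev, _ETA_MAX))
        lam_q = np.exp(np.minimum(eta_q, _ETA_MAX))
        q = self.w * lam_q  # (n, k)
        r = np.where(self.delta == 1, lam_e / (self.lam_p + lam_e), 0.0)
        qs = q.sum(axis=1)
        g = [np.sum(r) - np.sum(qs)]
        nb = self.design.n_baseline
        if nb:
            g_ev = self.b_event.T @ r
            g_q = np.einsum("nk,nkb->b", q, self.b_quad)
            g.extend(g_ev - g_q)
        if self.xf.shape[1]:
            g.extend(self.xf.T @ (r - qs))
        if self.xtd.shape[1]:
            g.extend(self.xtd.T @ (r * self.logt - np.sum(q * self.logu, axis=1)))
        return np.asarray(g, dtype=float)

    def check_rank(self) -> None:
        z = np.hstack(
            [
                np.ones((len(self.t), 1)),
                self.b_event,
                self.xf,
                self.xtd * self.logt[:, None],
            ]
        )
        rank = np.linalg.matrix_rank(z)
        if rank < z.shape[1]:
            names = ["baseline:const"] + self.design.param_names[1:]
            # identify near-dependent columns from the smallest right-singular vectors
            _, s, vt = np.linalg.svd(z, full_matrices=False)
            bad = set()
            for row in vt[rank:]:
                for j in np.nonzero(np.abs(row) > 0.1)[0]:
                    bad.add(names[j])
            raise DesignRankError(
                f"design matrix rank deficient (rank {rank} < {z.shape[1]}); "
                f"collinear columns: {sorted(bad)}"
            )


def _observed_information(score_fn, theta: np.ndarray) -> np.ndarray:
    """Central finite differences of the score; returns -Hessian of L."""
    p = theta.size
    h = 1e-5 * (1.0 + np.abs(theta))
    hess = np.empty((p, p))
    for k in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h[k]
        tm[k] -= h[k]
        hess[:, k] = (score_fn(tp) - score_fn(tm)) / (2 * h[k])
    hess = 0.5 * (hess + hess.T)
    return -hess


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------


@dataclass
class ModelPrediction:
    """Per-model predictions on a time grid for a set of patients."""

    times: np.ndarray
    hazard: np.ndarray  # (n_patients, n_times)
    cumhaz: np.ndarray
    survival: np.ndarray
    hazard_variance: np.ndarray | None = None
    cumhaz_variance: np.ndarray | None = None

    @property
    def cohort_survival(self) -> np.ndarray:
        return self.survival.mean(axis=0)

    def cohort_curve(self, kind: str = "model") -> NetSurvivalCurve:
        return NetSurvivalCurve(times=self.times, survival=self.cohort_survival, kind=kind)


@dataclass
class FittedModel:
    spec: ModelSpec
    design: ModelDesign
    params: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_params: int
    n_events: int
    n_obs: int
    converged: bool = True
    n_iter: int = 0
    stratum_col: str = "dep"

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n_events)

    def criterion(self, which: str) -> float:
        which = which.lower()
        if which == "aic":
            return self.aic
        if which == "bic":
            return self.bic
        raise ValueError(f"unknown criterion {which!r}")

    @property
    def param_names(self) -> list[str]:
        return self.design.param_names

    def param_table(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        return pd.DataFrame({"name": self.param_names, "estimate": self.params, "se": se})

    # -- hazard evaluation --------------------------------------------------
    def _design_rows(self, xf, xtd, t: float):
        logt = np.log(t)
        b = self.design.baseline_columns_t(np.asarray([t]))[0]
        n = xf.shape[0]
        z = np.hstack(
            [
                np.ones((n, 1)),
                np.broadcast_to(b, (n, b.size)),
                xf,
                xtd * logt,
            ]
        )
        return z

    def log_excess_hazard(self, patients: pd.DataFrame, t) -> np.ndarray:
        """Log excess hazard for each patient at each time in ``t``.

        Returns shape ``(n_patients, n_times)``.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t <= 0):
            raise ValueError("t must be positive (log-time baseline)")
        xf, xtd = self.design.covariate_matrices(patients)
        g0, gamma, bf, btd = self.design.split_params(self.params)
        logt = np.log(t)
        bcols = self.design.baseline_columns_t(t)
        base = np.full(t.size, g0) + (bcols @ gamma if gamma.size else 0.0)  # (n_times,)
        lp_f = xf @ bf if bf.size else np.zeros(xf.shape[0])
        lp_td = xtd @ btd if btd.size else np.zeros(xtd.shape[0])
        return base[None, :] + lp_f[:, None] + lp_td[:, None] * logt[None, :]

    def excess_hazard(self, patients: pd.DataFrame, t) -> np.ndarray:
        return np.exp(self.log_excess_hazard(patients, t))

    def cumulative_excess_hazard(self, patients: pd.DataFrame, t) -> np.ndarray:
        """Gauss-Legendre cumulative excess hazard, shape (n_patients, n_times)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t <= 0):
            raise ValueError("t must be positive")
        xf, xtd = self.design.covariate_matrices(patients)
        g0, gamma, bf, btd = self.design.split_params(self.params)
        lp_f = xf @ bf if bf.size else np.zeros(xf.shape[0])
        lp_td = xtd @ btd if btd.size else np.zeros(xtd.shape[0])
        out = np.empty((xf.shape[0], t.size))
        for k, tk in enumerate(t):
            u = tk / 2.0 * (_NODES + 1.0)
            w = tk / 2.0 * _WEIGHTS
            logu = np.log(u)
            b = self.design.baseline_columns_t(u)
            base = np.full(u.size, g0) + (b @ gamma if gamma.size else 0.0)  # (20,)
            eta = base[None, :] + lp_f[:, None] + lp_td[:, None] * logu[None, :]
            lam = np.exp(eta)
            if not np.all(np.isfinite(lam)):
                i, j = np.argwhere(~np.isfinite(lam))[0]
                raise FloatingPointError(
                    f"non-finite hazard at quadrature node t={u[j]:.6g} for patient {i}"
                )
            out[:, k] = lam @ w
        return out

    def predict(self, patients: pd.DataFrame, time_grid, with_variance: bool = False) -> ModelPrediction:
        t = np.atleast_1d(np.asarray(time_grid, dtype=float))
        haz = self.excess_hazard(patients, t)
        cum = self.cumulative_excess_hazard(patients, t)
        surv = np.exp(-cum)
        hvar = cvar = None
        if with_variance:
            hvar, cvar = self._delta_variances(patients, t, haz)
        return ModelPrediction(
            times=t, hazard=haz, cumhaz=cum, survival=surv,
            hazard_variance=hvar, cumhaz_variance=cvar,
        )

    def predict_net_survival(self, patients: pd.DataFrame, time_grid) -> tuple[NetSurvivalCurve, ModelPrediction]:
        """Cohort net survival curve (mean of individual curves) + detail."""
        pred = self.predict(patients, time_grid)
        return pred.cohort_curve(), pred

    def _delta_variances(self, patients, t, haz):
        """Delta-method variances of hazard and cumulative hazard."""
        xf, xtd = self.design.covariate_matrices(patients)
        n = xf.shape[0]
        hvar = np.empty((n, t.size))
        cvar = np.empty((n, t.size))
        cov = self.covariance
        for k, tk in enumerate(t):
            z = self._design_rows(xf, xtd, tk)
            hvar[:, k] = haz[:, k] ** 2 * np.einsum("ip,pq,iq->i", z, cov, z)
            # gradient of Lambda wrt theta via quadrature
            u = tk / 2.0 * (_NODES + 1.0)
            w = tk / 2.0 * _WEIGHTS
            logu = np.log(u)
            b = self.design.baseline_columns_t(u)  # (20, nb)
            g0, gamma, bf, btd = self.design.split_params(self.params)
            base = np.full(u.size, g0) + (b @ gamma if gamma.size else 0.0)
            lp_f = xf @ bf if bf.size else np.zeros(n)
            lp_td = xtd @ btd if btd.size else np.zeros(n)
            lam = np.exp(base[None, :] + lp_f[:, None] + lp_td[:, None] * logu[None, :])
            q = lam * w[None, :]  # (n, 20)
            grad = np.hstack(
                [
                    q.sum(axis=1)[:, None],
                    q @ b,
                    xf * q.sum(axis=1)[:, None],
                    xtd * (q @ logu)[:, None],
                ]
            )
            cvar[:, k] = np.einsum("ip,pq,iq->i", grad, cov, grad)
        return hvar, cvar

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def _basis(b):
            if b is None:
                return None
            return {
                "internal_knots": list(b.internal_knots),
                "boundary_knots": list(b.boundary_knots),
                "scale": b.scale,
            }

        coders = {}
        for var, c in self.design.coders.items():
            if isinstance(c, _CategoricalCoder):
                coders[var] = {"type": "categorical", "levels": [_json_safe(v) for v in c.levels]}
            else:
                coders[var] = {
                    "type": "continuous",
                    "center": c.center,
                    "basis": _basis(c.basis),
                    "col_means": list(c.col_means),
                }
        return {
            "spec": {
                "baseline_df": self.spec.baseline_df,
                "baseline_scale": self.spec.baseline_scale,
                "effects": [
                    {
                        "variable": e.variable,
                        "form": e.form,
                        "df": e.df,
                        "time_dependent": e.time_dependent,
                    }
                    for e in self.spec.effects
                ],
                "interactions": [
                    {"variables": list(ia.variables), "time_dependent": ia.time_dependent}
                    for ia in self.spec.interactions
                ],
            },
            "baseline_basis": _basis(self.design.baseline_basis),
            "coders": coders,
            "params": self.params.tolist(),
            "covariance": self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "n_events": self.n_events,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "stratum_col": self.stratum_col,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = ModelSpec(
            baseline_df=d["spec"]["baseline_df"],
            baseline_scale=d["spec"].get("baseline_scale", "log"),
            effects=tuple(EffectSpec(**e) for e in d["spec"]["effects"]),
            interactions=tuple(
                InteractionSpec(variables=tuple(ia["variables"]), time_dependent=ia["time_dependent"])
                for ia in d["spec"]["interactions"]
            ),
        )
        design = ModelDesign.__new__(ModelDesign)
        design.spec = spec

        def _basis(b):
            if b is None:
                return None
            return SplineBasis(
                internal_knots=tuple(b["internal_knots"]),
                boundary_knots=tuple(b["boundary_knots"]),
                scale=b["scale"],
            )

        design.baseline_basis = _basis(d["baseline_basis"])
        design.coders = {}
        for var, c in d["coders"].items():
            if c["type"] == "categorical":
                design.coders[var] = _CategoricalCoder(levels=tuple(c["levels"]))
            else:
                design.coders[var] = _ContinuousCoder(
                    center=c["center"], basis=_basis(c["basis"]), col_means=tuple(c["col_means"])
                )
        design.fixed_names = []
        design.td_names = []
        for e in spec.effects:
            names = design.coders[e.variable].names(e.variable)
            (design.td_names if e.time_dependent else design.fixed_names).extend(names)
        for ia in spec.interactions:
            a, b = ia.variables
            for na in design._ia_names(a):
                for nb in design._ia_names(b):
                    (design.td_names if ia.time_dependent else design.fixed_names).append(
                        f"{na}*{nb}"
                    )
        return cls(
            spec=spec,
            design=design,
            params=np.asarray(d["params"]),
            covariance=np.asarray(d["covariance"]),
            log_likelihood=d["log_likelihood"],
            n_params=d["n_params"],
            n_events=d["n_events"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            stratum_col=d.get("stratum_col", "dep"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _json_safe(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def log_likelihood(
    spec: ModelSpec, params, data: pd.DataFrame, table: LifeTable | None, stratum_col: str = "dep"
) -> float:
    """Relative-survival log-likelihood of ``params`` under ``spec``."""
    design = ModelDesign(spec, data)
    like = _LikelihoodData(design, data, table, stratum_col)
    return like.loglik(np.asarray(params, dtype=float))


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    table: LifeTable | None,
    stratum_col: str = "dep",
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> FittedModel:
    """Maximum-likelihood fit of an excess hazard model.

    ``table=None`` sets the background hazard to zero, reducing the model to
    ordinary parametric survival (useful for validation).
    """
    data = prepare_patients(data)
    d = int(data["status"].sum())
    if d < 1:
        raise ValueError("cannot fit an excess hazard model to a dataset with zero events")
    design = ModelDesign(spec, data)
    like = _LikelihoodData(design, data, table, stratum_col)
    like.check_rank()
    theta0 = np.zeros(design.n_params)
    theta0[0] = np.log(d / data["time"].sum())
    res = optimize.minimize(
        lambda th: -like.loglik(th),
        theta0,
        jac=lambda th: -like.score(th),
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    grad_norm = float(np.max(np.abs(like.score(res.x))))
    if not res.success and grad_norm > 1e-3:
        raise ConvergenceError(
            f"optimiser failed for spec [{spec.canonical}]: {res.message} "
            f"(iterations={res.nit}, |score|_max={grad_norm:.3g})"
        )
    info = _observed_information(like.score, res.x)
    cov = _safe_inverse(info)
    return FittedModel(
        spec=spec,
        design=design,
        params=res.x,
        covariance=cov,
        log_likelihood=float(like.loglik(res.x)),
        n_params=design.n_params,
        n_events=d,
        n_obs=len(data),
        converged=bool(res.success),
        n_iter=int(res.nit),
        stratum_col=stratum_col,
    )


def _safe_inverse(info: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("observed information singular; using pseudo-inverse", stacklevel=2)
        cov = np.linalg.pinv(info)
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if np.any(w < 0):
        cov = (v * np.clip(w, 0.0, None)) @ v.T  # project to PSD
    return cov
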