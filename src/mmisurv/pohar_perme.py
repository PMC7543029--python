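"""Non-parametric net survival: the Pohar-Perme estimator.

Patients who die of other causes are removed informatively with respect to
net survival, so each subject's contribution to the counting processes is
weighted by the inverse of their expected (population) survival,
``w_i(t) = 1 / S_P,i(t)``.  The excess cumulative hazard increments at each
event time by

    dLambda_E(t_k) = [ weighted deaths at t_k
                       - weighted expected deaths accumulated over the
                         at-risk time since the previous event time ]
                     / weighted number at risk at t_k

and net survival is ``exp(-Lambda_E)``.  The expected-death term integrates
each subject's life-table hazard exactly over their at-risk time, using
``d(1/S_P)/du = lambda_P / S_P``, i.e. the weighted integral over a cell is a
difference of inverse expected survivals.

The period variant restricts contributions to person-time falling inside a
calendar window: left truncation at window entry, censoring at window exit.
Variance is of Poisson type on the cumulative-hazard scale, mapped to the
survival scale by the delta method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import NetSurvivalCurve
from .excess_hazard import diagnosis_dates, prepare_patients
from .life_tables import LifeTable, PopulationPaths

__all__ = ["pp_cohort", "pp_period"]


def _weighted_increments(t, delta, entry, g_matrix, g_entry, g_exit, event_times):
    """Shared increment computation.

    ``g_matrix[i, k]`` is ``1/S_P,i`` at event time k, ``g_entry``/``g_exit``
    at each subject's entry/exit follow-up time.  Subjects contribute while
    ``entry < u <= t`` (t = exit time).
    """
    n_ev = event_times.size
    d_lambda = np.empty(n_ev)
    var_inc = np.empty(n_ev)
    n_risk = np.empty(n_ev, dtype=int)
    n_event = np.empty(n_ev, dtype=int)
    prev = 0.0
    g_prev = np.where(entry > 0.0, g_entry, 1.0)  # 1/S_P at the previous event time (or entry)
    for k, tk in enumerate(event_times):
        at_risk = (entry < tk) & (t >= tk)
        gk = g_matrix[:, k]
        w_risk = np.sum(gk[at_risk])
        dead_now = at_risk & (t == tk) & (delta == 1)
        w_dead = np.sum(gk[dead_now])
        # expected deaths accumulated over (prev, tk] while at risk; a subject
        # entering mid-interval starts accumulating at their entry time
        active = (entry < tk) & (t > prev)
        g_end = np.where(t >= tk, gk, g_exit)  # leave mid-interval at own exit time
        start = np.maximum(g_prev, g_entry)
        we = np.sum(np.where(active, np.maximum(g_end - start, 0.0), 0.0))
        if w_risk > 0:
            d_lambda[k] = (w_dead - we) / w_risk
            var_inc[k] = np.sum(gk[dead_now] ** 2) / w_risk**2
        else:
            d_lambda[k] = np.nan
            var_inc[k] = np.nan
        n_risk[k] = int(np.sum(at_risk))
        n_event[k] = int(np.sum(dead_now))
        # roll forward 1/S_P for subjects still in follow-up
        g_prev = np.where(t >= tk, gk, g_prev)
        prev = tk
    return d_lambda, var_inc, n_risk, n_event


def _estimate(data: pd.DataFrame, table: LifeTable | None, time_grid, entry, exit_t,
              delta_eff, kind: str, stratum_col: str):
    t = exit_t
    event_mask = (delta_eff == 1)
    event_times = np.unique(t[event_mask])
    n = len(data)
    if table is not None:
        age = data["age"].to_numpy(dtype=float)
        date = diagnosis_dates(data)
        sex = data["sex"].to_numpy() if "sex" in data.columns else np.repeat("all", n)
        strat = data[stratum_col].to_numpy() if stratum_col in data.columns else np.repeat("all", n)
        horizon = t + 1e-9
        paths = PopulationPaths(table, age, date, sex, strat, horizon)
        g_matrix = np.exp(paths.cumhaz_grid(event_times)) if event_times.size else np.empty((n, 0))
        g_entry = np.exp(paths.cumhaz_at(np.minimum(entry, t)))
        g_exit = np.exp(paths.cumhaz_at(t))
    else:
        g_matrix = np.ones((n, event_times.size))
        g_entry = np.ones(n)
        g_exit = np.ones(n)

    d_lambda, var_inc, n_risk, n_event = _weighted_increments(
        t, delta_eff, entry, g_matrix, g_entry, g_exit, event_times
    )
    truncated_at = None
    valid = ~np.isnan(d_lambda)
    if not valid.all():
        first_bad = int(np.argmax(~valid))
        truncated_at = float(event_times[first_bad - 1]) if first_bad else 0.0
        d_lambda, var_inc = d_lambda[valid], var_inc[valid]
        event_times = event_times[valid]
        n_risk, n_event = n_risk[valid], n_event[valid]

    cum = np.cumsum(d_lambda)
    cum_var = np.cumsum(var_inc)

    grid = np.asarray(time_grid, dtype=float)
    if event_times.size:
        idx = np.searchsorted(event_times, grid, side="right") - 1
        surv = np.where(idx >= 0, np.exp(-cum[np.clip(idx, 0, None)]), 1.0)
        var_l = np.where(idx >= 0, cum_var[np.clip(idx, 0, None)], 0.0)
    else:
        surv = np.ones(grid.size)
        var_l = np.zeros(grid.size)
    variance = surv**2 * var_l
    nr = np.empty(grid.size, dtype=int)
    ne = np.empty(grid.size, dtype=int)
    for j, gt in enumerate(grid):
        alive = (entry < gt) & (t >= gt)
        nr[j] = int(np.sum(alive))
        ne[j] = int(np.sum((t <= gt) & (delta_eff == 1)))
    surv = np.clip(surv, 0.0, None)
    return NetSurvivalCurve(
        times=grid,
        survival=surv,
        variance=variance,
        n_risk=nr,
        n_event=ne,
        kind=kind,
        truncated_at=truncated_at,
    )


def pp_cohort(
    data: pd.DataFrame,
    table: LifeTable | None,
    time_grid,
    stratum_col: str = "dep",
) -> NetSurvivalCurve:
    """Cohort Pohar-Perme net survival on ``time_grid``.

    With ``table=None`` (no background mortality) the estimator reduces to
    ``exp(-Nelson-Aalen)``.
    """
    data = prepare_patients(data)
    if len(data) == 0:
        raise ValueError("need at least one patient")
    t = data["time"].to_numpy(dtype=float)
    delta = data["status"].to_numpy(dtype=int)
    entry = np.zeros(len(data))
    return _estimate(data, table, time_grid, entry, t, delta, "pp-cohort", stratum_col)


def pp_period(
    data: pd.DataFrame,
    table: LifeTable | None,
    window: tuple[float, float],
    time_grid,
    stratum_col: str = "dep",
) -> NetSurvivalCurve:
    """Period-approach Pohar-Perme estimator.

    Only person-time whose calendar date lies in ``[window_start,
    window_end)`` contributes: a patient diagnosed before the window enters
    the risk set at follow-up time ``window_start - diagnosis_date`` (left
    truncation) and is censored at window exit.
    """
    start, end = float(window[0]), float(window[1])
    if not start < end:
        raise ValueError("period window must be non-empty")
    data = prepare_patients(data)
    t = data["time"].to_numpy(dtype=float)
    delta = data["status"].to_numpy(dtype=int)
    date = diagnosis_dates(data)
    entry = np.maximum(start - date, 0.0)
    exit_t = np.minimum(t, end - date)
    delta_eff = np.where(t <= end - date, delta, 0)
    contributes = (exit_t > entry) & (date < end)
    if not contributes.any():
        raise ValueError(f"no person-time falls inside the period window [{start}, {end})")
    sub = data.loc[contributes].reset_index(drop=True)
    return _estimate(
        sub,
        table,
        time_grid,
        entry[contributes],
        exit_t[contributes],
        delta_eff[contributes],
        "pp-period",
        stratum_col,
    )
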