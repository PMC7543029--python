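"""Criterion-weight model averaging of excess hazard predictions.

Each retained model ``m`` gets weight ``w_m = exp(-Delta_m/2) / sum_n
exp(-Delta_n/2)`` where ``Delta_m`` is its criterion distance to the best
model — the likelihood of the model given the data, normalised.  Averaging
acts on predicted quantities, never on parameters: the model-averaged excess
hazard and cumulative excess hazard are weight-sums of the per-model
predictions, individual net survival is ``exp(-Lambda_MA)`` and the cohort
curve is the mean of the individual curves.

The unconditional variance of the averaged hazard combines within-model
(delta-method) variance and between-model spread,

    var(lambda_MA) = [ sum_m w_m * sqrt( var_m + (lambda_m - lambda_MA)^2 ) ]^2,

which assumes perfect correlation of the between-model deviations and is
conservative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import NetSurvivalCurve
from .model_selection import ModelSet

__all__ = [
    "AveragedPrediction",
    "xic_weights",
    "evidence_ratio",
    "average_predictions",
    "unconditional_variance",
]


def xic_weights(model_set: ModelSet | np.ndarray) -> np.ndarray:
    """Normalised criterion weights ``exp(-Delta/2) / sum exp(-Delta/2)``.

    Accepts a :class:`ModelSet` or a raw array of criterion values; weights
    are invariant to adding a constant to all criteria.
    """
    if isinstance(model_set, ModelSet):
        deltas = model_set.deltas
    else:
        c = np.asarray(model_set, dtype=float)
        if c.size == 0 or not np.all(np.isfinite(c)):
            raise ValueError("criterion values must be a non-empty finite array")
        deltas = c - c.min()
    lik = np.exp(-0.5 * deltas)
    w = lik / lik.sum()
    if isinstance(model_set, ModelSet):
        model_set.weights = w
    return w


def evidence_ratio(model_set: ModelSet | np.ndarray, m: int, n: int) -> float:
    """Evidence ratio ``e_{m,n} = w_m / w_n = exp((Delta_n - Delta_m)/2)``."""
    w = xic_weights(model_set)
    return float(w[m] / w[n])


def unconditional_variance(weights, estimates, variances) -> np.ndarray:
    """Burnham-Anderson unconditional variance of a model-averaged estimate.

    ``estimates`` and ``variances`` have the model axis first; the result
    drops that axis.  Never smaller than ``[sum_m w_m sqrt(var_m)]^2``.
    """
    w = np.asarray(weights, dtype=float)
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if np.any(var < 0):
        raise ValueError("per-model variances must be non-negative")
    wb = w.reshape((-1,) + (1,) * (est.ndim - 1))
    avg = np.sum(wb * est, axis=0)
    return np.sum(wb * np.sqrt(var + (est - avg) ** 2), axis=0) ** 2


@dataclass
class AveragedPrediction:
    """Model-averaged predictions for a set of patients on a time grid."""

    times: np.ndarray
    weights: np.ndarray
    hazard: np.ndarray        # (n_patients, n_times)
    cumhaz: np.ndarray
    survival: np.ndarray      # individual S_MA,i(t) = exp(-Lambda_MA,i(t))
    hazard_variance: np.ndarray | None = None
    cumhaz_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @property
    def cohort_survival(self) -> np.ndarray:
        return self.survival.mean(axis=0)

    def cohort_curve(self) -> NetSurvivalCurve:
        return NetSurvivalCurve(
            times=self.times, survival=self.cohort_survival, kind="model-averaged"
        )

    def survival_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise interval for individual net survival.

        Normal interval on the cumulative-hazard scale mapped through
        ``exp(-.)`` (a monotone transform), using the unconditional variance
        of the averaged cumulative hazard.
        """
        if self.cumhaz_variance is None:
            raise ValueError("prediction was computed without variances")
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(self.cumhaz_variance)
        lo = np.exp(-(self.cumhaz + z * se))
        hi = np.exp(-np.maximum(self.cumhaz - z * se, 0.0))
        return lo, hi


def average_predictions(
    model_set: ModelSet,
    patients: pd.DataFrame,
    time_grid,
    with_variance: bool = False,
) -> AveragedPrediction:
    """Steps d-f of the averaging procedure for every patient on a grid."""
    t = np.atleast_1d(np.asarray(time_grid, dtype=float))
    if np.any(t <= 0):
        raise ValueError("time grid must be positive")
    w = xic_weights(model_set)
    preds = [m.predict(patients, t, with_variance=with_variance) for m in model_set.models]
    haz_stack = np.stack([p.hazard for p in preds])
    cum_stack = np.stack([p.cumhaz for p in preds])
    wb = w[:, None, None]
    haz = np.sum(wb * haz_stack, axis=0)
    cum = np.sum(wb * cum_stack, axis=0)
    hvar = cvar = None
    if with_variance:
        hvar = unconditional_variance(w, haz_stack, np.stack([p.hazard_variance for p in preds]))
        cvar = unconditional_variance(w, cum_stack, np.stack([p.cumhaz_variance for p in preds]))
    return AveragedPrediction(
        times=t,
        weights=w,
        hazard=haz,
        cumhaz=cum,
        survival=np.exp(-cum),
        hazard_variance=hvar,
        cumhaz_variance=cvar,
    )
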