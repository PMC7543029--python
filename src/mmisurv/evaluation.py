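"""Prediction accuracy: integrated square differences between survival curves.

For each patient group ``g`` (by default age band x deprivation quintile,
optionally x stage) the Integrated Square Difference between a predicted and
a reference net survival curve over a horizon ``H`` is

    ISD_g = int_0^H ( S_hat_g(u) - S_g(u) )^2 du,

approximated by 20-node Gauss-Legendre quadrature, and the summary over
groups is the Root Mean Integrated Square Difference

    RMISD = sqrt( (1/G) * sum_g ISD_g ).

Step-function reference curves (Pohar-Perme estimates) are evaluated at the
quadrature nodes by right-continuous step interpolation; model curves are
evaluated directly.  Horizons of one and five years are the conventional
choices for cancer-survival prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import roots_legendre

from .curves import NetSurvivalCurve

__all__ = [
    "EvaluationReport",
    "isd",
    "rmisd",
    "evaluate_at_horizons",
    "assign_age_band",
    "DEFAULT_AGE_BANDS",
]

GAUSS_NODES = 20
_NODES, _WEIGHTS = roots_legendre(GAUSS_NODES)

#: Default age banding for group definitions (years, inclusive bounds).
DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = (
    (15, 44),
    (45, 54),
    (55, 64),
    (65, 74),
    (75, 99),
)


def assign_age_band(age, bands=DEFAULT_AGE_BANDS) -> np.ndarray:
    """Label each age with its band, e.g. ``"55-64"``."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    out = np.empty(age.shape, dtype=object)
    for lo, hi in bands:
        mask = (age >= lo) & (age < hi + 1)
        out[mask] = f"{lo}-{hi}"
    if (out == None).any():  # noqa: E711 - elementwise
        bad = age[out == None][0]  # noqa: E711
        raise ValueError(f"age {bad} falls outside the configured age bands {bands}")
    return out


def _as_callable(curve, horizon: float, role: str):
    if callable(curve):
        return curve
    if isinstance(curve, NetSurvivalCurve):
        if curve.max_time < horizon - 1e-9:
            raise ValueError(
                f"{role} curve only supported up to t={curve.max_time:.4g} "
                f"but horizon is {horizon:.4g}"
            )
        return curve.at
    raise TypeError(f"{role} must be a NetSurvivalCurve or a callable, got {type(curve)!r}")


def isd(predicted, reference, horizon: float) -> float:
    """Integrated square difference of two curves over ``(0, horizon]``."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    f = _as_callable(predicted, horizon, "predicted")
    g = _as_callable(reference, horizon, "reference")
    u = horizon / 2.0 * (_NODES + 1.0)
    w = horizon / 2.0 * _WEIGHTS
    diff = np.asarray(f(u), dtype=float) - np.asarray(g(u), dtype=float)
    return float(np.sum(w * diff**2))


def rmisd(group_isds) -> float:
    """Root mean ISD over groups: ``sqrt(mean(ISD_g))``."""
    v = np.asarray(list(group_isds), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one group")
    if np.any(v < 0):
        raise ValueError("ISD values must be non-negative")
    return float(np.sqrt(v.mean()))


@dataclass
class EvaluationReport:
    """Per-group ISDs and their RMISD summary at one horizon."""

    horizon: float
    group_isd: dict[str, float]
    quadrature_nodes: int = GAUSS_NODES

    @property
    def rmisd(self) -> float:
        return rmisd(self.group_isd.values())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"group": list(self.group_isd), "isd": list(self.group_isd.values())}
        )
        df["horizon"] = self.horizon
        df["rmisd"] = self.rmisd
        return df


def evaluate_at_horizons(
    predicted: dict[str, NetSurvivalCurve],
    reference: dict[str, NetSurvivalCurve],
    horizons=(1.0, 5.0),
) -> dict[float, EvaluationReport]:
    """One report per horizon over matched group-keyed curve sets."""
    orphans = sorted(set(predicted) - set(reference))
    if orphans:
        raise ValueError(f"groups present in predictions but absent in references: {orphans}")
    if not predicted:
        raise ValueError("no groups to evaluate")
    reports = {}
    for h in horizons:
        reports[float(h)] = EvaluationReport(
            horizon=float(h),
            group_isd={g: isd(predicted[g], reference[g], h) for g in sorted(predicted)},
        )
    return reports
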