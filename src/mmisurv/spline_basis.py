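"""Restricted cubic spline bases.

The log baseline excess hazard is modelled as a restricted cubic spline in
log follow-up time; non-linear covariate effects use the same construction on
the identity scale.  The basis is the truncated-power restricted form used
throughout flexible parametric survival modelling: with knots
``k_1 < ... < k_K`` (the first and last being boundary knots) the ``df = K-1``
basis functions are

    B_1(v) = v
    B_j(v) = [ (v-k_j)_+^3 - l_j (v-k_1)_+^3 - (1-l_j)(v-k_K)_+^3 ] / (k_K-k_1)^2

for each internal knot ``k_j``, with ``l_j = (k_K-k_j)/(k_K-k_1)``.  The
cubic and quadratic terms cancel outside the boundary knots, so the basis is
linear in the tails and C2-continuous everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "place_knots", "evaluate_basis"]

#: Quantile probabilities are expressed to 4 decimals (33.33rd percentile,
#: not 1/3 exactly) so knot placement matches the usual printed convention.
_PROB_DECIMALS = 4


@dataclass(frozen=True)
class SplineBasis:
    """A restricted cubic spline basis on a working scale.

    Parameters
    ----------
    internal_knots : tuple of float
        Ordered knots strictly inside the boundary interval.
    boundary_knots : (float, float)
        Minimum and maximum knots; the basis is linear outside them.
    scale : {"log", "identity"}
        Working scale.  ``"log"`` means the basis is evaluated in
        ``log(t)``; callers are expected to pass log-transformed values.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    scale: str = "log"

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary knots must satisfy k_min < k_max, got {lo}, {hi}")
        for k in self.internal_knots:
            if not lo < k < hi:
                raise ValueError(f"internal knot {k} outside boundary interval ({lo}, {hi})")
        if list(self.internal_knots) != sorted(self.internal_knots):
            raise ValueError("internal knots must be ordered")

    @property
    def dimension(self) -> int:
        """Number of basis columns (degrees of freedom)."""
        return len(self.internal_knots) + 1

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray([self.boundary_knots[0], *self.internal_knots, self.boundary_knots[1]])


def place_knots(event_times: np.ndarray, df: int = 3, scale: str = "log") -> SplineBasis:
    """Place spline knots from the distribution of uncensored event times.

    For the default ``df=3``, internal knots sit at the tertiles (33.33rd and
    66.67th type-1 empirical percentiles) of the event-time distribution on
    the working scale, with boundary knots at the extremes.  ``df=1`` yields a
    pure linear basis (no internal knots).  Heavily tied samples that collapse
    knots onto each other lose the duplicated knots with a warning.

    Parameters
    ----------
    event_times : array-like
        Positive times of uncensored events.
    df : int
        Requested basis dimension (internal knots + 1).
    scale : {"log", "identity"}
        Scale on which knots are placed and the basis later evaluated.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(event_times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("event_times must be a non-empty 1-d array")
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    if scale == "log":
        v = np.log(t)
    elif scale == "identity":
        v = t
    else:
        raise ValueError(f"unknown scale {scale!r}")

    distinct = np.unique(v)
    if distinct.size < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct event times for df={df}, got {distinct.size}"
        )

    lo, hi = float(v.min()), float(v.max())
    if df == 1:
        return SplineBasis(internal_knots=(), boundary_knots=(lo, hi), scale=scale)

    probs = [round(j / df, _PROB_DECIMALS) for j in range(1, df)]
    internal = [float(np.quantile(v, p, method="inverted_cdf")) for p in probs]
    # collapse ties: duplicated internal knots, or knots falling on a boundary
    kept: list[float] = []
    for k in internal:
        if lo < k < hi and (not kept or k > kept[-1]):
            kept.append(k)
    if len(kept) != len(internal):
        warnings.warn(
            f"tied event times collapsed {len(internal) - len(kept)} internal knot(s); "
            f"basis dimension reduced to {len(kept) + 1}",
            stacklevel=2,
        )
    return SplineBasis(internal_knots=tuple(kept), boundary_knots=(lo, hi), scale=scale)


def evaluate_basis(basis: SplineBasis, v) -> np.ndarray:
    """Evaluate the basis columns at working-scale values ``v``.

    Returns an array of shape ``(len(v), basis.dimension)``; a scalar input
    returns shape ``(1, dimension)``.  Values beyond the boundary knots
    extrapolate linearly by construction.
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if not np.all(np.isfinite(v)):
        raise ValueError("basis argument must be finite")
    k_min, k_max = basis.boundary_knots
    span2 = (k_max - k_min) ** 2
    cols = [v]
    for kj in basis.internal_knots:
        lj = (k_max - kj) / (k_max - k_min)
        term = (
            np.maximum(v - kj, 0.0) ** 3
            - lj * np.maximum(v - k_min, 0.0) ** 3
            - (1.0 - lj) * np.maximum(v - k_max, 0.0) ** 3
        )
        cols.append(term / span2)
    return np.column_stack(cols)
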