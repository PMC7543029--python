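"""Net survival curve container shared across estimators and models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NetSurvivalCurve"]

_STEP_KINDS = frozenset({"pp-cohort", "pp-period"})


@dataclass
class NetSurvivalCurve:
    """A net survival curve on a time grid.

    ``kind`` records the provenance: ``pp-cohort`` / ``pp-period`` curves are
    right-continuous step functions (non-parametric estimators), while
    ``model`` / ``model-averaged`` / ``simple-model`` / ``truth`` curves are
    smooth and interpolated between grid points when evaluated off-grid.
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray | None = None
    n_risk: np.ndarray | None = None
    n_event: np.ndarray | None = None
    kind: str = "model"
    truncated_at: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        # non-parametric net-survival estimates may exceed 1 slightly after
        # the expected-mortality correction; model-based curves may not
        slack = 0.1 if self.kind in _STEP_KINDS else 1e-6
        if np.any(self.survival < -1e-12) or np.any(self.survival > 1 + slack):
            raise ValueError("survival estimates must lie in [0, 1] up to numerical tolerance")
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if np.any(self.variance < -1e-12):
                raise ValueError("variances must be non-negative")

    @property
    def is_step(self) -> bool:
        return self.kind in _STEP_KINDS

    @property
    def max_time(self) -> float:
        t = float(self.times[-1])
        return t if self.truncated_at is None else min(t, self.truncated_at)

    def at(self, t) -> np.ndarray:
        """Evaluate the curve at times ``t``, with ``S(0) = 1``.

        Step curves use right-continuous step interpolation (the value at the
        last grid time <= t); smooth curves interpolate linearly.
        """
        t = np.asarray(t, dtype=float)
        if self.is_step:
            idx = np.searchsorted(self.times, t, side="right") - 1
            out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, len(self.times) - 1)])
        else:
            out = np.interp(t, np.concatenate(([0.0], self.times)), np.concatenate(([1.0], self.survival)))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "survival": self.survival})
        for name, arr in (("variance", self.variance), ("n_risk", self.n_risk), ("n_event", self.n_event)):
            if arr is not None:
                df[name] = arr
        df["kind"] = self.kind
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "NetSurvivalCurve":
        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(),
            survival=df["survival"].to_numpy(),
            variance=df["variance"].to_numpy() if "variance" in df else None,
            n_risk=df["n_risk"].to_numpy() if "n_risk" in df else None,
            n_event=df["n_event"].to_numpy() if "n_event" in df else None,
            kind=str(df["kind"].iloc[0]) if "kind" in df else "model",
        )
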