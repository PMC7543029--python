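"""Information-criterion stepwise search retaining a SET of models.

The search starts from the simplest model (every variable linear when
continuous, proportional-hazards throughout) and tests one-step complexity
moves variable by variable: linear -> restricted cubic spline, proportional
-> time-dependent (a ``log t`` multiplier), then pairwise interactions.  At
each comparison the two candidates' criterion values (AIC or BIC) are
contrasted: if they differ by more than the retention threshold (default 2)
only the better model survives; if they lie within the threshold BOTH are
kept and each is expanded further.  The final model set contains every
frontier model whose criterion lies within the threshold of the minimum —
models with near-equal support from the data.

The number 2 is anchored by evidence ratios: the best model is only
``exp(2/2) ~ 2.7`` times more likely than a model two criterion units away,
which is weak evidence for discarding it.  Equivalently, AIC-based selection
of nested models differing by one parameter behaves like a likelihood-ratio
test at implied level ``P(chi2_1 > 2) = 0.157``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .excess_hazard import (
    EffectSpec,
    FittedModel,
    InteractionSpec,
    ModelSpec,
    fit,
)

__all__ = [
    "ModelSet",
    "candidate_upgrades",
    "select_models",
    "aic_implied_pvalue",
]

logger = logging.getLogger(__name__)


def aic_implied_pvalue(df_diff: int = 1) -> float:
    """Type-I error implied by preferring the larger of two nested models by AIC.

    AIC prefers the larger model when the LRT statistic exceeds ``2 * df``;
    the implied significance level is the upper-tail chi-square probability
    at that point (0.157 for one extra parameter).
    """
    return float(stats.chi2.sf(2.0 * df_diff, df_diff))


@dataclass
class ModelSet:
    """The retained models with their criterion distances and weights."""

    models: list[FittedModel]
    criterion: str
    threshold: float = 2.0
    search_log: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("a ModelSet needs at least one model")
        seen = set()
        for m in self.models:
            key = m.spec.canonical
            if key in seen:
                raise ValueError(f"duplicate spec in model set: {key}")
            seen.add(key)

    @property
    def criteria(self) -> np.ndarray:
        return np.asarray([m.criterion(self.criterion) for m in self.models])

    @property
    def xic_min(self) -> float:
        return float(self.criteria.min())

    @property
    def deltas(self) -> np.ndarray:
        c = self.criteria
        return c - c.min()

    @property
    def best(self) -> FittedModel:
        return self.models[int(np.argmin(self.criteria))]

    def __len__(self) -> int:
        return len(self.models)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spec": [m.spec.canonical for m in self.models],
                "criterion": self.criteria,
                "delta": self.deltas,
                "weight": self.weights if self.weights is not None else np.nan,
                "n_params": [m.n_params for m in self.models],
                "log_likelihood": [m.log_likelihood for m in self.models],
            }
        )


# ---------------------------------------------------------------------------
# legal complexity moves
# ---------------------------------------------------------------------------


def _is_continuous(data: pd.DataFrame, variable: str) -> bool:
    return pd.api.types.is_numeric_dtype(data[variable])


def candidate_upgrades(
    spec: ModelSpec, variable: str, data: pd.DataFrame | None = None, spline_df: int = 3
) -> list[ModelSpec]:
    """One-step complexity moves for ``variable`` within ``spec``.

    linear -> spline(df) for continuous variables; proportional ->
    time-dependent for any variable.  Interaction moves are generated by
    :func:`interaction_upgrades`.
    """
    effect = spec.effect_for(variable)
    moves: list[ModelSpec] = []
    continuous = effect.form != "categorical" and (
        data is None or _is_continuous(data, variable)
    )
    if effect.form == "linear" and continuous:
        moves.append(_replace_effect(spec, replace(effect, form="spline", df=spline_df)))
    if not effect.time_dependent:
        moves.append(_replace_effect(spec, replace(effect, time_dependent=True)))
    return moves


def interaction_upgrades(spec: ModelSpec) -> list[ModelSpec]:
    """Add an absent pairwise interaction, or upgrade a present one to TD."""
    moves = []
    names = sorted(e.variable for e in spec.effects)
    present = {ia.variables for ia in spec.interactions}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (a, b) not in present and (b, a) not in present:
                moves.append(
                    replace(spec, interactions=spec.interactions + (InteractionSpec((a, b)),))
                )
    for ia in spec.interactions:
        if not ia.time_dependent:
            others = tuple(x for x in spec.interactions if x != ia)
            moves.append(
                replace(spec, interactions=others + (replace(ia, time_dependent=True),))
            )
    return moves


def _replace_effect(spec: ModelSpec, new_effect: EffectSpec) -> ModelSpec:
    effects = tuple(
        new_effect if e.variable == new_effect.variable else e for e in spec.effects
    )
    return replace(spec, effects=effects)


# ---------------------------------------------------------------------------
# the adapted stepwise search
# ---------------------------------------------------------------------------


def select_models(
    data: pd.DataFrame,
    table,
    base_spec: ModelSpec,
    criterion: str = "aic",
    threshold: float = 2.0,
    algorithm: str = "adapted-stepwise",
    max_branches: int = 16,
    spline_df: int = 3,
    stratum_col: str = "dep",
    with_interactions: bool = True,
) -> ModelSet:
    """Run the criterion-based stepwise search and return the retained set.

    ``algorithm="adapted-stepwise"`` scans variables in order of their
    single-move criterion improvement over the base model, then scans
    pairwise interactions; ``"interaction-first"`` scans interactions before
    the main-effect moves (the Royston-Sauerbrei ordering of the original
    test-based procedure).  The search is deterministic: ties are broken by
    the canonical spec string.
    """
    if algorithm not in ("adapted-stepwise", "interaction-first"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    cache: dict[str, FittedModel] = {}
    log: list[str] = []

    def fitted(spec: ModelSpec) -> FittedModel:
        key = spec.canonical
        if key not in cache:
            cache[key] = fit(spec, data, table, stratum_col=stratum_col)
        return cache[key]

    def xic(spec: ModelSpec) -> float:
        return fitted(spec).criterion(criterion)

    base = fitted(base_spec)
    log.append(f"base [{base_spec.canonical}] {criterion.upper()}={xic(base_spec):.3f}")

    # variable ordering: decreasing single-move criterion improvement
    improvements = {}
    for e in base_spec.effects:
        best = np.inf
        for mv in candidate_upgrades(base_spec, e.variable, data, spline_df):
            try:
                best = min(best, xic(mv))
            except Exception as exc:  # noqa: BLE001 - any fit failure prunes the move
                log.append(f"prune [{mv.canonical}]: {exc}")
        improvements[e.variable] = xic(base_spec) - best
    order = sorted(improvements, key=lambda v: (-improvements[v], v))
    log.append("variable order: " + ", ".join(f"{v} ({improvements[v]:+.2f})" for v in order))

    frontier: dict[str, ModelSpec] = {base_spec.canonical: base_spec}

    def compare_and_update(parent: ModelSpec, child: ModelSpec, stack: list[ModelSpec]) -> None:
        try:
            d = xic(child) - xic(parent)
        except Exception as exc:  # noqa: BLE001
            log.append(f"prune [{child.canonical}]: {exc}")
            logger.warning("branch fit failed for %s: %s", child.canonical, exc)
            return
        if d < -threshold:
            log.append(
                f"replace [{parent.canonical}] -> [{child.canonical}] (d={d:+.2f})"
            )
            frontier.pop(parent.canonical, None)
            frontier[child.canonical] = child
            stack.append(child)
        elif d <= threshold:
            log.append(f"keep both [{parent.canonical}] + [{child.canonical}] (d={d:+.2f})")
            frontier[child.canonical] = child
            stack.append(child)
        else:
            log.append(f"discard [{child.canonical}] (d={d:+.2f})")

    def scan(moves_fn) -> None:
        for key in sorted(frontier):
            if key not in frontier:  # removed by an earlier replacement
                continue
            stack = [frontier[key]]
            while stack:
                spec = stack.pop()
                if spec.canonical not in frontier:
                    continue
                for child in sorted(moves_fn(spec), key=lambda s: s.canonical):
                    compare_and_update(spec, child, stack)
        _cap_frontier()

    def _cap_frontier() -> None:
        while len(frontier) > max_branches:
            worst = max(sorted(frontier), key=lambda k: xic(frontier[k]))
            log.append(f"cap: pruning worst branch [{worst}]")
            logger.warning("branch cap reached; pruning %s", worst)
            del frontier[worst]

    def scan_variables() -> None:
        for var in order:
            scan(lambda s, v=var: candidate_upgrades(s, v, data, spline_df))

    if algorithm == "interaction-first" and with_interactions:
        scan(interaction_upgrades)
        scan_variables()
    else:
        scan_variables()
        if with_interactions:
            scan(interaction_upgrades)

    # retained set: frontier models within threshold of the minimum
    specs = [frontier[k] for k in sorted(frontier)]
    xics = np.asarray([xic(s) for s in specs])
    xmin = xics.min()
    keep = [s for s, c in zip(specs, xics) if c - xmin <= threshold]
    keep.sort(key=lambda s: (xic(s), s.canonical))
    dropped = len(specs) - len(keep)
    if dropped:
        log.append(f"final: dropped {dropped} frontier model(s) with delta > {threshold}")
    log.append(
        "retained: "
        + "; ".join(f"[{s.canonical}] delta={xic(s) - xmin:.2f}" for s in keep)
    )
    return ModelSet(
        models=[fitted(s) for s in keep],
        criterion=criterion,
        threshold=threshold,
        search_log=log,
    )
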