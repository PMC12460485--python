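"""Sequential synthesis: visit sequences, conditions, and scenarios.

A :class:`SynthesisPlan` is an ordered *visit sequence* of variables, each
with a method:

* ``fixed`` — copied from the original data; usable as a predictor but
  never synthesized (the "starred" variables of a conditioning table);
* ``cart`` — fitted on observed data and regenerated by leaf-donor
  sampling, conditioning on a mix of original-source (starred) columns and
  previously synthesized columns;
* ``random_sample`` — i.i.d. draws with replacement from the observed
  marginal;
* ``derived`` — recomputed deterministically from already-synthesized
  columns (chronic load from synthetic acute load).

Seven named predictor-specification conditions are provided via
:func:`build_condition`, spanning a gradient from a plan that mirrors the
downstream injury regression (``base``) to plans loaded with time-lagged
predictors, with or without synthesizing the injury indicator itself.  Two
chronic-load scenarios exist throughout: ``independent`` (CL synthesized
as its own CART variable) and ``calculated`` (CL derived from the
synthetic acute load, preserving the deterministic AL->CL coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cart
from .panel import derive_chronic_load, lag_column_name, validate_panel

__all__ = [
    "VariableSpec",
    "SynthesisPlan",
    "PlanValidationResult",
    "CONDITION_NAMES",
    "CL_SCENARIOS",
    "build_condition",
    "prepare_panel",
    "validate_plan",
    "synthesize",
    "plan_to_dict",
    "plan_from_dict",
]

CONDITION_NAMES = (
    "base",
    "base_week",
    "time_lag_1wk",
    "time_lag_3wks",
    "time_lag_injury",
    "injury_time_lag",
    "no_playerid",
)
CL_SCENARIOS = ("independent", "calculated")

_METHODS = ("cart", "fixed", "random_sample", "derived")


@dataclass(frozen=True)
class VariableSpec:
    """One entry of the visit sequence.

    ``predictors`` is a list of ``(name, source)`` pairs with source
    ``"original"`` (starred: the original column is used both when fitting
    and when generating) or ``"synthetic"`` (the already-synthesized column
    is used when generating).
    """

    name: str
    method: str
    predictors: tuple = ()
    derived_rule: str | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in ("fixed", "random_sample") and self.predictors:
            raise ValueError(f"{self.method} variables take no predictors")
        if self.method == "derived" and not self.derived_rule:
            raise ValueError("derived variables must name a rule")
        if self.method == "cart" and not self.predictors:
            raise ValueError("cart variables need at least one predictor")
        for item in self.predictors:
            if len(item) != 2 or item[1] not in ("original", "synthetic"):
                raise ValueError(f"bad predictor entry {item!r}")


@dataclass(frozen=True)
class SynthesisPlan:
    """An ordered visit sequence plus the chronic-load scenario."""

    visit_sequence: tuple
    cl_scenario: str = "independent"
    condition: str | None = None
    cl_block_weeks: int = 4
    categorical: tuple = ("PlayerID",)
    hyperparams: cart.TreeHyperparams = field(default_factory=cart.TreeHyperparams)
    proper: bool = False

    def spec(self, name: str) -> VariableSpec:
        for v in self.visit_sequence:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def synthesized(self) -> list[str]:
        return [v.name for v in self.visit_sequence if v.method != "fixed"]

    @property
    def fixed(self) -> list[str]:
        return [v.name for v in self.visit_sequence if v.method == "fixed"]


def _lag_pairs(max_lag: int) -> list[tuple[str, str]]:
    names = []
    for var in ("AcuteLoad", "ChronicLoad"):
        for k in range(1, max_lag + 1):
            names.append((lag_column_name(var, k), "original"))
    # conventional ordering: AL lags first, then CL lags
    return names


def _cl_spec(scenario: str, cart_predictors: list[tuple[str, str]]) -> VariableSpec:
    if scenario == "calculated":
        return VariableSpec("ChronicLoad", "derived", derived_rule="chronic_from_acute")
    return VariableSpec("ChronicLoad", "cart", tuple(cart_predictors))


def build_condition(name: str, cl_scenario: str = "independent", **plan_kwargs) -> SynthesisPlan:
    """Build the synthesis plan for one named predictor-specification condition.

    ``base``           AL, CL by CART on {Injury*, PlayerID*} (CL also on
                       synthetic AL); Injury/PlayerID/WeekID fixed.
    ``base_week``      as ``base`` with WeekID* added as a predictor.
    ``time_lag_1wk``   WeekID replaced by the original-source 1-step lags of
                       AL and CL.
    ``time_lag_3wks``  1-, 2- and 3-step lags of AL and CL.
    ``time_lag_injury`` lags as above, Injury synthesized *last* by CART on
                       PlayerID*, lags*, synthetic AL and CL.
    ``injury_time_lag`` Injury synthesized *first* as a random sample; loads
                       by CART on PlayerID* and the lags.
    ``no_playerid``    as ``time_lag_injury`` without PlayerID anywhere.

    ``cl_scenario`` chooses how chronic load is produced: ``independent``
    (its own CART variable) or ``calculated`` (derived from synthetic AL).
    """
    if name not in CONDITION_NAMES:
        raise ValueError(f"unknown condition {name!r}; valid: {', '.join(CONDITION_NAMES)}")
    if cl_scenario not in CL_SCENARIOS:
        raise ValueError(
            f"unknown cl_scenario {cl_scenario!r}; valid: {', '.join(CL_SCENARIOS)}"
        )

    inj = ("Injury", "original")
    pid = ("PlayerID", "original")
    wk = ("WeekID", "original")
    al_syn = ("AcuteLoad", "synthetic")

    def fixed(*names: str) -> list[VariableSpec]:
        return [VariableSpec(n, "fixed") for n in names]

    if name == "base":
        al_pred = [inj, pid]
        seq = fixed("Injury", "PlayerID") + [
            VariableSpec("AcuteLoad", "cart", tuple(al_pred)),
            _cl_spec(cl_scenario, al_pred + [al_syn]),
        ]
    elif name == "base_week":
        al_pred = [inj, pid, wk]
        seq = fixed("Injury", "PlayerID", "WeekID") + [
            VariableSpec("AcuteLoad", "cart", tuple(al_pred)),
            _cl_spec(cl_scenario, al_pred + [al_syn]),
        ]
    elif name in ("time_lag_1wk", "time_lag_3wks"):
        lags = _lag_pairs(1 if name == "time_lag_1wk" else 3)
        al_pred = [inj, pid] + lags
        seq = (
            fixed("Injury", "PlayerID")
            + fixed(*[n for n, _ in lags])
            + [
                VariableSpec("AcuteLoad", "cart", tuple(al_pred)),
                _cl_spec(cl_scenario, al_pred + [al_syn]),
            ]
        )
    elif name in ("time_lag_injury", "no_playerid"):
        lags = _lag_pairs(3)
        base_pred = ([pid] if name == "time_lag_injury" else []) + lags
        inj_pred = base_pred + [al_syn, ("ChronicLoad", "synthetic")]
        seq = (
            (fixed("PlayerID") if name == "time_lag_injury" else [])
            + fixed(*[n for n, _ in lags])
            + [
                VariableSpec("AcuteLoad", "cart", tuple(base_pred)),
                _cl_spec(cl_scenario, base_pred + [al_syn]),
                VariableSpec("Injury", "cart", tuple(inj_pred)),
            ]
        )
    else:  # injury_time_lag
        lags = _lag_pairs(3)
        base_pred = [pid] + lags
        seq = (
            [VariableSpec("Injury", "random_sample")]
            + fixed("PlayerID")
            + fixed(*[n for n, _ in lags])
            + [
                VariableSpec("AcuteLoad", "cart", tuple(base_pred)),
                _cl_spec(cl_scenario, base_pred + [al_syn]),
            ]
        )
    return SynthesisPlan(
        visit_sequence=tuple(seq), cl_scenario=cl_scenario, condition=name, **plan_kwargs
    )


def plan_max_lag(plan: SynthesisPlan) -> int:
    """Largest lag order any variable in the plan refers to (0 if none)."""
    lags = [0]
    for v in plan.visit_sequence:
        for n in [v.name] + [p for p, _ in v.predictors]:
            if "_Lag" in n:
                lags.append(int(n.split("_Lag")[1]))
    return max(lags)


def prepare_panel(panel: pd.DataFrame, plan: SynthesisPlan) -> pd.DataFrame:
    """Add the original-source lag columns a plan refers to (if absent)."""
    from .panel import add_lag_features

    max_lag = plan_max_lag(plan)
    needed = [
        v
        for v in ("AcuteLoad", "ChronicLoad")
        if any(lag_column_name(v, k) not in panel.columns for k in range(1, max_lag + 1))
    ]
    if max_lag and needed:
        panel = add_lag_features(panel, needed, max_lag)
    return panel


@dataclass(frozen=True)
class PlanValidationResult:
    """All violations found; empty means valid (never raised, always returned)."""

    violations: tuple

    @property
    def valid(self) -> bool:
        return not self.violations


def validate_plan(plan: SynthesisPlan, panel: pd.DataFrame) -> PlanValidationResult:
    """Check plan invariants against a panel; reports *every* violation."""
    problems: list[str] = []
    seen: list[str] = []
    names = [v.name for v in plan.visit_sequence]
    for name in names:
        if names.count(name) > 1:
            msg = f"variable {name!r} appears more than once in the visit sequence"
            if msg not in problems:
                problems.append(msg)
    for v in plan.visit_sequence:
        for pname, source in v.predictors:
            if source == "synthetic":
                if pname not in seen:
                    problems.append(
                        f"{v.name}: synthetic-source predictor {pname!r} is not "
                        "synthesized earlier in the sequence"
                    )
            elif pname not in panel.columns:
                problems.append(
                    f"{v.name}: original-source predictor {pname!r} missing from panel"
                )
        if v.name not in panel.columns:
            problems.append(f"variable {v.name!r} missing from panel")
        if v.method != "fixed":
            seen.append(v.name)
    if plan.cl_scenario not in CL_SCENARIOS:
        problems.append(f"unknown cl_scenario {plan.cl_scenario!r}")
    return PlanValidationResult(tuple(problems))


class SynthesisError(RuntimeError):
    """A variable could not be synthesized; names the variable."""


def synthesize(
    panel: pd.DataFrame, plan: SynthesisPlan, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate one synthetic panel under ``plan``.

    The output has the same shape, ordering and fixed columns as the input.
    CART models are fitted on rows where the response and every predictor
    are observed (original values for original-source predictors); at
    generation time original-source predictors keep their original values
    while synthetic-source predictors use the freshly synthesized columns.
    Rows whose predictors are incomplete (early weeks lacking lag history)
    receive a marginal donor draw from the observed response over that same
    incomplete-row stratum.  Rows where the original response is missing
    stay missing.
    """
    panel = validate_panel(prepare_panel(panel, plan))
    result = validate_plan(plan, panel)
    if not result.valid:
        raise SynthesisError("invalid plan: " + "; ".join(result.violations))
    out = panel.copy()
    categorical = list(plan.categorical)

    for spec in plan.visit_sequence:
        try:
            if spec.method == "fixed":
                continue
            if spec.method == "random_sample":
                observed = panel[spec.name].dropna().to_numpy()
                values = observed[rng.integers(0, len(observed), size=len(panel))]
                if panel[spec.name].isna().any():
                    synth = pd.Series(values, index=out.index, dtype=float)
                    synth[panel[spec.name].isna()] = np.nan
                else:
                    synth = pd.Series(values, index=out.index, dtype=panel[spec.name].dtype)
                out[spec.name] = synth
            elif spec.method == "derived":
                if spec.derived_rule != "chronic_from_acute":
                    raise SynthesisError(f"unknown derived rule {spec.derived_rule!r}")
                out = derive_chronic_load(out, block_weeks=plan.cl_block_weeks, uncoupled=True)
            elif spec.method == "cart":
                out[spec.name] = _synthesize_cart(panel, out, spec, plan, rng, categorical)
        except Exception as exc:  # noqa: BLE001 - annotate with the variable name
            if isinstance(exc, SynthesisError):
                raise
            raise SynthesisError(f"failed synthesizing {spec.name!r}: {exc}") from exc
    return _refresh_derived_columns(out, plan)


def _refresh_derived_columns(out: pd.DataFrame, plan: SynthesisPlan) -> pd.DataFrame:
    """Recompute ACWR so it describes the *synthetic* loads.

    ACWR is a pure function of AcuteLoad and ChronicLoad and never appears
    in a visit sequence; leaving the original ratio in place would feed a
    stale regressor to the downstream injury analysis.  Lag columns, by
    contrast, are starred (fixed) variables taken from the original data
    and are left untouched.
    """
    if "ACWR" in out.columns:
        from .panel import compute_acwr

        out = compute_acwr(out)
    return out


def _synthesize_cart(
    panel: pd.DataFrame,
    out: pd.DataFrame,
    spec: VariableSpec,
    plan: SynthesisPlan,
    rng: np.random.Generator,
    categorical: list[str],
) -> pd.Series:
    pred_names = [p for p, _ in spec.predictors]
    # fitting always conditions on observed (original) values
    fit_X = panel[pred_names]
    y = panel[spec.name]
    response_missing = y.isna()
    fit_complete = ~(fit_X.isna().any(axis=1) | response_missing)
    if fit_complete.sum() == 0:
        raise SynthesisError(f"no complete rows to fit {spec.name!r}")
    kind = "categorical" if spec.name == "Injury" else "continuous"
    tree = cart.fit_tree(
        fit_X.loc[fit_complete],
        y.loc[fit_complete].to_numpy(),
        kind=kind,
        hp=plan.hyperparams,
        categorical=[c for c in categorical if c in pred_names],
    )
    # generation uses original values for starred sources, synthetic otherwise
    gen_X = pd.DataFrame(
        {
            p: (panel[p] if source == "original" else out[p])
            for p, source in spec.predictors
        }
    )
    gen_complete = ~(gen_X.isna().any(axis=1) | response_missing)
    values = pd.Series(np.nan, index=panel.index, dtype=float)
    if gen_complete.any():
        drawn = cart.synthesize_variable(
            tree, gen_X.loc[gen_complete], rng, proper=plan.proper
        )
        values.loc[gen_complete] = drawn.astype(float)
    # predictor-incomplete rows with an observed response: marginal donor
    # draw from the response over the same incomplete-row stratum
    stratum = ~gen_complete & ~response_missing
    if stratum.any():
        pool_mask = ~fit_complete & ~response_missing
        pool = y.loc[pool_mask if pool_mask.any() else ~response_missing].to_numpy()
        values.loc[stratum] = pool[rng.integers(0, len(pool), size=int(stratum.sum()))]
    if kind == "categorical" and not response_missing.any():
        return values.astype(panel[spec.name].dtype)
    return values


def plan_to_dict(plan: SynthesisPlan) -> dict:
    """Machine-readable plan description; round-trips via plan_from_dict."""
    return {
        "condition": plan.condition,
        "cl_scenario": plan.cl_scenario,
        "cl_block_weeks": plan.cl_block_weeks,
        "categorical": list(plan.categorical),
        "proper": plan.proper,
        "hyperparams": {
            "min_leaf": plan.hyperparams.min_leaf,
            "min_split": plan.hyperparams.min_split,
            "complexity": plan.hyperparams.complexity,
            "max_depth": plan.hyperparams.max_depth,
        },
        "visit_sequence": [
            {
                "name": v.name,
                "method": v.method,
                "predictors": [list(p) for p in v.predictors],
                "derived_rule": v.derived_rule,
            }
            for v in plan.visit_sequence
        ],
    }


def plan_from_dict(data: dict) -> SynthesisPlan:
    """Rebuild a plan from its machine-readable description."""
    seq = tuple(
        VariableSpec(
            name=v["name"],
            method=v["method"],
            predictors=tuple(tuple(p) for p in v["predictors"]),
            derived_rule=v.get("derived_rule"),
        )
        for v in data["visit_sequence"]
    )
    return SynthesisPlan(
        visit_sequence=seq,
        cl_scenario=data["cl_scenario"],
        condition=data.get("condition"),
        cl_block_weeks=data.get("cl_block_weeks", 4),
        categorical=tuple(data.get("categorical", ("PlayerID",))),
        hyperparams=cart.TreeHyperparams(**data["hyperparams"]),
        proper=data.get("proper", False),
    )
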