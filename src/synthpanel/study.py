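"""Study orchestration: conditions x scenarios x replicates, plus reporting.

Runs the full synthesis experiment on a panel: for each (condition,
chronic-load scenario) cell, generate seeded synthetic replicates, score
each with the global propensity metrics, the injury-GEE replication, and
the observation-level load MAE, and aggregate Mean (SD) summaries.  Also
emits the transparency *release sheet* that should accompany any released
synthetic dataset: which variables were synthesized, with which method and
predictors, the utility achieved, and what analyses the data do and do not
support.
"""

from __future__ import annotations

import json
import signal
import threading
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fixture import FixtureConfig, generate_fixture
from .global_utility import global_utility
from .panel import compute_acwr, read_panel, write_panel
from .specific_utility import GEEEstimationError, fit_injury_gee, observation_mae
from .synthesis import (
    CL_SCENARIOS,
    CONDITION_NAMES,
    build_condition,
    plan_to_dict,
    prepare_panel,
    synthesize,
)

__all__ = [
    "StudyConfig",
    "run_condition",
    "run_study",
    "summarize_replicates",
    "make_release_sheet",
    "replicate_seed",
    "load_study_config",
    "calibrate_fixture_to_se",
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run."""

    fixture: FixtureConfig | str = field(default_factory=FixtureConfig)
    conditions: tuple = CONDITION_NAMES
    cl_scenarios: tuple = CL_SCENARIOS
    n_replicates: int = 50
    master_seed: int = 0
    output_dir: str = "study_output"
    timeout_s: float | None = 60.0
    save_replicates: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        for c in self.conditions:
            if c not in CONDITION_NAMES:
                raise ValueError(f"unknown condition {c!r}")
        for s in self.cl_scenarios:
            if s not in CL_SCENARIOS:
                raise ValueError(f"unknown cl_scenario {s!r}")


def load_study_config(path) -> StudyConfig:
    """Read a YAML study config; ``fixture`` is a mapping or a CSV path."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fixture = raw.get("fixture", {})
    if isinstance(fixture, dict):
        fixture = FixtureConfig(**fixture)
    return StudyConfig(
        fixture=fixture,
        conditions=tuple(raw.get("conditions", CONDITION_NAMES)),
        cl_scenarios=tuple(raw.get("cl_scenarios", CL_SCENARIOS)),
        n_replicates=int(raw.get("n_replicates", 50)),
        master_seed=int(raw.get("master_seed", 0)),
        output_dir=str(raw.get("output_dir", "study_output")),
        timeout_s=raw.get("timeout_s", 60.0),
        save_replicates=bool(raw.get("save_replicates", False)),
    )


def replicate_seed(master_seed: int, condition: str, scenario: str, replicate: int) -> int:
    """Fixed counter scheme deriving one child seed per replicate cell."""
    entropy = np.random.SeedSequence(
        [master_seed, CONDITION_NAMES.index(condition), CL_SCENARIOS.index(scenario), replicate]
    )
    return int(entropy.generate_state(1)[0] % (2**31))


class ReplicateTimeout(RuntimeError):
    pass


@contextmanager
def _time_limit(seconds: float | None):
    # SIGALRM only works in the main thread; elsewhere the guard is a no-op
    if seconds is None or threading.current_thread() is not threading.main_thread():
        yield
        return

    def handler(signum, frame):  # pragma: no cover - timing dependent
        raise ReplicateTimeout(f"replicate exceeded {seconds} s")

    previous = signal.signal(signal.SIGALRM, handler)
    signal.setitimer(signal.ITIMER_REAL, seconds)
    try:
        yield
    finally:
        signal.setitimer(signal.ITIMER_REAL, 0)
        signal.signal(signal.SIGALRM, previous)


_METRIC_COLUMNS = [
    "pmse",
    "s_pmse",
    "po50",
    "gee_estimate",
    "gee_se",
    "gee_p",
    "abs_err_estimate",
    "abs_err_se",
    "abs_err_p",
    "obs_mae_AcuteLoad",
    "obs_mae_ChronicLoad",
    "time_s",
]


def run_condition(
    panel: pd.DataFrame,
    condition: str,
    scenario: str,
    n_replicates: int,
    seed: int,
    timeout_s: float | None = None,
    reference=None,
    save_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Score ``n_replicates`` seeded syntheses of one (condition, scenario).

    Returns one row per replicate; failures (GEE degeneracy, timeouts) are
    recorded with ``failed=True`` and the run continues.  Deterministic
    given ``seed``: replicate r uses a child seed derived by a fixed
    counter scheme.
    """
    plan = build_condition(condition, scenario)
    panel = prepare_panel(panel, plan)
    reference = reference or fit_injury_gee(panel)
    rows = []
    for r in range(n_replicates):
        child = replicate_seed(seed, condition, scenario, r)
        rng = np.random.default_rng(child)
        record: dict = {
            "condition": condition,
            "cl_scenario": scenario,
            "replicate": r,
            "seed": child,
            "failed": False,
            "error": "",
        }
        start = time.perf_counter()
        try:
            with _time_limit(timeout_s):
                synthetic = synthesize(panel, plan, rng)
                gu = global_utility(panel, synthetic)
                record.update(pmse=gu.pmse, s_pmse=gu.s_pmse, po50=gu.po50)
                gee = fit_injury_gee(synthetic)
                record.update(
                    gee_estimate=gee.estimate,
                    gee_se=gee.se,
                    gee_p=gee.p,
                    abs_err_estimate=abs(gee.estimate - reference.estimate),
                    abs_err_se=abs(gee.se - reference.se),
                    abs_err_p=abs(gee.p - reference.p),
                )
                om = observation_mae(panel, synthetic)
                record.update(
                    obs_mae_AcuteLoad=om.mae["AcuteLoad"],
                    obs_mae_ChronicLoad=om.mae["ChronicLoad"],
                )
                if save_dir is not None:
                    save_dir = Path(save_dir)
                    save_dir.mkdir(parents=True, exist_ok=True)
                    write_panel(synthetic, save_dir / f"synthetic_{r:04d}.csv")
        except (GEEEstimationError, ReplicateTimeout, Exception) as exc:  # noqa: BLE001
            record["failed"] = True
            record["error"] = f"{type(exc).__name__}: {exc}"
        record["time_s"] = time.perf_counter() - start
        rows.append(record)
    return pd.DataFrame(rows)


def summarize_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) per (condition, scenario) cell over successful replicates."""
    out = []
    for (condition, scenario), grp in replicates.groupby(
        ["condition", "cl_scenario"], sort=False
    ):
        ok = grp.loc[~grp["failed"]]
        row = {
            "condition": condition,
            "cl_scenario": scenario,
            "n_replicates": len(grp),
            "n_failed": int(grp["failed"].sum()),
        }
        for col in _METRIC_COLUMNS:
            vals = ok[col].dropna() if col in ok.columns else pd.Series(dtype=float)
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{col}_sd"] = float(vals.std(ddof=0)) if len(vals) else float("nan")
        # adjacent-pair consistency of the GEE estimate, when >= 2 replicates
        est = ok["gee_estimate"].dropna().to_numpy() if "gee_estimate" in ok.columns else []
        if len(est) >= 2:
            pair = np.abs(np.diff(est))
            row["adjacent_pair_estimate_mae"] = float(pair.mean())
        else:
            row["adjacent_pair_estimate_mae"] = float("nan")
        out.append(row)
    return pd.DataFrame(out)


def run_study(config: StudyConfig):
    """Run conditions x scenarios x replicates; persist artifacts.

    Writes per-cell replicate tables, a summary CSV/JSON, a plain-text log
    with per-stage timing, and one release sheet per cell.  Returns
    ``(summary, replicates)`` data frames.  A fully failed cell is reported
    in the log and does not abort the others.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(config.fixture, (str, Path)):
        panel = read_panel(config.fixture)
    else:
        panel = generate_fixture(config.fixture)
    panel = compute_acwr(panel)
    reference = fit_injury_gee(panel)
    log_lines = [f"study master_seed={config.master_seed}"]
    all_reps = []
    for condition in config.conditions:
        for scenario in config.cl_scenarios:
            t0 = time.perf_counter()
            reps = run_condition(
                panel,
                condition,
                scenario,
                config.n_replicates,
                config.master_seed,
                timeout_s=config.timeout_s,
                reference=reference,
                save_dir=(out_dir / f"{condition}_{scenario}") if config.save_replicates else None,
            )
            all_reps.append(reps)
            elapsed = time.perf_counter() - t0
            n_failed = int(reps["failed"].sum())
            log_lines.append(
                f"{condition}/{scenario}: {len(reps)} replicates, "
                f"{n_failed} failed, {elapsed:.1f} s"
            )
            if n_failed == len(reps):
                log_lines.append(f"  WARNING: every replicate failed for {condition}/{scenario}")
            reps.to_csv(out_dir / f"replicates_{condition}_{scenario}.csv", index=False)
    replicates = pd.concat(all_reps, ignore_index=True)
    summary = summarize_replicates(replicates)
    summary.to_csv(out_dir / "summary.csv", index=False)
    summary.to_json(out_dir / "summary.json", orient="records", indent=2)
    for condition in config.conditions:
        for scenario in config.cl_scenarios:
            plan = build_condition(condition, scenario)
            sheet = make_release_sheet(
                plan, summary[(summary.condition == condition) & (summary.cl_scenario == scenario)]
            )
            (out_dir / f"release_sheet_{condition}_{scenario}.md").write_text(sheet)
    (out_dir / "study.log").write_text("\n".join(log_lines) + "\n")
    return summary, replicates


def make_release_sheet(plan, summary: pd.DataFrame | None = None, notes: str = "") -> str:
    """Transparency document accompanying a released synthetic dataset.

    Lists every variable with its method, predictors and their source,
    the tree hyperparameters, the chronic-load scenario, the utility
    achieved, a limitations section, and a machine-readable block from
    which the plan can be rebuilt exactly.
    """
    lines = [
        f"# Synthetic data release sheet — condition `{plan.condition}`, "
        f"chronic load `{plan.cl_scenario}`",
        "",
        "## Generation process",
        "",
        "Sequential tree-based synthesis: each variable in the visit sequence",
        "is generated in order, conditioning on original (fixed) columns and",
        "previously synthesized columns as listed.",
        "",
        "| Variable | Method | Predictors (source) |",
        "|---|---|---|",
    ]
    for v in plan.visit_sequence:
        preds = ", ".join(f"{p} ({s})" for p, s in v.predictors) or "—"
        method = v.method if v.method != "derived" else f"derived: {v.derived_rule}"
        lines.append(f"| {v.name} | {method} | {preds} |")
    hp = plan.hyperparams
    lines += [
        "",
        f"CART hyperparameters: min_leaf={hp.min_leaf}, min_split={hp.min_split}, "
        f"complexity={hp.complexity}, max_depth={hp.max_depth}; "
        f"{'proper' if plan.proper else 'improper'} synthesis (donor draws "
        f"{'from bootstrapped leaves' if plan.proper else 'directly from fitted leaves'}).",
    ]
    if plan.cl_scenario == "calculated":
        lines += [
            "",
            "Chronic load derivation rule: ChronicLoad at week t equals the mean "
            f"of the synthetic AcuteLoad over the {plan.cl_block_weeks - 1} weeks "
            f"strictly before t (uncoupled {plan.cl_block_weeks}-week block); weeks "
            "without a full window are missing.",
        ]
    if summary is not None and len(summary):
        row = summary.iloc[0]
        lines += [
            "",
            "## Utility",
            "",
            f"- global: pMSE {row.get('pmse_mean', float('nan')):.5f} "
            f"({row.get('pmse_sd', float('nan')):.5f}), "
            f"s-pMSE {row.get('s_pmse_mean', float('nan')):.2f} "
            f"({row.get('s_pmse_sd', float('nan')):.2f}), "
            f"PO50 {row.get('po50_mean', float('nan')):.2f} "
            f"({row.get('po50_sd', float('nan')):.2f})",
            f"- specific (MAE vs reference GEE): estimate "
            f"{row.get('abs_err_estimate_mean', float('nan')):.3f}, "
            f"SE {row.get('abs_err_se_mean', float('nan')):.3f}, "
            f"p {row.get('abs_err_p_mean', float('nan')):.3f} "
            f"over {int(row.get('n_replicates', 0))} replicates "
            f"({int(row.get('n_failed', 0))} failed)",
        ]
    lines += [
        "",
        "## Limitations",
        "",
        "- These data support replication of analyses whose predictors match the",
        "  conditioning sets above; analyses relying on relationships that were",
        "  not conditioned on (e.g. temporal trajectories when no lag or week",
        "  predictors were used) may be biased.",
        "- Synthetic values are donor draws from observed values; no record",
        "  corresponds to a real individual, but marginal values are observed ones.",
    ]
    if "Injury" in plan.synthesized:
        lines.append(
            "- Injury timings are synthetic (fictitious within player); do not use "
            "for per-player injury chronology."
        )
    else:
        lines.append(
            "- Injury, and any identifier columns marked fixed, are the original "
            "values; assess disclosure risk before release."
        )
    if notes:
        lines += ["", "## Notes", "", notes]
    lines += [
        "",
        "## Machine-readable plan",
        "",
        "```json",
        json.dumps(plan_to_dict(plan), indent=2),
        "```",
        "",
    ]
    return "\n".join(lines)


def calibrate_fixture_to_se(
    config: FixtureConfig,
    target_se: float = 0.33,
    rel_tol: float = 0.10,
    max_iter: int = 20,
) -> tuple[FixtureConfig, "object"]:
    """Adjust ``beta0`` until the reference GEE standard error matches a target.

    The SE of the ACWR coefficient shrinks as the injury rate grows, so a
    bisection on the baseline log-odds is monotone (fixed seed per
    evaluation).  Returns the calibrated config and its reference GEE fit.
    """
    lo, hi = -9.0, -1.0
    cfg = config
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cfg = replace(config, beta0=mid)
        try:
            ref = fit_injury_gee(compute_acwr(generate_fixture(cfg)))
        except GEEEstimationError:
            lo = mid  # too few events: raise the baseline
            continue
        if best is None or abs(ref.se - target_se) < abs(best[1].se - target_se):
            best = (cfg, ref)
        if abs(ref.se - target_se) <= rel_tol * target_se:
            return cfg, ref
        if ref.se > target_se:
            lo = mid  # SE too large -> need more events -> larger beta0
        else:
            hi = mid
    if best is None:
        raise RuntimeError("could not estimate the reference GEE at any baseline")
    return best
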