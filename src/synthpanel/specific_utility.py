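"""Specific utility: GEE replication closeness and observation-level MAE.

Specific utility asks whether the synthetic data reproduce the answer the
original data gave to the study's research question: the association
between the acute:chronic workload ratio (ACWR) and injury, estimated by
a binomial GEE with logit link and exchangeable working correlation
clustered by player.  Closeness is summarised by the mean absolute error
(MAE), across synthetic replicates, of the GEE estimate, standard error
and p-value.  Observation-level MAE of the load variables (aligned by
player and week) measures instead how well individual temporal load
trajectories are retained — the two notions trade off against each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import compute_acwr

__all__ = [
    "GEEResult",
    "SpecificUtilityReport",
    "ObservationMAEReport",
    "GEEEstimationError",
    "fit_injury_gee",
    "specific_utility_mae",
    "observation_mae",
    "adjacent_pair_consistency",
]


class GEEEstimationError(RuntimeError):
    """The injury GEE could not be estimated on this panel."""


@dataclass(frozen=True)
class GEEResult:
    """ACWR coefficient of the injury GEE, on the log-odds scale."""

    estimate: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    n_clusters: int
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
        }


def fit_injury_gee(panel: pd.DataFrame, log_acwr: bool = False) -> GEEResult:
    """Binomial GEE of Injury on ACWR, exchangeable correlation by player.

    ACWR is computed on the fly if absent; rows with missing ACWR are
    dropped.  Robust (sandwich) standard errors; the 95% interval is the
    Wald interval ``estimate ± 1.96·se``.  ``log_acwr=True`` enters the
    ratio on the log scale instead of raw.
    """
    df = panel if "ACWR" in panel.columns else compute_acwr(panel)
    df = df.loc[df["ACWR"].notna(), ["PlayerID", "Injury", "ACWR"]].copy()
    if len(df) == 0:
        raise GEEEstimationError("no usable rows (ACWR everywhere missing)")
    if df["Injury"].sum() == 0:
        raise GEEEstimationError("no injuries among usable rows")
    clusters_with_events = df.groupby("PlayerID", observed=True)["Injury"].sum().gt(0).sum()
    if clusters_with_events < 2:
        raise GEEEstimationError("fewer than 2 clusters with injury events")
    x = np.log(df["ACWR"].to_numpy()) if log_acwr else df["ACWR"].to_numpy()
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                df["Injury"].to_numpy(),
                design,
                groups=df["PlayerID"].to_numpy(),
                family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            res = model.fit()
    except Exception as exc:
        raise GEEEstimationError(f"GEE fit failed: {exc}") from exc
    est = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(est) or not np.isfinite(se) or se <= 0:
        raise GEEEstimationError("GEE returned a non-finite estimate or SE")
    z = est / se
    p = float(2 * stats.norm.sf(abs(z)))
    return GEEResult(
        estimate=est,
        se=se,
        z=float(z),
        p=p,
        ci_low=est - 1.96 * se,
        ci_high=est + 1.96 * se,
        n_clusters=int(df["PlayerID"].nunique()),
        n_obs=int(len(df)),
    )


@dataclass(frozen=True)
class SpecificUtilityReport:
    """MAE (mean ± SD of absolute errors) of estimate, SE and p-value."""

    mae_estimate: float
    mae_se: float
    mae_p: float
    sd_estimate: float
    sd_se: float
    sd_p: float
    n_replicates: int

    def to_dict(self) -> dict:
        return {
            "mae_estimate": self.mae_estimate,
            "mae_se": self.mae_se,
            "mae_p": self.mae_p,
            "sd_estimate": self.sd_estimate,
            "sd_se": self.sd_se,
            "sd_p": self.sd_p,
            "n_replicates": self.n_replicates,
        }


def specific_utility_mae(
    reference: GEEResult, replicates: list[GEEResult]
) -> SpecificUtilityReport:
    """MAE of replicate GEE results against the reference fit.

    Callers exclude failed replicates before this point; at least one
    successful replicate is required.
    """
    if not replicates:
        raise ValueError("at least one successful replicate is required")
    errs = {
        name: np.array([abs(getattr(r, name) - getattr(reference, name)) for r in replicates])
        for name in ("estimate", "se", "p")
    }
    return SpecificUtilityReport(
        mae_estimate=float(errs["estimate"].mean()),
        mae_se=float(errs["se"].mean()),
        mae_p=float(errs["p"].mean()),
        sd_estimate=float(errs["estimate"].std(ddof=0)),
        sd_se=float(errs["se"].std(ddof=0)),
        sd_p=float(errs["p"].std(ddof=0)),
        n_replicates=len(replicates),
    )


@dataclass(frozen=True)
class ObservationMAEReport:
    """Per-variable mean |synthetic - original| over (player, week)-aligned rows."""

    mae: dict
    n_rows: dict

    def to_dict(self) -> dict:
        return {"mae": dict(self.mae), "n_rows": dict(self.n_rows)}


def observation_mae(
    original: pd.DataFrame,
    synthetic: pd.DataFrame,
    variables: list[str] = ("AcuteLoad", "ChronicLoad"),
) -> ObservationMAEReport:
    """Row-aligned MAE of load variables between original and synthetic panels."""
    keys = ["PlayerID", "WeekID"]
    lhs = original.set_index(keys).sort_index()
    rhs = synthetic.set_index(keys).sort_index()
    if not lhs.index.equals(rhs.index):
        missing = lhs.index.symmetric_difference(rhs.index)[:5].tolist()
        raise ValueError(f"(player, week) index mismatch, e.g. {missing}")
    mae, n_rows = {}, {}
    for var in variables:
        diff = (rhs[var] - lhs[var]).abs().dropna()
        mae[var] = float(diff.mean()) if len(diff) else float("nan")
        n_rows[var] = int(len(diff))
    return ObservationMAEReport(mae=mae, n_rows=n_rows)


def adjacent_pair_consistency(panels: list, metric) -> list[float]:
    """Apply ``metric(a, b)`` to consecutive pairs (1,2), (2,3), ... (R-1,R).

    ``panels`` may hold panels, GEE results or plain numbers — anything the
    metric accepts.  For asymmetric (reference-based) metrics the first
    element of each pair acts as the reference.  Returns R-1 values.
    """
    if len(panels) < 2:
        raise ValueError("at least 2 panels are required")
    return [float(metric(panels[i], panels[i + 1])) for i in range(len(panels) - 1)]
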