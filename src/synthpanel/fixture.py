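"""Synthetic stand-in generator for a football training-load/injury panel.

The original monitoring dataset (34 professional players followed for 120
weeks) is not publicly deposited.  This module generates a panel with the
statistical structure the downstream analysis assumes, so every stage of
the pipeline is testable end to end:

* weekly acute load: a player-specific random intercept plus a stationary
  AR(1) process, clamped at zero (loads are non-negative);
* chronic load: the uncoupled multi-week mean of acute load
  (:func:`synthpanel.panel.derive_chronic_load`);
* injury: Bernoulli with logit-linear risk in the acute:chronic workload
  ratio plus a player-level frailty (random intercept), which induces the
  exchangeable within-player correlation the GEE works with;
* optional injury->load feedback: the week after an injury the acute load
  is multiplied by ``post_injury_multiplier`` before downstream weeks are
  generated (off by default: multiplier 1).

Weeks whose ACWR is undefined (the first incomplete chronic-load window)
are forced injury-free so the injury model is estimable on exactly the
rows that carry an ACWR value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel import compute_acwr, derive_chronic_load, validate_panel

__all__ = [
    "FixtureConfig",
    "CalibrationError",
    "generate_fixture",
    "calibrate_baseline_risk",
    "summarize_fixture",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the stand-in data-generating process.

    Loads are in arbitrary weekly-load units (think session-RPE x minutes,
    magnitude ~2000); risk parameters are on the log-odds scale.  The
    injury effect ``beta1`` defaults to the 0.90 log-odds-per-ACWR-unit
    effect the reference analysis reports; ``beta0`` defaults to a value
    giving a marginal injury rate of roughly 0.04 per player-week.
    """

    n_players: int = 34
    n_weeks: int = 120
    mu_load: float = 2000.0
    sd_player: float = 300.0
    ar_phi: float = 0.5
    sd_week: float = 350.0
    beta0: float = -4.1
    beta1: float = 0.90
    sd_frailty: float = 0.3
    post_injury_multiplier: float = 1.0
    block_weeks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_players < 2:
            raise ValueError("n_players must be >= 2")
        if self.n_weeks < self.block_weeks + 1:
            raise ValueError("n_weeks must exceed the chronic-load block")
        if not abs(self.ar_phi) < 1:
            raise ValueError("ar_phi must lie in (-1, 1)")
        if not 0 < self.post_injury_multiplier <= 1:
            raise ValueError("post_injury_multiplier must lie in (0, 1]")
        if self.sd_player < 0 or self.sd_week <= 0 or self.sd_frailty < 0:
            raise ValueError("scale parameters must be non-negative (sd_week > 0)")


def _player_streams(config: FixtureConfig) -> list[np.random.Generator]:
    # one sub-stream per player, derived deterministically from the panel seed
    children = np.random.SeedSequence(config.seed).spawn(config.n_players)
    return [np.random.default_rng(s) for s in children]


def generate_fixture(config: FixtureConfig | None = None) -> pd.DataFrame:
    """Generate one seeded panel of ``n_players`` x ``n_weeks`` rows."""
    cfg = config or FixtureConfig()
    window = cfg.block_weeks - 1
    stat_sd = cfg.sd_week / np.sqrt(1.0 - cfg.ar_phi**2)
    frames = []
    for pid, rng in enumerate(_player_streams(cfg), start=1):
        u_p = rng.normal(0.0, cfg.sd_player)
        b_p = rng.normal(0.0, cfg.sd_frailty)
        eps = rng.normal(0.0, cfg.sd_week, size=cfg.n_weeks)
        eps[0] = rng.normal(0.0, stat_sd)
        uniforms = rng.uniform(size=cfg.n_weeks)

        al = np.empty(cfg.n_weeks)
        cl = np.full(cfg.n_weeks, np.nan)
        injury = np.zeros(cfg.n_weeks, dtype=int)
        dev = 0.0
        for t in range(cfg.n_weeks):
            dev = eps[t] if t == 0 else cfg.ar_phi * dev + eps[t]
            value = max(0.0, cfg.mu_load + u_p + dev)
            if t > 0 and injury[t - 1] == 1 and cfg.post_injury_multiplier < 1:
                value *= cfg.post_injury_multiplier
                # feedback propagates downstream through the AR recursion
                dev = value - cfg.mu_load - u_p
            al[t] = value
            if t >= window:
                cl[t] = al[t - window : t].mean()
                if cl[t] > 0:
                    acwr = al[t] / cl[t]
                    p = expit(cfg.beta0 + cfg.beta1 * acwr + b_p)
                    injury[t] = int(uniforms[t] < p)
        frames.append(
            pd.DataFrame(
                {
                    "PlayerID": pid,
                    "WeekID": np.arange(1, cfg.n_weeks + 1),
                    "AcuteLoad": al,
                    "ChronicLoad": cl,
                    "Injury": injury,
                }
            )
        )
    panel = pd.concat(frames, ignore_index=True)
    return validate_panel(panel)


@dataclass(frozen=True)
class CalibrationError(Exception):
    """Monotone search failed to hit the target rate; carries the best value."""

    best_beta0: float
    achieved_rate: float
    target_rate: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"calibration did not converge: best beta0={self.best_beta0:.4f} "
            f"gives rate {self.achieved_rate:.4f} (target {self.target_rate:.4f})"
        )


def _simulated_rate(cfg: FixtureConfig, beta0: float, n_reps: int) -> float:
    rates = []
    for r in range(n_reps):
        panel = generate_fixture(replace(cfg, beta0=beta0, seed=cfg.seed + 7919 * r))
        usable = panel["ChronicLoad"].notna()
        rates.append(panel.loc[usable, "Injury"].mean())
    return float(np.mean(rates))


def calibrate_baseline_risk(
    config: FixtureConfig,
    target_rate: float,
    tol: float = 0.002,
    n_reps: int = 20,
    max_iter: int = 40,
) -> float:
    """Find ``beta0`` whose simulated marginal injury rate matches the target.

    Bisection on ``beta0`` with common random numbers across evaluations
    (the same replicate seeds at every step), which makes the simulated
    rate strictly monotone in ``beta0``.  Closed form when the risk model
    degenerates to a constant (``beta1 == 0`` and ``sd_frailty == 0``).
    """
    if not 0 < target_rate < 0.5:
        raise ValueError("target_rate must lie in (0, 0.5)")
    if config.beta1 == 0 and config.sd_frailty == 0:
        return float(logit(target_rate))
    lo, hi = -15.0, 5.0
    best = (np.inf, config.beta0, np.nan)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rate = _simulated_rate(config, mid, n_reps)
        gap = abs(rate - target_rate)
        if gap < best[0]:
            best = (gap, mid, rate)
        if gap <= tol:
            return float(mid)
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(best_beta0=best[1], achieved_rate=best[2], target_rate=target_rate)


def summarize_fixture(panel: pd.DataFrame) -> dict:
    """Deterministic summary: injury rate, AL moments, mean lag-1 autocorrelation.

    The autocorrelation is the within-player Pearson correlation of acute
    load with its one-week lag, averaged over players; players with a
    constant load series contribute nothing (reported NaN if all are).
    """
    panel = validate_panel(panel)
    usable = panel["ChronicLoad"].notna()
    corrs = []
    for _, grp in panel.groupby("PlayerID", observed=True):
        al = grp["AcuteLoad"].to_numpy(dtype=float)
        if len(al) < 3 or np.std(al[:-1]) == 0 or np.std(al[1:]) == 0:
            continue
        corrs.append(np.corrcoef(al[:-1], al[1:])[0, 1])
    return {
        "n_players": int(panel["PlayerID"].nunique()),
        "n_weeks": int(panel.groupby("PlayerID", observed=True)["WeekID"].size().max()),
        "injury_rate": float(panel.loc[usable, "Injury"].mean()),
        "mean_acute_load": float(panel["AcuteLoad"].mean()),
        "sd_acute_load": float(panel["AcuteLoad"].std(ddof=0)),
        "mean_lag1_autocorr": float(np.mean(corrs)) if corrs else float("nan"),
    }


def fixture_with_acwr(config: FixtureConfig | None = None) -> pd.DataFrame:
    """Convenience: generate a fixture and append its ACWR column."""
    return compute_acwr(generate_fixture(config))
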