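"""Data model and feature engineering for longitudinal monitoring panels.

A *monitoring panel* is a long-format player-week table with five core
columns: ``PlayerID``, ``WeekID``, ``AcuteLoad``, ``ChronicLoad`` and
``Injury``.  Acute load (AL) proxies a player's weekly training load;
chronic load (CL) is a multi-week average of acute load, *uncoupled* when
the acute week itself is excluded from the averaging window.  The
acute:chronic workload ratio (ACWR = AL/CL) is the exposure in the injury
model downstream.

Panels are plain :class:`pandas.DataFrame` objects validated by
:func:`validate_panel`; all operations return new frames sorted by
``(PlayerID, WeekID)`` and represent missing cells as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CORE_COLUMNS",
    "PanelSchemaError",
    "PanelValidationError",
    "VariableSchema",
    "validate_panel",
    "read_panel",
    "write_panel",
    "derive_chronic_load",
    "add_lag_features",
    "compute_acwr",
    "lag_column_name",
]

#: Core column order used by the CSV interchange format.
CORE_COLUMNS = ["PlayerID", "WeekID", "AcuteLoad", "ChronicLoad", "Injury"]

#: Short prefixes used for lag-feature column names (AL_Lag1, CL_Lag2, ...).
LAG_PREFIXES = {"AcuteLoad": "AL", "ChronicLoad": "CL"}


class PanelSchemaError(ValueError):
    """A required column is absent or has the wrong type."""


class PanelValidationError(ValueError):
    """Panel content violates an invariant (duplicate weeks, bad Injury...)."""


@dataclass(frozen=True)
class VariableSchema:
    """Declared name/kind/role of one panel variable.

    ``kind`` is one of ``continuous``, ``binary``, ``categorical`` or
    ``identifier``.
    """

    name: str
    kind: str
    role: str = ""

    _KINDS = ("continuous", "binary", "categorical", "identifier")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")


#: Default schema of the five core variables.
DEFAULT_SCHEMA = [
    VariableSchema("PlayerID", "identifier", "cluster id"),
    VariableSchema("WeekID", "identifier", "time index"),
    VariableSchema("AcuteLoad", "continuous", "weekly training load"),
    VariableSchema("ChronicLoad", "continuous", "multi-week load average"),
    VariableSchema("Injury", "binary", "injury indicator"),
]


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel invariants; return the panel sorted by (player, week).

    Raises :class:`PanelSchemaError` for missing columns and
    :class:`PanelValidationError` for content violations.
    """
    for col in CORE_COLUMNS:
        if col not in panel.columns:
            raise PanelSchemaError(f"panel is missing required column {col!r}")
    out = panel.sort_values(["PlayerID", "WeekID"], kind="mergesort").reset_index(drop=True)

    week = out["WeekID"]
    if week.isna().any() or (week < 1).any() or (week != week.astype(int)).any():
        raise PanelValidationError("WeekID must be positive integers")
    dup = out.duplicated(subset=["PlayerID", "WeekID"])
    if dup.any():
        keys = out.loc[dup, ["PlayerID", "WeekID"]].head(5).to_records(index=False)
        raise PanelValidationError(f"duplicate (player, week) pairs, e.g. {list(keys)}")
    inj = out["Injury"]
    bad = ~inj.isin([0, 1]) | inj.isna()
    if bad.any():
        rows = out.index[bad][:5].tolist()
        raise PanelValidationError(
            f"Injury must be 0/1; offending rows (sorted order): {rows}"
        )
    al = out["AcuteLoad"]
    if (al.dropna() < 0).any():
        raise PanelValidationError("AcuteLoad must be non-negative where present")
    return out


def read_panel(path, schema=None) -> pd.DataFrame:
    """Read a panel CSV, validate it, and return it sorted by (player, week).

    Empty cells are read back as missing (NaN).  ``schema`` defaults to the
    five core variables; extra columns in the file are preserved.
    """
    schema = schema if schema is not None else DEFAULT_SCHEMA
    df = pd.read_csv(path)
    for var in schema:
        if var.name not in df.columns:
            raise PanelSchemaError(f"column {var.name!r} declared in schema but absent from {path}")
    return validate_panel(df)


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel CSV with the core columns first, missing cells empty."""
    panel = validate_panel(panel)
    extras = [c for c in panel.columns if c not in CORE_COLUMNS]
    panel[CORE_COLUMNS + extras].to_csv(path, index=False)


def _check_sorted_unique(panel: pd.DataFrame) -> None:
    grouped = panel.groupby("PlayerID", sort=False, observed=True)["WeekID"]
    if grouped.apply(lambda w: w.is_monotonic_increasing and w.is_unique).eq(False).any():
        raise PanelValidationError("weeks must be sorted and unique within player")


def derive_chronic_load(
    panel: pd.DataFrame,
    block_weeks: int = 4,
    uncoupled: bool = True,
    al_column: str = "AcuteLoad",
    out_column: str = "ChronicLoad",
) -> pd.DataFrame:
    """Recompute chronic load per player as a block mean of acute load.

    With ``uncoupled=True`` (default) the chronic load at week *t* is the
    mean of acute load over the ``block_weeks - 1`` weeks strictly before
    *t*: the 4-week block excluding the acute week itself, so the ratio
    AL/CL does not share a term between numerator and denominator.  With
    ``uncoupled=False`` the window is the ``block_weeks`` weeks ending at
    and including *t*.  Weeks lacking a full window get missing CL.

    Deterministic and idempotent given ``(panel, block_weeks, uncoupled)``.
    """
    if block_weeks < 2:
        raise ValueError("block_weeks must be >= 2")
    out = panel.sort_values(["PlayerID", "WeekID"], kind="mergesort").reset_index(drop=True)
    _check_sorted_unique(out)
    window = block_weeks - 1 if uncoupled else block_weeks
    grouped = out.groupby("PlayerID", sort=False, observed=True)[al_column]
    rolled = grouped.transform(lambda s: s.rolling(window, min_periods=window).mean())
    if uncoupled:
        rolled = rolled.groupby(out["PlayerID"], observed=True).shift(1)
    out[out_column] = rolled
    return out


def lag_column_name(variable: str, k: int) -> str:
    """Interchange name of the k-step lag of ``variable`` (AL_Lag1, ...)."""
    prefix = LAG_PREFIXES.get(variable, variable)
    return f"{prefix}_Lag{k}"


def add_lag_features(
    panel: pd.DataFrame, variables: list[str], max_lag: int
) -> pd.DataFrame:
    """Add within-player lagged copies ``Var_Lag(k)``, k = 1..max_lag.

    The first k weeks of each player are missing by construction; lags never
    cross a player boundary.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    out = panel.sort_values(["PlayerID", "WeekID"], kind="mergesort").reset_index(drop=True)
    _check_sorted_unique(out)
    for var in variables:
        if var not in out.columns:
            raise PanelSchemaError(f"unknown variable {var!r}")
        grouped = out.groupby("PlayerID", sort=False, observed=True)[var]
        for k in range(1, max_lag + 1):
            out[lag_column_name(var, k)] = grouped.shift(k)
    return out


def compute_acwr(panel: pd.DataFrame, out_column: str = "ACWR") -> pd.DataFrame:
    """Add ACWR = AcuteLoad / ChronicLoad; missing where CL is missing or 0.

    CL = 0 yields a missing ratio rather than infinity so downstream design
    matrices stay finite.
    """
    out = panel.copy()
    cl = out["ChronicLoad"].to_numpy(dtype=float)
    al = out["AcuteLoad"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cl > 0, al / cl, np.nan)
    out[out_column] = ratio
    return out
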