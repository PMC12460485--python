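"""Propensity-score global utility: pMSE, s-pMSE and PO50.

Global utility asks whether original and synthetic records are
distinguishable at all.  The two tables are stacked with an indicator
(1 = synthetic), a main-effects logistic regression of the indicator on
the panel variables is fitted, and three summaries of the fitted
propensity scores :math:`p_i` are reported:

* ``pMSE`` — :math:`N^{-1}\\sum_i (p_i - c)^2` with *c* the synthetic
  fraction of the stack; 0 when the datasets are indistinguishable.
* ``s-pMSE`` — pMSE divided by its expectation under the null of
  indistinguishability, :math:`(k-1)(1-c)^2 c / N` for a logistic model
  with *k* fitted parameters (intercept included); approximately 1 for a
  well-behaved synthesis.  A permutation-null z-score is available behind
  a flag for cross-checking.
* ``PO50`` — percentage points above 50 of stacked records correctly
  classified at the 0.5 threshold (ties counted half-correct); 0 is ideal.

Lower is better for all three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["GlobalUtilityReport", "fit_propensity", "compute_global_utility", "global_utility"]

#: Core propensity predictors; PlayerID (an identifier) is excluded unless
#: ``include_player=True``.  Lag columns present in both panels are added
#: automatically by :func:`default_predictors`.
CORE_PREDICTORS = ["WeekID", "AcuteLoad", "ChronicLoad", "Injury"]


def default_predictors(original: pd.DataFrame, synthetic: pd.DataFrame) -> list[str]:
    """Non-identifier variables shared by both panels: the core four plus
    any lag columns the condition created (ACWR, being a pure function of
    AL and CL, is excluded)."""
    shared = set(original.columns) & set(synthetic.columns)
    lags = sorted(c for c in shared if "_Lag" in c)
    return [c for c in CORE_PREDICTORS if c in shared] + lags


@dataclass(frozen=True)
class GlobalUtilityReport:
    pmse: float
    s_pmse: float | None
    po50: float
    c: float
    k: int
    n_stacked: int
    separation_flag: bool = False
    standardization: str = "expected_null_ratio"

    def to_dict(self) -> dict:
        return {
            "pmse": self.pmse,
            "s_pmse": self.s_pmse,
            "po50": self.po50,
            "c": self.c,
            "k": self.k,
            "n_stacked": self.n_stacked,
            "separation_flag": self.separation_flag,
            "standardization": self.standardization,
        }


def _design(
    stacked: pd.DataFrame,
    predictors: list[str],
    include_player: bool,
    interaction_order: int,
) -> pd.DataFrame:
    X = stacked[predictors].astype(float)
    # standardise continuous columns so product terms stay well-conditioned;
    # an affine rescaling leaves the logistic fit (hence pMSE) unchanged
    for col in X.columns:
        sd = X[col].std(ddof=0)
        if sd > 0:
            X[col] = (X[col] - X[col].mean()) / sd
    if interaction_order >= 2:
        cols = list(X.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                X[f"{a}:{b}"] = X[a] * X[b]
    if include_player and "PlayerID" in stacked.columns:
        dummies = pd.get_dummies(stacked["PlayerID"], prefix="PlayerID", drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    # degenerate (zero-variance) columns carry no signal and break the fit
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def fit_propensity(
    original: pd.DataFrame,
    synthetic: pd.DataFrame,
    predictors: list[str] | None = None,
    include_player: bool = False,
    interaction_order: int = 2,
):
    """Stack the panels and fit the indicator logistic regression.

    The default design has the main effects of ``predictors`` plus all
    their two-way interactions (the conventional default of the propensity
    utility literature); ``interaction_order=1`` fits main effects only.
    Rows with a missing value in any predictor are dropped (both panels
    share the early-week missing pattern, so this removes matched rows).
    Returns ``(probabilities, labels, c, k, separation_flag)``.
    """
    predictors = (
        predictors if predictors is not None else default_predictors(original, synthetic)
    )
    for col in predictors:
        if col not in original.columns or col not in synthetic.columns:
            raise KeyError(f"predictor {col!r} missing from a panel")
    stacked = pd.concat([original, synthetic], ignore_index=True)
    labels = np.concatenate([np.zeros(len(original)), np.ones(len(synthetic))])
    complete = stacked[predictors].notna().all(axis=1).to_numpy()
    stacked, labels = stacked.loc[complete].reset_index(drop=True), labels[complete]
    X = _design(stacked, predictors, include_player, interaction_order)
    n = len(stacked)
    c = float(labels.mean())
    k = X.shape[1] + 1
    design = sm.add_constant(X.to_numpy(), has_constant="add")

    separated = False
    probs = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(labels, design, family=sm.families.Binomial()).fit(maxiter=100)
            params = np.asarray(res.params)
            fitted = np.asarray(res.fittedvalues)
            # columns are standardised, so slopes beyond ~15 standardised
            # units (or near-degenerate fitted probabilities on most rows)
            # indicate (quasi-)complete separation
            extreme = np.mean((fitted > 1 - 1e-4) | (fitted < 1e-4))
            if np.all(np.isfinite(params)) and np.max(np.abs(params[1:])) < 15 and extreme < 0.5:
                probs = fitted
            else:
                separated = True
        except Exception:
            separated = True
    if probs is None:
        # bounded-coefficient fallback: ridge-penalised logistic fit
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X.to_numpy(), labels)
        probs = clf.predict_proba(X.to_numpy())[:, 1]
        separated = True
    return probs, labels, c, k, separated


def compute_global_utility(
    probabilities: np.ndarray,
    labels: np.ndarray,
    c: float,
    k: int,
    separation_flag: bool = False,
) -> GlobalUtilityReport:
    """Summarise fitted propensity scores into pMSE, s-pMSE and PO50."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    n = len(p)
    pmse = float(np.mean((p - c) ** 2))
    if k <= 1:
        s_pmse = None
    else:
        s_pmse = float(pmse / ((k - 1) * (1 - c) ** 2 * c / n))
    ties = p == 0.5
    correct_non_tie = np.sum(~ties & ((p > 0.5) == (y == 1)))
    correct = float(correct_non_tie + 0.5 * np.sum(ties))
    po50 = float(100.0 * correct / n - 50.0)
    return GlobalUtilityReport(
        pmse=pmse,
        s_pmse=s_pmse,
        po50=po50,
        c=c,
        k=k,
        n_stacked=n,
        separation_flag=separation_flag,
    )


def global_utility(
    original: pd.DataFrame,
    synthetic: pd.DataFrame,
    predictors: list[str] | None = None,
    include_player: bool = False,
    interaction_order: int = 2,
    standardization: str = "expected_null_ratio",
    rng: np.random.Generator | None = None,
    n_permutations: int = 200,
) -> GlobalUtilityReport:
    """One-call global utility of a synthetic panel against its original.

    ``standardization="permutation_z"`` replaces the expected-null-ratio
    s-pMSE with a z-score of pMSE against a permutation null (labels
    shuffled, model refitted).
    """
    probs, labels, c, k, sep = fit_propensity(
        original, synthetic, predictors, include_player, interaction_order
    )
    report = compute_global_utility(probs, labels, c, k, sep)
    if standardization == "permutation_z":
        rng = rng or np.random.default_rng(0)
        predictors = predictors if predictors is not None else default_predictors(original, synthetic)
        stacked = pd.concat([original, synthetic], ignore_index=True)
        complete = stacked[predictors].notna().all(axis=1)
        stacked = stacked.loc[complete].reset_index(drop=True)
        null_pmse = []
        base_labels = labels.copy()
        for _ in range(n_permutations):
            perm = rng.permutation(base_labels)
            lo = stacked.loc[perm == 0]
            hi = stacked.loc[perm == 1]
            p2, l2, c2, k2, _ = fit_propensity(
                lo, hi, predictors, include_player, interaction_order
            )
            null_pmse.append(np.mean((p2 - c2) ** 2))
        mu, sd = float(np.mean(null_pmse)), float(np.std(null_pmse, ddof=1))
        z = (report.pmse - mu) / sd if sd > 0 else np.nan
        report = GlobalUtilityReport(
            pmse=report.pmse,
            s_pmse=float(z),
            po50=report.po50,
            c=report.c,
            k=report.k,
            n_stacked=report.n_stacked,
            separation_flag=report.separation_flag,
            standardization="permutation_z",
        )
    return report
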