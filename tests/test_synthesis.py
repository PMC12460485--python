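"""Conditions, plan validation and the sequential synthesis pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synthpanel import (
    SynthesisPlan,
    VariableSpec,
    build_condition,
    plan_from_dict,
    plan_to_dict,
    prepare_panel,
    synthesize,
    validate_plan,
)
from synthpanel.panel import derive_chronic_load
from synthpanel.synthesis import CONDITION_NAMES, SynthesisError


class TestBuildCondition:
    def test_base_encoding(self):
        plan = build_condition("base", "independent")
        al = plan.spec("AcuteLoad")
        cl = plan.spec("ChronicLoad")
        assert al.method == "cart"
        assert al.predictors == (("Injury", "original"), ("PlayerID", "original"))
        assert cl.predictors == (
            ("Injury", "original"),
            ("PlayerID", "original"),
            ("AcuteLoad", "synthetic"),
        )
        assert plan.fixed == ["Injury", "PlayerID"]

    def test_base_week_adds_weekid_predictor(self):
        plan = build_condition("base_week", "independent")
        assert ("WeekID", "original") in plan.spec("AcuteLoad").predictors
        assert "WeekID" in plan.fixed

    def test_no_playerid_uses_exactly_the_six_lags(self):
        plan = build_condition("no_playerid", "independent")
        al = plan.spec("AcuteLoad")
        assert al.predictors == tuple(
            (f"{v}_Lag{k}", "original") for v in ("AL", "CL") for k in (1, 2, 3)
        )
        inj = plan.spec("Injury")
        assert inj.method == "cart"
        assert ("AcuteLoad", "synthetic") in inj.predictors
        assert ("ChronicLoad", "synthetic") in inj.predictors
        assert all("PlayerID" != p for p, _ in inj.predictors)

    def test_injury_time_lag_samples_injury_first(self):
        plan = build_condition("injury_time_lag", "independent")
        first = plan.visit_sequence[0]
        assert first.name == "Injury" and first.method == "random_sample"
        # loads do not condition on Injury in this condition
        assert all(p != "Injury" for p, _ in plan.spec("AcuteLoad").predictors)

    def test_time_lag_injury_synthesizes_injury_last_with_playerid(self):
        plan = build_condition("time_lag_injury", "independent")
        assert plan.visit_sequence[-1].name == "Injury"
        assert ("PlayerID", "original") in plan.spec("Injury").predictors

    def test_calculated_scenario_derives_chronic_load(self):
        plan = build_condition("base", "calculated")
        assert plan.spec("ChronicLoad").method == "derived"

    def test_unknown_names_rejected_listing_options(self):
        with pytest.raises(ValueError, match="base_week"):
            build_condition("bogus")
        with pytest.raises(ValueError, match="calculated"):
            build_condition("base", "bogus")

    def test_plan_round_trips_through_dict(self):
        for name in CONDITION_NAMES:
            plan = build_condition(name, "calculated")
            assert plan_from_dict(plan_to_dict(plan)) == plan


class TestValidatePlan:
    def test_base_plan_valid_on_complete_panel(self, small_panel):
        result = validate_plan(build_condition("base"), small_panel)
        assert result.valid

    def test_ordering_violation_reported(self, small_panel):
        plan = SynthesisPlan(
            visit_sequence=(
                VariableSpec("ChronicLoad", "cart", (("AcuteLoad", "synthetic"),)),
                VariableSpec("AcuteLoad", "cart", (("Injury", "original"),)),
            )
        )
        result = validate_plan(plan, small_panel)
        assert not result.valid
        assert any("not synthesized earlier" in v for v in result.violations)

    def test_missing_lag_column_reported(self, small_panel):
        plan = SynthesisPlan(
            visit_sequence=(
                VariableSpec("AcuteLoad", "cart", (("AL_Lag2", "original"),)),
            )
        )
        result = validate_plan(plan, small_panel)
        assert any("AL_Lag2" in v for v in result.violations)


class TestSynthesize:
    def test_identity_plan_returns_input(self, small_panel):
        plan = SynthesisPlan(
            visit_sequence=tuple(
                VariableSpec(n, "fixed")
                for n in ("Injury", "PlayerID", "AcuteLoad", "ChronicLoad")
            )
        )
        out = synthesize(small_panel, plan, np.random.default_rng(0))
        pd.testing.assert_frame_equal(
            out[small_panel.columns].drop(columns="ACWR"),
            small_panel.drop(columns="ACWR"),
        )

    def test_fixed_columns_identical_for_every_condition(self, small_panel):
        for name in CONDITION_NAMES:
            plan = build_condition(name, "independent")
            panel = prepare_panel(small_panel, plan)
            out = synthesize(panel, plan, np.random.default_rng(3))
            for col in plan.fixed:
                pd.testing.assert_series_equal(out[col], panel[col], check_names=False)

    def test_calculated_scenario_couples_cl_to_synthetic_al(self, small_panel):
        plan = build_condition("base", "calculated")
        out = synthesize(small_panel, plan, np.random.default_rng(1))
        recomputed = derive_chronic_load(out.drop(columns="ChronicLoad"))
        assert np.allclose(
            out["ChronicLoad"].to_numpy(),
            recomputed["ChronicLoad"].to_numpy(),
            equal_nan=True,
        )

    def test_independent_scenario_cl_values_come_from_observed_donors(self, small_panel):
        plan = build_condition("base", "independent")
        out = synthesize(small_panel, plan, np.random.default_rng(2))
        observed = set(small_panel["ChronicLoad"].dropna())
        assert set(out["ChronicLoad"].dropna()) <= observed

    def test_missingness_pattern_preserved(self, small_panel):
        plan = build_condition("base", "independent")
        out = synthesize(small_panel, plan, np.random.default_rng(4))
        assert out["ChronicLoad"].isna().equals(small_panel["ChronicLoad"].isna())

    def test_seed_determinism_and_seed_sensitivity(self, small_panel):
        plan = build_condition("base", "independent")
        a = synthesize(small_panel, plan, np.random.default_rng(7))
        b = synthesize(small_panel, plan, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)
        c = synthesize(small_panel, plan, np.random.default_rng(8))
        assert not a["AcuteLoad"].equals(c["AcuteLoad"])

    def test_random_sample_injury_counts_match_binomial(self, small_panel):
        plan = build_condition("injury_time_lag", "independent")
        panel = prepare_panel(small_panel, plan)
        p = panel["Injury"].mean()
        n = len(panel)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        inside = 0
        for seed in range(200):
            out = synthesize(panel, plan, np.random.default_rng(10_000 + seed))
            inside += lo <= out["Injury"].sum() <= hi
        assert inside >= 0.97 * 200

    def test_marginal_preservation_ks_below_0p1(self, default_panel):
        plan = build_condition("base", "independent")
        ks_al, ks_cl = [], []
        orig_al = default_panel["AcuteLoad"].to_numpy()
        orig_cl = default_panel["ChronicLoad"].dropna().to_numpy()
        for seed in range(20):
            out = synthesize(default_panel, plan, np.random.default_rng(seed))
            ks_al.append(stats.ks_2samp(out["AcuteLoad"], orig_al).statistic)
            ks_cl.append(stats.ks_2samp(out["ChronicLoad"].dropna(), orig_cl).statistic)
        assert np.mean(ks_al) < 0.1
        assert np.mean(ks_cl) < 0.1

    def test_invalid_plan_raises_synthesis_error(self, small_panel):
        plan = SynthesisPlan(
            visit_sequence=(VariableSpec("AcuteLoad", "cart", (("Nope", "original"),)),)
        )
        with pytest.raises(SynthesisError, match="Nope"):
            synthesize(small_panel, plan, np.random.default_rng(0))

    def test_lagged_condition_fills_early_weeks_from_marginal(self, small_panel):
        plan = build_condition("time_lag_3wks", "independent")
        panel = prepare_panel(small_panel, plan)
        out = synthesize(panel, plan, np.random.default_rng(5))
        # early weeks (no lag history) still receive observed AL values
        early = out.groupby("PlayerID").head(3)
        assert early["AcuteLoad"].notna().all()
        assert set(early["AcuteLoad"]) <= set(panel["AcuteLoad"])
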