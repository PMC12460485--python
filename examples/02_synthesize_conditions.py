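"""Synthesize a panel under two predictor-specification conditions.

Shows the trade-off at the heart of the pipeline: the `base` condition
conditions the loads only on Injury and PlayerID (good for replicating the
injury regression, poor at individual load trajectories), while
`time_lag_3wks` conditions on three weeks of lagged loads (the reverse).
"""

import numpy as np

from synthpanel import (
    FixtureConfig,
    build_condition,
    compute_acwr,
    generate_fixture,
    observation_mae,
    prepare_panel,
    synthesize,
)

original = compute_acwr(generate_fixture(FixtureConfig(seed=1)))

for name in ("base", "time_lag_3wks"):
    plan = build_condition(name, cl_scenario="independent")
    panel = prepare_panel(original, plan)
    synthetic = synthesize(panel, plan, np.random.default_rng(7))
    mae = observation_mae(panel, synthetic).mae
    print(
        f"{name:14s} synthesized {plan.synthesized} | "
        f"observation-level MAE: AL {mae['AcuteLoad']:.1f}, CL {mae['ChronicLoad']:.1f}"
    )

print(
    "\nLower observation MAE means individual weekly load trajectories are"
    "\nbetter retained; lag predictors roughly halve it relative to `base`."
)
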