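# synthpanel

Sequential CART synthesis and utility evaluation for longitudinal
athlete-monitoring panels.

## The problem

Training-load and injury datasets from professional sport are rarely
shareable: squads are small, athletes are public figures, and injury
timing alone can re-identify a player. *Data-driven synthetic data* —
records generated from models fitted to the observed data — offer a way
to release something analysable without releasing anyone's season. But a
synthetic dataset is only as good as the generation model's alignment
with the analysis it is meant to support, and that alignment has to be
measured, not assumed.

`synthpanel` implements the full measurement loop for a player-week panel
(`PlayerID`, `WeekID`, `AcuteLoad`, `ChronicLoad`, `Injury`):

* a **fixture generator** standing in for a confidential 34-player ×
  120-week football dataset: AR(1) weekly loads with player-level
  intercepts, uncoupled 4-week chronic load, and logistic injury risk in
  the acute:chronic workload ratio (ACWR = AL/CL) with player frailty;
* a **CART engine** with leaf-donor sampling (every synthetic value is an
  observed value drawn from a fitted tree's leaf);
* **sequential synthesis** under seven named predictor-specification
  conditions (from `base`, mirroring the injury regression, to
  `time_lag_3wks` and the injury-synthesizing conditions) and two
  chronic-load scenarios (`independent` vs `calculated` from synthetic
  acute load);
* **global utility** via a stacked propensity model: pMSE = N⁻¹Σ(p̂ᵢ−c)²,
  s-pMSE = pMSE / [(k−1)(1−c)²c/N], and PO50 (percentage points above 50
  correctly classified);
* **specific utility**: the binomial GEE of Injury on ACWR (logit link,
  exchangeable working correlation, clusters = players) refitted on each
  synthetic replicate, summarised by MAE of estimate / SE / p-value, plus
  observation-level load MAE and adjacent-pair consistency;
* a **study harness** that runs conditions × scenarios × replicates,
  aggregates Mean (SD) tables, and writes a transparency *release sheet*
  per condition.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
from synthpanel import (
    FixtureConfig, build_condition, compute_acwr, fit_injury_gee,
    generate_fixture, global_utility, synthesize,
)

original = compute_acwr(generate_fixture(FixtureConfig(seed=1)))
ref = fit_injury_gee(original)
print(f"reference GEE: estimate {ref.estimate:.3f}, SE {ref.se:.3f}")

plan = build_condition("base_week", cl_scenario="independent")
synthetic = synthesize(original, plan, np.random.default_rng(11))

gu = global_utility(original, synthetic)
syn = fit_injury_gee(synthetic)
print(f"pMSE {gu.pmse:.6f}  s-pMSE {gu.s_pmse:.3f}  PO50 {gu.po50:.2f}")
print(f"synthetic GEE estimate {syn.estimate:.3f} (|error| {abs(syn.estimate - ref.estimate):.3f})")
```

prints

```
reference GEE: estimate 1.119, SE 0.242
pMSE 0.000160  s-pMSE 1.017  PO50 0.92
synthetic GEE estimate 0.367 (|error| 0.752)
```

Read: the reference analysis on this fixture finds a 1.12 log-odds
increase in weekly injury risk per ACWR unit. The synthetic panel is
essentially indistinguishable from the original to a propensity model
(pMSE ≈ 1.6·10⁻⁴, s-pMSE ≈ 1, classification under one point better than
chance), yet the refitted injury effect moves by 0.75 — global and
specific utility are different things, which is the point of measuring
both.

The `examples/` scripts walk each capability end to end
(`python examples/01_generate_fixture.py`, …), and a thin CLI mirrors
them (`synthpanel fixture|synthesize|utility|study|report --help`).

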