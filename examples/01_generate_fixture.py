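"""Generate a stand-in athlete-monitoring panel and summarise it.

Builds the default 34-player x 120-week panel (AR(1) weekly loads with
player-level intercepts, uncoupled 4-week chronic load, logistic injury
risk in the acute:chronic workload ratio) and prints its summary moments.
"""

from synthpanel import FixtureConfig, generate_fixture, summarize_fixture, write_panel

panel = generate_fixture(FixtureConfig(seed=1))
summary = summarize_fixture(panel)

write_panel(panel, "fixture_panel.csv")
print(f"wrote fixture_panel.csv with {len(panel)} player-week rows")
for key, val in summary.items():
    print(f"  {key}: {val:.4g}" if isinstance(val, float) else f"  {key}: {val}")
print(
    "\nThe injury rate is the weekly injury probability on ACWR-defined weeks;"
    "\nmean_lag1_autocorr should sit near the configured AR coefficient (0.5)."
)
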