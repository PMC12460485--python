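# Methods

`synthpanel` implements a complete synthetic-data study for longitudinal
athlete-monitoring panels: a seeded generator that stands in for a
confidential 34-player football dataset, sequential CART synthesis under
named predictor-specification conditions, and the utility metrics used to
judge the result. This note records the models, the defaults and why, the
numerical choices, and what the pipeline's passing tests do and do not
show about real data.

## The data model

A panel is a long player-week table with `PlayerID`, `WeekID` (1-based),
`AcuteLoad` (AL, weekly training-load units), `ChronicLoad` (CL) and a
binary `Injury`. CL is the *uncoupled* 4-week block mean of AL: CL at week
*t* is the mean of AL over the 3 weeks strictly before *t*
(`derive_chronic_load(block_weeks=4, uncoupled=True)`). The exact
uncoupled window is genuinely ambiguous in the field's usage; the default
excludes the acute week (so AL/CL shares no term between numerator and
denominator) and is fully configurable (`block_weeks`, `uncoupled`).
Weeks lacking a full window carry missing CL and are excluded downstream
rather than back-filled — fabricating early-season chronic values would
contaminate the injury model's exposure. The acute:chronic workload ratio
ACWR = AL/CL is missing where CL is missing or zero (never infinite: the
regression design matrix must stay finite).

## The stand-in generator

The original dataset is not deposited, so the generator emulates the
minimal structure the downstream analysis exploits:

* **Loads.** AL(p, t) = max(0, mu + u_p + d(p, t)), with player intercept
  u_p ~ N(0, sd_player²) and a stationary AR(1) deviation
  d(p, t) = phi·d(p, t−1) + e(p, t), e ~ N(0, sd_week²). Defaults:
  mu = 2000, sd_player = 300, phi = 0.5, sd_week = 350 — weekly-load
  magnitudes and autocorrelation typical of professional football
  session-RPE-type loads, with between-player spread smaller than
  within-player weekly variation.
* **Injury.** Injury(p, t) ~ Bernoulli(expit(beta0 + beta1·ACWR(p, t) +
  b_p)), with frailty b_p ~ N(0, sd_frailty²) inducing the exchangeable
  within-player correlation the GEE is built for. beta1 defaults to 0.90
  log-odds per ACWR unit — the effect size the reference analysis
  reports — and beta0 = −4.1 gives a marginal rate near 0.04 per
  player-week, a plausible weekly time-loss-injury rate for a football
  squad. Weeks with undefined ACWR are forced injury-free so the injury
  model is estimable on exactly the ACWR-complete rows.
* **Feedback.** Optionally the week after an injury is multiplied by
  `post_injury_multiplier` before downstream weeks are generated
  (default 1 = off, matching the reference analysis, which ignores
  load-reduction after injury).

Randomness is one `SeedSequence` per panel with per-player child streams,
so panels are bit-reproducible and parallelisable. `calibrate_baseline_risk`
bisects beta0 against a simulated marginal rate using common random
numbers (the same replicate seeds at every step), which makes the search
objective strictly monotone; the degenerate constant-risk case has the
closed form logit(rate).

**What the generator does not emulate:** seasonal periodicity and
fixture-congestion structure, injury severity/time-loss spells, shared
team-week schedule shocks, and any injury determinants beyond a clean
ACWR logit. The last omission matters for interpretation (below).

## CART synthesis

Each condition is a visit sequence of variables with methods `fixed`
(copied, usable as predictor — the starred variables), `cart`,
`random_sample`, or `derived` (CL recomputed from synthetic AL). The CART
engine is a greedy binary recursive partition: SSE impurity for
continuous responses, n·Gini for categorical; exhaustive threshold scan
for numeric predictors; categorical predictors (PlayerID, 34 levels) are
ordered per node by mean response and scanned as ordered — the classic
CART shortcut, exact for binary/continuous responses and the only
tractable option at 34 levels. Stopping: `min_leaf` 5, `min_split` 10,
relative impurity-decrease threshold (`complexity`) 1e−8 of the root
impurity, no depth cap — the defaults of the tree-synthesis package
family this reproduces. Ties break toward the lowest predictor index and
smallest threshold, so fits are deterministic. Synthesis routes each row
to its leaf (unseen categories go to the majority side) and draws one
donor uniformly from the leaf's observed response values — *improper*
synthesis; a `proper` flag bootstraps donor pools first.

Model fitting always conditions on observed predictor values; generation
uses original values for starred sources and synthesized columns
otherwise, which is exactly the star convention of the condition table.
Rows whose lag predictors are missing (each player's first weeks) are
excluded from fitting and receive a marginal donor draw from the response
over that same incomplete-row stratum; rows whose original response is
missing stay missing, keeping the original and synthetic missingness
patterns aligned. Starred lag columns remain the original values in the
output (they are fixed variables); only ACWR is recomputed from the
synthetic loads, since a stale ratio would silently feed the original
exposure to the injury regression.

Condition `injury_time_lag` places the injury random sample first in the
visit sequence (a random-sample variable cannot condition on anything),
and the load trees in that condition do not condition on the synthetic
injuries — matching the condition table rather than intuition about
causal direction. Condition `time_lag_injury` is `no_playerid` plus
PlayerID as a predictor; the pathological runtimes reported for it
elsewhere stem from subset-search over high-cardinality factors, which
the mean-ordering shortcut avoids, so this implementation runs it at
ordinary speed (the study harness still carries a per-replicate timeout,
default 60 s, recording timeouts as failures).

## Global utility

Original and synthetic panels are stacked with an indicator (1 =
synthetic, fraction c) and a logistic propensity model is fitted. The
default design takes the non-identifier variables shared by both panels
(WeekID, AL, CL, Injury, plus any lag columns the condition created),
standardises them, and includes all main effects and two-way interactions;
`interaction_order=1` gives a main-effects-only design and
`include_player=True` adds PlayerID dummies. The interaction default is
deliberate: donor resampling against exactly-matched fixed columns leaves
almost no *marginal* signal, and only interaction terms can see joint
mismatches such as a broken AL–CL coupling; it is also the convention of
the propensity-utility literature this follows. Zero-variance columns are
dropped (reducing k); (quasi-)complete separation — standardised slopes
beyond ~15 or near-degenerate fitted probabilities on most rows — falls
back to a ridge-penalised fit and flags the report.

Metrics: pMSE = N⁻¹·Σ(p_i − c)²; s-pMSE = pMSE / [(k−1)(1−c)²c/N], the
expectation of pMSE under a correct-model synthesis null (a permutation
z-score is available behind `standardization="permutation_z"`); PO50 =
percentage of stacked rows correctly classified at the 0.5 threshold
minus 50, ties counted half-correct.

Two null subtleties are worth recording. First, the (k−1)(1−c)²c/N
expectation is derived for proper synthesis from a correctly specified
model; two fully *independent* samples have expectation (k−1)c(1−c)/N —
twice as large at c = 0.5 — and the null-calibration test rescales
accordingly. Second, the expectation assumes iid rows; panels are
clustered (player effects, AR, and CL's overlapping rolling windows), so
a fresh-panel null is heavily over-dispersed. Neither affects the
synthesis use case, where the fixed columns are matched by construction.

## Specific utility

The reference analysis is a binomial GEE of Injury on ACWR with logit
link, exchangeable working correlation, clusters = players, robust SEs
(statsmodels). ACWR enters untransformed by default (`log_acwr` switches
to the log scale). The 95% interval is the Wald interval
estimate ± 1.96·SE. Panels with no injuries, or fewer than two clusters
with events, raise an estimation error; the study harness records such
replicates as failed, never imputes them. Specific utility is the MAE,
across synthetic replicates, of the GEE estimate, SE and p-value against
the reference fit (p-values compared on their raw scale).
Observation-level MAE compares AL/CL row-by-row after aligning on
(player, week), measuring whether individual load trajectories survive;
adjacent-pair consistency applies any metric to replicate pairs
(1,2), (2,3), … to gauge generation-process variability.

## Study harness

`run_study` iterates conditions × scenarios × replicates with child seeds
derived from the master seed by a fixed counter scheme (so runs are
reproducible and parallelisable), aggregates Mean (SD) summaries over
successful replicates, and writes replicate tables, a summary CSV/JSON, a
timing log and one release sheet per cell. The release sheet lists every
variable's method and predictors (with original/synthetic source),
hyperparameters, the CL derivation rule when applicable, achieved
utility, a limitations section, and a machine-readable JSON block that
rebuilds the plan exactly. The desk default is 50 replicates per cell
(the full-scale study design uses 500; it is one config field away).
Problem sizes in the automated checks — 50-replicate global-utility runs,
100-replicate specific-utility and recovery runs, 3 study seeds for the
directional comparisons — were chosen to estimate each mean to well
within its decision band.

## What passing tests show — and what they do not

On the default fixture the pipeline reproduces the expected study
structure: pMSE far below 0.01 for every condition; s-pMSE of order 1;
PO50 under ~2 points; observation-level AL MAE roughly halving from the
`base` condition (~450 units, the no-information level 1.128·sd) to
`time_lag_3wks` (~250); and GEE-estimate MAE near the
E|N(0, √2·SE)| ≈ 0.8·√2·SE magnitude once the fixture is calibrated to
the reference SE.

One directional property of real data does *not* reproduce: in this
generator the injury process is purely ACWR-causal, so lag-conditioned
syntheses — which track original load trajectories closely — also
preserve the ACWR–injury association, and their GEE-estimate MAE is not
systematically worse than `base`. In observational data the association
evidently rides on structure that donor swapping destroys, so
specific utility degrades as temporal predictors are added while
trajectory fidelity improves. The generator's clean injury model is a
deliberate simplification; conclusions about that trade-off direction on
real data should not be drawn from this fixture.

## Known limitations

* Binary responses only for categorical CART (multiclass level-ordering
  falls back to mean class code; the panel never needs it).
* No surrogate splits; predictors must be complete at prediction time.
* The GEE model is the single-predictor form of the reference analysis;
  additional covariates are out of scope.
* Disclosure-risk quantification is out of scope; the release sheet's
  limitations section is documentation, not a privacy audit.
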