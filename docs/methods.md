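# Methods

## Scope and model

The package models a 30-day survival study of male CD2F1 mice after single
total-body γ-irradiation (6–14 Gy at 0.6 Gy/min), in which humane-endpoint
euthanasia under the Mouse Intervention Scoring System (MISS) replaces death
as the endpoint. Four computational pieces interlock:

1. **Scoring** (`miss_ars.scoring`) — the MISS sheets as data-driven decision
   rules. A score sheet is a set of criteria, each with ordered levels
   carrying integer points; the cumulative total maps into grading bands
   (normal / morbid / moribund) and certain levels carry flags that act
   regardless of total (`notify`, and the *definitive*
   `euthanize_immediate` levels for which death is imminent).
2. **Cohort data model** (`miss_ars.cohort`) — per-animal longitudinal
   records with two distinct baselines, following the study's anchoring:
   weight loss is relative to the last pre-irradiation weight (day ≤ 0),
   temperature change relative to the day −3 transponder reading.
3. **Simulator** (`miss_ars.simulate`) — a seeded generator of synthetic
   cohorts under the published study conditions (no raw data were deposited).
4. **Survival & replay** (`miss_ars.survival`, `miss_ars.endpoints`) —
   grouped probit dose–lethality estimation, 30-day step survival curves, and
   replay of observation schedules and euthanasia policies against a cohort
   with known ground truth.

## Score-sheet encodings and boundary decisions

The three shipped YAML sheets encode the printed tables. Decisions taken
where the printed sheets are ambiguous:

* **Weight bands.** The printed bands ("20–25%", "26–30%", "31–35%", "≥35%")
  leave gaps at (25, 26) and (30, 31) and touch at 35. Percent loss is
  continuous, so the bands are resolved as half-open intervals
  [20, 26) → 3, [26, 31) → 6, [31, 35) → 9, [35, ∞) → 12, with ≥35 winning
  at its boundary because it is the definitive level.
* **MISS 2 grading.** 0 normal, 1–7 morbid, ≥8 moribund, with the euthanasia
  cut-off at 8 — the two printed statements of this rule agree on the action
  boundary.
* **MISS 1 grading.** Never printed separately (its sheet defers to the
  recommended sheet), so the shipped MISS 1 config reuses the MISS 3 bands.
  This is a packaging choice, not an assertion about the original sheet.
* **Missing criteria are errors**, not implicit zeros: a silent zero would
  mask a missed assessment.

## Simulator

Each animal draws all latent parameters from a substream seeded by
`[global_seed, crc32(animal_id)]`, so adding animals or groups never
reshuffles existing trajectories, and a fixed configuration yields a
bit-identical cohort. Defaults encode the study conditions:

* design 20/20/20/20/26/26 (control, sham, 6, 8, 10, 14 Gy); baseline weight
  ~ N(28.4, 1.4²) g; baseline temperature ~ N(35, 1.5²) °C (the published
  "±3 °C" band is read as an approximate 2σ range);
* per-animal Bernoulli mortality with p = 0, 0, 0, 4/20, 25/26, 1 by group;
* latent death day ~ truncated normal on (0.5, 30]: mean 12.5 (sd 2.0) at
  8 Gy, 14.0 (sd 2.0) at 10 Gy, 8.0 (sd 1.2) at 14 Gy.

**Calibration note.** For 10 Gy the published summaries — mean death day
13.5, mean 20%-loss crossing day 10, and +5 days mean residual survival —
are not jointly satisfiable (10 + 5 ≠ 13.5; they average different
sub-cohorts). The default profile splits the difference once: latent death
mean 14.0 with the 20% crossing ≈ 4.9 days before death, giving pooled means
≈ 13.9–14.2 / 9.3–9.6 / 4.6–4.8, each within ±1 day of the respective
published figure. This calibration was fixed when the profiles were written
and is not a tuning knob.

**Weight.** Non-survivors hold baseline until an onset `weight_onset_lead`
days before latent death, then lose weight linearly (3.3 %/day at 10 Gy,
13.3 %/day at 14 Gy, matching the faster gastrointestinal-phase wasting) up
to a cap (37% / 40%); this reproduces the ordered 20% → 25% → 30% crossings
and their shrinking residual-survival windows. Survivors dip to a drawn
nadir (e.g. ~31% for the rare 10 Gy survivor, mirroring the reported
over-30% survivor; ~12% at 8 Gy so that roughly one surviving 8 Gy animal
crosses 20%) and partially recover by day 30. Multiplicative daily noise
(σ = 1% of baseline) represents scale and hydration variability. Weight is
sampled at every scheduled check (the study weighed daily plus at
euthanasia; per-check sampling is a simplification that keeps
threshold-crossing estimates on the check grid).

**Temperature.** Baseline-centred noise (σ = 1 °C) until
`temp_collapse_lead` days before death, then a linear fall of
`temp_collapse_depth`: 7 °C over the final 2 days at 8–10 Gy (35 → 28 °C, a
20% drop) and 13 °C over the final 4 days at 14 Gy (35 → 22 °C). The source
prints "(40%)" for the 35 → 22 °C drop although the arithmetic gives ≈37%;
`pct_temp_change` returns the arithmetic value. Survivors never collapse.
Readings are clipped to the 15.5–41.5 °C transponder plausibility range.

**Clinical signs.** Escalation is keyed to days-until-death (dose sets the
pace through the death-day distribution, not the stage map): mild signs
within ~6 days of death, a morbid phase ~2 days before the moribund window,
a moribund window of U(0.8, 1.5) days in which a MISS 3 total reaches ≥12,
and a terminal agonal phase (definitive signs) in the final ~2 h. A drawn
**sudden-death** fraction (default 7% of non-survivors, matching the
reported found-dead rate) skips the morbid/moribund escalation entirely and
shows only an ~1 h agonal phase; these animals also cap weight loss at 33%,
below the definitive ≥35% band — otherwise the weight criterion would catch
every would-be sudden death at lethal doses and the found-dead channel could
never occur. Under continuous observation even sudden deaths are caught in
the agonal hour (found-dead count 0); under realistic schedules most sudden
deaths fall between checks, so the expected found-dead fraction of
non-survivors is ≈ 6–7%, with wide per-cohort binomial scatter (the shipped
default-seed cohort draws a single sudden death, 1.8%).

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: mechanistic radiobiology (hematopoietic
kinetics, dose-rate effects), inter-observer scoring disagreement,
transponder misreads (missing temperatures are permitted by the data model
but not generated by default), measurement-error outliers (an injection knob
exists, default off), and any correlation between weight, temperature and
sign trajectories beyond their common anchoring to the latent death day.

## Probit dose–lethality

Grouped 30-day mortality (dose, n, deaths) is fit by maximum likelihood to
P(death | d) = Φ((d − μ)/σ). Optimization is Newton-type with line search on
(μ, log σ) (scipy's Newton-CG with an analytic gradient, plus a BFGS polish)
from a probit-transform moment start; the fit is checked in the tests
against an independent pure grid-refinement oracle (≤1e-6 in log-likelihood)
and against a statsmodels GLM probit. All-0 and all-n dose levels are
tolerated; a *perfect* dose step (complete separation) has no finite MLE and
returns `converged=False` with the bracketing doses rather than a silently
huge slope. LDp = μ + σΦ⁻¹(p); confidence limits are delta-method from the
observed information (the source prints an LD50 interval without naming a
method; the method name travels in `LDEstimate.method` so alternatives can
be compared). Euthanized and found-dead animals both count as deaths, since
the score system is an explicit surrogate for death as the endpoint. The
source also prints an LD50 of 8.58 [7.97–8.97] Gy alongside 8.6 Gy; the
grouped-count fit here gives 8.65 [8.26–9.04] Gy, and whether the printed
pair came from different fits is unknowable without the raw data.

## Schedule replay

Checks run at 06:00 and 19:00 (11 h overnight gap), four times daily in the
critical window (days 3–14 for groups ≥10 Gy) and for any animal currently
grading morbid; a morbid animal with respiratory signs is rechecked after 30
minutes. At each check the policy is evaluated on the animal's current state
(sign levels, plus the weight criterion derived from percent loss); a firing
policy euthanizes at that check, and a latent death inside an inter-check
interval surfaces as found dead at the next check. Euthanasia by a single
definitive criterion is tallied separately (the recommended sheet says to
consider such cases as found dead), and both tallies are reported. Premature
euthanasias are euthanized animals whose latent fate was survival — the
failure mode of the bare 20% weight cut-off, which the replay comparison
quantifies.

## Problem sizes and numerical choices

Calibration statistics pool 20 replicate cohorts (the package's standard
replication depth for stochastic summaries); probit parameter recovery uses
50 replicates of a 6-dose × 26-animal design. Tolerances asserted in tests
are ±1 day on pooled trajectory means, exact binomial 95% bands on group
mortality, and printed-precision ±0.15 Gy on LD estimates. Ties at grading
boundaries resolve by the half-open band convention above; the replay clamps
fate days to the 30-day window end.

## Known limitations

* The sign-escalation stage map is deliberately coarse (five stages); the
  published per-criterion mean maximum scores depend on unpublished raw data
  and are not reproduction targets.
* The found-dead fraction on a single 132-animal cohort has large binomial
  scatter; only its replicate-averaged behaviour is calibrated.
* MISS 2 scoring of simulated cohorts uses a stage-to-level mapping specific
  to that sheet's ontology; recorded (CSV) cohorts carry MISS 3-style level
  indices and can be replayed under MISS 1/3 policies only.
* The delta-method CI is symmetric in dose space; the printed asymmetric
  interval cannot be matched without knowing the original method.
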