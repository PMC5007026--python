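# miss-ars

Humane-endpoint scoring, synthetic cohort simulation, and probit
dose–lethality estimation for mouse total-body-irradiation (TBI) survival
studies.

## The problem

Thirty-day survival studies of acute radiation syndrome (ARS) historically
used death as the endpoint. A humane alternative scores clinical signs —
appearance, respiratory rate, general and provoked behavior, percent
body-weight loss — on an interventional score sheet and euthanizes animals
that reach a moribund cut-off, so that as few animals as possible die
unobserved between checks ("found dead"). This package implements the Mouse
Intervention Scoring System (MISS 1/2/3) as an executable decision engine
and asks the operational questions around it: given an observation schedule
and a euthanasia policy, who is caught, who is found dead, and who is
euthanized prematurely?

For whom: veterinary and radiobiology study staff evaluating endpoint
criteria, and modellers who need a reproducible synthetic ARS cohort to test
such policies against.

## What's inside

| piece | module | core idea |
|---|---|---|
| MISS score sheets | `miss_ars.scoring` | data-driven criteria/levels/points, grading bands, definitive (euthanize-immediately) flags; shipped YAML configs for MISS 1/2/3 |
| cohort data model | `miss_ars.cohort` | per-animal longitudinal records, % weight loss from the pre-irradiation baseline, % temperature change from day −3, CSV round trip |
| cohort simulator | `miss_ars.simulate` | seeded generator matching the study design (132 mice; 6–14 Gy), mortality fractions 0/20, 4/20, 25/26, 26/26, death-day and weight/temperature trajectory structure |
| dose–lethality | `miss_ars.survival` | probit MLE on grouped 30-day mortality: P(death\|d) = Φ((d−μ)/σ); LDp = μ + σΦ⁻¹(p) with delta-method CIs; step survival curves |
| schedule replay | `miss_ars.endpoints` | replay checks (2/day, 4/day in the critical window) and policies against latent ground truth; found-dead, premature-euthanasia and suffering-window metrics |
| CLI | `miss_ars.cli` | `miss simulate / validate / score / ld / replay / compare / reproduce` |

The numbered scripts under `analysis/` run the pipeline as a narrative
(simulate → trajectories → probit → policy replay) and write their tables
under `results/`.

## Worked example

```python
from miss_ars import builtin_table, score_observation, weight_loss_level
from miss_ars import fit_probit, ld_estimate

# Score one animal under the recommended sheet (MISS 3)
miss3 = builtin_table("MISS3")
levels = {
    "appearance": "Hunched and/or fluffed",        # 1 point
    "respiratory_rate": 0,
    "general_behavior": "Decreased mobility",      # 2 points
    "provoked_behavior": "Subdued even to stimulation (moves away slowly)",  # 3 points
    "weight_loss": weight_loss_level(27.0),        # 26-30% band -> 6 points
}
res = score_observation(miss3, levels)
print(res.total, res.grade, res.action)
# 12 moribund euthanize

# Probit LD estimates from the grouped 30-day mortality counts
fit = fit_probit([(6, 20, 0), (8, 20, 4), (10, 26, 25), (14, 26, 26)])
for p in (0.3, 0.5, 0.7):
    ld = ld_estimate(fit, p)
    print(f"LD{int(p*100)}/30 = {ld.dose:.2f} Gy  [{ld.ci_low:.2f}-{ld.ci_high:.2f}]")
# LD30/30 = 8.25 Gy  [7.82-8.67]
# LD50/30 = 8.65 Gy  [8.26-9.04]
# LD70/30 = 9.05 Gy  [8.62-9.47]
```

A cumulative score of 12 grades moribund and triggers euthanasia; the LD50
of ≈8.6 Gy is the dose at which half the animals die within 30 days.

From the shell, the same pipeline end to end:

```bash
miss reproduce --seed 20160831 --out scratch/report
miss compare --seed 20160831 --policy MISS3 --policy weight-20 --out scratch/compare.csv
```

The comparison shows the score-based policy's advantage over a bare 20%
weight-loss cut-off: zero premature euthanasias versus two on the same
simulated cohort (20% loss is survivable for some mice for many days).

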