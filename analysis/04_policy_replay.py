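#!/usr/bin/env python
"""Replay euthanasia policies against the simulated study.

Compares the recommended MISS 3 score sheet, the simplified MISS 2 study
sheet, and a bare 20% weight-loss cut-off on the same simulated cohort and
observation schedule (2 checks/day, 4/day in the critical window).  Writes
``results/policy_comparison.csv``.
"""

from pathlib import Path

from miss_ars import (
    DEFAULT_SEED,
    ObservationSchedule,
    Policy,
    builtin_table,
    compare_policies,
    default_config,
    simulate_cohort,
    threshold_ppv,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = simulate_cohort(default_config(seed=DEFAULT_SEED))
    policies = [
        Policy(name="MISS3", table=builtin_table("MISS3")),
        Policy(name="MISS2", table=builtin_table("MISS2")),
        Policy(name="weight-20pct", weight_cutoff_pct=20.0),
    ]
    table = compare_policies(sim, ObservationSchedule(), policies)
    table.to_csv(RESULTS / "policy_comparison.csv", index=False)
    cols = [
        "policy", "euthanized", "found_dead", "found_dead_fraction_of_nonsurvivors",
        "premature_euthanasia_count", "mean_suffering_window_days",
    ]
    print(table[cols].round(3).to_string(index=False))

    for thr in (20.0, 25.0, 30.0):
        ppv = threshold_ppv(sim, thr)
        print(f"PPV of {thr:.0f}% weight loss for 30-day death: {ppv:.2f}")


if __name__ == "__main__":
    main()
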