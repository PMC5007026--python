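"""Observation-schedule replay and welfare metrics.

The humane-endpoint question is operational: given a monitoring schedule
(twice daily outside the critical ARS window, up to four checks per day inside
it) and a euthanasia policy (a MISS score sheet and/or a standalone
weight-loss cut-off), which animals are caught moribund and euthanized, and
which die unobserved between checks ("found dead")?  :func:`replay` runs a
policy against a cohort that carries latent (ground-truth) death days and
tallies the welfare metrics: the found-dead fraction of non-survivors,
premature euthanasias (animals euthanized that would have survived), and the
suffering window between euthanasia and the latent death it pre-empted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .scoring import ScoreTable, score_observation, weight_loss_level

__all__ = [
    "ObservationSchedule",
    "Policy",
    "ReplayOutcome",
    "replay",
    "threshold_ppv",
    "compare_policies",
]

_AM, _PM = 6.0 / 24.0, 19.0 / 24.0


@dataclass(frozen=True)
class ObservationSchedule:
    """Daily check times (fractions of a day) and escalation rules.

    Baseline: two checks, 06:00 and 19:00 (11 h overnight gap).  Critical
    window: four evenly spaced checks 06:00-19:00, active on
    ``critical_days`` for dose groups at or above ``critical_min_dose_Gy``
    and for any animal currently grading morbid or worse.  A morbid animal
    with respiratory signs is rechecked after ``resp_recheck_h`` hours.
    """

    baseline_times: tuple[float, ...] = (_AM, _PM)
    critical_times: tuple[float, ...] = (
        _AM,
        _AM + (_PM - _AM) / 3.0,
        _AM + 2.0 * (_PM - _AM) / 3.0,
        _PM,
    )
    critical_days: tuple[int, int] = (3, 14)
    critical_min_dose_Gy: float = 10.0
    resp_recheck_h: float = 0.5

    def __post_init__(self) -> None:
        for name, times in (("baseline", self.baseline_times), ("critical", self.critical_times)):
            if len(times) == 0:
                raise ValueError(f"schedule with zero {name} checks")
            if any(not 0.0 <= t < 1.0 for t in times):
                raise ValueError(f"{name} check times must lie within one day")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name} check times must strictly increase")

    @classmethod
    def continuous(cls, per_day: int = 48) -> "ObservationSchedule":
        """A schedule with ``per_day`` evenly spaced checks (no overnight gap)."""
        times = tuple(i / per_day for i in range(per_day))
        return cls(baseline_times=times, critical_times=times)

    def checks_for(self, day: int, dose_Gy: Optional[float], escalated: bool) -> list[float]:
        """Absolute check times for one study day."""
        critical = escalated or (
            dose_Gy is not None
            and dose_Gy >= self.critical_min_dose_Gy
            and self.critical_days[0] <= day <= self.critical_days[1]
        )
        times = self.critical_times if critical else self.baseline_times
        return [day + t for t in times]

    @property
    def overnight_gap_h(self) -> float:
        return 24.0 * (1.0 + self.baseline_times[0] - self.baseline_times[-1])


@dataclass(frozen=True)
class Policy:
    """A euthanasia policy: a MISS table, a weight cut-off, or both."""

    name: str
    table: Optional[ScoreTable] = None
    weight_cutoff_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.table is None and self.weight_cutoff_pct is None:
            raise ValueError(f"policy {self.name!r}: no rule active")


@dataclass
class ReplayOutcome:
    """Per-animal fates and welfare metrics from one policy replay."""

    policy: str
    fates: pd.DataFrame  # id, group, fate, fate_day, definitive, latent_death_day

    @property
    def n(self) -> int:
        return len(self.fates)

    def metrics(self) -> dict:
        f = self.fates
        survived = int((f["fate"] == "survived").sum())
        euthanized = int((f["fate"] == "euthanized").sum())
        found_dead = int((f["fate"] == "found_dead").sum())
        assert survived + euthanized + found_dead == self.n
        nonsurv = euthanized + found_dead
        eu = f[f["fate"] == "euthanized"]
        premature = int(eu["latent_death_day"].isna().sum())
        correct = eu.dropna(subset=["latent_death_day"])
        window = (
            float((correct["latent_death_day"] - correct["fate_day"]).mean())
            if len(correct)
            else math.nan
        )
        definitive = int(f["definitive"].sum())
        return {
            "policy": self.policy,
            "n": self.n,
            "survived": survived,
            "euthanized": euthanized,
            "found_dead": found_dead,
            "nonsurvivors": nonsurv,
            "found_dead_fraction_of_nonsurvivors": (
                found_dead / nonsurv if nonsurv else math.nan
            ),
            # Single-criterion-12 euthanasias are tallied separately; the
            # recommended sheet asks that these be considered as found dead.
            "euthanized_by_definitive": definitive,
            "found_dead_fraction_incl_definitive": (
                (found_dead + definitive) / nonsurv if nonsurv else math.nan
            ),
            "premature_euthanasia_count": premature,
            "mean_suffering_window_days": window,
        }


def _scheme_for(table: ScoreTable) -> str:
    return "MISS2" if table.name.upper() == "MISS2" else "MISS3"


def _replay_animal(animal, schedule: ObservationSchedule, policy: Policy):
    death = animal.death_day
    scheme = _scheme_for(policy.table) if policy.table is not None else None
    escalated = False
    for day in range(0, 31):
        queue = list(schedule.checks_for(day, animal.dose_Gy, escalated))
        k = 0
        while k < len(queue):
            t = queue[k]
            k += 1
            if death is not None and death <= t:
                return "found_dead", min(t, 30.0), False
            loss = animal.pct_weight_loss_at(t)
            if policy.table is not None:
                levels = dict(animal.sign_levels_at(t, scheme))
                if policy.table.has_weight_criterion:
                    levels["weight_loss"] = weight_loss_level(loss)
                res = score_observation(policy.table, levels)
                if res.action == "euthanize":
                    return "euthanized", min(t, 30.0), res.triggered_by_definitive
                escalated = res.grade in ("morbid", "moribund")
                if (
                    res.grade == "morbid"
                    and animal.sign_levels_at(t, "MISS3").get("respiratory_rate", 0) > 0
                ):
                    recheck = t + schedule.resp_recheck_h / 24.0
                    if recheck < day + 1 and (k == len(queue) or recheck < queue[k]):
                        queue.insert(k, recheck)
            if policy.weight_cutoff_pct is not None and loss is not None:
                if loss >= policy.weight_cutoff_pct:
                    return "euthanized", min(t, 30.0), False
    return "survived", None, False


def replay(simcohort, schedule: ObservationSchedule, policy: Policy) -> ReplayOutcome:
    """Replay ``schedule`` + ``policy`` against a cohort with latent truth.

    At each scheduled check the animal's state is scored; if the policy fires
    the animal is euthanized at that check; a latent death inside an
    inter-check interval surfaces as found dead at the next check.  The replay
    is deterministic given the cohort.
    """
    rows = []
    for an in simcohort.animals:
        fate, day, definitive = _replay_animal(an, schedule, policy)
        rows.append(
            {
                "id": an.animal_id,
                "group": an.group,
                "fate": fate,
                "fate_day": day,
                "definitive": bool(definitive),
                "latent_death_day": an.death_day if an.death_day is not None else math.nan,
            }
        )
    return ReplayOutcome(policy=policy.name, fates=pd.DataFrame(rows))


def threshold_ppv(simcohort, threshold: float, horizon: Optional[float] = None) -> Optional[float]:
    """Positive predictive value of a weight-loss threshold for death.

    Fraction of animals whose observed weight loss ever reaches ``threshold``
    percent that subsequently die within the study (or within ``horizon`` days
    of crossing, when finite).  Returns ``None`` ("undefined") when no animal
    crosses.
    """
    crossers = 0
    deaths = 0
    for rec, an in zip(simcohort.study.animals, simcohort.animals):
        base = rec.baseline_weight_g
        cross_t = None
        for obs in rec.observations:
            if obs.weight_g is None:
                continue
            if 100.0 * (base - obs.weight_g) / base >= threshold:
                cross_t = obs.time
                break
        if cross_t is None:
            continue
        crossers += 1
        if an.death_day is not None and (
            horizon is None or an.death_day <= cross_t + horizon
        ):
            deaths += 1
    if crossers == 0:
        return None
    return deaths / crossers


def compare_policies(
    simcohort, schedule: ObservationSchedule, policies: Sequence[Policy]
) -> pd.DataFrame:
    """One metrics row per policy on the same cohort and schedule.

    Sorted by found-dead fraction of non-survivors (undefined last).
    """
    if not policies:
        raise ValueError("at least one policy required")
    rows = [replay(simcohort, schedule, p).metrics() for p in policies]
    df = pd.DataFrame(rows)
    return df.sort_values(
        "found_dead_fraction_of_nonsurvivors", na_position="last", kind="stable"
    ).reset_index(drop=True)
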