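"""Longitudinal individual-animal data model and delimited-text I/O.

An animal's history is a time-ordered list of :class:`Observation` records
(clinical-sign levels plus optional weight and microchip temperature), anchored
to two baselines measured before irradiation: the last pre-irradiation body
weight (day <= 0) and the day −3 transponder temperature.  Study time is in
decimal days with irradiation at day 0; the two daily health checks map to
06:00 (+0.25) and 19:00 (+0.79).

On-disk format: a cohort directory holds ``animals.csv`` (one manifest row per
animal) and ``observations.csv`` (long format, one row per observation and
criterion).  Lines starting with ``#`` are metadata headers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "Observation",
    "AnimalRecord",
    "CohortStudy",
    "CohortError",
    "GROUPS",
    "pct_weight_loss",
    "pct_temp_change",
    "read_cohort",
    "write_cohort",
]

log = logging.getLogger(__name__)

#: Canonical group labels in study order (doses in Gy as bare numbers).
GROUPS = ("control", "sham", "6", "8", "10", "14")

TIME_MIN, TIME_MAX = -14.0, 30.0
TEMP_MIN, TEMP_MAX = 15.0, 42.0
FATES = ("survived", "euthanized", "found_dead")


class CohortError(ValueError):
    """Invalid cohort data (bad row, duplicate ID, implausible measurement)."""


@dataclass(frozen=True)
class Observation:
    """One clinical assessment of one animal at one check."""

    animal_id: str
    time: float
    sign_levels: dict[str, int] = field(default_factory=dict)
    weight_g: Optional[float] = None
    temp_C: Optional[float] = None
    free_text: str = ""

    def __post_init__(self) -> None:
        if not TIME_MIN <= self.time <= TIME_MAX:
            raise CohortError(
                f"{self.animal_id}: time {self.time} outside [{TIME_MIN}, {TIME_MAX}]"
            )
        if self.weight_g is not None and not self.weight_g > 0:
            raise CohortError(f"{self.animal_id}: weight {self.weight_g} g not > 0")
        if self.temp_C is not None and not TEMP_MIN <= self.temp_C <= TEMP_MAX:
            raise CohortError(
                f"{self.animal_id}: temperature {self.temp_C} degC outside "
                f"plausibility window [{TEMP_MIN}, {TEMP_MAX}]"
            )


@dataclass
class AnimalRecord:
    """An animal's full longitudinal history, baselines, and fate."""

    animal_id: str
    group: str
    baseline_weight_g: Optional[float] = None
    baseline_temp_C: Optional[float] = None
    observations: list[Observation] = field(default_factory=list)
    fate: Optional[str] = None  # None = not yet adjudicated
    fate_day: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fate is not None and self.fate not in FATES:
            raise CohortError(f"{self.animal_id}: unknown fate {self.fate!r}")
        died = self.fate in ("euthanized", "found_dead")
        if died and self.fate_day is None:
            raise CohortError(f"{self.animal_id}: fate {self.fate} requires fate_day")
        if not died and self.fate_day is not None:
            raise CohortError(
                f"{self.animal_id}: fate_day given but fate is {self.fate!r}"
            )
        if self.fate_day is not None and self.fate_day > TIME_MAX:
            raise CohortError(f"{self.animal_id}: fate_day {self.fate_day} > {TIME_MAX}")
        times = [o.time for o in self.observations]
        if times != sorted(times):
            log.warning("%s: observations not time-sorted; sorting", self.animal_id)
            self.observations.sort(key=lambda o: o.time)

    @property
    def dose_Gy(self) -> Optional[float]:
        if self.group in ("control", "sham"):
            return None
        return float(self.group)

    def died(self) -> bool:
        return self.fate in ("euthanized", "found_dead")


@dataclass
class CohortStudy:
    """Dose-group-structured collection of animal records over 30 days."""

    animals: list[AnimalRecord]
    design: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate animal ids: {dupes}")
        if self.design:
            counts: dict[str, int] = {}
            for a in self.animals:
                counts[a.group] = counts.get(a.group, 0) + 1
            if counts != dict(self.design):
                raise CohortError(
                    f"group counts {counts} do not match design {dict(self.design)}"
                )

    def group(self, label: str) -> list[AnimalRecord]:
        out = [a for a in self.animals if a.group == str(label)]
        if not out:
            raise CohortError(f"no animals in group {label!r}")
        return out

    def animal(self, animal_id: str) -> AnimalRecord:
        for a in self.animals:
            if a.animal_id == animal_id:
                return a
        raise CohortError(f"no animal {animal_id!r}")


def _latest_at(record: AnimalRecord, time: float, attr: str) -> Optional[float]:
    # Only observations at <= time are consulted: no look-ahead.
    value = None
    for obs in record.observations:
        if obs.time > time:
            break
        v = getattr(obs, attr)
        if v is not None:
            value = v
    return value


def pct_weight_loss(record: AnimalRecord, time: float) -> Optional[float]:
    """Percent body-weight loss from baseline at the latest weighing <= ``time``.

    Returns ``None`` ("no data") when the animal has not been weighed yet —
    deliberately distinct from 0% loss.  Negative values mean gain.
    """
    if record.baseline_weight_g is None:
        raise CohortError(f"{record.animal_id}: no baseline weight")
    current = _latest_at(record, time, "weight_g")
    if current is None:
        return None
    base = record.baseline_weight_g
    return 100.0 * (base - current) / base


def pct_temp_change(record: AnimalRecord, time: float) -> Optional[float]:
    """Percent temperature drop from the day −3 baseline (positive = drop)."""
    if record.baseline_temp_C is None:
        raise CohortError(f"{record.animal_id}: no baseline temperature")
    current = _latest_at(record, time, "temp_C")
    if current is None:
        return None
    base = record.baseline_temp_C
    return 100.0 * (base - current) / base


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _meta_header(meta: Optional[dict]) -> str:
    import miss_ars

    items = {"version": miss_ars.__version__, **(meta or {})}
    return "# miss-ars " + " ".join(f"{k}={v}" for k, v in items.items()) + "\n"


def write_cohort(study: CohortStudy, path, meta: Optional[dict] = None) -> None:
    """Write ``animals.csv`` and ``observations.csv`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arow = []
    for a in study.animals:
        arow.append(
            {
                "id": a.animal_id,
                "group": a.group,
                "baseline_weight_g": a.baseline_weight_g,
                "baseline_temp_C": a.baseline_temp_C,
                "fate": a.fate if a.fate is not None else "",
                "fate_day": a.fate_day,
            }
        )
    orow = []
    for a in study.animals:
        for obs in a.observations:
            crits = sorted(obs.sign_levels) or [""]
            for j, crit in enumerate(crits):
                orow.append(
                    {
                        "id": a.animal_id,
                        "time": obs.time,
                        "criterion": crit,
                        "level": obs.sign_levels.get(crit, ""),
                        "weight_g": obs.weight_g if j == 0 else None,
                        "temp_C": obs.temp_C if j == 0 else None,
                        "notes": obs.free_text if j == 0 else "",
                    }
                )
    header = _meta_header(meta)
    for name, rows, cols in (
        ("animals.csv", arow, ["id", "group", "baseline_weight_g", "baseline_temp_C", "fate", "fate_day"]),
        ("observations.csv", orow, ["id", "time", "criterion", "level", "weight_g", "temp_C", "notes"]),
    ):
        df = pd.DataFrame(rows, columns=cols)
        with open(path / name, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)


def _opt_float(v) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_cohort(path) -> CohortStudy:
    """Read a cohort directory written by :func:`write_cohort`.

    Malformed rows are rejected with their (1-based, header-inclusive) line
    number; duplicate animal IDs are an error; per-animal observation streams
    arriving unsorted are sorted with a logged warning.
    """
    path = Path(path)
    adf = pd.read_csv(path / "animals.csv", comment="#", dtype={"id": str, "group": str})
    records: dict[str, AnimalRecord] = {}
    for i, row in adf.iterrows():
        fate = row.get("fate")
        fate = None if (not isinstance(fate, str) or fate == "") else fate
        rec = AnimalRecord(
            animal_id=str(row["id"]),
            group=str(row["group"]),
            baseline_weight_g=_opt_float(row.get("baseline_weight_g")),
            baseline_temp_C=_opt_float(row.get("baseline_temp_C")),
            fate=fate,
            fate_day=_opt_float(row.get("fate_day")),
        )
        if rec.animal_id in records:
            raise CohortError(f"animals.csv: duplicate animal id {rec.animal_id!r}")
        records[rec.animal_id] = rec

    opath = path / "observations.csv"
    odf = pd.read_csv(opath, comment="#", dtype={"id": str, "criterion": str})
    # Map frame index -> file line number for error messages.
    with open(opath, "r", encoding="utf-8") as fh:
        n_comment = 0
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    groups: dict[tuple[str, float], dict] = {}
    lineno_of: dict[tuple[str, float], int] = {}
    for i, row in odf.iterrows():
        lineno = int(i) + n_comment + 2  # +1 header, +1 one-based
        aid = str(row["id"])
        if aid not in records:
            raise CohortError(f"observations.csv line {lineno}: unknown animal {aid!r}")
        try:
            t = float(row["time"])
        except (TypeError, ValueError):
            raise CohortError(f"observations.csv line {lineno}: bad time {row['time']!r}")
        key = (aid, t)
        slot = groups.setdefault(
            key, {"signs": {}, "weight_g": None, "temp_C": None, "notes": ""}
        )
        lineno_of.setdefault(key, lineno)
        crit = row.get("criterion")
        if isinstance(crit, str) and crit:
            try:
                slot["signs"][crit] = int(row["level"])
            except (TypeError, ValueError):
                raise CohortError(
                    f"observations.csv line {lineno}: bad level {row['level']!r} "
                    f"for criterion {crit!r}"
                )
        for col in ("weight_g", "temp_C"):
            v = _opt_float(row.get(col))
            if v is not None:
                slot[col] = v
        notes = row.get("notes")
        if isinstance(notes, str) and notes:
            slot["notes"] = notes
    for (aid, t), slot in groups.items():
        try:
            obs = Observation(
                animal_id=aid,
                time=t,
                sign_levels=slot["signs"],
                weight_g=slot["weight_g"],
                temp_C=slot["temp_C"],
                free_text=slot["notes"],
            )
        except CohortError as exc:
            raise CohortError(
                f"observations.csv line {lineno_of[(aid, t)]}: {exc}"
            ) from exc
        records[aid].observations.append(obs)
    animals = []
    for rec in records.values():
        # re-run sorting/validation now that observations are attached
        animals.append(replace(rec, observations=sorted(rec.observations, key=lambda o: o.time)))
    design: dict[str, int] = {}
    for a in animals:
        design[a.group] = design.get(a.group, 0) + 1
    return CohortStudy(animals=animals, design=design)
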