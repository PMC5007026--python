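"""Data-driven clinical-sign scoring for the Mouse Intervention Scoring System.

The Mouse Intervention Scoring System (MISS) assigns integer point values to
ordered levels of clinical signs (appearance, respiratory rate, general and
provoked behavior, percent body-weight loss).  The cumulative total maps into
grading bands (``normal`` / ``morbid`` / ``moribund``); certain severe levels
carry flags that act regardless of the total: ``notify`` (escalate to the
responsible person immediately) and ``euthanize_immediate`` (a *definitive
criterion* — death is imminent and the animal must be euthanized).

Three score-sheet versions ship with the package as editable YAML configs
(``MISS1``, ``MISS2``, ``MISS3``); :func:`load_score_table` validates any
user-supplied variant against the same structural rules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Union

import yaml

__all__ = [
    "Criterion",
    "Level",
    "GradeBand",
    "ScoreTable",
    "ScoreResult",
    "ScoreTableError",
    "ScoringError",
    "load_score_table",
    "builtin_table",
    "score_observation",
    "weight_loss_level",
    "max_total_score",
    "ACTIONS",
]

FLAGS = ("none", "notify", "euthanize_immediate")
#: Escalation actions, ordered from least to most severe.
ACTIONS = ("none", "increase_monitoring", "notify", "euthanize")

#: Weight-loss bands for the MISS3 weight criterion, resolved to continuous
#: half-open intervals: <20 -> 0, [20,26) -> 3, [26,31) -> 6, [31,35) -> 9,
#: >=35 -> 12 (definitive).  The printed integer band labels are treated as
#: labels on a continuous scale; >=35 wins at its boundary because it is the
#: definitive level.
WEIGHT_BAND_EDGES = (20.0, 26.0, 31.0, 35.0)


class ScoreTableError(ValueError):
    """A score-table config violates the structural rules."""


class ScoringError(ValueError):
    """An observation cannot be scored against the requested table."""


@dataclass(frozen=True)
class Level:
    description: str
    points: int
    flag: str = "none"


@dataclass(frozen=True)
class Criterion:
    """One scored clinical criterion with its ordered severity levels."""

    name: str
    levels: tuple[Level, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ScoreTableError(f"criterion {self.name!r}: no levels")
        if self.levels[0].points != 0:
            raise ScoreTableError(
                f"criterion {self.name!r}: level 0 must score 0 points"
            )
        pts = [lv.points for lv in self.levels]
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ScoreTableError(
                f"criterion {self.name!r}: points must strictly increase "
                f"across levels (got {pts})"
            )
        for lv in self.levels:
            if lv.flag not in FLAGS:
                raise ScoreTableError(
                    f"criterion {self.name!r}: unknown flag {lv.flag!r}"
                )
        flagged = [i for i, lv in enumerate(self.levels) if lv.flag != "none"]
        if flagged and min(flagged) < len(self.levels) - 2:
            raise ScoreTableError(
                f"criterion {self.name!r}: only the highest one or two levels "
                f"may carry flags"
            )

    @property
    def max_points(self) -> int:
        return self.levels[-1].points

    def level_index(self, level: Union[int, str]) -> int:
        """Resolve a level given as an index or as its printed description."""
        if isinstance(level, str):
            for i, lv in enumerate(self.levels):
                if lv.description == level:
                    return i
            raise ScoringError(
                f"criterion {self.name!r}: unknown level description {level!r}"
            )
        i = int(level)
        if not 0 <= i < len(self.levels):
            raise ScoringError(
                f"criterion {self.name!r}: level index {i} out of range "
                f"0..{len(self.levels) - 1}"
            )
        return i


@dataclass(frozen=True)
class GradeBand:
    lo: int
    hi: int
    label: str


@dataclass(frozen=True)
class ScoreTable:
    """A named MISS score sheet: criteria, grading bands, cumulative cut-off."""

    name: str
    criteria: tuple[Criterion, ...]
    grading: tuple[GradeBand, ...]
    euthanasia_threshold: int

    def __post_init__(self) -> None:
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise ScoreTableError(f"table {self.name!r}: duplicate criterion names")
        # Grading bands must partition 0..max_total_score.
        bands = sorted(self.grading, key=lambda b: b.lo)
        expect = 0
        for b in bands:
            if b.lo != expect:
                raise ScoreTableError(
                    f"table {self.name!r}: grading gap/overlap at score {expect} "
                    f"(band {b.label!r} starts at {b.lo})"
                )
            if b.hi < b.lo:
                raise ScoreTableError(
                    f"table {self.name!r}: empty grading band {b.label!r}"
                )
            expect = b.hi + 1
        if expect != self.max_total_score + 1:
            raise ScoreTableError(
                f"table {self.name!r}: grading bands cover 0..{expect - 1}, "
                f"expected 0..{self.max_total_score}"
            )

    @property
    def max_total_score(self) -> int:
        return sum(c.max_points for c in self.criteria)

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise ScoringError(f"table {self.name!r} has no criterion {name!r}")

    @property
    def has_weight_criterion(self) -> bool:
        return any(c.name == "weight_loss" for c in self.criteria)

    def grade_of(self, total: int) -> str:
        for b in self.grading:
            if b.lo <= total <= b.hi:
                return b.label
        raise ScoringError(
            f"table {self.name!r}: total {total} outside grading bands"
        )


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one observation against one table."""

    table: str
    per_criterion: Mapping[str, int] = field(default_factory=dict)
    total: int = 0
    grade: str = "normal"
    action: str = "none"
    triggered_by_definitive: bool = False


def max_total_score(table: ScoreTable) -> int:
    """Highest achievable cumulative score (sum of per-criterion maxima)."""
    return table.max_total_score


def weight_loss_level(pct_loss: float) -> int:
    """Map a percent weight loss onto the MISS3 weight-criterion level index.

    Gains (negative loss) map to the <20% band.  The function is total.
    """
    x = float(pct_loss)
    level = 0
    for edge in WEIGHT_BAND_EDGES:
        if x >= edge:
            level += 1
    return level


def _parse_level(raw: dict, criterion: str) -> Level:
    try:
        desc = str(raw["description"])
        points = raw["points"]
    except (KeyError, TypeError) as exc:
        raise ScoreTableError(
            f"criterion {criterion!r}: level needs 'description' and 'points'"
        ) from exc
    if not isinstance(points, int) or points < 0:
        raise ScoreTableError(
            f"criterion {criterion!r}: points must be a non-negative integer "
            f"(got {points!r})"
        )
    return Level(desc, points, str(raw.get("flag", "none")))


def load_score_table(source) -> ScoreTable:
    """Load and validate a score table from YAML text, a path, or a dict.

    Raises :class:`ScoreTableError` naming the offending criterion or grading
    interval on any structural violation (non-monotone points, grading gaps,
    missing fields).
    """
    if isinstance(source, dict):
        doc = source
    else:
        if isinstance(source, io.IOBase):
            text = source.read()
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text, "r", encoding="utf-8") as fh:
                    text = fh.read()
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ScoreTableError("score-table config must be a mapping")
    for key in ("name", "criteria", "grading", "euthanasia_threshold"):
        if key not in doc:
            raise ScoreTableError(f"score-table config missing {key!r}")
    criteria = []
    for c in doc["criteria"]:
        cname = str(c.get("name", "<unnamed>"))
        levels = tuple(_parse_level(lv, cname) for lv in c.get("levels", []))
        criteria.append(Criterion(cname, levels))
    table = ScoreTable(
        name=str(doc["name"]),
        criteria=tuple(criteria),
        grading=tuple(
            GradeBand(
                int(b["min"]),
                int(b["max"]) if b.get("max") is not None else _grading_hi(criteria),
                str(b["label"]),
            )
            for b in doc["grading"]
        ),
        euthanasia_threshold=int(doc["euthanasia_threshold"]),
    )
    return table


def _grading_hi(criteria) -> int:
    return sum(c.max_points for c in criteria)


def builtin_table(name: str) -> ScoreTable:
    """Return one of the shipped tables: ``MISS1``, ``MISS2`` or ``MISS3``."""
    key = name.strip().upper().replace(" ", "")
    if key not in ("MISS1", "MISS2", "MISS3"):
        raise ScoreTableError(f"no built-in score table named {name!r}")
    text = (
        resources.files("miss_ars.tables")
        .joinpath(key.lower() + ".yaml")
        .read_text(encoding="utf-8")
    )
    return load_score_table(text)


def score_observation(table: ScoreTable, sign_levels: Mapping[str, Union[int, str]]) -> ScoreResult:
    """Score one clinical assessment against a table.

    ``sign_levels`` must supply a level (index or printed description) for
    *every* criterion the table defines; silent zeros would mask missed
    assessments, so a missing criterion is an error.  Scoring is pure: the
    same inputs always produce the same :class:`ScoreResult`.

    The action is ``euthanize`` whenever the grade is ``moribund``, the total
    reaches the cumulative threshold, or any definitive
    (``euthanize_immediate``) level fires — the last regardless of total.
    """
    per: dict[str, int] = {}
    definitive = False
    notify = False
    for crit in table.criteria:
        if crit.name not in sign_levels:
            raise ScoringError(
                f"observation supplies no level for criterion {crit.name!r} "
                f"of table {table.name!r}"
            )
        idx = crit.level_index(sign_levels[crit.name])
        lv = crit.levels[idx]
        per[crit.name] = lv.points
        if lv.flag == "euthanize_immediate":
            definitive = True
        elif lv.flag == "notify":
            notify = True
    total = sum(per.values())
    grade = table.grade_of(total)
    if definitive or grade == "moribund" or total >= table.euthanasia_threshold:
        action = "euthanize"
    elif notify:
        action = "notify"
    elif grade == "morbid":
        action = "increase_monitoring"
    else:
        action = "none"
    return ScoreResult(
        table=table.name,
        per_criterion=per,
        total=total,
        grade=grade,
        action=action,
        triggered_by_definitive=definitive,
    )
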