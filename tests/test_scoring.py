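"""Scoring-table validation, per-observation scoring, and invariants."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from miss_ars.scoring import (
    ACTIONS,
    ScoreTableError,
    ScoringError,
    builtin_table,
    load_score_table,
    max_total_score,
    score_observation,
    weight_loss_level,
)


def all_level_combinations(table):
    names = [c.name for c in table.criteria]
    ranges = [range(len(c.levels)) for c in table.criteria]
    for combo in itertools.product(*ranges):
        yield dict(zip(names, combo))


class TestShippedTables:
    def test_miss2_structure(self, miss2):
        assert len(miss2.criteria) == 3
        for crit in miss2.criteria:
            assert [lv.points for lv in crit.levels] == [0, 1, 2, 4]
        assert max_total_score(miss2) == 12
        assert miss2.euthanasia_threshold == 8

    def test_miss3_structure(self, miss3):
        assert [c.name for c in miss3.criteria] == [
            "appearance",
            "respiratory_rate",
            "general_behavior",
            "provoked_behavior",
            "weight_loss",
        ]
        wl = miss3.criterion("weight_loss")
        assert [lv.points for lv in wl.levels] == [0, 3, 6, 9, 12]
        assert wl.levels[-1].flag == "euthanize_immediate"
        assert max_total_score(miss3) == 60

    def test_miss3_grading_bands(self, miss3):
        assert miss3.grade_of(0) == "normal"
        assert miss3.grade_of(5) == "normal"
        assert miss3.grade_of(6) == "morbid"
        assert miss3.grade_of(11) == "morbid"
        assert miss3.grade_of(12) == "moribund"

    def test_miss1_reuses_miss3_bands(self, miss1):
        assert miss1.grade_of(5) == "normal"
        assert miss1.grade_of(11) == "morbid"
        assert miss1.grade_of(12) == "moribund"
        assert max_total_score(miss1) == 48

    def test_single_zero_criterion_table(self):
        table = load_score_table(
            {
                "name": "tiny",
                "euthanasia_threshold": 1,
                "criteria": [
                    {"name": "only", "levels": [{"description": "Normal", "points": 0}]}
                ],
                "grading": [{"label": "normal", "min": 0, "max": 0}],
            }
        )
        assert max_total_score(table) == 0


class TestConfigValidation:
    def test_grading_gap_rejected(self):
        with pytest.raises(ScoreTableError, match="gap"):
            load_score_table(
                {
                    "name": "bad",
                    "euthanasia_threshold": 8,
                    "criteria": [
                        {
                            "name": "appearance",
                            "levels": [
                                {"description": "Normal", "points": 0},
                                {"description": "Bad", "points": 12},
                            ],
                        }
                    ],
                    "grading": [
                        {"label": "normal", "min": 0, "max": 5},
                        {"label": "moribund", "min": 7, "max": 12},
                    ],
                }
            )

    def test_non_monotone_points_rejected(self):
        with pytest.raises(ScoreTableError, match="appearance"):
            load_score_table(
                {
                    "name": "bad",
                    "euthanasia_threshold": 1,
                    "criteria": [
                        {
                            "name": "appearance",
                            "levels": [
                                {"description": "Normal", "points": 0},
                                {"description": "A", "points": 3},
                                {"description": "B", "points": 2},
                            ],
                        }
                    ],
                    "grading": [{"label": "normal", "min": 0, "max": 3}],
                }
            )

    def test_nonzero_first_level_rejected(self):
        with pytest.raises(ScoreTableError, match="level 0"):
            load_score_table(
                {
                    "name": "bad",
                    "euthanasia_threshold": 1,
                    "criteria": [
                        {
                            "name": "x",
                            "levels": [{"description": "Normal", "points": 1}],
                        }
                    ],
                    "grading": [{"label": "normal", "min": 0, "max": 1}],
                }
            )

    def test_unknown_builtin(self):
        with pytest.raises(ScoreTableError):
            builtin_table("MISS9")


class TestScoreObservation:
    def test_miss2_euthanasia_at_eight(self, miss2):
        res = score_observation(
            miss2,
            {
                "appearance": "Dull/rough coat",
                "general_behavior": "No peer interaction, vocalization, restless or still",
                "provoked_behavior": "Subdued even to stimulation",
            },
        )
        assert res.total == 8
        assert res.action == "euthanize"
        assert not res.triggered_by_definitive

    @pytest.mark.parametrize("table_name", ["MISS1", "MISS2", "MISS3"])
    def test_all_normal_scores_zero(self, table_name):
        table = builtin_table(table_name)
        res = score_observation(table, {c.name: 0 for c in table.criteria})
        assert res.total == 0
        assert res.grade == "normal"
        assert res.action == "none"

    def test_definitive_righting_reflex(self, miss3):
        levels = {c.name: 0 for c in miss3.criteria}
        levels["provoked_behavior"] = "Does not right when placed on side within 5 seconds"
        res = score_observation(miss3, levels)
        assert res.total == 12
        assert res.triggered_by_definitive
        assert res.action == "euthanize"

    def test_missing_criterion_is_error(self, miss3):
        with pytest.raises(ScoringError, match="respiratory_rate"):
            score_observation(miss3, {"appearance": 0})

    def test_unknown_description_is_error(self, miss2):
        levels = {c.name: 0 for c in miss2.criteria}
        levels["appearance"] = "Glowing"
        with pytest.raises(ScoringError, match="Glowing"):
            score_observation(miss2, levels)

    def test_scoring_is_pure(self, miss3):
        levels = {c.name: 1 for c in miss3.criteria}
        assert score_observation(miss3, levels) == score_observation(miss3, levels)


class TestWeightLossBands:
    @pytest.mark.parametrize(
        "pct,points",
        [(-5.0, 0), (0.0, 0), (19.9, 0), (22.0, 3), (25.5, 3), (26.0, 6),
         (28.0, 6), (31.0, 9), (33.0, 9), (34.99, 9), (35.0, 12), (36.0, 12)],
    )
    def test_band_points(self, miss3, pct, points):
        wl = miss3.criterion("weight_loss")
        assert wl.levels[weight_loss_level(pct)].points == points

    def test_definitive_at_35(self, miss3):
        wl = miss3.criterion("weight_loss")
        assert wl.levels[weight_loss_level(36.0)].flag == "euthanize_immediate"

    @given(st.floats(min_value=-50, max_value=80, allow_nan=False))
    def test_monotone_total_function(self, pct):
        lvl = weight_loss_level(pct)
        assert 0 <= lvl <= 4
        assert weight_loss_level(pct + 1.0) >= lvl


@pytest.mark.parametrize("table_name", ["MISS1", "MISS2", "MISS3"])
def test_exhaustive_enumeration(table_name):
    """Every level combination: total in range, euthanize iff threshold/
    moribund band reached or a definitive criterion fires."""
    table = builtin_table(table_name)
    top = max_total_score(table)
    for levels in all_level_combinations(table):
        res = score_observation(table, levels)
        assert 0 <= res.total <= top
        assert res.total == sum(res.per_criterion.values())
        definitive = any(
            c.levels[levels[c.name]].flag == "euthanize_immediate" for c in table.criteria
        )
        should = (
            definitive
            or res.total >= table.euthanasia_threshold
            or table.grade_of(res.total) == "moribund"
        )
        assert (res.action == "euthanize") == should
        assert res.triggered_by_definitive == definitive


@given(
    table_name=st.sampled_from(["MISS1", "MISS2", "MISS3"]),
    data=st.data(),
)
def test_raising_one_level_never_downgrades(table_name, data):
    table = builtin_table(table_name)
    levels = {
        c.name: data.draw(st.integers(0, len(c.levels) - 1), label=c.name)
        for c in table.criteria
    }
    bumpable = [c for c in table.criteria if levels[c.name] < len(c.levels) - 1]
    if not bumpable:
        return
    crit = data.draw(st.sampled_from(bumpable), label="bumped")
    before = score_observation(table, levels)
    raised = dict(levels)
    raised[crit.name] += 1
    after = score_observation(table, raised)
    assert after.total >= before.total
    assert ACTIONS.index(after.action) >= ACTIONS.index(before.action)
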