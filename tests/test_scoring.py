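import warnings
from datetime import date

import numpy as np
import pytest

from rand36val.scoring import (
    ITEM_CHOICES,
    RECODE_TABLE,
    SUBSCALES,
    Rand36Record,
    completeness_summary,
    health_change_category,
    recode_item,
    score_all,
    score_subscale,
)

from conftest import make_record


class TestRecodeItem:
    @pytest.mark.parametrize(
        "item, raw, expected",
        [
            (3, 1, 0), (3, 2, 50), (3, 3, 100),   # 3-point functioning items
            (21, 1, 100), (21, 6, 0),             # reverse-scored 6-point
            (13, 1, 0), (13, 2, 100),             # yes/no role items
            (1, 1, 100), (1, 5, 0),               # reverse-scored 5-point
            (24, 1, 0), (24, 6, 100),             # forward 6-point
            (32, 1, 0), (32, 5, 100),             # forward 5-point
        ],
    )
    def test_recode_lookup(self, item, raw, expected):
        assert recode_item(item, raw) == expected

    def test_out_of_range_raw_names_item_and_value(self):
        with pytest.raises(ValueError, match="13") as err:
            recode_item(13, 7)
        assert "7" in str(err.value)

    def test_every_item_covered_with_plausible_choice_counts(self):
        assert set(RECODE_TABLE) == set(range(1, 37))
        assert set(ITEM_CHOICES.values()) <= {2, 3, 5, 6}


class TestScoreSubscale:
    def test_best_and_worst_records_hit_the_extremes(self):
        best, worst = make_record(fill="best"), make_record(fill="worst")
        for name in SUBSCALES:
            assert score_subscale(best, name) == 100
            assert score_subscale(worst, name) == 0

    def test_missing_member_item_blocks_complete_only(self):
        rec = make_record({21: None})
        assert score_subscale(rec, "Pain") is None
        # other subscales unaffected
        assert score_subscale(rec, "Physical functioning") == 100

    def test_half_rule_scores_with_half_answered(self):
        rec = make_record({3: None, 4: None, 5: None, 6: None, 7: None})
        assert score_subscale(rec, "Physical functioning") is None
        assert score_subscale(
            rec, "Physical functioning", missing_policy="half_rule"
        ) == 100

    def test_mean_and_median_aggregation(self):
        # Physical functioning raw responses giving 0,0,50,50,100,100,0,50,100,50
        values = [0, 0, 50, 50, 100, 100, 0, 50, 100, 50]
        raw = {item: {0: 1, 50: 2, 100: 3}[v] for item, v in zip(range(3, 13), values)}
        rec = make_record(raw)
        assert score_subscale(rec, "Physical functioning", "mean") == 50
        assert score_subscale(rec, "Physical functioning", "median") == 50

    def test_monotonicity_in_any_single_item(self, rng):
        # a strictly better response never lowers the subscale score
        for _ in range(30):
            name = list(SUBSCALES)[rng.integers(len(SUBSCALES))]
            items = SUBSCALES[name]
            raw = {
                item: int(rng.integers(1, ITEM_CHOICES[item] + 1)) for item in items
            }
            rec = make_record(raw)
            base = score_subscale(rec, name)
            item = items[rng.integers(len(items))]
            better = [
                r for r in RECODE_TABLE[item]
                if RECODE_TABLE[item][r] > RECODE_TABLE[item][raw[item]]
            ]
            if not better:
                continue
            improved = make_record({**raw, item: better[0]})
            assert score_subscale(improved, name) >= base

    def test_unknown_subscale_rejected(self):
        with pytest.raises(ValueError, match="unknown subscale"):
            score_subscale(make_record(), "Vitality")


class TestScoreAll:
    def test_best_record_scores_100_everywhere(self):
        scores = score_all(make_record(fill="best"))
        assert all(v == 100 for v in scores.scores.values())

    def test_item_order_is_irrelevant(self):
        rec = make_record()
        shuffled = Rand36Record(
            patient_id=rec.patient_id,
            group=rec.group,
            occasion=rec.occasion,
            date=rec.date,
            items=dict(reversed(list(rec.items.items()))),
        )
        assert score_all(rec) == score_all(shuffled)

    def test_missing_item2_only_blanks_health_change(self):
        scores = score_all(make_record({2: None}))
        assert scores.health_change is None
        assert all(v is not None for v in scores.scores.values())

    def test_health_change_reverse_recoded(self):
        # raw 1 = much better -> category 5; raw 5 = much worse -> category 1
        assert health_change_category(make_record({2: 1})) == 5
        assert health_change_category(make_record({2: 5})) == 1

    def test_composition_matches_per_subscale_calls(self, rng):
        raw = {
            item: int(rng.integers(1, ITEM_CHOICES[item] + 1))
            for item in RECODE_TABLE
        }
        rec = make_record(raw)
        scores = score_all(rec)
        for name in SUBSCALES:
            assert scores.scores[name] == score_subscale(rec, name)

    def test_invalid_raw_response_rejected_at_construction(self):
        with pytest.raises(ValueError, match="item 13"):
            make_record({13: 7})


class TestCompletenessSummary:
    def _paired(self, pid, baseline_overrides=None, followup_overrides=None):
        return [
            make_record(baseline_overrides, patient_id=pid, occasion="baseline"),
            make_record(followup_overrides, patient_id=pid, occasion="followup",
                        when=date(2017, 3, 11)),
        ]

    def test_complete_cohort_counts_everyone(self):
        cohort = self._paired("A") + self._paired("B")
        summary = completeness_summary(cohort)
        assert (summary["n_complete"] == 2).all()
        assert (summary["percent_complete"] == 100.0).all()

    def test_single_missing_item_only_hits_its_subscale(self):
        cohort = self._paired("A", baseline_overrides={21: None}) + self._paired("B")
        summary = completeness_summary(cohort).set_index("subscale")
        assert summary.loc["Pain", "n_complete"] == 1
        others = summary.drop(index="Pain")
        assert (others["n_complete"] == 2).all()

    def test_unpaired_patient_excluded_with_warning(self):
        cohort = self._paired("A") + [make_record(patient_id="C")]
        with pytest.warns(UserWarning, match="unpaired"):
            summary = completeness_summary(cohort)
        assert (summary["n_complete"] == 1).all()

    def test_mcar_missingness_matches_direct_tally(self, rng):
        # 5% MCAR holes; compare against an explicit per-patient tally
        cohort = []
        expected = {name: 0 for name in SUBSCALES}
        for k in range(40):
            holes = [
                {item: None for item in RECODE_TABLE if rng.random() < 0.05}
                for _ in range(2)
            ]
            cohort += [
                make_record(holes[0], patient_id=f"P{k}", occasion="baseline"),
                make_record(holes[1], patient_id=f"P{k}", occasion="followup"),
            ]
            for name, items in SUBSCALES.items():
                if all(i not in holes[0] and i not in holes[1] for i in items):
                    expected[name] += 1
        summary = completeness_summary(cohort).set_index("subscale")
        for name, count in expected.items():
            assert summary.loc[name, "n_complete"] == count
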