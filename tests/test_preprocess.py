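"""Validity filters, EMA aggregation and between/within decomposition."""

import numpy as np
import pandas as pd
import pytest

from timeuse_coda import coda, preprocess

from conftest import random_compositions


class TestDayFilter:
    def test_boundary_strictly_greater_than_two_hours(self, toy_days):
        out = preprocess.filter_valid_days(toy_days)
        b0 = out.query("participant_id == 'B'")["nonwear"]
        assert (b0 == 120.0).any()  # exactly two hours is retained
        assert not (out["nonwear"] > 120).any()  # 121 min is excluded

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["participant_id", "nonwear"])
        assert len(preprocess.filter_valid_days(empty)) == 0

    def test_negative_nonwear_rejected(self):
        df = pd.DataFrame({"participant_id": ["A"], "nonwear": [-1.0]})
        with pytest.raises(ValueError, match="negative"):
            preprocess.filter_valid_days(df)

    def test_idempotent_and_values_untouched(self, toy_days):
        once = preprocess.filter_valid_days(toy_days)
        twice = preprocess.filter_valid_days(once)
        pd.testing.assert_frame_equal(once, twice)
        merged = once.merge(toy_days, on=["participant_id", "date"], suffixes=("", "_raw"))
        for c in ("sb", "lpa", "mvpa", "sleep"):
            np.testing.assert_array_equal(merged[c], merged[f"{c}_raw"])


class TestParticipantFilter:
    def test_toy_fixture_three_participants_survive(self, toy_days):
        valid = preprocess.filter_valid_days(toy_days)
        out = preprocess.filter_participants(valid)
        assert sorted(out["participant_id"].unique()) == ["B", "C", "E"]
        assert out.groupby("participant_id").size().to_dict() == {"B": 2, "C": 3, "E": 7}

    def test_two_valid_days_is_retained(self):
        df = pd.DataFrame(
            {"participant_id": ["A", "A"], "nonwear": [0.0, 0.0]}
        )
        assert len(preprocess.filter_participants(df)) == 2

    def test_idempotent(self, toy_days):
        once = preprocess.filter_participants(preprocess.filter_valid_days(toy_days))
        pd.testing.assert_frame_equal(once, preprocess.filter_participants(once))


class TestAffectAggregation:
    @staticmethod
    def _responses(scores, pid="A", day="2023-06-05"):
        return pd.DataFrame(
            {
                "participant_id": pid,
                "timestamp": [f"{day} {9 + i}:00" for i in range(len(scores))],
                "happiness": scores,
                "anxiousness": scores,
                "tiredness": scores,
            }
        )

    def test_mean_of_two_responses(self):
        out = preprocess.aggregate_daily_affect(self._responses([7, 8]))
        assert out["happiness"].iloc[0] == pytest.approx(7.5)
        assert out["n_ema"].iloc[0] == 2

    def test_single_response_is_identity(self):
        out = preprocess.aggregate_daily_affect(self._responses([5]))
        assert out["happiness"].iloc[0] == 5

    def test_permutation_invariance(self):
        a = preprocess.aggregate_daily_affect(self._responses([2, 9, 4]))
        b = preprocess.aggregate_daily_affect(self._responses([9, 4, 2]))
        pd.testing.assert_frame_equal(a, b)

    def test_more_than_three_responses_is_protocol_violation(self):
        with pytest.raises(ValueError, match="3"):
            preprocess.aggregate_daily_affect(self._responses([1, 2, 3, 4]))

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError, match="happiness"):
            preprocess.aggregate_daily_affect(self._responses([11]))


class TestDecomposition:
    def _days(self, ilr1_values):
        rng = np.random.default_rng(0)
        n = len(ilr1_values)
        df = pd.DataFrame(
            {
                "participant_id": ["A"] * n,
                "ilr1": ilr1_values,
                "ilr2": rng.normal(size=n),
                "ilr3": rng.normal(size=n),
            }
        )
        return preprocess.decompose_between_within(df)

    def test_centering_example(self):
        out = self._days([1.0, 2.0, 3.0])
        assert (out["ilr_b1"] == 2.0).all()
        np.testing.assert_allclose(out["ilr_w1"], [-1, 0, 1])

    def test_single_day_person_has_zero_within(self):
        out = self._days([1.7])
        np.testing.assert_allclose(
            out[["ilr_w1", "ilr_w2", "ilr_w3"]].to_numpy(), 0.0
        )

    def test_reconstruction_and_zero_sum(self, small_table):
        for c, b, w in zip(
            preprocess.ILR_COLS, preprocess.ILR_B_COLS, preprocess.ILR_W_COLS
        ):
            np.testing.assert_allclose(
                small_table[b] + small_table[w], small_table[c], atol=1e-12
            )
            sums = small_table.groupby("participant_id")[w].sum()
            np.testing.assert_allclose(sums, 0.0, atol=1e-10)

    def test_between_equals_ilr_of_geometric_mean_composition(self, rng):
        """Person-mean ilr == ilr of that person's compositional centre."""
        comps = random_compositions(rng, 6)
        df = pd.DataFrame(comps, columns=list(coda.PARTS))
        df["participant_id"] = "A"
        out = preprocess.decompose_between_within(
            preprocess.add_ilr_coordinates(df)
        )
        expected = coda.ilr_transform(coda.geometric_mean_composition(comps))
        np.testing.assert_allclose(
            out[list(preprocess.ILR_B_COLS)].iloc[0], expected, atol=1e-10
        )


class TestAssemble:
    @staticmethod
    def _inputs(rng, n_pid=3, n_days=2, with_ema=True):
        rows = []
        for p in range(n_pid):
            for d in range(n_days):
                comp = random_compositions(rng, 1)[0]
                rows.append(
                    {
                        "participant_id": f"P{p}",
                        "date": pd.Timestamp("2023-06-05") + pd.Timedelta(days=d),
                        **dict(zip(coda.PARTS, comp)),
                        "nonwear": 10.0,
                    }
                )
        days = pd.DataFrame(rows)
        ema_rows = []
        if with_ema:
            for r in rows:
                ema_rows.append(
                    {
                        "participant_id": r["participant_id"],
                        "timestamp": r["date"] + pd.Timedelta(hours=10),
                        "happiness": 6,
                        "anxiousness": 3,
                        "tiredness": 4,
                    }
                )
        ema = pd.DataFrame(ema_rows)
        survey = pd.DataFrame(
            {
                "participant_id": [f"P{p}" for p in range(n_pid)],
                "life_satisfaction": 7,
                "age_band": "35-44",
                "gender": "Female",
                "ethnicity": "NZ European",
                "deprivation_decile": 8,
            }
        )
        return days, ema, survey

    def test_full_join_row_count(self, rng):
        days, ema, survey = self._inputs(rng)
        table = preprocess.assemble_analysis_table(days, ema, survey)
        assert len(table) == 6
        assert table["has_affect"].all()
        assert (table["day_index"] == [1, 2] * 3).all()

    def test_day_without_ema_flagged_affect_absent(self, rng):
        days, ema, survey = self._inputs(rng)
        ema = ema.iloc[1:]  # drop P0's first day
        table = preprocess.assemble_analysis_table(days, ema, survey)
        missing = table.loc[~table["has_affect"]]
        assert len(missing) == 1
        assert missing["n_ema"].iloc[0] == 0
        assert np.isnan(missing["happiness"].iloc[0])

    def test_missing_survey_row_names_participant(self, rng):
        days, ema, survey = self._inputs(rng)
        with pytest.raises(ValueError, match="P2"):
            preprocess.assemble_analysis_table(days, ema, survey.iloc[:2])
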