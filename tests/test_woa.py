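"""Weight-of-advice statistic: formula, capping, exclusions, bins, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from advicetrial import SimConfig, simulate_trial
from advicetrial.woa import (
    analysis_records,
    bin_woa,
    build_woa_table,
    compute_woa,
    per_protocol_filter,
    summarize,
    truncate_woa,
)
from tests.conftest import noise_free_config


class TestComputeWoa:
    def test_worked_example_half_weight(self):
        assert compute_woa(60, 90, 75) == pytest.approx(0.5)

    def test_tie_is_undefined(self):
        assert compute_woa(90, 90, 80) is None

    def test_full_discounting_is_zero(self):
        assert compute_woa(60, 90, 60) == pytest.approx(0.0)

    def test_overshoot_exceeds_one_before_capping(self):
        raw = compute_woa(60, 90, 95)
        assert raw == pytest.approx(35 / 30)
        assert truncate_woa(raw) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_woa(-1, 90, 75)
        with pytest.raises(ValueError):
            compute_woa(60, 101, 75)

    @settings(derandomize=True, max_examples=200)
    @given(
        i=st.integers(10, 60),
        f=st.integers(10, 60),
        a=st.integers(10, 60),
        c=st.integers(-10, 40),
    )
    def test_translation_invariance(self, i, f, a, c):
        # adding a constant to i, a, f leaves WOA unchanged
        if a == i:
            return
        base = compute_woa(i, a, f)
        shifted = compute_woa(i + c, a + c, f + c)
        assert shifted == pytest.approx(base)

    def test_sign_asymmetry_of_literal_formula(self):
        # advice below the initial estimate: movement toward the advice
        # yields a NEGATIVE raw score because only the denominator takes
        # the absolute value
        raw = compute_woa(80, 50, 65)  # halfway toward advice from above
        assert raw == pytest.approx(-0.5)
        # and movement away from advice (upward) is positive
        assert compute_woa(80, 50, 86) == pytest.approx(0.2)


class TestTruncation:
    @pytest.mark.parametrize(
        "raw,policy,expected",
        [
            (35 / 30, "clamp", 1.0),
            (0.42, "clamp", 0.42),
            (-0.5, "clamp", 0.0),
            (-0.5, "keep", -0.5),
            (-0.5, "drop", None),
            (1.8, "keep", 1.0),  # capping applies under every policy
        ],
    )
    def test_policies(self, raw, policy, expected):
        assert truncate_woa(raw, policy) == expected

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            truncate_woa(0.5, "winsorise")


class TestBinning:
    @pytest.mark.parametrize(
        "woa,expected",
        [(0.0, 1), (0.19, 1), (0.2, 2), (0.39, 2), (0.4, 3), (0.6, 4), (0.79, 4), (0.8, 5), (1.0, 5)],
    )
    def test_bin_edges(self, woa, expected):
        assert bin_woa(woa) == expected

    @settings(derandomize=True, max_examples=200)
    @given(w=st.floats(0, 1, allow_nan=False))
    def test_binning_partitions_unit_interval(self, w):
        assert bin_woa(w) in (1, 2, 3, 4, 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_woa(1.2)


class TestPerProtocolFilter:
    def _records(self):
        return pd.DataFrame(
            {
                "participant_id": ["a"] * 5 + ["b"] * 5,
                "completed": [True] * 5 + [True] * 4 + [False],
            }
        )

    def test_incomplete_participant_fully_dropped(self):
        out = per_protocol_filter(self._records())
        assert set(out["participant_id"]) == {"a"}
        assert len(out) == 5

    def test_identity_when_all_complete(self):
        df = self._records()
        df["completed"] = True
        pd.testing.assert_frame_equal(per_protocol_filter(df), df)

    def test_idempotent(self):
        once = per_protocol_filter(self._records())
        twice = per_protocol_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_exclusion_arithmetic_in_scored_table(self):
        # participants with any incomplete vignette are excluded wholesale
        df = simulate_trial(SimConfig(n_participants=100, seed=13))
        table = build_woa_table(df)
        incomplete = table.loc[table["reason"] == "incomplete", "participant_id"]
        completers = df.groupby("participant_id")["completed"].all()
        assert set(incomplete) == set(completers.index[~completers])
        analysed = analysis_records(table)["participant_id"].nunique()
        assert analysed == int(completers.sum())


class TestScoring:
    def test_tie_exclusion_reason(self):
        df = simulate_trial(SimConfig(n_participants=100, tie_probability=0.2, seed=8))
        table = build_woa_table(df)
        ties = table["reason"] == "tie"
        assert (table.loc[ties, "initial"] == table.loc[ties, "strength"]).all()
        assert table.loc[ties, "woa"].isna().all()

    def test_woa_in_unit_interval_and_binned(self, default_records):
        assert default_records["woa"].between(0, 1).all()
        assert default_records["bin"].between(1, 5).all()

    def test_raw_values_retained_under_clamp(self):
        df = simulate_trial(SimConfig(n_participants=100, response_sd=20.0, seed=8))
        table = build_woa_table(df, policy="clamp")
        clamped = table["woa"] == 0.0
        assert (table.loc[clamped & table["raw_woa"].notna(), "raw_woa"] <= 0.0).any()

    def test_missing_column_named_in_error(self):
        df = simulate_trial(SimConfig(n_participants=10, seed=1)).drop(columns=["final"])
        with pytest.raises(ValueError, match="final"):
            build_woa_table(df)


class TestSummaries:
    def test_constant_records(self):
        df = pd.DataFrame({"participant_id": list("abcd"), "woa": [0.5] * 4})
        out = summarize(df, "overall")
        assert out.loc[0, "mean"] == pytest.approx(0.5)
        assert out.loc[0, "sd"] == pytest.approx(0.0)

    def test_hand_computed_group_moments(self):
        df = pd.DataFrame(
            {
                "participant_id": list("abc"),
                "arm": ["ALGORITHM", "ALGORITHM", "CLINICIAN"],
                "woa": [0.0, 1.0, 0.5],
            }
        )
        out = summarize(df, "arm").set_index("arm")
        assert out.loc["ALGORITHM", "mean"] == pytest.approx(0.5)
        assert out.loc["ALGORITHM", "sd"] == pytest.approx(np.sqrt(0.5))
        assert out.loc["CLINICIAN", "mean"] == pytest.approx(0.5)
        assert out.loc["CLINICIAN", "sd"] == pytest.approx(0.0)

    def test_noise_free_arm_means_recover_true_weights(self):
        df = simulate_trial(noise_free_config(n_participants=200))
        table = build_woa_table(df)
        out = summarize(analysis_records(table), "arm").set_index("arm")
        assert out.loc["ALGORITHM", "mean"] == pytest.approx(0.44, abs=0.01)
        assert out.loc["CLINICIAN", "mean"] == pytest.approx(0.31, abs=0.01)

    def test_empty_group_yields_nan_row_not_crash(self):
        df = pd.DataFrame({"participant_id": [], "woa": []})
        out = summarize(df, "overall")
        assert out.loc[0, "n"] == 0
        assert np.isnan(out.loc[0, "mean"])

    def test_unknown_grouping_rejected(self, default_records):
        with pytest.raises(ValueError, match="grouping"):
            summarize(default_records, "by_zodiac_sign")
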