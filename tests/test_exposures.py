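"""Questionnaire coding, missingness filters, exposure windows and
mycotoxin estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from expomic.exposures import (
    FoodFrequencyProfile,
    assign_city,
    average_three_year_window,
    code_response,
    filter_missing,
    haversine_km,
    individual_mycotoxin_exposure,
    regional_concentration,
    spearman_prune,
)


class TestCodeResponse:
    @pytest.mark.parametrize("raw, expected", [
        ("never", 0.0),
        ("rarely", 2.0 / 30.4),
        ("occasionally", 1.5 / 7.0),
        ("often", 4.0 / 7.0),
        ("every day", 1.0),
    ])
    def test_frequency_vocabulary(self, raw, expected):
        assert code_response("frequency", raw) == pytest.approx(expected)

    def test_frequency_prints_at_three_decimals(self):
        # the conventional printed values are roundings of exact quotients
        assert round(code_response("frequency", "rarely"), 3) == 0.066
        assert round(code_response("frequency", "occasionally"), 3) == 0.214
        assert round(code_response("frequency", "often"), 3) == 0.571

    @pytest.mark.parametrize("raw, expected", [
        ("yes", 1), ("no", 0), ("true", 1), ("false", 0), (True, 1),
    ])
    def test_binary(self, raw, expected):
        assert code_response("binary", raw) == expected

    def test_ordinal_by_option_order(self):
        opts = ["strongly disagree", "disagree", "neutral", "agree",
                "strongly agree"]
        assert code_response("ordinal", "neutral", opts) == 2
        assert code_response("ordinal", "strongly agree", opts) == 4

    def test_idempotent_on_numeric(self):
        assert code_response("frequency", 0.571) == 0.571
        assert code_response("binary", 1) == 1

    def test_unknown_response_lists_vocabulary(self):
        with pytest.raises(ValueError, match="never"):
            code_response("frequency", "sometimes-ish")
        with pytest.raises(ValueError, match="yes"):
            code_response("binary", "maybe")


class TestFilterMissing:
    def test_variable_then_sample_order(self):
        # v1 60% missing -> dropped first; afterwards p4 is missing 1 of 2
        # retained variables (50%, not > 50%) and survives
        df = pd.DataFrame({
            "v1": [np.nan, np.nan, np.nan, 1, 2],
            "v2": [1, 2, 3, 4, np.nan],
            "v3": [1, 2, 3, np.nan, 5],
        }, index=[f"p{i}" for i in range(5)])
        out, log = filter_missing(df)
        assert log["dropped_variables"] == ["v1"]
        assert list(out.columns) == ["v2", "v3"]
        assert log["dropped_participants"] == []

    def test_participant_dropped_over_half(self):
        df = pd.DataFrame({
            "v1": [1.0, np.nan], "v2": [1.0, np.nan], "v3": [1.0, 3.0],
        })
        out, log = filter_missing(df)
        assert log["dropped_participants"] == [1]
        assert out.shape == (1, 3)

    def test_no_missingness_identity(self):
        df = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        out, log = filter_missing(df)
        pd.testing.assert_frame_equal(out, df)
        assert not log["empty"]

    def test_thresholds_hold_on_output(self, rng):
        df = pd.DataFrame(rng.standard_normal((60, 12)))
        mask = rng.random((60, 12)) < 0.35
        df = df.mask(mask)
        out, _ = filter_missing(df)
        assert (out.isna().mean(axis=0) <= 0.5 + 1e-12).all()
        assert (out.isna().mean(axis=1) <= 0.5 + 1e-12).all()


class TestSpearmanPrune:
    def test_duplicate_column_drops_one(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)})
        kept, dropped, log = spearman_prune(df)
        assert dropped == ["b"]  # tie on missing counts -> later name
        assert set(kept) == {"a", "c"}

    def test_independent_columns_mostly_untouched(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(r.standard_normal((500, 6)),
                              columns=list("abcdef"))
            _, dropped, _ = spearman_prune(df)
            hits += bool(dropped)
        assert hits <= 1  # none dropped in >= 95% of seeds

    def test_three_duplicates_drop_two(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x, "c": x})
        kept, dropped, _ = spearman_prune(df)
        assert len(kept) == 1 and len(dropped) == 2

    def test_member_with_more_missing_dropped(self, rng):
        x = rng.standard_normal(100)
        a = pd.Series(x).copy()
        a.iloc[:10] = np.nan
        df = pd.DataFrame({"a": a, "b": x})
        kept, dropped, _ = spearman_prune(df)
        assert dropped == ["a"]

    def test_constant_column_warns_not_dropped(self, rng):
        df = pd.DataFrame({"a": np.ones(30), "b": rng.standard_normal(30),
                           "c": rng.standard_normal(30)})
        with pytest.warns(UserWarning, match="constant"):
            kept, dropped, _ = spearman_prune(df)
        assert "a" in kept and not dropped


class TestExposureWindow:
    def test_full_window_mean(self):
        v, flag = average_three_year_window({2012: 1, 2013: 2, 2014: 3}, 2015)
        assert v == pytest.approx(2.0)
        assert flag == "window"

    def test_fallback_to_most_recent_preceding(self):
        v, flag = average_three_year_window({2009: 3, 2010: 3, 2011: 3}, 2015)
        assert v == pytest.approx(3.0)
        assert flag == "fallback"

    def test_partial_years_flagged(self):
        v, flag = average_three_year_window({2013: 4.0}, 2015)
        assert v == 4.0
        assert flag == "partial"

    def test_empty_or_no_preceding_is_missing(self):
        assert average_three_year_window({}, 2015)[1] == "missing"
        assert average_three_year_window({2016: 9}, 2015)[1] == "missing"


class TestMycotoxin:
    def test_regional_concentration_product(self):
        assert regional_concentration(0.5, 10) == 5.0
        assert regional_concentration(0.0, 99) == 0.0
        assert regional_concentration(1.0, 7.3) == 7.3

    def test_detection_rate_range_checked(self):
        with pytest.raises(ValueError):
            regional_concentration(1.2, 5)

    def test_exposure_weighted_sum(self):
        # hand evaluation: 5 * (0.5714*0.5 + 0.0658*0.3) = 1.52723
        p = FoodFrequencyProfile(grains=0.5714, dairy=0.0658, nuts=0.0)
        assert individual_mycotoxin_exposure(5.0, p) == pytest.approx(
            5 * (0.5714 * 0.5 + 0.0658 * 0.3))

    def test_weights_sum_to_one_passthrough(self):
        p = FoodFrequencyProfile(1.0, 1.0, 1.0)
        assert individual_mycotoxin_exposure(2.0, p) == pytest.approx(2.0)

    def test_zero_frequencies_zero_exposure(self):
        p = FoodFrequencyProfile(0.0, 0.0, 0.0)
        assert individual_mycotoxin_exposure(7.0, p) == 0.0

    def test_linearity_in_concentration(self):
        p = FoodFrequencyProfile(0.3, 0.2, 0.1)
        e1 = individual_mycotoxin_exposure(1.0, p)
        assert individual_mycotoxin_exposure(3.0, p) == pytest.approx(3 * e1)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            FoodFrequencyProfile(-0.1, 0.0, 0.0)


class TestAssignCity:
    CENTERS = {"alpha": (40.0, -75.0), "beta": (41.0, -75.0)}

    def test_exact_center(self):
        assert assign_city(40.0, -75.0, self.CENTERS) == "alpha"

    def test_offset_beyond_radius(self):
        # 0.1 deg latitude ~ 11.1 km > 5 km
        assert haversine_km(40.0, -75.0, 40.1, -75.0) == pytest.approx(
            11.12, abs=0.02)
        assert assign_city(40.1, -75.0, {"alpha": (40.0, -75.0)}) is None

    def test_nearest_wins_and_tie_lexicographic(self):
        centers = {"b_city": (0.0, 0.02), "a_city": (0.0, -0.02)}
        # equidistant point on the equator between the two centers
        assert assign_city(0.0, 0.0, centers) == "a_city"
        # closer to b_city
        assert assign_city(0.0, 0.015, centers) == "b_city"

    def test_invalid_coordinates(self):
        with pytest.raises(ValueError):
            assign_city(95.0, 0.0, self.CENTERS)
        with pytest.raises(ValueError):
            assign_city(0.0, 190.0, self.CENTERS)
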