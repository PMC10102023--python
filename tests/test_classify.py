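"""Threshold rules: window prediction, evaluation, tightest circular arc."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from horamortis import (
    DEFAULT_RULES,
    ThresholdRule,
    evaluate_predictions,
    mutual_exclusivity_check,
    predict_cohort,
    predict_window,
    tightest_window,
)
from horamortis.classify import (
    RuleConfigurationError,
    rules_from_json,
    validate_rules,
)


def _ratio_frame(records):
    """records: list of (case_id, tod, nb)."""
    return pd.DataFrame(
        {
            "case_id": [r[0] for r in records],
            "time_of_death": [r[1] for r in records],
            "nb_ratio": [r[2] for r in records],
            "bn_ratio": [1.0 / r[2] for r in records],
        }
    )


class TestPredictWindow:
    @pytest.mark.parametrize(
        "nb,tier,window",
        [
            (50.0, "high_morning", (3.0, 9.0)),
            (30.0, "low_morning", (1.0, 10.0)),
            (41.0, "high_morning", (3.0, 9.0)),
            (25.0, "none", None),  # strict inequality at the threshold
            (10.0, "none", None),
            (1 / 5.0, "high_evening", (15.0, 20.0)),  # bn = 5
            (1 / 2.0, "low_evening", (14.0, 22.0)),   # bn = 2
            (1 / 1.5, "none", None),                  # bn exactly 1.5
        ],
    )
    def test_default_rules(self, nb, tier, window):
        p = predict_window("x", nb, 1.0 / nb)
        assert p.tier == tier
        assert p.window == window

    def test_coverage_flag(self):
        assert predict_window("x", 50.0, 0.02, time_of_death=6.0).covered is True
        assert predict_window("x", 50.0, 0.02, time_of_death=12.0).covered is False
        # closed window: boundary counts as covered
        assert predict_window("x", 50.0, 0.02, time_of_death=9.0).covered is True
        assert predict_window("x", 50.0, 0.02).covered is None

    def test_high_tier_implies_low_threshold_exceeded(self):
        for rules_side, probe in (("nb", 100.0), ("bn", 1 / 100.0)):
            p = predict_window("x", probe, 1.0 / probe)
            assert p.tier.startswith("high_")
            low = [
                r
                for r in DEFAULT_RULES
                if r.ratio_key == rules_side and r.tier == "low"
            ][0]
            value = probe if rules_side == "nb" else 1.0 / probe
            assert value > low.threshold

    def test_default_windows_nested(self):
        by = {(r.ratio_key, r.tier): r.window for r in DEFAULT_RULES}
        for key in ("nb", "bn"):
            lo, hi = by[(key, "low")], by[(key, "high")]
            assert lo[0] <= hi[0] and hi[1] <= lo[1]


class TestEvaluate:
    def test_quarter_predicted_full_coverage(self):
        df = _ratio_frame(
            [("a", 6.0, 50.0), ("b", 12.0, 1.0), ("c", 13.0, 1.0), ("d", 23.0, 1.0)]
        )
        ev = evaluate_predictions(df)
        assert ev["n_total"] == 4 and ev["n_predicted"] == 1
        assert ev["predicted_fraction"] == pytest.approx(0.25)
        assert ev["coverage"] == pytest.approx(1.0)
        assert ev["tier_counts"]["high_morning"] == 1

    def test_no_predictions_reports_absent_coverage(self):
        df = _ratio_frame([("a", 6.0, 1.0), ("b", 12.0, 1.0)])
        ev = evaluate_predictions(df)
        assert ev["predicted_fraction"] == 0.0
        assert ev["coverage"] is None

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            evaluate_predictions(_ratio_frame([]))

    def test_no_morning_and_evening_double_prediction(self, ratios_10k):
        preds = predict_cohort(ratios_10k)
        # each case gets exactly one tier; with default rules a high nb
        # forces bn below its thresholds and vice versa
        assert len(preds) == len(ratios_10k)
        assert set(preds["tier"]) <= {
            "none", "low_morning", "high_morning", "low_evening", "high_evening"
        }


def brute_force_arc(times):
    """Minimal covering circular arc by trying every point as arc start."""
    best = None
    for s in times:
        span = max((t - s) % 24.0 for t in times)
        if best is None or span < best[2]:
            best = (s, (s + span) % 24.0, span)
    return best


class TestTightestWindow:
    def _frame(self, times, nb=50.0):
        return _ratio_frame([(f"c{i}", t, nb) for i, t in enumerate(times)])

    def test_simple_arc(self):
        start, end, length = tightest_window(self._frame([4.0, 5.0, 6.0]), "nb", 25.0)
        assert (start, end, length) == (4.0, 6.0, pytest.approx(2.0))

    def test_wrapping_arc(self):
        start, end, length = tightest_window(self._frame([23.0, 1.0, 2.0]), "nb", 25.0)
        assert (start, end) == (23.0, 2.0)
        assert length == pytest.approx(3.0)

    def test_single_case_degenerate(self):
        start, end, length = tightest_window(self._frame([7.5]), "nb", 25.0)
        assert (start, end, length) == (7.5, 7.5, 0.0)

    def test_no_case_above_threshold(self):
        with pytest.raises(ValueError):
            tightest_window(self._frame([4.0], nb=10.0), "nb", 25.0)

    def test_threshold_is_strict(self):
        df = _ratio_frame([("a", 4.0, 25.0), ("b", 6.0, 26.0)])
        start, end, length = tightest_window(df, "nb", 25.0)
        assert (start, end, length) == (6.0, 6.0, 0.0)

    @given(
        times=st.lists(
            st.floats(min_value=0, max_value=23.999), min_size=2, max_size=12
        )
    )
    def test_matches_brute_force(self, times):
        _, _, length = tightest_window(self._frame(times), "nb", 25.0)
        _, _, expected = brute_force_arc(times)
        assert length == pytest.approx(expected, abs=1e-9)

    def test_monotonicity_in_threshold(self, ratios_10k):
        """Raising the threshold shrinks both the predicted set and the arc."""
        prev_n, prev_len = None, None
        for thr in (5.0, 10.0, 25.0, 40.0):
            above = (ratios_10k["nb_ratio"] > thr).sum()
            _, _, length = tightest_window(ratios_10k, "nb", thr)
            if prev_n is not None:
                assert above <= prev_n
                assert length <= prev_len + 1e-9
            prev_n, prev_len = above, length


class TestRuleValidation:
    def test_default_rules_mutually_exclusive(self):
        assert mutual_exclusivity_check(DEFAULT_RULES) is True

    def test_overlapping_thresholds_detected(self):
        rules = (
            ThresholdRule("nb", 0.5, (1.0, 10.0), "low"),
            ThresholdRule("bn", 0.5, (14.0, 22.0), "low"),
        )
        assert mutual_exclusivity_check(rules) is False
        with pytest.raises(RuleConfigurationError):
            validate_rules(rules)

    @given(
        a=st.floats(min_value=0.1, max_value=100.0),
        b=st.floats(min_value=0.1, max_value=100.0),
    )
    def test_exclusivity_iff_threshold_product_exceeds_one(self, a, b):
        """Algebraic condition checked against a numeric scan of nb values."""
        rules = (
            ThresholdRule("nb", a, (1.0, 10.0), "low"),
            ThresholdRule("bn", b, (14.0, 22.0), "low"),
        )
        predicted = mutual_exclusivity_check(rules)
        nb_grid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 4001))
        both = (nb_grid > a) & (1.0 / nb_grid > b)
        if a * b > 1.0000001:
            assert predicted is True
            assert not both.any()
        elif a * b < 0.9999999:
            assert predicted is False

    def test_non_nested_windows_rejected(self):
        rules = (
            ThresholdRule("nb", 25.0, (1.0, 10.0), "low"),
            ThresholdRule("nb", 40.0, (0.5, 9.0), "high"),  # pokes out left
        )
        with pytest.raises(RuleConfigurationError):
            validate_rules(rules)

    def test_rules_json_round_trip(self):
        text = """
        [
          {"ratio_key": "nb", "threshold": 25, "window": [1, 10], "tier": "low"},
          {"ratio_key": "nb", "threshold": 40, "window": [3, 9], "tier": "high"},
          {"ratio_key": "bn", "threshold": 1.5, "window": [14, 22], "tier": "low"},
          {"ratio_key": "bn", "threshold": 4, "window": [15, 20], "tier": "high"}
        ]
        """
        assert rules_from_json(text) == DEFAULT_RULES

    def test_bad_rule_fields_rejected(self):
        with pytest.raises(RuleConfigurationError):
            ThresholdRule("nb", -1.0, (1.0, 10.0), "low")
        with pytest.raises(RuleConfigurationError):
            ThresholdRule("nb", 25.0, (10.0, 1.0), "low")
        with pytest.raises(RuleConfigurationError):
            ThresholdRule("xx", 25.0, (1.0, 10.0), "low")
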