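"""Non-wear detectors against hand-worked cases and exhaustive-scan oracles."""

import numpy as np
import pytest

from actiwear import (
    EpochSeries,
    NonwearRuleConfig,
    apply_rule,
    detect_choi,
    detect_fixed_window,
    detect_troiano,
)
from actiwear.core import NONWEAR
from actiwear.nonwear import FIXED_WINDOWS, RULE_NAMES, detect

from oracles import (
    choi_oracle,
    fixed_window_oracle,
    random_rule_trace,
    troiano_oracle,
    troiano_total_oracle,
)


def trace(*segments):
    """Build a minute trace from (value, length) segments."""
    return np.concatenate([np.full(n, v) for v, n in segments])


def nonwear_mask(intervals, n):
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        mask[iv.start_epoch : iv.end_epoch] = True
    return mask


def spans(intervals):
    return [(iv.start_epoch, iv.end_epoch) for iv in intervals]


class TestFixedWindow:
    def test_whole_trace_zero_run(self):
        assert spans(detect_fixed_window(np.zeros(120), 60)) == [(0, 120)]

    def test_threshold_is_inclusive(self):
        cpm = trace((50, 5), (0, 25), (50, 5))
        assert spans(detect_fixed_window(cpm, 20)) == [(5, 30)]
        assert spans(detect_fixed_window(cpm, 30)) == []

    def test_matches_run_enumeration_oracle(self, rng):
        for _ in range(500):
            cpm = np.where(rng.random(int(rng.integers(1, 200))) < 0.6, 0, 50)
            for window in FIXED_WINDOWS.values():
                got = nonwear_mask(detect_fixed_window(cpm, window), len(cpm))
                np.testing.assert_array_equal(got, fixed_window_oracle(cpm, window))

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            detect_fixed_window(np.zeros(10), 0)


class TestTroiano:
    def test_absorbs_low_count_interruption(self):
        cpm = trace((0, 30), (50, 1), (0, 30))
        assert spans(detect_troiano(cpm)) == [(0, 61)]
        # the same 61-min span is invisible to the plain 60-min zero window
        assert spans(detect_fixed_window(cpm, 60)) == []

    def test_count_at_ceiling_breaks_span(self):
        cpm = trace((0, 30), (200, 1), (0, 30))
        assert spans(detect_troiano(cpm)) == []

    def test_third_consecutive_nonzero_minute_breaks_span(self):
        cpm = trace((0, 60), (50, 3), (0, 60))
        assert spans(detect_troiano(cpm)) == [(0, 60), (63, 123)]

    def test_dominates_fixed60(self, rng):
        for _ in range(200):
            cpm = random_rule_trace(rng)
            troiano = nonwear_mask(detect_troiano(cpm), len(cpm))
            fixed60 = nonwear_mask(detect_fixed_window(cpm, 60), len(cpm))
            assert np.all(troiano | ~fixed60)  # fixed60 ⊆ troiano as minute sets

    def test_total_budget_mode_matches_brute_force(self, rng):
        config = NonwearRuleConfig(
            "troiano", 60, max_interruption_min=2,
            interruption_count_ceiling=100, interruption_mode="total",
        )
        for _ in range(60):
            cpm = random_rule_trace(rng, max_len=150)
            got = nonwear_mask(detect_troiano(cpm, config), len(cpm))
            np.testing.assert_array_equal(got, troiano_total_oracle(cpm))

    def test_total_mode_is_stricter_than_consecutive(self):
        # two separate 2-min interruptions: fine consecutively, over a 2-min total budget
        cpm = trace((0, 29), (50, 2), (0, 10), (50, 2), (0, 29))
        assert spans(detect_troiano(cpm)) == [(0, 72)]
        total = NonwearRuleConfig(
            "troiano", 60, max_interruption_min=2,
            interruption_count_ceiling=100, interruption_mode="total",
        )
        got = nonwear_mask(detect_troiano(cpm, total), len(cpm))
        np.testing.assert_array_equal(got, troiano_total_oracle(cpm))
        assert got.sum() == 0


class TestChoi:
    def test_pure_zero_run(self):
        assert spans(detect_choi(np.zeros(90))) == [(0, 90)]
        assert spans(detect_choi(np.zeros(89))) == []

    def test_interruption_with_adequate_flanks(self):
        cpm = trace((0, 45), (500, 1), (0, 45))
        assert spans(detect_choi(cpm)) == [(0, 91)]

    def test_short_left_flank_blocks_absorption(self):
        cpm = trace((0, 10), (500, 1), (0, 85))
        assert spans(detect_choi(cpm)) == []

    def test_interruption_magnitude_is_irrelevant(self):
        cpm = trace((0, 45), (9999, 2), (0, 45))
        assert spans(detect_choi(cpm)) == [(0, 92)]

    def test_three_minute_interruption_splits(self):
        cpm = trace((0, 90), (5, 3), (0, 90))
        assert spans(detect_choi(cpm)) == [(0, 90), (93, 183)]

    def test_chained_interruptions_with_shared_flank(self):
        cpm = trace((0, 40), (5, 1), (0, 30), (5, 1), (0, 40))
        assert spans(detect_choi(cpm)) == [(0, 112)]


class TestOracleEquivalence:
    def test_all_rules_match_exhaustive_scan(self, rng):
        for _ in range(300):
            cpm = random_rule_trace(rng)
            n = len(cpm)
            for window in FIXED_WINDOWS.values():
                got = nonwear_mask(detect_fixed_window(cpm, window), n)
                np.testing.assert_array_equal(got, fixed_window_oracle(cpm, window))
            np.testing.assert_array_equal(
                nonwear_mask(detect_troiano(cpm), n), troiano_oracle(cpm)
            )
            np.testing.assert_array_equal(
                nonwear_mask(detect_choi(cpm), n), choi_oracle(cpm)
            )


class TestProperties:
    def test_nonwear_monotone_in_window_length(self, rng):
        windows = sorted(FIXED_WINDOWS.values())
        for _ in range(100):
            cpm = random_rule_trace(rng)
            minutes = [
                nonwear_mask(detect_fixed_window(cpm, w), len(cpm)).sum() for w in windows
            ]
            assert all(a >= b for a, b in zip(minutes, minutes[1:]))

    def test_determinism(self, rng):
        cpm = random_rule_trace(rng)
        for rule in RULE_NAMES:
            config = NonwearRuleConfig.for_rule(rule)
            assert detect(cpm, config) == detect(cpm, config)


class TestApplyRule:
    def make_series(self, cpm):
        return EpochSeries("S001", 1, 0, 60, cpm)

    def test_all_nonzero_day_has_no_periods(self):
        series = self.make_series(np.full(1440, 50))
        for rule in RULE_NAMES:
            _, nonwear, count = apply_rule(series, NonwearRuleConfig.for_rule(rule))
            assert count == 0 and nonwear == []

    def test_counts_separated_runs(self):
        cpm = np.full(1440, 50)
        for start in (100, 300, 500):
            cpm[start : start + 40] = 0
        _, _, count = apply_rule(self.make_series(cpm), NonwearRuleConfig.for_rule("fixed30"))
        assert count == 3

    def test_wear_and_nonwear_tile_the_day(self, rng):
        cpm = random_rule_trace(rng, max_len=1440)
        series = EpochSeries("S001", 1, 0, 60, cpm[: min(len(cpm), 1440)])
        for rule in RULE_NAMES:
            wear, nonwear, _ = apply_rule(series, NonwearRuleConfig.for_rule(rule))
            total = sum(iv.length for iv in wear + nonwear)
            assert total == series.n_epochs

    def test_reintegrates_finer_epochs(self):
        counts = np.zeros(1440 * 4, dtype=int)  # 15-s epochs, all zero
        series = EpochSeries("S001", 1, 0, 15, counts)
        _, nonwear, count = apply_rule(series, NonwearRuleConfig.for_rule("fixed60"))
        assert count == 1 and spans(nonwear) == [(0, 1440)]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown rule"):
            NonwearRuleConfig.for_rule("fixed45")


class TestConfig:
    def test_fixed_rules_admit_no_interruptions(self):
        with pytest.raises(ValueError):
            NonwearRuleConfig("fixed30", 30, max_interruption_min=2)

    def test_vector_magnitude_axis_is_supported(self):
        cpm = np.zeros(1440, dtype=int)
        series = EpochSeries(
            "S001", 1, 0, 60, cpm, counts_ap=cpm.copy(), counts_ml=cpm.copy()
        )
        config = NonwearRuleConfig.for_rule("choi", axis_mode="vector_magnitude")
        _, nonwear, _ = apply_rule(series, config)
        assert spans(nonwear) == [(0, 1440)]
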