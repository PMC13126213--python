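"""Stopping rules versus independent brute-force scan oracles."""

import numpy as np
import pytest

from screensim import (
    BreakoutRule,
    CombinedRule,
    DataDrivenRule,
    KeyStudyRule,
    MinimumFindsRule,
    TimeBasedRule,
    safe_phase1_check,
)
from screensim.stopping import rules_from_config

from conftest import make_trace


# ---------------------------------------------------------------------------
# Brute-force oracles: check every position by direct prefix inspection
# ---------------------------------------------------------------------------

def oracle_data_driven(labels, cutoff):
    for p in range(cutoff, len(labels) + 1):
        if all(lab == 0 for lab in labels[p - cutoff:p]):
            return p
    return None


def oracle_time_based(n_s, fraction):
    for p in range(1, n_s + 1):
        if p / n_s >= fraction - 1e-12:
            return p
    return n_s


def oracle_key_study(trace, key_ids):
    found = set()
    for p, rid in enumerate(trace.ordered_ids, start=1):
        if rid in key_ids:
            found.add(rid)
        if found == set(key_ids):
            return p
    raise AssertionError("keys missing from trace")


class TestDataDriven:
    def test_fifty_in_a_row_after_one_relevant(self):
        trace = make_trace([1] + [0] * 50 + [1, 0])
        assert DataDrivenRule(cutoff=50).first_met(trace) == 51

    def test_all_relevant_never_stops(self):
        trace = make_trace([1] * 30)
        assert DataDrivenRule(cutoff=5).first_met(trace) is None

    def test_cutoff_one_is_first_irrelevant(self):
        trace = make_trace([1, 1, 0, 1, 0])
        assert DataDrivenRule(cutoff=1).first_met(trace) == 3

    def test_fractional_cutoff_scales_with_trace(self):
        trace = make_trace([1] * 10 + [0] * 90)  # N_s=100, 5% -> run of 5
        assert DataDrivenRule(cutoff=0.05).first_met(trace) == 15


class TestTimeBased:
    @pytest.mark.parametrize(
        "fraction,n_s,expected",
        [(0.10, 1000, 100), (1.0, 57, 57), (0.35, 1800, 630), (0.333, 10, 4)],
    )
    def test_ceiling_arithmetic(self, fraction, n_s, expected):
        trace = make_trace([1] + [0] * (n_s - 1))
        rule = TimeBasedRule(fraction=fraction)
        assert rule.first_met(trace) == expected
        assert rule.first_met(trace) == oracle_time_based(n_s, fraction)


class TestKeyStudy:
    def test_last_key_position(self):
        trace = make_trace([0] * 20, key_positions=(2, 16))
        rule = KeyStudyRule(key_ids=frozenset({"t00002", "t00016"}))
        assert rule.first_met(trace) == 17  # positions are 1-based

    def test_single_key_first_position(self):
        trace = make_trace([1, 0, 0], key_positions=(0,))
        assert KeyStudyRule(key_ids=frozenset({"t00000"})).first_met(trace) == 1

    def test_scattered_keys_match_oracle(self):
        rng = np.random.default_rng(8)
        trace = make_trace(rng.integers(0, 2, 60))
        keys = frozenset(f"t{i:05d}" for i in rng.choice(60, 7, replace=False))
        rule = KeyStudyRule(key_ids=keys)
        assert rule.first_met(trace) == oracle_key_study(trace, keys)

    def test_absent_key_errors(self):
        trace = make_trace([1, 0])
        with pytest.raises(ValueError, match="absent"):
            KeyStudyRule(key_ids=frozenset({"ghost"})).first_met(trace)


class TestCombined:
    def test_all_met_takes_the_latest_member(self):
        # 50-run completes at 8% of N_s = 1000; time-based 10% waits to 100
        labels = [1] * 30 + [0] * 50 + list(np.tile([1, 0], 460))
        trace = make_trace(labels[:1000])
        rule = CombinedRule(
            members=(TimeBasedRule(0.10), DataDrivenRule(50))
        )
        assert rule.first_met(trace) == 100

    def test_key_study_at_final_position(self):
        trace = make_trace([0] * 49 + [1], key_positions=(49,))
        rule = CombinedRule(
            members=(TimeBasedRule(0.5), KeyStudyRule(frozenset({"t00049"})))
        )
        assert rule.first_met(trace) == 50

    def test_outcome_metrics_definitionally_consistent(self):
        from screensim import confusion_at, sensitivity

        rng = np.random.default_rng(1)
        trace = make_trace(rng.integers(0, 2, 80))
        rule = CombinedRule(members=(TimeBasedRule(0.3), DataDrivenRule(2)))
        outcome = rule.outcome(trace)
        assert outcome.sensitivity_at_stop == pytest.approx(
            sensitivity(confusion_at(trace, outcome.stop_position))
        )
        assert outcome.sc_at_stop == pytest.approx(outcome.stop_position / 80)

    def test_unsatisfiable_member_yields_none_with_diagnostics(self):
        trace = make_trace([1] * 20)
        rule = CombinedRule(members=(TimeBasedRule(0.5), DataDrivenRule(3)))
        outcome = rule.outcome(trace)
        assert outcome.stop_position is None
        assert "data_driven" in outcome.diagnostics

    def test_needs_two_members(self):
        with pytest.raises(ValueError):
            CombinedRule(members=(TimeBasedRule(0.5),))


class TestBreakout:
    def test_early_breakout_beats_fallback(self):
        # all 10 relevant inside the first 100 of 1000; a 150-run of
        # irrelevant then completes at position 250, before the 40% fallback
        labels = [1] * 10 + [0] * 990
        trace = make_trace(labels)
        rule = BreakoutRule(breakout_fraction=0.15,
                            fallback=TimeBasedRule(0.40))
        assert rule.first_met(trace) == 10 + 150

    def test_no_run_falls_back(self):
        labels = list(np.tile([1, 0, 0], 100))
        trace = make_trace(labels)
        rule = BreakoutRule(breakout_fraction=0.15, fallback=TimeBasedRule(0.40))
        assert rule.first_met(trace) == TimeBasedRule(0.40).first_met(trace)

    def test_late_run_clipped_to_fallback(self):
        labels = [1, 0] * 200 + [0] * 100   # long run only at the very end
        trace = make_trace(labels)
        rule = BreakoutRule(breakout_fraction=0.15, fallback=TimeBasedRule(0.10))
        assert rule.first_met(trace) == TimeBasedRule(0.10).first_met(trace)


class TestSafePhase1:
    def test_worked_example_satisfied(self):
        assert safe_phase1_check(2000, 200, 6)

    def test_below_minimum_screened(self):
        assert not safe_phase1_check(2000, 19, 2)

    def test_requires_a_relevant_find(self):
        assert not safe_phase1_check(2000, 200, 0)

    def test_one_percent_rules_when_large(self):
        assert not safe_phase1_check(50000, 400, 3)   # 1% = 500 > 100
        assert safe_phase1_check(50000, 500, 3)

    def test_cannot_screen_more_than_total(self):
        with pytest.raises(ValueError):
            safe_phase1_check(100, 101, 1)


class TestOracleEquivalence:
    def test_random_traces_match_brute_force(self):
        """Rules agree with direct prefix-scan oracles on random traces."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(10, 120))
            labels = (rng.random(n) < rng.uniform(0.05, 0.5)).astype(int)
            trace = make_trace(labels)
            cutoff = int(rng.integers(1, 10))
            frac = float(rng.uniform(0.05, 1.0))
            assert DataDrivenRule(cutoff).first_met(trace) == oracle_data_driven(
                labels.tolist(), cutoff
            )
            assert TimeBasedRule(frac).first_met(trace) == oracle_time_based(n, frac)
            dd = oracle_data_driven(labels.tolist(), cutoff)
            tb = oracle_time_based(n, frac)
            combined = CombinedRule(
                members=(DataDrivenRule(cutoff), TimeBasedRule(frac))
            ).first_met(trace)
            assert combined == (None if dd is None else max(dd, tb))
            breakout = BreakoutRule(
                breakout_fraction=0.2, fallback=TimeBasedRule(frac)
            ).first_met(trace)
            run_len = -(-n // 5)  # ceil(0.2 n)
            run_pos = oracle_data_driven(labels.tolist(), run_len)
            assert breakout == min([p for p in (run_pos, tb) if p is not None])

    def test_cost_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        labels = (rng.random(300) < 0.1).astype(int)
        trace = make_trace(labels)
        prev = 0
        for cutoff in (2, 5, 10, 20):
            pos = DataDrivenRule(cutoff).first_met(trace)
            if pos is None:
                break
            assert pos >= prev
            prev = pos


class TestMinimumFinds:
    def test_doubling_criterion(self):
        trace = make_trace([1, 0, 1, 0, 0, 1, 0, 1])
        assert MinimumFindsRule(min_tp=3).first_met(trace) == 6
        assert MinimumFindsRule(min_tp=5).first_met(trace) is None


def test_rules_from_config_round_trip():
    config = [
        {"rule": "data_driven", "cutoff": 50},
        {"rule": "time_based", "fraction": 0.1},
        {
            "rule": "combined",
            "members": [
                {"rule": "time_based", "fraction": 0.1},
                {"rule": "data_driven", "cutoff": 50},
                {"rule": "minimum_finds", "min_tp": 12},
            ],
        },
        {
            "rule": "breakout",
            "breakout_fraction": 0.15,
            "fallback": {"rule": "time_based", "fraction": 0.4},
        },
    ]
    rules = rules_from_config(config)
    assert [r.rule_id for r in rules] == [
        "data_driven", "time_based", "combined", "breakout"
    ]
    assert isinstance(rules[2].members[2], MinimumFindsRule)
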