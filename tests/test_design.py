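"""Design generator and validator unit tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pavcal.design import (
    CS_MINUS,
    CS_PLUS,
    DesignSpec,
    InfeasibleDesignError,
    Violation,
    generate_trial_sequence,
    max_run_length_of,
    validate_sequence,
)


def _naive_max_run(flags):
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


class TestMaxRunLength:
    def test_oracle_cases(self):
        assert max_run_length_of([]) == 0
        assert max_run_length_of([False, False]) == 0
        assert max_run_length_of([True]) == 1
        assert max_run_length_of([True, True, False, True]) == 2
        assert max_run_length_of([False, True, True, True]) == 3

    @given(st.lists(st.booleans(), max_size=50))
    @settings(max_examples=100, derandomize=True)
    def test_matches_naive_scan(self, flags):
        assert max_run_length_of(flags) == _naive_max_run(flags)


class TestGeneration:
    def test_deterministic(self):
        a = generate_trial_sequence(DesignSpec(), seed=42)
        b = generate_trial_sequence(DesignSpec(), seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_trial_sequence(DesignSpec(), seed=0)
        b = generate_trial_sequence(DesignSpec(), seed=1)
        assert not a["condition"].equals(b["condition"])

    def test_counts(self, learning_events):
        tbl = learning_events
        assert len(tbl) == 96
        assert (tbl["condition"] == CS_PLUS).sum() == 48
        assert (tbl["condition"] == CS_MINUS).sum() == 48
        assert tbl["reinforced"].sum() == 24
        for _, grp in tbl.groupby("block"):
            assert (grp["condition"] == CS_PLUS).sum() == 24
            assert (grp["condition"] == CS_MINUS).sum() == 24
            assert grp["reinforced"].sum() == 12

    def test_first_csplus_reinforced_per_block(self, learning_events):
        for _, grp in learning_events.groupby("block"):
            plus = grp[grp["condition"] == CS_PLUS]
            assert bool(plus.iloc[0]["reinforced"])

    def test_run_lengths(self, learning_events):
        cond = learning_events["condition"].to_numpy()
        for lab in (CS_PLUS, CS_MINUS):
            assert max_run_length_of(cond == lab) <= 3
        assert max_run_length_of(learning_events["reinforced"].to_numpy()) <= 3

    def test_no_reinforced_csminus(self, learning_events):
        bad = (learning_events["condition"] == CS_MINUS) & learning_events["reinforced"]
        assert not bad.any()

    def test_recall_has_no_reinforcement(self):
        tbl = generate_trial_sequence(DesignSpec(), phase="recall", seed=5)
        assert not tbl["reinforced"].any()
        assert tbl["us_onset"].isna().all()

    def test_timing_arithmetic(self, learning_events):
        spec = DesignSpec()
        on = learning_events["cs_onset"].to_numpy()
        iti = learning_events["iti_duration"].to_numpy()
        np.testing.assert_allclose(np.diff(on), spec.cs_duration + iti[:-1])
        reinforced = learning_events["reinforced"].to_numpy(bool)
        us = learning_events["us_onset"].to_numpy()
        np.testing.assert_allclose(us[reinforced], on[reinforced] + spec.soa)
        assert np.isnan(us[~reinforced]).all()

    def test_iti_integer_range_coverage(self):
        seen = set()
        for seed in range(30):
            tbl = generate_trial_sequence(DesignSpec(), seed=seed)
            itis = tbl["iti_duration"].to_numpy()
            assert np.all(itis == itis.astype(int))
            assert itis.min() >= 9 and itis.max() <= 16
            seen.update(int(v) for v in itis)
        assert seen == set(range(9, 17))

    def test_swallow_cue_inside_iti(self, learning_events):
        spec = DesignSpec()
        delay = (
            learning_events["swallow_onset"]
            - learning_events["cs_onset"]
            - spec.cs_duration
        )
        assert (delay >= spec.swallow_delay_min).all()
        assert (delay <= spec.swallow_delay_max).all()

    def test_invalid_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            generate_trial_sequence(DesignSpec(), phase="extinction", seed=0)

    def test_infeasible_design_raises(self):
        spec = DesignSpec(
            trials_per_condition_per_block=8, max_run_length=1, reinforcement_rate=1.0
        )
        with pytest.raises(InfeasibleDesignError):
            generate_trial_sequence(spec, seed=0, max_retries=50)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_any_seed_yields_valid_table(self, seed):
        spec = DesignSpec()
        tbl = generate_trial_sequence(spec, seed=seed)
        assert validate_sequence(tbl, spec) == []


class TestValidation:
    def test_clean_table_validates(self, learning_events):
        assert validate_sequence(learning_events, DesignSpec()) == []

    def test_detects_reinforced_csminus(self, learning_events):
        tbl = learning_events.copy()
        row = tbl.index[tbl["condition"] == CS_MINUS][0]
        tbl.loc[row, "reinforced"] = True
        rules = {v.rule for v in validate_sequence(tbl, DesignSpec())}
        assert "csminus_reinforced" in rules

    def test_detects_run_violation(self, learning_events):
        tbl = learning_events.copy()
        tbl.loc[tbl.index[:5], "condition"] = CS_PLUS
        rules = {v.rule for v in validate_sequence(tbl, DesignSpec())}
        assert "cs_run_length" in rules

    def test_detects_bad_iti(self, learning_events):
        tbl = learning_events.copy()
        tbl.loc[tbl.index[0], "iti_duration"] = 99
        rules = {v.rule for v in validate_sequence(tbl, DesignSpec())}
        assert "iti_range" in rules

    def test_detects_bad_us_onset(self, learning_events):
        tbl = learning_events.copy()
        row = tbl.index[tbl["reinforced"]][0]
        tbl.loc[row, "us_onset"] += 1.0
        rules = {v.rule for v in validate_sequence(tbl, DesignSpec())}
        assert "us_onset" in rules

    def test_detects_unreinforced_first_csplus(self, learning_events):
        tbl = learning_events.copy()
        plus = tbl[tbl["condition"] == CS_PLUS]
        first = plus.index[0]
        # move its reinforcement to another CS+ so counts stay right
        other = plus.index[~plus["reinforced"]][0]
        tbl.loc[first, "reinforced"] = False
        tbl.loc[first, "us_onset"] = np.nan
        tbl.loc[other, "reinforced"] = True
        tbl.loc[other, "us_onset"] = tbl.loc[other, "cs_onset"] + 5.0
        rules = {v.rule for v in validate_sequence(tbl, DesignSpec())}
        assert "first_csplus_reinforced" in rules

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            validate_sequence(pd.DataFrame(columns=["condition"]), DesignSpec())

    def test_violation_reports_rows(self, learning_events):
        tbl = learning_events.copy()
        tbl.loc[tbl.index[3], "iti_duration"] = 99
        v = [x for x in validate_sequence(tbl, DesignSpec()) if x.rule == "iti_range"][0]
        assert isinstance(v, Violation)
        assert 3 in v.rows


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"trials_per_condition_per_block": 0},
            {"n_blocks": 0},
            {"reinforcement_rate": 1.5},
            {"iti_min": 20, "iti_max": 10},
            {"max_run_length": 0},
            {"soa": 7.0},  # must be < cs_duration
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DesignSpec(**kwargs).validate()

    def test_derived_counts(self):
        spec = DesignSpec()
        assert spec.trials_per_block == 48
        assert spec.n_trials == 96
        assert spec.reinforced_per_block == 12
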