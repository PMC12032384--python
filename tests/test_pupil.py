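"""Pupil pipeline: preprocessing, scoring arithmetic, exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from pavcal.design import CS_MINUS, CS_PLUS
from pavcal.pupil import (
    PupilExclusionSpec,
    PupilPreprocSpec,
    _speed_outliers,
    _trim_gap_edges,
    apply_pupil_exclusions,
    extract_pupil_segments,
    peak_score,
    preprocess_pupil,
    psr_amplitudes,
)
from pavcal.response_functions import get_rf
from pavcal.timeseries import TimeSeries


def _pupil_series(duration=60.0, rate=100.0, level=3.5):
    n = int(duration * rate)
    return TimeSeries(np.full(n, level), rate, units="mm"), np.zeros(n), np.zeros(n)


class TestSpeedFilter:
    def test_blink_edge_flagged(self):
        v = np.full(1000, 3.5)
        v[500] = 2.0  # 150 mm/s transient at 100 Hz
        bad = _speed_outliers(v, 100.0, 16.0)
        assert bad[500]

    def test_clean_signal_untouched_via_floor(self):
        """A noiseless smooth dilation must not be flagged even though the
        speed MAD collapses to ~zero (absolute 1 mm/s floor)."""
        t = np.arange(0.0, 10.0, 0.01)
        v = 3.5 + 0.3 * np.sin(2 * np.pi * 0.2 * t)  # max speed ~0.38 mm/s
        bad = _speed_outliers(v, 100.0, 16.0, floor=1.0)
        assert not bad.any()

    def test_trim_gap_edges(self):
        bad = np.zeros(10, dtype=bool)
        bad[5] = True
        out = _trim_gap_edges(bad, 2)
        np.testing.assert_array_equal(np.flatnonzero(out), [3, 4, 5, 6, 7])


class TestPreprocess:
    def test_range_and_gaze_gating(self):
        ts, gx, gy = _pupil_series()
        ts.values[100:150] = 0.5  # below plausible range
        gx[1000:1100] = 8.0  # beyond the 5 degree gaze limit
        out = preprocess_pupil(ts, gx, gy, spec=PupilPreprocSpec(zscore=False))
        assert out.missing[out.index_at(1.2)]
        assert out.missing[out.index_at(10.5)]
        assert not out.missing[out.index_at(30.0)]

    def test_foreshortening_correction(self):
        ts, gx, gy = _pupil_series(level=3.0)
        gx[:] = 3.0
        gy[:] = 4.0  # 5 degrees total deviation, at the gate boundary
        out = preprocess_pupil(ts, gx, gy, spec=PupilPreprocSpec(zscore=False))
        expected = 3.0 / np.cos(np.deg2rad(5.0))
        assert out.values[out.index_at(30.0)] == pytest.approx(expected, rel=1e-6)

    def test_blockwise_zscore(self):
        rate = 100.0
        n = int(200 * rate)
        rng = np.random.default_rng(0)
        vals = 3.5 + 0.2 * rng.standard_normal(n)
        vals[n // 2 :] += 1.0  # different level in block 2
        ts = TimeSeries(vals, rate, units="mm")
        events = pd.DataFrame(
            {
                "trial_index": [0, 1],
                "block": [0, 1],
                "condition": [CS_PLUS, CS_MINUS],
                "reinforced": [False, False],
                "cs_onset": [50.0, 150.0],
            }
        )
        out = preprocess_pupil(ts, np.zeros(n), np.zeros(n), events)
        assert out.units == "z"
        half = out.n // 2
        for chunk in (out.values[:half], out.values[half:]):
            assert abs(chunk.mean()) < 0.05
            assert chunk.std() == pytest.approx(1.0, abs=0.05)

    def test_fully_missing_raises(self):
        ts, gx, gy = _pupil_series(level=0.5)  # everything implausible
        with pytest.raises(ValueError, match="entirely missing"):
            preprocess_pupil(ts, gx, gy, spec=PupilPreprocSpec(zscore=False))


class TestSegmentScoring:
    def _events(self, onsets, conditions, reinforced=None):
        n = len(onsets)
        return pd.DataFrame(
            {
                "trial_index": np.arange(n),
                "condition": conditions,
                "reinforced": reinforced or [False] * n,
                "cs_onset": np.asarray(onsets, float),
            }
        )

    def test_projection_recovers_kernel_multiple(self):
        rf = get_rf("psr_rf5")
        rate = 100.0
        n = int(60 * rate)
        vals = np.zeros(n)
        rfn = rf.normalized()
        grid = np.arange(0.0, rf.window, 1.0 / rate)
        k0 = int(20.0 * rate)
        vals[k0 : k0 + grid.size] = 0.4 * rfn.evaluate(grid)
        ts = TimeSeries(vals, rate, units="mm")
        ev = self._events([20.0], [CS_PLUS])
        segs = extract_pupil_segments(ts, ev, rf)
        est = psr_amplitudes(segs, rf)
        assert est.loc[0, "amplitude"] == pytest.approx(0.4, rel=1e-6)

    def test_rf1_drops_reinforced_csplus(self):
        ts = TimeSeries(np.zeros(12000), 100.0, units="mm")
        ev = self._events(
            [20.0, 50.0, 80.0],
            [CS_PLUS, CS_PLUS, CS_MINUS],
            reinforced=[True, False, False],
        )
        segs = extract_pupil_segments(ts, ev, get_rf("psr_rf1"))
        assert list(segs.meta["trial_index"]) == [1, 2]
        # short kernels keep all trials
        segs5 = extract_pupil_segments(ts, ev, get_rf("psr_rf5"))
        assert list(segs5.meta["trial_index"]) == [0, 1, 2]

    def test_missing_baseline_marks_trial(self):
        ts = TimeSeries(np.zeros(12000), 100.0, units="mm")
        ts.missing[1900:2000] = True  # the second before onset at 20 s
        ev = self._events([20.0], [CS_PLUS])
        segs = extract_pupil_segments(ts, ev, get_rf("psr_rf5"))
        assert np.isnan(segs.data[0]).all()
        assert segs.meta.loc[0, "missing_fraction"] == 1.0

    def test_peak_score_arithmetic(self):
        rate = 100.0
        n = int(60 * rate)
        vals = np.full(n, 2.0)
        k0 = int(20.0 * rate)
        vals[k0 + 100 : k0 + 200] = 2.9  # peak 1-2 s post-onset
        vals[k0 + 450 : k0 + 480] = 2.5  # peak in the final pre-US second
        ts = TimeSeries(vals, rate, units="mm")
        ev = self._events([20.0], [CS_PLUS])
        finke = peak_score(ts, ev, method="finke")
        assert finke.loc[0, "amplitude"] == pytest.approx(0.9)
        pietrock = peak_score(ts, ev, method="pietrock")
        assert pietrock.loc[0, "amplitude"] == pytest.approx(0.5)

    def test_peak_score_unknown_method(self):
        ts = TimeSeries(np.zeros(600), 10.0)
        with pytest.raises(ValueError, match="method"):
            peak_score(ts, self._events([20.0], [CS_PLUS]), method="max")


class TestExclusions:
    def _frame(self, amps, missing=None):
        n = len(amps)
        df = pd.DataFrame(
            {
                "trial_index": np.arange(n),
                "condition": [CS_PLUS] * n,
                "reinforced": [False] * n,
                "amplitude": amps,
            }
        )
        if missing is not None:
            df["missing_fraction"] = missing
        return df

    def test_amplitude_gate(self):
        kept, excluded = apply_pupil_exclusions(self._frame([0.5, 7.0, -6.5, 1.0]))
        assert list(kept["trial_index"]) == [0, 3]
        assert not excluded  # exactly half dropped is not > 0.5

    def test_participant_excluded_when_most_trials_drop(self):
        kept, excluded = apply_pupil_exclusions(self._frame([0.5, 7.0, -6.5, np.nan]))
        assert list(kept["trial_index"]) == [0]
        assert excluded

    def test_participant_threshold_strictly_greater(self):
        # exactly half dropped does not exclude the participant
        kept, excluded = apply_pupil_exclusions(self._frame([0.5, 7.0, 1.0, -8.0]))
        assert len(kept) == 2
        assert not excluded

    def test_missing_fraction_gate(self):
        kept, excluded = apply_pupil_exclusions(
            self._frame([0.5, 0.5, 0.5], missing=[0.0, 0.6, 0.2])
        )
        assert list(kept["trial_index"]) == [0, 2]

    def test_nan_amplitude_dropped(self):
        kept, _ = apply_pupil_exclusions(self._frame([np.nan, 1.0, 1.0]))
        assert list(kept["trial_index"]) == [1, 2]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no trial"):
            apply_pupil_exclusions(self._frame([]))

    def test_spec_defaults(self):
        spec = PupilExclusionSpec()
        assert spec.max_abs_estimate_mm == 6.0
        assert spec.max_missing_fraction_per_trial == 0.5
        assert spec.max_excluded_trials_fraction == 0.5


class TestCohortRecovery:
    def test_noiseless_mm_recovery(self, noiseless_recording):
        from pavcal.pipeline import analyze_pupil

        rec = noiseless_recording
        est, excluded = analyze_pupil(rec, units="mm")
        assert not excluded
        truth = rec.truth
        for cond in (CS_PLUS, CS_MINUS):
            t_amp = truth.loc[truth["condition"] == cond, "pupil"].iloc[0]
            got = est.loc[est["condition"] == cond, "amplitude"].mean()
            assert got == pytest.approx(t_amp, rel=0.02)
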