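"""Effect-size statistics: oracles against closed forms and brute force."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pavcal.design import CS_MINUS, CS_PLUS
from pavcal.stats import (
    EffectSizeResult,
    calibration_report,
    correction_factor,
    exclude_outliers_3sd,
    halves_analysis,
    hedges_g,
    holm_bonferroni,
    paired_test_rejection_rate,
    paired_ttest,
    trial_subset_scan,
)


class TestCorrectionFactor:
    def test_exact_small_df_oracle(self):
        # direct closed form via math.gamma for a range of df
        for df in range(2, 60):
            exact = math.gamma(df / 2) / (math.sqrt(df / 2) * math.gamma((df - 1) / 2))
            assert correction_factor(df) == pytest.approx(exact, rel=1e-12)

    def test_approximation_agreement(self):
        for df in (10, 30, 100):
            approx = 1.0 - 3.0 / (4.0 * df - 1.0)
            assert correction_factor(df) == pytest.approx(approx, rel=1e-3)

    def test_less_than_one_and_increasing(self):
        vals = [correction_factor(df) for df in range(2, 50)]
        assert all(v < 1.0 for v in vals)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_df_validation(self):
        with pytest.raises(ValueError):
            correction_factor(0)


class TestHedgesG:
    @pytest.mark.parametrize(
        "t,n,expected",
        [
            (3.51, 37, 0.56),
            (2.48, 37, 0.40),
            (4.56, 33, 0.78),
            (3.26, 33, 0.55),
            (2.15, 34, 0.36),
            (1.98, 33, 0.34),
            (-1.67, 33, -0.28),
        ],
    )
    def test_reference_values(self, t, n, expected):
        assert round(hedges_g(t, n), 2) == expected

    def test_sign_follows_t(self):
        assert hedges_g(-2.0, 20) == -hedges_g(2.0, 20)

    def test_n_validation(self):
        with pytest.raises(ValueError):
            hedges_g(1.0, 1)


class TestPairedTTest:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(25) + 0.4
        y = rng.standard_normal(25)
        res = paired_ttest(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == 24
        assert res.g == pytest.approx(hedges_g(res.t, 25), rel=1e-12)

    def test_one_sided_halves_p_for_positive_t(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20) + 1.0
        y = rng.standard_normal(20)
        two = paired_ttest(x, y, sides="two")
        one = paired_ttest(x, y, sides="one")
        assert one.p == pytest.approx(two.p / 2.0, rel=1e-12)

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 2.5])
        y = np.array([0.5, 1.0, 1.0, np.nan, 2.0])
        res = paired_ttest(x, y)
        assert res.n == 3

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_errors(self):
        with pytest.raises(ValueError, match="paired"):
            paired_ttest([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="two complete pairs"):
            paired_ttest([1.0], [0.0])
        with pytest.raises(ValueError, match="sides"):
            paired_ttest([1.0, 2.0, 1.5], [0.0, 1.0, 0.2], sides="both")

    def test_result_df_contract(self):
        with pytest.raises(ValueError, match="df"):
            EffectSizeResult(t=1.0, df=10, n=10, p=0.5, g=0.1)


class TestOutlierExclusion:
    def test_oracle(self):
        # 19 well-behaved participants plus one at 50: z = 4.25 > 3
        rng = np.random.default_rng(0)
        x = np.concatenate([0.1 * rng.standard_normal(19), [50.0]])
        y = 0.1 * rng.standard_normal(20)
        keep = exclude_outliers_3sd(x, y)
        assert not keep[19]
        assert keep[:19].all()
        # oracle: condition-wise mean +- 3 sd with the full sample
        np.testing.assert_array_equal(
            keep,
            (np.abs(x - x.mean()) <= 3 * x.std(ddof=1))
            & (np.abs(y - y.mean()) <= 3 * y.std(ddof=1)),
        )

    def test_single_pass_not_iterated(self):
        # with 1000 included the sd is inflated, so 6.0 stays within 3 sd;
        # after removal it would not - a single pass must keep it
        rng = np.random.default_rng(1)
        x = np.concatenate([0.3 * rng.standard_normal(19), [6.0, 1000.0]])
        y = 0.1 * rng.standard_normal(21)
        keep = exclude_outliers_3sd(x, y)
        assert not keep[20]
        assert keep[19]

    def test_needs_three(self):
        with pytest.raises(ValueError):
            exclude_outliers_3sd([1.0, 2.0], [0.0, 1.0])


class TestTrialSubsetScan:
    def _trials(self):
        rows = []
        rng = np.random.default_rng(2)
        for pid in range(6):
            for i in range(8):
                cond = CS_PLUS if i % 2 == 0 else CS_MINUS
                rows.append(
                    {
                        "participant": pid,
                        "trial_index": i,
                        "condition": cond,
                        "reinforced": cond == CS_PLUS and i == 0,
                        "amplitude": (1.0 if cond == CS_PLUS else 0.0)
                        + 0.3 * rng.standard_normal(),
                    }
                )
        return pd.DataFrame(rows)

    def test_standard_scheme_row_count_and_oracle(self):
        trials = self._trials()
        scan = trial_subset_scan(trials, scheme="standard")
        assert list(scan["n_trials"]) == [1, 2, 3, 4]
        # oracle for n=1: first CS+ vs first CS- per participant
        xs, ys = [], []
        for _, grp in trials.groupby("participant"):
            xs.append(grp[grp["condition"] == CS_PLUS].iloc[0]["amplitude"])
            ys.append(grp[grp["condition"] == CS_MINUS].iloc[0]["amplitude"])
        ref = paired_ttest(xs, ys)
        assert scan.loc[0, "g"] == pytest.approx(ref.g, rel=1e-12)

    def test_nonreinforced_scheme_uses_double_csminus(self):
        trials = self._trials()
        scan = trial_subset_scan(trials, scheme="nonreinforced")
        # 3 nonreinforced CS+ per participant, 4 CS- -> max n = min(3, 4 // 2)
        assert list(scan["n_trials"]) == [1, 2]

    def test_skip_first_pair(self):
        trials = self._trials()
        scan = trial_subset_scan(trials, skip_first_pair=True)
        assert list(scan["n_trials"]) == [1, 2, 3]

    def test_bad_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            trial_subset_scan(self._trials(), scheme="late")


class TestHalvesAndHolm:
    def test_halves_analysis(self):
        rng = np.random.default_rng(3)
        def half():
            return pd.DataFrame(
                {
                    "participant": range(10),
                    "cs_plus": rng.standard_normal(10) + 1.0,
                    "cs_minus": rng.standard_normal(10),
                }
            )
        h1, h2 = halves_analysis(half(), half())
        assert h1.n == h2.n == 10
        assert h1.t != h2.t

    def test_holm_matches_bruteforce(self):
        p = np.array([0.011, 0.04, 0.002, 0.3])
        adj, rej = holm_bonferroni(p, alpha=0.05)
        # brute-force step-down
        order = np.argsort(p)
        m = p.size
        brute = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            brute[idx] = min(running, 1.0)
        np.testing.assert_allclose(adj, brute, rtol=1e-12)
        np.testing.assert_array_equal(rej, brute <= 0.05)

    def test_holm_empty(self):
        with pytest.raises(ValueError):
            holm_bonferroni([])


class TestCalibrationReport:
    def _estimates(self, n=20, shift=1.0, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "participant": range(n),
                "cs_plus": rng.standard_normal(n) + shift,
                "cs_minus": rng.standard_normal(n),
            }
        )

    def test_retention_flag(self):
        rep = calibration_report(
            {"strong": self._estimates(shift=1.5), "null": self._estimates(shift=0.0, seed=5)}
        )
        strong = rep[rep["channel"] == "strong"].iloc[0]
        null = rep[rep["channel"] == "null"].iloc[0]
        assert strong["retained"] and strong["g"] > 0.5
        assert not null["retained"]

    def test_insufficient_pairs_reported_nan(self):
        df = pd.DataFrame(
            {"participant": [0], "cs_plus": [1.0], "cs_minus": [0.0]}
        )
        rep = calibration_report({"tiny": df})
        assert np.isnan(rep.iloc[0]["g"])
        assert not rep.iloc[0]["retained"]

    def test_3sd_exclusion_applied(self):
        df = self._estimates()
        df.loc[0, "cs_plus"] = 1e6
        rep = calibration_report({"ch": df})
        assert rep.iloc[0]["n"] == len(df) - 1


class TestRejectionRate:
    def test_null_calibration(self):
        rate = paired_test_rejection_rate(4000, n=20, effect=0.0, seed=1)
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_power_increases_with_effect(self):
        low = paired_test_rejection_rate(2000, n=20, effect=0.2, seed=2)
        high = paired_test_rejection_rate(2000, n=20, effect=0.8, seed=2)
        assert high > low

    def test_one_sided_more_powerful(self):
        two = paired_test_rejection_rate(2000, n=20, effect=0.5, sides="two", seed=3)
        one = paired_test_rejection_rate(2000, n=20, effect=0.5, sides="one", seed=3)
        assert one > two

    def test_bad_sides(self):
        with pytest.raises(ValueError):
            paired_test_rejection_rate(10, 5, 0.0, sides="three")
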