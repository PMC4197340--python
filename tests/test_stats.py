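"""Paired tests, table arithmetic, ICC and sample size, each checked
against an independent oracle (exact permutation, pingouin, statsmodels,
Monte-Carlo simulation)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tarsokin.errors import ContractViolationError
from tarsokin.stats import (build_summary_tables, icc_consistency,
                            mean_difference_from_summary, paired_sample_size,
                            paired_t, round_half_away)


def signflip_p(d):
    """Exact two-sided sign-flip permutation p for paired differences."""
    d = np.asarray(d, float)
    n = len(d)
    t_obs = abs(d.mean() / (d.std(ddof=1) / np.sqrt(n)))
    count = 0
    total = 0
    for signs in itertools.product([1.0, -1.0], repeat=n):
        x = d * signs
        t = abs(x.mean() / (x.std(ddof=1) / np.sqrt(n)))
        count += t >= t_obs - 1e-12
        total += 1
    return count / total


class TestPairedT:
    def test_matches_scipy(self, rng):
        a = rng.normal(0, 2, 9)
        b = rng.normal(1, 2, 9)
        res = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.mean_difference == pytest.approx((a - b).mean(), abs=1e-12)

    def test_identical_samples_degenerate(self):
        a = np.arange(5.0)
        with pytest.raises(ContractViolationError):
            paired_t(a, a)

    def test_scale_invariance(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 8)
        r1 = paired_t(a, b)
        r2 = paired_t(10 * a, 10 * b)
        assert r2.t == pytest.approx(r1.t, abs=1e-10)
        assert r2.p == pytest.approx(r1.p, abs=1e-10)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ContractViolationError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMeanDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (3.2, 0.7, 2.5),            # subtalar eversion, late period
        (-20.5, -17.9, -2.6),       # talocrural flexion at toe contact
        (4.0, 4.0, 0.0),
        (1.58, 1.39, 0.2),          # peak vGRF per body weight
    ])
    def test_summary_cells(self, a, b, expected):
        assert mean_difference_from_summary(a, b) == pytest.approx(expected)

    def test_round_half_away_from_zero(self):
        assert round_half_away(0.05, 1) == 0.1
        assert round_half_away(-0.05, 1) == -0.1
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(-2.25, 1) == -2.3


class TestICC:
    def test_identical_columns_perfect(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0], [7.0]]), (1, 3))
        assert icc_consistency(X) == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        X = rng.normal(size=(6, 3)) + rng.normal(0, 3, size=(6, 1))
        df = pd.DataFrame({
            "item": np.repeat(np.arange(6), 3),
            "rater": np.tile(np.arange(3), 6),
            "y": X.ravel()})
        ref = pingouin.intraclass_corr(df, targets="item", raters="rater",
                                       ratings="y")
        # consistency, single rater: labelled ICC3 or ICC(C,1) by version
        mask = ref["Type"].isin(["ICC3", "ICC(C,1)"])
        icc3 = ref.loc[mask, "ICC"].iloc[0]
        assert icc_consistency(X) == pytest.approx(icc3, abs=1e-9)

    def test_small_matrix_anova_oracle(self):
        X = np.array([[9.0, 10.0, 8.0],
                      [6.0, 7.0, 6.5],
                      [8.0, 8.5, 7.0],
                      [7.0, 6.0, 6.0]])
        # explicit two-way ANOVA mean squares
        n, k = X.shape
        msr = k * np.var(X.mean(1), ddof=1)
        grand = X.mean()
        ss_err = (((X - X.mean(1, keepdims=True) - X.mean(0, keepdims=True)
                    + grand) ** 2).sum())
        mse = ss_err / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse)
        assert icc_consistency(X) == pytest.approx(expected, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        X = rng.normal(size=(50, 3))
        assert abs(icc_consistency(X)) < 0.3

    def test_too_small_rejected(self):
        with pytest.raises(ContractViolationError):
            icc_consistency(np.ones((1, 3)))


class TestSampleSize:
    def test_matches_statsmodels(self):
        sm_power = pytest.importorskip("statsmodels.stats.power")
        for d in (0.8, 1.2, 1.5, 2.0):
            n = paired_sample_size(d, alpha=0.05, power=0.9)
            ref = sm_power.TTestPower().solve_power(
                effect_size=d, alpha=0.05, power=0.9,
                alternative="two-sided")
            assert n == int(np.ceil(ref))

    def test_returned_n_achieves_power_by_simulation(self, rng):
        d = 1.5
        n = paired_sample_size(d, alpha=0.05, power=0.9)
        reps = 20_000
        for m, expect_reach in ((n, True), (n - 1, False)):
            x = rng.normal(d, 1.0, size=(reps, m))
            t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(m))
            p = 2 * sps.t.sf(np.abs(t), df=m - 1)
            power = (p < 0.05).mean()
            if expect_reach:
                assert power >= 0.9 - 0.01
            else:
                assert power < 0.9 + 0.01

    def test_monotone_in_effect_size(self):
        ns = [paired_sample_size(d) for d in (0.5, 0.8, 1.2, 2.0)]
        assert ns == sorted(ns, reverse=True)

    def test_stricter_alpha_needs_more(self):
        assert (paired_sample_size(1.0, alpha=0.01)
                >= paired_sample_size(1.0, alpha=0.05))

    def test_invalid_inputs(self):
        with pytest.raises(ContractViolationError):
            paired_sample_size(0.0)
        with pytest.raises(ContractViolationError):
            paired_sample_size(1.0, alpha=1.5)


@pytest.fixture(scope="module")
def cohort():
    from tarsokin.synthetic import CohortSpec, make_cohort
    return make_cohort(CohortSpec(n_subjects=7, n_trials=2, seed=11))


class TestSummaryTables:
    def test_recovers_true_mean_differences(self, cohort):
        trials, effects = cohort
        table1, table2, comparisons = build_summary_tables(trials)
        for key in ("tc|talocrural|dorsiflexion", "tc|subtalar|eversion"):
            true_d = effects.loc[effects.variable == key,
                                 "true_difference"].mean()
            meas = comparisons[key].mean_difference
            # measurement noise 0.25 deg/frame, 2 trials averaged
            assert meas == pytest.approx(true_d, abs=0.5)
        assert len(table1) == 6
        assert len(table2) == 13

    def test_peak_vgrf_row(self, cohort):
        trials, effects = cohort
        _, table2, comparisons = build_summary_tables(trials)
        c = comparisons["peak_vgrf_bw"]
        true_d = effects.loc[effects.variable == "peak_vgrf_bw",
                             "true_difference"].mean()
        assert c.mean_difference == pytest.approx(true_d, abs=0.05)

    def test_single_subject_refuses_between_subject_stats(self, cohort):
        trials, _ = cohort
        solo = [t for t in trials if t.subject == "S01"]
        t1, t2, comparisons = build_summary_tables(solo)
        c = comparisons["tc|talocrural|dorsiflexion"]
        assert np.isnan(c.t) and np.isnan(c.p)
        assert len(t1) == 6                     # table still emitted

    def test_identical_conditions_null(self, rng):
        from tarsokin.events import TrialRecord
        from tarsokin.synthetic import CohortSpec, make_cohort
        trials, _ = make_cohort(CohortSpec(n_subjects=5, n_trials=1,
                                           seed=3,
                                           between_subject_scale=1.0))
        # clone barefoot trials as "shod" with fresh measurement noise:
        # the two conditions then differ only by noise
        from tarsokin.kinematics import JointAngleSeries
        cloned = []
        for t in trials:
            if t.condition != "barefoot":
                continue
            cloned.append(t)
            noisy = {j: JointAngleSeries(
                joint=j, time_ms=s.time_ms,
                dorsiflexion=s.dorsiflexion + rng.normal(0, 0.2, s.time_ms.shape),
                eversion=s.eversion + rng.normal(0, 0.2, s.time_ms.shape),
                external_rotation=(s.external_rotation
                                   + rng.normal(0, 0.2, s.time_ms.shape)))
                for j, s in t.angles.items()}
            cloned.append(TrialRecord(subject=t.subject, condition="shod",
                                      trial_index=t.trial_index,
                                      angles=noisy, grf=t.grf,
                                      events=t.events))
        _, _, comparisons = build_summary_tables(cloned)
        c = comparisons["tc|talocrural|dorsiflexion"]
        assert abs(c.mean_difference) < 0.5
        assert c.p > 0.05
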