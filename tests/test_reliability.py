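"""Reliability statistics: ANOVA arithmetic, ICC forms and CIs (checked
against an independent implementation), correlations, regressions."""

import numpy as np
import pandas as pd
import pytest

import reachtrack as rt
from reachtrack.reliability import (SubjectTrialMatrix, fisher_ci,
                                    subject_trial_matrix)
from reachtrack.synth import sigma_b_for_icc2k, simulate_metric_matrix


def _matrix(values, metric="speed_mmps"):
    v = np.asarray(values, float)
    return SubjectTrialMatrix(metric, v, np.arange(len(v), dtype=float) + 50)


class TestAnova:
    def test_identical_trials_have_zero_msc_mse(self):
        m = _matrix([[1, 1], [2, 2], [3, 3]])
        msr, msc, mse = rt.anova_two_way_no_rep(m)
        assert msc == pytest.approx(0.0, abs=1e-12)
        assert mse == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_4x2_matrix(self):
        # rows (1,2),(3,4),(5,6),(7,8): grand mean 4.5, row means
        # 1.5/3.5/5.5/7.5 -> SSR = 40, MSR = 40/3; col means 4, 5 ->
        # SSC = 2, MSC = 2; total SS = 42 -> SSE = 0
        m = _matrix([[1, 2], [3, 4], [5, 6], [7, 8]])
        msr, msc, mse = rt.anova_two_way_no_rep(m)
        assert msr == pytest.approx(40.0 / 3.0, abs=1e-12)
        assert msc == pytest.approx(2.0, abs=1e-12)
        assert mse == pytest.approx(0.0, abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(12, 2))
        a = rt.anova_two_way_no_rep(_matrix(v))
        b = rt.anova_two_way_no_rep(_matrix(v[rng.permutation(12)]))
        assert a == pytest.approx(b, abs=1e-12)

    def test_missing_cells_rejected(self):
        v = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
        with pytest.raises(ValueError, match="missing"):
            _matrix(v)


class TestICC:
    def test_identical_columns_give_icc_1(self):
        r = rt.icc_2k(_matrix([[1, 1], [2, 2], [3, 3], [4, 4]]))
        assert r.icc == pytest.approx(1.0, abs=1e-12)
        assert r.icc3k == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_4x2_value(self):
        # MSR = 40/3, MSC = 2, MSE = 0, n = 4:
        # ICC(2,k) = MSR / (MSR + MSC/4) = (40/3)/(40/3 + 0.5)
        r = rt.icc_2k(_matrix([[1, 2], [3, 4], [5, 6], [7, 8]]))
        assert r.icc == pytest.approx((40 / 3) / (40 / 3 + 0.5), abs=1e-12)

    def test_zero_subject_variance_reports_zero(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            r = rt.icc_2k(_matrix([[2.0, 3.0]] * 5))
        assert r.icc == 0.0

    def test_matches_independent_implementation(self):
        """Point estimates and CIs agree with pingouin's two-way forms."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        v = rng.normal(0, 1, (40, 2)) + rng.normal(0, 1.2, (40, 1)) \
            + np.array([0.0, 0.3])
        r = rt.icc_2k(_matrix(v))
        df = pd.DataFrame({"subj": np.repeat(np.arange(40), 2),
                           "rater": np.tile([1, 2], 40),
                           "y": v.ravel()})
        ref = pg.intraclass_corr(df, "subj", "rater", "y").set_index("Type")
        assert r.icc == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-10)
        assert r.icc3k == pytest.approx(ref.loc["ICC(C,k)", "ICC"],
                                        abs=1e-10)
        assert r.icc_ci95 == pytest.approx(ref.loc["ICC(A,k)", "CI95"],
                                           abs=0.01)
        assert r.icc3k_ci95 == pytest.approx(ref.loc["ICC(C,k)", "CI95"],
                                             abs=0.01)

    def test_variance_component_recovery(self):
        """sigma_b = 1, sigma_w = 0.84, k = 2 gives theoretical ICC(2,k)
        1/(1 + 0.84^2/2) ~ 0.739; the seed-averaged estimate at n = 200
        lands within 0.05."""
        target = 1.0 / (1.0 + 0.84 ** 2 / 2.0)
        ests = [rt.icc_2k(_matrix(simulate_metric_matrix(
            200, 1.0, 0.84, seed=s))).icc for s in range(40)]
        assert np.mean(ests) == pytest.approx(target, abs=0.05)

    def test_consistency_at_least_agreement_when_trial_shift(self):
        # a systematic trial-2 shift inflates MSC: ICC(3,k) >= ICC(2,k)
        m = simulate_metric_matrix(60, 1.0, 0.5, trial_shifts=[0.0, 0.8],
                                   seed=2)
        r = rt.icc_2k(_matrix(m))
        msr, msc, mse = rt.anova_two_way_no_rep(_matrix(m))
        assert msc > mse
        assert r.icc3k >= r.icc

    def test_ci_contains_estimate_and_shrinks_with_n(self):
        sb = sigma_b_for_icc2k(0.8)
        widths = []
        for n in (20, 200):
            r = rt.icc_2k(_matrix(simulate_metric_matrix(n, sb, 1.0,
                                                         seed=5)))
            assert r.icc_ci95[0] <= r.icc <= r.icc_ci95[1]
            widths.append(r.icc_ci95[1] - r.icc_ci95[0])
        assert widths[1] < widths[0]


class TestLCC:
    def test_perfect_correlations(self):
        base = np.arange(1.0, 9.0)
        r = rt.lcc(_matrix(np.column_stack([base, 2 * base + 1])))
        assert r.lcc == pytest.approx(1.0)
        r = rt.lcc(_matrix(np.column_stack([base, -base])))
        assert r.lcc == pytest.approx(-1.0)

    def test_zero_variance_column_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rt.lcc(_matrix([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0],
                            [1.0, 5.0]]))

    def test_agrees_with_icc_when_no_trial_shift(self):
        """With equal trial means and n = 111, the agreement ICC and the
        Pearson correlation estimate the same quantity."""
        sb = sigma_b_for_icc2k(0.85)
        # lcc estimates the single-measure correlation; Spearman-Brown it
        # up to the k = 2 average-measures scale before comparing
        diffs = []
        for s in range(30):
            m = _matrix(simulate_metric_matrix(111, sb, 1.0, seed=s))
            r2k = rt.icc_2k(m).icc
            l1 = rt.lcc(m).lcc
            l2k = 2 * l1 / (1 + l1)
            diffs.append(r2k - l2k)
        assert abs(np.mean(diffs)) < 0.02


class TestFisherCI:
    def test_bounds_bracket_estimate(self):
        lo, hi = fisher_ci(0.85, 111)
        assert lo < 0.85 < hi
        lo2, hi2 = fisher_ci(0.85, 400)
        assert (hi2 - lo2) < (hi - lo)

    def test_degenerate_perfect_correlation(self):
        assert fisher_ci(1.0, 10) == (1.0, 1.0)


class TestRegressions:
    def test_exact_linear_relation(self):
        ages = np.linspace(40, 90, 20)
        r = rt.age_regression(2.0 * ages, ages)
        assert r.slope == pytest.approx(2.0, abs=1e-10)
        assert r.p_value < 1e-20

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rt.age_regression(np.arange(5.0), np.full(5, 70.0))

    def test_trial_vs_trial_identity(self):
        base = np.arange(1.0, 11.0)
        r = rt.trial_vs_trial(_matrix(np.column_stack([base, base])))
        assert r.slope == pytest.approx(1.0, abs=1e-12)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)

    def test_trial_vs_trial_attenuation(self):
        """Within-subject noise attenuates the trial-2-on-trial-1 slope
        toward sb^2/(sb^2 + sw^2)."""
        sb, sw = 1.0, 0.8
        slopes = [rt.trial_vs_trial(_matrix(simulate_metric_matrix(
            300, sb, sw, seed=s))).slope for s in range(20)]
        assert np.mean(slopes) == pytest.approx(
            sb**2 / (sb**2 + sw**2), abs=0.05)

    def test_two_subjects_rejected_at_construction(self):
        with pytest.raises(ValueError):
            SubjectTrialMatrix("speed_mmps",
                               np.array([[1.0, 2.0], [3.0, 4.0]]),
                               np.array([50.0, 60.0]))


class TestMatrixConstruction:
    def test_pre_averaging_and_listwise_drop(self):
        rows = []
        for pid, age in (("a", 50), ("b", 60), ("c", 70), ("d", 80)):
            for trial in (1, 2):
                for sub in ("large1", "small"):
                    rows.append({"participant_id": pid, "age": age,
                                 "trial": trial, "subtask": sub,
                                 "speed_mmps": age / 10 + trial})
        df = pd.DataFrame(rows)
        # knock out one cell for subject d
        df.loc[(df.participant_id == "d") & (df.trial == 2),
               "speed_mmps"] = np.nan
        m = subject_trial_matrix(df, "speed_mmps")
        assert m.n == 3
        assert "d" not in m.participant_ids
        assert m.values[:, 0] == pytest.approx([6.0, 7.0, 8.0])
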