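"""Paired t, 1-df repeated-measures ANOVA, effect sizes, behavioral summary."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import facemvpa as fm
from facemvpa.report import analyze_cell_table, cell_table, decide_verdict
from facemvpa.stats import CONTRASTS_2X2, behavioral_summary, one_sample_t


def rm_anova_ss_oracle(Y: np.ndarray) -> dict[str, float]:
    """Independent full sums-of-squares 2x2 within-subject ANOVA decomposition.

    ``Y`` has shape (subjects, 2, 2) for factors A and B.  Returns F for the
    two main effects and the interaction, each tested against its
    effect-by-subject error term.
    """
    n, a_lev, b_lev = Y.shape
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    ss_a = n * b_lev * ((m_a - grand) ** 2).sum()
    ss_b = n * a_lev * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b_lev * ((m_sa - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bs = a_lev * ((m_sb - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = (resid**2).sum()
    df_err = n - 1
    return {
        "A": (ss_a / 1) / (ss_as / df_err),
        "B": (ss_b / 1) / (ss_bs / df_err),
        "AxB": (ss_ab / 1) / (ss_abs / df_err),
    }


class TestPairedT:
    def test_identical_samples(self):
        r = fm.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.t, r.d, r.p) == (0.0, 0.0, 1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(9), rng.standard_normal(9)
        r1, r2 = fm.paired_t(a, b), fm.paired_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.d == pytest.approx(-r2.d)
        assert r1.p == pytest.approx(r2.p)

    def test_textbook_arithmetic_oracle(self):
        """Hand-computed mean/sd of diffs for a = (1,2,3,4), b = (0,2,2,5)."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([0.0, 2.0, 2.0, 5.0])
        # diffs = (1, 0, 1, -1): mean 0.25, sd sqrt((0.75^2+0.25^2+0.75^2+1.25^2)/3)
        diffs = a - b
        mean = 0.25
        sd = np.sqrt(((diffs - mean) ** 2).sum() / 3)
        r = fm.paired_t(a, b)
        assert r.mean_diff == pytest.approx(mean)
        assert r.t == pytest.approx(mean / (sd / 2))
        assert r.d == pytest.approx(mean / sd)
        assert r.df == 3

    def test_agrees_with_scipy(self, rng):
        from scipy import stats as sps

        a, b = rng.standard_normal(13), rng.standard_normal(13)
        mine = fm.paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_nonzero_constant_diff(self):
        r = fm.paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert r.degenerate and np.isnan(r.t)

    def test_pairwise_deletion_of_missing(self):
        a = np.array([1.0, np.nan, 3.0, 4.0, 2.0])
        b = np.array([0.0, 5.0, 2.0, np.nan, 1.0])
        r = fm.paired_t(a, b)
        assert r.n == 3

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fm.paired_t([1.0], [2.0])


class TestPartialEtaSq:
    @pytest.mark.parametrize(
        "F,df2,expected",
        [(5.09, 12, 0.30), (21.14, 11, 0.66), (6.13, 11, 0.36), (0.0, 12, 0.0)],
    )
    def test_reported_effect_sizes(self, F, df2, expected):
        assert round(fm.partial_eta_sq(F, 1, df2), 2) == expected

    @given(
        f1=st.floats(0.0, 50.0),
        f2=st.floats(0.0, 50.0),
        df2=st.integers(2, 40),
    )
    def test_monotone_in_F(self, f1, f2, df2):
        lo, hi = sorted((f1, f2))
        assert fm.partial_eta_sq(lo, 1, df2) <= fm.partial_eta_sq(hi, 1, df2)

    def test_decreasing_in_df2(self):
        assert fm.partial_eta_sq(5.0, 1, 10) > fm.partial_eta_sq(5.0, 1, 20)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fm.partial_eta_sq(-1.0, 1, 10)
        with pytest.raises(ValueError):
            fm.partial_eta_sq(1.0, 0, 10)


class TestRmAnova1df:
    @pytest.mark.parametrize("trial_seed", range(6))
    def test_matches_sums_of_squares_oracle(self, trial_seed):
        rng = np.random.default_rng(2000 + trial_seed)
        Y = rng.standard_normal((6, 2, 2))
        table = Y.reshape(6, 4)  # cells ordered (A1B1, A1B2, A2B1, A2B2)
        ref = rm_anova_ss_oracle(Y)
        got_a = fm.rm_anova_1df(table, (1, 1, -1, -1))
        got_b = fm.rm_anova_1df(table, (1, -1, 1, -1))
        got_ab = fm.rm_anova_1df(table, (1, -1, -1, 1))
        assert got_a.F == pytest.approx(ref["A"], abs=1e-8)
        assert got_b.F == pytest.approx(ref["B"], abs=1e-8)
        assert got_ab.F == pytest.approx(ref["AxB"], abs=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.standard_normal((8, 2, 2))
        long = pd.DataFrame(
            [
                {"subject": s, "A": a, "B": b, "y": Y[s, a, b]}
                for s in range(8)
                for a in range(2)
                for b in range(2)
            ]
        )
        ref = pg.rm_anova(data=long, dv="y", within=["A", "B"], subject="subject", detailed=True)
        got = {
            "A": fm.rm_anova_1df(Y.reshape(8, 4), (1, 1, -1, -1)),
            "B": fm.rm_anova_1df(Y.reshape(8, 4), (1, -1, 1, -1)),
            "A * B": fm.rm_anova_1df(Y.reshape(8, 4), (1, -1, -1, 1)),
        }
        for _, row in ref.iterrows():
            if row["Source"] in got:
                eff = got[row["Source"]]
                assert eff.F == pytest.approx(row["F"], rel=1e-6)
                assert eff.p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_f_is_square_of_contrast_t(self, rng):
        table = rng.standard_normal((10, 4))
        eff = fm.rm_anova_1df(table, (1, -1, -1, 1))
        scores = table @ np.array([1, -1, -1, 1]) / 2.0
        tt = one_sample_t(scores)
        assert eff.F == pytest.approx(tt.t**2, abs=1e-10)
        assert eff.p == pytest.approx(tt.p, abs=1e-10)

    def test_flat_subject_rows_give_zero_interaction(self):
        # each subject's four cells are equal -> every contrast score is 0
        table = np.outer([0.3, 0.1, 0.5, 0.2, 0.4, 0.25, 0.33], np.ones(4))
        eff = fm.rm_anova_1df(table, (1, -1, -1, 1))
        assert eff.F == 0.0 and eff.p == 1.0

    def test_subject_order_invariance(self, rng):
        table = rng.standard_normal((9, 4))
        a = fm.rm_anova_1df(table, (1, -1, -1, 1))
        b = fm.rm_anova_1df(table[::-1], (1, -1, -1, 1))
        assert a.F == pytest.approx(b.F, abs=1e-12)

    def test_listwise_deletion_reduces_df(self, rng):
        table = rng.standard_normal((8, 4))
        table[2, 1] = np.nan
        eff = fm.rm_anova_1df(table, (1, -1, -1, 1))
        assert eff.df2 == 6 and eff.n == 7

    def test_fewer_than_two_complete_subjects_rejected(self, rng):
        table = rng.standard_normal((3, 4))
        table[:2, 0] = np.nan
        with pytest.raises(ValueError, match="complete subjects"):
            fm.rm_anova_1df(table, (1, -1, -1, 1))

    def test_partial_eta_identity(self, rng):
        table = rng.standard_normal((12, 4))
        eff = fm.rm_anova_1df(table, (1, -1, 1, -1))
        assert eff.partial_eta_sq == pytest.approx(
            eff.F / (eff.F + eff.df2), abs=1e-12
        )


class TestBehavioralSummary:
    def _cohort(self, n_subjects=4, seed=0):
        out = {}
        for s in range(n_subjects):
            recs = []
            for run in range(1, 3):
                d = fm.generate_experimental_design(run, seed=fm.child_seed(seed, s))
                recs.extend(fm.simulate_behavior(d, seed=fm.child_seed(seed, s)))
            out[f"sub-{s}"] = recs
        return out

    def test_group_accuracy_ordering_and_tests(self):
        summary = behavioral_summary(self._cohort(n_subjects=6))
        assert summary["group_accuracy"]["veridical"] > summary["group_accuracy"]["scrambled"]
        assert summary["accuracy_test"].t > 0
        assert summary["group_mean_rt_s"]["veridical"] < summary["group_mean_rt_s"]["scrambled"]

    def test_all_correct_behavior_degenerate(self):
        p = fm.BehaviorParams(p_correct_veridical=1.0, p_correct_scrambled=1.0, p_no_response=0.0)
        out = {}
        for s in range(3):
            d = fm.generate_experimental_design(1, seed=s)
            out[s] = fm.simulate_behavior(d, p, seed=s)
        summary = behavioral_summary(out)
        assert summary["group_accuracy"] == {"veridical": 1.0, "scrambled": 1.0}
        assert summary["accuracy_test"].degenerate

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            behavioral_summary({"only": []})

    def test_rt_correct_only_changes_means(self):
        cohort = self._cohort(n_subjects=3, seed=5)
        with_incorrect = behavioral_summary(cohort, rt_correct_only=False)
        correct_only = behavioral_summary(cohort, rt_correct_only=True)
        assert (
            with_incorrect["group_mean_rt_s"]["scrambled"]
            != correct_only["group_mean_rt_s"]["scrambled"]
        )


class TestVerdict:
    def _analysis(self, rows: np.ndarray):
        cols = [f"{c}:{r}" for c, r in fm.CELLS]
        return analyze_cell_table(pd.DataFrame(rows, columns=cols))

    def test_holistic_pattern(self, rng):
        rows = rng.normal(0.4, 0.02, size=(13, 4))
        rows[:, 0] += 0.3  # veridical-correct only
        v = decide_verdict(self._analysis(rows))
        assert v["scenario"] == "holistic"

    def test_parts_pattern(self, rng):
        rows = rng.normal(0.4, 0.02, size=(13, 4))
        rows[:, 0] += 0.3
        rows[:, 2] += 0.3  # correct cells in both conditions
        v = decide_verdict(self._analysis(rows))
        assert v["scenario"] == "parts_based"

    def test_both_pattern(self, rng):
        rows = rng.normal(0.4, 0.02, size=(13, 4))
        rows[:, 0] += 0.4
        rows[:, 2] += 0.15
        v = decide_verdict(self._analysis(rows))
        assert v["scenario"] == "both"

    def test_null_pattern(self, rng):
        rows = rng.normal(0.4, 0.05, size=(13, 4))
        v = decide_verdict(self._analysis(rows))
        assert v["scenario"] == "null"
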