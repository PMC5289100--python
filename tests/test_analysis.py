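"""Summation ratios, group summaries and the mixed-design ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from noiseletter import (
    CohortSpec,
    group_fold_difference,
    mixed_anova,
    round_half_up,
    simulate_cohort,
    summarize_groups,
    summation_ratio,
    summation_table,
)


class TestSummationRatio:
    @pytest.mark.parametrize(
        "mono, bino, expected",
        [
            (0.44, 0.39, 1.12),   # older-group CM means
            (-0.18, -0.24, 1.15), # younger-group LM means
        ],
    )
    def test_printed_group_ratios(self, mono, bino, expected):
        assert round_half_up(summation_ratio(mono, bino), 2) == expected

    def test_identical_eyes_give_unity(self):
        assert summation_ratio(0.123, 0.123) == pytest.approx(1.0)

    @given(
        mono=st.floats(-0.5, 0.8),
        bino=st.floats(-0.5, 0.8),
    )
    @settings(deadline=None, derandomize=True)
    def test_log_of_ratio_is_the_logmar_difference(self, mono, bino):
        assert np.log10(summation_ratio(mono, bino)) == pytest.approx(mono - bino, abs=1e-12)

    def test_ratio_above_one_means_binocular_better(self):
        assert summation_ratio(0.4, 0.3) > 1.0  # binocular lower logMAR = better
        assert summation_ratio(0.3, 0.4) < 1.0


class TestFoldDifference:
    def test_binocular_cm_group_difference(self):
        fold, diff = group_fold_difference(0.39, 0.20)
        assert diff == pytest.approx(0.19)          # ~two chart lines
        assert fold == pytest.approx(10 ** 0.19)    # ~1.549

    def test_no_difference(self):
        fold, diff = group_fold_difference(0.2, 0.2)
        assert fold == pytest.approx(1.0) and diff == pytest.approx(0.0)


class TestGroupSummaries:
    @staticmethod
    def _cohort_frame(cells):
        rows = []
        for (group, stim, view), values in cells.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "participant_id": f"{group}-{i}",
                        "group": group,
                        "stimulus_type": stim,
                        "viewing": view,
                        "threshold_logmar": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_mean_and_se(self):
        df = self._cohort_frame({("older", "CM", "binocular"): [0.3, 0.5]})
        out = summarize_groups(df)
        assert out.loc[0, "mean_logmar"] == pytest.approx(0.4)
        assert out.loc[0, "se_logmar"] == pytest.approx(0.1)

    def test_constant_cell_has_zero_se(self):
        df = self._cohort_frame({("older", "CM", "binocular"): [0.4, 0.4, 0.4]})
        assert summarize_groups(df).loc[0, "se_logmar"] == pytest.approx(0.0)

    def test_five_value_cell_matches_hand_computation(self):
        values = [0.31, 0.40, 0.44, 0.37, 0.48]
        df = self._cohort_frame({("older", "CM", "monocular"): values})
        out = summarize_groups(df)
        assert out.loc[0, "mean_logmar"] == pytest.approx(sum(values) / 5)
        sd = (sum((v - sum(values) / 5) ** 2 for v in values) / 4) ** 0.5
        assert out.loc[0, "se_logmar"] == pytest.approx(sd / 5 ** 0.5)

    def test_empty_cell_is_named(self):
        df = self._cohort_frame(
            {
                ("older", "CM", "binocular"): [0.3, 0.5],
                ("younger", "CM", "monocular"): [0.2, 0.3],
            }
        )
        with pytest.raises(ValueError, match="older.*CM.*monocular"):
            summarize_groups(df)


class TestSummationTable:
    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        # heterogeneous participants: E[10^d] > 10^E[d] (Jensen), so the
        # per-participant aggregation exceeds the ratio of group means
        rows = []
        diffs = [0.0, 0.05, 0.40]
        for i, d in enumerate(diffs):
            for view, thr in (("monocular", 0.2 + d), ("binocular", 0.2)):
                rows.append(
                    {
                        "participant_id": f"p{i}",
                        "group": "older",
                        "stimulus_type": "LM",
                        "viewing": view,
                        "threshold_logmar": thr,
                    }
                )
        df = pd.DataFrame(rows)
        table = summation_table(df)
        mean_of_ratios = table.loc[0, "mean_ratio"]
        ratio_of_means = 10 ** np.mean(diffs)
        assert mean_of_ratios == pytest.approx(np.mean([10 ** d for d in diffs]))
        assert mean_of_ratios > ratio_of_means

    def test_requires_both_viewings(self):
        df = pd.DataFrame(
            [
                {
                    "participant_id": "p0",
                    "group": "older",
                    "stimulus_type": "LM",
                    "viewing": "monocular",
                    "threshold_logmar": 0.1,
                }
            ]
        )
        with pytest.raises(ValueError):
            summation_table(df)


def _mixed_design_frame(older, younger):
    """Balanced 2-group x 2-within table; values[subject] = (lm, cm)."""
    rows = []
    for group, cells in (("older", older), ("younger", younger)):
        for i, (lm, cm) in enumerate(cells):
            for stim, v in (("LM", lm), ("CM", cm)):
                rows.append(
                    {
                        "participant_id": f"{group}-{i}",
                        "group": group,
                        "stimulus_type": stim,
                        "threshold_logmar": v,
                    }
                )
    return pd.DataFrame(rows)


def _anova_oracle(older, younger):
    """Textbook split-plot sums of squares for a 2x2 mixed design."""
    y = np.array([older, younger], dtype=float)  # (group, subject, within)
    g, n, w = y.shape
    grand = y.mean()
    m_group = y.mean(axis=(1, 2))
    m_within = y.mean(axis=(0, 1))
    m_gw = y.mean(axis=1)
    m_subj = y.mean(axis=2)
    ss_between = w * n * ((m_group - grand) ** 2).sum()
    ss_subj_within_g = w * ((m_subj - m_group[:, None]) ** 2).sum()
    ss_within = g * n * ((m_within - grand) ** 2).sum()
    ss_inter = n * (
        (m_gw - m_group[:, None] - m_within[None, :] + grand) ** 2
    ).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between - ss_subj_within_g - ss_within - ss_inter
    df_b, df_sw = g - 1, g * (n - 1)
    df_w, df_i, df_ew = w - 1, (g - 1) * (w - 1), (w - 1) * g * (n - 1)
    return {
        "between": (ss_between / df_b) / (ss_subj_within_g / df_sw),
        "within": (ss_within / df_w) / (ss_err_within / df_ew),
        "interaction": (ss_inter / df_i) / (ss_err_within / df_ew),
    }


class TestMixedAnova:
    def test_identical_cell_means_give_zero_f(self):
        older = [(0.1 + d, 0.4 + d) for d in (-0.02, 0.0, 0.02)]
        younger = [(0.1 + d, 0.4 + d) for d in (-0.02, 0.0, 0.02)]
        res = {
            r.effect: r
            for r in mixed_anova(
                _mixed_design_frame(older, younger), "stimulus_type", "group"
            )
        }
        assert res["group"].F == pytest.approx(0.0, abs=1e-9)
        assert res["Interaction"].F == pytest.approx(0.0, abs=1e-9)

    def test_matches_sums_of_squares_oracle(self):
        older = [(0.12, 0.45), (0.05, 0.52), (0.10, 0.40), (0.02, 0.39), (0.08, 0.47)]
        younger = [(-0.05, 0.30), (0.00, 0.22), (-0.12, 0.35), (-0.02, 0.28), (-0.09, 0.25)]
        expected = _anova_oracle(older, younger)
        res = {
            r.effect: r
            for r in mixed_anova(
                _mixed_design_frame(older, younger), "stimulus_type", "group"
            )
        }
        assert res["group"].F == pytest.approx(expected["between"], rel=1e-9)
        assert res["stimulus_type"].F == pytest.approx(expected["within"], rel=1e-9)
        assert res["Interaction"].F == pytest.approx(expected["interaction"], rel=1e-9)

    def test_degrees_of_freedom_for_ten_subjects(self):
        df = simulate_cohort(CohortSpec(n_runs=1), seed=55)
        sub = df[df["viewing"] == "binocular"]
        for r in mixed_anova(sub, "stimulus_type", "group"):
            assert (r.df_between, r.df_within) == (1, 8)

    def test_unbalanced_design_rejected(self):
        older = [(0.1, 0.4), (0.2, 0.5)]
        younger = [(0.0, 0.3), (0.1, 0.2), (0.05, 0.25)]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(_mixed_design_frame(older, younger), "stimulus_type", "group")

    def test_shift_invariance(self):
        older = [(0.12, 0.45), (0.05, 0.52), (0.10, 0.40)]
        younger = [(-0.05, 0.30), (0.00, 0.22), (-0.12, 0.35)]
        base = mixed_anova(_mixed_design_frame(older, younger), "stimulus_type", "group")
        shifted_frame = _mixed_design_frame(older, younger)
        shifted_frame["threshold_logmar"] += 0.7
        shifted = mixed_anova(shifted_frame, "stimulus_type", "group")
        for a, b in zip(base, shifted):
            assert a.F == pytest.approx(b.F, rel=1e-9)


def test_round_half_up_matches_table_convention():
    assert round_half_up(1.125, 2) == 1.13
    assert round_half_up(1.114999, 2) == 1.11
    assert round_half_up(1.115, 2) == 1.12
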