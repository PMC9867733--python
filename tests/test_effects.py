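"""Classical track: t-tests, Cohen's d, chi-square, Bonferroni, tables."""

import numpy as np
import pandas as pd
import pytest

from ssrinet import (DirectEffectTrajectory, baseline_table, bonferroni_alpha,
                     chi_square_2x2, cohens_d, direct_vs_overall,
                     overall_effects, simulate_trial, students_t)


class TestStudentsT:
    def test_identical_groups(self):
        t, df, p = students_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_hand_example(self):
        t, df, p = students_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.225, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.288, abs=1e-3)

    def test_constant_shift_closed_form(self, rng):
        a = rng.normal(0, 1, 50)
        c = 0.7
        b = a + c
        t, df, _ = students_t(a, b)
        s = np.sqrt(a.var(ddof=1))  # pooled sd equals either group's sd
        assert t == pytest.approx(-c * np.sqrt(50 / 2) / s)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            students_t([1.0], [1, 2, 3])


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0

    def test_hand_example(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_scale_invariance(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        assert cohens_d(10 * a, 10 * b) == pytest.approx(cohens_d(a, b))

    def test_zero_pooled_sd_is_nan(self):
        assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))

    def test_d_equals_t_times_factor(self, rng):
        """d = t * sqrt(1/n1 + 1/n0) exactly for the pooled construction."""
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.3, 1.2, 25)
        t, _, _ = students_t(a, b)
        assert cohens_d(a, b) == pytest.approx(t * np.sqrt(1 / 40 + 1 / 25), rel=1e-12)


class TestChiSquare:
    def test_balanced_table_zero(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0 and p == pytest.approx(1.0)

    def test_hand_example(self):
        stat, _ = chi_square_2x2([[20, 10], [10, 20]])
        assert stat == pytest.approx(60 * (20 * 20 - 10 * 10) ** 2 / (30 * 30 * 30 * 30))
        assert stat == pytest.approx(6.667, abs=1e-3)

    def test_doubling_cells_doubles_statistic(self):
        s1, _ = chi_square_2x2([[20, 10], [10, 20]])
        s2, _ = chi_square_2x2([[40, 20], [20, 40]])
        assert s2 == pytest.approx(2 * s1)

    def test_transposition_invariance(self):
        s1, _ = chi_square_2x2([[17, 5], [8, 30]])
        s2, _ = chi_square_2x2(np.array([[17, 5], [8, 30]]).T)
        assert s1 == pytest.approx(s2)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestBonferroni:
    def test_seventeen_items_rounds_to_003(self):
        assert round(bonferroni_alpha(17, 0.05), 3) == 0.003

    @pytest.mark.parametrize("n,expected", [(1, 0.05), (10, 0.005)])
    def test_simple_values(self, n, expected):
        assert bonferroni_alpha(n, 0.05) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0, 0.05)
        with pytest.raises(ValueError):
            bonferroni_alpha(5, 1.5)


class TestBaselineTable:
    def test_counts_and_no_false_positives(self, small_ordinal_ds):
        table = baseline_table(small_ordinal_ds)
        symptoms = table[table.kind == "symptom"]
        assert len(symptoms) == 17
        base_n = (small_ordinal_ds.frame.week == 0).sum()
        assert (symptoms.n_ssri + symptoms.n_placebo == base_n).all()
        assert set(table.variable) >= {"age", "sex"}

    def test_single_arm_errors(self, small_ordinal_ds):
        frame = small_ordinal_ds.frame.copy()
        frame["arm"] = 1
        ds = type(small_ordinal_ds)(frame=frame, items=small_ordinal_ds.items)
        with pytest.raises(ValueError, match="single-arm"):
            baseline_table(ds)

    def test_null_generator_controls_fwer(self, null_gt):
        hits = 0
        for seed in range(20):
            ds = simulate_trial(null_gt, 600, weeks=(0,), seed=300 + seed)
            table = baseline_table(ds)
            if table[table.kind == "symptom"]["significant"].any():
                hits += 1
        assert hits <= 1  # FWER 0.05-ish across 20 replicates


class TestOverallEffects:
    def test_null_effects_small(self, null_gt):
        ds = simulate_trial(null_gt, 5000, weeks=(0, 6), seed=50, latent_only=True)
        table = overall_effects(ds, [6])
        assert (table.cohens_d.abs() < 0.1).all()

    def test_mood_d_grows_with_time(self, small_latent_ds):
        table = overall_effects(small_latent_ds, [1, 6])
        mood = table[table.symptom == "depressed_mood"].set_index("week")
        assert mood.loc[6, "cohens_d"] < mood.loc[1, "cohens_d"] < 0.05

    def test_arm_flip_flips_d(self, small_latent_ds):
        table = overall_effects(small_latent_ds, [6])
        flipped_frame = small_latent_ds.frame.copy()
        flipped_frame["arm"] = 1 - flipped_frame["arm"]
        ds2 = type(small_latent_ds)(frame=flipped_frame,
                                    items=small_latent_ds.items, latent=True)
        table2 = overall_effects(ds2, [6])
        assert np.allclose(table.cohens_d.to_numpy(), -table2.cohens_d.to_numpy())


class TestDirectVsOverall:
    def _traj(self, direct):
        values = pd.DataFrame({"guilt": [direct]}, index=pd.Index([6], name="week"))
        return DirectEffectTrajectory(values=values)

    def _table(self, d):
        return pd.DataFrame([{"week": 6, "symptom": "guilt", "cohens_d": d}])

    def test_indirect_dominant_flag(self):
        out = direct_vs_overall(self._traj(0.0), self._table(-0.3))
        assert out.loc[0, "flag"] == "indirect_dominant"

    def test_no_flag_when_both_zero(self):
        out = direct_vs_overall(self._traj(0.0), self._table(0.0))
        assert out.loc[0, "flag"] == ""

    def test_direct_dominant_flag(self):
        out = direct_vs_overall(self._traj(0.2), self._table(0.01))
        assert out.loc[0, "flag"] == "direct_dominant"

    def test_mismatched_labels_error(self):
        table = pd.DataFrame([{"week": 6, "symptom": "mood", "cohens_d": 0.1}])
        with pytest.raises(ValueError, match="match"):
            direct_vs_overall(self._traj(0.0), table)

    def test_mood_strong_direct_and_overall(self, recovery_latent_ds):
        """Depressed mood shows both a strong overall effect and a strong
        direct edge at week 6: it can never be flagged indirect-dominant."""
        from ssrinet import direct_effects, fit_weekly_networks

        models = fit_weekly_networks(recovery_latent_ds, [6], seed=8)
        traj = direct_effects(models)
        table = overall_effects(recovery_latent_ds, [6])
        out = direct_vs_overall(traj, table)
        mood = out[(out.week == 6) & (out.symptom == "depressed_mood")].iloc[0]
        assert mood.direct_effect < -0.05 and mood.cohens_d < -0.1
        assert mood.flag != "indirect_dominant"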