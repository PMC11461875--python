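"""ANOVA and Tukey HSD: closed-form checks, calibration, and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tendonquant import (
    ValidationError,
    analyze_cohort,
    one_way_anova,
    simulate_metric_table,
    tukey_hsd,
    two_way_anova,
)


def long_table(values_by_cell: dict, metric: str = "m") -> pd.DataFrame:
    rows = []
    for (group, week), values in values_by_cell.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "section_id": f"{group}{week}_{i}",
                    "group": group,
                    "week": week,
                    "metric": metric,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


class TestTwoWay:
    def test_balanced_toy_table_matches_hand_computed_ss(self):
        # cells: A1={10,12} A2={20,22} B1={30,32} B2={40,42}
        # grand mean 26; group means 16/36 -> SS_group = 4*100+4*100 = 800
        # week means 21/31 -> SS_week = 4*25+4*25 = 200; interaction 0
        # within-cell SS = 4 cells * ((1)^2+(1)^2) = 8
        table = long_table(
            {
                ("A", 1): [10, 12],
                ("A", 2): [20, 22],
                ("B", 1): [30, 32],
                ("B", 2): [40, 42],
            }
        )
        res = two_way_anova(table, "m")
        assert res.effect("group").ss == pytest.approx(800.0)
        assert res.effect("week").ss == pytest.approx(200.0)
        assert res.effect("group:week").ss == pytest.approx(0.0, abs=1e-9)
        assert res.residual_ss == pytest.approx(8.0)
        total_df = sum(e.df for e in res.effects.values()) + res.residual_df
        assert total_df == res.n - 1

    def test_all_equal_observations_give_p_one(self):
        table = long_table({(g, w): [5.0, 5.0] for g in "AB" for w in (1, 2)})
        res = two_way_anova(table, "m")
        for eff in res.effects.values():
            assert eff.F == 0.0 and eff.p == 1.0

    def test_empty_cell_error_names_the_cell(self):
        table = long_table({("A", 1): [1, 2], ("A", 2): [3, 4], ("B", 1): [5, 6]})
        with pytest.raises(ValidationError, match="group=B, week=2"):
            two_way_anova(table, "m")

    def test_permutation_invariance(self, rng):
        table = simulate_metric_table(rng)
        res = two_way_anova(table, "mean_intensity")
        shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        res2 = two_way_anova(shuffled, "mean_intensity")
        for name in res.effects:
            assert res.effect(name).F == pytest.approx(res2.effect(name).F)
            assert res.effect(name).p == pytest.approx(res2.effect(name).p)

    def test_null_rejection_rate_near_alpha(self, rng):
        # quick check at 200 replicates; the finer calibration run lives in
        # the acceptance suite
        hits = sum(
            two_way_anova(simulate_metric_table(rng), "mean_intensity")
            .effect("group")
            .p
            < 0.05
            for _ in range(200)
        )
        assert 0.01 <= hits / 200 <= 0.10


class TestOneWay:
    def test_f_equals_squared_t_for_two_groups(self, rng):
        a = rng.normal(10, 2, size=8)
        b = rng.normal(12, 2, size=9)
        table = long_table({("FL", 3): a, ("FL", 12): b})
        res = one_way_anova(table, "m", factor="week")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.effect("week").F == pytest.approx(t**2)
        assert res.effect("week").p == pytest.approx(p)

    def test_identical_group_means_give_large_p(self, rng):
        noise = rng.normal(0, 1, size=6)
        table = long_table({("FL", w): 50 + noise for w in (3, 12, 20)})
        assert one_way_anova(table, "m", factor="week").effect("week").p > 0.99

    def test_power_at_three_sigma_shift(self, rng):
        hits = 0
        for _ in range(200):
            table = long_table(
                {
                    ("FL", 3): rng.normal(0, 1, 5),
                    ("FL", 12): rng.normal(0, 1, 5),
                    ("FL", 20): rng.normal(3, 1, 5),
                }
            )
            hits += one_way_anova(table, "m", factor="week").effect("week").p < 0.05
        assert hits >= 190


class TestTukey:
    def test_identical_groups_accept(self):
        table = long_table({("A", 1): [4.0, 4.0, 4.0], ("B", 1): [4.0, 4.0, 4.0]})
        (res,) = tukey_hsd(table, "m", between="group")
        assert res.p_adj == pytest.approx(1.0)
        assert not res.reject

    def test_single_shifted_group_detected(self, rng):
        table = long_table(
            {
                ("A", 1): rng.normal(0, 1, 6),
                ("B", 1): rng.normal(0, 1, 6),
                ("C", 1): rng.normal(10, 1, 6),
            }
        )
        results = {frozenset((r.group_a, r.group_b)): r for r in
                   tukey_hsd(table, "m", between="group")}
        assert results[frozenset(("A", "C"))].reject
        assert results[frozenset(("B", "C"))].reject
        assert not results[frozenset(("A", "B"))].reject

    def test_adjusted_p_dominates_pairwise_t(self, rng):
        # oracle: with the same pooled error estimate, the studentized-range
        # adjustment can only raise the p value of each contrast
        for _ in range(20):
            data = {
                ("A", 1): rng.normal(0, 1, 5),
                ("B", 1): rng.normal(0.5, 1, 5),
                ("C", 1): rng.normal(1.0, 1, 5),
            }
            table = long_table(data)
            groups = list(data.values())
            df_resid = sum(len(g) - 1 for g in groups)
            mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_resid
            for r in tukey_hsd(table, "m", between="group"):
                na = len(data[(r.group_a, 1)])
                nb = len(data[(r.group_b, 1)])
                t = abs(r.mean_diff) / np.sqrt(mse * (1 / na + 1 / nb))
                raw = 2 * sps.t.sf(t, df_resid)
                assert r.p_adj >= raw - 1e-12

    def test_within_stratum_restriction(self, rng):
        table = simulate_metric_table(
            rng, group_effects={"ML": 3.0, "RL": 1.0, "FL": 1.0}
        )
        # effect visible within each week stratum
        for wk in (1, 2, 3):
            res = tukey_hsd(table, "mean_intensity", within=("week", wk))
            ml_pairs = [r for r in res if "ML" in (r.group_a, r.group_b)]
            assert all(r.reject for r in ml_pairs)

    def test_stratum_with_single_group_rejected(self):
        table = long_table({("A", 1): [1, 2, 3]})
        with pytest.raises(ValidationError):
            tukey_hsd(table, "m", between="group", within=("week", 1))


class TestAnalyzeCohort:
    def test_missing_late_weeks_skipped_with_warning(self, rng):
        table = simulate_metric_table(rng)  # weeks 1-3 only
        analysis = analyze_cohort(table)
        assert "mean_intensity" in analysis.early_anova
        assert "mean_intensity" not in analysis.late_anova
        assert any("late-healing" in w for w in analysis.warnings)

    def test_group_effect_propagates_to_results(self, rng):
        table = simulate_metric_table(
            rng, group_effects={"ML": 1.8, "RL": 1.3, "FL": 1.0}
        )
        analysis = analyze_cohort(table)
        assert analysis.early_anova["mean_intensity"].effect("group").p < 0.001
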