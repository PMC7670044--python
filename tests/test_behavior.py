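"""Rates, signal-detection measures, paired tests, TOST, and the ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plsmem.behavior import (DegenerateInputError, MissingCellError,
                             accuracy_anova_table, collapse_hit_rate,
                             paired_t, rm_anova_2way, score_responses,
                             sdt_measures, sdt_summary, tost_paired)


def _toy_responses(correct_pattern=True):
    rows = []
    for subj in (1, 2):
        for rt in ("incentivize-old", "incentivize-new"):
            for it in ("1x", "3x", "new"):
                for tr in range(4):
                    correct = correct_pattern if isinstance(
                        correct_pattern, bool) else correct_pattern(tr)
                    resp = ("old" if it != "new" else "new") if correct \
                        else ("new" if it != "new" else "old")
                    rows.append((subj, 1, rt, tr, it, f"w{tr}", resp,
                                 correct, 1000.0 + 100 * tr))
    return pd.DataFrame(rows, columns=[
        "subject", "run", "run_type", "trial", "item_type", "word",
        "response", "correct", "rt_ms"])


class TestScoreResponses:
    def test_all_correct_gives_unit_rates(self):
        rates = score_responses(_toy_responses(True))
        assert (rates["rate"] == 1.0).all()
        assert len(rates) == 2 * 2 * 3

    def test_cohort_row_count(self, cohort_responses):
        rates = score_responses(cohort_responses)
        assert len(rates) == 14 * 2 * 3

    def test_rt_averages_correct_trials_only(self):
        # trials 0,1 correct (1000, 1100), trials 2,3 wrong
        rates = score_responses(_toy_responses(lambda tr: tr < 2))
        assert np.allclose(rates["mean_rt_correct_ms"], 1050.0)
        assert np.allclose(rates["rate"], 0.5)

    def test_empty_table_rejected(self):
        with pytest.raises(MissingCellError):
            score_responses(_toy_responses(True).iloc[:0])

    def test_cohort_rates_match_generative_means(self, cohort_responses):
        """Cell means of the simulated cohort track the calibrated p."""
        from plsmem.design import DEFAULT_P_OLD
        rates = score_responses(cohort_responses)
        for (rt, it), p_old in DEFAULT_P_OLD.items():
            p_correct = p_old if it != "new" else 1.0 - p_old
            cell = rates[(rates.run_type == rt) & (rates.item_type == it)]
            sem = cell["rate"].std(ddof=1) / np.sqrt(len(cell))
            assert abs(cell["rate"].mean() - p_correct) < 3 * sem, (rt, it)


class TestSdtMeasures:
    def test_chance_point(self):
        assert sdt_measures(0.5, 0.5, 64, 128) == (0.0, 0.0)

    def test_symmetric_rates_give_zero_criterion(self):
        d, c = sdt_measures(0.7, 0.3, 64, 128)
        assert abs(c) < 1e-12
        assert d > 0

    def test_group_mean_rates(self):
        # frozen from the inverse standard-normal CDF:
        # z(0.835) = 0.974114, z(0.29) = -0.553385
        d, c = sdt_measures(0.835, 0.29, 128, 128)
        assert d == pytest.approx(1.527499, abs=1e-5)
        assert c == pytest.approx(-0.210365, abs=1e-5)

    def test_literal_sign_convention_flips_c(self):
        d_std, c_std = sdt_measures(0.835, 0.29, 128, 128)
        d_lit, c_lit = sdt_measures(0.835, 0.29, 128, 128,
                                    criterion_sign="literal")
        assert d_std == d_lit and c_std == -c_lit

    def test_extreme_rates_corrected(self):
        d, c = sdt_measures(1.0, 0.0, 64, 128)
        d_ref, c_ref = sdt_measures(1.0 - 1 / 128, 1 / 256, 64, 128)
        assert np.isfinite(d) and d == d_ref and c == c_ref

    @given(H=st.floats(0.05, 0.95), F=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_mirror_symmetry(self, H, F):
        """Swapping (H, F) -> (1-F, 1-H) preserves d' and flips c."""
        d1, c1 = sdt_measures(H, F, 64, 64)
        d2, c2 = sdt_measures(1 - F, 1 - H, 64, 64)
        assert d1 == pytest.approx(d2, abs=1e-10)
        assert c1 == pytest.approx(-c2, abs=1e-10)


class TestCollapseHitRate:
    @pytest.mark.parametrize("r1, r3, n1, n3, expected", [
        (0.74, 0.93, 64, 64, 0.835),
        (1.0, 1.0, 10, 10, 1.0),
        (0.6, 0.8, 10, 30, 0.75),
    ])
    def test_pooling(self, r1, r3, n1, n3, expected):
        assert collapse_hit_rate(r1, r3, n1, n3) == pytest.approx(expected)


class TestPairedT:
    def test_zero_mean_difference(self):
        t, df, p, dz = paired_t([1.0, 2.0, 3.0], [2.0, 1.0, 3.5])
        assert t == pytest.approx(dz * np.sqrt(3))
        assert abs(t) < 1 and df == 2

    def test_hand_computed_example(self):
        # diffs (1, 2, 3): mean 2, sd 1, dz = 2, t = 2 sqrt(3)
        t, df, p, dz = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert df == 2 and dz == pytest.approx(2.0)

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_dz_t_identity(self, a):
        b = [x + i * 0.1 for i, x in enumerate(a)]   # non-constant diffs
        t, df, p, dz = paired_t(a, b)
        assert abs(dz - t / np.sqrt(len(a))) < 1e-12


class TestTost:
    def test_reported_equivalence_statistics(self):
        """dz = -0.26, n = 14: binding t is 0.90 at bound 0.50 (not
        equivalent) and 2.02 at bound 0.80 (equivalent)."""
        r50 = tost_paired(-0.26, 14, 0.50)
        assert r50.t_binding == pytest.approx(0.898, abs=0.001)
        assert r50.df == 13 and not r50.equivalent
        r80 = tost_paired(-0.26, 14, 0.80)
        assert r80.t_binding == pytest.approx(2.020, abs=0.001)
        assert r80.equivalent

    def test_zero_effect_symmetry(self):
        r = tost_paired(0.0, 14, 0.5)
        assert r.t_lower == pytest.approx(-r.t_upper)
        assert r.t_lower == pytest.approx(0.5 * np.sqrt(14))
        assert r.p_lower == pytest.approx(r.p_upper)

    @given(dz=st.floats(-0.4, 0.4), n=st.integers(5, 40))
    @settings(max_examples=50, deadline=None)
    def test_binding_p_decreases_with_bound(self, dz, n):
        ps = [tost_paired(dz, n, b).p_binding for b in (0.3, 0.5, 0.8, 1.2)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_bound_rejected(self):
        with pytest.raises(ValueError):
            tost_paired(0.1, 14, 0.0)


def _anova_table(n=14, item_effect=0.0, run_effect=0.0, interaction=0.0,
                 noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    items = ("1x", "3x", "new")
    runs = ("incentivize-old", "incentivize-new")
    for s in range(n):
        for i, it in enumerate(items):
            for j, rt in enumerate(runs):
                val = (item_effect * i + run_effect * j
                       + interaction * i * j
                       + rng.normal(0, noise) if noise else
                       item_effect * i + run_effect * j + interaction * i * j)
                rows.append((s, it, rt, val + 0.1 * s))
    return pd.DataFrame(rows, columns=["subject", "item_type", "run_type",
                                       "value"])


class TestRmAnova:
    def test_degrees_of_freedom(self):
        out = rm_anova_2way(_anova_table(n=14, item_effect=1.0, noise=0.5))
        item = out[out.effect == "item_type"].iloc[0]
        assert (item.df_num, item.df_den) == (2, 26)
        inter = out[out.effect == "item_type x run_type"].iloc[0]
        assert (inter.df_num, inter.df_den) == (2, 26)

    def test_constant_data_yields_zero_ss(self):
        out = rm_anova_2way(_anova_table(n=6))
        assert np.allclose(out["ss_effect"], 0.0)
        assert np.allclose(out["F"], 0.0)

    def test_planted_additive_effect_noise_free(self):
        out = rm_anova_2way(_anova_table(n=6, item_effect=2.0)).set_index(
            "effect")
        F_item = out.loc["item_type", "F"]
        assert np.isinf(F_item) or F_item > 1e10
        assert out.loc["item_type", "p"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["item_type x run_type", "ss_effect"] == \
            pytest.approx(0.0, abs=1e-18)

    def test_partition_sums_to_total(self):
        out = rm_anova_2way(_anova_table(n=10, item_effect=0.7,
                                         run_effect=0.3, interaction=0.2,
                                         noise=1.0, seed=3))
        total = out.attrs["ss_total"]
        parts = out["ss_effect"].sum() + out["ss_error"].sum() \
            + out.attrs["ss_subject"]
        assert parts == pytest.approx(total, rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        tab = _anova_table(n=8, item_effect=0.5, run_effect=0.2,
                           interaction=0.3, noise=1.0, seed=5)
        ours = rm_anova_2way(tab).set_index("effect")
        theirs = pg.rm_anova(data=tab, dv="value",
                             within=["item_type", "run_type"],
                             subject="subject", detailed=True)
        mapping = {"item_type": "item_type", "run_type": "run_type",
                   "item_type * run_type": "item_type x run_type"}
        for pg_name, our_name in mapping.items():
            row = theirs[theirs.Source == pg_name].iloc[0]
            assert ours.loc[our_name, "F"] == pytest.approx(row["F"],
                                                            rel=1e-6)
            assert ours.loc[our_name, "p"] == pytest.approx(row["p_unc"],
                                                            rel=1e-6,
                                                            abs=1e-12)

    def test_missing_cell_rejected(self):
        tab = _anova_table(n=4, noise=1.0).iloc[:-1]
        with pytest.raises(MissingCellError):
            rm_anova_2way(tab)

    def test_criterion_recovery_in_cohort(self, cohort_responses):
        """The payoff manipulation's planted criterion shift is recovered:
        mean c is lower (more liberal) in incentivize-old runs."""
        sdt = sdt_summary(score_responses(cohort_responses))
        c_old = sdt[sdt.run_type == "incentivize-old"]["c"].mean()
        c_new = sdt[sdt.run_type == "incentivize-new"]["c"].mean()
        assert c_old < c_new
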