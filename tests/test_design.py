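"""Word pool, counterbalanced design, and behavioral simulation."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plsmem.design import (ConfigurationError, DesignParams, SdtParams,
                           generate_design, generate_word_pool,
                           simulate_responses, write_events_tsv)


class TestWordPool:
    def test_default_pool_structure(self, default_params):
        pool = generate_word_pool(default_params)
        assert len(pool.words) == 512
        assert pool.n_lists == 8
        lists = [pool.words_in_list(l) for l in range(1, 9)]
        assert all(len(ws) == 64 for ws in lists)
        # disjoint and covering
        flat = [w for ws in lists for w in ws]
        assert len(set(flat)) == 512
        # one category per list, half concrete half abstract
        cat_by_list = {
            l: {c for w, lid, c in zip(pool.words, pool.list_id,
                                       pool.category) if lid == l}
            for l in range(1, 9)
        }
        assert all(len(cats) == 1 for cats in cat_by_list.values())
        counts = pd.Series(
            [next(iter(c)) for c in cat_by_list.values()]).value_counts()
        assert counts["concrete"] == counts["abstract"] == 4

    def test_small_pool_covers_all_words(self):
        params = DesignParams(pool_size=8, n_lists=2, rng_seed=1)
        pool = generate_word_pool(params)
        assert sorted(pool.words_in_list(1) + pool.words_in_list(2)) == \
            sorted(pool.words)
        assert not set(pool.words_in_list(1)) & set(pool.words_in_list(2))

    def test_deterministic_per_seed(self, default_params):
        assert generate_word_pool(default_params) == \
            generate_word_pool(default_params)

    def test_indivisible_pool_rejected(self):
        with pytest.raises(ConfigurationError):
            DesignParams(pool_size=510, n_lists=8)


class TestDesign:
    def test_run_composition(self, default_design):
        design = default_design
        assert len(design.runs) == 8
        for run in design.runs:
            counts = run.trials["item_type"].value_counts()
            assert counts["1x"] == 16
            assert counts["3x"] == 16
            assert counts["new"] == 32
            assert counts["null"] == 4
        run_types = [r.run_type for r in design.runs]
        assert run_types.count("incentivize-old") == 4
        assert run_types.count("incentivize-new") == 4

    def test_study_list_size_and_repetitions(self, default_design):
        reps = pd.Series(default_design.study_list)
        assert len(reps) == 256
        assert (reps.value_counts() == pd.Series({1: 128, 3: 128})).all()

    def test_tested_old_words_were_studied(self, default_design):
        studied = set(default_design.study_list)
        for run in default_design.runs:
            old = run.trials.query("item_type in ('1x', '3x')")["word"]
            assert set(old) <= studied
            new = run.trials.query("item_type == 'new'")["word"]
            assert not set(new) & studied

    def test_itis_within_bounds(self, default_design, default_params):
        p = default_params
        trial_span = p.test_fix_ms + p.test_word_ms
        for run in default_design.runs:
            onsets = run.trials["onset_ms"].to_numpy()
            itis = np.diff(onsets) - trial_span
            assert (itis >= p.iti_range_ms[0]).all()
            assert (itis <= p.iti_range_ms[1]).all()

    def test_counterbalance_covers_every_list(self, default_params):
        pool = generate_word_pool(default_params)
        studied_by_cb = []
        for cb in (0, 1):
            d = generate_design(pool, default_params, counterbalance_id=cb)
            studied_by_cb.append({
                lid for w, lid in zip(pool.words, pool.list_id)
                if w in d.study_list})
        assert studied_by_cb[0] | studied_by_cb[1] == set(range(1, 9))
        assert not studied_by_cb[0] & studied_by_cb[1]

    def test_events_tsv_deterministic(self, default_params):
        def render():
            pool = generate_word_pool(default_params)
            d = generate_design(pool, default_params)
            buf = io.StringIO()
            write_events_tsv(d, buf)
            return buf.getvalue()

        assert render() == render()

    def test_pool_too_small_rejected(self):
        params = DesignParams(pool_size=64, n_lists=8, rng_seed=0)
        pool = generate_word_pool(params)
        with pytest.raises(ConfigurationError):
            generate_design(pool, params)


class TestSimulateResponses:
    def test_one_row_per_non_null_trial(self, default_design):
        resp = simulate_responses(default_design, SdtParams(), rng_seed=0)
        assert len(resp) == 8 * 64
        assert (resp["rt_ms"] > 0).all()
        # correctness consistent with item type and response
        old = resp["item_type"].isin(["1x", "3x"])
        assert (resp.loc[old, "correct"] ==
                (resp.loc[old, "response"] == "old")).all()
        assert (resp.loc[~old, "correct"] ==
                (resp.loc[~old, "response"] == "new")).all()

    def test_chance_performance_at_zero_sensitivity(self, default_design):
        sdt = SdtParams(
            mode="sdt",
            d_prime={(rt, it): 0.0 for rt in ("incentivize-old",
                                              "incentivize-new")
                     for it in ("1x", "3x")},
            c={"incentivize-old": 0.0, "incentivize-new": 0.0},
            subject_dprime_sd=0.0, subject_c_sd=0.0)
        resp = pd.concat([
            simulate_responses(default_design, sdt, rng_seed=s)
            for s in range(8)])
        p_old = (resp["response"] == "old").mean()
        se = np.sqrt(0.25 / len(resp))
        assert abs(p_old - 0.5) < 4 * se

    def test_liberal_criterion_raises_both_rates(self, default_design):
        """Lowering c raises hits and false alarms, leaving d' unchanged.

        Closed-form check: with lambda = d'/2 + c, the hit rate is
        Phi(d' - lambda) and the false-alarm rate Phi(-lambda); the Monte
        Carlo rates must match, and the recovered z(H) - z(F) must stay at
        the generative d' for both criteria.
        """
        d = 1.5
        rates = {}
        for c_val in (-0.5, 0.5):
            sdt = SdtParams(
                mode="sdt",
                d_prime={(rt, it): d for rt in ("incentivize-old",
                                                "incentivize-new")
                         for it in ("1x", "3x")},
                c={"incentivize-old": c_val, "incentivize-new": c_val},
                subject_dprime_sd=0.0, subject_c_sd=0.0)
            resp = pd.concat([
                simulate_responses(default_design, sdt, rng_seed=100 + s)
                for s in range(10)])
            old = resp["item_type"] != "new"
            H = (resp.loc[old, "response"] == "old").mean()
            F = (resp.loc[~old, "response"] == "old").mean()
            lam = d / 2.0 + c_val
            n_old, n_new = old.sum(), (~old).sum()
            assert abs(H - stats.norm.cdf(d - lam)) < \
                3 * np.sqrt(H * (1 - H) / n_old)
            assert abs(F - stats.norm.cdf(-lam)) < \
                3 * np.sqrt(max(F * (1 - F), 1e-3) / n_new)
            rates[c_val] = (H, F)
        H_lib, F_lib = rates[-0.5]
        H_con, F_con = rates[0.5]
        assert H_lib > H_con and F_lib > F_con
        d_lib = stats.norm.ppf(H_lib) - stats.norm.ppf(F_lib)
        d_con = stats.norm.ppf(H_con) - stats.norm.ppf(F_con)
        assert abs(d_lib - d) < 0.1 and abs(d_con - d) < 0.1

    def test_rate_recovery_converges(self, default_design):
        """Empirical cell rates converge to generative probabilities."""
        sdt = SdtParams(mode="rate", subject_concentration=np.inf)
        resp = pd.concat([
            simulate_responses(default_design, sdt, rng_seed=200 + s)
            for s in range(10)])
        for (rt, it), p_true in sdt.p_old.items():
            cell = resp[(resp.run_type == rt) & (resp.item_type == it)]
            p_emp = (cell["response"] == "old").mean()
            se = np.sqrt(p_true * (1 - p_true) / len(cell))
            assert abs(p_emp - p_true) < 3 * se, (rt, it)

    def test_missing_cell_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            SdtParams(mode="rate", p_old={("incentivize-old", "1x"): 0.5})

    def test_rate_outside_unit_interval_rejected(self):
        bad = dict(SdtParams().p_old)
        bad[("incentivize-old", "1x")] = 1.2
        with pytest.raises(ConfigurationError):
            SdtParams(mode="rate", p_old=bad)
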