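"""Screening cascade: rank-sum testing, stage filters, ranking, RF selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from crcmeth.errors import InputError
from crcmeth.screening import (
    BetaMatrix,
    ScreenConfig,
    compute_site_stats,
    rank_sites,
    restrict_to_genes,
    rf_select,
    run_screen,
    site_rank_sum_test,
    stage1_differential_filter,
    stage2_blood_filter,
)
from crcmeth.synth import BetaSimConfig, generate_beta_matrix


def exact_rank_sum_p(x, y):
    """Brute-force two-sided rank-sum P: enumerate every assignment of the
    pooled ranks to the first arm (valid for tie-free data)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    stats_all = np.array(
        [sum(c) for c in itertools.combinations(ranks, n1)]
    )
    mean = stats_all.mean()  # rank-sum distribution is symmetric about its mean
    extreme = np.sum(np.abs(stats_all - mean) >= abs(obs - mean) - 1e-9)
    return float(extreme / stats_all.size)


class TestRankSum:
    def test_identical_arms_give_p_one(self):
        assert site_rank_sum_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_complete_separation_matches_enumeration(self):
        tumor = [0.9, 0.8, 0.85, 0.95]
        normal = [0.1, 0.15, 0.2, 0.05]
        p = site_rank_sum_test(tumor, normal)
        assert p == pytest.approx(2 / 70)
        assert p == pytest.approx(exact_rank_sum_p(np.array(tumor), np.array(normal)))

    def test_single_value_per_arm_is_underpowered(self):
        assert site_rank_sum_test([0.5], [0.7]) == pytest.approx(1.0)

    def test_empty_arm_rejected(self):
        with pytest.raises(InputError):
            site_rank_sum_test([], [0.5])

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=3, max_size=6),
        st.lists(st.floats(0, 1, width=32), min_size=3, max_size=6),
    )
    def test_small_sample_p_matches_enumeration(self, x, y):
        x, y = np.array(x, float), np.array(y, float)
        pooled = np.concatenate([x, y])
        if np.unique(pooled).size != pooled.size:
            return  # enumeration oracle below assumes no ties
        assert site_rank_sum_test(x, y) == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)


class TestStages:
    def test_stage1_retains_only_hand_computed_survivor(self, toy_matrix):
        # cgA passes all three criteria; cgB fails the delta threshold;
        # cgC has a clear difference but tumor beta below the 0.2 floor
        cfg = ScreenConfig(delta_min=0.12)
        out = stage1_differential_filter(toy_matrix, cfg)
        assert list(out.index) == ["cgA"]
        stats = compute_site_stats(toy_matrix, cfg)
        assert stats.loc["cgA", "delta_beta"] == pytest.approx(0.5)
        assert stats.loc["cgB", "delta_beta"] == pytest.approx(0.1)
        assert stats.loc["cgC", "mean_beta_tumor"] == pytest.approx(0.15, abs=0.01)

    def test_stage1_empty_on_identical_arms(self):
        rng = np.random.default_rng(0)
        v = rng.beta(2, 8, size=(20, 12))
        vals = pd.DataFrame(np.hstack([v[:, :6], v[:, :6], v[:, 6:9]]),
                            index=[f"cg{i}" for i in range(20)],
                            columns=[f"S{i}" for i in range(15)])
        groups = pd.Series(["tumor"] * 6 + ["normal"] * 6 + ["blood"] * 3, index=vals.columns)
        m = BetaMatrix(vals, groups)
        assert len(stage1_differential_filter(m, ScreenConfig())) == 0

    def test_stage1_vacuous_thresholds_keep_positive_delta_sites(self, toy_matrix):
        cfg = ScreenConfig(delta_min=0.0, p_max=1.0, beta_tumor_min=0.0)
        out = stage1_differential_filter(toy_matrix, cfg)
        stats = compute_site_stats(toy_matrix, cfg)
        assert set(out.index) == set(stats.index[stats.delta_beta >= 0])

    @pytest.mark.parametrize(
        "beta_tumor,beta_blood,kept",
        [(0.6, 0.5, False), (0.3, 0.0, True), (0.5, 0.25, True), (0.5, 0.26, False)],
    )
    def test_stage2_margin_arithmetic(self, beta_tumor, beta_blood, kept):
        t = pd.DataFrame(
            {"mean_beta_tumor": [beta_tumor], "mean_beta_normal": [0.1],
             "mean_beta_blood": [beta_blood], "delta_beta": [beta_tumor - 0.1], "p_value": [0.001]},
            index=["cgX"],
        )
        out = stage2_blood_filter(t, ScreenConfig())
        assert (len(out) == 1) is kept

    def test_stage2_zero_margin_is_identity(self, toy_matrix):
        stats = compute_site_stats(toy_matrix, ScreenConfig())
        out = stage2_blood_filter(stats, ScreenConfig(blood_margin_min=0.0))
        # every toy site has tumor mean >= blood mean
        assert list(out.index) == list(stats.index)

    def test_stage2_absolute_blood_rule(self, toy_matrix):
        stats = compute_site_stats(toy_matrix, ScreenConfig())
        out = stage2_blood_filter(stats, ScreenConfig(blood_rule="absolute", blood_beta_max=0.15))
        assert set(out.index) == {"cgA", "cgC"}  # cgB blood beta 0.20

    def test_stage_filters_commute(self, toy_matrix):
        cfg = ScreenConfig(delta_min=0.12)
        stats = compute_site_stats(toy_matrix, cfg)
        s12 = stage2_blood_filter(stage1_differential_filter(toy_matrix, cfg, stats_table=stats), cfg)
        s21 = stage1_differential_filter(toy_matrix, cfg, stats_table=stage2_blood_filter(stats, cfg))
        assert list(s12.index) == list(s21.index)


class TestRankAndRestrict:
    def test_rank_descending_by_delta(self):
        t = pd.DataFrame(
            {"delta_beta": [0.3, 0.5, 0.4], "p_value": [0.01] * 3},
            index=["cg1", "cg2", "cg3"],
        )
        assert list(rank_sites(t).index) == ["cg2", "cg3", "cg1"]

    def test_rank_ties_broken_by_p_then_id(self):
        t = pd.DataFrame(
            {"delta_beta": [0.4, 0.4, 0.4], "p_value": [0.001, 0.0001, 0.001]},
            index=["cgB", "cgC", "cgA"],
        )
        assert list(rank_sites(t).index) == ["cgC", "cgA", "cgB"]

    def test_rank_single_site(self):
        t = pd.DataFrame({"delta_beta": [0.4], "p_value": [0.01]}, index=["cgX"])
        assert list(rank_sites(t).index) == ["cgX"]

    def test_restrict_to_whitelist(self):
        t = pd.DataFrame(
            {"gene": ["SDC2", "SDC2", "SHOX2", "SEPT9", "TP53"], "delta_beta": [0.3] * 5},
            index=[f"cg{i}" for i in range(5)],
        )
        out = restrict_to_genes(t, {"SDC2", "SHOX2"})
        assert len(out) == 3
        assert restrict_to_genes(t, set()).empty
        assert len(restrict_to_genes(t, set(t.gene))) == 5

    def test_restrict_requires_annotation(self):
        t = pd.DataFrame({"gene": ["", ""], "delta_beta": [0.3, 0.2]}, index=["cg1", "cg2"])
        with pytest.raises(InputError):
            restrict_to_genes(t, {"SDC2"})


class TestRfSelect:
    def _matrix_with_splitter(self):
        rng = np.random.default_rng(5)
        n = 12
        splitter_t = rng.uniform(0.8, 0.95, n)
        splitter_n = rng.uniform(0.02, 0.15, n)
        noise = rng.uniform(0.4, 0.6, 2 * n + 3)
        vals = pd.DataFrame(
            [np.r_[splitter_t, splitter_n, [0.1, 0.1, 0.1]],
             np.r_[noise[: 2 * n], noise[2 * n :]]],
            index=["cgSplit", "cgNoise"],
            columns=[f"T{i}" for i in range(n)] + [f"N{i}" for i in range(n)] + ["B0", "B1", "B2"],
        )
        groups = pd.Series(["tumor"] * n + ["normal"] * n + ["blood"] * 3, index=vals.columns)
        return BetaMatrix(vals, groups)

    def _candidates(self, m, cfg):
        return compute_site_stats(m, cfg)

    def test_perfect_splitter_ranks_first(self):
        m = self._matrix_with_splitter()
        cfg = ScreenConfig(n_select=1, rf_trees=100, seed=0)
        out = rf_select(self._candidates(m, cfg), m, cfg)
        assert list(out.index) == ["cgSplit"]
        assert out.loc["cgSplit", "importance"] > 0.5

    def test_n_select_equal_to_candidates_returns_all(self):
        m = self._matrix_with_splitter()
        cfg = ScreenConfig(n_select=2, rf_trees=50, seed=0)
        out = rf_select(self._candidates(m, cfg), m, cfg)
        assert set(out.index) == {"cgSplit", "cgNoise"}

    def test_deterministic_under_fixed_seed(self):
        m = self._matrix_with_splitter()
        cfg = ScreenConfig(n_select=1, rf_trees=50, seed=42)
        a = rf_select(self._candidates(m, cfg), m, cfg)
        b = rf_select(self._candidates(m, cfg), m, cfg)
        assert list(a.index) == list(b.index)
        assert a["importance"].tolist() == b["importance"].tolist()

    def test_too_few_candidates_rejected(self):
        m = self._matrix_with_splitter()
        cfg = ScreenConfig(n_select=5)
        with pytest.raises(InputError):
            rf_select(self._candidates(m, cfg), m, cfg)


class TestRunScreen:
    def test_cascade_counts_monotone_and_final_spiked(self):
        m, truth = generate_beta_matrix(BetaSimConfig(seed=11))
        rep = run_screen(m, ScreenConfig(seed=11))
        counts = list(rep.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        spiked = set(truth.loc[truth.spiked, "site_id"])
        assert set(rep.selected) <= spiked
        assert len(rep.selected) == 2

    def test_each_stage_output_subset_of_input(self):
        m, _ = generate_beta_matrix(BetaSimConfig(n_sites=300, n_differential=20, seed=3))
        rep = run_screen(m, ScreenConfig(seed=3))
        t = rep.site_table
        assert (t.pass_stage2 <= t.pass_stage1).all()
        assert (t.pass_genes <= t.pass_stage2).all()
        assert (t.selected <= t.pass_genes).all()

    def test_gene_whitelist_restricts_selection(self):
        m, truth = generate_beta_matrix(BetaSimConfig(seed=11))
        ann = truth.set_index("site_id")["gene"]
        rep = run_screen(m, ScreenConfig(seed=11, gene_whitelist=("SDC2", "SHOX2")), annotation=ann)
        assert all(ann[s] in ("SDC2", "SHOX2") for s in rep.selected)
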