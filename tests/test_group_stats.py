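"""Kruskal–Wallis + Dunn machinery, pairwise matrices, normality battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cubkit.group_stats import (
    InsufficientGroupsError,
    kw_dunn,
    normality_battery,
    pairwise_yeast_codon_matrix,
    within_yeast_group_comparison,
)
from cubkit.simulate import SimulationConfig, simulate_corpus
from cubkit.tables import orf_rscu_table


class TestKwDunn:
    def test_identical_constant_groups(self):
        res = kw_dunn({"a": np.ones(5), "b": np.ones(5)})
        assert res[0].kw_h == 0.0 and not res[0].significant

    def test_clearly_separated_groups(self):
        res = kw_dunn({"a": np.array([1.0, 2, 3, 4]), "b": np.array([101.0, 102, 103, 104])})
        assert res[0].significant
        assert res[0].median_diff == pytest.approx(-100.0)

    def test_mean_rank_brute_force_oracle(self):
        # Dunn z rebuilt literally from pooled ranks must match
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        res = kw_dunn({"a": a, "b": b})[0]
        pooled = np.concatenate([a, b])
        order = pooled.argsort()
        ranks = np.empty(len(pooled))
        ranks[order] = np.arange(1, len(pooled) + 1)  # no ties: plain ranks
        n = len(pooled)
        z = (ranks[:12].mean() - ranks[12:].mean()) / np.sqrt(
            n * (n + 1) / 12 * (1 / 12 + 1 / 15)
        )
        assert res.dunn_z == pytest.approx(z, abs=1e-12)

    def test_two_group_matches_mann_whitney_asymptotic(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 25), rng.normal(0.8, 1, 25)
        res = kw_dunn({"a": a, "b": b})[0]
        mw = stats.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        assert res.dunn_p == pytest.approx(mw.pvalue, rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.lognormal(0, 1, 20), "b": rng.lognormal(0.5, 1, 20)}
        before = kw_dunn(groups)[0]
        after = kw_dunn({k: np.log(v) for k, v in groups.items()})[0]
        assert before.dunn_p == pytest.approx(after.dunn_p, abs=1e-12)

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        r1 = kw_dunn({"a": a, "b": b})[0]
        r2 = kw_dunn({"a": rng.permutation(a), "b": rng.permutation(b)})[0]
        assert r1.dunn_p == pytest.approx(r2.dunn_p)

    def test_small_groups_dropped_then_error(self):
        with pytest.raises(InsufficientGroupsError):
            kw_dunn({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})

    def test_bonferroni_adjustment_over_pairs(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(0, 1, 15) for g in "abc"}
        res = kw_dunn(groups, adjust="bonferroni")
        assert len(res) == 3
        for r in res:
            assert r.dunn_p_adj == pytest.approx(min(1.0, r.dunn_p * 3))

    def test_type_one_error_calibration(self):
        # two-group null: significance rate within 3 MC SE of alpha
        rng = np.random.default_rng(42)
        reps = 200
        hits = sum(
            kw_dunn({"a": rng.lognormal(0, 1, 30), "b": rng.lognormal(0, 1, 30)})[0].significant
            for _ in range(reps)
        )
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) <= 3 * se


@pytest.fixture(scope="module")
def null_tables():
    # three yeasts simulated from one shared archetype: a true null
    cfg = SimulationConfig(n_yeasts=3, n_orfs_per_yeast=120, seed=31,
                           n_archetypes=1, archetype_noise=0.0,
                           with_labels=False, with_pathways=False,
                           with_regulation=False)
    ds, _ = simulate_corpus(cfg)
    return {y: orf_rscu_table(d) for y, d in ds.items()}


class TestPairwiseYeastMatrix:
    def test_symmetry_and_bounds(self, null_tables):
        out = pairwise_yeast_codon_matrix(null_tables)
        m = out["matrix"]
        assert (m.values == m.values.T).all()
        assert m.values.max() <= 59
        assert (np.diag(m.values) == 0).all()

    def test_null_rate_near_alpha(self, null_tables):
        out = pairwise_yeast_codon_matrix(null_tables, alpha=0.05)
        frac = out["results"]["significant"].mean()
        assert frac < 0.15  # identical generators: near the type-I rate

    def test_planted_opposed_preferences_detected(self):
        cfg = SimulationConfig(n_yeasts=2, n_orfs_per_yeast=150, seed=32,
                               planted_preferred_mass=0.8,
                               with_labels=False, with_pathways=False,
                               with_regulation=False)
        ds, _ = simulate_corpus(cfg)
        tabs = {y: orf_rscu_table(d) for y, d in ds.items()}
        out = pairwise_yeast_codon_matrix(tabs)
        # independently planted profiles disagree for most families
        assert out["matrix"].iloc[0, 1] > 20

    def test_single_yeast_rejected(self, null_tables):
        one = {k: v for k, v in list(null_tables.items())[:1]}
        with pytest.raises(InsufficientGroupsError):
            pairwise_yeast_codon_matrix(one)


class TestWithinYeastComparison:
    def test_planted_expression_gradient(self):
        cfg = SimulationConfig(n_yeasts=1, n_orfs_per_yeast=300, seed=33,
                               expression_coupling=[("GGT", 0.5)],
                               group_proportions={"L1": 0.4, "L3": 0.2, "L5": 0.4},
                               with_labels=False, with_pathways=False,
                               with_regulation=False)
        ds, _ = simulate_corpus(cfg)
        y = ds["yeast001"]
        tab = orf_rscu_table(y)
        from cubkit.dataset import assign_expression_group

        labels = pd.Series([assign_expression_group(o.rpkm) for o in y.orfs],
                           index=tab.index)
        out = within_yeast_group_comparison(tab, labels)
        res = out["results"]
        ggt = res[res["unit"] == "GGT"].set_index(["group_a", "group_b"])
        assert ggt.loc[("L1", "L5"), "significant"]
        # the far pair separates at least as strongly as the near pair
        assert ggt.loc[("L1", "L5"), "dunn_p_adj"] <= ggt.loc[("L1", "L3"), "dunn_p_adj"]

    def test_single_group_rejected(self):
        tab = pd.DataFrame({"GGT": np.random.default_rng(0).normal(1, 0.1, 10)})
        labels = pd.Series(["L5"] * 10, index=tab.index)
        with pytest.raises(InsufficientGroupsError):
            within_yeast_group_comparison(tab, labels)


class TestNormalityBattery:
    def test_skewed_mixture_rejected_by_all(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.lognormal(0, 1, 2500), rng.lognormal(3, 0.5, 2500)])
        p = normality_battery(x)
        assert len(p) == 4 and (p < 0.05).all()

    def test_normal_sample_mostly_retained(self):
        rng = np.random.default_rng(7)
        rejections = []
        for _ in range(20):
            p = normality_battery(rng.normal(0, 1, 500))
            rejections.append((p < 0.05).any())
        assert np.mean(rejections) < 0.5

    def test_constant_sample_degenerate(self):
        p = normality_battery(np.ones(100))
        assert p.isna().all()

    def test_too_small_skipped(self):
        assert normality_battery(np.arange(5)).empty
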