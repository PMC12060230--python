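"""Mann-Whitney tests, family-wise permutation correction and Q_ST."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from songqtl import popdiff
from songqtl import synthetic_data as sd
from songqtl.trait_io import StrainTraitTable


def enumeration_two_sided_p(a, b):
    """Brute-force two-sided MW p: fraction of labelings at least as extreme."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    mu = n1 * len(b) / 2.0

    def u_of(idx):
        ranks = stats.rankdata(pooled)
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    obs = abs(u_of(range(n1)) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(combo) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = popdiff.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)  # 2/20 labelings

    def test_identical_multisets_give_p_one(self):
        res = popdiff.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            popdiff.mann_whitney([], [1.0])

    def test_ties_fall_back_to_normal_approximation(self):
        res = popdiff.mann_whitney([1, 1, 2], [2, 3, 3])
        assert res.method == "normal"
        ref = stats.mannwhitneyu([1, 1, 2], [2, 3, 3], method="asymptotic")
        assert res.pvalue == pytest.approx(ref.pvalue)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_exact_branch_matches_enumeration_small_groups(self, data):
        n1 = data.draw(st.integers(1, 5))
        n2 = data.draw(st.integers(1, 5))
        vals = data.draw(st.lists(st.integers(0, 10_000), min_size=n1 + n2,
                                  max_size=n1 + n2, unique=True))
        a, b = np.array(vals[:n1], float), np.array(vals[n1:], float)
        got = popdiff.mann_whitney(a, b)
        assert got.method == "exact"
        assert got.pvalue == pytest.approx(enumeration_two_sided_p(a, b), abs=1e-12)

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            ref = stats.mannwhitneyu(a, b, method="exact")
            got = popdiff.mann_whitney(a, b)
            assert got.u == pytest.approx(ref.statistic)
            assert got.pvalue == pytest.approx(ref.pvalue, rel=1e-12)


def _table_from_matrix(X, n1, n2, traits=None):
    strains = [f"FR{i}" for i in range(n1)] + [f"ZI{i}" for i in range(n2)]
    traits = traits or [f"t{j}" for j in range(X.shape[1])]
    means = pd.DataFrame(X, index=pd.Index(strains, name="strain"), columns=traits)
    return StrainTraitTable(means, means.notna().astype(int),
                            pd.Series(["FR"] * n1 + ["ZI"] * n2, index=means.index))


class TestFamilywisePermutation:
    def test_single_trait_family_fpr_converges_to_raw_p(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(17, 1))
        X[:10, 0] += 1.2
        table = _table_from_matrix(X, 10, 7)
        res = popdiff.familywise_permutation_fpr(table, n_perm=40_000, seed=1)
        assert res["fpr"].iloc[0] == pytest.approx(res["raw_p"].iloc[0], abs=0.01)

    def test_exhaustive_small_design_matches_brute_force(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(6, 2))
        X[:3] += 1.5
        table = _table_from_matrix(X, 3, 3)
        res = popdiff.familywise_permutation_fpr(table, exhaustive=True)
        min_ps = []
        for combo in itertools.combinations(range(6), 3):
            g1 = list(combo)
            g2 = [i for i in range(6) if i not in combo]
            min_ps.append(min(popdiff.mann_whitney(X[g1, j], X[g2, j]).pvalue
                              for j in range(2)))
        min_ps = np.array(min_ps)
        for j in range(2):
            p_emp = popdiff.mann_whitney(X[:3, j], X[3:, j]).pvalue
            assert res["fpr"].iloc[j] == pytest.approx(np.mean(min_ps <= p_emp))

    def test_fixed_seed_is_bit_reproducible(self, pop_panel_null):
        _, table, _ = pop_panel_null
        a = popdiff.familywise_permutation_fpr(table, n_perm=500, seed=42)
        b = popdiff.familywise_permutation_fpr(table, n_perm=500, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_fpr_dominates_raw_p_and_is_monotone(self, pop_panel_null):
        _, table, _ = pop_panel_null
        res = popdiff.familywise_permutation_fpr(table, n_perm=2000, seed=8)
        assert (res["fpr"] >= res["raw_p"] - 1e-9).all()  # family-wise control
        ordered = res.sort_values("raw_p")
        assert (np.diff(ordered["fpr"].values) >= -1e-12).all()

    def test_trait_with_missing_cell_is_dropped(self, pop_panel_null):
        _, table, _ = pop_panel_null
        broken = StrainTraitTable(table.means.copy(), table.counts.copy(), table.cohort)
        broken.means.iloc[0, 0] = np.nan
        res = popdiff.familywise_permutation_fpr(broken, n_perm=100, seed=0)
        assert table.means.columns[0] not in res.index
        assert len(res) == len(table.means.columns) - 1

    def test_wrong_strain_count_is_error(self, pop_panel_null):
        _, table, _ = pop_panel_null
        with pytest.raises(ValueError):
            popdiff.familywise_permutation_fpr(table, populations=("FR", "XX"))


class TestQst:
    def test_identical_population_means_give_zero(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 30)
        res = popdiff.qst(base, base)
        assert res.qst == 0.0

    def test_zero_within_variance_gives_one(self):
        res = popdiff.qst([1.0, 1.0, 1.0], [2.0, 2.0])
        assert res.qst == 1.0

    def test_too_few_strains_is_error(self):
        with pytest.raises(ValueError):
            popdiff.qst([1.0], [2.0, 3.0])

    def test_recovers_planted_variance_components(self):
        # fixed shift delta with delta^2/2 = V_b = 0.04; V_w = 0.01
        rng = np.random.default_rng(17)
        delta = np.sqrt(2 * 0.04)
        ests = [popdiff.qst(rng.normal(0, 0.1, 200),
                            rng.normal(delta, 0.1, 200)).qst for _ in range(20)]
        assert np.mean(ests) == pytest.approx(0.8, abs=0.02)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(2)
        fr, zi = rng.normal(0, 1, 10), rng.normal(1, 1, 7)
        a = popdiff.qst(fr, zi).qst
        b = popdiff.qst(3.5 * fr + 2.0, 3.5 * zi + 2.0).qst
        assert a == pytest.approx(b, rel=1e-12)

    def test_outbred_form_is_smaller(self):
        rng = np.random.default_rng(4)
        fr, zi = rng.normal(0, 1, 10), rng.normal(2, 1, 7)
        assert popdiff.qst(fr, zi, inbred=False).qst < popdiff.qst(fr, zi).qst


class TestQstFstQuantile:
    def test_q_above_all_values_gives_100(self):
        assert popdiff.qst_fst_quantile(0.9, [0.1, 0.2, 0.3]) == 100.0

    def test_median_sits_near_50(self):
        vals = np.linspace(0, 1, 101)
        pct = popdiff.qst_fst_quantile(float(np.median(vals)), vals)
        assert abs(pct - 50.0) <= 100.0 / len(vals)

    def test_matches_brute_force_rank_count(self):
        from songqtl import popgen_scan as pg
        cfg = sd.SimConfig(n_hap1=10, n_hap2=7, n_hap_windows=40, bn_F=0.2)
        p1, p2, _, _ = sd.simulate_haplotypes(cfg, 31)
        fst = pg.site_fst_distribution(p1, p2, n1=10, n2=7, seed=0)
        q = 0.797
        assert popdiff.qst_fst_quantile(q, fst) == pytest.approx(
            100.0 * np.sum(fst < q) / len(fst))

    def test_empty_distribution_is_error(self):
        with pytest.raises(ValueError):
            popdiff.qst_fst_quantile(0.5, [])
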