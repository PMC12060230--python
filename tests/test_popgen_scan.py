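"""Hudson F_ST (per site, per window), chi_MD and per-arm outlier calls."""

import numpy as np
import pandas as pd
import pytest

from songqtl import popgen_scan as pg
from songqtl import synthetic_data as sd
from songqtl.popgen_scan import HaplotypePanel


def hand_site_fst(p1, n1, p2, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


class TestSiteFst:
    def test_equal_frequencies_near_zero(self):
        res = pg.site_fst(50, 100, 50, 100)
        assert abs(res.fst) < 0.02

    def test_fixed_difference_is_one(self):
        res = pg.site_fst(10, 10, 0, 10)
        assert res.fst == pytest.approx(1.0)

    def test_hand_evaluated_formula(self):
        res = pg.site_fst(8, 10, 2, 10)
        num, den = hand_site_fst(0.8, 10, 0.2, 10)
        assert res.num == pytest.approx(num)
        assert res.den == pytest.approx(den)
        assert res.fst == pytest.approx(num / den)

    def test_jointly_monomorphic_is_undefined(self):
        assert np.isnan(pg.site_fst(0, 10, 0, 10).fst)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            pg.site_fst(1, 1, 2, 10)


def _panel_pair(seed=0, n1=12, n2=12, n_sites=20, length=1000):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, length + 1), n_sites, replace=False))
    H1 = rng.integers(0, 2, (n1, n_sites)).astype(np.int8)
    H2 = rng.integers(0, 2, (n2, n_sites)).astype(np.int8)
    return HaplotypePanel(H1, pos), HaplotypePanel(H2, pos), length


class TestWindowFst:
    def test_identical_panels_near_zero_at_large_n(self):
        # equal frequencies: expectation 0 with a small negative finite-sample
        # bias of order -1/(n-1)
        p1, _, length = _panel_pair(1, n1=400, n2=400)
        p2 = HaplotypePanel(p1.haplotypes.copy(), p1.positions)
        assert pg.window_fst_full(p1, p2, 0, length) == pytest.approx(0.0, abs=0.01)

    def test_all_fixed_differences_give_one(self):
        pos = np.array([10, 20, 30])
        p1 = HaplotypePanel(np.ones((5, 3), dtype=np.int8), pos)
        p2 = HaplotypePanel(np.zeros((5, 3), dtype=np.int8), pos)
        assert pg.window_fst_full(p1, p2, 0, 100) == pytest.approx(1.0)
        assert pg.window_fst_maxsnp(p1, p2, 0, 100) == pytest.approx(1.0)

    def test_full_window_matches_sum_of_terms_oracle(self):
        p1, p2, length = _panel_pair(2)
        c1, n1 = p1.allele_counts()
        c2, n2 = p2.allele_counts()
        nums, dens = [], []
        for j in range(len(p1.positions)):
            num, den = hand_site_fst(c1[j] / n1[j], n1[j], c2[j] / n2[j], n2[j])
            if den > 0:
                nums.append(num)
                dens.append(den)
        expected = sum(nums) / sum(dens)
        assert pg.window_fst_full(p1, p2, 0, length) == pytest.approx(expected, abs=1e-12)

    def test_maxsnp_equals_max_of_per_site_values(self):
        p1, p2, length = _panel_pair(3)
        c1, n1 = p1.allele_counts()
        c2, n2 = p2.allele_counts()
        ratios = []
        for j in range(len(p1.positions)):
            num, den = hand_site_fst(c1[j] / n1[j], n1[j], c2[j] / n2[j], n2[j])
            if den > 0:
                ratios.append(num / den)
        assert pg.window_fst_maxsnp(p1, p2, 0, length) == pytest.approx(max(ratios))

    def test_single_snp_window_equals_site_fst(self):
        p1, p2, _ = _panel_pair(4, n_sites=5)
        s = int(p1.positions[2])
        c1, n1 = p1.allele_counts()
        c2, n2 = p2.allele_counts()
        expected = pg.site_fst(int(c1[2]), int(n1[2]), int(c2[2]), int(n2[2])).fst
        assert pg.window_fst_full(p1, p2, s - 1, s) == pytest.approx(expected)

    def test_invariant_to_haplotype_order_and_label_swap(self):
        p1, p2, length = _panel_pair(5)
        a = pg.window_fst_full(p1, p2, 0, length)
        rng = np.random.default_rng(0)
        p1s = HaplotypePanel(p1.haplotypes[rng.permutation(p1.n_haplotypes)], p1.positions)
        p1f = HaplotypePanel(1 - p1.haplotypes, p1.positions)
        p2f = HaplotypePanel(1 - p2.haplotypes, p2.positions)
        assert pg.window_fst_full(p1s, p2, 0, length) == pytest.approx(a)
        assert pg.window_fst_full(p1f, p2f, 0, length) == pytest.approx(a)

    def test_balding_nichols_estimator_consistency(self):
        cfg = sd.SimConfig(n_hap_windows=60, bn_F=0.2)
        p1, p2, windows, _ = sd.simulate_haplotypes(cfg, 8)
        vals = [pg.window_fst_full(p1, p2, int(w.start), int(w.end))
                for w in windows.itertuples()]
        assert np.nanmean(vals) == pytest.approx(0.2, abs=0.03)


class TestChiMd:
    def test_identical_haplotypes_both_populations_give_one(self):
        pos = np.array([5, 40, 80])
        H = np.zeros((4, 3), dtype=np.int8)
        p = HaplotypePanel(H, pos)
        q = HaplotypePanel(H.copy(), pos)
        assert pg.window_chi_md(p, q, 0, 100) == pytest.approx(1.0)

    def test_midpoint_difference_halves_identity(self):
        # pop1 identical over the window; pop2 differs at the middle site:
        # two single-site runs with midpoint spans ~ half the window each
        pos = np.array([1, 50, 99])
        p1 = HaplotypePanel(np.array([[0, 1, 0], [0, 1, 0]], dtype=np.int8), pos)
        p2 = HaplotypePanel(np.array([[0, 1, 0], [0, 0, 0]], dtype=np.int8), pos)
        chi = pg.window_chi_md(p1, p2, 0, 100)
        assert chi == pytest.approx(98.0 / 51.0)  # ~2 under the run-length rule
        # reciprocal orientation inverts exactly
        assert pg.window_chi_md(p2, p1, 0, 100) == pytest.approx(51.0 / 98.0)

    def test_missing_sites_skip_without_breaking_runs(self):
        pos = np.array([10, 20, 30, 40])
        a = np.array([[0, 1, 0, 1]], dtype=np.int8)
        b = np.array([[0, -1, 0, 1]], dtype=np.int8)
        H = np.vstack([a, b])
        got = pg._pair_identity_bp(H[0], H[1], pos, 0, 50, max_missing_frac=0.5)
        assert got == pytest.approx(30.0)  # run 10..40 via compared sites only

    def test_zero_reference_identity_gives_inf(self):
        pos = np.array([10, 20])
        p1 = HaplotypePanel(np.zeros((2, 2), dtype=np.int8), pos)
        p2 = HaplotypePanel(np.array([[0, 1], [1, 0]], dtype=np.int8), pos)
        assert pg.window_chi_md(p1, p2, 0, 30) == np.inf

    def test_sweep_elevates_chi_md_over_neutral(self):
        cfg = sd.SimConfig(n_hap_windows=30, sweep_window=15)
        chis, neutral = [], []
        for s in range(8):
            p1, p2, windows, _ = sd.simulate_haplotypes(cfg, 700 + s)
            stats = pg.windows_stats(p1, p2, windows)
            chis.append(stats["chi_md"].iloc[15])
            neutral.append(stats["chi_md"].drop(15).median())
        assert np.median(chis) > np.median(neutral)
        assert sum(c > n for c, n in zip(chis, neutral)) >= 7

    def test_pair_subsampling_is_seeded_and_close(self):
        p1, p2, length = _panel_pair(9, n1=14, n2=14, n_sites=30)
        full = pg.window_chi_md(p1, p2, 0, length)
        sub1 = pg.window_chi_md(p1, p2, 0, length, max_pairs=40, seed=5)
        sub2 = pg.window_chi_md(p1, p2, 0, length, max_pairs=40, seed=5)
        assert sub1 == sub2
        assert sub1 == pytest.approx(full, rel=0.25)


class TestArmOutliers:
    def test_top_fraction_flagged_exactly(self):
        rng = np.random.default_rng(10)
        vals = rng.permutation(1000).astype(float)
        stats = pd.DataFrame({"arm": "3R", "start": np.arange(1000),
                              "end": np.arange(1000) + 1,
                              "fst_fullwin": vals, "fst_maxsnp": 0.0,
                              "chi_md": 1.0})
        out = pg.arm_outliers(stats, q=0.01, min_windows=10)
        flagged = set(np.flatnonzero(out["outlier_fst_fullwin"]))
        assert flagged == set(np.argsort(vals)[-10:])

    def test_all_equal_values_flag_everything(self):
        stats = pd.DataFrame({"arm": "3R", "start": np.arange(50),
                              "end": np.arange(50) + 1,
                              "fst_fullwin": 0.5, "fst_maxsnp": 0.5, "chi_md": 1.0})
        out = pg.arm_outliers(stats, q=0.01, min_windows=10)
        assert out["outlier_any"].all()

    def test_matches_sort_and_threshold_oracle_per_arm(self):
        rng = np.random.default_rng(11)
        stats = pd.DataFrame({
            "arm": np.repeat(["2L", "3R"], 200),
            "start": np.tile(np.arange(200), 2),
            "end": np.tile(np.arange(200), 2) + 1,
            "fst_fullwin": rng.normal(size=400),
            "fst_maxsnp": rng.normal(size=400),
            "chi_md": rng.lognormal(size=400),
        })
        out = pg.arm_outliers(stats, q=0.05, min_windows=10)
        for arm in ("2L", "3R"):
            sub = out[out["arm"] == arm]
            for col in pg.STAT_COLUMNS:
                thr = np.quantile(sub[col], 0.95)
                np.testing.assert_array_equal(sub[f"outlier_{col}"].values,
                                              (sub[col] >= thr).values)

    def test_quantile_ranks_in_unit_interval(self):
        p1, p2, windows, _ = sd.simulate_haplotypes(
            sd.SimConfig(n_hap_windows=20), 12)
        stats = pg.windows_stats(p1, p2, windows)
        out = pg.arm_outliers(stats, min_windows=5)
        for col in pg.STAT_COLUMNS:
            r = out[f"rank_{col}"].dropna()
            assert ((r > 0) & (r <= 1)).all()


class TestPanelIO:
    def test_tsv_round_trip(self, tmp_path):
        p1, _, _ = _panel_pair(13)
        p1.to_tsv(tmp_path / "p.tsv")
        back = HaplotypePanel.from_tsv(tmp_path / "p.tsv")
        np.testing.assert_array_equal(back.haplotypes, p1.haplotypes)
        np.testing.assert_array_equal(back.positions, p1.positions)

    def test_vcf_haploid_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        H = rng.integers(0, 2, (6, 10)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 500), 10, replace=False))
        lines = ["##fileformat=VCFv4.2",
                 '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                 "##contig=<ID=3R,length=1000>",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(f"s{i}" for i in range(6))]
        for j in range(10):
            gts = "\t".join(str(H[i, j]) for i in range(6))
            lines.append(f"3R\t{pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}")
        vcf = tmp_path / "p.vcf"
        vcf.write_text("\n".join(lines) + "\n")
        back = HaplotypePanel.from_vcf(vcf)
        np.testing.assert_array_equal(back.positions, pos)
        np.testing.assert_array_equal(back.haplotypes, H)
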