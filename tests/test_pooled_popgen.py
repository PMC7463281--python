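import math

import numpy as np
import pandas as pd
import pytest

from xdrive import pooled_popgen as pg
from xdrive import simulate
from xdrive.coalescent import DemographyScenario

from conftest import make_exact_sync_table, make_sync_table


class TestSyncIO:
    def test_parse_toy_file(self, tmp_path):
        path = tmp_path / "toy.sync"
        path.write_text(
            "chr1\t10\tA\t30:0:0:20:0:0\t50:0:0:0:0:0\n"
            "chr1\t11\tC\t0:0:48:0:0:0\t0:0:47:1:0:0\n"
            "chr1\t12\tG\t0:0:0:50:0:0\t0:0:0:49:0:0\n"
        )
        pools = [pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)]
        t = pg.load_sync_table(path, pools)
        assert len(t) == 3
        assert t.counts[0, 0, 0] == 30 and t.counts[0, 0, 3] == 20
        assert t.counts[1, 1, 2] == 47 and t.counts[1, 1, 3] == 1
        assert list(t.pos) == [10, 11, 12]

    def test_non_numeric_count_names_line(self, tmp_path):
        path = tmp_path / "bad.sync"
        path.write_text(
            "chr1\t10\tA\t30:0:0:20:0:0\t50:0:0:0:0:0\n"
            "chr1\t11\tC\t0:0:x:0:0:0\t0:0:47:1:0:0\n"
        )
        with pytest.raises(ValueError, match=":2"):
            pg.load_sync_table(path, [pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)])

    def test_wrong_column_count(self, tmp_path):
        path = tmp_path / "bad.sync"
        path.write_text("chr1\t10\tA\t30:0:0:20:0:0\n")
        with pytest.raises(ValueError, match="columns"):
            pg.load_sync_table(path, [pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)])

    def test_duplicate_position_rejected(self):
        counts = np.zeros((2, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 5
        with pytest.raises(ValueError, match="duplicate"):
            pg.SyncSiteTable(
                chrom=np.array(["chr1", "chr1"]),
                pos=np.array([7, 7]),
                ref=np.array(["A", "A"]),
                counts=counts,
                pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
            )

    def test_round_trip(self, tmp_path):
        sc = DemographyScenario(locus_length=300)
        table, _ = simulate.sim_pooled_counts(sc, depth=40, seed=9)
        path = tmp_path / "rt.sync"
        pg.write_sync_table(table, path)
        back = pg.load_sync_table(path, table.pools)
        assert np.array_equal(back.counts, table.counts)
        assert np.array_equal(back.pos, table.pos)
        assert np.array_equal(back.ref, table.ref)


class TestFilterSites:
    def make_table(self, cov_site=(50, 50)):
        freq = [0.5, 1.0, 0.25, 1.0]
        t = make_sync_table(freq, [0.5, 1.0, 0.75, 1.0], depth=50, seed=1)
        return t

    def test_low_coverage_uncallable(self):
        # coverage 5 in a pool of haploid size 8 fails the callability rule
        counts = np.zeros((3, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 50
        counts[1, 0, 0] = 5
        t = pg.SyncSiteTable(
            chrom=np.array(["c"] * 3), pos=np.array([1, 2, 3]),
            ref=np.array(["A"] * 3), counts=counts,
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
        )
        out = pg.filter_sites(t)
        assert not out.callable_mask[1]
        assert out.callable_mask[0] and out.callable_mask[2]

    def test_high_coverage_outlier_uncallable(self):
        counts = np.zeros((20, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 50
        counts[7, 1, 0] = 500
        t = pg.SyncSiteTable(
            chrom=np.array(["c"] * 20), pos=np.arange(1, 21),
            ref=np.array(["A"] * 20), counts=counts,
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
        )
        out = pg.filter_sites(t)
        assert not out.callable_mask[7]

    def test_indel_margin_masks_nearby_sites(self):
        counts = np.zeros((11, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 50
        t = pg.SyncSiteTable(
            chrom=np.array(["c"] * 11), pos=np.arange(1, 12),
            ref=np.array(["A"] * 11), counts=counts,
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
        )
        indels = pd.DataFrame({"chrom": ["c"], "pos": [6]})
        out = pg.filter_sites(t, indel_positions=indels)
        # positions 1..11, indel at 6: 1..11 within +-5 except 1..0 -> 1,2..  pos 1..11 distance <=5 covers 1..11
        masked = ~out.callable_mask
        assert masked[np.abs(out.pos - 6) <= 5].all()
        assert out.callable_mask[np.abs(out.pos - 6) > 5].all()

    def test_triallelic_site_removed(self):
        counts = np.zeros((2, 2, 6), dtype=np.int64)
        counts[0, :, 0] = 50
        counts[1, 0, 0] = 20
        counts[1, 0, 1] = 20
        counts[1, 1, 2] = 50
        t = pg.SyncSiteTable(
            chrom=np.array(["c", "c"]), pos=np.array([1, 2]),
            ref=np.array(["A", "A"]), counts=counts,
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
        )
        out = pg.filter_sites(t)
        assert len(out) == 1
        assert out.pos[0] == 1

    def test_empty_table_ok(self):
        t = pg.SyncSiteTable(
            chrom=np.array([], dtype=str), pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=str), counts=np.zeros((0, 2, 6), dtype=np.int64),
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
        )
        assert len(pg.filter_sites(t)) == 0


def fst_oracle(freq, cov, sizes):
    """Literal scalar transcription of the pooled ANOVA moment estimator.

    Written directly from the moment equations for reads drawn with
    replacement from n_i pooled chromosomes:
      E[p_i(1-p_i)]   = b * (C_i-1)(n_i-1)/(C_i n_i)
      Var(p_i)        = a + b * (C_i+n_i-1)/(C_i n_i)
    solved site by site for (a, b) via the within/between sums of squares,
    then combined over sites as a ratio of sums.
    """
    num = den = 0.0
    for s in range(len(freq)):
        C1, C2 = cov[s]
        n1, n2 = sizes
        p1, p2 = freq[s]
        Ct = C1 + C2
        ssi = C1 * p1 * (1 - p1) + C2 * p2 * (1 - p2)
        b = ssi / ((C1 - 1) * (n1 - 1) / n1 + (C2 - 1) * (n2 - 1) / n2)
        pbar = (C1 * p1 + C2 * p2) / Ct
        ssp = C1 * (p1 - pbar) ** 2 + C2 * (p2 - pbar) ** 2
        beta1 = (C1 + n1 - 1) / (C1 * n1)
        beta2 = (C2 + n2 - 1) / (C2 * n2)
        nc = Ct - (C1**2 + C2**2) / Ct
        m = (C1 * beta1 + C2 * beta2) - (C1**2 * beta1 + C2**2 * beta2) / Ct
        a = (ssp - b * m) / nc
        num += a
        den += a + b
    return num / den


class TestFstWindows:
    def test_identical_pools_near_zero(self):
        # identical counts carry no between-pool signal; in the
        # read-limited regime (pools much larger than depth) the estimate
        # sits within a hair of zero
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0.2, 0.8, 100)
        t = make_sync_table(freqs, freqs, depth=80, sizes=(1000, 1000), seed=4)
        ws = pg.fst_windows(t, ("p1", "p2"), window_snps=100)
        assert len(ws) == 1
        assert abs(ws[0].estimate) <= 0.02
        # with 8-chromosome pools the same configuration is conditionally
        # negative of order -1/(n-1): reported as computed and flagged
        t8 = make_sync_table(freqs, freqs, depth=80, sizes=(8, 8), seed=4)
        w8 = pg.fst_windows(t8, ("p1", "p2"), window_snps=100)[0]
        assert -1 / 7 - 0.05 <= w8.estimate <= 0.0
        assert w8.flags == "negative"

    def test_fixed_differences_near_one(self):
        n = 100
        t = make_sync_table([0.0] * n, [1.0] * n, depth=100, seed=5)
        ws = pg.fst_windows(t, ("p1", "p2"), window_snps=100)
        assert ws[0].estimate >= 0.95

    def test_matches_literal_transcription(self):
        rng = np.random.default_rng(8)
        f1 = rng.uniform(0.05, 0.95, 10)
        f2 = rng.uniform(0.05, 0.95, 10)
        t = make_sync_table(f1, f2, depth=60, seed=6)
        freq, cov, sizes, usable = pg._site_arrays_for_pair(t, ("p1", "p2"))
        poly = usable & (np.nanmax(freq, axis=1) > 0) & (np.nanmin(freq, axis=1) < 1)
        ws = pg.fst_windows(t, ("p1", "p2"), window_snps=10)
        expected = fst_oracle(freq[poly], cov[poly], sizes)
        assert ws[0].estimate == pytest.approx(expected, abs=1e-12)

    def test_panmictic_mean_near_zero(self):
        # two pools of 8 chromosomes drawn from one panmictic population
        rng = np.random.default_rng(12)
        n_snps = 100 * 120
        p = rng.uniform(0.1, 0.9, n_snps)
        f1 = rng.binomial(8, p) / 8
        f2 = rng.binomial(8, p) / 8
        t = make_sync_table(f1, f2, depth=50, seed=13)
        ws = pg.fst_windows(t, ("p1", "p2"), window_snps=100)
        vals = np.array([w.estimate for w in ws if not w.partial])
        assert len(vals) >= 100
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) <= 3 * se

    def test_monotone_in_divergence_time(self):
        from scipy.stats import spearmanr

        times = np.linspace(2e5, 3e6, 10)
        means = []
        for i, t_origin in enumerate(times):
            sc = DemographyScenario(origin_time=t_origin, split_time=2 * t_origin + 2e6,
                                    locus_length=4000)
            table, _ = simulate.sim_pooled_counts(sc, depth=50, n_windows=12,
                                                  seed=100 + i)
            ws = pg.fst_windows(table, ("ST", "SR"), window_snps=40)
            vals = [w.estimate for w in ws if not (w.partial or math.isnan(w.estimate))]
            means.append(np.mean(vals))
        rho = spearmanr(times, means).statistic
        assert rho >= 0.9

    def test_monomorphic_window_is_na(self):
        t = make_sync_table([1.0] * 5, [1.0] * 5, depth=50, seed=7)
        ws = pg.fst_windows(t, ("p1", "p2"), window_snps=5)
        assert ws == []  # no polymorphic SNPs -> no windows

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(21)
        f1 = rng.uniform(0.1, 0.9, 100)
        f2 = np.clip(f1 + rng.normal(0, 0.25, 100), 0, 1)
        t = make_sync_table(f1, f2, depth=60, seed=22)
        ws = pg.fst_windows(t, ("p1", "p2"), window_snps=100, n_boot=200, seed=1)
        w = ws[0]
        assert w.ci_low <= w.estimate <= w.ci_high


class TestDiversityWindows:
    def test_monomorphic_window_pi_zero(self):
        t = make_sync_table([1.0] * 50, [1.0] * 50, depth=50, seed=2)
        ws = pg.diversity_windows(t, "p1", "pi", window_bp=50)
        assert ws[0].estimate == 0.0

    def test_min_count_excludes_singleton_reads(self):
        # one variant read below the min-count threshold: no diversity
        counts = np.zeros((10, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 50
        counts[4, 0, 0] = 49
        counts[4, 0, 3] = 1
        t = pg.SyncSiteTable(
            chrom=np.array(["c"] * 10), pos=np.arange(1, 11),
            ref=np.array(["A"] * 10), counts=counts,
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
        )
        ws = pg.diversity_windows(t, "a", "pi", window_bp=10, min_count=2)
        assert ws[0].estimate == 0.0
        ws1 = pg.diversity_windows(t, "a", "pi", window_bp=10, min_count=1)
        assert ws1[0].estimate > 0.0

    def test_pi_recovers_generating_heterozygosity(self):
        # mean windowed pi over replicate loci within 10% of the known
        # sample heterozygosity of the generating coalescent draws
        sc = DemographyScenario(locus_length=1000)
        est, truth = [], []
        for rep in range(200):
            table, tr = simulate.sim_pooled_counts(sc, depth=60, seed=1000 + rep)
            ws = pg.diversity_windows(table, "ST", "pi", window_bp=1000)
            est.append(ws[0].estimate)
            truth.append(tr["windows"].pi_ST.iloc[0])
        assert np.mean(est) == pytest.approx(np.mean(truth), rel=0.10)

    def test_tajimas_d_reads_match_true_counts(self):
        # read-based windowed D agrees with D computed from the true pool
        # allele counts, on average over replicates, within 3 SE
        from xdrive.coalescent import tajimas_d_from_counts

        sc = DemographyScenario(locus_length=1000)
        diffs = []
        for rep in range(120):
            table, tr = simulate.sim_pooled_counts(sc, depth=60, seed=2000 + rep)
            ws = pg.diversity_windows(table, "ST", "tajimas_d", window_bp=1000)
            if math.isnan(ws[0].estimate):
                continue
            sites = tr["sites"]
            f = sites.freq_ST.values
            seg = (f > 0) & (f < 1)
            pi_sum = (2 * f * (1 - f) * 8 / 7)[seg].sum()
            d_true = tajimas_d_from_counts(pi_sum, int(seg.sum()), 8)
            diffs.append(ws[0].estimate - d_true)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se

    def test_uncallable_window_skipped(self):
        counts = np.zeros((20, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 50
        t = pg.SyncSiteTable(
            chrom=np.array(["c"] * 20), pos=np.arange(1, 21),
            ref=np.array(["A"] * 20), counts=counts,
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
            callable_mask=np.array([False] * 10 + [True] * 10),
        )
        ws = pg.diversity_windows(t, "a", "pi", window_bp=20, max_uncallable=0.4)
        assert ws[0].flags == "skipped_uncallable"
        assert math.isnan(ws[0].estimate)

    def test_intergenic_mask_excludes_genes(self):
        counts = np.zeros((30, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 25
        counts[:, :, 3] = 25  # every site at 50/50: high diversity
        t = pg.SyncSiteTable(
            chrom=np.array(["c"] * 30), pos=np.arange(1, 31),
            ref=np.array(["A"] * 30), counts=counts,
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
        )
        genes = pd.DataFrame({"chrom": ["c"], "start": [1], "end": [15]})
        ws = pg.diversity_windows(t, "a", "pi", window_bp=30, gene_intervals=genes)
        assert ws[0].n_sites == 15


class TestDxy:
    def test_identical_monomorphic_pools(self):
        t = make_sync_table([1.0] * 20, [1.0] * 20, depth=50, seed=1)
        res = pg.dxy(t, ("p1", "p2"), n_boot=0)
        assert res["dxy_expectation"] == 0.0
        assert res["dxy_draw"] == 0.0

    def test_five_fixed_of_hundred(self):
        f1 = [1.0] * 100
        f2 = [1.0] * 95 + [0.0] * 5
        t = make_sync_table(f1, f2, depth=80, seed=2)
        res = pg.dxy(t, ("p1", "p2"), n_boot=0, seed=0)
        assert res["dxy_expectation"] == pytest.approx(0.05, abs=1e-12)

    def test_half_vs_fixed_expectation_and_draws(self):
        # one site with p=(0.5, 0.5) against q=(1, 0) in ten sites:
        # exact expectation 0.05; draw-based mean within 3 SE over 1e4 draws
        counts = np.zeros((10, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 50
        counts[0, 0, 0] = 25
        counts[0, 0, 3] = 25
        t = pg.SyncSiteTable(
            chrom=np.array(["c"] * 10), pos=np.arange(1, 11),
            ref=np.array(["A"] * 10), counts=counts,
            pools=[pg.PoolInfo("a", 8), pg.PoolInfo("b", 8)],
        )
        res = pg.dxy(t, ("a", "b"), n_boot=0, n_draws=10_000, seed=3)
        assert res["dxy_expectation"] == pytest.approx(0.05, abs=1e-12)
        se = math.sqrt(0.05 * 0.95 / 10) / math.sqrt(10_000)
        assert abs(res["dxy_draw"] - 0.05) <= 3 * se

    def test_pool_swap_and_relabel_invariance(self):
        rng = np.random.default_rng(17)
        f1 = rng.uniform(0, 1, 50)
        f2 = rng.uniform(0, 1, 50)
        t = make_sync_table(f1, f2, depth=60, seed=18)
        a = pg.dxy(t, ("p1", "p2"), n_boot=0)["dxy_expectation"]
        b = pg.dxy(t, ("p2", "p1"), n_boot=0)["dxy_expectation"]
        assert a == pytest.approx(b, abs=1e-15)
        # relabel alleles: swap the A and G count columns everywhere
        t2 = make_sync_table(f1, f2, depth=60, seed=18)
        t2.counts[:, :, [0, 3]] = t2.counts[:, :, [3, 0]]
        c = pg.dxy(t2, ("p1", "p2"), n_boot=0)["dxy_expectation"]
        assert a == pytest.approx(c, abs=1e-15)

    def test_outgroup_comparison(self):
        t = make_sync_table([1.0] * 10, [1.0] * 10, depth=50, seed=4,
                            outgroup=["A"] * 8 + ["G"] * 2)
        res = pg.dxy(t, ("p1", "outgroup"), n_boot=0)
        assert res["dxy_expectation"] == pytest.approx(0.2, abs=1e-12)

    def test_no_callable_sites_errors(self):
        t = make_sync_table([1.0] * 5, [1.0] * 5, depth=50, seed=5)
        t.callable_mask[:] = False
        with pytest.raises(ValueError, match="callable"):
            pg.dxy(t, ("p1", "p2"), n_boot=0)


class TestClassifySites:
    def toy_table(self):
        """12 hand-built sites covering every category."""
        spec = [
            # (pool1 A, pool1 G, pool2 A, pool2 G, outgroup)
            (50, 0, 0, 50, "G"),   # fixed derived in pool1 (anc G)
            (50, 0, 0, 50, "A"),   # fixed derived in pool2 (anc A)
            (50, 0, 0, 50, ""),    # unpolarizable (no outgroup base)
            (50, 0, 0, 50, "C"),   # unpolarizable (outgroup not among alleles)
            (25, 25, 30, 20, "A"), # shared polymorphism
            (25, 25, 50, 0, "A"),  # private pool1
            (25, 25, 0, 50, "G"),  # private pool1
            (50, 0, 25, 25, "A"),  # private pool2
            (50, 0, 50, 0, "A"),   # monomorphic
            (0, 50, 0, 50, "G"),   # monomorphic
            (50, 0, 50, 0, "G"),   # monomorphic (derived in both; still monomorphic)
            (50, 0, 0, 50, "G"),   # fixed derived in pool1
        ]
        counts = np.zeros((len(spec), 2, 6), dtype=np.int64)
        og = []
        for i, (a1, g1, a2, g2, o) in enumerate(spec):
            counts[i, 0, 0] = a1
            counts[i, 0, 3] = g1
            counts[i, 1, 0] = a2
            counts[i, 1, 3] = g2
            og.append(o)
        return pg.SyncSiteTable(
            chrom=np.array(["c"] * len(spec)), pos=np.arange(1, len(spec) + 1),
            ref=np.array(["A"] * len(spec)), counts=counts,
            pools=[pg.PoolInfo("p1", 8), pg.PoolInfo("p2", 8)],
            outgroup=np.array(og),
        )

    def test_hand_enumerated_counts(self):
        df, summary = pg.classify_sites(self.toy_table(), ("p1", "p2"))
        c = summary["counts"]
        assert c["fixed_derived_pool1"] == 2
        assert c["fixed_derived_pool2"] == 1
        assert c["unpolarizable"] == 2
        assert c["shared_polymorphism"] == 1
        assert c["private_polymorphism_pool1"] == 2
        assert c["private_polymorphism_pool2"] == 1
        assert c["monomorphic"] == 3
        assert c["uncallable"] == 0

    def test_counts_sum_to_total(self):
        t = self.toy_table()
        _, summary = pg.classify_sites(t, ("p1", "p2"))
        assert sum(summary["counts"].values()) == len(t)

    def test_fixed_shared_ratio(self):
        _, summary = pg.classify_sites(self.toy_table(), ("p1", "p2"))
        assert summary["fixed_shared_ratio_pool1"] == pytest.approx(2.0)
        assert summary["fixed_shared_ratio_pool2"] == pytest.approx(1.0)

    def test_outgroup_removal_converts_only_fixed_categories(self):
        t = self.toy_table()
        df_with, _ = pg.classify_sites(t, ("p1", "p2"))
        t.outgroup = None
        df_without, _ = pg.classify_sites(t, ("p1", "p2"))
        changed = df_with.category != df_without.category
        assert set(df_with.category[changed]) <= {"fixed_derived_pool1", "fixed_derived_pool2"}
        assert set(df_without.category[changed]) == {"unpolarizable"}
        keep = {"shared_polymorphism", "private_polymorphism_pool1",
                "private_polymorphism_pool2", "monomorphic"}
        assert (df_with.category[~changed][df_with.category[~changed].isin(keep)]
                == df_without.category[~changed][df_without.category[~changed].isin(keep)]).all()

    def test_uncallable_site(self):
        t = self.toy_table()
        t.callable_mask[0] = False
        df, summary = pg.classify_sites(t, ("p1", "p2"))
        assert df.category.iloc[0] == "uncallable"
        assert summary["counts"]["uncallable"] == 1
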