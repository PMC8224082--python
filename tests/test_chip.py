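"""ChIP binding: counting, thresholds, NB-Wald, BH, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special
from scipy import stats as sps

from myoquant.chip import (
    GeneCountTable,
    GeneModel,
    bh_adjust,
    classify_bound,
    count_reads_per_gene,
    estimate_dispersion,
    nb_wald_test,
    reads_per_kbp,
    size_factors,
    vst_and_cluster,
)
from myoquant.synthetic import CountSimSpec, simulate_chip_counts


def make_table(counts, conditions, lengths=None):
    samples = [f"s{i}" for i in range(counts.shape[1])]
    return GeneCountTable(
        counts=pd.DataFrame(counts, columns=samples),
        sample_info=pd.DataFrame({"condition": conditions}, index=samples),
        gene_lengths=None if lengths is None else pd.Series(lengths),
    )


class TestCounting:
    def test_single_read_inside_single_gene(self):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [200]})
        genes = [GeneModel("g1", "chr1", 100, 1000)]
        counts = count_reads_per_gene(reads, genes, extend_to_bp=None)
        assert counts["g1"] == 1

    def test_no_reads_all_zero(self):
        genes = [GeneModel("g1", "chr1", 0, 500), GeneModel("g2", "chr2", 0, 500)]
        counts = count_reads_per_gene(pd.DataFrame(columns=["chrom", "start", "end"]), genes)
        assert (counts == 0).all()

    def test_malformed_interval_reports_row(self):
        reads = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [10, 50], "end": [20, 40]})
        with pytest.raises(ValueError, match="row 1"):
            count_reads_per_gene(reads, [GeneModel("g", "chr1", 0, 100)], extend_to_bp=None)

    def test_matches_exhaustive_midpoint_oracle(self, rng):
        for _ in range(30):
            n_reads, n_genes = 200, 10
            starts = rng.integers(0, 10000, n_reads)
            lengths = rng.integers(20, 120, n_reads)
            reads = pd.DataFrame(
                {"chrom": "chrT", "start": starts, "end": starts + lengths}
            )
            g_start = rng.integers(0, 9000, n_genes)
            g_len = rng.integers(200, 2500, n_genes)
            genes = [
                GeneModel(f"g{i}", "chrT", int(s), int(s + l))
                for i, (s, l) in enumerate(zip(g_start, g_len))
            ]
            got = count_reads_per_gene(reads, genes, extend_to_bp=None)
            mids = (reads["start"] + reads["end"]) / 2
            for g in genes:
                expected = int(((mids >= g.start) & (mids < g.end)).sum())
                assert got[g.gene_id] == expected

    def test_invariant_under_read_and_gene_permutation(self, rng):
        starts = rng.integers(0, 5000, 100)
        reads = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 50})
        genes = [GeneModel(f"g{i}", "c", int(200 * i), int(200 * i + 500)) for i in range(8)]
        base = count_reads_per_gene(reads, genes, extend_to_bp=None)
        shuffled = count_reads_per_gene(
            reads.sample(frac=1, random_state=1).reset_index(drop=True),
            list(np.array(genes, dtype=object)[rng.permutation(8)]),
            extend_to_bp=None,
        )
        assert (base.sort_index() == shuffled.sort_index()).all()

    def test_fragment_extension_shifts_midpoint_by_strand(self):
        # 50 bp read at [1000, 1050); extended to 300 bp the midpoint moves
        reads = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [1000, 1000], "end": [1050, 1050], "strand": ["+", "-"]}
        )
        genes = [GeneModel("right", "c", 1100, 1200), GeneModel("left", "c", 850, 1000)]
        counts = count_reads_per_gene(reads, genes, extend_to_bp=300)
        # + read spans [1000,1300): midpoint 1150 -> "right"; - read spans [750,1050): midpoint 900 -> "left"
        assert counts["right"] == 1 and counts["left"] == 1


class TestThresholdRule:
    def test_reads_per_kbp_values(self):
        assert reads_per_kbp(300, 6000) == pytest.approx(50.0)
        assert reads_per_kbp(100, 1000) == pytest.approx(100.0)
        assert reads_per_kbp(0, 1234) == 0.0
        with pytest.raises(ValueError):
            reads_per_kbp(10, 0)

    @pytest.mark.parametrize(
        "count,length,expected_bound",
        [
            (50, 2000, False),  # rpk 25 passes but 50 < 100 reads
            (100, 5882, True),  # rpk ~17.0 and exactly 100 reads: boundary inclusive
            (1000, 100000, False),  # high count but rpk 10 < 17
            (100, 1000, True),
            (99, 1000, False),
        ],
    )
    def test_dual_threshold_rule(self, count, length, expected_bound):
        call = classify_bound([count], [length])
        assert bool(call.loc[0, "bound"]) is expected_bound

    def test_monotone_in_count(self, rng):
        lengths = rng.integers(500, 50000, 200)
        counts = rng.integers(0, 400, 200)
        before = classify_bound(counts, lengths)["bound"]
        after = classify_bound(counts + rng.integers(0, 50, 200), lengths)["bound"]
        assert not (before & ~after).any()


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        t = make_table(np.tile([[10], [20], [30]], (1, 4)), ["MB", "MB", "MT", "MT"])
        assert np.allclose(size_factors(t), 1.0)

    def test_doubling_one_sample_doubles_its_factor(self, rng):
        counts = rng.integers(1, 200, size=(100, 4))
        t1 = make_table(counts, ["MB", "MB", "MT", "MT"])
        doubled = counts.copy()
        doubled[:, 2] *= 2
        t2 = make_table(doubled, ["MB", "MB", "MT", "MT"])
        f1, f2 = size_factors(t1), size_factors(t2)
        # doubling sample 2 doubles its ratio to the (slightly larger) geometric mean
        scale = 2 ** (1 - 1 / 4)
        assert f2.iloc[2] / f1.iloc[2] == pytest.approx(scale, rel=1e-9)

    def test_median_of_ratios_hand_oracle(self):
        counts = np.array([[10, 20, 30], [100, 100, 100], [4, 8, 4], [50, 25, 75], [9, 9, 18]])
        t = make_table(counts, ["MB", "MB", "MT"])
        geo = np.exp(np.log(counts).mean(axis=1, keepdims=True))
        expected = np.median(counts / geo, axis=0)
        assert np.allclose(size_factors(t), expected)

    def test_no_all_positive_gene_raises(self):
        t = make_table(np.array([[0, 5], [5, 0]]), ["MB", "MT"])
        with pytest.raises(ValueError):
            size_factors(t)


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        t = make_table(np.full((3, 6), 50), ["MB"] * 3 + ["MT"] * 3)
        disp = estimate_dispersion(t, size_factors(t))
        assert np.allclose(disp, 1e-8)

    def test_poisson_counts_near_zero_dispersion(self, rng):
        counts = rng.poisson(1000, size=(2000, 6))
        t = make_table(counts, ["MB"] * 3 + ["MT"] * 3)
        disp = estimate_dispersion(t, size_factors(t))
        assert float(disp.median()) <= 0.01

    def test_nb_dispersion_recovered_at_n20(self):
        spec = CountSimSpec(
            n_genes=2000, samples_per_condition=20, baseline_mean=500, dispersion=0.2,
            bound_fraction=0.0, differential_fraction=0.0, seed=5,
        )
        table, _ = simulate_chip_counts(spec)
        disp = estimate_dispersion(table, size_factors(table))
        assert float(disp.median()) == pytest.approx(0.2, abs=0.05)

    def test_single_sample_condition_rejected(self):
        t = make_table(np.ones((3, 3), dtype=int), ["MB", "MB", "MT"])
        with pytest.raises(ValueError):
            estimate_dispersion(t, size_factors(t))


def nb_loglik(theta, y, s, alpha):
    mu = s * np.exp(theta)
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


class TestNbWald:
    def test_point_estimate_is_log2_ratio_of_group_means(self):
        counts = np.array([[10, 10, 10, 40, 40, 40]])
        t = make_table(counts, ["MB"] * 3 + ["MT"] * 3)
        sf = pd.Series(1.0, index=t.counts.columns)
        disp = pd.Series([0.1], index=t.counts.index)
        res = nb_wald_test(t, sf, disp)
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_group_means_maximize_nb_likelihood(self):
        """Fitted log-means agree with brute-force 1-D likelihood maximization."""
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.1, size=(3, 6))
        t = make_table(counts, ["MB"] * 3 + ["MT"] * 3)
        sf = pd.Series(rng.uniform(0.7, 1.3, 6), index=t.counts.columns)
        disp = pd.Series([0.2, 0.05, 0.4], index=t.counts.index)
        res = nb_wald_test(t, sf, disp)
        s_mb, s_mt = sf.to_numpy()[:3], sf.to_numpy()[3:]
        for i in range(3):
            y_mb, y_mt = counts[i, :3], counts[i, 3:]
            a = disp.iloc[i]
            th_mb = optimize.minimize_scalar(
                lambda th: -nb_loglik(th, y_mb, s_mb, a), bounds=(-5, 15), method="bounded",
                options={"xatol": 1e-10},
            ).x
            th_mt = optimize.minimize_scalar(
                lambda th: -nb_loglik(th, y_mt, s_mt, a), bounds=(-5, 15), method="bounded",
                options={"xatol": 1e-10},
            ).x
            assert res["log2fc"].iloc[i] == pytest.approx((th_mt - th_mb) / np.log(2), abs=1e-4)

    def test_matches_statsmodels_glm_wald_z(self):
        """Cross-check the Wald statistic against an independent NB GLM fit."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        counts = rng.negative_binomial(10, 0.2, size=(4, 8))
        t = make_table(counts, ["MB"] * 4 + ["MT"] * 4)
        sf = pd.Series(1.0, index=t.counts.columns)
        disp = pd.Series([0.1, 0.2, 0.15, 0.3], index=t.counts.index)
        res = nb_wald_test(t, sf, disp)
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        for i in range(4):
            fam = sm.families.NegativeBinomial(alpha=disp.iloc[i])
            fit = sm.GLM(counts[i], X, family=fam).fit()
            z = fit.params[1] / fit.bse[1]
            assert res["wald_stat"].iloc[i] == pytest.approx(z, rel=1e-3, abs=1e-3)

    def test_null_p_values_approximately_uniform(self):
        spec = CountSimSpec(
            n_genes=2000, samples_per_condition=3, baseline_mean=100, dispersion=0.1,
            bound_fraction=0.0, differential_fraction=0.0, seed=21,
        )
        table, _ = simulate_chip_counts(spec)
        sf = size_factors(table)
        res = nb_wald_test(table, sf, estimate_dispersion(table, sf))
        p = res["p_value"].dropna().to_numpy()
        ks = sps.kstest(p, "uniform").statistic
        assert ks <= 0.05

    def test_all_zero_gene_p_undefined(self):
        counts = np.array([[0, 0, 0, 0], [5, 6, 7, 8]])
        t = make_table(counts, ["MB", "MB", "MT", "MT"])
        sf = pd.Series(1.0, index=t.counts.columns)
        disp = pd.Series([0.1, 0.1], index=t.counts.index)
        res = nb_wald_test(t, sf, disp)
        assert np.isnan(res["p_value"].iloc[0])
        assert np.isfinite(res["p_value"].iloc[1])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            make_table(np.array([[1.5, 2.0], [3.0, 4.0]]), ["MB", "MT"])


class TestBhAdjust:
    def test_textbook_step_up_example(self):
        padj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_unit_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_direct_formula_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            got = bh_adjust(p)
            # direct step-up: padj_(i) = min_{j >= i} min(1, m p_(j) / j)
            order = np.argsort(p)
            m = p.size
            stair = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            direct = np.empty(m)
            direct[order] = np.minimum(stair, 1.0)
            assert np.allclose(got, direct, atol=1e-12)
            assert np.allclose(got, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_monotone_and_dominates_raw_p(self, rng):
        p = rng.uniform(size=100)
        padj = bh_adjust(p)
        assert (padj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestClustering:
    def test_duplicated_sample_merges_first_at_zero(self):
        counts = np.array([[10, 10, 50], [20, 20, 5], [7, 7, 30]])
        t = make_table(counts, ["MB", "MB", "MT"])
        sf = pd.Series(1.0, index=t.counts.columns)
        res = vst_and_cluster(t, sf)
        assert res.distances.iloc[0, 1] == pytest.approx(0.0)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}

    def test_merge_heights_match_hand_computed_complete_linkage(self):
        # 4 samples on a line: VST profiles chosen so distances are simple
        vst_profiles = np.array([[0.0], [1.0], [10.0], [10.5]])
        counts = np.round(2 ** vst_profiles - 1).astype(int)
        # build a table whose log2(x+1) equals vst_profiles exactly
        t = make_table(counts.T.repeat(1, axis=0), ["MB", "MB", "MT", "MT"])
        sf = pd.Series(1.0, index=t.counts.columns)
        res = vst_and_cluster(t, sf)
        # complete linkage by hand: merge (2,3)@0.5, (0,1)@1.0, then all@10.5
        # (counts are rounded to integers, so heights match to ~1e-3)
        heights = sorted(res.linkage[:, 2])
        assert heights == pytest.approx([0.5, 1.0, 10.5], abs=5e-3)

    def test_conditions_separate_with_strong_differential_signal(self):
        spec = CountSimSpec(
            n_genes=300, samples_per_condition=3, differential_fraction=0.1,
            differential_log2fc=2.0, seed=2,
        )
        table, _ = simulate_chip_counts(spec)
        res = vst_and_cluster(table, size_factors(table))
        a, b = res.first_bipartition()
        conds = table.sample_info["condition"]
        assert len({conds[s] for s in a}) == 1 and len({conds[s] for s in b}) == 1

    def test_single_sample_rejected(self):
        t = make_table(np.array([[1], [2]]), ["MB"])
        with pytest.raises(ValueError):
            vst_and_cluster(t, pd.Series(1.0, index=t.counts.columns))
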