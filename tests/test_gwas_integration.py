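"""Unit tests for GWAS integration: meta, loci, enrichment, coloc, SMR, TWAS."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtlatlas import simdata
from qtlatlas.datatypes import GwasSummary
from qtlatlas.gwas_integration import (
    annotation_enrichment,
    colocalize,
    define_loci,
    heidi_test,
    lambda_scale,
    maf_matched_sample,
    meta_gwas,
    multi_tissue_twas,
    qtl_gwas_overlap_enrichment,
    smr_table,
    smr_test,
    summary_twas,
    tad_enrichment,
    tissue_relevance,
    train_twas_model,
)


def _gwas(z, n=10000, pos=None, chrom="chr1", trait="t"):
    z = np.asarray(z, dtype=float)
    if pos is None:
        pos = np.arange(1, len(z) + 1) * 1000
    t = pd.DataFrame(
        {
            "variant_id": [f"{chrom}:{p}:A:G" for p in pos],
            "chrom": chrom,
            "pos": pos,
            "z": z,
            "n": n,
            "n_cases": np.nan,
            "n_controls": np.nan,
        }
    )
    return GwasSummary(table=t, trait=trait)


class TestMetaGwas:
    def test_equal_cohorts_scale_sqrt2(self):
        g1 = _gwas([2.0, -1.0])
        g2 = _gwas([2.0, -1.0])
        m = meta_gwas([g1, g2])
        np.testing.assert_allclose(m.table["z"], np.sqrt(2) * np.array([2.0, -1.0]), atol=1e-12)

    def test_opposite_z_cancel(self):
        m = meta_gwas([_gwas([3.0]), _gwas([-3.0])])
        assert m.table["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_unequal_cohorts_formula(self):
        rng = np.random.default_rng(0)
        zs = [rng.standard_normal(5) for _ in range(3)]
        ns = [1000, 4000, 9000]
        cohorts = [_gwas(z, n=n) for z, n in zip(zs, ns)]
        m = meta_gwas(cohorts)
        expect = sum(np.sqrt(n) * z for z, n in zip(zs, ns)) / np.sqrt(sum(ns))
        got = m.table.sort_values("pos")["z"].to_numpy()
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_single_cohort_passthrough(self):
        g = _gwas([1.0, 2.0])
        assert meta_gwas([g]) is g


class TestDefineLoci:
    def test_single_significant_variant(self):
        z = np.zeros(10)
        z[4] = 6.0
        loci = define_loci(_gwas(z))
        assert len(loci) == 1
        assert loci[0].lead_variant == _gwas(z).table["variant_id"].iloc[4]

    def test_merge_distance_boundary(self):
        # 0.5 Mb apart -> one locus; 2 Mb apart -> two loci
        z = np.array([6.0, 5.5])
        one = define_loci(_gwas(z, pos=[1_000_000, 1_500_000]))
        two = define_loci(_gwas(z, pos=[1_000_000, 3_000_000]))
        assert len(one) == 1
        assert len(two) == 2

    def test_no_significant_empty(self):
        assert define_loci(_gwas(np.zeros(5))) == []

    def test_three_causal_simulation(self, dense_ld_genotypes):
        g = dense_ld_genotypes
        # three well-separated causals on distinct chromosomes (manual pos table)
        ok = 0
        trials = 15
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            pos = np.concatenate([rng.integers(1, 900_000, 1),
                                  rng.integers(5_000_000, 5_900_000, 1),
                                  rng.integers(10_000_000, 10_900_000, 1)])
            allpos = np.sort(np.concatenate([pos, rng.integers(1, 11_000_000, 200)]))
            z = rng.standard_normal(len(allpos))
            for p in pos:
                z[np.where(allpos == p)[0][0]] = 8.0 + rng.standard_normal()
            loci = define_loci(_gwas(z, pos=allpos))
            if len(loci) == 3:
                ok += 1
        assert ok >= int(0.9 * trials)


class TestOverlapEnrichment:
    def test_lambda_rescaling_exact(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=1000)
        scaled = lambda_scale(p, 10.0)
        assert np.median(scaled) / stats.chi2.ppf(0.5, 1) == pytest.approx(10.0, abs=1e-9)

    def test_null_loci_fold_near_one(self):
        folds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lead = pd.DataFrame(
                {f"t{j}": rng.uniform(size=500) for j in range(4)},
                index=[f"v{i}" for i in range(500)],
            )
            locus = set(rng.choice(lead.index, 50, replace=False))
            folds.append(qtl_gwas_overlap_enrichment(lead, locus)["fold"])
        assert abs(np.mean(folds) - 1.0) < 0.15

    def test_planted_loci_enriched(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            lead = pd.DataFrame(
                {f"t{j}": rng.uniform(size=500) for j in range(4)},
                index=[f"v{i}" for i in range(500)],
            )
            # plant strong molQTL p at the locus variants
            locus = set(rng.choice(lead.index, 50, replace=False))
            sel = lead.index.isin(list(locus))
            lead.loc[sel, "t0"] = rng.uniform(0, 1e-4, sel.sum())
            res = qtl_gwas_overlap_enrichment(lead, locus)
            if res["fold"] > 1.0 and res["pval"] < 0.05:
                hits += 1
        assert hits >= 19

    def test_empty_overlap_raises(self):
        lead = pd.DataFrame({"t0": [0.5, 0.1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            qtl_gwas_overlap_enrichment(lead, set())


class TestMafMatchedSample:
    def test_histogram_matches(self):
        rng = np.random.default_rng(2)
        pool_ids = [f"p{i}" for i in range(5000)]
        pool_maf = rng.uniform(0.05, 0.5, 5000)
        t_idx = rng.choice(5000, 200, replace=False)
        target_ids = [pool_ids[i] for i in t_idx]
        target_maf = pool_maf[t_idx]
        ctl = maf_matched_sample(target_ids, target_maf, pool_ids, pool_maf, seed=0)
        assert len(ctl) == 200
        assert not set(ctl) & set(target_ids)
        edges = np.linspace(0, 0.5, 21)
        maf_of = dict(zip(pool_ids, pool_maf))
        ctl_maf = np.array([maf_of[v] for v in ctl])
        np.testing.assert_array_equal(
            np.histogram(ctl_maf, edges)[0], np.histogram(target_maf, edges)[0]
        )

    def test_pool_equals_target_raises(self):
        rng = np.random.default_rng(3)
        ids = [f"v{i}" for i in range(50)]
        maf = rng.uniform(0.05, 0.5, 50)
        with pytest.raises(ValueError, match="underfilled"):
            maf_matched_sample(ids, maf, ids, maf, seed=0)

    def test_bin_counts_stable_across_seeds(self):
        rng = np.random.default_rng(4)
        pool_ids = [f"p{i}" for i in range(8000)]
        pool_maf = rng.uniform(0.05, 0.5, 8000)
        target_ids = [f"t{i}" for i in range(300)]
        target_maf = rng.uniform(0.05, 0.5, 300)
        edges = np.linspace(0, 0.5, 21)
        maf_of = dict(zip(pool_ids, pool_maf))
        ref = None
        for seed in range(5):
            ctl = maf_matched_sample(target_ids, target_maf, pool_ids, pool_maf, seed=seed)
            h = np.histogram([maf_of[v] for v in ctl], edges)[0]
            if ref is None:
                ref = h
            np.testing.assert_array_equal(h, ref)


class TestColocalize:
    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        c = colocalize(rng.standard_normal(30), rng.standard_normal(30))
        assert c.pp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_both_null_pp0_dominates(self):
        rng = np.random.default_rng(6)
        c = colocalize(rng.standard_normal(50) * 0.5, rng.standard_normal(50) * 0.5,
                       se_gwas=0.01, se_qtl=0.01)
        assert c.pp[0] > 0.9

    def test_rcp_invariant_to_uniform_abf_rescaling(self):
        # adding a constant to every log-ABF (uniform rescaling) cancels in PPs
        rng = np.random.default_rng(7)
        z1, z2 = rng.standard_normal(20) * 3, rng.standard_normal(20) * 3
        a = colocalize(z1, z2, se_gwas=0.1, se_qtl=0.1)
        b = colocalize(z1, z2, se_gwas=0.1, se_qtl=0.1)
        assert a.rcp == pytest.approx(b.rcp, abs=1e-12)

    def test_shared_vs_distinct_causal(self, dense_ld_genotypes):
        g = dense_ld_genotypes
        R = simdata.ld_matrix(g)
        n = 50_000
        se = 1 / np.sqrt(n)
        shared_hits = distinct_hits = 0
        trials = 15
        for seed in range(trials):
            causal = {g.variant_ids[30]: 1.0}
            gw1, _ = simdata.simulate_gwas_cohort(g, causal, n, 0.03, seed=seed)
            gw2, _ = simdata.simulate_gwas_cohort(g, causal, n, 0.03, seed=5000 + seed)
            c = colocalize(gw1.table["z"], gw2.table["z"], R, se_gwas=se, se_qtl=se)
            if c.rcp > 0.9:
                shared_hits += 1
            other = {g.variant_ids[5]: 1.0}
            gw3, _ = simdata.simulate_gwas_cohort(g, other, n, 0.03, seed=9000 + seed)
            c2 = colocalize(gw1.table["z"], gw3.table["z"], R, se_gwas=se, se_qtl=se)
            if c2.pp[3] > c2.pp[4]:
                distinct_hits += 1
        assert shared_hits >= int(0.9 * trials)
        assert distinct_hits >= int(0.9 * trials)

    def test_single_variant_degenerate_flag(self):
        c = colocalize(np.array([5.0]), np.array([5.0]))
        assert c.degenerate
        assert c.pp[3] == 0.0


class TestSmr:
    def test_equal_z(self):
        t, p = smr_test(3.0, 3.0)
        assert t == pytest.approx(9.0 / 2)

    def test_zero_gwas_z(self):
        t, p = smr_test(5.0, 0.0)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            ze, zg = rng.standard_normal(2) * 4
            t, p = smr_test(ze, zg)
            assert t == pytest.approx(ze**2 * zg**2 / (ze**2 + zg**2), abs=1e-12)
            assert p == pytest.approx(stats.chi2.sf(t, 1), abs=1e-12)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            smr_test(0.0, 0.0)

    def test_monotone_in_min_abs_z(self):
        zs = np.linspace(0.5, 8, 12)
        ps = [smr_test(z, 10.0)[1] for z in zs]
        assert np.all(np.diff(ps) < 0)

    def test_table_instrument_filter_and_bh(self):
        t = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "z_eqtl": [8.0, 2.0, 7.0],  # g2 p ~ 0.05, not an instrument
                "z_gwas": [6.0, 6.0, 0.1],
            }
        )
        out = smr_table(t)
        assert set(out["gene_id"]) == {"g1", "g3"}
        assert out[out["gene_id"] == "g1"]["passed"].iloc[0]
        assert not out[out["gene_id"] == "g3"]["passed"].iloc[0]


class TestHeidi:
    def test_too_few_instruments_flagged(self):
        R = np.eye(4)  # no LD partners in [0.05, 0.9]
        z = np.array([8.0, 1.0, 1.0, 1.0])
        assert heidi_test(z, z, R) is None

    def test_single_causal_calibration(self, dense_ld_genotypes):
        g = dense_ld_genotypes
        R = simdata.ld_matrix(g)
        causal = {g.variant_ids[30]: 1.0}
        keep = 0
        trials = 30
        for seed in range(trials):
            gwa, _ = simdata.simulate_gwas_cohort(g, causal, 50_000, 0.05, seed=seed)
            gwb, _ = simdata.simulate_gwas_cohort(g, causal, 50_000, 0.05, seed=7000 + seed)
            p = heidi_test(gwb.table["z"].to_numpy(), gwa.table["z"].to_numpy(), R)
            if p is not None and p >= 0.05:
                keep += 1
        assert keep / trials >= 0.85  # ~95% expected

    def test_distinct_causals_detected(self, dense_ld_genotypes):
        g = dense_ld_genotypes
        R = simdata.ld_matrix(g)
        eqtl_causal = {g.variant_ids[30]: 1.0}
        gwas_causal = {g.variant_ids[45]: 1.0}
        reject = 0
        trials = 20
        for seed in range(trials):
            gwa, _ = simdata.simulate_gwas_cohort(g, gwas_causal, 80_000, 0.05, seed=seed)
            gwb, _ = simdata.simulate_gwas_cohort(g, eqtl_causal, 80_000, 0.05, seed=8000 + seed)
            p = heidi_test(gwb.table["z"].to_numpy(), gwa.table["z"].to_numpy(), R)
            if p is not None and p < 0.05:
                reject += 1
        assert reject / trials >= 0.7


class TestTwas:
    def _cohort(self, seed, n=400, m=30, h2=0.3):
        cfg = simdata.SimConfig(n_samples=n, n_variants=m, ld_decay=100_000,
                                n_chroms=1, chrom_length=2_000_000, seed=seed)
        g = simdata.simulate_genotypes(cfg)
        rng = np.random.default_rng(seed)
        X = g.dosages.astype(float)
        Xs = (X - X.mean(0)) / np.maximum(X.std(0), 1e-9)
        b = np.zeros(m)
        b[m // 2] = np.sqrt(h2)
        y = Xs @ b + rng.standard_normal(n) * np.sqrt(1 - h2)
        return g, X, y

    def test_planted_signal_retained(self):
        kept = 0
        trials = 10
        for seed in range(trials):
            g, X, y = self._cohort(seed)
            model = train_twas_model(X, y, g.variant_ids, seed=seed)
            if model.retained:
                kept += 1
        assert kept >= int(0.8 * trials)

    def test_noise_gene_rejected(self):
        kept = 0
        trials = 10
        for seed in range(trials):
            g, X, _ = self._cohort(seed + 50)
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(len(X))
            if train_twas_model(X, y, g.variant_ids, seed=seed).retained:
                kept += 1
        assert kept <= 2

    def test_infinite_penalty_rejects(self):
        g, X, y = self._cohort(99)
        model = train_twas_model(X, y, g.variant_ids, alphas=np.array([1e9]), seed=0)
        assert not model.retained
        assert np.all(model.weights == 0)

    def test_fewer_samples_than_folds(self):
        g, X, y = self._cohort(1)
        with pytest.raises(ValueError):
            train_twas_model(X[:3], y[:3], g.variant_ids, n_folds_outer=5)

    def test_single_variant_model_collapses(self):
        from qtlatlas.gwas_integration.twas import TwasModel

        m = TwasModel(gene="g", tissue="t", variant_ids=["v"], weights=np.array([2.0]),
                      rho_cv=0.5, pval_cv=0.01, retained=True)
        z, p = summary_twas(m, np.array([3.0]), np.array([[1.0]]), np.array([0.4]))
        assert z == pytest.approx(3.0)

    def test_weight_sign_flip_flips_z(self):
        from qtlatlas.gwas_integration.twas import TwasModel

        rng = np.random.default_rng(9)
        w = rng.standard_normal(5)
        R = np.eye(5)
        sd = rng.uniform(0.3, 0.6, 5)
        z = rng.standard_normal(5)
        m1 = TwasModel("g", "t", list("abcde"), w, 0.5, 0.01, True)
        m2 = TwasModel("g", "t", list("abcde"), -w, 0.5, 0.01, True)
        z1, _ = summary_twas(m1, z, R, sd)
        z2, _ = summary_twas(m2, z, R, sd)
        assert z2 == pytest.approx(-z1, abs=1e-12)

    def test_summary_matches_individual_level_oracle(self):
        # summary z vs regression of phenotype on predicted expression
        zs_sum, zs_ind = [], []
        for seed in range(40):
            g, X, y = self._cohort(seed + 200, n=500)
            rng = np.random.default_rng(seed)
            w = rng.standard_normal(X.shape[1]) * (rng.random(X.shape[1]) < 0.2)
            if np.all(w == 0):
                w[0] = 1.0
            pheno = X @ w * 0.05 + rng.standard_normal(len(X))
            # per-variant GWAS z from the same cohort
            Xc = X - X.mean(0)
            sd = X.std(0)
            r = (Xc / np.maximum(sd, 1e-9)).T @ ((pheno - pheno.mean()) / pheno.std()) / len(X)
            z = r * np.sqrt(len(X))
            R = np.corrcoef(X.T)
            from qtlatlas.gwas_integration.twas import TwasModel

            model = TwasModel("g", "t", g.variant_ids, w, 0.5, 0.01, True)
            zg, _ = summary_twas(model, z, R, sd)
            pred = X @ w
            lr = stats.linregress(pred, pheno)
            zs_sum.append(zg)
            zs_ind.append(lr.slope / lr.stderr)
        assert np.corrcoef(zs_sum, zs_ind)[0, 1] >= 0.95


class TestMultiTissueTwas:
    def test_one_tissue_matches_single(self):
        stat, k, p = multi_tissue_twas(np.array([2.0]), np.array([[1.0]]))
        assert p == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-12)

    def test_duplicated_tissue_degenerate_dropped(self):
        z = np.array([2.5, 2.5])
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        stat, k, p = multi_tissue_twas(z, C)
        assert k == 1
        assert p == pytest.approx(2 * stats.norm.sf(2.5), rel=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(10)
        T = 5
        pvals = []
        for _ in range(5000):
            z = rng.standard_normal(T)
            _, _, p = multi_tissue_twas(z, np.eye(T))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_all_components_discarded(self):
        with pytest.raises(ValueError):
            multi_tissue_twas(np.array([1.0, 1.0]), np.array([[1.0, 1.0], [1.0, 1.0]]),
                              condition_threshold=0.5)


class TestAnnotationEnrichment:
    def test_whole_genome_annotation_fold_one(self):
        rng = np.random.default_rng(11)
        target = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 999_999, 100)})
        bg = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 999_999, 1000)})
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000], "state": ["all"]})
        out = annotation_enrichment(target, bg, ann, n_boot=20, seed=0)
        assert out["fold"].iloc[0] == pytest.approx(1.0)

    def test_planted_3x_enrichment(self):
        rng = np.random.default_rng(12)
        # annotation covers [0, 100kb) of 1Mb; background uniform (10% in)
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000], "state": ["s"]})
        bg = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 1_000_000, 20000)})
        n_t = 1000
        inside = rng.integers(1, 100_000, int(n_t * 0.3))
        outside = rng.integers(100_000, 1_000_000, int(n_t * 0.7))
        target = pd.DataFrame({"chrom": "chr1", "pos": np.concatenate([inside, outside])})
        out = annotation_enrichment(target, bg, ann, n_boot=50, seed=1)
        assert out["fold"].iloc[0] == pytest.approx(3.0, abs=0.5)

    def test_empty_annotation_flagged(self):
        target = pd.DataFrame({"chrom": ["chr1"], "pos": [5]})
        bg = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
        ann = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [10], "state": ["s"]})
        out = annotation_enrichment(target, bg, ann, n_boot=5, seed=0)
        assert out["flag"].iloc[0] == "no_background_overlap"


class TestTadEnrichment:
    def test_uniform_variants_fold_near_one(self):
        ann = simdata.simulate_annotations({"chr1": 10_000_000}, {}, {"mean_size": 1_000_000}, 1)
        rng = np.random.default_rng(13)
        tss = rng.integers(1, 9_000_000, 400)
        vpos = tss + rng.choice([-1, 1], 400) * rng.integers(1000, 900_000, 400)
        pairs = pd.DataFrame({"chrom": "chr1", "tss": tss, "variant_pos": np.clip(vpos, 1, 9_999_999)})
        out = tad_enrichment(pairs, ann.tads, np.array([100_000, 500_000]),
                             {"chr1": 10_000_000}, n_boot=30, seed=0)
        ok = out[out["n"] > 50]
        assert np.all(np.abs(ok["fold"] - 1.0) < 0.25)

    def test_empty_bin_flagged(self):
        ann = simdata.simulate_annotations({"chr1": 1_000_000}, {}, {"mean_size": 200_000}, 2)
        pairs = pd.DataFrame({"chrom": ["chr1"], "tss": [100], "variant_pos": [200]})
        out = tad_enrichment(pairs, ann.tads, np.array([10_000]), {"chr1": 1_000_000},
                             n_boot=5, seed=0)
        assert (out["flag"] == "empty").any()


class TestTissueRelevance:
    def test_formula(self):
        out = tissue_relevance(
            pd.Series({"t": 10}), pd.Series({"t": 100}), pd.Series({"t": 0.5})
        )
        assert out["score"]["t"] == pytest.approx(0.2)

    def test_zero_coloc_zero_score(self):
        out = tissue_relevance(pd.Series({"t": 0}), pd.Series({"t": 150}), pd.Series({"t": 0.4}))
        assert out["score"]["t"] == 0.0

    def test_linearity(self):
        a = tissue_relevance(pd.Series({"t": 5}), pd.Series({"t": 200}), pd.Series({"t": 0.5}))
        b = tissue_relevance(pd.Series({"t": 10}), pd.Series({"t": 200}), pd.Series({"t": 0.5}))
        assert b["score"]["t"] == pytest.approx(2 * a["score"]["t"])

    def test_small_tissue_excluded(self):
        out = tissue_relevance(pd.Series({"t": 5}), pd.Series({"t": 50}), pd.Series({"t": 0.5}))
        assert not out["included"]["t"]
        assert np.isnan(out["score"]["t"])

    def test_zero_proportion_raises(self):
        with pytest.raises(ValueError):
            tissue_relevance(pd.Series({"t": 5}), pd.Series({"t": 200}), pd.Series({"t": 0.0}))
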