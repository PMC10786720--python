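"""End-to-end demonstration pipeline on a toy two-chromosome cohort.

Chains every stage — synthetic cohort, phenotype preparation, cis-QTL calling
(expression and grouped splicing), a second tissue for sharing statistics,
GWAS simulation, colocalization, TWAS, cross-species meta-analysis and the
tissue-relevance table — deterministically from a single seed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import cis_qtl, cross_species, multi_tissue, phenoprep, simdata
from .gwas_integration import colocalize, summary_twas, tissue_relevance, train_twas_model


def run_end_to_end(seed: int = 0, n_samples: int = 200) -> dict:
    cfg = simdata.SimConfig(
        n_samples=n_samples,
        n_variants=400,
        n_features_per_kind={"gene": 30, "intron": 8},
        breed_proportions=(0.5, 0.5),
        breed_drift=0.15,
        ld_decay=150_000,
        n_chroms=2,
        chrom_length=3_000_000,
        n_planted_qtl=6,
        effect_size_dist=("fixed", 1.2),
        noise_sd=0.5,
        seed=seed,
    )
    genotypes = simdata.simulate_genotypes(cfg)

    # --- tissue 1: expression ---
    counts, truth = simdata.simulate_molecular_phenotypes(genotypes, cfg)
    lengths = (counts.features["end"] - counts.features["start"]).to_numpy(float)
    expr, _ = phenoprep.prepare_expression(counts, lengths)
    pcs = phenoprep.genotype_pcs(genotypes)
    k = min(5, min(expr.n_features, expr.n_samples) - 1)
    factors, _ = phenoprep.estimate_hidden_factors(expr, k=k)
    cov = np.column_stack([pcs.values.to_numpy(), factors])

    nominal = cis_qtl.nominal_scan(genotypes, expr, cov)
    perm = cis_qtl.permutation_pass(genotypes, expr, cov, seed=seed)
    calls = cis_qtl.call_egenes(perm, nominal)
    egenes = set(calls.records[calls.records["is_emolecule"]]["feature_id"])
    egene_prop = max(len(egenes) / max(len(calls.records), 1), 1e-6)

    # --- splicing ---
    introns, s_truth = simdata.simulate_intron_clusters(
        genotypes, cfg, n_clusters=8, mean_cluster_total=300.0
    )
    psi, _ = phenoprep.compute_psi_and_filter(introns)
    sgroups = pd.DataFrame()
    if psi.n_features:
        sperm = cis_qtl.grouped_permutation_pass(genotypes, psi, cov, seed=seed)
        if len(sperm):
            sgroups = cis_qtl.call_egenes(sperm).records

    # --- tissue 2 shares the planted effects (different expression noise) ---
    cfg2 = simdata.SimConfig(**{**cfg.__dict__, "seed": seed + 10_000})
    counts2, _ = simdata.simulate_molecular_phenotypes(genotypes, cfg2, planted=truth.planted_qtl)
    expr2, _ = phenoprep.prepare_expression(counts2, lengths)
    shared = sorted(set(expr.feature_ids) & set(expr2.feature_ids))
    nominal2 = cis_qtl.nominal_scan(
        genotypes, expr2.select_features(shared), cov
    )
    # pi1 replication: tissue-2 p at tissue-1 discovery-significant pairs
    import warnings

    disc = calls.significant_pairs[["feature_id", "variant_id"]]
    rep = nominal2.merge(disc, on=["feature_id", "variant_id"])
    if len(rep) < 5:  # tiny cohorts: fall back to eGene lead pairs
        leads = perm[["feature_id", "lead_variant"]].rename(columns={"lead_variant": "variant_id"})
        rep = nominal2.merge(leads, on=["feature_id", "variant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pi1_rep = multi_tissue.pi1(rep["pval"].to_numpy()) if len(rep) >= 5 else np.nan

    # m-values / meta for the strongest lead pair seen in both tissues
    sharing = {}
    for _, lead_rec in perm.sort_values("p_beta").iterrows():
        pair1 = nominal[
            (nominal["feature_id"] == lead_rec["feature_id"])
            & (nominal["variant_id"] == lead_rec["lead_variant"])
        ]
        pair2 = nominal2[
            (nominal2["feature_id"] == lead_rec["feature_id"])
            & (nominal2["variant_id"] == lead_rec["lead_variant"])
        ]
        if len(pair1) and len(pair2):
            b = np.array([pair1["slope"].iloc[0], pair2["slope"].iloc[0]])
            se = np.array([pair1["slope_se"].iloc[0], pair2["slope_se"].iloc[0]])
            mres = multi_tissue.m_values(b, se, ["t1", "t2"], seed=seed)
            sharing = {"meta": mres.meta, "m": mres.m, "active": mres.active}
            break

    # --- GWAS sharing causals with two planted eGenes ---
    planted_egenes = [q for q in truth.planted_qtl if q.feature_id in egenes]
    coloc_targets = planted_egenes[:2]
    n_gwas = 30_000
    R = simdata.ld_matrix(genotypes)
    vindex = {v: i for i, v in enumerate(genotypes.variant_ids)}
    coloc_rows = []
    gwas_list = []
    for tgt in coloc_targets:
        gw, _ = simdata.simulate_gwas_cohort(
            genotypes, {tgt.variant_id: 1.0}, n_gwas, 0.03,
            seed=seed + 31 + vindex[tgt.variant_id], shared_with_qtl=True,
        )
        gwas_list.append(gw)
    for tgt, gw in zip(coloc_targets, gwas_list):
        for gene in egenes:
            sub = nominal[nominal["feature_id"] == gene]
            vids = sub["variant_id"].tolist()
            idx = np.array([vindex[v] for v in vids])
            z_qtl = (sub["slope"] / sub["slope_se"]).to_numpy()
            z_gwas = gw.table.set_index("variant_id").loc[vids, "z"].to_numpy()
            res = colocalize(
                z_gwas, z_qtl, R[np.ix_(idx, idx)],
                se_gwas=1 / np.sqrt(n_gwas), se_qtl=1 / np.sqrt(n_samples),
            )
            coloc_rows.append(
                {"target": tgt.feature_id, "gene": gene, "tissue": "t1", "rcp": res.rcp}
            )
    coloc_table = pd.DataFrame(coloc_rows, columns=["target", "gene", "tissue", "rcp"])
    colocalized = (
        set(coloc_table[coloc_table["rcp"] > 0.9]["gene"]) if len(coloc_table) else set()
    )

    # --- TWAS on the first coloc target, meta-TWAS with a synthetic partner ---
    twas = {}
    if coloc_targets:
        tgt = coloc_targets[0]
        fi = expr.feature_ids.index(tgt.feature_id)
        frow = expr.features.iloc[fi]
        cis_idx = cis_qtl.cis_window_indices(genotypes, frow["chrom"], int(frow["tss"]))
        X = genotypes.dosages[:, cis_idx].astype(float)
        y = cis_qtl.residualize(expr.values[fi], cov)
        model = train_twas_model(
            X, y, [genotypes.variant_ids[i] for i in cis_idx], gene=tgt.feature_id, seed=seed
        )
        gw = gwas_list[0]
        z_g = gw.table.set_index("variant_id").loc[model.variant_ids, "z"].to_numpy()
        if np.any(model.weights != 0):
            zt, pt = summary_twas(model, z_g, R[np.ix_(cis_idx, cis_idx)], X.std(axis=0))
            twas = {"gene": tgt.feature_id, "rho_cv": model.rho_cv, "z": zt, "pval": pt,
                    "retained": model.retained}

    # --- cross-species ---
    ta, tb, omap = simdata.simulate_ortholog_twas_pair(500, 0.5, seed=seed)
    xcorr = cross_species.ortholog_effect_correlation(ta, tb, omap, n_perm=200, seed=seed)
    meta = cross_species.meta_twas(ta, tb, omap)

    # --- relevance table ---
    relevance = tissue_relevance(
        pd.Series({"t1": len(colocalized)}),
        pd.Series({"t1": n_samples}),
        pd.Series({"t1": egene_prop}),
    )

    return {
        "genotypes": genotypes,
        "truth": truth,
        "splice_truth": s_truth,
        "calls": calls,
        "egenes": egenes,
        "sgroups": sgroups,
        "pi1": pi1_rep,
        "sharing": sharing,
        "coloc": coloc_table,
        "colocalized_genes": colocalized,
        "planted_coloc_genes": {t.feature_id for t in coloc_targets},
        "twas": twas,
        "xspecies_r": xcorr["r"],
        "meta_twas_significant": int(meta["significant"].sum()),
        "relevance": relevance,
    }
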