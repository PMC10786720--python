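"""Cross-species comparison at the orthologous-gene level: effect-size
correlation with a permutation null, meta-TWAS, and gain/loss analysis."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _join_orthologs(
    twas_a: pd.DataFrame, twas_b: pd.DataFrame, ortholog_map: pd.DataFrame
) -> pd.DataFrame:
    om = ortholog_map
    if om["gene_a"].duplicated().any() or om["gene_b"].duplicated().any():
        raise ValueError("ortholog map must be one-to-one")
    a = twas_a.set_index("gene_id")
    b = twas_b.set_index("gene_id")
    joined = om[om["gene_a"].isin(a.index) & om["gene_b"].isin(b.index)].copy()
    skipped = len(om) - len(joined)
    if skipped:
        logger.info("%d ortholog pairs lack a result in one species; excluded", skipped)
    for col in a.columns:
        joined[f"{col}_a"] = a.loc[joined["gene_a"], col].to_numpy()
        joined[f"{col}_b"] = b.loc[joined["gene_b"], col].to_numpy()
    return joined.reset_index(drop=True)


def ortholog_effect_correlation(
    twas_a: pd.DataFrame,
    twas_b: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    use_absolute: bool = True,
    min_genes: int = 30,
) -> dict:
    """Pearson correlation of |effect| across orthologs with a permutation p.

    The null shuffles the ortholog map (species-B effects permuted against
    species A), preserving each species' marginal distribution.
    """
    joined = _join_orthologs(twas_a, twas_b, ortholog_map)
    if len(joined) < min_genes:
        return {"r": np.nan, "p_perm": np.nan, "n_genes": len(joined), "tested": False}
    ea = joined["effect_a"].to_numpy(dtype=float)
    eb = joined["effect_b"].to_numpy(dtype=float)
    if use_absolute:
        ea, eb = np.abs(ea), np.abs(eb)
    r_obs = float(np.corrcoef(ea, eb)[0, 1])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
    hits = 0
    for _ in range(n_perm):
        r_null = np.corrcoef(ea, rng.permutation(eb))[0, 1]
        if abs(r_null) >= abs(r_obs):
            hits += 1
    p_perm = (1.0 + hits) / (1.0 + n_perm)
    return {"r": r_obs, "p_perm": p_perm, "n_genes": len(joined), "tested": True}


def correlation_table_fdr(results: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """BH over all tested trait-tissue correlation pairs at FDR 10%."""
    out = results.copy()
    tested = out["tested"].to_numpy(dtype=bool)
    out["qval"] = np.nan
    if tested.any():
        _, q, _, _ = multipletests(out.loc[tested, "p_perm"].to_numpy(), method="fdr_bh")
        out.loc[tested, "qval"] = q
    out["significant"] = out["qval"] < fdr
    return out


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Case-control effective n = 4 / (1/n_cases + 1/n_controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def meta_twas(
    twas_a: pd.DataFrame,
    twas_b: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Cross-species meta-TWAS: z_meta = (n_i z_i + n_j z_j) / sqrt(n_i^2 + n_j^2).

    Case-control inputs should carry n already converted by
    effective_sample_size (or columns n_cases/n_controls, converted here).
    Symmetric in its two species arguments.
    """
    def _eff_n(t: pd.DataFrame) -> np.ndarray:
        if {"n_cases", "n_controls"} <= set(t.columns) and t["n_cases"].notna().all():
            return np.array(
                [effective_sample_size(c, d) for c, d in zip(t["n_cases"], t["n_controls"])]
            )
        return t["n"].to_numpy(dtype=float)

    ta, tb = twas_a.copy(), twas_b.copy()
    ta["n"] = _eff_n(ta)
    tb["n"] = _eff_n(tb)
    joined = _join_orthologs(ta, tb, ortholog_map)
    za = joined["z_a"].to_numpy(dtype=float)
    zb = joined["z_b"].to_numpy(dtype=float)
    na = joined["n_a"].to_numpy(dtype=float)
    nb = joined["n_b"].to_numpy(dtype=float)
    denom = np.sqrt(na**2 + nb**2)
    zmeta = (na * za + nb * zb) / denom
    out = joined[["gene_a", "gene_b"]].copy()
    out["z_a"], out["z_b"], out["n_a"], out["n_b"] = za, zb, na, nb
    out["z_meta"] = zmeta
    out["pval"] = 2.0 * stats.norm.sf(np.abs(zmeta))
    _, q, _, _ = multipletests(out["pval"].to_numpy(), method="fdr_bh")
    out["qval"] = q
    out["significant"] = out["qval"] < fdr
    return out


def concordant_gain_analysis(
    meta_results: pd.DataFrame,
    single_results: pd.DataFrame,
    fdr: float = 0.05,
) -> dict:
    """Genes newly significant in meta vs single-species, and the reverse.

    Both frames need columns gene (shared universe), pval. Significance by BH
    at `fdr` within each frame.
    """
    mg = set(meta_results["gene"])
    sg = set(single_results["gene"])
    if mg != sg:
        raise ValueError("meta and single-species gene universes differ")

    def _sig(t: pd.DataFrame) -> set:
        _, q, _, _ = multipletests(t["pval"].to_numpy(dtype=float), method="fdr_bh")
        return set(t["gene"].to_numpy()[q < fdr])

    sig_meta = _sig(meta_results)
    sig_single = _sig(single_results)
    gained = sorted(sig_meta - sig_single)
    lost = sorted(sig_single - sig_meta)
    return {"gained": gained, "lost": lost, "n_gained": len(gained), "n_lost": len(lost)}
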