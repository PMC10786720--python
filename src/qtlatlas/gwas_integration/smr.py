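"""Summary-based Mendelian randomization and the HEIDI heterogeneity test."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

INSTRUMENT_P = 1e-5


def smr_test(z_eqtl: float, z_gwas: float) -> tuple[float, float]:
    """T_SMR = z_e^2 z_g^2 / (z_e^2 + z_g^2), p from chi-square(1)."""
    ze2, zg2 = float(z_eqtl) ** 2, float(z_gwas) ** 2
    denom = ze2 + zg2
    if denom == 0:
        raise ZeroDivisionError("both z statistics are zero")
    t = ze2 * zg2 / denom
    return t, float(stats.chi2.sf(t, 1))


def smr_table(
    pairs: pd.DataFrame,
    fdr: float = 0.05,
    instrument_p: float = INSTRUMENT_P,
    gwas_p_max: float = 1e-5,
) -> pd.DataFrame:
    """SMR over a table with columns gene_id, z_eqtl, z_gwas.

    Genes whose instrument (top eQTL) p is not below instrument_p are skipped;
    BH is applied across tested genes; passing requires adjusted p_smr < fdr
    and GWAS p < gwas_p_max at the instrument.
    """
    t = pairs.copy()
    p_inst = 2.0 * stats.norm.sf(np.abs(t["z_eqtl"].to_numpy(dtype=float)))
    t["instrument_p"] = p_inst
    t = t[t["instrument_p"] < instrument_p].copy()
    if t.empty:
        t["t_smr"] = []
        t["p_smr"] = []
        t["p_smr_adj"] = []
        t["passed"] = []
        return t
    res = [smr_test(ze, zg) for ze, zg in zip(t["z_eqtl"], t["z_gwas"])]
    t["t_smr"] = [r[0] for r in res]
    t["p_smr"] = [r[1] for r in res]
    _, adj, _, _ = multipletests(t["p_smr"].to_numpy(), method="fdr_bh")
    t["p_smr_adj"] = adj
    p_gwas = 2.0 * stats.norm.sf(np.abs(t["z_gwas"].to_numpy(dtype=float)))
    t["passed"] = (t["p_smr_adj"] < fdr) & (p_gwas < gwas_p_max)
    return t.reset_index(drop=True)


def heidi_test(
    z_eqtl: np.ndarray,
    z_gwas: np.ndarray,
    ld: np.ndarray,
    top_index: int | None = None,
    min_snps: int = 3,
    max_snps: int = 20,
    r2_min: float = 0.05,
    r2_max: float = 0.9,
) -> float | None:
    """Heterogeneity-in-dependent-instruments p-value (None if untestable).

    Uses b_xy(i) = z_gwas(i)/z_eqtl(i) in z units; deviations from the top
    variant's ratio are tested jointly with a delta-method covariance built
    from LD, via a Satterthwaite-scaled chi-square on the eigenvalues of the
    deviation correlation matrix. Instruments are variants with
    r2_min <= r^2 <= r2_max against the top variant, capped at max_snps by
    descending eQTL significance.
    """
    ze = np.asarray(z_eqtl, dtype=float)
    zg = np.asarray(z_gwas, dtype=float)
    R = np.asarray(ld, dtype=float)
    m = len(ze)
    if top_index is None:
        top_index = int(np.argmax(ze**2))
    r2 = R[top_index] ** 2
    cand = np.where((r2 >= r2_min) & (r2 <= r2_max) & (np.arange(m) != top_index) & (ze != 0))[0]
    if cand.size > max_snps:
        cand = cand[np.argsort(-np.abs(ze[cand]))[:max_snps]]
    if cand.size < min_snps:
        return None

    t = top_index
    bxy = zg / np.where(ze != 0, ze, np.nan)
    d = bxy[cand] - bxy[t]

    idx = np.concatenate([cand, [t]])
    k = len(cand)
    # delta-method covariance of b_xy over idx
    ZE, ZG = ze[idx], zg[idx]
    Rs = R[np.ix_(idx, idx)]
    cov_bxy = Rs / np.outer(ZE, ZE) + Rs * np.outer(ZG, ZG) / np.outer(ZE**2, ZE**2)
    cov_d = (
        cov_bxy[:k, :k]
        - cov_bxy[:k, k][:, None]
        - cov_bxy[k, :k][None, :]
        + cov_bxy[k, k]
    )
    var_d = np.clip(np.diag(cov_d), 1e-30, None)
    zd = d / np.sqrt(var_d)
    stat = float(np.sum(zd**2))
    corr = cov_d / np.sqrt(np.outer(var_d, var_d))
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    s1, s2 = lam.sum(), float(np.sum(lam**2))
    if s2 == 0:
        return None
    scale = s2 / s1
    dof = s1**2 / s2
    return float(stats.chi2.sf(stat / scale, dof))
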