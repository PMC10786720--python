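"""Genotype x context interaction QTL for continuous context covariates.

Fits phenotype ~ genotype + context + genotype*context + covariates per cis
pair and reports the interaction term, with BH correction across all tested
pairs per context. Variants must stay common (MAF >= 0.05) within both the
lower and upper context halves to avoid leverage artifacts.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cis_qtl import DEFAULT_WINDOW, _as_cov_array, cis_window_indices
from .datatypes import GenotypeMatrix, PhenotypeMatrix

logger = logging.getLogger(__name__)


def _context_half_maf_ok(dosages: np.ndarray, context: np.ndarray, maf_min: float) -> np.ndarray:
    order = np.argsort(context, kind="stable")
    half = len(context) // 2
    lo, hi = order[:half], order[half:]
    ok = np.ones(dosages.shape[1], dtype=bool)
    for part in (lo, hi):
        p = dosages[part].mean(axis=0) / 2.0
        ok &= np.minimum(p, 1 - p) >= maf_min
    return ok


def interaction_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    covariates,
    context: np.ndarray | pd.Series,
    context_name: str = "context",
    window_bp: int = DEFAULT_WINDOW,
    fdr: float = 0.05,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Interaction scan over all cis pairs for one continuous context."""
    ctx = np.asarray(context, dtype=float)
    if ctx.std() == 0:
        raise ValueError("context is constant")
    if len(ctx) != genotypes.n_samples:
        raise ValueError("context length does not match samples")
    cov = _as_cov_array(covariates)
    n = genotypes.n_samples
    D = genotypes.dosages.astype(float)
    ok = _context_half_maf_ok(D, ctx, maf_min)
    vids = np.asarray(genotypes.variant_ids)

    base_cols = [np.ones(n), ctx]
    if cov is not None:
        base_cols.append(cov)
    base = np.column_stack(base_cols)

    rows = []
    for i, (_, f) in enumerate(phenotypes.features.iterrows()):
        idx = cis_window_indices(genotypes, f["chrom"], int(f["tss"]), window_bp)
        idx = idx[ok[idx]]
        y = phenotypes.values[i]
        for vi in idx:
            g = D[:, vi]
            X = np.column_stack([base, g, g * ctx])
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < X.shape[1]:
                continue
            resid = y - X @ beta
            dof = n - X.shape[1]
            s2 = resid @ resid / dof
            XtX_inv = np.linalg.pinv(X.T @ X)
            se = np.sqrt(s2 * np.diag(XtX_inv))
            t_int = beta[-1] / se[-1]
            p_int = 2.0 * stats.t.sf(abs(t_int), dof)
            rows.append(
                {
                    "feature_id": f["feature_id"],
                    "variant_id": str(vids[vi]),
                    "context": context_name,
                    "g_slope": beta[-2],
                    "context_slope": beta[1],
                    "interaction_slope": beta[-1],
                    "interaction_se": se[-1],
                    "interaction_pval": p_int,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "variant_id", "context", "g_slope", "context_slope",
            "interaction_slope", "interaction_se", "interaction_pval",
        ],
    )
    if len(out):
        _, q, _, _ = multipletests(out["interaction_pval"].to_numpy(), method="fdr_bh")
        out["qval"] = q
        out["significant"] = out["qval"] < fdr
    else:
        out["qval"] = []
        out["significant"] = []
    return out


def stratified_effect_summary(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    variant: str,
    context: np.ndarray,
    n_bins: int = 4,
    min_bin_size: int = 10,
    split_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per context-quantile-bin genotype slope, with a Spearman trend statistic.

    Bins with fewer than min_bin_size samples are merged into their neighbor
    (with a warning). The returned frame carries a `trend_rho` attribute:
    Spearman correlation of bin index vs slope.
    """
    vi = genotypes.variant_ids.index(variant)
    g = genotypes.dosages[:, vi].astype(float)
    y = np.asarray(phenotype, dtype=float)
    ctx = np.asarray(context, dtype=float)
    if split_values is not None:
        edges = np.concatenate([[-np.inf], np.asarray(split_values, float), [np.inf]])
    else:
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.concatenate([[-np.inf], np.quantile(ctx, qs), [np.inf]])
    assign = np.digitize(ctx, edges[1:-1])
    # merge underfilled bins into left neighbor
    labels = sorted(set(assign))
    sizes = {b: int((assign == b).sum()) for b in labels}
    for b in labels:
        if sizes[b] < min_bin_size and len(set(assign)) > 1:
            warnings.warn(f"bin {b} underfilled ({sizes[b]} samples); merged with neighbor")
            remaining = sorted(set(assign) - {b})
            tgt = max([x for x in remaining if x < b], default=min(remaining))
            assign[assign == b] = tgt
            sizes = {bb: int((assign == bb).sum()) for bb in sorted(set(assign))}
    rows = []
    for k, b in enumerate(sorted(set(assign))):
        m = assign == b
        gs, ys = g[m], y[m]
        if gs.std() == 0:
            slope, se = np.nan, np.nan
        else:
            res = stats.linregress(gs, ys)
            slope, se = res.slope, res.stderr
        rows.append({"bin": k, "n": int(m.sum()), "mean_context": float(ctx[m].mean()),
                     "slope": slope, "se": se})
    out = pd.DataFrame(rows)
    good = out["slope"].notna()
    if good.sum() >= 2:
        rho = stats.spearmanr(out.loc[good, "bin"], out.loc[good, "slope"]).statistic
    else:
        rho = np.nan
    out.attrs["trend_rho"] = float(rho) if rho == rho else np.nan
    return out
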