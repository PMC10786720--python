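"""TWAS: nested cross-validated elastic-net expression models, summary-level
single-tissue association, and multi-tissue combination."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


@dataclass
class TwasModel:
    gene: str
    tissue: str
    variant_ids: list
    weights: np.ndarray
    rho_cv: float
    pval_cv: float
    retained: bool
    alpha: float = np.nan


def train_twas_model(
    dosages: np.ndarray,
    expression: np.ndarray,
    variant_ids: list,
    gene: str = "gene",
    tissue: str = "tissue",
    n_folds_outer: int = 5,
    n_folds_inner: int = 5,
    mixing: float = 0.5,
    alphas: np.ndarray | None = None,
    seed: int = 0,
    rho_min: float = 0.1,
    pval_max: float = 0.05,
) -> TwasModel:
    """Nested-CV elastic net of expression on cis dosages.

    Outer folds give out-of-sample predictions for rho_cv (Pearson) and its
    correlation-test p; the penalty is chosen by inner CV within each outer
    training split. The final weights come from an inner-CV fit on all data.
    Retention rule: rho_cv > rho_min and p < pval_max.
    """
    X = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    n = len(y)
    if n < n_folds_outer:
        raise ValueError("fewer samples than outer folds")
    if X.shape[1] < 1:
        raise ValueError("need at least one cis variant")
    if alphas is None:
        alphas = np.logspace(-3, 1, 20)

    pred = np.full(n, np.nan)
    outer = KFold(n_splits=n_folds_outer, shuffle=True, random_state=seed)
    for tr, te in outer.split(X):
        model = ElasticNetCV(
            l1_ratio=mixing, alphas=alphas, cv=n_folds_inner, random_state=seed, max_iter=5000
        )
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])

    if np.std(pred) == 0 or np.std(y) == 0:
        rho, pval = 0.0, 1.0
    else:
        rho, pval = stats.pearsonr(pred, y)
    final = ElasticNetCV(l1_ratio=mixing, alphas=alphas, cv=n_folds_inner, random_state=seed, max_iter=5000)
    final.fit(X, y)
    w = final.coef_
    retained = (rho > rho_min) and (pval < pval_max) and np.any(w != 0)
    return TwasModel(
        gene=gene,
        tissue=tissue,
        variant_ids=list(variant_ids),
        weights=w,
        rho_cv=float(rho),
        pval_cv=float(pval),
        retained=bool(retained),
        alpha=float(final.alpha_),
    )


def summary_twas(
    model: TwasModel,
    gwas_z: np.ndarray,
    ld_reference: np.ndarray,
    variant_sd: np.ndarray,
) -> tuple[float, float]:
    """Summary-statistic TWAS: z_gene = sum(w_l sd_l z_l) / sd_gene.

    sd_gene^2 = w' D R D w with D = diag(variant sd) and R the LD reference
    correlation; returns (z, two-sided p).
    """
    w = np.asarray(model.weights, dtype=float)
    z = np.asarray(gwas_z, dtype=float)
    sd = np.asarray(variant_sd, dtype=float)
    R = np.asarray(ld_reference, dtype=float)
    if not (len(w) == len(z) == len(sd) == R.shape[0] == R.shape[1]):
        raise ValueError("weights, z, sd and LD must align")
    ws = w * sd
    var_g = float(ws @ R @ ws)
    if var_g <= 0:
        raise ValueError("predicted expression has zero variance in the reference")
    z_gene = float(np.sum(ws * z) / np.sqrt(var_g))
    return z_gene, float(2.0 * stats.norm.sf(abs(z_gene)))


def multi_tissue_twas(
    tissue_z: np.ndarray,
    expr_correlation: np.ndarray,
    condition_threshold: float = 30.0,
) -> tuple[float, int, float]:
    """Combine per-tissue TWAS z via PCA of the predicted-expression correlation.

    Keeps eigencomponents with eigenvalue >= max eigenvalue / condition_threshold;
    statistic = sum of squared whitened projections ~ chi-square(k).
    Returns (statistic, k, p).
    """
    z = np.asarray(tissue_z, dtype=float)
    C = np.atleast_2d(np.asarray(expr_correlation, dtype=float))
    if C.shape != (len(z), len(z)):
        raise ValueError("correlation matrix must match z length")
    lam, V = np.linalg.eigh(C)
    keep = lam >= lam.max() / condition_threshold
    if not keep.any():
        raise ValueError("all eigencomponents discarded")
    proj = V[:, keep].T @ z
    statistic = float(np.sum(proj**2 / lam[keep]))
    k = int(keep.sum())
    return statistic, k, float(stats.chi2.sf(statistic, k))
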