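"""Tissue-sharing statistics: fixed-effect meta-analysis, m-values, pairwise
effect correlations, Storey's pi1 replication, and clustering similarity."""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import rand_score, adjusted_rand_score

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fixed-effect meta-analysis
# ---------------------------------------------------------------------------

def fixed_effect_meta(slopes: np.ndarray, ses: np.ndarray) -> dict:
    """Inverse-variance-weighted meta effect: b = sum(w b_t)/sum(w), w = se^-2."""
    b = np.asarray(slopes, dtype=float)
    se = np.asarray(ses, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if len(b) == 1:
        warnings.warn("single tissue: meta-analysis is a passthrough")
        z = b[0] / se[0]
        return {"slope": float(b[0]), "se": float(se[0]), "z": float(z),
                "pval": float(2 * stats.norm.sf(abs(z)))}
    w = 1.0 / se**2
    meta_b = float(np.sum(w * b) / np.sum(w))
    meta_se = float(np.sum(w) ** -0.5)
    z = meta_b / meta_se
    return {"slope": meta_b, "se": meta_se, "z": float(z),
            "pval": float(2 * stats.norm.sf(abs(z)))}


# ---------------------------------------------------------------------------
# m-values (posterior probability that an effect exists in each tissue)
# ---------------------------------------------------------------------------

def _log_config_likelihood(b: np.ndarray, se: np.ndarray, active: np.ndarray, prior_sd: float) -> float:
    """Marginal log-likelihood of one activity configuration.

    Inactive tissues: b_t ~ N(0, se_t^2). Active tissues share a latent effect
    mu ~ N(0, prior_sd^2) with b_t ~ N(mu, se_t^2); mu integrates out in
    closed form via precision algebra.
    """
    ll = 0.0
    inact = ~active
    if inact.any():
        ll += float(np.sum(stats.norm.logpdf(b[inact], 0.0, se[inact])))
    if active.any():
        prec = 1.0 / se[active] ** 2
        post_prec = 1.0 / prior_sd**2 + prec.sum()
        mu_hat = np.sum(prec * b[active]) / post_prec
        ll += float(np.sum(stats.norm.logpdf(b[active], 0.0, se[active])))
        # Gaussian integral correction for the shared latent effect
        ll += 0.5 * (np.log(1.0 / prior_sd**2) - np.log(post_prec)) + 0.5 * mu_hat**2 * post_prec
    return ll


@dataclass
class MValueResult:
    meta: dict
    m: np.ndarray
    active: np.ndarray  # m > threshold
    tissues: list


def m_values(
    slopes: np.ndarray,
    ses: np.ndarray,
    tissues: list | None = None,
    prior_effect_sd: float = 0.2,
    prior_active: float = 0.5,
    max_exact_tissues: int = 12,
    n_samples: int = 20000,
    seed: int = 0,
    active_threshold: float = 0.7,
    force_exact: bool = False,
) -> MValueResult:
    """Posterior probability that the effect exists in each tissue.

    Marginalizes over all 2^T activity configurations with per-configuration
    Bayes factors under a shared N(0, prior_effect_sd^2) effect prior; exact
    enumeration for T <= max_exact_tissues, self-normalized importance
    sampling (proposal from per-tissue marginal approximations) above.
    """
    if prior_effect_sd <= 0:
        raise ValueError("prior_effect_sd must be positive")
    b = np.asarray(slopes, dtype=float)
    se = np.asarray(ses, dtype=float)
    T = len(b)
    if tissues is None:
        tissues = [f"tissue{t}" for t in range(T)]
    meta = fixed_effect_meta(b, se) if T > 1 else fixed_effect_meta(b, se)

    lp_active = np.log(prior_active) if prior_active > 0 else -np.inf
    lp_inactive = np.log1p(-prior_active) if prior_active < 1 else -np.inf

    if T <= max_exact_tissues or force_exact:
        n_cfg = 2**T
        logw = np.empty(n_cfg)
        masks = np.empty((n_cfg, T), dtype=bool)
        for c in range(n_cfg):
            act = np.array([(c >> t) & 1 == 1 for t in range(T)])
            masks[c] = act
            lp = act.sum() * lp_active + (T - act.sum()) * lp_inactive
            logw[c] = lp + _log_config_likelihood(b, se, act, prior_effect_sd)
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        m = w @ masks
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        # proposal: independent per-tissue activity from single-tissue BFs
        lbf = (
            stats.norm.logpdf(b, 0.0, np.sqrt(se**2 + prior_effect_sd**2))
            - stats.norm.logpdf(b, 0.0, se)
        )
        odds = np.exp(np.clip(lbf + lp_active - lp_inactive, -30, 30))
        q = np.clip(odds / (1 + odds), 0.02, 0.98)
        acts = rng.random((n_samples, T)) < q[None, :]
        logw = np.empty(n_samples)
        for s in range(n_samples):
            act = acts[s]
            lp = act.sum() * lp_active + (T - act.sum()) * lp_inactive
            lq = float(np.sum(np.where(act, np.log(q), np.log1p(-q))))
            logw[s] = lp + _log_config_likelihood(b, se, act, prior_effect_sd) - lq
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        m = w @ acts
    m = np.clip(m, 0.0, 1.0)
    return MValueResult(meta=meta, m=m, active=m > active_threshold, tissues=list(tissues))


# ---------------------------------------------------------------------------
# pairwise sharing, pi1, clustering similarity
# ---------------------------------------------------------------------------

def pairwise_effect_correlation(
    effects: pd.DataFrame,
    significant: pd.DataFrame | None = None,
    min_pairs: int = 2,
    mask_mode: str = "either",
) -> pd.DataFrame:
    """Tissue x tissue Spearman correlation of effect sizes.

    effects: pairs x tissues slope table (NaN = untested). significant: same
    shape boolean mask; a pair enters the (t1, t2) correlation if significant
    in at least one of the two tissues ("either") or both ("both").
    """
    tissues = list(effects.columns)
    E = effects.to_numpy(dtype=float)
    S = None if significant is None else significant.to_numpy(dtype=bool)
    out = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    for i, j in combinations(range(len(tissues)), 2):
        ok = np.isfinite(E[:, i]) & np.isfinite(E[:, j])
        if S is not None:
            sel = (S[:, i] | S[:, j]) if mask_mode == "either" else (S[:, i] & S[:, j])
            ok &= sel
        if ok.sum() < min_pairs:
            out.iloc[i, j] = out.iloc[j, i] = np.nan
            continue
        rho = stats.spearmanr(E[ok, i], E[ok, j]).statistic
        out.iloc[i, j] = out.iloc[j, i] = rho
    return out


def pi1(
    pvalues: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> float:
    """Storey's pi1 = 1 - pi0: grid estimator smoothed by a cubic in lambda.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)); a cubic polynomial fit
    over the grid is evaluated at max(lambda) and clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if p.size < 100:
        warnings.warn(f"pi1 on only {p.size} p-values is unstable")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    # binomial-variance weights (var ~ pi0 / (m (1 - lambda))) temper the
    # endpoint noise that dominates the evaluated fit
    coef = np.polyfit(lam, pi0_lam, deg=3, w=1.0 - lam)
    pi0 = float(np.clip(np.polyval(coef, lam.max()), 0.0, 1.0))
    return 1.0 - pi0


def rand_index(labels_a: np.ndarray, labels_b: np.ndarray, adjusted: bool = False) -> float:
    """Unadjusted (default) or adjusted Rand index between two clusterings."""
    if adjusted:
        return float(adjusted_rand_score(labels_a, labels_b))
    return float(rand_score(labels_a, labels_b))


def clustering_similarity(
    matrices: dict,
    k_range: range | None = None,
    n_restarts: int = 50,
    seed: int = 0,
    adjusted: bool = False,
) -> pd.DataFrame:
    """Median pairwise Rand index across k for each data-type pair.

    matrices maps data-type name -> objects x features array (same objects,
    e.g. tissues, in the same order everywhere). For each k in k_range each
    matrix is k-means clustered (best of n_restarts seeded inits); the Rand
    index is taken per k and the median over k reported.
    """
    names = list(matrices)
    n_obj = next(iter(matrices.values())).shape[0]
    for name, X in matrices.items():
        if X.shape[0] != n_obj:
            raise ValueError(f"matrix {name} has {X.shape[0]} objects, expected {n_obj}")
    if k_range is None:
        k_range = range(2, 21)
    ks = [k for k in k_range if k < n_obj]
    skipped = [k for k in k_range if k >= n_obj]
    if skipped:
        warnings.warn(f"skipping k >= n_objects: {skipped}")
    labels: dict = {}
    for name, X in matrices.items():
        for k in ks:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            labels[(name, k)] = km.fit_predict(np.asarray(X, dtype=float))
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, j in combinations(range(len(names)), 2):
        ris = [rand_index(labels[(names[i], k)], labels[(names[j], k)], adjusted) for k in ks]
        out.iloc[i, j] = out.iloc[j, i] = float(np.median(ris))
    return out
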