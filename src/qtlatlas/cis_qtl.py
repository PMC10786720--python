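"""Cis molecular-QTL mapping.

Nominal linear scan in a +/-1 Mb TSS window, adaptive permutation pass with a
beta approximation of the empirical p-value, two-layer FDR with per-feature
nominal thresholds, grouped splicing mode, forward-backward conditional
signals, allelic-fold-change effect sizes, a trans scan, and single-causal
approximate-Bayes-factor fine-mapping.

All scans operate on covariate-residualized phenotypes and genotypes
(Frisch-Waugh-Lovell), with nominal p from a t distribution on
n - n_covariates - 2 degrees of freedom.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc
from statsmodels.stats.multitest import multipletests

from .datatypes import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def _covariate_basis(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis of [1, C]; raises on rank deficiency."""
    if covariates is None or covariates.size == 0:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    q, r = np.linalg.qr(C)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-10 * diag.max()):
        bad = list(np.where(diag < 1e-10 * diag.max())[0])
        raise ValueError(f"rank-deficient covariates (collinear columns at indices {bad})")
    return q


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Project out [intercept, covariates]; input rows/1-D along samples axis -1."""
    v = np.asarray(values, dtype=float)
    single = v.ndim == 1
    if single:
        v = v[None, :]
    q = _covariate_basis(covariates, v.shape[1])
    res = v - (v @ q) @ q.T
    return res[0] if single else res


def _as_cov_array(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, CovariateMatrix):
        return covariates.as_array()
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float)
    return np.asarray(covariates, dtype=float)


def _n_covariates(covariates) -> int:
    c = _as_cov_array(covariates)
    return 0 if c is None else c.shape[1]


# ---------------------------------------------------------------------------
# nominal scan
# ---------------------------------------------------------------------------

def _corr_to_stats(r: np.ndarray, dof: int, y_sd: np.ndarray, g_sd: np.ndarray):
    """Map correlations to slope / se / t / p given degrees of freedom."""
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(dof / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    slope = r * y_sd / g_sd
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(t != 0, slope / t, y_sd / g_sd / np.sqrt(dof))
    return slope, se, t, p


def cis_window_indices(
    genotypes: GenotypeMatrix, chrom: str, tss: int, window_bp: int = DEFAULT_WINDOW
) -> np.ndarray:
    v = genotypes.variants
    mask = (v["chrom"].to_numpy() == chrom) & (np.abs(v["pos"].to_numpy() - tss) <= window_bp)
    return np.where(mask)[0]


def _variant_filter(genotypes: GenotypeMatrix, maf_min: float, mac_min: int) -> np.ndarray:
    return (genotypes.maf() >= maf_min) & (genotypes.mac() >= mac_min)


def nominal_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    covariates=None,
    window_bp: int = DEFAULT_WINDOW,
    maf_min: float = 0.05,
    mac_min: int = 6,
) -> pd.DataFrame:
    """Per feature-variant OLS in the cis window; returns a NominalPair table."""
    if genotypes.sample_ids != list(phenotypes.sample_ids):
        raise ValueError("sample sets of genotypes and phenotypes differ")
    cov = _as_cov_array(covariates)
    n = genotypes.n_samples
    dof = n - _n_covariates(covariates) - 2
    ok = _variant_filter(genotypes, maf_min, mac_min)
    maf = genotypes.maf()

    G = residualize(genotypes.dosages.astype(float).T, cov).T  # samples x variants
    g_sd = G.std(axis=0)
    Y = residualize(phenotypes.values, cov)
    y_sd = Y.std(axis=1)

    vpos = genotypes.variants["pos"].to_numpy()
    rows = []
    for i, (_, f) in enumerate(phenotypes.features.iterrows()):
        idx = cis_window_indices(genotypes, f["chrom"], int(f["tss"]), window_bp)
        idx = idx[ok[idx] & (g_sd[idx] > 0)]
        if idx.size == 0:
            logger.info("feature %s has no cis variants; skipped", f["feature_id"])
            continue
        y = Y[i]
        if y_sd[i] == 0:
            continue
        r = (G[:, idx].T @ y) / (n * g_sd[idx] * y_sd[i])
        slope, se, t, p = _corr_to_stats(r, dof, y_sd[i], g_sd[idx])
        sign = 1 if f["strand"] == "+" else -1
        dist = (vpos[idx] - int(f["tss"])) * sign
        rows.append(
            pd.DataFrame(
                {
                    "feature_id": f["feature_id"],
                    "variant_id": np.asarray(genotypes.variant_ids)[idx],
                    "slope": slope,
                    "slope_se": se,
                    "tstat": t,
                    "pval": p,
                    "maf": maf[idx],
                    "tss_distance": dist,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["feature_id", "variant_id", "slope", "slope_se", "tstat", "pval", "maf", "tss_distance"]
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# permutations + beta approximation
# ---------------------------------------------------------------------------

def fit_beta_mle(pvals: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> tuple[float, float]:
    """Beta(a, b) maximum likelihood via Newton on (log a, log b), MoM start."""
    x = np.clip(np.asarray(pvals, dtype=float), 1e-300, 1.0)
    # jitter exact ties/endpoints to keep the likelihood finite
    x = np.clip(x, 1e-12, 1 - 1e-12)
    m, v = x.mean(), x.var()
    if v <= 0:
        return 1.0, 1.0
    common = m * (1 - m) / v - 1.0
    a = max(m * common, 1e-3)
    b = max((1 - m) * common, 1e-3)
    sl1, sl2 = np.log(x).mean(), np.log1p(-x).mean()
    from scipy.special import polygamma, psi

    theta = np.array([np.log(a), np.log(b)])
    for _ in range(max_iter):
        a, b = np.exp(theta)
        da = psi(a + b) - psi(a) + sl1
        db = psi(a + b) - psi(b) + sl2
        grad = np.array([a * da, b * db])
        tri_ab = polygamma(1, a + b)
        H = np.array(
            [
                [a * da + a * a * (tri_ab - polygamma(1, a)), a * b * tri_ab],
                [a * b * tri_ab, b * db + b * b * (tri_ab - polygamma(1, b))],
            ]
        )
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        new = theta - step
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - theta)) < tol:
            theta = new
            break
        theta = new
    a, b = np.exp(theta)
    return float(a), float(b)


@dataclass
class PermutationRecord:
    feature_id: str
    lead_variant: str
    lead_pval: float
    n_perm: int
    p_direct: float
    beta_shape1: float
    beta_shape2: float
    p_beta: float
    lead_slope: float = np.nan
    lead_slope_se: float = np.nan


def _min_p_stream(
    y: np.ndarray,
    Gn: np.ndarray,
    dof: int,
    rng: np.random.Generator,
    max_perm: int,
    adaptive_stop: int,
    obs_r2: float,
    chunk: int = 200,
):
    """Permutation maxima of r^2; yields (n_perm, hits, all max-r2 values)."""
    n = len(y)
    total, hits = 0, 0
    maxima = []
    yn = y / np.linalg.norm(y)
    while total < max_perm:
        b = min(chunk, max_perm - total)
        perm = np.argsort(rng.random((b, n)), axis=1)
        R = yn[perm] @ Gn  # (b, m) correlations
        mx = (R**2).max(axis=1)
        maxima.append(mx)
        hits += int((mx >= obs_r2).sum())
        total += b
        if hits >= adaptive_stop:
            break
    return total, hits, np.concatenate(maxima)


def _r2_to_p(r2: np.ndarray, dof: int) -> np.ndarray:
    """Two-sided p of the t statistic implied by r^2 at dof (regularized beta)."""
    return betainc(dof / 2.0, 0.5, np.clip(1.0 - r2, 0.0, 1.0))


def permutation_pass(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    covariates=None,
    max_perm: int = 1000,
    adaptive_stop: int = 100,
    seed: int = 0,
    window_bp: int = DEFAULT_WINDOW,
    maf_min: float = 0.05,
    mac_min: int = 6,
) -> pd.DataFrame:
    """Adaptive permutation pass; one PermutationRecord row per feature.

    Sample labels of the residualized phenotype are permuted; each permutation
    records the minimum nominal p over the cis window (equivalently the max
    r^2). Stops early after `adaptive_stop` permutations beat the observed
    lead p. Empirical p = (1 + hits) / (1 + n_perm); a Beta distribution is
    fit to the permutation minima by ML and evaluated at the observed lead p.
    Per-feature seeding is counter-based (seed, feature index), so results do
    not depend on scheduling.
    """
    if max_perm < 10:
        raise ValueError("max_perm must be >= 10")
    cov = _as_cov_array(covariates)
    n = genotypes.n_samples
    dof = n - _n_covariates(covariates) - 2
    ok = _variant_filter(genotypes, maf_min, mac_min)

    G = residualize(genotypes.dosages.astype(float).T, cov).T
    g_norm = np.linalg.norm(G, axis=0)
    Y = residualize(phenotypes.values, cov)

    vids = np.asarray(genotypes.variant_ids)
    records = []
    for i, (_, f) in enumerate(phenotypes.features.iterrows()):
        idx = cis_window_indices(genotypes, f["chrom"], int(f["tss"]), window_bp)
        idx = idx[ok[idx] & (g_norm[idx] > 0)]
        if idx.size == 0:
            logger.info("feature %s has no cis variants; skipped", f["feature_id"])
            continue
        y = Y[i]
        if y.std() == 0:
            continue
        Gn = G[:, idx] / g_norm[idx]
        yn = y / np.linalg.norm(y)
        r = yn @ Gn
        obs_r2 = float(np.max(r**2))
        lead_local = int(np.argmax(r**2))
        obs_p = float(_r2_to_p(np.array([obs_r2]), dof)[0])

        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        n_perm, hits, max_r2 = _min_p_stream(y, Gn, dof, rng, max_perm, adaptive_stop, obs_r2)
        p_direct = (1.0 + hits) / (1.0 + n_perm)
        perm_min_p = _r2_to_p(max_r2, dof)
        a, b = fit_beta_mle(perm_min_p)
        p_beta = float(stats.beta.cdf(obs_p, a, b))

        y_sd, g_sd = y.std(), G[:, idx[lead_local]].std()
        slope, se, _, _ = _corr_to_stats(np.array([r[lead_local]]), dof, y_sd, np.array([g_sd]))
        records.append(
            PermutationRecord(
                feature_id=f["feature_id"],
                lead_variant=str(vids[idx[lead_local]]),
                lead_pval=obs_p,
                n_perm=n_perm,
                p_direct=p_direct,
                beta_shape1=a,
                beta_shape2=b,
                p_beta=p_beta,
                lead_slope=float(slope[0]),
                lead_slope_se=float(se[0]),
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])


def grouped_permutation_pass(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    covariates=None,
    max_perm: int = 1000,
    adaptive_stop: int = 100,
    seed: int = 0,
    window_bp: int = DEFAULT_WINDOW,
    maf_min: float = 0.05,
    mac_min: int = 6,
) -> pd.DataFrame:
    """Permutation pass over feature groups (sQTL mode).

    The observed statistic is the minimum nominal p over all member-variant
    pairs of the group; each permutation permutes samples once per group
    (shared across member introns) and records the group-wide minimum.
    """
    if max_perm < 10:
        raise ValueError("max_perm must be >= 10")
    if phenotypes.features["group_id"].isna().any():
        raise ValueError("all features need a group id")
    cov = _as_cov_array(covariates)
    n = genotypes.n_samples
    dof = n - _n_covariates(covariates) - 2
    ok = _variant_filter(genotypes, maf_min, mac_min)

    G = residualize(genotypes.dosages.astype(float).T, cov).T
    g_norm = np.linalg.norm(G, axis=0)
    Y = residualize(phenotypes.values, cov)
    vids = np.asarray(genotypes.variant_ids)

    records = []
    groups = list(phenotypes.features.groupby("group_id", sort=False).groups.items())
    for gi, (group, fidx) in enumerate(groups):
        fidx = np.asarray(fidx)
        f0 = phenotypes.features.iloc[fidx[0]]
        idx = cis_window_indices(genotypes, f0["chrom"], int(f0["tss"]), window_bp)
        idx = idx[ok[idx] & (g_norm[idx] > 0)]
        if idx.size == 0:
            logger.info("group %s has no cis variants; skipped", group)
            continue
        Gn = G[:, idx] / g_norm[idx]
        Ys = Y[fidx]
        norms = np.linalg.norm(Ys, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        Yn = Ys / norms
        R = Yn @ Gn  # introns x variants
        obs_r2 = float(np.max(R**2))
        li, lj = np.unravel_index(np.argmax(R**2), R.shape)
        obs_p = float(_r2_to_p(np.array([obs_r2]), dof)[0])

        rng = np.random.default_rng(np.random.SeedSequence([seed, gi]))
        total, hits = 0, 0
        maxima = []
        while total < max_perm:
            b = min(200, max_perm - total)
            perm = np.argsort(rng.random((b, n)), axis=1)
            mx = np.zeros(b)
            for yr in Yn:  # same permutation across the group's introns
                Rp = yr[perm] @ Gn
                mx = np.maximum(mx, (Rp**2).max(axis=1))
            maxima.append(mx)
            hits += int((mx >= obs_r2).sum())
            total += b
            if hits >= adaptive_stop:
                break
        max_r2 = np.concatenate(maxima)
        p_direct = (1.0 + hits) / (1.0 + total)
        a, bb = fit_beta_mle(_r2_to_p(max_r2, dof))
        p_beta = float(stats.beta.cdf(obs_p, a, bb))

        y = Ys[li]
        y_sd, g_sd = y.std(), G[:, idx[lj]].std()
        slope, se, _, _ = _corr_to_stats(np.array([R[li, lj]]), dof, y_sd, np.array([g_sd]))
        records.append(
            {
                "feature_id": phenotypes.features.iloc[fidx[li]]["feature_id"],
                "group_id": group,
                "lead_variant": str(vids[idx[lj]]),
                "lead_pval": obs_p,
                "n_perm": total,
                "p_direct": p_direct,
                "beta_shape1": a,
                "beta_shape2": bb,
                "p_beta": p_beta,
                "lead_slope": float(slope[0]),
                "lead_slope_se": float(se[0]),
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# two-layer FDR
# ---------------------------------------------------------------------------

@dataclass
class CallSet:
    records: pd.DataFrame  # permutation records + qval, nominal_threshold, is_emolecule
    pt: float
    fdr: float
    significant_pairs: pd.DataFrame | None = None


def call_egenes(
    records: pd.DataFrame,
    nominal_pairs: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> CallSet:
    """Layer-2 FDR: BH over beta-approximated empirical p, pt, per-feature thresholds.

    q-values by Benjamini-Hochberg over p_beta; eMolecules have q < fdr; the
    genome-wide empirical threshold pt is the p_beta of the feature whose
    q-value is closest to fdr (ties broken toward the larger p, so the lead
    pair of every called feature passes its own nominal threshold); each
    feature's nominal threshold is the Beta inverse-CDF of pt at its shapes.
    """
    if records.empty:
        raise ValueError("no permutation records")
    rec = records.copy()
    _, qvals, _, _ = multipletests(rec["p_beta"].to_numpy(), method="fdr_bh")
    rec["qval"] = qvals
    rec["is_emolecule"] = rec["qval"] < fdr
    order = np.lexsort((-rec["p_beta"].to_numpy(), np.abs(rec["qval"].to_numpy() - fdr)))
    pt = float(rec["p_beta"].to_numpy()[order[0]])
    rec["nominal_threshold"] = stats.beta.ppf(pt, rec["beta_shape1"], rec["beta_shape2"])

    sig = None
    if nominal_pairs is not None:
        thr = rec.set_index("feature_id")["nominal_threshold"]
        emol = rec.set_index("feature_id")["is_emolecule"]
        np_ = nominal_pairs.copy()
        np_["nominal_threshold"] = np_["feature_id"].map(thr)
        np_["is_emolecule"] = np_["feature_id"].map(emol).fillna(False)
        sig = np_[np_["is_emolecule"] & (np_["pval"] <= np_["nominal_threshold"])].drop(
            columns=["is_emolecule"]
        )
    return CallSet(records=rec, pt=pt, fdr=fdr, significant_pairs=sig)


# ---------------------------------------------------------------------------
# conditionally independent signals
# ---------------------------------------------------------------------------

@dataclass
class IndependentSignal:
    feature_id: str
    rank: int
    variant_id: str
    slope: float
    slope_se: float
    pval: float


def _best_assoc(y, G_idx, G, cov_extra, cov, dof_extra):
    """Scan y ~ each column of G[:, G_idx] conditioning on cov + cov_extra."""
    n = len(y)
    C = cov if cov_extra is None else (
        np.column_stack([cov, cov_extra]) if cov is not None else cov_extra
    )
    yr = residualize(y, C)
    Gr = residualize(G[:, G_idx].T, C).T
    g_sd = Gr.std(axis=0)
    usable = g_sd > 1e-12
    if not usable.any():
        return None
    dof = n - (0 if C is None else C.shape[1]) - 2
    y_sd = yr.std()
    if y_sd == 0:
        return None
    r = np.full(len(G_idx), 0.0)
    r[usable] = (Gr[:, usable].T @ yr) / (n * g_sd[usable] * y_sd)
    slope, se, t, p = _corr_to_stats(r, dof, y_sd, np.where(usable, g_sd, 1.0))
    p = np.where(usable, p, 1.0)
    j = int(np.argmin(p))
    return j, float(slope[j]), float(se[j]), float(p[j])


def conditional_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    feature_row: pd.Series,
    covariates,
    nominal_threshold: float,
    window_bp: int = DEFAULT_WINDOW,
    maf_min: float = 0.05,
    mac_min: int = 6,
    max_signals: int = 10,
) -> list[IndependentSignal]:
    """Forward-backward stepwise discovery of independent cis signals.

    Forward: repeatedly add the best variant (as a dosage covariate) while its
    conditional p passes the feature's nominal threshold. Backward: re-scan
    for each signal conditioning on all the others; keep the best passing
    variant. Returns signals ranked by conditional p.
    """
    cov = _as_cov_array(covariates)
    ok = _variant_filter(genotypes, maf_min, mac_min)
    idx = cis_window_indices(genotypes, feature_row["chrom"], int(feature_row["tss"]), window_bp)
    idx = idx[ok[idx]]
    if idx.size == 0:
        return []
    G = genotypes.dosages.astype(float)
    y = np.asarray(phenotype, dtype=float)
    vids = np.asarray(genotypes.variant_ids)

    chosen: list[int] = []
    for _ in range(max_signals):
        extra = G[:, [idx[j] for j in chosen]] if chosen else None
        hit = _best_assoc(y, idx, G, extra, cov, len(chosen))
        if hit is None:
            break
        j, slope, se, p = hit
        if p > nominal_threshold or j in chosen:
            break
        chosen.append(j)
    if not chosen:
        return []

    # backward: re-test each signal conditional on all others (variant may move)
    final: list[tuple[int, float, float, float]] = []
    for k in range(len(chosen)):
        others = [idx[j] for j2, j in enumerate(chosen) if j2 != k]
        extra = G[:, others] if others else None
        hit = _best_assoc(y, idx, G, extra, cov, len(others))
        if hit is None:
            continue
        j, slope, se, p = hit
        if p <= nominal_threshold:
            final.append((idx[j], slope, se, p))
    # dedupe on variant, keep most significant, rank by p
    best: dict[int, tuple[int, float, float, float]] = {}
    for v, slope, se, p in final:
        if v not in best or p < best[v][3]:
            best[v] = (v, slope, se, p)
    ranked = sorted(best.values(), key=lambda x: x[3])
    return [
        IndependentSignal(
            feature_id=feature_row["feature_id"],
            rank=r + 1,
            variant_id=str(vids[v]),
            slope=slope,
            slope_se=se,
            pval=p,
        )
        for r, (v, slope, se, p) in enumerate(ranked)
    ]


# ---------------------------------------------------------------------------
# effect sizes, trans, fine-mapping
# ---------------------------------------------------------------------------

def estimate_afc(
    counts: np.ndarray,
    library_sizes: np.ndarray,
    dosage: np.ndarray,
    covariates=None,
) -> float:
    """Log2 allelic fold change: OLS slope of log2 normalized counts on dosage."""
    c = np.asarray(counts, dtype=float)
    if np.all(c == 0):
        raise ValueError("all-zero counts: aFC undefined")
    lib = np.asarray(library_sizes, dtype=float)
    y = np.log2(c / lib * lib.mean() + 1.0)
    cov = _as_cov_array(covariates)
    X = np.column_stack([np.ones(len(y)), np.asarray(dosage, float)])
    if cov is not None:
        X = np.column_stack([X, cov])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


def trans_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    covariates=None,
    exclusion_bp: int = 5_000_000,
    fdr: float = 0.05,
    maf_min: float = 0.05,
    mac_min: int = 6,
    pval_report: float = 1.0,
) -> pd.DataFrame:
    """Trans scan: variants on another chromosome or >= exclusion_bp from the TSS.

    BH correction over all performed tests; rows with pval <= pval_report are
    returned (all by default) with q-values and a significance flag.
    """
    cov = _as_cov_array(covariates)
    n = genotypes.n_samples
    dof = n - _n_covariates(covariates) - 2
    ok = _variant_filter(genotypes, maf_min, mac_min)

    G = residualize(genotypes.dosages.astype(float).T, cov).T
    g_sd = G.std(axis=0)
    usable = ok & (g_sd > 0)
    Y = residualize(phenotypes.values, cov)
    y_sd = Y.std(axis=1)

    vchrom = genotypes.variants["chrom"].to_numpy()
    vpos = genotypes.variants["pos"].to_numpy()
    vids = np.asarray(genotypes.variant_ids)

    rows = []
    for i, (_, f) in enumerate(phenotypes.features.iterrows()):
        if y_sd[i] == 0:
            continue
        far = (vchrom != f["chrom"]) | (np.abs(vpos - int(f["tss"])) >= exclusion_bp)
        idx = np.where(far & usable)[0]
        if idx.size == 0:
            continue
        r = (G[:, idx].T @ Y[i]) / (n * g_sd[idx] * y_sd[i])
        slope, se, t, p = _corr_to_stats(r, dof, y_sd[i], g_sd[idx])
        rows.append(
            pd.DataFrame(
                {
                    "feature_id": f["feature_id"],
                    "variant_id": vids[idx],
                    "slope": slope,
                    "slope_se": se,
                    "tstat": t,
                    "pval": p,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["feature_id", "variant_id", "slope", "slope_se", "tstat", "pval", "qval", "significant"])
    out = pd.concat(rows, ignore_index=True)
    _, q, _, _ = multipletests(out["pval"].to_numpy(), method="fdr_bh")
    out["qval"] = q
    out["significant"] = out["qval"] < fdr
    out["trans"] = True
    return out[out["pval"] <= pval_report].reset_index(drop=True)


def wakefield_abf(z: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor (alternative vs null) per variant."""
    z = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def abf_finemap(
    z: np.ndarray,
    ld: np.ndarray | None = None,
    prior_sd_effect: float = 0.15,
    se: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Single-causal fine-mapping: PIP = normalized Wakefield ABF over the region.

    se defaults to 1 (z-scale); pass per-variant standard errors for
    effect-scale priors.
    """
    z = np.asarray(z, dtype=float)
    if ld is not None:
        ld = np.asarray(ld, dtype=float)
        if ld.shape != (len(z), len(z)):
            raise ValueError("LD matrix dimensions do not match z")
    se_arr = np.broadcast_to(np.asarray(se, dtype=float), z.shape)
    labf = wakefield_abf(z, se_arr, prior_sd_effect)
    labf = labf - labf.max()
    w = np.exp(labf)
    return w / w.sum()
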