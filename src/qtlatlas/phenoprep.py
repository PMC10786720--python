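"""Phenotype preparation: TPM, expression filters, TMM, INT, PSI, confounders.

Fixed pipeline order: counts -> TPM -> expression filter -> TMM -> INT for
expression; intron counts -> PSI -> three splicing filters -> standardize for
splicing.
"""
from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .datatypes import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def tpm_from_counts(counts: PhenotypeMatrix, feature_lengths: np.ndarray) -> PhenotypeMatrix:
    """Transcripts-per-million: rate per kilobase rescaled so columns sum to 1e6."""
    lengths = np.asarray(feature_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("feature lengths must be positive")
    c = counts.values
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    colsum = c.sum(axis=0)
    zero = np.where(colsum == 0)[0]
    if zero.size:
        raise ValueError(f"zero total count in sample(s): {[counts.sample_ids[i] for i in zero]}")
    rate = c / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    return PhenotypeMatrix(values=tpm, features=counts.features.copy(), sample_ids=list(counts.sample_ids))


def filter_lowly_expressed(
    tpm: PhenotypeMatrix,
    counts: PhenotypeMatrix,
    tpm_min: float = 0.1,
    count_min: float = 6,
    max_low_fraction: float = 0.80,
) -> list[str]:
    """Keep features unless low-TPM or low-count in strictly more than 80% of samples."""
    if tpm.values.shape != counts.values.shape:
        raise ValueError("tpm and counts dimensions differ")
    if tpm.feature_ids != counts.feature_ids:
        raise ValueError("tpm and counts feature ids differ")
    n = tpm.n_samples
    frac_low_tpm = (tpm.values < tpm_min).sum(axis=1) / n
    frac_low_count = (counts.values < count_min).sum(axis=1) / n
    drop = (frac_low_tpm > max_low_fraction) | (frac_low_count > max_low_fraction)
    return [f for f, d in zip(tpm.feature_ids, drop) if not d]


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (edgeR trim-and-weight rule)."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any():
        return 1.0
    f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
    return float(2.0**f)


def tmm_normalize(
    counts: PhenotypeMatrix, ref_sample: str | None = None
) -> tuple[pd.Series, PhenotypeMatrix]:
    """Trimmed-mean-of-M-values scaling factors and the rescaled matrix.

    Reference sample: 75th-percentile rule (upper quartile of counts/libsize
    closest to the mean upper quartile). Factors are normalized to geometric
    mean 1; the returned matrix is counts / (libsize * factor) * 1e6.
    """
    c = counts.values
    if c.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = c.sum(axis=0)
    if np.any(lib == 0):
        bad = [counts.sample_ids[i] for i in np.where(lib == 0)[0]]
        raise ValueError(f"all-zero sample(s): {bad}")
    uq = np.array([np.quantile(c[:, j][c[:, j] > 0] / lib[j], 0.75) for j in range(c.shape[1])])
    if ref_sample is None:
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = counts.sample_ids.index(ref_sample)
    factors = np.array(
        [_tmm_pair_factor(c[:, j], c[:, ref_j], lib[j], lib[ref_j]) for j in range(c.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    norm = c / (lib * factors)[None, :] * 1e6
    return (
        pd.Series(factors, index=counts.sample_ids, name="tmm_factor"),
        PhenotypeMatrix(values=norm, features=counts.features.copy(), sample_ids=list(counts.sample_ids)),
    )


def inverse_normal_transform(values: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Rank-based INT along the last axis: Phi^-1((rank - offset) / n), average ranks for ties."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    single = v.ndim == 1
    if single:
        v = v[None, :]
    n = v.shape[1]
    out = np.empty_like(v)
    for i in range(v.shape[0]):
        if np.all(v[i] == v[i, 0]):
            out[i] = 0.0
            continue
        ranks = stats.rankdata(v[i], method="average")
        out[i] = ndtri((ranks - offset) / n)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------

def compute_psi_and_filter(
    intron_counts: PhenotypeMatrix,
    n: int | None = None,
    *,
    standardize: bool = True,
) -> tuple[PhenotypeMatrix, pd.DataFrame]:
    """PSI per intron with the three splicing filters, then per-intron z-scoring.

    Filters (drop an intron if): zero count in strictly more than 50% of
    samples; fewer than max(10, 0.1 n) unique PSI values; low complexity,
    meaning for z-scores z_i of the cluster read fraction across individuals
    both sum(|z_i| < 0.25) >= n - 3 and sum(|z_i| > 6) <= 3 hold. Clusters
    reduced below 2 introns are dropped entirely. Samples with a zero cluster
    total get the intron's mean PSI (flagged in the log). Surviving rows are
    z-scored and take the owning gene's TSS as coordinate.
    Returns (filtered matrix, filter log).
    """
    if n is None:
        n = intron_counts.n_samples
    if n != intron_counts.n_samples:
        raise ValueError("n does not match sample count")
    feats = intron_counts.features
    log_rows = []
    kept_rows = []
    kept_meta = []
    for cluster, idx in feats.groupby("group_id", sort=False).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            raise ValueError(f"cluster {cluster} has fewer than 2 introns")
        counts = intron_counts.values[idx]
        totals = counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            psi = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), np.nan)
        # impute missing PSI (zero cluster total) to the intron's row mean
        for r in range(psi.shape[0]):
            miss = np.isnan(psi[r])
            if miss.any():
                psi[r, miss] = np.nanmean(psi[r])
                log_rows.append(
                    {"feature_id": feats.iloc[idx[r]]["feature_id"], "rule": "imputed_missing_psi"}
                )
        keep_local = []
        for r in range(psi.shape[0]):
            fid = feats.iloc[idx[r]]["feature_id"]
            if (counts[r] == 0).sum() > 0.5 * n:
                log_rows.append({"feature_id": fid, "rule": "zero_in_gt50pct"})
                continue
            if len(np.unique(psi[r])) < max(10, 0.1 * n):
                log_rows.append({"feature_id": fid, "rule": "too_few_unique"})
                continue
            sd = psi[r].std()
            z = (psi[r] - psi[r].mean()) / sd if sd > 0 else np.zeros(n)
            if (np.abs(z) < 0.25).sum() >= n - 3 and (np.abs(z) > 6).sum() <= 3:
                log_rows.append({"feature_id": fid, "rule": "low_complexity"})
                continue
            keep_local.append(r)
        if len(keep_local) < 2:
            for r in keep_local:
                log_rows.append(
                    {"feature_id": feats.iloc[idx[r]]["feature_id"], "rule": "cluster_below_2"}
                )
            continue
        for r in keep_local:
            kept_rows.append(psi[r])
            kept_meta.append(idx[r])

    if not kept_rows:
        empty = PhenotypeMatrix(
            values=np.empty((0, n)),
            features=feats.iloc[[]].reset_index(drop=True),
            sample_ids=list(intron_counts.sample_ids),
        )
        return empty, pd.DataFrame(log_rows, columns=["feature_id", "rule"])

    values = np.vstack(kept_rows)
    meta = feats.iloc[kept_meta].reset_index(drop=True).copy()
    if standardize:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    out = PhenotypeMatrix(values=values, features=meta, sample_ids=list(intron_counts.sample_ids))
    return out, pd.DataFrame(log_rows, columns=["feature_id", "rule"])


# ---------------------------------------------------------------------------
# confounders
# ---------------------------------------------------------------------------

def estimate_hidden_factors(
    expression: PhenotypeMatrix | np.ndarray, k: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k sample-space factors of the standardized expression matrix.

    Probabilistic-PCA surrogate for latent-confounder estimation: rows are
    z-scored, the SVD taken, and the top right-singular vectors returned as
    orthonormal factors (samples x k) with their explained-variance weights.
    Deterministic: each factor's largest-magnitude entry is made positive.
    """
    X = expression.values if isinstance(expression, PhenotypeMatrix) else np.asarray(expression, float)
    n_feat, n_samp = X.shape
    if k >= min(n_feat, n_samp):
        raise ValueError(f"k={k} too large for a {n_feat}x{n_samp} matrix")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    factors = Vt[:k].T
    flip = np.sign(factors[np.argmax(np.abs(factors), axis=0), np.arange(k)])
    factors = factors * flip
    weights = s[:k] ** 2 / np.sum(s**2)
    return factors, weights


def genotype_pcs(genotypes: GenotypeMatrix, n_samples: int | None = None) -> CovariateMatrix:
    """Genotype PCs on standardized dosages: 5 when n < 200, 10 when n >= 200."""
    X = genotypes.dosages.astype(float)
    if n_samples is None:
        n_samples = X.shape[0]
    poly = X.std(axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic variants")
    X = X[:, poly]
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    n_pcs = 5 if n_samples < 200 else 10
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    n_pcs = min(n_pcs, int((s > 1e-8).sum()))
    pcs = U[:, :n_pcs]
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    df = pd.DataFrame(pcs, index=genotypes.sample_ids, columns=cols)
    return CovariateMatrix(values=df, kinds={c: "genotype_pc" for c in cols})


def covariate_variance_explained(
    factors: np.ndarray, known: pd.DataFrame
) -> pd.Series:
    """R-squared of each known covariate regressed on all factors jointly."""
    F = np.column_stack([np.ones(len(factors)), np.asarray(factors, float)])
    out = {}
    for col in known.columns:
        y = known[col].to_numpy(dtype=float)
        if y.std() == 0:
            out[col] = np.nan
            logger.warning("constant known covariate %s: R2 undefined", col)
            continue
        beta, *_ = np.linalg.lstsq(F, y, rcond=None)
        resid = y - F @ beta
        out[col] = float(1.0 - resid.var() / y.var())
    return pd.Series(out, name="r2")


def tau_specificity(median_expression: pd.DataFrame, log_transform: bool = True) -> pd.Series:
    """Yanai tissue-specificity index per gene over per-tissue medians.

    tau = sum_i (1 - x_i / max_i x_i) / (N - 1), computed on log2(x + 1).
    All-zero genes are returned as NaN.
    """
    X = median_expression.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    if np.any(X < 0):
        raise ValueError("expression must be non-negative")
    if log_transform:
        X = np.log2(X + 1.0)
    mx = X.max(axis=1)
    tau = np.full(X.shape[0], np.nan)
    ok = mx > 0
    tau[ok] = (1.0 - X[ok] / mx[ok, None]).sum(axis=1) / (X.shape[1] - 1)
    return pd.Series(tau, index=median_expression.index, name="tau")


def prepare_expression(
    counts: PhenotypeMatrix, feature_lengths: np.ndarray
) -> tuple[PhenotypeMatrix, pd.DataFrame]:
    """Full expression pipeline: TPM -> filter -> TMM -> INT. Returns (matrix, filter log)."""
    tpm = tpm_from_counts(counts, feature_lengths)
    kept = filter_lowly_expressed(tpm, counts)
    keep_idx = [i for i, f in enumerate(counts.feature_ids) if f in set(kept)]
    dropped = sorted(set(counts.feature_ids) - set(kept))
    flog = pd.DataFrame({"feature_id": dropped, "rule": "lowly_expressed"})
    fc = counts.subset_features(keep_idx)
    _, norm = tmm_normalize(fc)
    values = inverse_normal_transform(norm.values)
    return (
        PhenotypeMatrix(values=values, features=fc.features.copy(), sample_ids=list(fc.sample_ids)),
        flog,
    )
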