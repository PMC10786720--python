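"""Enrichment analyses: molQTL at GWAS loci, MAF-matched backgrounds,
annotation and TAD enrichment of fine-mapped variants, tissue relevance."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)


def lambda_scale(pvalues: np.ndarray, lambda_target: float = 10.0) -> np.ndarray:
    """Rescale chi-square(1) statistics so their median is lambda_target times
    the null chi-square(1) median (genomic-control-style comparability)."""
    chi2 = stats.chi2.isf(np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1.0), 1)
    med = np.median(chi2)
    if med <= 0:
        raise ValueError("degenerate p-value set")
    return chi2 * (lambda_target * _CHI2_MEDIAN_1DF / med)


def qtl_gwas_overlap_enrichment(
    lead_pvalues: pd.DataFrame,
    gwas_locus_variants: set,
    lambda_target: float = 10.0,
) -> dict:
    """Overlap enrichment of molQTL signal at GWAS-locus variants.

    lead_pvalues: variants x tissues table of each variant's best (per-gene
    lead) molQTL p per tissue, NaN where untested. Per tissue the p-values are
    converted to chi-square(1) and median-rescaled to lambda_target; the
    per-variant maximum scaled statistic across tissues (i.e. the minimum p)
    forms the background, from which the GWAS-locus subset is compared by a
    one-sided Wilcoxon rank-sum test. Returns fold of medians, p, and sizes.
    """
    scaled = np.full(lead_pvalues.shape, np.nan)
    for j, tissue in enumerate(lead_pvalues.columns):
        p = lead_pvalues[tissue].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if ok.sum() == 0:
            continue
        scaled[ok, j] = lambda_scale(p[ok], lambda_target)
    background = np.nanmax(scaled, axis=1)
    valid = np.isfinite(background)
    background = background[valid]
    variants = lead_pvalues.index.to_numpy()[valid]
    in_locus = np.isin(variants, list(gwas_locus_variants))
    if in_locus.sum() == 0 or (~in_locus).sum() == 0:
        raise ValueError("empty overlap between GWAS loci and the molQTL variant set")
    target = background[in_locus]
    rest = background[~in_locus]
    u = stats.mannwhitneyu(target, rest, alternative="greater")
    return {
        "fold": float(np.median(target) / np.median(rest)),
        "pval": float(u.pvalue),
        "n_target": int(in_locus.sum()),
        "n_background": int(len(background)),
    }


def maf_matched_sample(
    target_ids: list,
    target_maf: np.ndarray,
    pool_ids: list,
    pool_maf: np.ndarray,
    n_bins: int = 20,
    seed: int = 0,
) -> list:
    """Sample controls from the pool matching the target's MAF histogram.

    Bin-for-bin equal counts, without replacement, never returning a target
    variant. Raises naming the first underfilled bin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    t_maf = np.asarray(target_maf, dtype=float)
    p_maf = np.asarray(pool_maf, dtype=float)
    pool_ids = np.asarray(pool_ids, dtype=object)
    exclude = set(target_ids)
    usable = np.array([v not in exclude for v in pool_ids])
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    t_bin = np.clip(np.digitize(t_maf, edges) - 1, 0, n_bins - 1)
    p_bin = np.clip(np.digitize(p_maf, edges) - 1, 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        need = int((t_bin == b).sum())
        if need == 0:
            continue
        avail = np.where(usable & (p_bin == b))[0]
        if len(avail) < need:
            raise ValueError(
                f"MAF bin [{edges[b]:.3f}, {edges[b+1]:.3f}) underfilled: "
                f"need {need}, pool has {len(avail)}"
            )
        out.extend(pool_ids[rng.choice(avail, size=need, replace=False)])
    return out


def _in_any_interval(pos: np.ndarray, chrom: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for c, sub in intervals.groupby("chrom"):
        m = chrom == c
        if not m.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        j = np.searchsorted(starts, pos[m], side="right") - 1
        ok = j >= 0
        inside = np.zeros(m.sum(), dtype=bool)
        inside[ok] = pos[m][ok] < ends[j[ok]]
        hit[m] = inside
    return hit


def annotation_enrichment(
    target: pd.DataFrame,
    background: pd.DataFrame,
    annotations: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold enrichment of (PIP-weighted) target variants in each annotation.

    target/background: columns chrom, pos and optionally pip (weights);
    annotations: chrom, start, end, state. fold = weighted target fraction in
    the annotation over background fraction, sd by bootstrap over variants.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    tw = target["pip"].to_numpy(dtype=float) if "pip" in target else np.ones(len(target))
    rows = []
    for state, sub in annotations.groupby("state"):
        t_in = _in_any_interval(target["pos"].to_numpy(), target["chrom"].to_numpy(), sub)
        b_in = _in_any_interval(background["pos"].to_numpy(), background["chrom"].to_numpy(), sub)
        b_frac = b_in.mean() if len(b_in) else 0.0
        if b_frac == 0:
            rows.append({"state": state, "fold": np.nan, "sd": np.nan, "flag": "no_background_overlap"})
            continue
        t_frac = float(np.sum(tw * t_in) / np.sum(tw))
        boots = []
        for _ in range(n_boot):
            bi = rng.integers(0, len(target), size=len(target))
            boots.append(np.sum(tw[bi] * t_in[bi]) / np.sum(tw[bi]) / b_frac)
        rows.append({"state": state, "fold": t_frac / b_frac, "sd": float(np.std(boots)), "flag": ""})
    return pd.DataFrame(rows)


def tad_enrichment(
    pairs: pd.DataFrame,
    tads: pd.DataFrame,
    distance_bins: np.ndarray,
    chrom_lengths: dict,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of variant-TSS pairs falling in the same TAD, per distance bin.

    pairs: columns chrom, tss, variant_pos. Expected co-TAD fraction comes
    from distance-preserving relocation of the variant (same |distance|,
    random direction and random TSS position); fold = observed / expected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 43]))
    chrom = pairs["chrom"].to_numpy()
    tss = pairs["tss"].to_numpy(dtype=np.int64)
    vpos = pairs["variant_pos"].to_numpy(dtype=np.int64)
    dist = np.abs(vpos - tss)

    def co_tad(c, a, b):
        hit_a = _tad_of(c, a)
        hit_b = _tad_of(c, b)
        return (hit_a >= 0) & (hit_a == hit_b)

    tad_lookup = {}
    for c, sub in tads.groupby("chrom"):
        order = np.argsort(sub["start"].to_numpy())
        tad_lookup[c] = (sub["start"].to_numpy()[order], sub["end"].to_numpy()[order])

    def _tad_of(c_arr, p_arr):
        out = np.full(len(p_arr), -1, dtype=np.int64)
        for c in np.unique(c_arr):
            if c not in tad_lookup:
                continue
            starts, ends = tad_lookup[c]
            m = c_arr == c
            j = np.searchsorted(starts, p_arr[m], side="right") - 1
            ok = (j >= 0) & (p_arr[m] < ends[np.clip(j, 0, len(ends) - 1)])
            res = np.where(ok, j, -1)
            out[m] = res
        return out

    observed = co_tad(chrom, tss, vpos)
    binned = np.digitize(dist, distance_bins)
    rows = []
    for b in range(len(distance_bins) + 1):
        m = binned == b
        lo = 0 if b == 0 else distance_bins[b - 1]
        hi = np.inf if b == len(distance_bins) else distance_bins[b]
        if m.sum() == 0:
            rows.append({"bin": b, "lo": lo, "hi": hi, "n": 0, "fold": np.nan, "sd": np.nan,
                         "flag": "empty"})
            continue
        obs = observed[m].mean()
        folds = []
        for _ in range(n_boot):
            L = np.array([chrom_lengths[c] for c in chrom[m]])
            new_tss = (rng.random(m.sum()) * (L - 1)).astype(np.int64) + 1
            sign = rng.choice([-1, 1], size=m.sum())
            new_v = np.clip(new_tss + sign * dist[m], 1, L - 1)
            exp = co_tad(chrom[m], new_tss, new_v).mean()
            folds.append(obs / exp if exp > 0 else np.nan)
        folds = np.asarray(folds, dtype=float)
        rows.append({"bin": b, "lo": lo, "hi": hi, "n": int(m.sum()),
                     "fold": float(np.nanmean(folds)), "sd": float(np.nanstd(folds)), "flag": ""})
    return pd.DataFrame(rows)


def tissue_relevance(
    n_colocalized: pd.Series,
    n_samples: pd.Series,
    egene_proportion: pd.Series,
    min_samples: int = 100,
) -> pd.DataFrame:
    """Relevance score = colocalized genes / (sample size * eGene proportion).

    Tissues below the sample-size floor are excluded with a flag.
    """
    if (egene_proportion <= 0).any():
        raise ValueError("eGene proportion must be positive")
    if (n_samples <= 0).any():
        raise ValueError("sample size must be positive")
    score = n_colocalized / (n_samples * egene_proportion)
    out = pd.DataFrame(
        {
            "n_colocalized": n_colocalized,
            "n_samples": n_samples,
            "egene_proportion": egene_proportion,
            "score": score,
            "included": n_samples >= min_samples,
        }
    )
    out.loc[~out["included"], "score"] = np.nan
    return out
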