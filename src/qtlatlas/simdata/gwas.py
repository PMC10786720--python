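"""GWAS cohort simulation at the summary-statistic level.

Default mode draws z directly from the multivariate normal implied by LD and
causal effects (RSS model); an individual-level mode simulates genotypes and
phenotypes and computes marginal z for oracle cross-checks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import ConfigurationError, GenotypeMatrix, GwasSummary, PlantedGwas, SimTruth


def ld_matrix(genotypes: GenotypeMatrix, idx: np.ndarray | None = None) -> np.ndarray:
    """Correlation matrix of standardized dosages (the LD reference)."""
    X = genotypes.dosages.astype(float)
    if idx is not None:
        X = X[:, idx]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    return (X.T @ X) / X.shape[0]


def _standardized_effects(
    genotypes: GenotypeMatrix, causal_spec: dict, h2_locus: float
) -> tuple[np.ndarray, np.ndarray]:
    vids = genotypes.variant_ids
    vid_index = {v: i for i, v in enumerate(vids)}
    for v in causal_spec:
        if v not in vid_index:
            raise ConfigurationError(f"causal variant {v} not in reference")
    idx = np.array([vid_index[v] for v in causal_spec], dtype=int)
    raw = np.asarray([causal_spec[v] for v in causal_spec], dtype=float)
    b = np.zeros(genotypes.n_variants)
    b[idx] = raw
    if h2_locus > 0:
        R = ld_matrix(genotypes)
        var_g = float(b @ R @ b)
        if var_g <= 0:
            raise ConfigurationError("degenerate causal configuration")
        b *= np.sqrt(h2_locus / var_g)
    else:
        b[:] = 0.0
    return b, idx


def simulate_gwas_cohort(
    genotypes_or_ld_ref: GenotypeMatrix,
    causal_spec: dict,
    n_gwas: int,
    h2_locus: float,
    seed: int,
    *,
    mode: str = "rss",
    trait: str = "trait",
    shared_with_qtl: bool = False,
) -> tuple[GwasSummary, SimTruth]:
    """Simulate per-variant GWAS z statistics for one cohort.

    causal_spec maps variant id -> relative effect weight (standardized scale);
    weights are rescaled so the locus explains h2_locus of phenotypic variance.
    """
    if not (0.0 <= h2_locus < 1.0):
        raise ConfigurationError("h2_locus must be in [0, 1)")
    ref = genotypes_or_ld_ref
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    b, causal_idx = _standardized_effects(ref, causal_spec, h2_locus)
    R = ld_matrix(ref)

    if mode == "rss":
        mean = np.sqrt(n_gwas) * (R @ b)
        # sample correlated noise via eigen square root (R may be singular)
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 0.0, None)
        noise = V @ (np.sqrt(w) * rng.standard_normal(len(b)))
        z = mean + noise
    elif mode == "individual":
        # resample reference haplo-rows to build a cohort of size n_gwas
        rows = rng.integers(0, ref.n_samples, size=n_gwas)
        G = ref.dosages[rows].astype(float)
        G = (G - G.mean(axis=0))
        sd = G.std(axis=0)
        sd[sd == 0] = 1.0
        Gs = G / sd
        y = Gs @ b + rng.standard_normal(n_gwas) * np.sqrt(max(1.0 - h2_locus, 1e-12))
        y = (y - y.mean()) / y.std()
        r = (Gs.T @ y) / n_gwas
        z = r * np.sqrt(n_gwas)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")

    table = ref.variants[["variant_id", "chrom", "pos"]].copy()
    table["z"] = z
    table["n"] = n_gwas
    table["n_cases"] = np.nan
    table["n_controls"] = np.nan
    truth = SimTruth(
        planted_gwas=[
            PlantedGwas(variant_id=ref.variant_ids[i], effect=float(b[i]), shared_with_qtl=shared_with_qtl)
            for i in causal_idx
        ]
    )
    return GwasSummary(table=table, trait=trait), truth
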