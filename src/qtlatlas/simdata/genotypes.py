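"""Genotype simulation: AR(1) haplotype model with breed structure.

Haplotypes are generated from a latent Gaussian chain along each chromosome
with adjacent-variant correlation exp(-d / ld_decay); thresholding the latent
value at the breed-specific allele-frequency quantile yields the allele, so
LD decays geometrically with distance and breed drift shifts frequencies.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ..datatypes import ConfigurationError, GenotypeMatrix, variant_id
from .config import SimConfig

_MIN_MAF = 0.05


def _variant_positions(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sorted 1-based positions and chromosome index per variant."""
    per_chrom = np.full(config.n_chroms, config.n_variants // config.n_chroms)
    per_chrom[: config.n_variants % config.n_chroms] += 1
    chrom_idx = np.repeat(np.arange(config.n_chroms), per_chrom)
    pos = np.empty(config.n_variants, dtype=np.int64)
    start = 0
    for c, k in enumerate(per_chrom):
        p = np.sort(rng.choice(config.chrom_length - 1, size=k, replace=False)) + 1
        pos[start : start + k] = p
        start += k
    return pos, chrom_idx


def _latent_chain(
    n_hap: int, pos: np.ndarray, chrom_idx: np.ndarray, ld_decay: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent AR(1) field, one row per haplotype, one column per variant."""
    m = len(pos)
    eps = rng.standard_normal((n_hap, m))
    x = np.empty((n_hap, m))
    x[:, 0] = eps[:, 0]
    if ld_decay > 0:
        d = np.diff(pos).astype(float)
        r = np.exp(-d / ld_decay)
        r[np.diff(chrom_idx) != 0] = 0.0  # chains restart at chromosome breaks
    else:
        r = np.zeros(m - 1)
    for j in range(1, m):
        x[:, j] = r[j - 1] * x[:, j - 1] + np.sqrt(1.0 - r[j - 1] ** 2) * eps[:, j]
    return x


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Generate a diploid dosage matrix with LD, breed structure and MAF >= 0.05.

    Variants whose realized MAF falls below 0.05 are resampled (independently
    of the LD chain) with allele frequencies pushed toward 0.5 until they pass.
    """
    if config.n_samples < 20:
        raise ConfigurationError("n_samples must be >= 20")
    if config.n_variants < 10:
        raise ConfigurationError("n_variants must be >= 10")

    rng = config.rng(stream=1)
    pos, chrom_idx = _variant_positions(config, rng)
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx])

    n_breeds = len(config.breed_proportions)
    counts = np.floor(np.asarray(config.breed_proportions) * config.n_samples).astype(int)
    counts[0] += config.n_samples - counts.sum()
    breed_of_sample = np.repeat(np.arange(n_breeds), counts)

    base_freq = rng.uniform(*config.maf_range, size=config.n_variants)
    drift = config.breed_drift * rng.standard_normal((n_breeds, config.n_variants))
    breed_freq = np.clip(base_freq[None, :] + drift, 0.02, 0.98)
    thresh = ndtri(breed_freq)  # latent < threshold -> alternative allele

    n_hap = 2 * config.n_samples
    breed_of_hap = np.repeat(breed_of_sample, 2)
    latent = _latent_chain(n_hap, pos, chrom_idx, config.ld_decay, rng)
    alleles = (latent < thresh[breed_of_hap, :]).astype(np.int8)
    dosage = alleles[0::2] + alleles[1::2]

    # enforce realized MAF floor by resampling failing columns
    for _ in range(50):
        p = dosage.mean(axis=0) / 2.0
        bad = np.where(np.minimum(p, 1 - p) < _MIN_MAF)[0]
        if bad.size == 0:
            break
        redraw_freq = rng.uniform(0.2, 0.5, size=bad.size)
        fresh = (rng.random((n_hap, bad.size)) < redraw_freq[None, :]).astype(np.int8)
        dosage[:, bad] = fresh[0::2] + fresh[1::2]

    ref, alt = "A", "G"
    variants = pd.DataFrame(
        {
            "variant_id": [variant_id(c, int(p), ref, alt) for c, p in zip(chroms, pos)],
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
        }
    )
    # continuous ancestry proportion: noisy indicator of breed 0 membership
    ancestry = np.clip(
        (breed_of_sample == 0).astype(float) * 0.8 + 0.1 + 0.05 * rng.standard_normal(config.n_samples),
        0.0,
        1.0,
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(config.n_samples)],
            "breed": [f"breed{b}" for b in breed_of_sample],
            "ancestry": ancestry,
        }
    )
    return GenotypeMatrix(dosages=dosage.astype(np.int8), variants=variants, samples=samples)
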