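"""Paired cross-species TWAS tables with a planted |effect| correlation."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import ConfigurationError

_HN_MEAN = np.sqrt(2.0 / np.pi)
_HN_SD = np.sqrt(1.0 - 2.0 / np.pi)
_SHIFT = 2.0  # keeps shifted standardized half-normals strictly positive


def _std_half_normal(n: int, rng: np.random.Generator) -> np.ndarray:
    h = np.abs(rng.standard_normal(n))
    return (h - _HN_MEAN) / _HN_SD


def simulate_ortholog_twas_pair(
    n_genes: int,
    planted_correlation: float,
    seed: int,
    *,
    n_a: int = 1000,
    n_b: int = 1000,
    trait: str = "trait",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TWAS effect tables for two species with a planted correlation of |effect|.

    Magnitudes are affine transforms of standardized half-normal draws built so
    that corr(|effect_A|, |effect_B|) equals planted_correlation in expectation;
    signs are independent Rademacher. Returns (twas_A, twas_B, ortholog_map).
    """
    if not (-1.0 <= planted_correlation <= 1.0):
        raise ConfigurationError("planted_correlation must lie in [-1, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    h_a = _std_half_normal(n_genes, rng)
    h_ind = _std_half_normal(n_genes, rng)
    rho = planted_correlation
    h_b = rho * h_a + np.sqrt(max(0.0, 1.0 - rho**2)) * h_ind
    mag_a = 0.3 * (h_a + _SHIFT)
    mag_b = 0.3 * (h_b + _SHIFT)
    sign_a = rng.choice([-1.0, 1.0], size=n_genes)
    sign_b = rng.choice([-1.0, 1.0], size=n_genes)

    genes_a = [f"pigG{i:05d}" for i in range(n_genes)]
    genes_b = [f"humG{i:05d}" for i in range(n_genes)]

    def _table(genes, mags, signs, n):
        eff = signs * mags
        return pd.DataFrame(
            {
                "gene_id": genes,
                "effect": eff,
                "z": eff * np.sqrt(n) * 0.1,
                "trait": trait,
                "tissue": "tissueX",
                "n": n,
            }
        )

    omap = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    return _table(genes_a, mag_a, sign_a, n_a), _table(genes_b, mag_b, sign_b, n_b), omap
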