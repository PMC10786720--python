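"""Simulation configuration."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datatypes import ConfigurationError


@dataclass
class SimConfig:
    """Knobs for the synthetic cohort.

    effect_size_dist specifies planted slopes on the log2 (aFC-like) scale:
    either ("fixed", value) or ("normal", sd).
    """

    n_samples: int = 200
    n_variants: int = 500
    n_features_per_kind: dict = field(default_factory=lambda: {"gene": 50})
    breed_proportions: tuple = (0.5, 0.5)
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float = 50_000.0  # correlation half-distance in bp (e^-1 distance)
    n_hidden_factors: int = 0
    effect_size_dist: tuple = ("fixed", 1.0)
    noise_sd: float = 0.5
    seed: int = 0
    # layout / structure extras
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    breed_drift: float = 0.0  # sd of per-breed allele-frequency perturbation
    n_planted_qtl: int = 0
    factor_sd: float = 0.3  # sd of hidden-factor loadings on log scale
    factor_structure_weight: float = 0.7  # factor-1 variance share aligned with ancestry
    mean_library_size: float = 2e6

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ConfigurationError("n_variants must be positive")
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if len(self.breed_proportions) == 0:
            raise ConfigurationError("breed_proportions must be non-empty")
        if abs(sum(self.breed_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("breed_proportions must sum to 1")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within [0, 0.5]")
        if self.ld_decay < 0:
            raise ConfigurationError("ld_decay must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Counter-based child generator; distinct streams are independent."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    def draw_effects(self, n: int, rng: np.random.Generator) -> np.ndarray:
        kind, param = self.effect_size_dist
        if kind == "fixed":
            return np.full(n, float(param))
        if kind == "normal":
            return rng.normal(0.0, float(param), size=n)
        raise ConfigurationError(f"unknown effect_size_dist kind: {kind!r}")
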