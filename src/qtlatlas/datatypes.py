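"""Core data containers shared across the pipeline.

All matrices are dense numpy arrays wrapped with pandas metadata tables so
that features, variants and samples stay joinable across modules via stable
string identifiers (``chrom:pos:ref:alt`` for variants).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

PHENOTYPE_KINDS = ("gene", "exon", "lncRNA", "enhancer", "intron")


class ConfigurationError(ValueError):
    """Raised for degenerate or inconsistent configuration."""


def variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage table plus variant and sample metadata.

    dosages: int array (n_samples, n_variants) with values in {0, 1, 2}.
    variants: DataFrame with columns variant_id, chrom, pos (1-based), ref, alt.
    samples: DataFrame with columns sample_id, breed, ancestry (continuous
        ancestry proportion in [0, 1]).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match metadata "
                f"({len(self.samples)} samples, {len(self.variants)} variants)"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def allele_freq(self) -> np.ndarray:
        """Alternative-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def mac(self) -> np.ndarray:
        ac = self.dosages.sum(axis=0)
        return np.minimum(ac, 2 * self.n_samples - ac)

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            variants=self.variants.copy(),
            samples=self.samples.iloc[idx].reset_index(drop=True),
        )

    def subset_variants(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=self.samples.copy(),
        )


@dataclass
class PhenotypeMatrix:
    """Features x samples value table with feature coordinates.

    values: float array (n_features, n_samples).
    features: DataFrame with columns feature_id, chrom, start, end (0-based
        half-open), tss (1-based), strand, kind, group_id and optionally
        gene_id (owning gene for introns/exons).
    """

    values: np.ndarray
    features: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.features), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match metadata "
                f"({len(self.features)} features, {len(self.sample_ids)} samples)"
            )
        fid = self.features["feature_id"]
        if fid.duplicated().any():
            dupes = fid[fid.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features["feature_id"])

    def subset_features(self, idx: Sequence[int]) -> "PhenotypeMatrix":
        idx = np.asarray(idx)
        return PhenotypeMatrix(
            values=self.values[idx],
            features=self.features.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def select_features(self, ids: Sequence[str]) -> "PhenotypeMatrix":
        keep = set(ids)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep]
        return self.subset_features(idx)


@dataclass
class CovariateMatrix:
    """Samples x covariates table with a kind label per covariate.

    kinds maps covariate name -> one of {"genotype_pc", "hidden_factor", "known"}.
    """

    values: pd.DataFrame
    kinds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and np.any(arr.std(axis=0) == 0):
            bad = [c for c, s in zip(self.values.columns, arr.std(axis=0)) if s == 0]
            raise ValueError(f"constant covariate columns: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class PlantedQtl:
    feature_id: str
    variant_id: str
    slope: float
    tissues: tuple = ()


@dataclass
class PlantedGwas:
    variant_id: str
    effect: float
    shared_with_qtl: bool = False


@dataclass
class PlantedInteraction:
    feature_id: str
    variant_id: str
    context: str
    slope: float


@dataclass
class SimTruth:
    """Ledger of every planted effect, for parameter-recovery tests."""

    planted_qtl: list = field(default_factory=list)
    planted_gwas: list = field(default_factory=list)
    planted_factors: np.ndarray | None = None
    planted_interactions: list = field(default_factory=list)

    def validate_against(self, genotypes: GenotypeMatrix, phenotypes: PhenotypeMatrix) -> None:
        vids = set(genotypes.variant_ids)
        fids = set(phenotypes.feature_ids)
        for q in self.planted_qtl:
            if q.variant_id not in vids:
                raise ValueError(f"planted variant {q.variant_id} missing from genotypes")
            if q.feature_id not in fids:
                raise ValueError(f"planted feature {q.feature_id} missing from phenotypes")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "qtl", "feature_id": q.feature_id, "variant_id": q.variant_id,
             "slope": q.slope, "extra": ",".join(map(str, q.tissues))}
            for q in self.planted_qtl
        ]
        rows += [
            {"kind": "gwas", "feature_id": "", "variant_id": g.variant_id,
             "slope": g.effect, "extra": str(g.shared_with_qtl)}
            for g in self.planted_gwas
        ]
        rows += [
            {"kind": "interaction", "feature_id": it.feature_id, "variant_id": it.variant_id,
             "slope": it.slope, "extra": it.context}
            for it in self.planted_interactions
        ]
        return pd.DataFrame(rows, columns=["kind", "feature_id", "variant_id", "slope", "extra"])


@dataclass
class GwasSummary:
    """Per-variant GWAS summary statistics for one trait/cohort."""

    table: pd.DataFrame  # variant_id, chrom, pos, z, n, n_cases, n_controls
    trait: str = "trait"

    def __post_init__(self) -> None:
        req = {"variant_id", "chrom", "pos", "z", "n"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"GwasSummary missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.table["z"].to_numpy(dtype=float))):
            raise ValueError("non-finite z in GWAS summary")
        if (self.table["n"] <= 0).any():
            raise ValueError("non-positive n in GWAS summary")

    def pvalues(self) -> np.ndarray:
        from scipy import stats

        return 2.0 * stats.norm.sf(np.abs(self.table["z"].to_numpy(dtype=float)))


@dataclass
class AnnotationSet:
    """Labeled interval tracks (chromatin states) and TAD tiling."""

    states: pd.DataFrame  # chrom, start, end, state
    tads: pd.DataFrame  # chrom, start, end, tad_id
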