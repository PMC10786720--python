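import numpy as np
import pandas as pd
import pytest

from qtlatlas import simdata
from qtlatlas.datatypes import GenotypeMatrix, PhenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig(
        n_samples=150,
        n_variants=300,
        n_features_per_kind={"gene": 20, "intron": 10},
        n_planted_qtl=5,
        effect_size_dist=("fixed", 1.0),
        breed_drift=0.2,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simdata.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_genotypes, small_config):
    return simdata.simulate_molecular_phenotypes(small_genotypes, small_config)


@pytest.fixture(scope="session")
def dense_ld_genotypes():
    """One short chromosome with strong LD, for coloc/HEIDI/fine-mapping."""
    cfg = simdata.SimConfig(
        n_samples=400, n_variants=60, seed=5, ld_decay=400_000, n_chroms=1, chrom_length=2_000_000
    )
    return simdata.simulate_genotypes(cfg)


def manual_genotypes(dosages: np.ndarray, positions=None, chrom="chr1") -> GenotypeMatrix:
    """Hand-built GenotypeMatrix for closed-form checks."""
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {
            "variant_id": [f"{chrom}:{p}:A:G" for p in positions],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"S{i}" for i in range(n)], "breed": "b0", "ancestry": 0.5}
    )
    return GenotypeMatrix(dosages=dosages.astype(np.int8), variants=variants, samples=samples)


def manual_phenotypes(values: np.ndarray, tss=None, chrom="chr1", kind="gene") -> PhenotypeMatrix:
    f, n = values.shape
    if tss is None:
        tss = np.full(f, 1000)
    features = pd.DataFrame(
        {
            "feature_id": [f"F{i}" for i in range(f)],
            "chrom": chrom,
            "start": np.asarray(tss) - 1,
            "end": np.asarray(tss) + 999,
            "tss": tss,
            "strand": "+",
            "kind": kind,
            "group_id": [f"F{i}" for i in range(f)],
        }
    )
    return PhenotypeMatrix(
        values=values.astype(float), features=features, sample_ids=[f"S{i}" for i in range(n)]
    )
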