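"""Count-scale molecular phenotypes with planted cis effects and confounders."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import (
    ConfigurationError,
    GenotypeMatrix,
    PhenotypeMatrix,
    PlantedQtl,
    SimTruth,
)
from .config import SimConfig

CIS_WINDOW = 1_000_000
_LN2 = np.log(2.0)


def _place_features(
    genotypes: GenotypeMatrix, n_features: int, rng: np.random.Generator, kind: str, prefix: str
) -> pd.DataFrame:
    """Feature intervals placed so every feature has cis variants in range."""
    vpos = genotypes.variants["pos"].to_numpy()
    vchrom = genotypes.variants["chrom"].to_numpy()
    anchor = rng.integers(0, genotypes.n_variants, size=n_features)
    tss = np.maximum(vpos[anchor] + rng.integers(-200_000, 200_000, size=n_features), 1)
    strand = np.where(rng.random(n_features) < 0.5, "+", "-")
    length = rng.integers(1_000, 50_000, size=n_features)
    start = np.where(strand == "+", tss - 1, np.maximum(tss - length, 0))
    end = start + length
    return pd.DataFrame(
        {
            "feature_id": [f"{prefix}{i:05d}" for i in range(n_features)],
            "chrom": vchrom[anchor],
            "start": start,
            "end": end,
            "tss": tss,
            "strand": strand,
            "kind": kind,
            "group_id": [f"{prefix}{i:05d}" for i in range(n_features)],
        }
    )


def _cis_variant_indices(genotypes: GenotypeMatrix, chrom: str, tss: int) -> np.ndarray:
    v = genotypes.variants
    mask = (v["chrom"] == chrom) & (np.abs(v["pos"] - tss) <= CIS_WINDOW)
    return np.where(mask.to_numpy())[0]


def _pick_planted(
    genotypes: GenotypeMatrix,
    features: pd.DataFrame,
    n_planted: int,
    slopes: np.ndarray,
    rng: np.random.Generator,
) -> list[PlantedQtl]:
    planted = []
    order = rng.permutation(len(features))[:n_planted]
    for k, fi in enumerate(order):
        row = features.iloc[fi]
        cis = _cis_variant_indices(genotypes, row["chrom"], int(row["tss"]))
        if cis.size == 0:
            raise ConfigurationError(f"feature {row['feature_id']} has no cis variants")
        common = cis[genotypes.maf()[cis] >= 0.25]  # prefer well-powered variants
        vi = int(rng.choice(common if common.size else cis))
        if genotypes.maf()[vi] == 0:
            raise ConfigurationError("planted effect requested on a monomorphic variant")
        planted.append(
            PlantedQtl(
                feature_id=row["feature_id"],
                variant_id=genotypes.variant_ids[vi],
                slope=float(slopes[k]),
            )
        )
    return planted


def simulate_molecular_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    *,
    kind: str = "gene",
    planted: list[PlantedQtl] | None = None,
) -> tuple[PhenotypeMatrix, SimTruth]:
    """Log-normal-Poisson counts with planted per-allele log2 slopes.

    log-rate = baseline + ln(2) * slope * dosage + loadings @ hidden factors
    + N(0, noise_sd); rates are scaled to per-sample library sizes and
    Poisson-sampled, so an OLS of log2 counts on dosage recovers the slope.
    """
    rng = config.rng(stream=2)
    n_features = int(config.n_features_per_kind.get(kind, 50))
    features = _place_features(genotypes, n_features, rng, kind, prefix=kind[0].upper())

    if planted is None:
        slopes = config.draw_effects(config.n_planted_qtl, rng)
        planted = _pick_planted(genotypes, features, config.n_planted_qtl, slopes, rng)
    else:
        vids = {v: i for i, v in enumerate(genotypes.variant_ids)}
        for q in planted:
            if q.variant_id not in vids:
                raise ConfigurationError(f"planted variant {q.variant_id} not in genotypes")
            if genotypes.maf()[vids[q.variant_id]] == 0:
                raise ConfigurationError("planted effect requested on a monomorphic variant")

    n = genotypes.n_samples
    baseline = rng.normal(5.0, 1.0, size=n_features)
    log_mu = np.tile(baseline[:, None], (1, n))

    vid_index = {v: i for i, v in enumerate(genotypes.variant_ids)}
    fid_index = {f: i for i, f in enumerate(features["feature_id"])}
    for q in planted:
        dos = genotypes.dosages[:, vid_index[q.variant_id]].astype(float)
        log_mu[fid_index[q.feature_id]] += _LN2 * q.slope * dos

    factors = None
    if config.n_hidden_factors > 0:
        factors = rng.standard_normal((config.n_hidden_factors, n))
        # factor 1 partially tracks ancestry so it confounds the genotype scan
        w = config.factor_structure_weight
        anc = genotypes.samples["ancestry"].to_numpy(dtype=float)
        if anc.std() > 0 and w > 0:
            anc_z = (anc - anc.mean()) / anc.std()
            factors[0] = w * anc_z + np.sqrt(1.0 - w**2) * factors[0]
        loadings = rng.normal(0.0, config.factor_sd, size=(n_features, config.n_hidden_factors))
        log_mu += loadings @ factors

    # noise_sd is on the log2 scale, matching the planted slopes
    log_mu += _LN2 * rng.normal(0.0, config.noise_sd, size=(n_features, n))
    mu = np.exp(log_mu)
    lib = config.mean_library_size * np.exp(rng.normal(0.0, 0.2, size=n))
    # constant scale (not the per-sample feature sum) keeps log-scale slopes intact
    scale = float(np.exp(baseline).sum())
    rate = mu / scale * lib[None, :]
    counts = rng.poisson(rate).astype(float)

    pheno = PhenotypeMatrix(values=counts, features=features, sample_ids=genotypes.sample_ids)
    truth = SimTruth(planted_qtl=list(planted), planted_factors=factors)
    truth.validate_against(genotypes, pheno)
    return pheno, truth


def simulate_intron_clusters(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    *,
    n_clusters: int | None = None,
    introns_per_cluster: int = 3,
    planted: list[PlantedQtl] | None = None,
    mean_cluster_total: float = 100.0,
) -> tuple[PhenotypeMatrix, SimTruth]:
    """Intron-cluster counts: multinomial splits with planted logit shifts.

    A planted sQTL with slope s shifts the first intron's log-odds within its
    cluster by s per alternative allele; cluster totals are log-normal-Poisson.
    """
    if introns_per_cluster < 2:
        raise ConfigurationError("clusters must have >= 2 introns")
    rng = config.rng(stream=3)
    if n_clusters is None:
        n_clusters = int(config.n_features_per_kind.get("intron", 20))
    genes = _place_features(genotypes, n_clusters, rng, "gene", prefix="SG")

    n = genotypes.n_samples
    vid_index = {v: i for i, v in enumerate(genotypes.variant_ids)}

    if planted is None:
        slopes = config.draw_effects(config.n_planted_qtl, rng)
        chosen = rng.permutation(n_clusters)[: config.n_planted_qtl]
        planted = []
        for k, ci in enumerate(chosen):
            row = genes.iloc[ci]
            cis = _cis_variant_indices(genotypes, row["chrom"], int(row["tss"]))
            if cis.size == 0:
                raise ConfigurationError("cluster gene has no cis variants")
            common = cis[genotypes.maf()[cis] >= 0.25]
            vi = int(rng.choice(common if common.size else cis))
            planted.append(
                PlantedQtl(
                    feature_id=f"{row['feature_id']}:clu{ci}:in0",
                    variant_id=genotypes.variant_ids[vi],
                    slope=float(slopes[k]),
                )
            )

    planted_by_cluster: dict[int, PlantedQtl] = {}
    for q in planted:
        ci = int(q.feature_id.split(":clu")[1].split(":")[0])
        planted_by_cluster[ci] = q

    rows = []
    values = []
    for ci in range(n_clusters):
        g = genes.iloc[ci]
        k = introns_per_cluster
        base_logits = rng.normal(0.0, 0.7, size=k)
        logits = np.tile(base_logits[:, None], (1, n))
        if ci in planted_by_cluster:
            q = planted_by_cluster[ci]
            dos = genotypes.dosages[:, vid_index[q.variant_id]].astype(float)
            logits[0] += q.slope * dos
        probs = np.exp(logits)
        probs /= probs.sum(axis=0, keepdims=True)
        totals = rng.poisson(mean_cluster_total * np.exp(rng.normal(0.0, 0.3, size=n)))
        counts = np.empty((k, n))
        for s in range(n):
            counts[:, s] = rng.multinomial(totals[s], probs[:, s])
        values.append(counts)
        istart = np.sort(rng.integers(int(g["start"]), int(g["end"]) + k + 1, size=k))
        for j in range(k):
            rows.append(
                {
                    "feature_id": f"{g['feature_id']}:clu{ci}:in{j}",
                    "chrom": g["chrom"],
                    "start": int(istart[j]),
                    "end": int(istart[j]) + 500,
                    "tss": int(g["tss"]),
                    "strand": g["strand"],
                    "kind": "intron",
                    "group_id": f"clu{ci}",
                    "gene_id": g["feature_id"],
                }
            )
    features = pd.DataFrame(rows)
    pheno = PhenotypeMatrix(
        values=np.vstack(values), features=features, sample_ids=genotypes.sample_ids
    )
    truth = SimTruth(planted_qtl=list(planted))
    truth.validate_against(genotypes, pheno)
    return pheno, truth
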