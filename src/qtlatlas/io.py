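"""Readers and writers for the plain-text interchange formats.

Genotypes travel as VCF (GT fields, 1-based positions), phenotypes as
tab-separated BED-like matrices (0-based half-open intervals; columns chrom,
start, end, feature_id, group_id, strand, tss, kind, then one column per
sample), covariates / GWAS summaries / truth ledgers as TSV.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AnnotationSet, CovariateMatrix, GenotypeMatrix, GwasSummary, PhenotypeMatrix

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}
_GT_PARSE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1, "1/1": 2, "1|1": 2}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    samples = genotypes.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        D = genotypes.dosages
        for j, (_, v) in enumerate(genotypes.variants.iterrows()):
            gts = "\t".join(_GT_CODE[int(d)] for d in D[:, j])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t{v['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path, sample_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a diploid biallelic VCF (uncompressed text) into dosages."""
    path = Path(path)
    samples: list[str] = []
    rows = []
    dosage_rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            dos = [_GT_PARSE[p.split(":")[gt_i]] for p in parts[9:]]
            rows.append({"variant_id": vid, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
            dosage_rows.append(dos)
    variants = pd.DataFrame(rows)
    dosages = np.asarray(dosage_rows, dtype=np.int8).T
    if sample_meta is None:
        sample_meta = pd.DataFrame({"sample_id": samples, "breed": "unknown", "ancestry": np.nan})
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=sample_meta)


_BED_META_COLS = ["chrom", "start", "end", "feature_id", "group_id", "strand", "tss", "kind"]


def write_phenotype_bed(pheno: PhenotypeMatrix, path: str | Path) -> None:
    meta = pheno.features.copy()
    for col in _BED_META_COLS:
        if col not in meta.columns:
            meta[col] = ""
    values = pd.DataFrame(pheno.values, columns=pheno.sample_ids, index=meta.index)
    df = pd.concat([meta[_BED_META_COLS], values], axis=1)
    df = df.rename(columns={"chrom": "#chrom"})
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_bed(path: str | Path) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"#chrom": "chrom"})
    sample_cols = [c for c in df.columns if c not in _BED_META_COLS]
    features = df[_BED_META_COLS].copy()
    values = df[sample_cols].to_numpy(dtype=float)
    return PhenotypeMatrix(values=values, features=features, sample_ids=sample_cols)


def write_covariates(cov: CovariateMatrix, path: str | Path) -> None:
    cov.values.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates(path: str | Path) -> CovariateMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CovariateMatrix(values=df, kinds={c: "known" for c in df.columns})


def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    t = gwas.table.copy()
    t["trait"] = gwas.trait
    t.to_csv(path, sep="\t", index=False)


def read_gwas(path: str | Path) -> GwasSummary:
    t = pd.read_csv(path, sep="\t")
    trait = str(t["trait"].iloc[0]) if "trait" in t.columns and len(t) else "trait"
    return GwasSummary(table=t.drop(columns=["trait"], errors="ignore"), trait=trait)


def write_annotations(ann: AnnotationSet, state_path: str | Path, tad_path: str | Path) -> None:
    ann.states.to_csv(state_path, sep="\t", index=False, header=False)
    ann.tads.to_csv(tad_path, sep="\t", index=False, header=False)


def read_bed_intervals(path: str | Path, names: list[str]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=names)
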