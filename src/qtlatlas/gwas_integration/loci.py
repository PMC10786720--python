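"""Meta-GWAS and locus definition."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..datatypes import GwasSummary

logger = logging.getLogger(__name__)


def meta_gwas(cohorts: list[GwasSummary]) -> GwasSummary:
    """Sample-size-weighted z meta-analysis over cohorts sharing variant ids.

    z_meta = sum(sqrt(n_i) z_i) / sqrt(sum n_i); variants are inner-joined on
    id (the chrom:pos:ref:alt convention enforces allele alignment).
    """
    if len(cohorts) == 0:
        raise ValueError("no cohorts")
    if len(cohorts) == 1:
        return cohorts[0]
    common = set(cohorts[0].table["variant_id"])
    for c in cohorts[1:]:
        common &= set(c.table["variant_id"])
    dropped = sum(len(c.table) for c in cohorts) - len(cohorts) * len(common)
    if dropped:
        logger.info("meta_gwas: %d cohort rows outside the shared variant set", dropped)
    base = cohorts[0].table[cohorts[0].table["variant_id"].isin(common)].copy()
    base = base.sort_values("variant_id").reset_index(drop=True)
    num = np.zeros(len(base))
    n_tot = np.zeros(len(base))
    for c in cohorts:
        t = c.table[c.table["variant_id"].isin(common)].sort_values("variant_id")
        n = t["n"].to_numpy(dtype=float)
        num += np.sqrt(n) * t["z"].to_numpy(dtype=float)
        n_tot += n
    out = base[["variant_id", "chrom", "pos"]].copy()
    out["z"] = num / np.sqrt(n_tot)
    out["n"] = n_tot
    out["n_cases"] = np.nan
    out["n_controls"] = np.nan
    return GwasSummary(table=out.sort_values(["chrom", "pos"]).reset_index(drop=True),
                       trait=cohorts[0].trait)


@dataclass
class Locus:
    trait: str
    lead_variant: str
    chrom: str
    start: int
    end: int
    lead_pval: float
    members: list


def define_loci(
    gwas: GwasSummary, p_threshold: float = 1e-5, merge_bp: int = 1_000_000
) -> list[Locus]:
    """Greedy distance clumping of significant variants into loci."""
    t = gwas.table.copy()
    t["pval"] = 2.0 * stats.norm.sf(np.abs(t["z"].to_numpy(dtype=float)))
    sig = t[t["pval"] < p_threshold].copy()
    loci: list[Locus] = []
    while len(sig):
        lead = sig.loc[sig["pval"].idxmin()]
        near = sig[(sig["chrom"] == lead["chrom"]) & (np.abs(sig["pos"] - lead["pos"]) <= merge_bp)]
        loci.append(
            Locus(
                trait=gwas.trait,
                lead_variant=str(lead["variant_id"]),
                chrom=str(lead["chrom"]),
                start=int(near["pos"].min()),
                end=int(near["pos"].max()),
                lead_pval=float(lead["pval"]),
                members=list(near["variant_id"]),
            )
        )
        sig = sig.drop(near.index)
    return loci


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"trait": l.trait, "lead_variant": l.lead_variant, "chrom": l.chrom,
             "start": l.start, "end": l.end, "lead_pval": l.lead_pval,
             "n_members": len(l.members)}
            for l in loci
        ]
    )
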