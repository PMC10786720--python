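"""Colocalization of a QTL and a GWAS signal via approximate Bayes factors.

Standard five-hypothesis posterior under a single causal variant per trait:
H0 no signal, H1/H2 one trait only, H3 two distinct causals, H4 one shared
causal. RCP is reported as PP4.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ..cis_qtl import wakefield_abf


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    rcp: float
    per_variant: np.ndarray  # colocalization probability per variant
    degenerate: bool = False

    @property
    def pp0(self):
        return float(self.pp[0])

    @property
    def pp4(self):
        return float(self.pp[4])


def colocalize(
    z_gwas: np.ndarray,
    z_qtl: np.ndarray,
    ld: np.ndarray | None = None,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_gwas: float = 0.15,
    prior_sd_qtl: float = 0.15,
    se_gwas: np.ndarray | float = 1.0,
    se_qtl: np.ndarray | float = 1.0,
) -> ColocResult:
    """ABF colocalization of two association signals over aligned variants."""
    z1 = np.asarray(z_gwas, dtype=float)
    z2 = np.asarray(z_qtl, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("z vectors must align")
    m = len(z1)
    degenerate = m < 2
    se1 = np.broadcast_to(np.asarray(se_gwas, dtype=float), z1.shape)
    se2 = np.broadcast_to(np.asarray(se_qtl, dtype=float), z2.shape)
    l1 = wakefield_abf(z1, se1, prior_sd_gwas)
    l2 = wakefield_abf(z2, se2, prior_sd_qtl)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    # sum over i != j of exp(l1_i + l2_j) = exp(lsum1 + lsum2) - exp(lsum12)
    both = lsum1 + lsum2
    if both > lsum12:
        lsum_distinct = both + np.log1p(-np.exp(lsum12 - both))
    else:
        lsum_distinct = -np.inf

    lh = np.array(
        [
            0.0,
            np.log(p1) + lsum1,
            np.log(p2) + lsum2,
            (np.log(p1) + np.log(p2) + lsum_distinct) if m > 1 else -np.inf,
            np.log(p12) + lsum12,
        ]
    )
    lh -= logsumexp(lh)
    pp = np.exp(lh)
    w = l1 + l2
    w = np.exp(w - logsumexp(w))
    return ColocResult(pp=pp, rcp=float(pp[4]), per_variant=w * pp[4], degenerate=degenerate)
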