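"""Interval-annotation simulation: state tracks with exact coverage, TAD tilings."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import AnnotationSet, ConfigurationError


def _coverage_intervals(
    length: int, coverage: float, n_intervals: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Non-overlapping intervals whose total length is exactly round(coverage * length)."""
    covered = int(round(coverage * length))
    if covered <= 0:
        return []
    n_intervals = max(1, min(n_intervals, covered))
    # random positive partition of covered into interval lengths, and of the
    # remainder into n_intervals + 1 gap lengths
    ilen = rng.multinomial(covered - n_intervals, rng.dirichlet(np.ones(n_intervals))) + 1
    gap_total = length - covered
    gaps = rng.multinomial(gap_total, rng.dirichlet(np.ones(n_intervals + 1)))
    out = []
    cursor = 0
    for k in range(n_intervals):
        cursor += int(gaps[k])
        out.append((cursor, cursor + int(ilen[k])))
        cursor += int(ilen[k])
    return out


def simulate_annotations(
    chrom_lengths: dict,
    state_spec: dict,
    tad_spec: dict,
    seed: int,
) -> AnnotationSet:
    """Generate labeled state tracks and a TAD tiling per chromosome.

    state_spec maps state name -> {"coverage": fraction, "n_intervals": count};
    tad_spec has {"mean_size": bp}. TADs tile each chromosome exactly.
    """
    for c, L in chrom_lengths.items():
        if L <= 0:
            raise ConfigurationError(f"non-positive length for {c}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))

    state_rows = []
    for state, spec in state_spec.items():
        cov = float(spec["coverage"])
        if not (0.0 <= cov <= 1.0):
            raise ConfigurationError(f"coverage for {state} outside [0, 1]")
        n_iv = int(spec.get("n_intervals", 50))
        for chrom, L in chrom_lengths.items():
            for s, e in _coverage_intervals(int(L), cov, n_iv, rng):
                state_rows.append({"chrom": chrom, "start": s, "end": e, "state": state})

    mean_size = int(tad_spec.get("mean_size", 1_000_000))
    if mean_size <= 0:
        raise ConfigurationError("TAD mean_size must be positive")
    tad_rows = []
    tid = 0
    for chrom, L in chrom_lengths.items():
        n_tads = max(1, int(round(L / mean_size)))
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_tads - 1, replace=False)) if n_tads > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [L]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            tad_rows.append({"chrom": chrom, "start": int(s), "end": int(e), "tad_id": f"tad{tid}"})
            tid += 1

    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "tad_id"])
    return AnnotationSet(states=states, tads=tads)
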