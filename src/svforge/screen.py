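"""Two-condition breed-differential genotype screen on founders, and
position-based candidate genotyping in offspring.

A locus passes the screen when one diploid genotype class can be assigned to
one breed and the remaining two classes to the other breed such that the
class frequency exceeds 80% in the first breed (>= 5 of 6 founders at the
default sizes) and the complement-class frequency exceeds 50% in the second
(>= 8 of 15).  Both breed-direction assignments are tested.  Thresholds use
nominal breed sizes; missing founder genotypes count toward neither side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, MergedLocus, SampleInfo

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    freq_a: float = 0.80
    freq_b: float = 0.50

    def __post_init__(self) -> None:
        for f in (self.freq_a, self.freq_b):
            if not (0 < f <= 1):
                raise ValueError("screen frequencies must be in (0, 1]")


def minimal_pass_count(n: int, freq: float) -> int:
    """Smallest integer count strictly exceeding freq * n."""
    return math.floor(freq * n) + 1


def screen_differential_loci(gm: GenotypeMatrix,
                             breed_a_samples: list[str],
                             breed_b_samples: list[str],
                             config: ScreenConfig | None = None):
    """Return (candidate locus indices, per-locus detail table).

    The detail table records, for each passing locus, which genotype class
    was breed-specific and in which breed direction.
    """
    config = config or ScreenConfig()
    ids = gm.sample_ids
    if set(breed_a_samples) & set(breed_b_samples):
        raise ValueError("breed sample sets must be disjoint")
    try:
        ia = [ids.index(s) for s in breed_a_samples]
        ib = [ids.index(s) for s in breed_b_samples]
    except ValueError as e:
        raise ValueError(f"founder set smaller than configured: {e}") from e

    need_a = minimal_pass_count(len(ia), config.freq_a)
    need_b = minimal_pass_count(len(ib), config.freq_b)

    rows = []
    hits = []
    locus_ids = gm.locus_ids
    for li in range(gm.n_loci):
        da = gm.dosages[li, ia]
        db = gm.dosages[li, ib]
        counts_a = {g: int(np.sum(da == g)) for g in (0.0, 1.0, 2.0)}
        counts_b = {g: int(np.sum(db == g)) for g in (0.0, 1.0, 2.0)}
        passed = None
        for g in (0.0, 1.0, 2.0):
            comp = [x for x in (0.0, 1.0, 2.0) if x != g]
            # direction 1: class g specific to breed A
            if (counts_a[g] >= need_a and
                    sum(counts_b[x] for x in comp) >= need_b):
                passed = ("A", g)
                break
            # direction 2: class g specific to breed B
            if (counts_b[g] >= need_b and
                    sum(counts_a[x] for x in comp) >= need_a):
                passed = ("B", g)
                break
        if passed:
            hits.append(li)
            rows.append({"locus_idx": li, "locus_id": locus_ids[li],
                         "direction": passed[0], "genotype_class": passed[1]})
    return np.array(hits, dtype=int), pd.DataFrame(
        rows, columns=["locus_idx", "locus_id", "direction", "genotype_class"])


@dataclass(frozen=True)
class OffspringEvidence:
    """One per-sample genotype observation keyed by genomic position."""

    sample: str
    chrom: str
    pos: int
    svtype: str
    dosage: float
    confidence: float = 0.0


def genotype_candidates_in_offspring(candidates: list[MergedLocus],
                                     evidence: list[OffspringEvidence],
                                     offspring: list[SampleInfo],
                                     tolerance: int = 1000):
    """Build a candidates x offspring dosage matrix from positional evidence.

    Evidence matches a candidate when chromosome and SV type agree and the
    position is within ``tolerance`` of the candidate's representative start.
    Unmatched cells are missing; duplicate evidence for one (locus, sample)
    keeps the highest-confidence record.  Returns the GenotypeMatrix and a
    report with the overall genotyping success rate (percent, 2 decimals).
    """
    sample_ids = [s.sample for s in offspring]
    sample_idx = {s: i for i, s in enumerate(sample_ids)}
    by_key: dict[tuple[str, str, str], list[OffspringEvidence]] = {}
    for ev in evidence:
        if ev.sample in sample_idx:
            by_key.setdefault((ev.sample, ev.chrom, ev.svtype), []).append(ev)
    for grp in by_key.values():
        grp.sort(key=lambda e: e.pos)

    dosages = np.full((len(candidates), len(offspring)), np.nan)
    dup_count = 0
    for ci, cand in enumerate(candidates):
        for s, si in sample_idx.items():
            grp = by_key.get((s, cand.chrom, cand.svtype))
            if not grp:
                continue
            matches = [e for e in grp
                       if abs(e.pos - cand.rep_start) <= tolerance]
            if not matches:
                continue
            if len(matches) > 1:
                dup_count += 1
                matches.sort(key=lambda e: e.confidence, reverse=True)
            dosages[ci, si] = matches[0].dosage
    if dup_count:
        log.info("kept highest-confidence record for %d duplicated "
                 "(locus, sample) cells", dup_count)
    total = dosages.size
    rate = 100.0 * (total - int(np.isnan(dosages).sum())) / total if total else 0.0
    report = {"n_cells": total,
              "n_genotyped": total - int(np.isnan(dosages).sum()),
              "success_rate_pct": round(rate, 2)}
    return GenotypeMatrix(candidates, offspring, dosages), report
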