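"""Locus-level quality/length filters and genotype-matrix filters.

DEL/DUP/INV loci must have QUAL strictly above 200 and a length between 50 bp
and 1 Mb; MEI loci must carry the PASS filter token.  Genotype matrices are
filtered in a fixed order: samples by call rate, then loci by call rate, then
loci by minor allele frequency (computed after sample removal, over
non-missing genotypes only).  All thresholds are strict ('>').
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GenotypeMatrix, MergedLocus


@dataclass(frozen=True)
class QcConfig:
    min_qual: float = 200.0
    mei_filter_token: str = "PASS"
    min_len: int = 50
    max_len: int = 1_000_000
    sample_call_rate: float = 0.90
    locus_call_rate: float = 0.90
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.min_len < self.max_len):
            raise ValueError("need 0 < min_len < max_len")
        for v in (self.sample_call_rate, self.locus_call_rate, self.min_maf):
            if not (0 < v < 1):
                raise ValueError("rates and MAF must be in (0, 1)")


def filter_loci(loci: list[MergedLocus], config: QcConfig | None = None):
    """Split loci into (kept, removed) with per-locus removal reasons.

    Returns ``kept`` (list of loci) and ``removed`` (list of
    (locus, [reasons]) pairs); reasons are exhaustive per locus.
    """
    config = config or QcConfig()
    kept, removed = [], []
    for locus in loci:
        reasons = []
        if locus.svtype == "MEI":
            if locus.filter_status != config.mei_filter_token:
                reasons.append("mei-filter")
        else:
            if locus.qual is None:
                reasons.append("no-qual")
            elif not locus.qual > config.min_qual:
                reasons.append("low-qual")
        if locus.length < config.min_len:
            reasons.append("under-length")
        if locus.length > config.max_len:
            reasons.append("over-length")
        if reasons:
            removed.append((locus, reasons))
        else:
            kept.append(locus)
    return kept, removed


def filter_genotype_matrix(gm: GenotypeMatrix, config: QcConfig | None = None):
    """Apply sample call-rate, locus call-rate and MAF filters, in that order.

    Returns the filtered matrix and a stage report dict.
    """
    config = config or QcConfig()
    report = {"n_samples_in": gm.n_samples, "n_loci_in": gm.n_loci}

    keep_s = np.where(gm.sample_call_rate() > config.sample_call_rate)[0]
    report["samples_dropped_call_rate"] = gm.n_samples - len(keep_s)
    gm = gm.subset(sample_idx=keep_s)

    keep_l = np.where(gm.locus_call_rate() > config.locus_call_rate)[0]
    report["loci_dropped_call_rate"] = gm.n_loci - len(keep_l)
    gm = gm.subset(locus_idx=keep_l)

    keep_m = np.where(gm.maf() > config.min_maf)[0]
    report["loci_dropped_maf"] = gm.n_loci - len(keep_m)
    gm = gm.subset(locus_idx=keep_m)

    report["n_samples_out"] = gm.n_samples
    report["n_loci_out"] = gm.n_loci
    if gm.n_loci == 0:
        raise ValueError("no loci survive genotype-matrix filtering")
    return gm, report
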