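"""Core domain containers for the SV analysis pipeline.

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted at the I/O boundary.  A structural variant (SV) is a deletion (DEL),
duplication (DUP), inversion (INV) or mobile-element insertion (MEI; ERV, LINE
or SINE family).  MEIs are represented as point insertions: ``end == start``
and ``length`` is the inserted element length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SV_TYPES = ("DEL", "DUP", "INV", "MEI")
MEI_FAMILIES = ("ERV", "LINE", "SINE")

MISSING = np.nan


@dataclass(frozen=True)
class SVRecord:
    """A single SV call from one caller on one sample — the atom of merging.

    For DEL/DUP/INV the length is recomputed from the breakpoints as
    ``end - start + 1``; for MEI it is the inserted element length.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    qual: float | None = None
    filter_status: str = "PASS"
    orientation: str = "."
    mei_family: str = "none"
    caller: str = "unknown"
    sample: str = "unknown"

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.svtype == "MEI":
            if self.end != self.start:
                raise ValueError("MEI records are point insertions (end == start)")
            if self.mei_family not in MEI_FAMILIES:
                raise ValueError(f"MEI needs a family in {MEI_FAMILIES}")
        else:
            if self.end < self.start:
                raise ValueError(f"end < start for {self.svtype} record")
            if self.mei_family != "none":
                raise ValueError("mei_family must be 'none' for non-MEI records")
        if self.length < 0:
            raise ValueError("negative length")

    @classmethod
    def from_breakpoints(cls, chrom: str, start: int, end: int, svtype: str,
                         mei_length: int | None = None, **kw) -> "SVRecord":
        """Build a record with the canonical length convention."""
        if svtype == "MEI":
            if mei_length is None:
                raise ValueError("MEI needs mei_length")
            return cls(chrom, start, start, svtype, mei_length, **kw)
        return cls(chrom, start, end, svtype, end - start + 1, **kw)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class MergedLocus:
    """A population-level SV locus aggregating member calls.

    Representative breakpoints are the lower medians of the member
    breakpoints, which is deterministic and robust to outlying callers.
    """

    locus_id: str
    chrom: str
    rep_start: int
    rep_end: int
    svtype: str
    length: int
    members: list[SVRecord] = field(default_factory=list)
    mei_family: str = "none"

    def __post_init__(self) -> None:
        for m in self.members:
            if m.chrom != self.chrom or m.svtype != self.svtype:
                raise ValueError("members must share chrom and svtype")

    @property
    def caller_support(self) -> set[str]:
        return {m.caller for m in self.members}

    @property
    def sample_support(self) -> set[str]:
        return {m.sample for m in self.members}

    @property
    def qual(self) -> float | None:
        """Locus quality = max over member-call quals (union merge keeps the
        best evidence)."""
        quals = [m.qual for m in self.members if m.qual is not None]
        return max(quals) if quals else None

    @property
    def filter_status(self) -> str:
        if any(m.filter_status == "PASS" for m in self.members):
            return "PASS"
        return self.members[0].filter_status if self.members else "PASS"

    @classmethod
    def from_members(cls, locus_id: str, members: Sequence[SVRecord]) -> "MergedLocus":
        if not members:
            raise ValueError("a locus needs at least one member")
        starts = sorted(m.start for m in members)
        ends = sorted(m.end for m in members)
        rep_start = lower_median(starts)
        rep_end = lower_median(ends)
        svtype = members[0].svtype
        if svtype == "MEI":
            rep_end = rep_start
            length = lower_median(sorted(m.length for m in members))
            family = members[0].mei_family
        else:
            length = rep_end - rep_start + 1
            family = "none"
        return cls(locus_id, members[0].chrom, rep_start, rep_end, svtype,
                   length, list(members), family)


def lower_median(sorted_values: Sequence[int]) -> int:
    """Lower median of a pre-sorted sequence (deterministic tie-break)."""
    return sorted_values[(len(sorted_values) - 1) // 2]


@dataclass(frozen=True)
class SampleInfo:
    """Sample metadata: breed, generation (F0 founder or F2 offspring), and
    the sex/slaughter-batch covariates used as GWAS fixed effects."""

    sample: str
    breed: str
    generation: str
    sex: str | None = None
    batch: str | None = None
    purebred: bool = False

    def __post_init__(self) -> None:
        if self.generation not in ("F0", "F2"):
            raise ValueError("generation must be F0 or F2")
        if self.generation == "F2" and (self.sex is None or self.batch is None):
            raise ValueError(f"F2 sample {self.sample} needs sex and batch")


class GenotypeMatrix:
    """Loci x samples dosage matrix with values in {0, 1, 2, NaN}.

    Dosage counts alternate (SV-carrying) alleles; NaN marks a missing call.
    """

    def __init__(self, loci: list, samples: list[SampleInfo], dosages: np.ndarray):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(loci), len(samples)):
            raise ValueError(
                f"dosage shape {dosages.shape} != ({len(loci)}, {len(samples)})")
        ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.loci = list(loci)
        self.samples = list(samples)
        self.dosages = dosages

    # -- basic geometry ----------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id if hasattr(l, "locus_id") else str(l)
                for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample for s in self.samples]

    # -- summaries ---------------------------------------------------------
    def sample_call_rate(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.ones(self.n_samples)
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def locus_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_loci)
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, locus_idx=None, sample_idx=None) -> "GenotypeMatrix":
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return GenotypeMatrix(
            [self.loci[i] for i in li],
            [self.samples[j] for j in si],
            self.dosages[np.ix_(li, si)],
        )

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the locus mean."""
        X = self.dosages.copy()
        with np.errstate(invalid="ignore"):
            means = np.nanmean(X, axis=1)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(X))
        X[idx] = means[idx[0]]
        return X


@dataclass
class Gene:
    """One gene with disjoint exon/UTR intervals; introns are derived as the
    span complement of exons and UTRs."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e in self.exons + self.utr5 + self.utr3:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"feature {s}-{e} outside span of gene {self.gene_id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        blocks = sorted(self.exons + self.utr5 + self.utr3)
        introns = []
        cursor = self.start
        for s, e in blocks:
            if s > cursor:
                introns.append((cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= self.end:
            introns.append((cursor, self.end))
        return introns


class GeneModel:
    """A collection of genes, indexed by chromosome."""

    def __init__(self, genes: Iterable[Gene] = ()):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            self.genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chroms(self) -> list[str]:
        return sorted({g.chrom for g in self.genes.values()})

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted((g for g in self.genes.values() if g.chrom == chrom),
                      key=lambda g: (g.start, g.end))


class PhenotypeTable:
    """Per-F2-sample continuous traits plus sex/batch covariate columns."""

    COVARIATES = ("sex", "batch")

    def __init__(self, df: pd.DataFrame):
        if "sample" in df.columns:
            df = df.set_index("sample")
        for c in self.COVARIATES:
            if c not in df.columns:
                raise ValueError(f"phenotype table needs a {c!r} column")
        self.df = df

    @property
    def traits(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.COVARIATES]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def trait_values(self, trait: str) -> np.ndarray:
        y = self.df[trait].to_numpy(dtype=float)
        if len(pd.unique(y[~np.isnan(y)])) < 2:
            raise ValueError(f"trait {trait!r} has fewer than 2 distinct values")
        return y
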