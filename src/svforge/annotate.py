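"""Positional annotation of SV loci against a gene model.

Each locus receives exactly one category with precedence
coverage > exon > UTR5 > UTR3 > intron > gene_upstream > gene_downstream >
intergenic, and one impact class from a fixed rule table.  DEL/DUP are
annotated by their full span; INV by their two breakpoints (an inversion's
interior is neither gained nor lost); MEI by the insertion point.
Upstream/downstream are strand-aware within a 1 kb flank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .types import GeneModel, MergedLocus

log = logging.getLogger(__name__)

CATEGORIES = ("coverage", "exon", "UTR5", "UTR3", "intron",
              "gene_upstream", "gene_downstream", "intergenic")
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass
class AnnotationResult:
    locus_id: str
    svtype: str
    category: str
    impact: str | None = None
    gene_ids: list[str] = field(default_factory=list)


class GeneIndex:
    """Interval index over gene spans for fast positional queries."""

    def __init__(self, model: GeneModel, flank: int = 1000):
        self.model = model
        self.flank = flank
        self.trees: dict[str, IntervalTree] = {}
        for chrom in model.chroms:
            tree = IntervalTree()
            for g in model.genes_on(chrom):
                # pad by flank so one query also finds up/downstream genes
                tree.addi(max(1, g.start - flank), g.end + flank + 1, g)
            self.trees[chrom] = tree

    def query(self, chrom: str, start: int, end: int):
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end + 1)]


def _overlaps(iv_list, s, e):
    return any(b >= s and a <= e for a, b in iv_list)


def _span_category(gene, s, e, flank):
    """Category of query interval [s, e] relative to one gene."""
    if s <= gene.end and e >= gene.start:          # overlaps gene body
        if s <= gene.start and e >= gene.end:
            return "coverage"
        if _overlaps(gene.exons, s, e):
            return "exon"
        if _overlaps(gene.utr5, s, e):
            return "UTR5"
        if _overlaps(gene.utr3, s, e):
            return "UTR3"
        return "intron"
    if gene.strand == "+":
        up = (max(1, gene.start - flank), gene.start - 1)
        down = (gene.end + 1, gene.end + flank)
    else:
        up = (gene.end + 1, gene.end + flank)
        down = (max(1, gene.start - flank), gene.start - 1)
    if s <= up[1] and e >= up[0]:
        return "gene_upstream"
    if s <= down[1] and e >= down[0]:
        return "gene_downstream"
    return "intergenic"


def locate_sv(locus: MergedLocus, index: GeneIndex) -> AnnotationResult:
    """Assign the positional category and overlapped genes for one locus."""
    flank = index.flank
    if locus.svtype in ("DEL", "DUP"):
        queries = [(locus.rep_start, locus.rep_end)]
    elif locus.svtype == "INV":
        queries = [(locus.rep_start, locus.rep_start),
                   (locus.rep_end, locus.rep_end)]
    else:                                          # MEI insertion point
        queries = [(locus.rep_start, locus.rep_start)]

    if locus.chrom not in index.trees:
        log.warning("locus %s on chromosome %s absent from gene model",
                    locus.locus_id, locus.chrom)
        return AnnotationResult(locus.locus_id, locus.svtype, "intergenic")

    best = "intergenic"
    genes: dict[str, str] = {}                     # gene_id -> its category
    for s, e in queries:
        for gene in index.query(locus.chrom, s, e):
            cat = _span_category(gene, s, e, flank)
            if cat == "intergenic":
                continue
            prev = genes.get(gene.gene_id)
            if prev is None or _RANK[cat] < _RANK[prev]:
                genes[gene.gene_id] = cat
            if _RANK[cat] < _RANK[best]:
                best = cat
    gene_ids = sorted(genes) if best != "intergenic" else []
    return AnnotationResult(locus.locus_id, locus.svtype, best, None, gene_ids)


def classify_effect(category: str, svtype: str) -> str:
    """Fixed impact rule table.

    exon/coverage -> HIGH; UTR -> MODERATE for copy-number types (DEL/DUP),
    LOW for balanced/insertion types (INV/MEI); everything else -> MODIFIER.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if category in ("exon", "coverage"):
        return "HIGH"
    if category in ("UTR5", "UTR3"):
        return "MODERATE" if svtype in ("DEL", "DUP") else "LOW"
    return "MODIFIER"


def annotate_loci(loci: list[MergedLocus], model: GeneModel,
                  flank: int = 1000) -> list[AnnotationResult]:
    index = GeneIndex(model, flank)
    results = []
    for locus in loci:
        res = locate_sv(locus, index)
        res.impact = classify_effect(res.category, locus.svtype)
        results.append(res)
    return results


def summarize_positions(annotations: list[AnnotationResult]) -> pd.DataFrame:
    """Per-type category fractions (each row sums to 1)."""
    if not annotations:
        return pd.DataFrame(columns=CATEGORIES)
    df = pd.DataFrame([(a.svtype, a.category) for a in annotations],
                      columns=["svtype", "category"])
    counts = df.groupby(["svtype", "category"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=CATEGORIES, fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
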