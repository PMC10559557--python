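"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (SVTYPE/END/SVLEN/MEINFO INFO keys, optional GT), GFF3 / BED12 gene
models, and TSV sample / phenotype tables.  Internal coordinates are 1-based
inclusive; BED is converted at this boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (Gene, GeneModel, GenotypeMatrix, MergedLocus,
                    PhenotypeTable, SampleInfo, SVRecord, SV_TYPES)

log = logging.getLogger(__name__)

_ALT = {"DEL": "<DEL>", "DUP": "<DUP>", "INV": "<INV>", "MEI": "<INS:ME>"}

_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=MEINFO,Number=4,Type=String,Description="Mobile element info: NAME,START,END,POLARITY">',
    '##INFO=<ID=ORIENT,Number=1,Type=String,Description="Breakpoint strand configuration">',
    '##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller">',
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Source sample">',
    '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers of a merged locus">',
    '##INFO=<ID=SAMPLES,Number=.,Type=String,Description="Supporting samples of a merged locus">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _chrom_key(chrom: str):
    """Natural chromosome order; falls back to lexicographic."""
    token = chrom.lstrip("chr")
    if token.isdigit():
        return (0, int(token), chrom)
    return (1, 0, chrom)


def read_sv_vcf(path, caller_label: str = "unknown",
                sample_label: str = "unknown") -> list[SVRecord]:
    """Read SV records from a VCF.

    Records lacking SVTYPE, or with an SVTYPE outside {DEL, DUP, INV, MEI},
    are skipped and counted in a warning.  CALLER/SAMPLE/ORIENT INFO keys, if
    present, override the supplied labels.  Lengths are recomputed from the
    breakpoints; disagreements with a caller-reported SVLEN are counted.
    """
    records: list[SVRecord] = []
    skipped = 0
    svlen_mismatch = 0
    for v in VCF(str(path)):
        svtype = v.INFO.get("SVTYPE")
        if svtype is None or svtype not in SV_TYPES:
            skipped += 1
            continue
        start = v.POS
        qual = None if v.QUAL is None else round(float(v.QUAL), 2)
        filt = v.FILTER or "PASS"
        orient = v.INFO.get("ORIENT") or "."
        caller = v.INFO.get("CALLER") or caller_label
        sample = v.INFO.get("SAMPLE") or sample_label
        reported_len = v.INFO.get("SVLEN")
        if svtype == "MEI":
            meinfo = v.INFO.get("MEINFO")
            if meinfo is None:
                skipped += 1
                continue
            parts = meinfo if isinstance(meinfo, (tuple, list)) else str(meinfo).split(",")
            family = str(parts[0])
            length = int(parts[2]) - int(parts[1]) + 1
            rec = SVRecord(v.CHROM, start, start, "MEI", length, qual, filt,
                           orient, family, caller, sample)
        else:
            end = int(v.INFO.get("END", v.end))
            length = end - start + 1
            rec = SVRecord(v.CHROM, start, end, svtype, length, qual, filt,
                           orient, "none", caller, sample)
        if reported_len is not None and abs(int(reported_len)) != rec.length:
            svlen_mismatch += 1
        records.append(rec)
    if skipped:
        log.warning("%s: skipped %d records without a usable SVTYPE", path, skipped)
    if svlen_mismatch:
        log.info("%s: %d records had SVLEN disagreeing with breakpoints "
                 "(breakpoint-derived length kept)", path, svlen_mismatch)
    return records


def _record_line(rec: SVRecord, idx: str) -> str:
    info = [f"SVTYPE={rec.svtype}", f"END={rec.end}", f"SVLEN={rec.length}"]
    if rec.svtype == "MEI":
        info.append(f"MEINFO={rec.mei_family},1,{rec.length},+")
    info += [f"ORIENT={rec.orientation}", f"CALLER={rec.caller}",
             f"SAMPLE={rec.sample}"]
    qual = "." if rec.qual is None else f"{rec.qual:.2f}"
    return "\t".join([rec.chrom, str(rec.start), idx, "N", _ALT[rec.svtype],
                      qual, rec.filter_status, ";".join(info)])


def _locus_line(locus: MergedLocus) -> str:
    info = [f"SVTYPE={locus.svtype}", f"END={locus.rep_end}",
            f"SVLEN={locus.length}"]
    if locus.svtype == "MEI":
        info.append(f"MEINFO={locus.mei_family},1,{locus.length},+")
    info += [f"CALLERS={','.join(sorted(locus.caller_support))}",
             f"SAMPLES={','.join(sorted(locus.sample_support))}"]
    qual = "." if locus.qual is None else f"{locus.qual:.2f}"
    return "\t".join([locus.chrom, str(locus.rep_start), locus.locus_id, "N",
                      _ALT[locus.svtype], qual, locus.filter_status,
                      ";".join(info)])


def write_sv_vcf(items, path, genotype_matrix: GenotypeMatrix | None = None) -> None:
    """Write SVRecords or MergedLoci as VCF 4.2, deterministically ordered by
    (chromosome, start, type).  With a genotype matrix, GT columns are added
    (0/0, 0/1, 1/1 or ./.)."""
    items = list(items)
    loci_mode = bool(items) and isinstance(items[0], MergedLocus)
    if loci_mode:
        key = lambda l: (_chrom_key(l.chrom), l.rep_start, l.svtype, l.locus_id)
    else:
        key = lambda r: (_chrom_key(r.chrom), r.start, r.svtype, r.end,
                         r.caller, r.sample)
    order = sorted(range(len(items)), key=lambda i: key(items[i]))

    lines = list(_HEADER)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    gt_rows = None
    if genotype_matrix is not None:
        if not loci_mode or genotype_matrix.n_loci != len(items):
            raise ValueError("genotype matrix must align with the loci written")
        cols += ["FORMAT"] + genotype_matrix.sample_ids
        gt_rows = genotype_matrix.dosages
    lines.append("\t".join(cols))
    for i in order:
        if loci_mode:
            line = _locus_line(items[i])
            if gt_rows is not None:
                gts = [_GT.get(d, "./.") for d in gt_rows[i]]
                line = "\t".join([line, "GT"] + gts)
        else:
            line = _record_line(items[i], ".")
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_vcf(path, samples: list[SampleInfo] | None = None
                      ) -> GenotypeMatrix:
    """Read a merged-locus VCF with GT columns into a GenotypeMatrix."""
    vcf = VCF(str(path))
    names = list(vcf.samples)
    if samples is not None:
        by_id = {s.sample: s for s in samples}
        infos = [by_id[n] for n in names]
    else:
        infos = [SampleInfo(n, "unknown", "F0") for n in names]
    loci, rows = [], []
    for i, v in enumerate(vcf):
        svtype = v.INFO.get("SVTYPE")
        if svtype not in SV_TYPES:
            continue
        end = v.POS if svtype == "MEI" else int(v.INFO.get("END", v.end))
        length = int(v.INFO.get("SVLEN", end - v.POS + 1))
        family = "none"
        if svtype == "MEI":
            meinfo = v.INFO.get("MEINFO")
            parts = meinfo if isinstance(meinfo, (tuple, list)) else str(meinfo).split(",")
            family = str(parts[0])
        member = SVRecord(v.CHROM, v.POS, end, svtype, length, v.QUAL,
                          v.FILTER or "PASS", ".", family)
        loci.append(MergedLocus(v.ID or f"locus{i}", v.CHROM, v.POS, end,
                                svtype, length, [member], family))
        gts = v.gt_types  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        row = np.where(gts == 0, 0.0,
                       np.where(gts == 1, 1.0,
                                np.where(gts == 3, 2.0, np.nan)))
        rows.append(row)
    dosages = np.array(rows) if rows else np.empty((0, len(infos)))
    return GenotypeMatrix(loci, infos, dosages)


# ---------------------------------------------------------------------------
# gene models


def _subtract(blocks, cuts):
    """Remove `cuts` intervals from `blocks` (all 1-based inclusive)."""
    out = []
    for bs, be in blocks:
        pieces = [(bs, be)]
        for cs, ce in cuts:
            nxt = []
            for ps, pe in pieces:
                if ce < ps or cs > pe:
                    nxt.append((ps, pe))
                    continue
                if ps < cs:
                    nxt.append((ps, cs - 1))
                if ce < pe:
                    nxt.append((ce + 1, pe))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


def read_gene_model(path) -> GeneModel:
    """Read a GFF3 (gene/exon/UTR features) or BED12 gene model.

    UTR intervals are subtracted from exons so the positional categories
    (exon vs UTR) are disjoint.  An exon outside its gene span raises a model
    error naming the gene.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path) -> GeneModel:
    import gffutils

    text = Path(path).read_text()
    if not text.strip():
        return GeneModel()
    db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                            force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        exons, utr5, utr3 = [], [], []
        for child in db.children(g.id):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        for s, e in exons:
            if s < g.start or e > g.end:
                raise ValueError(f"exon {s}-{e} outside span of gene {g.id}")
        exons = _subtract(exons, utr5 + utr3)
        genes.append(Gene(g.id, g.seqid, g.start, g.end, g.strand or "+",
                          exons, sorted(utr5), sorted(utr3)))
    return GeneModel(genes)


def _read_bed12(path) -> GeneModel:
    cols = ["chrom", "chromStart", "chromEnd", "name", "score", "strand",
            "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
            "blockStarts"]
    try:
        df = pd.read_csv(path, sep="\t", names=cols, comment="#", header=None)
    except pd.errors.EmptyDataError:
        return GeneModel()
    genes = []
    for _, row in df.iterrows():
        gstart = int(row.chromStart) + 1          # 0-based half-open -> 1-based
        gend = int(row.chromEnd)
        thick_s = int(row.thickStart) + 1
        thick_e = int(row.thickEnd)
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        blocks = [(gstart + o, gstart + o + sz - 1)
                  for o, sz in zip(offsets, sizes)]
        coding = [(max(s, thick_s), min(e, thick_e)) for s, e in blocks
                  if e >= thick_s and s <= thick_e]
        left = [(s, min(e, thick_s - 1)) for s, e in blocks if s < thick_s]
        right = [(max(s, thick_e + 1), e) for s, e in blocks if e > thick_e]
        strand = str(row.strand)
        utr5, utr3 = (left, right) if strand == "+" else (right, left)
        for s, e in blocks:
            if s < gstart or e > gend:
                raise ValueError(f"exon {s}-{e} outside span of gene {row['name']}")
        genes.append(Gene(str(row["name"]), str(row.chrom), gstart, gend,
                          strand, sorted(coding), sorted(utr5), sorted(utr3)))
    return GeneModel(genes)


def write_gene_model_gff3(model: GeneModel, path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(model.genes.values(), key=lambda g: (_chrom_key(g.chrom), g.start)):
        lines.append("\t".join([g.chrom, "svforge", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", f"ID={g.gene_id}"]))
        for kind, ivs in (("exon", g.exons), ("five_prime_UTR", g.utr5),
                          ("three_prime_UTR", g.utr3)):
            for s, e in ivs:
                lines.append("\t".join([g.chrom, "svforge", kind, str(s),
                                        str(e), ".", g.strand, ".",
                                        f"Parent={g.gene_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def write_samples_tsv(samples: list[SampleInfo], path) -> None:
    pd.DataFrame([{
        "sample": s.sample, "breed": s.breed, "generation": s.generation,
        "sex": s.sex or "", "batch": s.batch or "",
        "purebred": int(s.purebred),
    } for s in samples]).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        out.append(SampleInfo(r["sample"], r["breed"], r["generation"],
                              r["sex"] or None, r["batch"] or None,
                              bool(int(r.get("purebred", "0") or 0))))
    return out


def write_phenotypes_tsv(table: PhenotypeTable, path) -> None:
    table.df.reset_index().rename(columns={"index": "sample"}).to_csv(
        path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))
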