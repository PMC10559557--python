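"""Union merging of multi-caller SV callsets.

Two same-type, same-orientation calls on one chromosome link when both
breakpoints lie within ``breakpoint_distance`` (default 1,000 bp) of each
other; clusters are the transitive closure of links (single linkage), so the
result is invariant to input order.  Inversions are merged instead by
reciprocal overlap (> 75%) within two length strata (at most 100 kb / above
100 kb) so that large variants cannot swallow small ones.  Union semantics:
every input call ends up in exactly one output locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby

from .types import MergedLocus, SVRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeConfig:
    breakpoint_distance: int = 1000
    inv_overlap_fraction: float = 0.75
    size_split: int = 100_000
    db_overlap_fraction: float = 0.75
    inv_overlap_strict: bool = True      # INV merge uses strict '>'
    db_overlap_strict: bool = False      # DB novelty uses '>='
    both_breakpoints: bool = True        # require both |dstart| and |dend| <= distance

    def __post_init__(self) -> None:
        if self.breakpoint_distance < 0:
            raise ValueError("breakpoint_distance must be >= 0")
        for f in (self.inv_overlap_fraction, self.db_overlap_fraction):
            if not (0 < f <= 1):
                raise ValueError("overlap fractions must be in (0, 1]")
        if self.size_split <= 0:
            raise ValueError("size_split must be positive")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(shared/len(a), shared/len(b)) on 1-based inclusive intervals."""
    (s1, e1), (s2, e2) = a, b
    if e1 < s1 or e2 < s2:
        raise ValueError("reciprocal overlap needs intervals of positive length")
    shared = min(e1, e2) - max(s1, s2) + 1
    if shared <= 0:
        return 0.0
    return min(shared / (e1 - s1 + 1), shared / (e2 - s2 + 1))


def _canonical(clusters, id_prefix: str) -> list[MergedLocus]:
    loci = []
    for members in clusters:
        members = sorted(members, key=lambda r: (r.start, r.end, r.caller, r.sample))
        loci.append(MergedLocus.from_members("tmp", members))
    loci.sort(key=lambda l: (l.chrom, l.rep_start, l.rep_end, l.svtype))
    for i, l in enumerate(loci):
        l.locus_id = f"{id_prefix}{i}"
    return loci


def cluster_calls(records: list[SVRecord], config: MergeConfig,
                  id_prefix: str = "locus") -> list[MergedLocus]:
    """Single-linkage breakpoint-distance clustering of DEL/DUP/MEI calls.

    Expects one (chromosome, type, orientation) stratum; inversions go
    through :func:`merge_inversions`.
    """
    if not records:
        return []
    chroms = {r.chrom for r in records}
    if len(chroms) > 1:
        raise ValueError(f"mixed chromosomes in one stratum: {sorted(chroms)}")
    if {r.svtype for r in records} - {"DEL", "DUP", "MEI"}:
        raise ValueError("cluster_calls handles DEL/DUP/MEI only")

    order = sorted(range(len(records)), key=lambda i: (records[i].start,
                                                       records[i].end))
    uf = _UnionFind(len(records))
    d = config.breakpoint_distance
    for a in range(len(order)):
        i = order[a]
        for b in range(a + 1, len(order)):
            j = order[b]
            if records[j].start - records[i].start > d:
                break
            if config.both_breakpoints and abs(records[j].end - records[i].end) > d:
                continue
            uf.union(i, j)
    groups: dict[int, list[SVRecord]] = {}
    for i, r in enumerate(records):
        groups.setdefault(uf.find(i), []).append(r)
    return _canonical(groups.values(), id_prefix)


def merge_inversions(inv_records: list[SVRecord], config: MergeConfig,
                     id_prefix: str = "inv") -> list[MergedLocus]:
    """Reciprocal-overlap merge of inversions within two length strata.

    Lengths at exactly ``size_split`` fall in the lower stratum; loci from
    different strata never merge, reproducing the guard against large
    variants covering small variants.
    """
    if any(r.svtype != "INV" for r in inv_records):
        raise ValueError("merge_inversions expects INV records only")
    low = [r for r in inv_records if r.length <= config.size_split]
    high = [r for r in inv_records if r.length > config.size_split]
    loci = []
    for stratum, tag in ((low, "s"), (high, "l")):
        loci.extend(_cluster_by_overlap(stratum, config, f"{id_prefix}{tag}"))
    loci.sort(key=lambda l: (l.chrom, l.rep_start, l.rep_end))
    for i, l in enumerate(loci):
        l.locus_id = f"{id_prefix}{i}"
    return loci


def _cluster_by_overlap(records, config, id_prefix):
    if not records:
        return []
    order = sorted(range(len(records)), key=lambda i: (records[i].start,
                                                       records[i].end))
    uf = _UnionFind(len(records))
    thr = config.inv_overlap_fraction
    for a in range(len(order)):
        i = order[a]
        for b in range(a + 1, len(order)):
            j = order[b]
            if records[j].start > records[i].end:
                break
            ro = reciprocal_overlap(records[i].span, records[j].span)
            linked = ro > thr if config.inv_overlap_strict else ro >= thr
            if linked:
                uf.union(i, j)
    groups: dict[int, list[SVRecord]] = {}
    for i, r in enumerate(records):
        groups.setdefault(uf.find(i), []).append(r)
    return _canonical(groups.values(), id_prefix)


def _dedupe(records: list[SVRecord]) -> list[SVRecord]:
    seen, out, dups = set(), [], 0
    for r in records:
        key = (r.caller, r.sample, r.chrom, r.start, r.end, r.svtype)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        out.append(r)
    if dups:
        log.warning("collapsed %d duplicate (caller, sample, position, type) records",
                    dups)
    return out


def merge_callsets(records: list[SVRecord], config: MergeConfig | None = None
                   ) -> list[MergedLocus]:
    """Union-merge a flat list of calls across callers and samples.

    Records are stratified by (chromosome, type, orientation; plus MEI family
    for insertions) and clustered within each stratum.  Because clustering is
    a transitive closure, merging everything in one pass is equivalent to the
    two-stage within-sample / across-samples application, and re-merging the
    member calls of merged loci reproduces the same loci (stage-two
    idempotence).
    """
    config = config or MergeConfig()
    records = _dedupe(records)
    keyfn = lambda r: (r.chrom, r.svtype, r.orientation, r.mei_family)
    loci: list[MergedLocus] = []
    for key, grp in groupby(sorted(records, key=keyfn), key=keyfn):
        grp = list(grp)
        if key[1] == "INV":
            loci.extend(merge_inversions(grp, config, id_prefix="tmp"))
        else:
            loci.extend(cluster_calls(grp, config, id_prefix="tmp"))
    loci.sort(key=lambda l: (l.chrom, l.rep_start, l.rep_end, l.svtype))
    for i, l in enumerate(loci):
        l.locus_id = f"locus{i}"
    return loci


def merge_loci(loci: list[MergedLocus], config: MergeConfig | None = None
               ) -> list[MergedLocus]:
    """Stage-two merge: re-cluster the member calls of existing loci."""
    members = [m for l in loci for m in l.members]
    return merge_callsets(members, config)


def compare_to_database(loci: list[MergedLocus], reference: list[SVRecord],
                        config: MergeConfig | None = None):
    """Label each locus known/novel against a reference SV set.

    DEL/DUP/INV match a same-type reference interval at reciprocal overlap
    >= ``db_overlap_fraction``; MEIs match by insertion-point distance
    <= ``breakpoint_distance``.  Returns (novel flags aligned with `loci`,
    per-type novel counts).
    """
    config = config or MergeConfig()
    if not reference:
        log.warning("reference SV set is empty: all loci labelled novel")
    by_type: dict[tuple[str, str], list[SVRecord]] = {}
    for r in reference:
        by_type.setdefault((r.chrom, r.svtype), []).append(r)
    for grp in by_type.values():
        grp.sort(key=lambda r: r.start)

    novel_flags: list[bool] = []
    novel_counts = {t: 0 for t in ("DEL", "DUP", "INV", "MEI")}
    thr = config.db_overlap_fraction
    for locus in loci:
        candidates = by_type.get((locus.chrom, locus.svtype), [])
        known = False
        for ref in candidates:
            if locus.svtype == "MEI":
                if abs(ref.start - locus.rep_start) <= config.breakpoint_distance:
                    known = True
                    break
            else:
                if ref.start > locus.rep_end:
                    break
                if ref.end < locus.rep_start:
                    continue
                ro = reciprocal_overlap((locus.rep_start, locus.rep_end), ref.span)
                if (ro > thr) if config.db_overlap_strict else (ro >= thr):
                    known = True
                    break
        novel_flags.append(not known)
        if not known:
            novel_counts[locus.svtype] += 1
    return novel_flags, novel_counts
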