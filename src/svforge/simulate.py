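"""Synthetic two-breed F2 intercross with planted structural variants.

The generator produces every input the pipeline consumes, with known ground
truth: a gene model; true SV loci placed with configurable positional-category
weights; two diverged founder breeds (Balding-Nichols allele-frequency model
with divergence parameter F); multi-caller noisy callsets (per-caller
sensitivity, breakpoint jitter, false positives, quality scores); an F2
population bred F0 -> F1 -> F2 with Haldane recombination and exact Mendelian
transmission; per-cell offspring genotyping evidence degraded by dropout and
error; and a continuous trait built from planted causal SV effects, a
polygenic term g ~ N(0, sigma2_g K), sex and slaughter-batch effects, and
residual noise.

All randomness flows from the single config seed through named substreams,
so identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .screen import OffspringEvidence
from .types import (Gene, GeneModel, GenotypeMatrix, PhenotypeTable,
                    SampleInfo, SVRecord)

_STREAMS = {"truth": 0, "callsets": 1, "f2": 2, "evidence": 3,
            "phenotypes": 4, "reference": 5, "founder_geno": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class CallerProfile:
    name: str
    svtypes: tuple[str, ...]
    sensitivity: float = 0.75
    jitter_sd: float = 80.0
    jitter_max: int = 400
    fp_per_mb: float = 0.03
    qual_mean: float = 450.0
    qual_sd: float = 150.0
    fp_qual_mean: float = 120.0
    fp_qual_sd: float = 60.0
    mei_pass_prob: float = 0.95
    fp_mei_pass_prob: float = 0.30


def default_callers() -> tuple[CallerProfile, ...]:
    """Four read-pair/split-read style callers for DEL/DUP/INV plus one
    mobile-element caller, with differing sensitivities."""
    span = ("DEL", "DUP", "INV")
    return (
        CallerProfile("callerA", span, sensitivity=0.85),
        CallerProfile("callerB", span, sensitivity=0.75),
        CallerProfile("callerC", span, sensitivity=0.70),
        CallerProfile("callerD", span, sensitivity=0.60),
        CallerProfile("meicaller", ("MEI",), sensitivity=0.90),
    )


def _dict(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic intercross.

    Defaults emulate the real design at desk scale: 15 + 15 founders of two
    diverged breeds (six breed-A founders tagged purebred), 513 F2 offspring,
    four SV types with MEI families, five callers merged by union, offspring
    genotyping with ~3% dropout.
    """

    seed: int = 0
    chrom_lengths: dict = _dict(chr1=40_000_000, chr2=30_000_000,
                                chr3=20_000_000)
    n_sv: dict = _dict(DEL=550, DUP=100, INV=160, MEI=190)
    length_ranges: dict = _dict(DEL=(50, 2000), DUP=(1000, 50_000),
                                INV=(100, 50_000))
    mei_family_probs: dict = _dict(SINE=0.80, LINE=0.15, ERV=0.05)
    mei_family_lengths: dict = _dict(SINE=290, LINE=6000, ERV=8000)
    category_weights: dict = _dict(intergenic=0.60, intron=0.35, exon=0.02,
                                   utr5=0.01, gene_upstream=0.02)
    gene_spacing: int = 100_000
    min_locus_separation: int = 3000
    divergence_f: float = 0.15
    breed_a: str = "Min"
    breed_b: str = "LargeWhite"
    n_founders_a: int = 15
    n_founders_b: int = 15
    n_purebred_a: int = 6
    n_f1: int = 30
    n_f2: int = 513
    recomb_cm_per_mb: float = 1.0
    n_batches: int = 8
    callers: tuple = field(default_factory=default_callers)
    founder_dropout: float = 0.02
    founder_error: float = 0.01
    offspring_dropout: float = 0.03
    offspring_error: float = 0.01
    db_coverage: float = 0.50
    db_decoy_fraction: float = 0.20
    n_causal: int = 1
    causal_variance_share: float = 0.15
    causal_p_a: float = 0.95
    causal_p_b: float = 0.05
    polygenic_variance: float = 0.30
    residual_variance: float = 0.55
    sex_effect: float = 0.5
    batch_sd: float = 0.3
    trait_name: str = "body_length"
    trait_mean: float = 100.0

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @classmethod
    def small(cls, seed: int = 0, **kw) -> "SimConfig":
        """A reduced configuration for fast end-to-end runs."""
        base = dict(seed=seed,
                    chrom_lengths=dict(chr1=20_000_000, chr2=15_000_000),
                    n_sv=dict(DEL=120, DUP=20, INV=20, MEI=30),
                    n_f1=20, n_f2=500, n_batches=4)
        base.update(kw)
        return cls(**base)


@dataclass
class TrueLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    mei_family: str
    length: int
    category: str
    p_a: float
    p_b: float
    causal: bool = False

    def to_record(self, caller: str = "truth", sample: str = "truth",
                  start: int | None = None, end: int | None = None,
                  qual: float | None = None,
                  filter_status: str = "PASS") -> SVRecord:
        s = self.start if start is None else start
        e = self.end if end is None else end
        if self.svtype == "MEI":
            e = s
        length = self.length if self.svtype == "MEI" else e - s + 1
        return SVRecord(self.chrom, s, e, self.svtype, length, qual,
                        filter_status, ".", self.mei_family, caller, sample)


@dataclass
class Truth:
    loci: list[TrueLocus]
    gene_model: GeneModel
    founders: list[SampleInfo]
    founder_dosages: np.ndarray      # loci x founders
    config: SimConfig

    @property
    def causal_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.loci) if l.causal]


# ---------------------------------------------------------------------------
# gene model and locus placement

_GENE_SPAN = 16_400


def build_gene_model(config: SimConfig) -> GeneModel:
    """Deterministic gene layout: one ~16.4 kb gene per `gene_spacing` bp,
    alternating strand, with a 200 bp UTR at each end and five 400 bp exons
    separated by introns."""
    genes = []
    k = 0
    for chrom, length in config.chrom_lengths.items():
        s = 50_000
        while s + _GENE_SPAN < length - 50_000:
            strand = "+" if k % 2 == 0 else "-"
            low_utr = [(s, s + 199)]
            high_utr = [(s + 16_200, s + 16_399)]
            exons = [(s + 200 + i * 3_900, s + 200 + i * 3_900 + 399)
                     for i in range(5)]
            utr5, utr3 = (low_utr, high_utr) if strand == "+" else (high_utr, low_utr)
            genes.append(Gene(f"gene{k}", chrom, s, s + _GENE_SPAN - 1, strand,
                              exons, utr5, utr3))
            k += 1
            s += config.gene_spacing
    return GeneModel(genes)


def _feature_pools(model: GeneModel, config: SimConfig):
    """Candidate placement intervals per positional category."""
    margin = 1500
    pools: dict[str, list[tuple[str, int, int]]] = {
        "intergenic": [], "intron": [], "exon": [], "utr5": [],
        "gene_upstream": []}
    for chrom, length in config.chrom_lengths.items():
        genes = model.genes_on(chrom)
        cursor = 1
        for g in genes:
            if g.start - margin > cursor + margin:
                pools["intergenic"].append((chrom, cursor + margin,
                                            g.start - margin))
            cursor = g.end
            for iv in g.introns:
                pools["intron"].append((chrom, iv[0], iv[1]))
            for iv in g.exons:
                pools["exon"].append((chrom, iv[0], iv[1]))
            for iv in g.utr5:
                pools["utr5"].append((chrom, iv[0], iv[1]))
            flank = ((chrom, max(1, g.start - 1000), g.start - 1)
                     if g.strand == "+" else (chrom, g.end + 1, g.end + 1000))
            pools["gene_upstream"].append(flank)
        if length - margin > cursor + margin:
            pools["intergenic"].append((chrom, cursor + margin, length - margin))
    return pools


def simulate_truth(config: SimConfig) -> Truth:
    """Generate the gene model, true SV loci and founder genotypes."""
    rng = _rng(config.seed, "truth")
    model = build_gene_model(config)
    pools = _feature_pools(model, config)
    cats = list(config.category_weights)
    weights = np.array([config.category_weights[c] for c in cats], dtype=float)
    weights = weights / weights.sum()
    pool_lens = {c: np.array([e - s + 1 for _, s, e in pools[c]], dtype=float)
                 for c in cats}

    import bisect
    occupied: dict[str, list[int]] = {c: [] for c in config.chrom_lengths}
    occ_end: dict[str, list[int]] = {c: [] for c in config.chrom_lengths}
    sep = config.min_locus_separation

    def _free(chrom, s, e):
        starts, ends = occupied[chrom], occ_end[chrom]
        i = bisect.bisect_left(starts, s)
        if i < len(starts) and starts[i] <= e + sep:
            return False
        if i > 0 and ends[i - 1] >= s - sep:
            return False
        return True

    def _occupy(chrom, s, e):
        i = bisect.bisect_left(occupied[chrom], s)
        occupied[chrom].insert(i, s)
        occ_end[chrom].insert(i, e)

    loci: list[TrueLocus] = []
    for svtype, count in config.n_sv.items():
        for k in range(count):
            placed = False
            for _try in range(300):
                cat = cats[rng.choice(len(cats), p=weights)]
                ivs = pools[cat]
                iv = ivs[rng.choice(len(ivs), p=pool_lens[cat] / pool_lens[cat].sum())]
                chrom, fs, fe = iv
                iv_len = fe - fs + 1
                if svtype == "MEI":
                    fam = rng.choice(list(config.mei_family_probs),
                                     p=list(config.mei_family_probs.values()))
                    length = config.mei_family_lengths[str(fam)]
                    pos = int(rng.integers(fs, fe + 1))
                    s, e = pos, pos
                    fam = str(fam)
                else:
                    lo, hi = config.length_ranges[svtype]
                    length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                    length = max(50, min(length, int(0.8 * iv_len)))
                    if length < 50 or length > iv_len:
                        continue
                    s = int(rng.integers(fs, fe - length + 2))
                    e = s + length - 1
                    fam = "none"
                if not _free(chrom, s, e):
                    continue
                _occupy(chrom, s, e)
                loci.append(TrueLocus(f"true_{svtype}{k}", chrom, s, e, svtype,
                                      fam, length, cat, 0.0, 0.0))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place {svtype} locus {k}: genome too crowded")

    loci.sort(key=lambda l: (l.chrom, l.start, l.end))

    # Balding-Nichols breed frequencies around a shared ancestral frequency
    F = config.divergence_f
    for l in loci:
        p_anc = rng.uniform(0.05, 0.95)
        if F <= 0:
            l.p_a = l.p_b = p_anc
        else:
            a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
            l.p_a = float(rng.beta(a, b))
            l.p_b = float(rng.beta(a, b))

    # plant causal loci: strongly breed-differential DELs in neutral space
    eligible = [i for i, l in enumerate(loci)
                if l.svtype == "DEL" and l.category in ("intron", "intergenic")
                and l.length >= 200]
    causal = rng.choice(eligible, size=config.n_causal, replace=False)
    for i in causal:
        loci[i].causal = True
        loci[i].p_a = config.causal_p_a
        loci[i].p_b = config.causal_p_b

    founders = (
        [SampleInfo(f"M{i + 1}", config.breed_a, "F0",
                    purebred=i < config.n_purebred_a)
         for i in range(config.n_founders_a)]
        + [SampleInfo(f"LW{i + 1}", config.breed_b, "F0")
           for i in range(config.n_founders_b)])
    L = len(loci)
    dosages = np.empty((L, len(founders)))
    p_a = np.array([l.p_a for l in loci])
    p_b = np.array([l.p_b for l in loci])
    na = config.n_founders_a
    dosages[:, :na] = rng.binomial(2, p_a[:, None], size=(L, na))
    dosages[:, na:] = rng.binomial(2, p_b[:, None],
                                   size=(L, config.n_founders_b))
    return Truth(loci, model, founders, dosages, config)


# ---------------------------------------------------------------------------
# caller observation model


def simulate_callsets(truth: Truth, config: SimConfig | None = None
                      ) -> dict[tuple[str, str], list[SVRecord]]:
    """Per-(caller, founder) noisy callsets: sensitivity, breakpoint jitter
    (truncated below half the merge distance by default), false positives,
    and caller quality scores."""
    config = config or truth.config
    rng = _rng(config.seed, "callsets")
    genome_mb = sum(config.chrom_lengths.values()) / 1e6
    chroms = list(config.chrom_lengths)
    chrom_w = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()

    out: dict[tuple[str, str], list[SVRecord]] = {}
    for prof in config.callers:
        type_idx = [i for i, l in enumerate(truth.loci)
                    if l.svtype in prof.svtypes]
        for fi, founder in enumerate(truth.founders):
            recs: list[SVRecord] = []
            for i in type_idx:
                locus = truth.loci[i]
                if truth.founder_dosages[i, fi] < 1:
                    continue
                if rng.random() >= prof.sensitivity:
                    continue
                if locus.svtype == "MEI":
                    cap = prof.jitter_max
                else:
                    cap = min(prof.jitter_max, (locus.length - 1) // 2)
                j1, j2 = np.clip(rng.normal(0, prof.jitter_sd, 2), -cap, cap)
                s = max(1, locus.start + int(round(j1)))
                e = locus.end + int(round(j2))
                qual = round(max(1.0, rng.normal(prof.qual_mean, prof.qual_sd)), 2)
                filt = "PASS"
                if locus.svtype == "MEI":
                    e = s
                    if rng.random() >= prof.mei_pass_prob:
                        filt = "not_pass"
                recs.append(locus.to_record(prof.name, founder.sample, s,
                                            max(s, e), qual, filt))
            n_fp = rng.poisson(prof.fp_per_mb * genome_mb)
            for _ in range(n_fp):
                chrom = chroms[rng.choice(len(chroms), p=chrom_w)]
                svtype = str(rng.choice(prof.svtypes))
                qual = round(max(1.0, rng.normal(prof.fp_qual_mean, prof.fp_qual_sd)), 2)
                if svtype == "MEI":
                    fam = str(rng.choice(list(config.mei_family_probs),
                                         p=list(config.mei_family_probs.values())))
                    length = config.mei_family_lengths[fam]
                    pos = int(rng.integers(1, config.chrom_lengths[chrom]))
                    filt = ("PASS" if rng.random() < prof.fp_mei_pass_prob
                            else "not_pass")
                    recs.append(SVRecord(chrom, pos, pos, "MEI", length, qual,
                                         filt, ".", fam, prof.name,
                                         founder.sample))
                else:
                    lo, hi = config.length_ranges[svtype]
                    length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                    pos = int(rng.integers(1, config.chrom_lengths[chrom] - length))
                    recs.append(SVRecord(chrom, pos, pos + length - 1, svtype,
                                         length, qual, "PASS", ".", "none",
                                         prof.name, founder.sample))
            out[(prof.name, founder.sample)] = recs
    return out


# ---------------------------------------------------------------------------
# F2 intercross


def _recomb_probs(loci: list[TrueLocus], cm_per_mb: float) -> np.ndarray:
    """Per-interval recombination probabilities under the Haldane map
    (0.5 at each chromosome start)."""
    r = np.full(len(loci), 0.5)
    for i in range(1, len(loci)):
        if loci[i].chrom == loci[i - 1].chrom:
            d_morgan = (loci[i].start - loci[i - 1].start) * cm_per_mb * 1e-8
            r[i] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    return r


def _gamete(hap: np.ndarray, r: np.ndarray, rng: np.random.Generator
            ) -> np.ndarray:
    """Form one gamete from a (2, L) haplotype pair with crossover
    probabilities r (r[0] = 0.5 picks the starting haplotype)."""
    switches = rng.random(len(r)) < r
    state = np.cumsum(switches) % 2
    return hap[state, np.arange(hap.shape[1])]


def _phase(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random phasing of (L, n) dosages into (n, 2, L) haplotypes."""
    L, n = dosages.shape
    haps = np.zeros((n, 2, L), dtype=np.int8)
    hom = dosages.T == 2
    haps[:, 0, :][hom] = 1
    haps[:, 1, :][hom] = 1
    het = dosages.T == 1
    which = rng.integers(0, 2, size=(n, L))
    haps[:, 0, :][het & (which == 0)] = 1
    haps[:, 1, :][het & (which == 1)] = 1
    return haps


def simulate_f2(truth: Truth, config: SimConfig | None = None):
    """Breed F0 -> F1 (breed-A x breed-B) -> F2 (F1 x F1) with Haldane
    recombination and exact Mendelian transmission.

    Returns (dosages loci x n_f2, F2 SampleInfo list, pedigree DataFrame).
    """
    config = config or truth.config
    if config.n_founders_a < 2 or config.n_founders_b < 2:
        raise ValueError("need at least 2 founders per breed")
    rng = _rng(config.seed, "f2")
    r = _recomb_probs(truth.loci, config.recomb_cm_per_mb)
    haps = _phase(truth.founder_dosages, rng)
    na = config.n_founders_a

    f1 = []
    f1_ped = []
    for i in range(config.n_f1):
        sire = int(rng.integers(0, na))
        dam = na + int(rng.integers(0, config.n_founders_b))
        f1.append(np.stack([_gamete(haps[sire], r, rng),
                            _gamete(haps[dam], r, rng)]))
        f1_ped.append((sire, dam))

    L = len(truth.loci)
    dosages = np.empty((L, config.n_f2))
    samples, ped = [], []
    for i in range(config.n_f2):
        a, b = rng.choice(config.n_f1, size=2, replace=False)
        g1 = _gamete(f1[a], r, rng)
        g2 = _gamete(f1[b], r, rng)
        dosages[:, i] = g1 + g2
        sex = "M" if rng.random() < 0.5 else "F"
        batch = f"b{int(rng.integers(0, config.n_batches))}"
        sid = f"F2_{i:03d}"
        samples.append(SampleInfo(sid, "F2cross", "F2", sex, batch))
        ped.append({"sample": sid, "f1_sire": int(a), "f1_dam": int(b),
                    "f0_sire_a": f1_ped[a][0], "f0_dam_a": f1_ped[a][1],
                    "f0_sire_b": f1_ped[b][0], "f0_dam_b": f1_ped[b][1]})
    return dosages, samples, pd.DataFrame(ped)


# ---------------------------------------------------------------------------
# genotyping evidence and founder genotype observation


def simulate_offspring_evidence(truth: Truth, f2_dosages: np.ndarray,
                                f2_samples: list[SampleInfo],
                                config: SimConfig | None = None,
                                loci_idx=None) -> list[OffspringEvidence]:
    """Per-cell genotype evidence at true positions, degraded by dropout and
    genotype error."""
    config = config or truth.config
    rng = _rng(config.seed, "evidence")
    if loci_idx is None:
        loci_idx = range(len(truth.loci))
    evidence: list[OffspringEvidence] = []
    for i in loci_idx:
        locus = truth.loci[i]
        drop = rng.random(len(f2_samples)) < config.offspring_dropout
        err = rng.random(len(f2_samples)) < config.offspring_error
        conf = rng.random(len(f2_samples))
        for j, s in enumerate(f2_samples):
            if drop[j]:
                continue
            d = float(f2_dosages[i, j])
            if err[j]:
                d = float(rng.choice([x for x in (0.0, 1.0, 2.0) if x != d]))
            evidence.append(OffspringEvidence(s.sample, locus.chrom,
                                              locus.start, locus.svtype, d,
                                              float(conf[j])))
    return evidence


def simulate_founder_genotypes(loci, truth_match: list[int | None],
                               truth: Truth, config: SimConfig | None = None
                               ) -> GenotypeMatrix:
    """Observed founder genotypes at merged loci: true dosages (where the
    locus matches a true one) degraded by dropout/error; unmatched
    (false-positive) loci are homozygous reference up to dropout."""
    config = config or truth.config
    rng = _rng(config.seed, "founder_geno")
    n = len(truth.founders)
    dosages = np.zeros((len(loci), n))
    for li, t in enumerate(truth_match):
        if t is not None:
            dosages[li] = truth.founder_dosages[t]
        err = rng.random(n) < config.founder_error
        for j in np.where(err)[0]:
            dosages[li, j] = rng.choice(
                [x for x in (0.0, 1.0, 2.0) if x != dosages[li, j]])
        drop = rng.random(n) < config.founder_dropout
        dosages[li, drop] = np.nan
    return GenotypeMatrix(list(loci), truth.founders, dosages)


def make_reference_db(truth: Truth, config: SimConfig | None = None
                      ) -> list[SVRecord]:
    """A synthetic public SV database: a fraction of true loci (slightly
    perturbed but within the overlap/distance match rules) plus decoys."""
    config = config or truth.config
    rng = _rng(config.seed, "reference")
    ref: list[SVRecord] = []
    for l in truth.loci:
        if rng.random() >= config.db_coverage:
            continue
        if l.svtype == "MEI":
            shift = int(rng.integers(-400, 401))
            s = max(1, l.start + shift)
            ref.append(l.to_record("db", "db", s, s))
        else:
            shift = int(rng.integers(-max(1, l.length // 10),
                                     max(1, l.length // 10) + 1))
            s = max(1, l.start + shift)
            ref.append(l.to_record("db", "db", s, l.end + shift))
    n_decoys = int(config.db_decoy_fraction * len(ref))
    chroms = list(config.chrom_lengths)
    for _ in range(n_decoys):
        chrom = chroms[int(rng.integers(len(chroms)))]
        svtype = str(rng.choice(("DEL", "DUP", "INV", "MEI")))
        if svtype == "MEI":
            pos = int(rng.integers(1, config.chrom_lengths[chrom]))
            ref.append(SVRecord(chrom, pos, pos, "MEI", 300, None, "PASS",
                                ".", "SINE", "db", "db"))
        else:
            length = int(rng.integers(100, 5000))
            pos = int(rng.integers(1, config.chrom_lengths[chrom] - length))
            ref.append(SVRecord(chrom, pos, pos + length - 1, svtype, length,
                                None, "PASS", ".", "none", "db", "db"))
    return ref


# ---------------------------------------------------------------------------
# phenotypes


def effect_for_variance_share(share: float, dosage_var: float,
                              other_variance: float) -> float:
    """Effect size beta such that beta^2 * dosage_var is `share` of the total
    trait variance (causal + other variance components)."""
    if not (0 <= share < 1):
        raise ValueError("variance share must be in [0, 1)")
    if dosage_var <= 0:
        raise ValueError("causal dosage has zero variance")
    return float(np.sqrt(share * other_variance / ((1 - share) * dosage_var)))


def simulate_phenotypes(truth: Truth, f2_dosages: np.ndarray,
                        f2_samples: list[SampleInfo],
                        K: np.ndarray | None = None,
                        config: SimConfig | None = None):
    """Build the trait y = mu + sex + batch + sum_j beta_j d_j + g + e.

    g ~ N(0, sigma2_g K) and e ~ N(0, sigma2_e I), with every per-sample
    draw made in sample-id-sorted space and scattered back to input order,
    so permuting the samples (with the matching permutation of K and the
    dosage columns) permutes the phenotypes exactly.  When K is None it
    defaults to allele-sharing kinship computed from `f2_dosages`.  beta_j
    is set so each causal SV explains `causal_variance_share` of the total
    variance.  Returns the PhenotypeTable and a ground-truth record.
    """
    config = config or truth.config
    rng = _rng(config.seed, "phenotypes")
    n = len(f2_samples)
    causal = truth.causal_indices
    for i in causal:
        if i >= f2_dosages.shape[0]:
            raise ValueError("causal locus absent from genotypes")

    other_var = config.polygenic_variance + config.residual_variance
    betas = {}
    genetic = np.zeros(n)
    for i in causal:
        d = f2_dosages[i]
        beta = effect_for_variance_share(config.causal_variance_share,
                                         float(np.var(d)), other_var)
        betas[truth.loci[i].locus_id] = beta
        genetic = genetic + beta * d

    sex = np.array([1.0 if s.sex == "M" else 0.0 for s in f2_samples])
    batches = sorted({s.batch for s in f2_samples})
    batch_eff = {b: float(rng.normal(0, config.batch_sd)) for b in batches}
    batch_term = np.array([batch_eff[s.batch] for s in f2_samples])

    if K is None:
        from .gwas import kinship as _kinship
        K = _kinship(GenotypeMatrix(truth.loci, f2_samples, f2_dosages),
                     "IBS").values
    id_order = np.argsort([s.sample for s in f2_samples])
    if config.polygenic_variance > 0:
        Ks = K[np.ix_(id_order, id_order)]
        Lc = np.linalg.cholesky(config.polygenic_variance * Ks
                                + 1e-8 * np.eye(n))
        g = np.empty(n)
        g[id_order] = Lc @ rng.standard_normal(n)
    else:
        g = np.zeros(n)
    e = np.empty(n)
    e[id_order] = rng.standard_normal(n) * np.sqrt(config.residual_variance)

    y = (config.trait_mean + config.sex_effect * sex + batch_term
         + genetic + g + e)
    df = pd.DataFrame({
        "sample": [s.sample for s in f2_samples],
        "sex": [s.sex for s in f2_samples],
        "batch": [s.batch for s in f2_samples],
        config.trait_name: y,
    })
    truth_record = {
        "seed": config.seed,
        "causal_betas": betas,
        "causal_loci": [truth.loci[i].locus_id for i in causal],
        "sigma2_g": config.polygenic_variance,
        "sigma2_e": config.residual_variance,
        "sex_effect": config.sex_effect,
        "batch_effects": batch_eff,
        "realized_causal_var": float(np.var(genetic)),
        "realized_total_var": float(np.var(y)),
    }
    return PhenotypeTable(df), truth_record
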