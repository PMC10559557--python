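# Methods

This note documents the models behind svforge, the defaults and why they
were chosen, the numerical choices, and what the synthetic study does and
does not establish.

## Coordinates and record model

All internal coordinates are 1-based inclusive (VCF convention); BED input
is converted at the I/O boundary. For DEL/DUP/INV the length is always
recomputed from the breakpoints as `end − start + 1`; a caller-reported
SVLEN that disagrees is counted and logged but never trusted, so one
unambiguous convention holds everywhere. MEIs are point insertions
(`end == start`) whose length is the inserted element length from MEINFO and
whose family (ERV/LINE/SINE) is kept separately. Quality scores are carried
at 0.01 resolution, which makes VCF round trips exact.

## Union merging

Two calls link when they share chromosome, SV type and breakpoint
orientation and both `|Δstart| ≤ 1000` and `|Δend| ≤ 1000` bp. Requiring
both breakpoints is the strict reading of a single "breakpoint distance"
rule; a start-only variant can be had via `MergeConfig(both_breakpoints=False)`.
Clusters are the transitive closure of links (single linkage), which makes
the output provably invariant to input order and lets an all-pairs
brute-force closure serve as a test oracle. Because closure is associative,
merging all callers and samples in one pass equals the two-stage
within-sample / across-sample application, and re-merging merged loci is a
no-op on well-separated clusters.

Inversions are special-cased because different callers emit reversed
breakpoint pairs: they merge by reciprocal overlap strictly greater than
0.75, computed on inclusive intervals, within two length strata split at
100 kb (the boundary value goes to the lower stratum; strata never mix).
MEIs cluster by insertion-point distance within the same 1,000 bp tolerance
and never across families, since family mixing would corrupt per-family
counts.

Representative breakpoints are lower medians of member breakpoints —
deterministic, robust to a single outlying caller, and exactly reproducible.
Locus QUAL is the maximum over members: a union merge keeps the best
evidence for a locus.

Database novelty uses reciprocal overlap ≥ 0.75 against same-type reference
intervals (inclusive, because public releases publish rounded coordinates),
with MEIs matched by insertion-point distance instead.

## Quality control

Locus filters: QUAL strictly > 200 for DEL/DUP/INV, the PASS token for
MEIs, and length within [50 bp, 1 Mb]; every removal carries an exhaustive
reason list. Matrix filters run in a fixed order — samples by call rate
> 0.90, then loci by call rate > 0.90, then loci by MAF > 0.05 with MAF
computed on non-missing dosages after sample removal. The filters are
monotone in their thresholds, which the tests exercise. In the pipeline the
matrix filters apply to the genotyped F2 matrix; the founder map is subject
only to the locus-level filters.

## Positional annotation and impact

Each locus gets exactly one category under the precedence
coverage > exon > UTR5 > UTR3 > intron > gene_upstream > gene_downstream >
intergenic. DEL/DUP are annotated by full span; INV by its two breakpoints
only (an inversion's interior is neither gained nor lost); MEI by insertion
point. Up/downstream are strand-aware within a 1 kb flank. UTR intervals
are subtracted from exons at model load so the categories partition the
gene body. The impact table is deliberately explicit and small: exon or
whole-gene coverage → HIGH; UTR → MODERATE for copy-number types (DEL/DUP),
LOW for INV/MEI; everything else → MODIFIER. It is a documented convention,
not a reproduction of any annotation engine's internal rules, and the
per-type HIGH percentages of real annotation tools are therefore not a
comparison surface for this package.

## Weir–Cockerham F_ST

The per-locus two-population estimator is implemented exactly from the 1984
variance components (a, b, c; θ = a/(a+b+c)) with missing genotypes
excluded per locus per group. Negative estimates are retained and ranking
uses raw θ; a locus is undefined (NaN, with a reason) when either group has
fewer than two called genotypes or when a+b+c = 0 (monomorphic). The top-5%
rule selects θ ≥ the k-th largest defined value with k = ceil(0.05·m), ties
inclusive — "top 5%" is a floor, not an exact count. With fewer than 1/q
defined loci everything is returned with a warning.

## PCA and trees

The relationship matrix uses mean-imputed dosages centered by 2p̂ and scaled
by sqrt(2p̂(1−p̂)) per locus (monomorphic loci skipped), G = ZᵀZ/m, so the
diagonal averages ≈ 1; sample coordinates are eigvec·sqrt(eigval).
Imputation is used for the GRM only — frequency estimators (F_ST, screen,
MAF) always work on raw missing-aware counts. The neighbor-joining tree uses
1 − mean allele sharing over pairwise non-missing loci and scikit-bio's
classical NJ; a pair with no shared called loci is an error rather than a
guessed distance.

## Breed-differential screen

The two conditions are formalized as: there exist a genotype class g and a
breed direction such that count(g) in breed A exceeds 0.8·|A| while the two
complementary classes jointly exceed 0.5·|B| in breed B (or the mirrored
assignment). Thresholds compare against nominal breed sizes, so missing
founder genotypes help neither side — with |A| = 6 and |B| = 15 the minimal
passing counts are 5 and 8. The complement is evaluated jointly (the two
remaining classes pooled); this is the natural reading of "the remaining two
genotypes were set for the other breed", and the class-wise alternative
would only shrink the candidate set.

Offspring genotyping consumes per-sample evidence records keyed by
(chromosome, position, SV type); a candidate matches evidence within the
merge tolerance (1,000 bp) of its representative start, duplicate evidence
keeps the highest confidence, and the success rate is reported as a
percentage with two decimals. Read-level genotypers are out of scope; in the
synthetic world the evidence is the true genotype degraded by dropout and
error.

## Mixed-model association

Variance components are estimated once on the null model by REML over
δ = σ²_e/σ²_g, profiled through the spectral decomposition of K: the
restricted likelihood is evaluated on a fixed 101-point grid of log δ over
[−10, 10] and refined by bounded scalar minimization between the grid
neighbors — deterministic for given inputs, with a boundary flag when the
optimum pins an end. Kinship is IBS allele sharing (VanRaden GRM available),
mean-imputed, with a 1e-6 ridge. Each marker is then tested by GLS with the
covariance frozen (the EMMAX approximation) and a Wald t-test with
n − p − 1 degrees of freedom; per-marker missing dosages are mean-imputed
so n stays constant, and monomorphic markers return NaN with a reason.
With identity kinship and zero genetic variance the procedure reduces
exactly to OLS, which the tests assert to 1e-9. Three genotype PCs enter as
covariates by default (the covariate count is free in the design; three is
a conventional choice), along with sex and slaughter-batch fixed effects.
Significance is Bonferroni α divided by the number of markers actually
tested for that trait.

## The synthetic study

The generator emulates the study design the pipeline targets, at desk
scale. Defaults: a 90 Mb genome in three chromosomes with a deterministic
gene layout (one 16.4 kb gene per 100 kb, five 400 bp exons, 200 bp UTRs);
1,000 true SV loci (550 DEL / 100 DUP / 160 INV / 190 MEI, roughly the
published per-type proportions) placed by category weights (0.60
intergenic, 0.35 intron, 0.05 genic/flank) with a 3 kb minimum separation
so cluster identity is provable; log-uniform lengths (DEL 50–2,000 bp, DUP
1–50 kb, INV 0.1–50 kb, MEI family lengths 290/6,000/8,000 bp with
SINE-dominated family weights). Breed allele frequencies follow a
Balding–Nichols model around a shared ancestral frequency with divergence
F = 0.15. Founders are 15 + 15 with six breed-A founders tagged purebred;
the F2 population (default 513; the power analyses use 500) descends from
30 F1 of breed-A × breed-B matings with Haldane recombination at 1 cM/Mb
and exact Mendelian transmission.

Five caller profiles (four span callers with sensitivities 0.60–0.85 plus
one MEI caller at 0.90) observe each carrier with truncated-normal
breakpoint jitter (SD 80 bp, capped at 400 bp < half the merge distance, and
at half the SV length so spans cannot invert), Gaussian QUAL scores leaving
roughly a tenth below 200, Poisson false positives at 0.03/Mb per
caller-sample, and a 5% MEI non-PASS rate. Founder genotype observation
uses 2% dropout / 1% error; offspring evidence uses 3% dropout / 1% error,
putting the genotyping success rate near 97%.

One causal deletion (≥ 200 bp, intronic or intergenic, breed frequencies
0.95/0.05) carries an effect sized to explain 15% of trait variance over a
polygenic background g ~ N(0, σ²_g K) (σ²_g = 0.30, with K the
allele-sharing kinship of the true genome-wide dosages), sex (+0.5) and
batch (SD 0.3) fixed effects, and residual σ²_e = 0.55. All per-sample
draws are made in sample-id-sorted space and scattered back, so permuting
the input samples permutes the phenotypes exactly. Every random stream
derives from the single config seed through named substreams.

What the synthetic study does **not** emulate: read-level evidence and
depth-dependent caller behavior; ancestral linkage disequilibrium within
breeds (founder genotypes are independent across loci, so F2 LD comes only
from pedigree recombination); multi-allelic loci and breakend/translocation
variants; genuinely overlapping SVs (the 3 kb separation rules them out);
and reference-genome artifacts. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model, not
performance on real sequencing data.

## Numerical and scale choices

Tolerances: the F_ST implementation must match an independent evaluation to
1e-10; GLS/OLS equivalence to 1e-9; merge oracles are exact set equalities.
Null-calibration checks run at n = 500 with 5,000 markers; heritability
recovery at n = 500 over 50 replicates; the end-to-end causal-recovery
check runs 20 seeded replicates of the full pipeline at n_F2 = 500, sizes
chosen to keep each replicate a few seconds while leaving the binomial
margins meaningful. The default study (1,000 loci, 513 F2) runs in a few
seconds; the acceptance script executes it once per invocation.

## Known limitations

Single-linkage merging can chain distinct loci through intermediate calls
when true loci sit closer than the tolerance; the generator's separation
guarantee sidesteps this, real data would not. Kinship estimated from only
the screened (breed-differential) markers carries the breed-ancestry axis
and a noticeable per-marker share, so EMMAX-style correction can be
conservative for strongly stratified causal loci at small marker counts
(proximal contamination); with the default candidate counts the planted
causal locus still ranks first in ≥ 90% of replicates. REML assumes a
single genetic variance component; dominance and epistasis are out of
scope, as is exact per-marker REML.
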