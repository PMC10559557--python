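"""End-to-end synthetic study: simulate -> merge -> QC -> population genetics
-> screen -> offspring genotyping -> mixed-model GWAS."""

from __future__ import annotations

import bisect

import numpy as np
import pandas as pd

from .annotate import annotate_loci, summarize_positions
from .gwas import fit_null_reml, kinship, mlm_association
from .merge import MergeConfig, compare_to_database, merge_callsets
from .popgen import grm_pca, top_quantile_loci, weir_cockerham_fst
from .qc import QcConfig, filter_genotype_matrix, filter_loci
from .screen import ScreenConfig, genotype_candidates_in_offspring, \
    screen_differential_loci
from .simulate import (SimConfig, Truth, make_reference_db, simulate_callsets,
                       simulate_f2, simulate_founder_genotypes,
                       simulate_offspring_evidence, simulate_phenotypes,
                       simulate_truth)


def match_loci_to_truth(loci, truth: Truth, tolerance: int = 1000
                        ) -> list[int | None]:
    """Nearest same-type true locus within `tolerance` of each merged locus's
    representative start (None for unmatched / false-positive loci)."""
    by_key: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
    for i, t in enumerate(truth.loci):
        starts, idx = by_key.setdefault((t.chrom, t.svtype), ([], []))
        starts.append(t.start)
        idx.append(i)
    out: list[int | None] = []
    for locus in loci:
        entry = by_key.get((locus.chrom, locus.svtype))
        best = None
        if entry:
            starts, idx = entry
            j = bisect.bisect_left(starts, locus.rep_start)
            for cand in (j - 1, j):
                if 0 <= cand < len(starts):
                    dist = abs(starts[cand] - locus.rep_start)
                    if dist <= tolerance and (best is None or dist < best[0]):
                        best = (dist, idx[cand])
        out.append(best[1] if best else None)
    return out


def design_matrix(samples, pcs: np.ndarray | None = None) -> np.ndarray:
    """Intercept + sex indicator + batch dummies (first batch dropped) +
    principal-component covariates."""
    sex = np.array([1.0 if s.sex == "M" else 0.0 for s in samples])
    batches = sorted({s.batch for s in samples})
    cols = [np.ones(len(samples)), sex]
    for b in batches[1:]:
        cols.append(np.array([1.0 if s.batch == b else 0.0 for s in samples]))
    X = np.column_stack(cols)
    if pcs is not None:
        X = np.column_stack([X, pcs])
    return X


def run_study(config: SimConfig, q_top: float = 0.05, n_pcs: int = 3,
              alpha: float = 0.05) -> dict:
    """Run the whole pipeline on one synthetic study; returns a result dict
    with every intermediate a test or report might need."""
    mcfg = MergeConfig()
    qcfg = QcConfig()

    truth = simulate_truth(config)
    callsets = simulate_callsets(truth, config)
    records = [r for recs in callsets.values() for r in recs]
    merged = merge_callsets(records, mcfg)
    kept, removed = filter_loci(merged, qcfg)

    # founder genotypes keep only the locus-level QUAL/length filters; the
    # call-rate/MAF filters belong to the genotyped F2 matrix downstream
    match = match_loci_to_truth(kept, truth, mcfg.breakpoint_distance)
    founder_gm = simulate_founder_genotypes(kept, match, truth, config)

    # population genetics on founders
    labels = np.array([s.breed for s in founder_gm.samples])
    fst = weir_cockerham_fst(founder_gm, labels)
    top_idx, fst_threshold = top_quantile_loci(fst, q_top)
    top_by_type = pd.Series(
        [founder_gm.loci[i].svtype for i in top_idx]).value_counts().to_dict()
    founder_pca = grm_pca(founder_gm, 2)

    annotations = annotate_loci(kept, truth.gene_model)
    position_summary = summarize_positions(annotations)

    reference = make_reference_db(truth, config)
    novel_flags, novel_counts = compare_to_database(kept, reference, mcfg)

    # breed-differential screen on the purebred-A founders vs all breed-B
    a_ids = [s.sample for s in founder_gm.samples
             if s.breed == config.breed_a and s.purebred]
    b_ids = [s.sample for s in founder_gm.samples if s.breed == config.breed_b]
    cand_idx, screen_table = screen_differential_loci(
        founder_gm, a_ids, b_ids, ScreenConfig())
    candidates = [founder_gm.loci[i] for i in cand_idx]

    # offspring
    f2_dosages, f2_samples, pedigree = simulate_f2(truth, config)
    cand_match = match_loci_to_truth(candidates, truth,
                                     mcfg.breakpoint_distance)
    ev_idx = sorted({t for t in cand_match if t is not None})
    evidence = simulate_offspring_evidence(truth, f2_dosages, f2_samples,
                                           config, loci_idx=ev_idx)
    f2_gm, geno_report = genotype_candidates_in_offspring(
        candidates, evidence, f2_samples, mcfg.breakpoint_distance)
    f2_gm, f2_qc = filter_genotype_matrix(f2_gm, qcfg)

    # trait: polygenic background g ~ N(0, sigma2_g K) with K defaulting to
    # the allele-sharing kinship of the true genome-wide dosages
    phenotypes, pheno_truth = simulate_phenotypes(truth, f2_dosages,
                                                  f2_samples, None, config)

    # EMMAX-style association
    K_hat = kinship(f2_gm, "IBS").values
    pcs = grm_pca(f2_gm, n_pcs).axes
    X = design_matrix(f2_gm.samples, pcs)
    order = [phenotypes.sample_ids.index(s) for s in f2_gm.sample_ids]
    y = phenotypes.trait_values(config.trait_name)[order]
    vc = fit_null_reml(y, X, K_hat)
    assoc = mlm_association(f2_gm, y, X, vc, alpha=alpha)

    # where did the planted causal loci land?
    assoc_match = match_loci_to_truth(f2_gm.loci, truth,
                                      mcfg.breakpoint_distance)
    causal_rows = [i for i, t in enumerate(assoc_match)
                   if t is not None and truth.loci[t].causal]
    pvals = assoc["p_value"].to_numpy()
    order_p = np.argsort(np.where(np.isnan(pvals), np.inf, pvals))
    ranks = np.empty(len(pvals), dtype=int)
    ranks[order_p] = np.arange(1, len(pvals) + 1)
    causal_ranks = [int(ranks[i]) for i in causal_rows]

    return {
        "truth": truth,
        "n_records": len(records),
        "merged": merged,
        "kept": kept,
        "removed": removed,
        "founder_gm": founder_gm,
        "fst": fst,
        "fst_top_idx": top_idx,
        "fst_threshold": fst_threshold,
        "fst_top_by_type": top_by_type,
        "founder_pca": founder_pca,
        "annotations": annotations,
        "position_summary": position_summary,
        "novel_flags": novel_flags,
        "novel_counts": novel_counts,
        "screen_table": screen_table,
        "candidates": candidates,
        "f2_gm": f2_gm,
        "f2_qc": f2_qc,
        "geno_report": geno_report,
        "phenotypes": phenotypes,
        "pheno_truth": pheno_truth,
        "vc": vc,
        "assoc": assoc,
        "causal_ranks": causal_ranks,
    }
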