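"""Generator tests: determinism, placement counts, observation-model
closed forms, Mendelian transmission and the Haldane map."""

import numpy as np
import pytest
from scipy import stats

from svforge import (SimConfig, effect_for_variance_share, merge_callsets,
                     simulate_callsets, simulate_f2, simulate_phenotypes,
                     simulate_truth)
from svforge.simulate import _gamete, _recomb_probs


def noiseless_callers():
    from svforge.simulate import CallerProfile
    span = ("DEL", "DUP", "INV")
    return (CallerProfile("cA", span, sensitivity=1.0, jitter_sd=0.0,
                          jitter_max=0, fp_per_mb=0.0),
            CallerProfile("cM", ("MEI",), sensitivity=1.0, jitter_sd=0.0,
                          jitter_max=0, fp_per_mb=0.0, mei_pass_prob=1.0))


class TestTruth:
    def test_same_seed_same_truth(self):
        cfg = SimConfig.small(3)
        t1, t2 = simulate_truth(cfg), simulate_truth(cfg)
        assert [vars(a) for a in t1.loci] == [vars(b) for b in t2.loci]
        np.testing.assert_array_equal(t1.founder_dosages, t2.founder_dosages)

    def test_requested_counts_exact(self):
        cfg = SimConfig.small(4, n_sv=dict(DEL=200, MEI=50))
        truth = simulate_truth(cfg)
        by_type = {}
        for l in truth.loci:
            by_type[l.svtype] = by_type.get(l.svtype, 0) + 1
        assert by_type == {"DEL": 200, "MEI": 50}

    def test_zero_divergence_means_equal_breed_frequencies(self):
        cfg = SimConfig.small(5, divergence_f=0.0)
        truth = simulate_truth(cfg)
        non_causal = [l for l in truth.loci if not l.causal]
        diffs = [abs(l.p_a - l.p_b) for l in non_causal]
        assert max(diffs) == 0.0

    def test_divergence_parameter_spreads_frequencies(self):
        base = SimConfig.small(6, n_causal=0)
        lo = simulate_truth(base.with_(divergence_f=0.05))
        hi = simulate_truth(base.with_(divergence_f=0.40))
        mean_abs = lambda t: np.mean([abs(l.p_a - l.p_b) for l in t.loci])
        assert mean_abs(lo) < mean_abs(hi)

    def test_founders_match_study_design(self):
        truth = simulate_truth(SimConfig.small(7))
        assert len(truth.founders) == 30
        assert sum(s.purebred for s in truth.founders) == 6
        assert all(s.generation == "F0" for s in truth.founders)


class TestCallsets:
    def test_noiseless_limit_recovers_truth_exactly(self):
        cfg = SimConfig.small(8, callers=noiseless_callers())
        truth = simulate_truth(cfg)
        records = [r for recs in simulate_callsets(truth, cfg).values()
                   for r in recs]
        loci = merge_callsets(records)
        carriers = {(l.chrom, l.start, l.end if l.svtype != "MEI" else l.start,
                     l.svtype)
                    for i, l in enumerate(truth.loci)
                    if (truth.founder_dosages[i] > 0).any()}
        merged = {(l.chrom, l.rep_start, l.rep_end, l.svtype) for l in loci}
        assert merged == carriers

    def test_union_detection_probability(self):
        from svforge.simulate import CallerProfile
        span = ("DEL", "DUP", "INV")
        callers = tuple(CallerProfile(f"c{i}", span, sensitivity=0.7,
                                      jitter_sd=0.0, jitter_max=0,
                                      fp_per_mb=0.0) for i in range(4))
        cfg = SimConfig.small(9, callers=callers,
                              n_sv=dict(DEL=150, DUP=20, INV=20))
        truth = simulate_truth(cfg)
        callsets = simulate_callsets(truth, cfg)
        detected_by_any = set()
        for (caller, sample), recs in callsets.items():
            for r in recs:
                detected_by_any.add((r.chrom, r.start, r.sample))
        trials = hits = 0
        for i, l in enumerate(truth.loci):
            for fi, f in enumerate(truth.founders):
                if truth.founder_dosages[i, fi] > 0:
                    trials += 1
                    hits += (l.chrom, l.start, f.sample) in detected_by_any
        expect = 1 - 0.3 ** 4
        se = np.sqrt(expect * (1 - expect) / trials)
        assert abs(hits / trials - expect) < 4 * se

    def test_false_positive_count_poisson_consistent(self):
        from svforge.simulate import CallerProfile
        lam = 0.5    # per Mb, per caller-sample
        callers = (CallerProfile("c0", ("DEL",), sensitivity=0.0,
                                 jitter_sd=0.0, jitter_max=0, fp_per_mb=lam),)
        cfg = SimConfig.small(10, callers=callers, n_sv=dict(DEL=10))
        truth = simulate_truth(cfg)
        records = [r for recs in simulate_callsets(truth, cfg).values()
                   for r in recs]
        genome_mb = sum(cfg.chrom_lengths.values()) / 1e6
        mean = lam * genome_mb * len(truth.founders)
        assert abs(len(records) - mean) < 4 * np.sqrt(mean)


class TestF2:
    def test_fixed_locus_stays_fixed(self):
        cfg = SimConfig.small(11, n_f2=200)
        truth = simulate_truth(cfg)
        truth.founder_dosages[5] = 0.0
        dos, samples, ped = simulate_f2(truth, cfg)
        assert (dos[5] == 0).all()

    def test_cross_segregates_one_two_one(self):
        cfg = SimConfig.small(12, n_f2=2000)
        truth = simulate_truth(cfg)
        li = 10
        truth.founder_dosages[li, :15] = 0.0
        truth.founder_dosages[li, 15:] = 2.0
        dos, samples, _ = simulate_f2(truth, cfg)
        counts = [int((dos[li] == g).sum()) for g in (0, 1, 2)]
        chi2, p = stats.chisquare(counts, f_exp=[500, 1000, 500])
        assert p > 0.01

    def test_haldane_recombination_fraction(self):
        rng = np.random.default_rng(77)
        hap = np.array([[1, 1], [0, 0]], dtype=np.int8)
        d_morgan = 1_000_000 * 1.0 * 1e-8          # 1 Mb at 1 cM/Mb
        r_expected = 0.5 * (1 - np.exp(-2 * d_morgan))
        r = np.array([0.5, r_expected])
        n = 40_000
        recomb = 0
        for _ in range(n):
            g = _gamete(hap, r, rng)
            recomb += g[0] != g[1]
        se = np.sqrt(r_expected * (1 - r_expected) / n)
        assert abs(recomb / n - r_expected) < 4 * se

    def test_recomb_probs_reset_between_chromosomes(self):
        cfg = SimConfig.small(13)
        truth = simulate_truth(cfg)
        r = _recomb_probs(truth.loci, cfg.recomb_cm_per_mb)
        chrom_starts = [i for i in range(len(truth.loci))
                        if i == 0 or truth.loci[i].chrom != truth.loci[i - 1].chrom]
        assert all(r[i] == 0.5 for i in chrom_starts)
        assert all(r[i] < 0.5 for i in range(len(r)) if i not in chrom_starts)

    def test_mendelian_dosages_are_gamete_sums(self):
        cfg = SimConfig.small(14, n_f2=100)
        truth = simulate_truth(cfg)
        dos, samples, ped = simulate_f2(truth, cfg)
        assert set(np.unique(dos)) <= {0.0, 1.0, 2.0}
        assert len(samples) == 100 and len(ped) == 100


class TestPhenotypes:
    def test_all_effects_zero_gives_constant_trait(self):
        cfg = SimConfig.small(15, n_f2=50, n_causal=0,
                              polygenic_variance=0.0, residual_variance=0.0,
                              sex_effect=0.0, batch_sd=0.0)
        truth = simulate_truth(cfg)
        dos, samples, _ = simulate_f2(truth, cfg)
        with pytest.raises(ValueError, match="distinct"):
            # a constant trait is degenerate by contract
            table, _ = simulate_phenotypes(truth, dos, samples, None, cfg)
            table.trait_values(cfg.trait_name)

    def test_causal_variance_share_realized(self):
        cfg = SimConfig.small(16, n_f2=300)
        truth = simulate_truth(cfg)
        dos, samples, _ = simulate_f2(truth, cfg)
        shares = []
        for k in range(50):
            c = cfg.with_(seed=1000 + k)
            _, rec = simulate_phenotypes(truth, dos, samples, np.eye(300), c)
            shares.append(rec["realized_causal_var"] / rec["realized_total_var"])
        assert abs(np.mean(shares) - 0.15) < 0.03

    def test_permuting_samples_permutes_phenotypes(self):
        cfg = SimConfig.small(17, n_f2=60)
        truth = simulate_truth(cfg)
        dos, samples, _ = simulate_f2(truth, cfg)
        table, _ = simulate_phenotypes(truth, dos, samples, None, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(samples))
        table_p, _ = simulate_phenotypes(
            truth, dos[:, perm], [samples[i] for i in perm], None, cfg)
        y = table.df[cfg.trait_name].to_numpy()
        yp = table_p.df[cfg.trait_name].to_numpy()
        np.testing.assert_allclose(yp, y[perm], atol=1e-10)

    def test_effect_size_solves_variance_share(self):
        beta = effect_for_variance_share(0.15, 0.5, 0.85)
        assert beta ** 2 * 0.5 / (beta ** 2 * 0.5 + 0.85) == \
            pytest.approx(0.15)

    def test_missing_causal_locus_is_an_error(self):
        cfg = SimConfig.small(18, n_f2=20)
        truth = simulate_truth(cfg)
        dos, samples, _ = simulate_f2(truth, cfg)
        with pytest.raises(ValueError, match="causal"):
            simulate_phenotypes(truth, dos[:2], samples, None, cfg)
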