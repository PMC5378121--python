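"""The clade simulator: inversions, trees, loss, hit tables, sequences."""

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

from synterate import (
    SignedPermutation,
    SimulationConfig,
    apply_random_inversion,
    best_bidirectional_hits,
    evolve_gene_orders,
    filter_hits,
    find_exact_repeats,
    goc,
    hky_ml_distance,
    map_to_permutation,
    simulate_aligned_16s,
    simulate_hit_tables,
    simulate_nucleotide_genome,
)
from synterate.features import delta_gc_skew


class TestApplyRandomInversion:
    def test_forced_segment_is_signed_reversal(self):
        perm = SignedPermutation.identity(5)
        assert list(perm.reverse_segment(1, 3)) == [1, -4, -3, -2, 5]

    def test_reversal_is_involution(self):
        perm = SignedPermutation((2, -5, 1, 3, -4))
        assert perm.reverse_segment(1, 3).reverse_segment(1, 3) == perm

    def test_changes_exactly_one_segment(self, rng):
        perm = SignedPermutation.identity(30)
        out = apply_random_inversion(perm, rng)
        changed = [i for i in range(30) if out[i] != perm[i]]
        assert changed == list(range(changed[0], changed[-1] + 1))
        assert all(out[i] == -perm[changed[0] + changed[-1] - i]
                   for i in changed)

    def test_protected_adjacency_never_cut(self, rng):
        perm = SignedPermutation.identity(12)
        protected = {frozenset((3, 4))}
        for _ in range(300):
            out = apply_random_inversion(perm, rng, protected=protected)
            labels = [abs(e) for e in out]
            k = labels.index(3)
            assert labels[(k + 1) % 12] == 4 or labels[k - 1] == 4

    def test_symmetric_endpoints_mirror_about_origin(self, rng):
        """Symmetric inversions put their two cut points at (nearly)
        equal circular distance from the origin."""
        n = 100
        perm = SignedPermutation.identity(n)
        diffs = []
        for _ in range(2000):
            out = apply_random_inversion(perm, rng, symmetric=True,
                                         origin_index=0)
            changed = [i for i in range(n) if out[i] != perm[i]]
            a, b = changed[0], changed[-1] + 1
            dist = lambda s: min(s % n, n - s % n)
            diffs.append(abs(dist(a) - dist(b)))
        assert np.mean(np.array(diffs) <= 1) > 0.99

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            apply_random_inversion(SignedPermutation((1,)), rng)  # too small
        with pytest.raises(ValueError):
            apply_random_inversion(SignedPermutation.identity(5), rng,
                                   symmetric=True)  # origin missing


class TestEvolveGeneOrders:
    def test_zero_rates_leave_tips_identical(self):
        cfg = SimulationConfig(n_species=5, n_genes=50, rate_N=0.0,
                               rate_R=0.0, gene_loss_rate=0.0, seed=3)
        clade = evolve_gene_orders(cfg)
        for sp in clade.species:
            assert clade.orders[sp] == list(range(1, 51))
        for a, b in clade.pairs():
            assert goc(map_to_permutation(clade.ortholog_map(a, b))) == 1.0

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_species=6, n_genes=80, rate_N=200.0,
                               depth=0.05, seed=9)
        c1, c2 = evolve_gene_orders(cfg), evolve_gene_orders(cfg)
        assert c1.orders == c2.orders
        assert c1.events == c2.events
        assert (c1.divergence == c2.divergence).all().all()

    def test_star_tree_pairwise_divergence(self):
        cfg = SimulationConfig(n_species=4, n_genes=30, tree_model="star",
                               depth=0.05, rate_N=0.0, gene_loss_rate=0.0,
                               seed=1)
        clade = evolve_gene_orders(cfg)
        for a, b in clade.pairs():
            assert clade.x(a, b) == pytest.approx(0.1)

    def test_inversion_counts_are_poisson(self):
        """Branch event counts follow Poisson(rate x depth): chi-square
        goodness of fit over 1000 star-tree replicates at alpha=0.01."""
        counts = []
        for seed in range(1000):
            cfg = SimulationConfig(n_species=1, n_genes=25, tree_model="star",
                                   depth=1.0, rate_N=5.0, gene_loss_rate=0.0,
                                   seed=seed)
            clade = evolve_gene_orders(cfg)
            counts.append(clade.events[0]["inversions"])
        counts = np.array(counts)
        edges = [0, 2, 3, 4, 5, 6, 7, 9, np.inf]
        obs = np.array([((counts >= lo) & (counts < hi)).sum()
                        for lo, hi in zip(edges[:-1], edges[1:])])
        probs = np.array([poisson.cdf(hi - 1, 5.0) - poisson.cdf(lo - 1, 5.0)
                          for lo, hi in zip(edges[:-1], edges[1:])])
        stat = chisquare(obs, probs / probs.sum() * obs.sum())
        assert stat.pvalue > 0.01

    def test_mean_inversions_match_rate(self):
        total = 0
        reps, rate, depth = 300, 8.0, 0.5
        for seed in range(reps):
            cfg = SimulationConfig(n_species=1, n_genes=40, tree_model="star",
                                   depth=depth, rate_N=rate,
                                   gene_loss_rate=0.0, seed=2000 + seed)
            total += evolve_gene_orders(cfg).events[0]["inversions"]
        mean = total / reps
        se = np.sqrt(rate * depth / reps)
        assert abs(mean - rate * depth) < 3 * se

    def test_protected_fraction_floors_goc(self):
        """Adjacencies marked protected are never cut, so GOC cannot
        fall below roughly the protected fraction even after heavy
        rearrangement."""
        cfg = SimulationConfig(n_species=6, n_genes=200, depth=0.3,
                               rate_N=3000.0, protected_frac=0.3,
                               gene_loss_rate=0.0, seed=21)
        clade = evolve_gene_orders(cfg)
        gocs = [goc(map_to_permutation(clade.ortholog_map(a, b)))
                for a, b in clade.pairs()]
        assert min(gocs) >= 0.3 - 0.02

    def test_gene_loss_varies_shared_counts(self):
        cfg = SimulationConfig(n_species=6, n_genes=400, depth=0.1,
                               rate_N=100.0, gene_loss_rate=2.0, seed=4)
        clade = evolve_gene_orders(cfg)
        shared = [len(clade.retained[a] & clade.retained[b])
                  for a, b in clade.pairs()]
        assert min(shared) < 400 and len(set(shared)) > 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_species=0)
        with pytest.raises(ValueError):
            SimulationConfig(depth=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_resistant=5, n_species=4)
        with pytest.raises(ValueError):
            SimulationConfig(protected_frac=1.0)


class TestHitTables:
    def test_clean_tables_recover_exact_map(self, small_clade):
        a, b = small_clade.species[0], small_clade.species[3]
        ab, ba = simulate_hit_tables(small_clade, a, b, identity_decay=0.0,
                                     paralog_rate=0.0, rng=0,
                                     identity_noise_sd=0.0)
        omap = best_bidirectional_hits(ab, ba)
        true = small_clade.ortholog_map(a, b)
        assert len(omap) == len(true)

    def test_identity_decay_crosses_filter_threshold(self, small_clade):
        a, b = small_clade.species[0], small_clade.species[1]
        # decay strong enough that identity < 40% at this pair's x
        x = small_clade.x(a, b)
        decay = -np.log(0.30) / x
        ab, _ = simulate_hit_tables(small_clade, a, b, identity_decay=decay,
                                    rng=0, identity_noise_sd=0.0)
        assert filter_hits(ab) == []

    def test_spurious_paralogs_mostly_filtered(self, small_clade):
        """Reciprocal-best filtering removes paralog hits: over
        replicates, the surviving spurious fraction stays below the
        injection rate."""
        a, b = small_clade.species[0], small_clade.species[2]
        true_pairs = set(zip(*[small_clade.ortholog_map(a, b).genes_a,
                               small_clade.ortholog_map(a, b).genes_b]))
        spurious = total = 0
        for rep in range(100):
            ab, ba = simulate_hit_tables(small_clade, a, b, paralog_rate=0.1,
                                         rng=rep)
            omap = best_bidirectional_hits(filter_hits(ab), filter_hits(ba))
            got = set(zip(omap.genes_a, omap.genes_b))
            spurious += len(got - true_pairs)
            total += len(got)
        assert spurious / total < 0.1

    def test_unknown_species(self, small_clade):
        with pytest.raises(KeyError):
            simulate_hit_tables(small_clade, "nope", small_clade.species[0])


class TestNucleotideGenome:
    def test_gc_content_recovered_at_1mb(self):
        seq, _ = simulate_nucleotide_genome(1_000_000, gc=0.67, rng=0)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.67) < 0.01

    def test_zero_skew_amplitude(self):
        seq, _ = simulate_nucleotide_genome(100_000, gc=0.5, skew_amp=0.0,
                                            oric=0, rng=1)
        assert abs(delta_gc_skew(seq, 0)) < 0.02

    def test_planted_skew_recovered(self):
        seq, _ = simulate_nucleotide_genome(1_000_000, gc=0.5, skew_amp=0.1,
                                            oric=250_000, rng=2)
        skew = delta_gc_skew(seq, 250_000)
        assert skew == pytest.approx(0.2, abs=0.02)

    def test_planted_direct_repeat_found(self):
        seq, _ = simulate_nucleotide_genome(
            30_000, planted_repeats=[(500, "direct", 1)], rng=3)
        reps = [r for r in find_exact_repeats(seq, min_length=100)
                if r.length >= 500]
        assert len(reps) == 1

    def test_planted_inverted_repeat_found(self):
        seq, _ = simulate_nucleotide_genome(
            20_000, planted_repeats=[(200, "inverted", 1)], rng=4)
        reps = [r for r in find_exact_repeats(seq, min_length=100)
                if r.orientation == "inverted" and r.length >= 200]
        assert len(reps) == 1

    def test_rrna_annotation(self):
        _, annot = simulate_nucleotide_genome(20_000, rrna_positions=[5000],
                                              rng=5)
        assert annot.n_rrna == 1
        assert annot.genes.iloc[0]["start"] == 5000

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_nucleotide_genome(0)
        with pytest.raises(ValueError):
            simulate_nucleotide_genome(1000, gc=1.5)
        with pytest.raises(ValueError):
            simulate_nucleotide_genome(1000, planted_repeats=[(600, "direct", 1)])


class TestAligned16S:
    def test_zero_divergence_identical(self):
        a, b = simulate_aligned_16s(0.0, length=500, rng=0)
        assert a == b

    def test_difference_fraction_matches_jukes_cantor(self):
        """With kappa=1 and equal frequencies, HKY reduces to JC: the
        expected differing-site fraction is (3/4)(1 - exp(-4x/3))."""
        x = 0.2
        a, b = simulate_aligned_16s(x, kappa=1.0, length=100_000, rng=1)
        observed = np.mean([ca != cb for ca, cb in zip(a, b)])
        expected = 0.75 * (1 - np.exp(-4 * x / 3))
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(observed - expected) < 3 * se

    def test_ml_estimate_recovers_truth(self):
        ests = [hky_ml_distance(*simulate_aligned_16s(0.15, kappa=2.0,
                                                      length=10_000, rng=s),
                                kappa=2.0)
                for s in range(20)]
        assert np.mean(ests) == pytest.approx(0.15, abs=0.01)

    def test_invalid_frequencies(self):
        with pytest.raises(ValueError):
            simulate_aligned_16s(0.1, freqs=[0.5, 0.5, 0.2, 0.2])
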