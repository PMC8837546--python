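"""Burden models, chromosome allocation and the two violation simulators."""

import numpy as np
import pytest

from biallelic.simulators import (
    BurdenModel,
    ChromosomeAllocation,
    CohortPool,
    DonorCatalog,
    allocate_to_chromosomes,
    run_neighbour_resampling,
    run_uniform_permutation,
    sample_chromosome_spectrum,
    sample_total_burden,
    select_representative_pool,
    summarize_tallies,
)
from biallelic.spectra import MutationRecord, compute_spectrum

from conftest import (
    block_toy_genome,
    ct_alphabet_genome,
    ct_alphabet_spectrum,
    single_channel_catalog,
)


class TestBurdenModel:
    def test_gamma_mode_equals_observed_burden(self):
        model = BurdenModel(n_t_obs=10_000)
        mode = (model.shape - 1) / model.rate
        assert mode == pytest.approx(10_000, rel=1e-9)

    def test_gamma_sd_matches_requested(self):
        model = BurdenModel(n_t_obs=10_000, cv=0.05)
        sd = np.sqrt(model.shape) / model.rate
        assert sd == pytest.approx(500.0, rel=1e-9)

    def test_zero_burden_stays_zero(self):
        rng = np.random.default_rng(0)
        assert sample_total_burden(BurdenModel(0), rng) == 0

    def test_invalid_cv(self):
        with pytest.raises(ValueError):
            BurdenModel(100, cv=0.0)

    def test_monte_carlo_moments(self):
        # gamma-Poisson: mean = E[lambda], var = E[lambda] + Var[lambda]
        model = BurdenModel(n_t_obs=10_000, cv=0.05)
        rng = np.random.default_rng(1)
        draws = np.array(
            [sample_total_burden(model, rng) for _ in range(50_000)]
        )
        mean_lam = model.shape / model.rate
        var = mean_lam + model.shape / model.rate**2
        se = np.sqrt(var / len(draws))
        assert abs(draws.mean() - mean_lam) < 3 * se

    def test_monte_carlo_mode_near_observed(self):
        model = BurdenModel(n_t_obs=10_000, cv=0.05)
        rng = np.random.default_rng(2)
        draws = np.array(
            [sample_total_burden(model, rng) for _ in range(50_000)]
        )
        hist, edges = np.histogram(draws, bins=60)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(mode - 10_000) < 2 * draws.std()


class TestChromosomeAllocation:
    def test_single_chromosome_gets_everything(self):
        alloc = ChromosomeAllocation(["chr1"], np.array([50.0]))
        rng = np.random.default_rng(3)
        counts = allocate_to_chromosomes(123, alloc, rng)
        assert counts.tolist() == [123]

    def test_counts_conserved(self):
        alloc = ChromosomeAllocation(
            ["a", "b", "c"], np.array([10.0, 20.0, 5.0])
        )
        rng = np.random.default_rng(4)
        for _ in range(20):
            assert allocate_to_chromosomes(97, alloc, rng).sum() == 97

    def test_dirichlet_multinomial_mean(self):
        # alpha = (100, 1): expected fraction to chrom 1 is 100/101
        alloc = ChromosomeAllocation(["a", "b"], np.array([99.0, 0.0]))
        rng = np.random.default_rng(5)
        n = 50
        fracs = np.array(
            [allocate_to_chromosomes(n, alloc, rng)[0] / n
             for _ in range(20_000)]
        )
        # var of the Dirichlet-multinomial fraction
        a0 = 101.0
        p = 100 / 101
        var = p * (1 - p) * (a0 + n) / (n * (a0 + 1))
        assert abs(fracs.mean() - p) < 3 * np.sqrt(var / len(fracs))

    def test_empty_chromosome_list_rejected(self):
        with pytest.raises(ValueError):
            ChromosomeAllocation([], np.array([]))


class TestChromosomeSpectrum:
    def test_zero_count_chromosome_mean_is_prior(self):
        overall = np.zeros(96)
        overall[:4] = 25.0
        rng = np.random.default_rng(6)
        draws = np.array(
            [
                sample_chromosome_spectrum(np.zeros(96), overall, 100, rng)
                for _ in range(4000)
            ]
        )
        psi = (overall + 1) * (2 / 3) / 100
        expected = psi / psi.sum()
        assert np.allclose(
            draws.mean(axis=0)[:4], expected[:4], atol=0.01
        )

    def test_dominant_channel_mean(self):
        chrom = np.zeros(96)
        chrom[0] = 500.0
        overall = chrom.copy()
        rng = np.random.default_rng(7)
        draws = np.array(
            [
                sample_chromosome_spectrum(chrom, overall, 500, rng)
                for _ in range(2000)
            ]
        )
        psi = (overall + 1) * (2 / 3) / 500
        expected = (chrom[0] + psi[0]) / (chrom + psi).sum()
        assert draws.mean(axis=0)[0] == pytest.approx(expected, abs=0.005)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(8)
        pi = sample_chromosome_spectrum(
            np.ones(96), np.ones(96) * 5, 480, rng
        )
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        rng = np.random.default_rng(9)
        bad = np.zeros(96)
        bad[0] = -1
        with pytest.raises(ValueError):
            sample_chromosome_spectrum(bad, np.ones(96), 10, rng)


def _brute_force_parallel(
    n_loci: int, n_hits: int, replicates: int, seed: int
) -> np.ndarray:
    """Independent oracle: sample allelic positions directly.

    Mimics a single-channel simulation where an already-mutated copy cannot
    be re-hit (its context left the spectrum): each hit lands on a uniformly
    random *unmutated* allelic copy, and a violation is a locus with both
    copies mutated (always parallel).
    """
    rng = np.random.default_rng(seed)
    out = np.empty(replicates)
    for r in range(replicates):
        copies = rng.choice(2 * n_loci, size=n_hits, replace=False)
        loci = copies // 2
        out[r] = len(loci) - len(np.unique(loci))
    return out


class TestUniformPermutation:
    def test_single_mutation_never_violates(self):
        genome = block_toy_genome(np.ones(50, dtype=bool))
        catalog = single_channel_catalog(genome, "ACA", "T", 1, seed=10)
        tallies = run_uniform_permutation(genome=genome, catalog=catalog,
                                          replicates=30, seed=11)
        assert all(t.total == 0 for t in tallies)

    def test_parallel_rate_matches_brute_force_oracle(self):
        # 2,000 identical-context loci, single-channel spectrum
        n_loci, n = 2000, 100
        genome = block_toy_genome(np.ones(n_loci, dtype=bool))
        catalog = single_channel_catalog(genome, "ACA", "T", n, seed=12)
        reps = 400
        tallies = run_uniform_permutation(
            genome=genome, catalog=catalog, replicates=reps, seed=13,
            burden_cv=1e-6,
        )
        sim = np.array([t.parallel for t in tallies])
        oracle = _brute_force_parallel(n_loci, n, 4000, seed=14)
        se = np.sqrt(
            sim.var(ddof=1) / reps + oracle.var(ddof=1) / len(oracle)
        )
        assert abs(sim.mean() - oracle.mean()) < 3 * se
        # single-channel: back/forward impossible (mutated context leaves the
        # spectrum); divergent needs an off-channel hit, which only the tiny
        # pseudocount mass can produce
        assert all(t.back == t.forward == 0 for t in tallies)
        assert np.mean([t.divergent for t in tallies]) < 0.05

    def test_spectrum_fidelity_on_fixed_context_toy(self):
        # simulated hits are spectrally indistinguishable from the catalog
        from biallelic.spectra import TrinucleotideSpectrum, cosine_similarity
        from biallelic.synthetic import generate_catalog

        genome = ct_alphabet_genome(4000, seed=15)
        spectrum = ct_alphabet_spectrum(genome)
        records, _ = generate_catalog(genome, spectrum, 400, seed=16)
        tallies = run_uniform_permutation(
            records, genome, replicates=150, seed=17
        )
        catalog_spec = compute_spectrum(records, genome)
        pooled = summarize_tallies(tallies).pooled_hit_spectrum
        sim = TrinucleotideSpectrum(pooled)
        assert cosine_similarity(sim, catalog_spec) >= 0.999

    def test_conservation_of_burden(self):
        genome = block_toy_genome(np.ones(300, dtype=bool))
        catalog = single_channel_catalog(genome, "ACA", "T", 40, seed=18)
        tallies = run_uniform_permutation(
            genome=genome, catalog=catalog, replicates=50, seed=19
        )
        for t in tallies:
            # parallel+divergent bounded by the sampled burden
            assert t.parallel + t.divergent <= t.n_t_sim

    def test_birthday_scaling_in_burden(self):
        # biallelic count ~ n^2 on a fixed toy
        n_loci = 2000
        genome = block_toy_genome(np.ones(n_loci, dtype=bool))
        means = {}
        for n in (60, 120):
            catalog = single_channel_catalog(genome, "ACA", "T", n, seed=20)
            tallies = run_uniform_permutation(
                genome=genome, catalog=catalog, replicates=600,
                seed=21 + n, burden_cv=1e-6,
            )
            means[n] = np.mean([t.parallel for t in tallies])
        ratio = means[120] / means[60]
        assert ratio == pytest.approx(4.0, abs=1.2)

    def test_empty_catalog_rejected(self):
        genome = block_toy_genome(np.ones(10, dtype=bool))
        with pytest.raises(ValueError):
            run_uniform_permutation([], genome, replicates=1, seed=0)


def _rec(chrom, pos, ref, alt, driver=False, sample="s"):
    return MutationRecord(chrom, pos, ref, (alt,), is_driver=driver,
                          sample_id=sample)


class TestRepresentativePool:
    def _donor(self, genome, sample, histology, positions, alt="T"):
        recs = [
            _rec("chr1", p, genome.base("chr1", p), alt, sample=sample)
            for p in positions
        ]
        return DonorCatalog(sample, histology, recs)

    def test_identical_spectrum_same_histology_included(self, toy_genome):
        target = self._donor(toy_genome, "t", "melanoma", [2, 46])
        donor = self._donor(toy_genome, "d", "melanoma", [2, 46])
        pool = select_representative_pool(target, [donor], toy_genome)
        assert pool.donor_ids == ["d"]
        assert pool.eligible

    def test_disjoint_spectrum_excluded(self, toy_genome):
        target = self._donor(toy_genome, "t", "melanoma", [2, 46])  # A[C>T]A
        donor = self._donor(toy_genome, "d", "melanoma", [22], alt="A")
        pool = select_representative_pool(target, [donor], toy_genome)
        assert pool.records == []
        assert not pool.eligible

    def test_histology_mismatch_excluded(self, toy_genome):
        target = self._donor(toy_genome, "t", "melanoma", [2, 46])
        donor = self._donor(toy_genome, "d", "lung", [2, 46])
        pool = select_representative_pool(target, [donor], toy_genome)
        assert pool.records == []

    def test_pool_below_half_burden_is_ineligible(self, toy_genome):
        # target burden 4 in one channel; same-channel pool of 1 < 0.5 * 4
        target = self._donor(toy_genome, "t", "melanoma", [2])
        target = DonorCatalog("t", "melanoma", target.records * 4)
        donor = self._donor(toy_genome, "d", "melanoma", [46])
        pool = select_representative_pool(target, [donor], toy_genome)
        assert len(pool.records) == 1
        assert not pool.eligible

    def test_drivers_never_pooled(self, toy_genome):
        target = self._donor(toy_genome, "t", "melanoma", [2])
        driver_rec = _rec("chr1", 46, "C", "T", driver=True, sample="d")
        clean_rec = _rec("chr1", 2, "C", "T", sample="d")
        donor = DonorCatalog("d", "melanoma", [driver_rec, clean_rec])
        pool = select_representative_pool(target, [donor], toy_genome)
        assert all(not r.is_driver for r in pool.records)
        assert len(pool.records) == 1


class TestNeighbourResampling:
    def test_disjoint_pool_never_violates(self):
        target = [_rec("chr1", p, "C", "T") for p in (10, 20, 30, 40)]
        pool = CohortPool(
            "t", [_rec("chr1", p, "C", "T", sample="d") for p in
                  (110, 120, 130, 140)], eligible=True,
        )
        tallies = run_neighbour_resampling(target, pool, 50, seed=30)
        assert all(t.biallelic == 0 for t in tallies)

    def test_enumerable_parallel_rate(self):
        # target {p: C>T}, n=2 => allele A keeps 1, allele B draws 1 of 2
        # pool records {p: C>T, q: C>T}: P(parallel) = 1/2
        target = [_rec("chr1", 10, "C", "T"), _rec("chr1", 20, "C", "T")]
        pool = CohortPool(
            "t",
            [_rec("chr1", 10, "C", "T", sample="d"),
             _rec("chr1", 99, "C", "T", sample="d")],
            eligible=True,
        )
        reps = 4000
        tallies = run_neighbour_resampling(target, pool, reps, seed=31)
        rate = np.mean([t.parallel for t in tallies])
        # allele A holds position 10 in half the replicates; pool draw hits
        # position 10 in half: joint 1/4
        se = np.sqrt(0.25 * 0.75 / reps)
        assert abs(rate - 0.25) < 4 * se

    def test_same_alt_is_parallel_different_alt_divergent(self):
        target = [_rec("chr1", 10, "C", "T"), _rec("chr1", 20, "C", "T")]
        pool_par = CohortPool(
            "t", [_rec("chr1", 10, "C", "T", sample="d")], eligible=True
        )
        pool_div = CohortPool(
            "t", [_rec("chr1", 10, "C", "G", sample="d")], eligible=True
        )
        par = summarize_tallies(
            run_neighbour_resampling(target, pool_par, 200, seed=32)
        )
        div = summarize_tallies(
            run_neighbour_resampling(target, pool_div, 200, seed=32)
        )
        assert par.mean["divergent"] == 0
        assert div.mean["parallel"] == 0
        assert par.mean["parallel"] > 0
        assert div.mean["divergent"] > 0

    def test_never_back_or_forward(self):
        target = [_rec("chr1", p, "C", "T") for p in range(10, 90, 10)]
        pool = CohortPool(
            "t",
            [_rec("chr1", p, "C", "T", sample="d") for p in range(10, 90, 10)],
            eligible=True,
        )
        tallies = run_neighbour_resampling(target, pool, 100, seed=33)
        assert all(t.back == 0 and t.forward == 0 for t in tallies)

    def test_indel_identity_rule(self):
        # same position, same inserted sequence -> parallel; different -> divergent
        target = [
            MutationRecord("chr1", 10, "A", ("AT",), vtype="indel"),
            MutationRecord("chr1", 20, "A", ("AG",), vtype="indel"),
        ]
        pool_same = CohortPool(
            "t", [MutationRecord("chr1", 10, "A", ("AT",), vtype="indel",
                                 sample_id="d")], eligible=True,
        )
        pool_diff = CohortPool(
            "t", [MutationRecord("chr1", 10, "A", ("ATT",), vtype="indel",
                                 sample_id="d")], eligible=True,
        )
        same = summarize_tallies(
            run_neighbour_resampling(target, pool_same, 200, seed=34,
                                     vtype="indel")
        )
        diff = summarize_tallies(
            run_neighbour_resampling(target, pool_diff, 200, seed=34,
                                     vtype="indel")
        )
        assert same.mean["divergent"] == 0 and same.mean["parallel"] > 0
        assert diff.mean["parallel"] == 0 and diff.mean["divergent"] > 0

    def test_pool_smaller_than_half_burden_errors(self):
        target = [_rec("chr1", p, "C", "T") for p in (10, 20, 30, 40)]
        pool = CohortPool(
            "t", [_rec("chr1", 99, "C", "T", sample="d")], eligible=True
        )
        with pytest.raises(ValueError, match="pool"):
            run_neighbour_resampling(target, pool, 5, seed=35)

    def test_driver_records_excluded_from_allele_a(self):
        driver = _rec("chr1", 10, "C", "T", driver=True)
        target = [driver] + [_rec("chr1", p, "C", "T") for p in (20, 30)]
        pool = CohortPool(
            "t", [_rec("chr1", 10, "C", "T", sample="d")], eligible=True
        )
        # the only pool record collides with the driver position; since the
        # driver never enters allele A, no violation can arise
        tallies = run_neighbour_resampling(target, pool, 100, seed=36)
        assert all(t.biallelic == 0 for t in tallies)


class TestSummaries:
    def test_all_zero_tallies(self):
        from biallelic.simulators import ViolationTally

        tallies = [ViolationTally(replicate=i) for i in range(5)]
        s = summarize_tallies(tallies)
        assert s.mean["parallel"] == 0
        assert s.fraction_with_violation == 0

    def test_mean_arithmetic(self):
        from biallelic.simulators import ViolationTally

        tallies = [
            ViolationTally(replicate=i, parallel=k)
            for i, k in enumerate((0, 1, 2, 3))
        ]
        assert summarize_tallies(tallies).mean["parallel"] == 1.5

    def test_percentiles_match_sort_based_oracle(self):
        from biallelic.simulators import ViolationTally

        rng = np.random.default_rng(40)
        values = rng.poisson(5, size=400)
        tallies = [
            ViolationTally(replicate=i, parallel=int(v))
            for i, v in enumerate(values)
        ]
        s = summarize_tallies(tallies)
        assert s.q025["parallel"] == pytest.approx(
            np.percentile(values.astype(float), 2.5)
        )
        assert s.q975["parallel"] == pytest.approx(
            np.percentile(values.astype(float), 97.5)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_tallies([])
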