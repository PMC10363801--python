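"""Forward simulator: mutation-selection balance, breeding schemes,
phenotype generation and cohort export."""

import warnings

import numpy as np
import pytest
from scipy import stats

from inbreedkit.genome import Chromosome, GenomeConfig, MutationModel
from inbreedkit.markers import f_yan
from inbreedkit.pedigree import Pedigree
from inbreedkit.simulate import (
    TraitParams,
    _gamete,
    assign_phenotypes,
    breed_schemes,
    competitive_fitness,
    export_cohort,
    simulate_base_population,
)

from conftest import NEUTRAL, small_genome


class TestBasePopulation:
    def test_no_mutation_no_markers_means_no_variation(self):
        pop = simulate_base_population(
            small_genome(), NEUTRAL, n=20, generations=10, seed=0
        )
        assert pop.n_loci == 0

    def test_recessive_lethals_never_survive_as_homozygotes(self):
        lethal_only = MutationModel(u=0.0, lethal_rate=0.06)
        pop = simulate_base_population(
            small_genome(male_recombination=False), lethal_only,
            n=100, generations=30, seed=5,
        )
        lethal = pop.loci_s >= 1.0
        if lethal.any():
            d = pop.dosages()[:, lethal]
            assert not np.any(d == 2)

    def test_mean_heterozygous_count_matches_single_locus_recursion(self):
        """Mean heterozygous deleterious variants per individual vs a
        Wright-Fisher single-locus chain (selection then binomial sampling)
        iterated to generation 50 and integrated over the s distribution."""
        n, gens, u = 100, 50, 0.06
        mean_s, h_const = 0.2, 0.25
        mut = MutationModel(
            u=u, mean_s=mean_s, lethal_rate=0.0,
            h_rule=lambda s: np.full_like(np.asarray(s, dtype=float), h_const),
        )

        def oracle(n2):
            grid = 40
            qs_grid = (np.arange(grid) + 0.5) / grid
            trunc_mass = 1.0 - np.exp(-1.0 / mean_s)
            svals = -mean_s * np.log(1.0 - qs_grid * trunc_mass)
            k = np.arange(n2 + 1)
            total = 0.0
            for s in svals:
                q = k / n2
                p = 1.0 - q
                wbar = p * p + 2 * p * q * (1 - h_const * s) + q * q * (1 - s)
                q_sel = (q * q * (1 - s) + p * q * (1 - h_const * s)) / wbar
                T = stats.binom.pmf(k[None, :], n2, q_sel[:, None])
                v = np.zeros(n2 + 1)
                v[1] = 1.0
                acc = 0.0
                for _ in range(gens):
                    qv = k / n2
                    acc += float(np.sum(v * 2 * qv * (1 - qv)))
                    v = v @ T
                total += n2 * u * acc / len(svals)
            return total

        expected = oracle(2 * n)
        rng = np.random.default_rng(31)
        genome = small_genome(morgans=0.55, male_recombination=False)
        reps = []
        for _ in range(8):
            pop = simulate_base_population(
                genome, mut, n=n, generations=gens,
                seed=int(rng.integers(2**31)),
            )
            sel = pop.loci_s > 0
            reps.append(float((pop.dosages()[:, sel] == 1).sum(axis=1).mean()))
        reps = np.asarray(reps)
        assert abs(reps.mean() - expected) <= 2 * reps.std(ddof=1)

    def test_neutral_frequencies_are_a_martingale(self):
        """With selection disabled, the mean allele-frequency change across
        replicate populations is zero within 3 SE."""
        rng = np.random.default_rng(17)
        genome = small_genome(n_chrom=4, morgans=1.0)
        deltas = []
        for _ in range(40):
            pop = simulate_base_population(
                genome, NEUTRAL, n=50, generations=0,
                seed=int(rng.integers(2**31)), n_marker_loci=100,
            )
            before = pop.allele_frequencies()
            # one generation of random mating, stepped manually so that
            # fixed and lost loci stay in the frequency average
            slices = pop.chrom_slices()
            maps = np.asarray(
                [c.map_length_morgans for c in genome.chromosomes]
            )
            males = np.flatnonzero(pop.sex)
            females = np.flatnonzero(~pop.sex)
            H = pop.haplotypes
            new = np.empty_like(H)
            for i in range(pop.n_individuals):
                mom = females[rng.integers(females.size)]
                dad = males[rng.integers(males.size)]
                new[2 * i] = _gamete(
                    H[2 * mom], H[2 * mom + 1], pop.loci_pos_m, slices, maps,
                    True, rng,
                )
                new[2 * i + 1] = _gamete(
                    H[2 * dad], H[2 * dad + 1], pop.loci_pos_m, slices, maps,
                    True, rng,
                )
            deltas.append(float((new.mean(axis=0) - before).mean()))
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean()) <= 3 * se + 1e-4

    def test_invalid_census_or_generations_rejected(self):
        with pytest.raises(ValueError):
            simulate_base_population(small_genome(), NEUTRAL, n=0, generations=1)
        with pytest.raises(ValueError):
            simulate_base_population(small_genome(), NEUTRAL, n=21, generations=1)
        with pytest.raises(ValueError):
            simulate_base_population(small_genome(), NEUTRAL, n=10, generations=-1)

    def test_reproducible_given_seed(self):
        a = simulate_base_population(
            small_genome(), NEUTRAL, n=20, generations=5, seed=9,
            n_marker_loci=200,
        )
        b = simulate_base_population(
            small_genome(), NEUTRAL, n=20, generations=5, seed=9,
            n_marker_loci=200,
        )
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.loci_pos_bp, b.loci_pos_bp)


@pytest.fixture(scope="module")
def schemes(neutral_base):
    return breed_schemes(neutral_base, 3, seed=123)


@pytest.fixture(scope="module")
def mutation_free_cohorts(neutral_base):
    noninbred, inbred, _ = breed_schemes(neutral_base, 4, seed=7)
    return noninbred, inbred


class TestBreedingSchemes:
    def test_noninbred_adults_have_zero_pedigree_f(self, schemes):
        noninbred, _, frame = schemes
        ped = Pedigree.from_frame(frame)
        for male, female in noninbred.pair_indices:
            for idx in (male, female):
                assert ped.inbreeding(noninbred.population.ids[idx]) == 0

    def test_noninbred_adults_are_pairwise_unrelated(self, schemes):
        noninbred, _, frame = schemes
        ped = Pedigree.from_frame(frame)
        ids = [
            noninbred.population.ids[i]
            for pair in noninbred.pair_indices
            for i in pair
        ]
        for a in ids:
            for b in ids:
                if a != b:
                    assert ped.kinship(a, b) == 0

    def test_inbred_adults_have_quarter_pedigree_f(self, schemes):
        _, inbred, frame = schemes
        ped = Pedigree.from_frame(frame)
        for male, female in inbred.pair_indices:
            for idx in (male, female):
                assert float(ped.inbreeding(inbred.population.ids[idx])) == 0.25

    def test_progeny_of_inbred_pair_would_have_f_three_eighths(self, schemes):
        _, inbred, frame = schemes
        ped = Pedigree.from_frame(frame)
        male, female = inbred.pair_indices[0]
        kin = ped.kinship(
            inbred.population.ids[male], inbred.population.ids[female]
        )
        assert float(kin) == 0.375

    def test_base_too_small_rejected(self):
        tiny = simulate_base_population(
            small_genome(), NEUTRAL, n=10, generations=0, seed=1,
            n_marker_loci=50,
        )
        with pytest.raises(ValueError):
            breed_schemes(tiny, 4, seed=1)

    def test_realized_full_sib_sharing_averages_one_half(self):
        """Gene-drop with uniquely labelled founder haplotypes: realized
        genome sharing between full sibs is 0.5 within 3 SE over 250
        families (matching the pedigree expectation 2 x 1/4)."""
        rng = np.random.default_rng(55)
        genome = small_genome()  # 2 x 0.5 Morgan, both sexes recombine
        n_loci = 1500
        pos_bp = np.sort(rng.choice(30_000_000, size=n_loci, replace=False))
        chrom = np.repeat([0, 1], n_loci // 2)
        pos_m = 0.5 * (pos_bp / 30_000_000)
        slices = [(0, n_loci // 2), (n_loci // 2, n_loci)]
        maps = np.asarray([0.5, 0.5])
        sharing = []
        for _ in range(250):
            # four founder haplotypes labelled 0..3
            dad = (np.full(n_loci, 0, dtype=np.uint8),
                   np.full(n_loci, 1, dtype=np.uint8))
            mom = (np.full(n_loci, 2, dtype=np.uint8),
                   np.full(n_loci, 3, dtype=np.uint8))
            sibs = []
            for _k in range(2):
                egg = _gamete(mom[0], mom[1], pos_m, slices, maps, True, rng)
                sperm = _gamete(dad[0], dad[1], pos_m, slices, maps, True, rng)
                sibs.append((egg, sperm))
            (a1, a2), (b1, b2) = sibs
            ibd = sum(
                np.mean(x == y) for x in (a1, a2) for y in (b1, b2)
            ) / 4.0
            sharing.append(2 * ibd)
        sharing = np.asarray(sharing)
        se = sharing.std(ddof=1) / np.sqrt(sharing.size)
        assert abs(sharing.mean() - 0.5) <= 3 * se

    def test_cohort_mean_f_yan_approximates_minus_one_over_two_n(
        self, neutral_base
    ):
        """A random-mating cohort of n individuals drawn from a large base,
        measured against its own sample frequencies, has mean F_YAN about
        -1/(2n) (slightly negative from the heterozygote excess)."""
        rng = np.random.default_rng(99)
        pop = neutral_base
        slices = pop.chrom_slices()
        maps = np.asarray(
            [c.map_length_morgans for c in pop.genome.chromosomes]
        )
        males = np.flatnonzero(pop.sex)
        females = np.flatnonzero(~pop.sex)
        n_cohort = 50
        means = []
        for _rep in range(12):
            rows = np.empty((n_cohort, pop.n_loci), dtype=np.int16)
            for i in range(n_cohort):
                mom = females[rng.integers(females.size)]
                dad = males[rng.integers(males.size)]
                egg = _gamete(
                    pop.haplotypes[2 * mom], pop.haplotypes[2 * mom + 1],
                    pop.loci_pos_m, slices, maps, True, rng,
                )
                sperm = _gamete(
                    pop.haplotypes[2 * dad], pop.haplotypes[2 * dad + 1],
                    pop.loci_pos_m, slices, maps, True, rng,
                )
                rows[i] = egg.astype(np.int16) + sperm.astype(np.int16)
            means.append(float(f_yan(rows.astype(float)).mean()))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - (-1 / (2 * n_cohort))) <= 3 * se


class TestPhenotypes:
    def test_no_load_and_no_noise_means_no_depression(self, mutation_free_cohorts):
        noninbred, inbred = mutation_free_cohorts
        params = TraitParams(kappa=64.0, sigma_env=0.0)
        values = {}
        for cohort in (noninbred, inbred):
            recs = assign_phenotypes(cohort, params, seed=3)
            values[cohort.scheme] = [r.p for r in recs]
        # all viabilities are 1: lambda identical across schemes
        pooled = values["noninbred"] + values["inbred"]
        assert np.mean(values["noninbred"]) == pytest.approx(
            np.mean(values["inbred"]), rel=0.2
        )
        # and the fitted slope on pedigree F is consistent with zero
        f = [0.0] * 4 + [0.25] * 4
        logp = np.log(values["noninbred"] + values["inbred"])
        from inbreedkit.regression import id_regression

        res = id_regression(f, logp, n_boot=0, n_perm=0)
        assert abs(res.slope) <= 3 * res.se + 1e-9

    def test_competitive_fitness_ratio(self):
        assert competitive_fitness(90, 44) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            competitive_fitness(-1, 4)

    def test_w_attached_to_designate_with_eight_contributors(
        self, mutation_free_cohorts
    ):
        noninbred, _ = mutation_free_cohorts
        recs = assign_phenotypes(noninbred, TraitParams(), group_size=4, seed=5)
        designates = [r for r in recs if r.sequenced_designate]
        others = [r for r in recs if not r.sequenced_designate]
        assert len(designates) == 1 and len(others) == 3
        assert designates[0].w is not None
        assert len(designates[0].contributing_parent_ids) == 8
        assert all(r.w is None for r in others)
        assert all(r.p >= 0 for r in recs)

    def test_group_size_must_divide_pairs(self, mutation_free_cohorts):
        noninbred, _ = mutation_free_cohorts
        with pytest.raises(ValueError):
            assign_phenotypes(noninbred, TraitParams(), group_size=3, seed=1)

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            TraitParams(kappa=-5.0)


class TestPartialGenotypingLink:
    def test_male_only_trait_capture_fraction(self):
        """Regressing the pair-mean log viability (the productivity driver)
        on the male's alone gives the design capture fraction: exactly 1/2
        for unrelated mates; elevated above 1/2 — though below the
        genome-sharing ceiling 7/8, because an inbred proband's variance is
        inflated by (1 + F) — for full-sib mates."""
        rng = np.random.default_rng(66)
        from conftest import MILD_MUTATION

        genome = small_genome(morgans=0.55, male_recombination=False)

        def fraction(pairs_lv):
            # each entry is one replicate's list of (male, pair-mean) log
            # viabilities; center within replicates so that shared base-load
            # variation does not inflate the covariance
            male = np.concatenate(
                [np.asarray([m for m, _p in rep]) - np.mean([m for m, _p in rep])
                 for rep in pairs_lv]
            )
            pair = np.concatenate(
                [np.asarray([p for _m, p in rep]) - np.mean([p for _m, p in rep])
                 for rep in pairs_lv]
            )
            fc = male - male.mean()
            slope = float(fc @ (pair - pair.mean())) / float(fc @ fc)
            resid = pair - pair.mean() - slope * fc
            se = float(
                np.sqrt((resid @ resid) / (male.size - 2) / float(fc @ fc))
            )
            return slope, se

        ni_vals, ib_vals = [], []
        for _ in range(12):
            base = simulate_base_population(
                genome, MILD_MUTATION, n=200, generations=60,
                seed=int(rng.integers(2**31)),
            )
            noninbred, inbred, _ = breed_schemes(
                base, 16, seed=int(rng.integers(2**31))
            )
            for cohort, acc in ((noninbred, ni_vals), (inbred, ib_vals)):
                lv = cohort.population.log_viability()
                acc.append(
                    [(lv[m], 0.5 * (lv[m] + lv[f]))
                     for m, f in cohort.pair_indices]
                )
        slope_ni, se_ni = fraction(ni_vals)
        slope_ib, se_ib = fraction(ib_vals)
        assert slope_ni == pytest.approx(0.5, abs=2 * se_ni)
        assert slope_ib > slope_ni + 2 * np.hypot(se_ni, se_ib)
        assert slope_ib < 1.0


class TestExport:
    def test_seventeen_plus_seventeen_sequenced_males(self):
        base = simulate_base_population(
            small_genome(male_recombination=False), NEUTRAL, n=700,
            generations=0, seed=2, n_marker_loci=400,
        )
        noninbred, inbred, _ = breed_schemes(base, 68, seed=3)
        X, panel, samples, groups, pair_ids = export_cohort(
            [noninbred, inbred], n_sequenced_per_scheme=17, seed=4
        )
        assert X.shape[0] == 34
        assert groups.count("noninbred") == 17
        assert groups.count("inbred") == 17
        assert panel.n_snps == X.shape[1]

    def test_density_request_capped_with_warning(self, neutral_base):
        noninbred, inbred, _ = breed_schemes(neutral_base, 4, seed=11)
        with pytest.warns(UserWarning, match="segregate"):
            X, panel, samples, groups, pair_ids = export_cohort(
                [noninbred, inbred], n_sequenced_per_scheme=1,
                marker_count=10**7, seed=5,
            )
        assert panel.n_snps == X.shape[1]

    def test_round_trip_dosages_preserved(self, neutral_base, tmp_path):
        from inbreedkit.io import read_vcf, write_vcf

        noninbred, inbred, _ = breed_schemes(neutral_base, 4, seed=13)
        X, panel, samples, groups, pair_ids = export_cohort(
            [noninbred, inbred], n_sequenced_per_scheme=1, marker_count=150,
            seed=6,
        )
        path = tmp_path / "cohort.vcf"
        write_vcf(path, X, panel.chrom, panel.pos, samples)
        X2, chrom2, pos2, samples2, skipped = read_vcf(path)
        assert samples2 == samples
        assert skipped == 0
        np.testing.assert_array_equal(X2, X)

    def test_zero_marker_request_rejected(self, neutral_base):
        noninbred, inbred, _ = breed_schemes(neutral_base, 4, seed=15)
        with pytest.raises(ValueError):
            export_cohort([noninbred], n_sequenced_per_scheme=1, marker_count=0)
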