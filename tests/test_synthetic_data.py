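"""Tests of the synthetic-data generators against closed-form expectations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ervpop.core import Demography, ErvConstruct
from ervpop.synthetic_data import (
    default_construct,
    make_case_control,
    make_erv_genome,
    make_methylation_track,
    neutral_alignment,
    simulate_ltr_pairs,
    simulate_population,
)
from ervpop.wright_fisher import final_allele_counts
from ervpop import popgen


class TestMakeErvGenome:
    def test_planted_tsd_is_duplicated_target_site(self):
        construct = ErvConstruct(ltr_seq="ACGTACGTAC", internal_seq="G" * 100, tsd_len=6)
        seq, truth = make_erv_genome(2000, construct, 700, seed=0, target_site="TAGTTA")
        assert truth.tsd == "TAGTTA"
        # the TSD flanks the element on both sides
        assert seq[truth.start - 6 : truth.start] == "TAGTTA"
        assert seq[truth.end : truth.end + 6] == "TAGTTA"

    def test_truth_coordinates_slice_out_planted_parts(self):
        construct = default_construct(3, ltr_len=300, internal_len=2000)
        seq, truth = make_erv_genome(10_000, construct, 4000, seed=1)
        assert seq[slice(*truth.ltr5)] == construct.ltr_seq
        assert seq[slice(*truth.ltr3)] == construct.ltr_seq
        assert seq[slice(*truth.internal)] == construct.internal_seq

    def test_zero_tsd_means_no_duplication(self):
        construct = ErvConstruct(ltr_seq="A" * 20, internal_seq="C" * 50, tsd_len=0)
        seq, truth = make_erv_genome(500, construct, 100, seed=2)
        assert truth.tsd is None
        assert len(seq) == 500 + construct.length

    @given(
        genome_length=st.integers(200, 2000),
        ltr_len=st.integers(10, 50),
        internal_len=st.integers(30, 200),
        tsd_len=st.integers(0, 8),
    )
    def test_length_bookkeeping(self, genome_length, ltr_len, internal_len, tsd_len):
        construct = ErvConstruct(
            ltr_seq="A" * ltr_len, internal_seq="C" * internal_len, tsd_len=tsd_len
        )
        seq, truth = make_erv_genome(genome_length, construct, 50, seed=0)
        assert len(seq) == genome_length + 2 * ltr_len + internal_len + tsd_len
        assert truth.length == construct.length

    def test_position_out_of_range_raises(self):
        construct = ErvConstruct(ltr_seq="A" * 10, internal_seq="C" * 30, tsd_len=6)
        with pytest.raises(ValueError):
            make_erv_genome(100, construct, 99, seed=0)


class TestSimulatePopulation:
    DEM = Demography.constant(300)

    def test_insertion_at_present_leaves_ltrs_identical_and_no_private_sites(self):
        # at T=0 the insertion just arose, so exactly one carrier copy exists
        hapset, truth = simulate_population(
            self.DEM, 0, 1e-4, 5000, 400, 8, seed=1, n_carriers=1
        )
        assert all(a == b for a, b in truth.ltr_pairs)
        assert truth.mutation_positions.size == 0

    def test_zero_mutation_rate_gives_identical_carriers(self):
        hapset, truth = simulate_population(
            self.DEM, 500, 0.0, 5000, 400, 8, seed=2, n_carriers=5
        )
        carriers = [
            s for s, n in zip(hapset.seqs, hapset.names) if hapset.labels[n] == "carrier"
        ]
        assert len(set(carriers)) == 1

    def test_loss_is_a_status_not_an_exception(self):
        # a single copy in a large population is almost always lost
        lost = 0
        for seed in range(20):
            _, truth = simulate_population(
                Demography.constant(2000), 400, 1e-8, 1000, 100, 4, seed=seed
            )
            lost += not truth.survived
        assert lost > 0

    def test_carrier_flags_match_labels(self):
        hapset, truth = simulate_population(
            self.DEM, 100, 1e-6, 2000, 200, 10, seed=3, n_carriers=6
        )
        for name, flag in zip(hapset.names, truth.carrier_flags):
            assert (hapset.labels[name] == "carrier") == flag

    def test_ltr_divergence_matches_molecular_clock(self):
        # mean per-site 5'-3' LTR distance across carriers ~ 2*mu*T
        t_ins, mu, ltr_len = 800, 2e-5, 500
        dists = []
        for seed in range(60):
            _, truth = simulate_population(
                self.DEM, t_ins, mu, 1000, ltr_len, 4, seed=seed, n_carriers=2
            )
            for a, b in truth.ltr_pairs:
                dists.append(sum(x != y for x, y in zip(a, b)) / ltr_len)
        expected = 2 * mu * t_ins
        assert np.mean(dists) == pytest.approx(expected, rel=0.25)


class TestWrightFisherInvariants:
    def test_neutral_fixation_probability_is_one_over_2n(self):
        n_dip, reps = 100, 50_000
        rng = np.random.default_rng(77)
        counts = final_allele_counts(Demography.constant(n_dip), 4000, reps, rng)
        assert np.all((counts == 0) | (counts == 2 * n_dip))  # all absorbed by 20N gens
        p_fix = (counts == 2 * n_dip).mean()
        expect = 1 / (2 * n_dip)
        se = np.sqrt(expect * (1 - expect) / reps)
        assert abs(p_fix - expect) < 3 * se

    @pytest.mark.parametrize("t", [10, 50])
    def test_heterozygosity_decays_by_one_over_2n_per_generation(self, t):
        n_dip, reps = 100, 10_000
        rng = np.random.default_rng(5)
        counts = final_allele_counts(
            Demography.constant(n_dip), t, reps, rng, init_copies=n_dip
        )
        p = counts / (2 * n_dip)
        het = np.mean(2 * p * (1 - p))
        expected = 0.5 * (1 - 1 / (2 * n_dip)) ** t
        assert het == pytest.approx(expected, rel=0.05)


class TestNeutralAlignment:
    def test_pairwise_diversity_matches_theta(self, rng):
        pis = [
            popgen.nucleotide_diversity(
                neutral_alignment(10, 2000, 0.005, np.random.default_rng(s))
            )
            for s in range(300)
        ]
        assert np.mean(pis) == pytest.approx(0.005, rel=0.1)


class TestMakeCaseControl:
    def test_zero_causal_frequency_means_no_cases(self):
        _, phenotypes = make_case_control(200, 50, 10, 0.0, seed=0)
        assert phenotypes.sum() == 0

    def test_dominant_prevalence_matches_hardy_weinberg(self):
        # 1 - (1-q)^2 at q=0.1363 is 0.254, the observed trait prevalence
        q = 0.1363
        prevalences = [
            make_case_control(260, 5, 2, q, seed=s)[1].mean() for s in range(200)
        ]
        assert np.mean(prevalences) == pytest.approx(1 - (1 - q) ** 2, abs=0.01)

    def test_null_dataset_phenotype_is_independent_of_genotype(self):
        genotypes, phenotypes = make_case_control(500, 40, None, 0.3, seed=1)
        assert 0 < phenotypes.sum() < 500
        # correlation between phenotype and any site stays small on average
        cors = [
            abs(np.corrcoef(genotypes[:, j], phenotypes)[0, 1]) for j in range(40)
        ]
        assert np.mean(cors) < 0.1

    def test_genotypes_are_hardy_weinberg_counts(self):
        genotypes, _ = make_case_control(2000, 3, 1, 0.4, seed=2)
        assert set(np.unique(genotypes)) <= {0, 1, 2}
        assert genotypes[:, 1].mean() / 2 == pytest.approx(0.4, abs=0.03)


class TestMakeMethylationTrack:
    def _element(self):
        construct = default_construct(0, ltr_len=400, internal_len=3000)
        _, truth = make_erv_genome(12_000, construct, 5000, seed=0)
        return truth

    def test_noiseless_levels_are_exact(self):
        element = self._element()
        track, labels = make_methylation_track(
            400, element, seed=1, body_level=0.9, ltr_level=0.2,
            background_level=0.8, noise_sd=0.0,
        )
        for label, level in (("ltr", 0.2), ("body", 0.9), ("background", 0.8)):
            assert np.all(track.scores[labels == label] == level)

    def test_positions_strictly_increasing_and_scores_bounded(self):
        element = self._element()
        track, _ = make_methylation_track(300, element, seed=2, noise_sd=0.15)
        assert np.all(np.diff(track.positions) > 0)
        assert track.scores.min() >= 0 and track.scores.max() <= 1
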