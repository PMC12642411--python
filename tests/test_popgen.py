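"""Diversity statistics against brute-force oracles and closed forms."""

import numpy as np
import pytest

import oracles
from ervpop.core import HaplotypeSet
from ervpop.popgen import (
    carrier_stats,
    ehh,
    ld_r2,
    nucleotide_diversity,
    segregating_sites,
    sliding_window_stats,
    tajimas_d,
    window_quantile_flags,
)
from ervpop.synthetic_data import neutral_alignment, random_sequence


def random_alignment(rng, n=8, length=60, n_mut=15):
    anc = random_sequence(length, rng)
    seqs = [list(anc) for _ in range(n)]
    for _ in range(n_mut):
        i = rng.integers(n)
        j = rng.integers(length)
        seqs[i][j] = "ACGT"[rng.integers(4)]
    return ["".join(s) for s in seqs]


class TestSegregatingSites:
    def test_identical_haplotypes_have_none(self):
        assert segregating_sites(["ACGT" * 5] * 3) == 0

    def test_single_variable_column(self):
        assert segregating_sites(["ACGT", "ACGA", "ACGA"]) == 1

    def test_gap_columns_skipped_by_default(self):
        assert segregating_sites(["AC-T", "ACGA"]) == 1
        assert segregating_sites(["AC-T", "ACGA"], skip_gap_columns=False) == 1

    def test_matches_bruteforce_on_random_alignments(self, rng):
        for _ in range(100):
            seqs = random_alignment(rng)
            assert segregating_sites(seqs) == oracles.brute_segregating_sites(seqs)


class TestNucleotideDiversity:
    def test_two_haplotypes_one_difference_in_ten(self):
        assert nucleotide_diversity(["AAAAAAAAAA", "AAAAAAAAAC"]) == pytest.approx(0.1)

    def test_identical_haplotypes_have_zero(self):
        assert nucleotide_diversity(["ACGTACGT"] * 5) == 0.0

    def test_matches_bruteforce_pair_loop(self, rng):
        for _ in range(100):
            seqs = random_alignment(rng)
            assert nucleotide_diversity(seqs) == pytest.approx(oracles.brute_pi(seqs))


class TestTajimasD:
    def test_undefined_when_no_segregating_sites(self):
        assert tajimas_d(["ACGT" * 4] * 5) is None

    def test_matches_textbook_formula_on_fixed_toy_input(self):
        seqs = ["AAAA", "AAAC", "AGAC", "AAAA"]
        assert tajimas_d(seqs) == pytest.approx(oracles.brute_tajimas_d(seqs))

    def test_matches_bruteforce_on_random_alignments(self, rng):
        checked = 0
        for _ in range(100):
            seqs = random_alignment(rng)
            expected = oracles.brute_tajimas_d(seqs)
            got = tajimas_d(seqs)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)
                checked += 1
        assert checked > 50

    def test_sign_reflects_frequency_spectrum(self):
        base = "A" * 12
        # all singletons: negative D
        singletons = []
        for i in range(6):
            s = list(base)
            s[2 * i] = "C"
            singletons.append("".join(s))
        d_singletons = tajimas_d(singletons)
        # intermediate-frequency variants: positive D
        half = []
        for i in range(6):
            s = list(base)
            if i < 3:
                for j in range(4):
                    s[j] = "C"
            half.append("".join(s))
        d_half = tajimas_d(half)
        assert d_singletons < 0 < d_half


class TestSlidingWindows:
    def _hapset(self, carrier_seqs, noncarrier_seqs):
        names = [f"c{i}" for i in range(len(carrier_seqs))] + [
            f"n{i}" for i in range(len(noncarrier_seqs))
        ]
        labels = {n: ("carrier" if n.startswith("c") else "non-carrier") for n in names}
        return HaplotypeSet(names, carrier_seqs + noncarrier_seqs, labels)

    def test_identical_sequences_give_zero_s_everywhere(self):
        hs = self._hapset(["A" * 12_000] * 4, ["A" * 12_000] * 4)
        table = sliding_window_stats(hs, window=5000)
        assert (table["S"] == 0).all()
        assert len(table) == 6  # 3 windows x 2 classes

    def test_windows_tile_the_alignment(self):
        hs = self._hapset(["ACGT" * 3000] * 3, ["ACGT" * 3000] * 3)
        table = sliding_window_stats(hs, window=5000)
        one = table[table.class_label == "carrier"].sort_values("start")
        assert list(one["start"]) == [0, 5000, 10000]
        assert list(one["end"]) == [5000, 10000, 12000]

    def test_matched_subsampling_with_equal_classes_is_noop(self, rng):
        seqs_a = random_alignment(rng, n=5, length=200, n_mut=40)
        seqs_b = random_alignment(rng, n=5, length=200, n_mut=40)
        hs = self._hapset(seqs_a, seqs_b)
        unmatched = sliding_window_stats(hs, window=100, seed=0)
        matched = sliding_window_stats(hs, window=100, match_sample_sizes=True, seed=0)
        assert unmatched.equals(matched)

    def test_subsampled_s_never_exceeds_full_sample_s(self, rng):
        seqs_a = random_alignment(rng, n=10, length=300, n_mut=60)
        seqs_b = random_alignment(rng, n=4, length=300, n_mut=20)
        hs = self._hapset(seqs_a, seqs_b)
        full = sliding_window_stats(hs, window=100, seed=3)
        sub = sliding_window_stats(hs, window=100, match_sample_sizes=True, seed=3)
        for (_, f), (_, s) in zip(full.iterrows(), sub.iterrows()):
            assert s["S"] <= f["S"]

    def test_young_carrier_class_has_fewer_segregating_sites(self):
        # carriers descend from one recent founder; non-carriers are diverse
        from ervpop.core import Demography
        from ervpop.synthetic_data import simulate_population

        wins = 0
        for seed in range(20):
            hs, _ = simulate_population(
                Demography.constant(300), 50, 1e-6, 10_000, 100, 12,
                seed=seed, n_carriers=6, background_pi=0.002,
            )
            table = sliding_window_stats(hs, window=10_000, seed=seed)
            s = table.set_index("class_label")["S"]
            wins += s["carrier"] < s["non-carrier"]
        assert wins >= 18


class TestEhh:
    def test_equals_one_at_core(self, rng):
        seqs = random_alignment(rng, n=10, length=40, n_mut=20)
        allele = seqs[0][20]
        curve = ehh(seqs, 20, allele)
        assert curve.values[curve.positions == 20][0] == 1.0

    def test_identical_carriers_stay_at_one(self):
        seqs = ["ACGTACGT"] * 4 + ["AAAAAAAA"]
        curve = ehh(seqs, 3, "T")
        assert np.all(curve.values == 1.0)

    def test_matches_bruteforce_pair_enumeration(self, rng):
        for _ in range(30):
            seqs = random_alignment(rng, n=20, length=30, n_mut=25)
            core = 15
            allele = max(set(s[core] for s in seqs), key=[s[core] for s in seqs].count)
            curve = ehh(seqs, core, allele)
            expected = oracles.brute_ehh(seqs, core, allele)
            for pos, val in zip(curve.positions, curve.values):
                assert val == pytest.approx(expected[pos])

    def test_non_increasing_outward(self, rng):
        seqs = random_alignment(rng, n=15, length=50, n_mut=40)
        core = 25
        allele = seqs[0][core]
        curve = ehh(seqs, core, allele)
        right = curve.values[curve.positions >= core]
        left = curve.values[curve.positions <= core][::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)


class TestLdR2:
    def test_perfectly_coupled_sites(self):
        seqs = ["AA", "AA", "CC", "CC"]
        assert ld_r2(seqs, [(0, 1)])[0] == pytest.approx(1.0)

    def test_independent_sites_near_zero(self, rng):
        n = 2000
        col1 = rng.choice(list("AC"), n)
        col2 = rng.choice(list("GT"), n)
        seqs = [a + b for a, b in zip(col1, col2)]
        assert ld_r2(seqs, [(0, 1)])[0] < 0.01

    def test_matches_contingency_table(self, rng):
        for _ in range(50):
            n = 30
            col1 = rng.choice(list("AG"), n)
            col2 = rng.choice(list("CT"), n)
            seqs = [a + b for a, b in zip(col1, col2)]
            if len(set(col1)) < 2 or len(set(col2)) < 2:
                continue
            assert ld_r2(seqs, [(0, 1)])[0] == pytest.approx(
                oracles.brute_r2(seqs, 0, 1)
            )

    def test_monomorphic_site_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(["AA", "AA", "AC"], [(0, 1)])


class TestWindowQuantileFlags:
    def test_constant_statistic_flags_all_at_equality(self):
        flags, summary = window_quantile_flags([1.0] * 25, q=0.95)
        assert flags.all()
        assert summary["quantile"] == 1.0

    def test_single_extreme_value_flagged_at_q99(self):
        values = np.zeros(100)
        values[42] = 10.0
        flags, _ = window_quantile_flags(values, q=0.99)
        assert flags[42] and flags.sum() == 1

    def test_normal_quantile_matches_closed_form(self, rng):
        values = rng.normal(size=10_000)
        _, summary = window_quantile_flags(values, q=0.95)
        assert summary["quantile"] == pytest.approx(1.645, abs=0.1)


class TestCarrierStats:
    @pytest.mark.parametrize(
        "n_case,n_total,expected",
        [(66, 260, (25.4, 2.7)), (0, 100, (0.0, 0.0)), (50, 100, (50.0, 5.0))],
    )
    def test_prevalence_and_binomial_se(self, n_case, n_total, expected):
        assert carrier_stats(n_case, n_total) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            carrier_stats(5, 4)
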