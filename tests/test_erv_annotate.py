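"""Annotation of planted elements: LTR pairs, TSDs, ORFs, presence/absence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from ervpop.core import ErvConstruct
from ervpop.erv_annotate import (
    annotate_element,
    catalog_from_truth,
    find_ltr_pair,
    find_tsd,
    is_complete_element,
    presence_absence,
    scan_orfs,
)
from ervpop.synthetic_data import (
    default_construct,
    make_erv_genome,
    mutate_sequence,
    random_sequence,
)


class TestFindLtrPair:
    def test_clean_planted_pair_recovered_exactly(self):
        construct = default_construct(1, ltr_len=500, internal_len=4000)
        seq, truth = make_erv_genome(15_000, construct, 6000, seed=101, target_site="TAGTTA")
        pair = find_ltr_pair(seq, min_ltr_len=200, max_ltr_len=1000)
        assert pair is not None
        assert pair.ltr5 == truth.ltr5
        assert pair.ltr3 == truth.ltr3
        assert pair.identity == 1.0

    def test_mutated_pair_recovered_within_tolerance(self):
        construct = default_construct(2, ltr_len=600, internal_len=5000)
        seq, truth = make_erv_genome(15_000, construct, 6000, seed=202, target_site="TAGTTA")
        hits = 0
        for seed in range(20):
            mutated = mutate_sequence(seq, 0.01, np.random.default_rng(seed))
            pair = find_ltr_pair(mutated, min_ltr_len=200, max_ltr_len=1200)
            if pair is None:
                continue
            errors = [
                abs(pair.ltr5[0] - truth.ltr5[0]), abs(pair.ltr5[1] - truth.ltr5[1]),
                abs(pair.ltr3[0] - truth.ltr3[0]), abs(pair.ltr3[1] - truth.ltr3[1]),
            ]
            hits += max(errors) <= 5 and pair.identity >= 0.95
        assert hits >= 18

    def test_random_sequence_has_no_repeat(self):
        rng = np.random.default_rng(9)
        assert find_ltr_pair(random_sequence(10_000, rng), min_ltr_len=100) is None

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError):
            find_ltr_pair("ACGT" * 10, min_ltr_len=100)


class TestFindTsd:
    def test_planted_hexamer_recovered(self):
        construct = ErvConstruct(ltr_seq="ACGTACGTAC", internal_seq="G" * 60, tsd_len=6)
        seq, truth = make_erv_genome(1000, construct, 300, seed=3, target_site="TAGTTA")
        assert find_tsd(seq, (truth.start, truth.end)) == "TAGTTA"

    def test_no_duplication_returns_none(self):
        seq = "A" * 20 + "CCCCCCCC" + "T" * 20
        assert find_tsd(seq, (20, 28)) is None

    def test_eight_mer_duplication_found_in_full(self):
        word = "ACGTTGCA"
        seq = "G" * 30 + word + "C" * 40 + word + "G" * 30
        found = find_tsd(seq, (38, 78), min_len=4, max_len=8)
        assert found == word

    def test_insufficient_flank_raises(self):
        with pytest.raises(ValueError):
            find_tsd("ACGTACGT", (2, 6), max_len=8)

    @given(st.integers(0, 200))
    def test_result_is_suffix_of_left_flank_and_prefix_of_right_flank(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(400, rng)
        span = (150, 250)
        tsd = find_tsd(seq, span)
        if tsd is not None:
            assert seq[span[0] - len(tsd) : span[0]] == tsd
            assert seq[span[1] : span[1] + len(tsd)] == tsd


class TestScanOrfs:
    def test_single_forward_orf(self, rng):
        codons = []
        while len(codons) < 300:
            c = random_sequence(3, rng)
            if c not in ("TAA", "TAG", "TGA", "ATG"):
                codons.append(c)
        seq = "CCC" + "ATG" + "".join(codons) + "TAA" + "CCC"
        forward = [o for o in scan_orfs(seq, min_aa=100) if o[1] == "+"]
        assert len(forward) == 1
        assert forward[0][0] == (3, 3 + 3 + 900 + 3)

    def test_reverse_complement_has_same_orf_on_minus_strand(self, rng):
        codons = []
        while len(codons) < 150:
            c = random_sequence(3, rng)
            if c not in ("TAA", "TAG", "TGA", "ATG"):
                codons.append(c)
        seq = "ATG" + "".join(codons) + "TAA"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_orfs(seq, min_aa=100)
        rev = scan_orfs(rc, min_aa=100)
        fwd_plus = [o for o in fwd if o[1] == "+"]
        rev_minus = [o for o in rev if o[1] == "-"]
        assert len(fwd_plus) == 1 and len(rev_minus) == 1
        assert (fwd_plus[0][0][1] - fwd_plus[0][0][0]) == (
            rev_minus[0][0][1] - rev_minus[0][0][0]
        )

    def test_ambiguous_bases_break_orfs(self):
        seq = "ATG" + "GCA" * 200 + "NNN" + "GCA" * 10 + "TAA"
        assert scan_orfs(seq, min_aa=100) == []

    def test_matches_sixframe_bruteforce_on_random_sequences(self, rng):
        for _ in range(50):
            seq = random_sequence(3000, rng)
            got = {(tuple(sp), s, f) for sp, s, f in scan_orfs(seq, min_aa=30)}
            expected = {
                (tuple(sp), s, f) for sp, s, f in oracles.brute_orfs(seq, 30)
            }
            assert got == expected


class TestCompleteElementClassification:
    def test_planted_default_construct_is_complete(self):
        construct = default_construct(4)
        seq, _ = make_erv_genome(25_000, construct, 10_000, seed=404, target_site="TAGTTA")
        element = annotate_element(seq, min_ltr_len=200, max_ltr_len=1200)
        assert element is not None
        assert is_complete_element(element)

    def test_monotone_in_thresholds(self):
        construct = default_construct(5)
        seq, _ = make_erv_genome(25_000, construct, 10_000, seed=505, target_site="TAGTTA")
        element = annotate_element(seq, min_ltr_len=200, max_ltr_len=1200)
        grid_identity = [0.5, 0.8, 0.95, 1.0]
        grid_cov = [0.2, 0.5, 0.7, 0.9]
        previous = None
        for min_id in grid_identity:
            row = [
                is_complete_element(element, min_identity=min_id, min_orf_coverage=c)
                for c in grid_cov
            ]
            # raising either threshold can only remove complete calls
            assert all(not later or earlier for earlier, later in zip(row, row[1:]))
            if previous is not None:
                assert all(
                    not now or before for before, now in zip(previous, row)
                )
            previous = row


class TestPresenceAbsence:
    def _panel(self, pattern, seed=0):
        """Build unaligned haplotypes containing the elements marked 1 in
        ``pattern`` (loci x haplotypes), plus per-locus catalogs."""
        rng = np.random.default_rng(seed)
        n_loci, n_haps = pattern.shape
        catalogs = []
        locus_parts = []
        for locus in range(n_loci):
            construct = default_construct(
                int(rng.integers(1 << 30)), ltr_len=150, internal_len=600,
                n_orfs=1, orf_aa=120,
            )
            genome, truth = make_erv_genome(
                3000, construct, 1500, seed=int(rng.integers(1 << 30)),
                target_site="TAGTTA",
            )
            catalogs.append(
                catalog_from_truth(f"locus_{locus}", genome, truth, anchor_len=300)
            )
            tsd_len = len(truth.tsd)
            occupied = genome
            # the empty site keeps a single copy of the target site
            empty = genome[: truth.start] + genome[truth.end + tsd_len :]
            locus_parts.append((occupied, empty))
        haplotypes = {}
        for h in range(n_haps):
            parts = [
                locus_parts[l][0] if pattern[l, h] else locus_parts[l][1]
                for l in range(n_loci)
            ]
            haplotypes[f"hap_{h}"] = "".join(parts)
        return haplotypes, catalogs

    def test_fixed_and_polymorphic_loci_classified(self):
        pattern = np.zeros((2, 11), dtype=int)
        pattern[0, :] = 1            # fixed locus
        pattern[1, :6] = 1           # polymorphic: 6 of 11 haplotypes
        haplotypes, catalogs = self._panel(pattern, seed=1)
        result = presence_absence(haplotypes, catalogs)
        assert result.locus_call["locus_0"] == "fixed"
        assert result.locus_call["locus_1"] == "polymorphic"

    def test_matrix_matches_planted_truth(self):
        rng = np.random.default_rng(11)
        pattern = (rng.random((5, 8)) < 0.5).astype(int)
        pattern[:, 0] = 1  # every locus present somewhere
        haplotypes, catalogs = self._panel(pattern, seed=2)
        result = presence_absence(haplotypes, catalogs)
        for l in range(5):
            for h in range(8):
                expected = "present" if pattern[l, h] else "absent"
                assert result.matrix.loc[f"locus_{l}", f"hap_{h}"] == expected
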