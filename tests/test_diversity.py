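"""Polymorphism summaries against brute-force oracles and printed arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flaxpopgen.diversity import (
    analysed_sites,
    concatenated_pi,
    haplotype_count,
    locus_diversity,
    nucleotide_diversity,
    percent_reduction,
    segregating_sites,
    watterson_theta,
)
from flaxpopgen.errors import InputError
from flaxpopgen.seq_io import LocusAlignment, SequenceRecord, concatenate
from flaxpopgen.synthetic_data import generate_toy

from .test_seq_io import make_aln


def random_alignment(rng, n, L, gap_rate=0.0):
    arr = rng.choice(list("ACGT"), size=(n, L))
    if gap_rate:
        mask = rng.random((n, L)) < gap_rate
        arr[mask] = "-"
    return make_aln(["".join(row) for row in arr])


# ----------------------------------------------------------------- oracles

def pi_oracle(aln):
    """All-pairs nested-loop nucleotide diversity (independent of the impl)."""
    keep = [
        j
        for j in range(aln.length)
        if all(r.residues[j] in "ACGT" for r in aln.records)
    ]
    n = aln.n
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.records[i].residues, aln.records[j].residues
            total += sum(a[c] != b[c] for c in keep)
    k = total / (n * (n - 1) / 2)
    return k, (k / len(keep) if keep else float("nan"))


def s_oracle(aln):
    keep = [
        j
        for j in range(aln.length)
        if all(r.residues[j] in "ACGT" for r in aln.records)
    ]
    return sum(
        1 for j in keep if len({r.residues[j] for r in aln.records}) > 1
    )


# ----------------------------------------------------------------- tests

class TestAnalysedSites:
    def test_clean_alignment_keeps_all_columns(self):
        aln = make_aln(["ACGT", "ACGA"])
        assert list(analysed_sites(aln)) == [0, 1, 2, 3]

    def test_single_gap_excludes_column(self):
        aln = generate_toy("gap-column")
        assert 3 not in analysed_sites(aln)

    def test_ambiguity_code_excludes_column(self):
        aln = make_aln(["ACRT", "ACGT"])
        assert list(analysed_sites(aln)) == [0, 1, 3]

    def test_matches_bruteforce_on_planted_gaps(self, rng):
        aln = random_alignment(rng, 20, 50, gap_rate=0.02)
        expected = [
            j
            for j in range(50)
            if all(r.residues[j] in "ACGT" for r in aln.records)
        ]
        assert list(analysed_sites(aln)) == expected


class TestSegregatingSites:
    def test_identical_records_give_zero(self):
        assert segregating_sites(generate_toy("all-identical")) == 0

    def test_single_variable_column(self):
        assert segregating_sites(make_aln(["ACGT", "ACGA", "ACGA"])) == 1

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(10):
            aln = random_alignment(rng, 8, 30, gap_rate=0.03)
            assert segregating_sites(aln) == s_oracle(aln)

    def test_requires_two_sequences(self):
        with pytest.raises(InputError):
            segregating_sites(make_aln(["ACGT"]))


class TestHaplotypes:
    def test_identical_sequences_one_haplotype(self):
        assert haplotype_count(generate_toy("all-identical")) == 1

    def test_all_distinct(self):
        aln = make_aln(["AAAA", "AAAT", "AATT", "ATTT"])
        assert haplotype_count(aln) == 4

    def test_gap_column_distinguishes_only_with_gaps_included(self):
        aln = generate_toy("gap-column")
        assert haplotype_count(aln, "include-gaps") == 2
        assert haplotype_count(aln, "exclude-gap-sites") == 1


class TestNucleotideDiversity:
    def test_two_sequences_one_difference(self):
        aln = make_aln(["A" * 100, "A" * 99 + "T"])
        k, pi = nucleotide_diversity(aln)
        assert k == 1.0
        assert pi == pytest.approx(0.01)

    def test_identical_sequences_zero(self):
        _, pi = nucleotide_diversity(generate_toy("all-identical"))
        assert pi == 0.0

    def test_all_gap_columns_undefined(self):
        aln = make_aln(["--", "--"])
        k, pi = nucleotide_diversity(aln)
        assert math.isnan(pi)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 10), st.integers(5, 40), st.integers(0, 10_000))
    def test_matches_all_pairs_oracle(self, n, L, seed):
        aln = random_alignment(np.random.default_rng(seed), n, L, gap_rate=0.05)
        if len(analysed_sites(aln)) == 0:
            return
        k, pi = nucleotide_diversity(aln)
        k_o, pi_o = pi_oracle(aln)
        assert k == pytest.approx(k_o)
        assert pi == pytest.approx(pi_o)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(3, 10), st.integers(5, 40), st.integers(0, 10_000))
    def test_k_bounded_by_segregating_sites(self, n, L, seed):
        aln = random_alignment(np.random.default_rng(seed), n, L)
        k, _ = nucleotide_diversity(aln)
        assert k <= segregating_sites(aln) + 1e-12


class TestWattersonTheta:
    def test_zero_segregating_sites(self):
        assert watterson_theta(0, 10)[0] == 0.0

    def test_pair_equals_s(self):
        assert watterson_theta(7, 2)[0] == 7.0

    def test_known_harmonic_value(self):
        # a1(10) = 2.828968...; 9 / a1 = 3.18137...
        theta, _ = watterson_theta(9, 10)
        assert theta == pytest.approx(3.18137, abs=1e-5)


class TestConcatenatedPi:
    def test_constant_pi_is_preserved(self):
        assert concatenated_pi([(0.01, 100), (0.01, 300)]) == pytest.approx(0.01)

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            concatenated_pi([])

    def test_agrees_with_diversity_of_concatenation(self, small_study):
        per_locus = []
        for aln in small_study.loci.values():
            d = locus_diversity(aln)
            per_locus.append((d.pi, d.L_net))
        concat, _ = concatenate(small_study)
        _, pi_concat = nucleotide_diversity(concat)
        assert concatenated_pi(per_locus) == pytest.approx(pi_concat)


class TestPercentReduction:
    def test_printed_totals_give_27_percent(self):
        assert percent_reduction(0.0097, 0.0071) == 27

    def test_equal_inputs_zero(self):
        assert percent_reduction(0.01, 0.01) == 0

    def test_total_loss_is_100(self):
        assert percent_reduction(0.01, 0.0) == 100

    def test_zero_wild_rejected(self):
        with pytest.raises(InputError):
            percent_reduction(0.0, 0.01)
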