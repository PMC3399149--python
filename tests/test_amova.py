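"""AMOVA variance decomposition, Phi-statistics and permutation tests."""

import numpy as np
import pytest

from flaxpopgen.amova import (
    DistanceMatrix,
    GroupingModel,
    amova_one_level,
    group_specific_fst,
    pairwise_differences,
    pairwise_group_fst,
)
from flaxpopgen.errors import InputError
from flaxpopgen.synthetic_data import generate_toy

from .test_diversity import random_alignment
from .test_seq_io import make_aln


def two_group_model(labels_a, labels_b):
    return GroupingModel("two", {"A": labels_a, "B": labels_b})


class TestPairwiseDifferences:
    def test_identical_records_all_zero(self):
        d = pairwise_differences(generate_toy("all-identical"))
        assert np.all(d.d == 0)

    def test_symmetry_on_random_input(self, rng):
        aln = random_alignment(rng, 8, 40)
        d = pairwise_differences(aln).d
        assert np.array_equal(d, d.T)

    def test_hand_counted_toy(self):
        aln = make_aln(["AAAA", "AAAT", "AATT", "TTTT"])
        d = pairwise_differences(aln).d
        assert d[0, 1] == 1 and d[0, 2] == 2 and d[0, 3] == 4
        assert d[1, 2] == 1 and d[1, 3] == 3 and d[2, 3] == 2


class TestAmovaOneLevel:
    def test_total_differentiation_gives_phi_one(self):
        aln = generate_toy("two-group-divergent")
        dist = pairwise_differences(aln)
        model = two_group_model(["a1", "a2", "a3"], ["b1", "b2", "b3"])
        res = amova_one_level(dist, model, n_perm=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_hand_computed_ssd_decomposition(self):
        """6 samples, 2 groups of 3; distances verified by hand algebra.

        d(a_i, a_j) = 0 within A; d(b_i, b_j) = 2 within B; d(a, b) = 4.
        SSD_total = (3*2 + 9*4)/6 = 7; SSD_within = 0/3 + 3*2/3 = 2;
        SSD_among = 5; sigma_w = 2/4 = 0.5; n' = 3;
        sigma_a = (5/1 - 0.5)/3 = 1.5; phi = 1.5/2 = 0.75.
        """
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.zeros((6, 6))
        for i in range(3):
            for j in range(3, 6):
                d[i, j] = d[j, i] = 4
        for i, j in [(3, 4), (3, 5), (4, 5)]:
            d[i, j] = d[j, i] = 2
        dist = DistanceMatrix(labels, d)
        model = two_group_model(labels[:3], labels[3:])
        res = amova_one_level(dist, model, n_perm=0)
        assert res.ssd_total == pytest.approx(7.0)
        assert res.ssd_within == pytest.approx(2.0)
        assert res.ssd_among == pytest.approx(5.0)
        assert res.sigma_within == pytest.approx(0.5)
        assert res.sigma_among == pytest.approx(1.5)
        assert res.phi_st == pytest.approx(0.75)

    def test_ssd_conservation_on_random_data(self, rng):
        aln = random_alignment(rng, 12, 60)
        dist = pairwise_differences(aln)
        ids = aln.sample_ids
        model = GroupingModel("m", {"A": ids[:4], "B": ids[4:8], "C": ids[8:]})
        res = amova_one_level(dist, model, n_perm=0)
        assert res.ssd_among + res.ssd_within == pytest.approx(res.ssd_total)

    def test_null_calibration_on_exchangeable_data(self):
        """Arbitrary labels on panmictic data: phi near 0, p rarely small."""
        rng = np.random.default_rng(9)
        phis, rejections = [], 0
        trials = 30
        for _ in range(trials):
            aln = random_alignment(rng, 12, 80)
            dist = pairwise_differences(aln)
            ids = aln.sample_ids
            model = two_group_model(ids[:6], ids[6:])
            res = amova_one_level(dist, model, n_perm=200, seed=int(rng.integers(2**31)))
            phis.append(res.phi_st)
            rejections += res.p_perm <= 0.05
        assert abs(np.mean(phis)) < 0.1
        assert rejections <= 6  # ~binomial(30, 0.05) upper tail

    def test_single_group_rejected(self):
        aln = generate_toy("two-group-divergent")
        dist = pairwise_differences(aln)
        with pytest.raises(InputError):
            amova_one_level(dist, GroupingModel("one", {"A": aln.sample_ids}), 0)

    def test_permutation_p_seed_reproducible(self, rng):
        aln = random_alignment(rng, 10, 50)
        dist = pairwise_differences(aln)
        model = two_group_model(aln.sample_ids[:5], aln.sample_ids[5:])
        p1 = amova_one_level(dist, model, 300, seed=4).p_perm
        p2 = amova_one_level(dist, model, 300, seed=4).p_perm
        assert p1 == p2


class TestPairwiseAndGroupSpecificFst:
    def test_two_group_amova_agrees_with_pairwise_entry(self, rng):
        aln = random_alignment(rng, 12, 60)
        dist = pairwise_differences(aln)
        ids = aln.sample_ids
        model = GroupingModel("m", {"A": ids[:4], "B": ids[4:8], "C": ids[8:]})
        fst, _ = pairwise_group_fst(dist, model, n_perm=0)
        sub = GroupingModel("ab", {"A": ids[:4], "B": ids[4:8]})
        direct = amova_one_level(dist, sub, n_perm=0).phi_st
        assert fst.loc["A", "B"] == pytest.approx(direct)

    def test_matrix_symmetric_diagonal_undefined(self, rng):
        aln = random_alignment(rng, 12, 60)
        dist = pairwise_differences(aln)
        ids = aln.sample_ids
        model = GroupingModel("m", {"A": ids[:4], "B": ids[4:8], "C": ids[8:]})
        fst, _ = pairwise_group_fst(dist, model, n_perm=0)
        assert np.allclose(fst.values, fst.values.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(fst.values)))

    def test_duplicated_group_against_itself_not_differentiated(self):
        # a group contrasted with an exact copy of itself shows no positive
        # differentiation (phi can go below 0: groups are *more* alike
        # within than random labelling expects)
        aln = make_aln(["AAAA", "AAAT", "AATT", "AAAA", "AAAT", "AATT"])
        dist = pairwise_differences(aln)
        model = two_group_model(["s1", "s2", "s3"], ["s4", "s5", "s6"])
        res = amova_one_level(dist, model, n_perm=0)
        assert res.phi_st <= 0.05

    def test_distinct_group_has_maximal_specific_fst(self):
        aln = make_aln(
            ["AAAA", "AAAA", "AAAA", "AAAA", "TTTT", "TTTT"]
        )
        dist = pairwise_differences(aln)
        model = GroupingModel(
            "m", {"g1": ["s1", "s2"], "g2": ["s3", "s4"], "g3": ["s5", "s6"]}
        )
        gs = group_specific_fst(dist, model)
        assert gs.idxmax() == "g3"

    def test_group_specific_deterministic(self, rng):
        aln = random_alignment(rng, 12, 60)
        dist = pairwise_differences(aln)
        ids = aln.sample_ids
        model = GroupingModel("m", {"A": ids[:6], "B": ids[6:]})
        assert group_specific_fst(dist, model).equals(group_specific_fst(dist, model))
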