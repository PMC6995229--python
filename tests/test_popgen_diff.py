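"""popgen_diff: site classes, Dxy, Hudson's Fst, Snn and its permutation test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from hspreg import errors
from hspreg.io_formats import Arrangement
from hspreg.popgen_diff import (
    PopulationSplit,
    classify_sites,
    complete_deletion,
    differentiate,
    differentiation_table,
    dxy,
    hudson_fst,
    pairwise_diff_matrix,
    results_to_table,
    snn,
    snn_permutation_test,
)
from hspreg.synthetic_data import SeqSimConfig, generate_haplotypes

from conftest import (
    make_alignment,
    oracle_dxy,
    oracle_fst,
    oracle_snn,
    random_alignment,
    two_pop_split,
)

WORKED = make_alignment(["AAAA", "AAAT", "TTTA", "TTTT"])
WORKED_SPLIT = PopulationSplit(("s0", "s1"), ("s2", "s3"))


class TestCompleteDeletion:
    def test_gap_free_alignment_unchanged(self):
        aln = make_alignment(["ACGT", "ACGA"])
        out = complete_deletion(aln)
        assert [r.sequence for r in out] == ["ACGT", "ACGA"]

    def test_single_gap_column_removed(self):
        aln = make_alignment(["AC-TACGTAC", "ACGTACGTAC"])
        assert complete_deletion(aln).length == 9

    def test_n_treated_like_gap(self):
        aln = make_alignment(["ACNT", "ACGT"])
        assert complete_deletion(aln).length == 3

    def test_all_columns_gapped_is_degenerate(self):
        aln = make_alignment(["-A", "A-"])
        with pytest.raises(errors.DegenerateAlignmentError):
            complete_deletion(aln)

    def test_restriction_keeps_columns_gapped_only_in_excluded(self):
        aln = make_alignment(["ACGT", "ACGT", "-CGT"])
        out = complete_deletion(aln, ids=["s0", "s1"])
        assert out.length == 4  # gap is only in the excluded sequence
        strict = complete_deletion(aln, ids=["s0", "s1"], strict=True)
        assert strict.length == 3


class TestClassifySites:
    def test_hand_enumerated_four_columns(self):
        aln = make_alignment(["ACGT", "ACGA", "ACTT", "ACTT"])
        c = classify_sites(aln, WORKED_SPLIT)
        assert (c.monomorphic, c.fixed_diff, c.sp1_sf2, c.sp2_sf1, c.shared) == (
            2,
            1,
            1,
            0,
            0,
        )

    def test_symmetric_polymorphism_is_shared(self):
        aln = make_alignment(["AT", "AA", "AT", "AA"])
        c = classify_sites(aln, WORKED_SPLIT)
        assert (c.shared, c.monomorphic) == (1, 1)

    def test_gap_rejected(self):
        aln = make_alignment(["A-", "AA", "AT", "AA"])
        with pytest.raises(errors.GapError):
            classify_sites(aln, WORKED_SPLIT)

    @pytest.mark.parametrize("seed", range(20))
    def test_classes_partition_all_columns(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 6, 25)
        split = two_pop_split(aln, 3)
        c = classify_sites(aln, split)  # SiteClassCounts validates the sum identity
        assert c.analysed_sites == 25

    def test_swapping_populations_swaps_exclusive_counts(self, rng):
        aln = random_alignment(rng, 6, 40)
        split = two_pop_split(aln, 3)
        a = classify_sites(aln, split)
        b = classify_sites(aln, split.swapped())
        assert (a.sp1_sf2, a.sp2_sf1) == (b.sp2_sf1, b.sp1_sf2)
        assert (a.shared, a.fixed_diff, a.monomorphic) == (
            b.shared,
            b.fixed_diff,
            b.monomorphic,
        )


class TestPairwiseMatrix:
    def test_identical_sequences_zero(self):
        aln = make_alignment(["ACGT", "ACGT"])
        assert pairwise_diff_matrix(aln).tolist() == [[0, 0], [0, 0]]

    def test_opposite_sequences(self):
        aln = make_alignment(["AAAA", "TTTT"])
        assert pairwise_diff_matrix(aln)[0, 1] == 4

    def test_matches_double_loop(self, rng):
        aln = random_alignment(rng, 6, 100)
        mat = pairwise_diff_matrix(aln)
        seqs = [r.sequence for r in aln]
        for i in range(6):
            for j in range(6):
                assert mat[i, j] == sum(a != b for a, b in zip(seqs[i], seqs[j]))


class TestDxyFstSnn:
    def test_identical_populations_have_zero_dxy(self):
        aln = make_alignment(["ACGT"] * 4)
        assert dxy(aln, WORKED_SPLIT) == 0.0

    def test_worked_example(self):
        assert dxy(WORKED, WORKED_SPLIT) == pytest.approx(0.875)
        assert hudson_fst(WORKED, WORKED_SPLIT) == pytest.approx(5 / 7)
        assert snn(WORKED, WORKED_SPLIT) == pytest.approx(1.0)

    def test_fixed_populations_give_fst_one(self):
        aln = make_alignment(["AAAA", "AAAA", "TTTT", "TTTT"])
        assert hudson_fst(aln, WORKED_SPLIT) == pytest.approx(1.0)

    def test_invariant_identical_populations_fst_undefined(self):
        aln = make_alignment(["ACGT"] * 4)
        with pytest.raises(errors.UndefinedFstError):
            hudson_fst(aln, WORKED_SPLIT)

    def test_duplicated_population_fst_nonpositive(self, rng):
        seqs = ["ACGTACGTAA", "ACGAACGTAA", "ACGTACTTAA"]
        aln = make_alignment(seqs + seqs)
        f = hudson_fst(aln, two_pop_split(aln, 3))
        assert f <= 0

    def test_all_identical_sequences_snn_is_tie_share(self):
        aln = make_alignment(["AAAA"] * 4)
        assert snn(aln, WORKED_SPLIT) == pytest.approx(1 / 3)

    def test_label_swap_invariance(self, rng):
        aln = random_alignment(rng, 6, 30)
        split = two_pop_split(aln, 3)
        assert dxy(aln, split) == pytest.approx(dxy(aln, split.swapped()))
        assert hudson_fst(aln, split) == pytest.approx(hudson_fst(aln, split.swapped()))
        assert snn(aln, split) == pytest.approx(snn(aln, split.swapped()))

    def test_weighted_hw_equals_unweighted_for_equal_sizes(self, rng):
        aln = random_alignment(rng, 8, 30)
        split = two_pop_split(aln, 4)
        assert hudson_fst(aln, split) == pytest.approx(
            hudson_fst(aln, split, weighted=True)
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_statistics_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 4))
        n2 = int(rng.integers(2, 4))
        L = int(rng.integers(5, 31))
        aln = random_alignment(rng, n1 + n2, L)
        split = two_pop_split(aln, n1)
        seqs1 = [r.sequence for r in aln][:n1]
        seqs2 = [r.sequence for r in aln][n1:]
        assert dxy(aln, split) == pytest.approx(oracle_dxy(seqs1, seqs2))
        if oracle_dxy(seqs1, seqs2) > 0:
            assert hudson_fst(aln, split) == pytest.approx(oracle_fst(seqs1, seqs2))
        assert snn(aln, split) == pytest.approx(oracle_snn(seqs1, seqs2))


class TestSnnPermutationTest:
    def test_zero_permutations_rejected(self):
        with pytest.raises(errors.ParameterError):
            snn_permutation_test(WORKED, WORKED_SPLIT, n_permutations=0)

    def test_perfectly_structured_small_sample_p_near_exhaustive(self):
        # With 2+2 sequences there are C(4,2)=6 label assignments; exactly 2
        # (the true split and its mirror) reproduce Snn=1, so the exact
        # permutation null gives p = 1/3.
        exhaustive = []
        labels0 = [0, 0, 1, 1]
        seqs = [r.sequence for r in WORKED]
        from conftest import oracle_snn as osnn

        for combo in itertools.combinations(range(4), 2):
            s1 = [seqs[i] for i in combo]
            s2 = [seqs[i] for i in range(4) if i not in combo]
            exhaustive.append(osnn(s1, s2))
        assert sum(v >= 1.0 for v in exhaustive) == 2
        s, p = snn_permutation_test(WORKED, WORKED_SPLIT, n_permutations=2000, seed=0)
        assert s == pytest.approx(1.0)
        assert p == pytest.approx(1 / 3, abs=0.04)

    def test_determinism(self):
        a = snn_permutation_test(WORKED, WORKED_SPLIT, n_permutations=200, seed=42)
        b = snn_permutation_test(WORKED, WORKED_SPLIT, n_permutations=200, seed=42)
        assert a == b

    def test_null_p_values_are_valid_and_not_anticonservative(self):
        # iid sequences carry no population signal.  Snn takes values on a
        # small lattice (fractions of nearest-neighbour counts), so its
        # tie-inclusive permutation p-values are conservative rather than
        # exactly uniform; the defensible property is validity:
        # P(p <= alpha) <= alpha (within Monte Carlo error) at every alpha.
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(300):
            aln = random_alignment(rng, 10, 40)
            split = two_pop_split(aln, 5)
            _, p = snn_permutation_test(
                aln, split, n_permutations=99, seed=int(rng.integers(2**31))
            )
            ps.append(p)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.10, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + 3 * se
        # not degenerate: small p-values do occur under the null
        assert (ps <= 0.25).mean() > 0.05


class TestDifferentiationTable:
    def test_single_region_row_populated(self):
        res = differentiate(WORKED, WORKED_SPLIT, region="five_prime", copy="A", seed=1)
        assert res.counts.analysed_sites == 4
        assert res.dxy == pytest.approx(0.875)
        assert res.fst == pytest.approx(5 / 7)
        assert 0 < res.snn_p <= 1

    def test_synthetic_counts_equal_generator_truth(self):
        cfg = SeqSimConfig(
            n_fixed_diff=4,
            n_excl_poly_pop1=6,
            n_excl_poly_pop2=2,
            n_shared_poly=3,
            gap_columns=3,
            length=300,
            seed=5,
        )
        aln, truth = generate_haplotypes(cfg)
        split = PopulationSplit(
            tuple(r.id for r in aln if r.arrangement is Arrangement.OST),
            tuple(r.id for r in aln if r.arrangement is Arrangement.O347),
        )
        res = differentiate(aln, split, n_permutations=99, seed=0)
        want = truth.class_counts()
        assert res.counts.fixed_diff == want.get("fixed_diff", 0)
        assert res.counts.sp1_sf2 == want.get("sp1_sf2", 0)
        assert res.counts.sp2_sf1 == want.get("sp2_sf1", 0)
        assert res.counts.shared == want.get("shared", 0)
        assert res.counts.analysed_sites == cfg.length - cfg.gap_columns

    def test_concatenated_row_added_per_region(self):
        cfg_a = SeqSimConfig(n_fixed_diff=2, length=80, gene_copy="A", seed=1)
        cfg_b = SeqSimConfig(n_excl_poly_pop1=2, length=60, gene_copy="B", seed=2)
        aln_a, _ = generate_haplotypes(cfg_a)
        aln_b, _ = generate_haplotypes(cfg_b)
        split = PopulationSplit(
            tuple(r.id for r in aln_a if r.arrangement is Arrangement.OST),
            tuple(r.id for r in aln_a if r.arrangement is Arrangement.O347),
        )
        rows = differentiation_table(
            [
                (aln_a, split, "five_prime", "A"),
                (aln_b, split, "five_prime", "B"),
            ],
            n_permutations=49,
            seed=0,
        )
        assert [(r.region, r.copy) for r in rows] == [
            ("five_prime", "A"),
            ("five_prime", "B"),
            ("five_prime", "concatenated"),
        ]
        conc = rows[-1]
        assert conc.counts.analysed_sites == 80 + 60
        # concatenation of per-copy variation: classes add up
        assert conc.counts.fixed_diff == rows[0].counts.fixed_diff
        assert conc.counts.sp1_sf2 == rows[1].counts.sp1_sf2

    def test_table_rendering_has_published_columns(self):
        res = differentiate(WORKED, WORKED_SPLIT, region="r", copy="A", seed=0)
        df = results_to_table([res])
        assert list(df.columns) == [
            "Region",
            "Gene copy",
            "SP1SF2",
            "SP2SF1",
            "Shared",
            "Fixed",
            "Sites",
            "Dxy",
            "Fst",
            "Snn",
            "P",
        ]

    def test_determinism_same_seed(self):
        a = differentiate(WORKED, WORKED_SPLIT, n_permutations=100, seed=3)
        b = differentiate(WORKED, WORKED_SPLIT, n_permutations=100, seed=3)
        assert a == b
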