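import numpy as np
import pytest
import scipy.stats as st_sp
from hypothesis import given
from hypothesis import strategies as st

from bsamap import (
    Block,
    BlockParams,
    BulkSiteCount,
    CrossDesign,
    InputError,
    ValidationError,
    binomial_test_p,
    block_p_value,
    build_blocks,
    fisher_exact_two_sided,
)
from oracles import binomial_oracle, fisher_two_sided_oracle


def bulk_site(pos, wt, mut, other=0, chrom="chr1"):
    return BulkSiteCount(chrom, pos, "A", "G", wt, mut, other)


class TestFisherExact:
    def test_modal_table_has_p_one(self):
        assert fisher_exact_two_sided(((5, 5), (5, 5))) == 1.0

    def test_transposition_symmetry_and_oracle_on_example(self):
        p = fisher_exact_two_sided(((10, 0), (15, 5)))
        assert p == pytest.approx(fisher_exact_two_sided(((10, 15), (0, 5))), abs=1e-12)
        assert p == pytest.approx(fisher_two_sided_oracle(((10, 0), (15, 5))), abs=1e-12)

    def test_small_sweep_matches_enumeration_oracle(self):
        """Exhaustive agreement with the Fraction oracle for totals <= 12."""
        for total in range(1, 13):
            for r1 in range(total + 1):
                r2 = total - r1
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        table = ((a, r1 - a), (c, r2 - c))
                        assert fisher_exact_two_sided(table) == pytest.approx(
                            fisher_two_sided_oracle(table), abs=1e-12
                        )

    @given(st.tuples(*[st.integers(0, 40)] * 4).filter(lambda t: sum(t) > 0))
    def test_agrees_with_scipy(self, cells):
        a, b, c, d = cells
        ours = fisher_exact_two_sided(((a, b), (c, d)))
        scipys = st_sp.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(scipys, rel=1e-6, abs=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_two_sided(((-1, 2), (3, 4)))
        with pytest.raises(ValidationError):
            fisher_exact_two_sided(((0, 0), (0, 0)))


class TestBinomialTest:
    @pytest.mark.parametrize("k", range(0, 25, 4))
    @pytest.mark.parametrize("sidedness", ["two_sided", "greater"])
    def test_matches_summation_oracle(self, k, sidedness):
        assert binomial_test_p(k, 24, 0.75, sidedness) == pytest.approx(
            binomial_oracle(k, 24, 3, 4, sidedness), abs=1e-12
        )

    def test_per_side_monotone_in_deviation(self):
        """Moving k away from the null expectation never raises p (each side)."""
        for depth in (20, 37, 100):
            mode = int((depth + 1) * 0.75)  # binomial pmf mode
            upper = [binomial_test_p(k, depth, 0.75) for k in range(mode, depth + 1)]
            lower = [binomial_test_p(k, depth, 0.75) for k in range(mode, -1, -1)]
            assert all(a >= b - 1e-12 for a, b in zip(upper, upper[1:]))
            assert all(a >= b - 1e-12 for a, b in zip(lower, lower[1:]))


class TestBuildBlocks:
    def test_greedy_accumulation_and_trailing_discard(self):
        depths = [8, 7, 9, 25, 4]
        sites = [bulk_site(100 * (i + 1), wt=d // 2, mut=d - d // 2) for i, d in enumerate(depths)]
        blocks, discarded = build_blocks(sites, BlockParams(min_block_depth=20))
        assert [(b.n_snps, b.depth) for b in blocks] == [(3, 24), (1, 25)]
        assert blocks[0].start_pos == 100 and blocks[0].end_pos == 300
        assert [s.pos for s in discarded] == [500]

    def test_single_site_at_exact_minimum(self):
        blocks, discarded = build_blocks([bulk_site(10, 5, 15)], BlockParams(20))
        assert len(blocks) == 1 and blocks[0].n_snps == 1 and not discarded

    def test_all_low_depth_yields_no_blocks(self):
        sites = [bulk_site(10 * (i + 1), 1, 0) for i in range(19)]
        blocks, discarded = build_blocks(sites, BlockParams(20))
        assert blocks == [] and len(discarded) == 19

    def test_other_reads_do_not_count_toward_depth(self):
        blocks, discarded = build_blocks(
            [bulk_site(10, 5, 10, other=50)], BlockParams(20)
        )
        assert blocks == [] and len(discarded) == 1

    def test_unsorted_or_multichrom_input_rejected(self):
        with pytest.raises(InputError):
            build_blocks([bulk_site(20, 10, 10), bulk_site(10, 10, 10)])
        with pytest.raises(InputError):
            build_blocks([bulk_site(10, 10, 10), bulk_site(20, 10, 10, chrom="chr2")])

    @given(
        depths=st.lists(st.tuples(st.integers(0, 15), st.integers(0, 15)), max_size=60),
        min_depth=st.integers(1, 40),
    )
    def test_block_partition_conserves_reads(self, depths, min_depth):
        sites = [bulk_site(10 * (i + 1), wt, mut + (1 if wt + mut == 0 else 0)) for i, (wt, mut) in enumerate(depths)]
        blocks, discarded = build_blocks(sites, BlockParams(min_block_depth=min_depth))
        total = sum(s.depth for s in sites)
        assert sum(b.depth for b in blocks) + sum(s.depth for s in discarded) == total
        for b in blocks:
            assert b.depth >= min_depth


class TestBlockPValue:
    def test_observation_equal_to_expectation_gives_p_one(self):
        block = Block("chr1", 1, 9, 3, mut_reads=15, wt_reads=5)
        p = block_p_value(block, CrossDesign.bc1_to_mutant(), BlockParams(test="fisher"))
        assert p == 1.0
        assert block.p_value == 1.0

    def test_one_sided_binomial_pure_mutant_block(self):
        block = Block("chr1", 1, 9, 3, mut_reads=20, wt_reads=0)
        p = block_p_value(
            block, CrossDesign.bc1_to_mutant(),
            BlockParams(test="binomial", sidedness="greater"),
        )
        assert p == pytest.approx(0.75**20, rel=1e-12)
        assert p == pytest.approx(binomial_oracle(20, 20, 3, 4, "greater"), rel=1e-12)

    def test_pure_wildtype_block_is_significant_under_both_tests(self):
        design = CrossDesign.bc1_to_mutant()
        for test in ("fisher", "binomial"):
            block = Block("chr1", 1, 9, 3, mut_reads=0, wt_reads=20)
            p = block_p_value(block, design, BlockParams(test=test))
            assert p < 0.01
        # exact values from the enumeration oracles
        assert block_p_value(
            Block("chr1", 1, 9, 3, 0, 20), design, BlockParams(test="fisher")
        ) == pytest.approx(fisher_two_sided_oracle(((0, 20), (15, 5))), abs=1e-12)
        assert block_p_value(
            Block("chr1", 1, 9, 3, 0, 20), design, BlockParams(test="binomial")
        ) == pytest.approx(binomial_oracle(0, 20, 3, 4, "two_sided"), abs=1e-12)

    def test_zero_depth_block_rejected(self):
        with pytest.raises(ValidationError):
            block_p_value(Block("chr1", 1, 1, 1, 0, 0), CrossDesign.bc1_to_mutant())

    def test_fisher_expected_row_uses_half_up_rounding(self):
        # depth 22 at null 0.75 -> expected mutant reads 16.5 -> 17
        block = Block("chr1", 1, 5, 2, mut_reads=17, wt_reads=5)
        p = block_p_value(block, CrossDesign.bc1_to_mutant(), BlockParams(test="fisher"))
        assert p == 1.0
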