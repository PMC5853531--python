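"""Block construction and block-level exact tests.

Consecutive low-depth SNPs are pooled left-to-right into blocks until the
informative (wt + mut) depth reaches a minimum (default 20). Each block's
pooled counts are then tested against the cross design's null mutant-allele
frequency with an exact test, either

* ``binomial`` (default): exact binomial test of ``mut_reads`` out of
  ``depth`` against ``null_freq``, or
* ``fisher``: two-sided Fisher's exact test of the observed counts against
  the rounded expected counts at ``null_freq``.

The Fisher p-value is computed by exact hypergeometric enumeration in
integer arithmetic (no floating-point tie ambiguity): it is the sum of the
probabilities of all tables with the observed margins whose probability
does not exceed that of the observed table.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb, log10
from typing import List, Sequence, Tuple

from scipy.stats import binomtest

from .errors import InputError, ValidationError
from .genetics import round_half_up
from .types import Block, BlockParams, BulkSiteCount, CrossDesign

#: p-values are floored at this value before log10 transforms. This only
#: guards against -inf; it cannot change any threshold decision.
P_FLOOR = 1e-300


def neglog10(p: float) -> float:
    """-log10(p) with the p-value floored at :data:`P_FLOOR`."""
    return -log10(max(p, P_FLOOR))


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1 << 18)
def _fisher_cached(a: int, b: int, c: int, d: int, sidedness: str) -> float:
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    if sidedness == "greater":
        num = sum(comb(r1, x) * comb(r2, c1 - x) for x in range(a, hi + 1))
    else:
        num = 0
        for x in range(lo, hi + 1):
            w = comb(r1, x) * comb(r2, c1 - x)
            if w <= w_obs:
                num += w
    p = num / comb(n, c1)
    return min(1.0, p)


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact test for a 2x2 table of non-negative ints.

    The p-value sums, over all tables sharing the observed margins, the
    hypergeometric probabilities that are at most the observed table's
    probability. Probabilities are compared as exact integers, so ties are
    handled without floating-point epsilons.
    """
    (a, b), (c, d) = table
    return _fisher(a, b, c, d, "two_sided")


def _fisher(a: int, b: int, c: int, d: int, sidedness: str) -> float:
    for v in (a, b, c, d):
        if int(v) != v or v < 0:
            raise ValidationError(f"table entries must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        raise ValidationError("table must have at least one positive entry")
    return _fisher_cached(a, b, c, d, sidedness)


def binomial_test_p(k: int, n: int, p0: float, sidedness: str = "two_sided") -> float:
    """Exact binomial test of k successes in n trials against rate p0.

    Two-sided p-values use the minimum-likelihood convention (sum of all
    outcome probabilities not exceeding the observed one), matching the
    Fisher convention above.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    alternative = "two-sided" if sidedness == "two_sided" else "greater"
    return float(binomtest(k, n, p0, alternative=alternative).pvalue)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

def build_blocks(
    sites: Sequence[BulkSiteCount], params: BlockParams = BlockParams()
) -> Tuple[List[Block], List[BulkSiteCount]]:
    """Pool consecutive SNPs of one chromosome into minimum-depth blocks.

    Greedy left-to-right: a block starts at the first unassigned SNP and
    absorbs consecutive SNPs until its pooled informative depth
    (wt + mut reads; ``other`` reads are excluded) reaches
    ``min_block_depth``, then closes. A trailing run that never reaches
    the minimum is discarded.

    Returns
    -------
    (blocks, discarded)
        ``blocks`` in genomic order; ``discarded`` the trailing sites that
        did not form a block.
    """
    if not sites:
        return [], []
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise InputError(f"build_blocks expects a single chromosome, got {sorted(chroms)}")
    positions = [s.pos for s in sites]
    if any(q <= p for p, q in zip(positions, positions[1:])):
        raise InputError("bulk sites must be sorted by position without duplicates")

    blocks: List[Block] = []
    open_sites: List[BulkSiteCount] = []
    depth = 0
    for site in sites:
        open_sites.append(site)
        depth += site.depth
        if depth >= params.min_block_depth:
            blocks.append(
                Block(
                    chrom=site.chrom,
                    start_pos=open_sites[0].pos,
                    end_pos=open_sites[-1].pos,
                    n_snps=len(open_sites),
                    mut_reads=sum(s.mut_count for s in open_sites),
                    wt_reads=sum(s.wt_count for s in open_sites),
                )
            )
            open_sites = []
            depth = 0
    return blocks, open_sites


def block_p_value(
    block: Block, design: CrossDesign, params: BlockParams = BlockParams()
) -> float:
    """Exact-test p-value for one block against the design null frequency.

    For ``test="fisher"`` the observed (mut, wt) counts are compared with
    the rounded expected counts at ``null_freq`` over the same depth; for
    ``test="binomial"`` the p-value is the exact binomial tail of
    ``mut_reads`` out of ``depth`` at ``null_freq``. The result is stored
    on ``block.p_value`` and returned.
    """
    depth = block.depth
    if depth == 0:
        raise ValidationError(
            f"block {block.chrom}:{block.start_pos}-{block.end_pos} has zero depth; p undefined"
        )
    if params.test == "fisher":
        e_mut = int(round_half_up(design.null_freq * depth))
        e_wt = depth - e_mut
        p = _fisher(block.mut_reads, block.wt_reads, e_mut, e_wt, params.sidedness)
    else:
        p = binomial_test_p(block.mut_reads, depth, design.null_freq, params.sidedness)
    p = max(p, P_FLOOR)
    block.p_value = p
    return p


def assign_block_pvalues(
    blocks: Sequence[Block], design: CrossDesign, params: BlockParams = BlockParams()
) -> List[Block]:
    """Compute and store p-values for every block; returns the same list."""
    for block in blocks:
        block_p_value(block, design, params)
    return list(blocks)
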