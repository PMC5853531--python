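"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written along a different arithmetic path
from the implementation: exact rational (Fraction) probabilities, direct
enumeration, no shared helpers.
"""

from fractions import Fraction
from math import comb, log10
from typing import List, Sequence, Tuple


def fisher_two_sided_oracle(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher p by exhaustive enumeration with Fraction pmf.

    Enumerates every 2x2 table sharing the observed margins, computes each
    hypergeometric probability exactly, and sums those not exceeding the
    observed table's probability.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs:
            total += px
    return float(min(total, Fraction(1)))


def binomial_oracle(k: int, n: int, p_num: int, p_den: int, sidedness: str) -> float:
    """Exact binomial test p-value by direct summation with Fraction pmf.

    The null success probability is given as the rational p_num/p_den so
    the enumeration is exact. Two-sided p sums all outcome probabilities
    not exceeding the observed one (minimum-likelihood convention).
    """
    p = Fraction(p_num, p_den)
    q = 1 - p

    def pmf(x: int) -> Fraction:
        return comb(n, x) * p**x * q ** (n - x)

    if sidedness == "greater":
        total = sum((pmf(x) for x in range(k, n + 1)), Fraction(0))
    else:
        p_obs = pmf(k)
        total = sum((pmf(x) for x in range(0, n + 1) if pmf(x) <= p_obs), Fraction(0))
    return float(min(total, Fraction(1)))


def window_mean_oracle(
    block_mids: Sequence[int], block_ps: Sequence[float], start: int, end: int
) -> Tuple[int, float]:
    """(n, mean -log10 p) over blocks whose midpoint lies in [start, end]."""
    scores = [
        -log10(p) for m, p in zip(block_mids, block_ps) if start <= m <= end
    ]
    if not scores:
        return 0, float("nan")
    return len(scores), sum(scores) / len(scores)


def origin_runs_oracle(
    profile: Sequence[Tuple[int, float]], min_purity: float, min_snps: int
) -> List[Tuple[int, int, int]]:
    """(start, end, n) of maximal high-purity runs, by a direct index scan."""
    out = []
    i = 0
    items = list(profile)
    while i < len(items):
        if items[i][1] >= min_purity:
            j = i
            while j + 1 < len(items) and items[j + 1][1] >= min_purity:
                j += 1
            if j - i + 1 >= min_snps:
                out.append((items[i][0], items[j][0], j - i + 1))
            i = j + 1
        else:
            i += 1
    return out


def origin_runs_sites_oracle(
    sites: Sequence[Tuple[int, int, int]],
    min_purity: float,
    min_snps: int,
    min_depth: int,
    tolerated: int,
) -> List[Tuple[int, int, int]]:
    """Site-level run oracle with the error-tolerant break rule.

    ``sites`` are (pos, wt_count, mut_count). Under-depth sites are
    ignored; pure sites join the current run; impure sites with at most
    ``tolerated`` wild-type reads are ignored; other impure sites break
    the run.
    """
    out = []
    run: List[int] = []
    for pos, wt, mut in sites:
        depth = wt + mut
        if depth < min_depth:
            continue
        if mut / depth >= min_purity:
            run.append(pos)
        elif wt > tolerated:
            if len(run) >= min_snps:
                out.append((run[0], run[-1], len(run)))
            run = []
    if len(run) >= min_snps:
        out.append((run[0], run[-1], len(run)))
    return out
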