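"""Mendelian bookkeeping: segregation-ratio goodness of fit, design
allele-frequency expectations, and sequencing fold-coverage arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence, Tuple

from scipy import stats

from .errors import InputError, ValidationError
from .types import CrossDesign


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero at the given decimal place.

    Python's builtin ``round`` is banker's rounding; reported statistics
    here follow the half-up convention instead so printed values are
    reproducible from the exact ones.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SegregationResult:
    """Chi-square goodness-of-fit result for phenotype class counts."""

    observed: Tuple[int, ...]
    expected_ratio: Tuple[int, ...]
    expected: Tuple[float, ...]
    chi2: float
    df: int
    p: float


def chi_square_gof(observed: Sequence[int], expected_ratio: Sequence[int]) -> SegregationResult:
    """Test observed class counts against an expected Mendelian ratio.

    Expected counts are ``total * ratio_k / sum(ratio)``; the statistic is
    the plain Pearson chi-square with no continuity correction, with
    ``len(observed) - 1`` degrees of freedom.

    Parameters
    ----------
    observed : sequence of int
        Class counts, e.g. (green, yellow) plants.
    expected_ratio : sequence of positive int
        Mendelian ratio, e.g. (1, 1) for a backcross or (3, 1) for an F2
        recessive trait.
    """
    obs = tuple(int(x) for x in observed)
    ratio = tuple(int(r) for r in expected_ratio)
    if len(obs) < 2:
        raise InputError("need at least two phenotype classes")
    if len(obs) != len(ratio):
        raise InputError("observed and expected_ratio must have equal length")
    if any(x < 0 for x in obs):
        raise ValidationError("observed counts must be non-negative")
    if any(r <= 0 for r in ratio):
        raise ValidationError("expected ratio terms must be positive")
    total = sum(obs)
    if total <= 0:
        raise InputError("total observed count must be positive")
    denom = sum(ratio)
    expected = tuple(total * r / denom for r in ratio)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, expected))
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(obs, ratio, expected, float(chi2), df, p)


def expected_bulk_allele_freq(design: CrossDesign, locus: str) -> float:
    """Expected mutant-allele frequency in the selected bulk.

    ``locus`` is ``"unlinked"`` (segregating freely from the causal gene)
    or ``"causal"`` (the selected locus itself, fixed in the bulk).
    BC1-to-mutant progeny are half Mm, half MM, so an unlinked locus in a
    recessive-selected bulk sits at 0.75; in an F2 recessive bulk
    selection does not shift unlinked frequencies from 0.5.
    """
    if locus == "causal":
        return design.causal_freq
    if locus == "unlinked":
        return design.null_freq
    raise InputError(f"locus must be 'unlinked' or 'causal', got {locus!r}")


def fold_coverage(total_bases: float, genome_size: float) -> float:
    """Sequencing depth as genome folds, rounded half-up to 1 decimal.

    ``fold_coverage(94.7e9, 2.5e9)`` is 37.9.
    """
    if genome_size <= 0:
        raise InputError("genome_size must be positive")
    return round_half_up(total_bases / genome_size, 1)
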