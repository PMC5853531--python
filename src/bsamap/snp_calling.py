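"""Homozygous parent-vs-reference SNP calling from per-site base counts.

A site becomes a marker SNP when (i) its depth reaches ``min_depth``
(default 10), (ii) the major base accounts for at least ``min_purity``
(default 90%) of all observations at the site, and (iii) the major base
differs from the reference. The purity denominator includes non-ACGT
("other") observations, i.e. purity is taken over all alleles observed,
not just the four canonical bases.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

from .errors import InputError, ValidationError
from .types import BASES, ParentSnp, SiteBaseCount, SnpCallParams


def site_purity(site: SiteBaseCount) -> Tuple[str, float]:
    """Return the major base and its fraction of all observations.

    Ties between equally frequent bases are broken in the fixed order
    A < C < G < T.
    """
    depth = site.depth
    if depth == 0:
        raise ValidationError(f"site {site.chrom}:{site.pos} has zero depth; purity undefined")
    major = max(BASES, key=lambda b: (site.counts[b], -BASES.index(b)))
    return major, site.counts[major] / depth


def call_parent_snps(
    sites: Sequence[SiteBaseCount], params: SnpCallParams = SnpCallParams()
) -> List[ParentSnp]:
    """Call homozygous parent SNPs against the reference.

    ``sites`` must be sorted by (chrom, pos) with no duplicate positions.
    Emitted SNPs carry ``wt_allele = ref_base`` and ``mut_allele`` = the
    major base observed in the parent reads.
    """
    _check_sorted_unique(sites)
    snps: List[ParentSnp] = []
    for site in sites:
        depth = site.depth
        if depth < params.min_depth or depth == 0:
            continue
        major, purity = site_purity(site)
        if purity < params.min_purity:
            continue
        if major == site.ref_base:
            continue
        snps.append(
            ParentSnp(
                chrom=site.chrom,
                pos=site.pos,
                wt_allele=site.ref_base,
                mut_allele=major,
                parent_depth=depth,
                parent_purity=purity,
            )
        )
    return snps


def _check_sorted_unique(sites: Sequence[SiteBaseCount]) -> None:
    seen_chroms = set()
    prev_chrom = None
    prev_pos = -1
    for site in sites:
        if site.chrom != prev_chrom:
            if site.chrom in seen_chroms:
                raise InputError(f"sites not grouped by chromosome: {site.chrom} reappears")
            seen_chroms.add(site.chrom)
            prev_chrom = site.chrom
            prev_pos = -1
        if site.pos == prev_pos:
            raise InputError(f"duplicate position {site.chrom}:{site.pos}")
        if site.pos < prev_pos:
            raise InputError(f"sites not sorted at {site.chrom}:{site.pos}")
        prev_pos = site.pos
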