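"""Sequence-origin narrowing inside candidate regions.

Because the selected bulk shares the mutant-parent haplotype around the
causal gene, stretches of a candidate region where the bulk reads derive
(near-)exclusively from the mutant parent pinpoint the locus more finely
than the window scan. This module profiles the per-SNP mutant-allele read
fraction and reports maximal runs of consecutive high-purity SNPs.

Sites below ``min_site_depth`` informative reads are skipped, not zeroed:
missing data does not break a run. A profiled SNP breaks a run when it is
impure (purity below ``min_purity``) *and* its wild-type read count
exceeds ``tolerated_discordant_reads`` — a single discordant read at
typical pool depth is consistent with sequencing error, whereas two or
more are evidence of a recombinant haplotype in the bulk.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

from .errors import InputError
from .types import BulkSiteCount, CandidateRegion, NarrowParams, OriginSegment


def purity_profile(
    sites: Sequence[BulkSiteCount], min_site_depth: int = 5
) -> List[Tuple[int, float]]:
    """Per-SNP mutant-allele read fraction for one chromosome.

    Returns (pos, purity) pairs for sites with wt + mut depth at least
    ``min_site_depth``; under-depth sites are omitted.
    """
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise InputError(f"purity_profile expects a single chromosome, got {sorted(chroms)}")
    prev = 0
    profile: List[Tuple[int, float]] = []
    for site in sites:
        if site.pos <= prev:
            raise InputError("bulk sites must be sorted by position without duplicates")
        prev = site.pos
        depth = site.depth
        if depth < min_site_depth:
            continue
        profile.append((site.pos, site.mut_count / depth))
    return profile


def find_origin_runs(
    profile: Sequence[Tuple[int, float]],
    params: NarrowParams = NarrowParams(),
    chrom: str = "",
) -> List[OriginSegment]:
    """Maximal runs of consecutive profiled SNPs with purity >= min_purity.

    A run is reported iff it contains at least ``min_snps`` SNPs. Runs are
    disjoint by construction and do not depend on anything but the sorted
    profile.
    """
    segments: List[OriginSegment] = []
    run: List[Tuple[int, float]] = []

    def flush() -> None:
        if len(run) >= params.min_snps:
            purities = [p for _, p in run]
            segments.append(
                OriginSegment(
                    chrom=chrom,
                    start=run[0][0],
                    end=run[-1][0],
                    n_snps=len(run),
                    mean_purity=sum(purities) / len(purities),
                )
            )
        run.clear()

    for pos, purity in profile:
        if purity >= params.min_purity:
            run.append((pos, purity))
        else:
            flush()
    flush()
    return segments


def find_origin_runs_in_sites(
    sites: Sequence[BulkSiteCount], params: NarrowParams = NarrowParams()
) -> List[OriginSegment]:
    """Run finding with the error-tolerant break rule, from full site records.

    Like :func:`find_origin_runs` but, having read counts available, a
    profiled site only breaks a run when its purity is below
    ``min_purity`` AND its wild-type read count exceeds
    ``tolerated_discordant_reads``. Tolerated-impure sites neither break
    a run nor join it.
    """
    chrom = sites[0].chrom if sites else ""
    segments: List[OriginSegment] = []
    run: List[Tuple[int, float]] = []

    def flush() -> None:
        if len(run) >= params.min_snps:
            purities = [p for _, p in run]
            segments.append(
                OriginSegment(
                    chrom=chrom,
                    start=run[0][0],
                    end=run[-1][0],
                    n_snps=len(run),
                    mean_purity=sum(purities) / len(purities),
                )
            )
        run.clear()

    for site in sites:
        depth = site.depth
        if depth < params.min_site_depth:
            continue
        purity = site.mut_count / depth
        if purity >= params.min_purity:
            run.append((site.pos, purity))
        elif site.wt_count > params.tolerated_discordant_reads:
            flush()
    flush()
    return segments


def narrow_regions(
    bulk_sites: Sequence[BulkSiteCount],
    regions: Sequence[CandidateRegion],
    params: NarrowParams = NarrowParams(),
) -> List[OriginSegment]:
    """Run origin narrowing restricted to each candidate region.

    ``bulk_sites`` may span the whole genome; for each region the sites
    falling inside it are scanned for high-purity runs with the
    error-tolerant break rule. Segments are returned sorted by
    (chrom, start).
    """
    segments: List[OriginSegment] = []
    for region in regions:
        in_region = [
            s
            for s in bulk_sites
            if s.chrom == region.chrom and region.start <= s.pos <= region.end
        ]
        in_region.sort(key=lambda s: s.pos)
        prev = 0
        for s in in_region:
            if s.pos == prev:
                raise InputError(f"duplicate bulk site at {s.chrom}:{s.pos}")
            prev = s.pos
        segments.extend(find_origin_runs_in_sites(in_region, params))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments
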