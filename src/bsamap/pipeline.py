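"""Convenience wiring of the full scan: bulk counts -> blocks -> windows -> regions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

from .blocks import assign_block_pvalues, build_blocks
from .errors import InputError
from .types import (
    Block,
    BlockParams,
    BulkSiteCount,
    CandidateRegion,
    CrossDesign,
    GenomeLayout,
    ParentSnp,
    ScanParams,
    Window,
)
from .windows import call_candidate_regions, scan_windows


@dataclass
class ScanResult:
    """Output bundle of one genome scan."""

    blocks: List[Block]
    windows: List[Window]
    regions: List[CandidateRegion]
    n_discarded_sites: int


def run_scan(
    bulk_sites: Sequence[BulkSiteCount],
    layout: GenomeLayout,
    design: CrossDesign,
    block_params: BlockParams = BlockParams(),
    scan_params: ScanParams = ScanParams(),
    snps: Optional[Sequence[ParentSnp]] = None,
) -> ScanResult:
    """Run the block/window scan over a whole genome of bulk counts.

    ``bulk_sites`` must be grouped by chromosome and position-sorted
    within each chromosome. When ``snps`` is given, bulk sites are first
    restricted to positions present in the SNP set (useful when the bulk
    table was produced outside this package).
    """
    if snps is not None:
        keep: Set[tuple] = {(s.chrom, s.pos) for s in snps}
        bulk_sites = [s for s in bulk_sites if (s.chrom, s.pos) in keep]

    by_chrom: Dict[str, List[BulkSiteCount]] = {}
    for site in bulk_sites:
        if site.chrom not in layout:
            raise InputError(f"bulk site on unknown chromosome {site.chrom!r}")
        by_chrom.setdefault(site.chrom, []).append(site)

    blocks: List[Block] = []
    n_discarded = 0
    for chrom, _ in layout:
        sites = by_chrom.get(chrom, [])
        if not sites:
            continue
        chrom_blocks, discarded = build_blocks(sites, block_params)
        blocks.extend(chrom_blocks)
        n_discarded += len(discarded)
    assign_block_pvalues(blocks, design, block_params)
    windows = scan_windows(blocks, layout, scan_params)
    regions = call_candidate_regions(windows, scan_params)
    return ScanResult(
        blocks=blocks, windows=windows, regions=regions, n_discarded_sites=n_discarded
    )
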