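"""Sliding-window average -log10(P) genome scan and region calling.

Windows tile each chromosome from position 1 with a fixed step (defaults:
2 Mb windows, 100 kb step); the last windows are truncated at the
chromosome end. A block belongs to a window iff its midpoint lies inside.
The window score is the arithmetic mean of -log10(P) over member blocks.
Windows with fewer than ``min_blocks`` blocks are filtered (noise
control); the remaining windows are significant iff their score strictly
exceeds ``threshold``. Significant windows that overlap or abut are merged
into candidate regions.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Sequence

import numpy as np

from .blocks import neglog10
from .errors import InputError
from .types import Block, CandidateRegion, GenomeLayout, ScanParams, Window


def scan_windows(
    blocks: Sequence[Block], layout: GenomeLayout, params: ScanParams = ScanParams()
) -> List[Window]:
    """Score sliding windows across the whole genome.

    ``blocks`` may span any number of chromosomes but must all carry
    p-values; chromosomes are taken from ``layout`` in layout order.
    Windows with no blocks report an undefined score (``None``), not 0.
    """
    by_chrom: Dict[str, List[Block]] = defaultdict(list)
    for block in blocks:
        if block.chrom not in layout:
            raise InputError(f"block on unknown chromosome {block.chrom!r}")
        if block.p_value is None:
            raise InputError(
                f"block {block.chrom}:{block.start_pos}-{block.end_pos} has no p-value"
            )
        by_chrom[block.chrom].append(block)

    windows: List[Window] = []
    for chrom, length in layout:
        chrom_blocks = sorted(by_chrom.get(chrom, []), key=lambda b: b.midpoint)
        mids = np.array([b.midpoint for b in chrom_blocks], dtype=np.int64)
        scores = np.array([neglog10(b.p_value) for b in chrom_blocks], dtype=float)
        # prefix sums give O(1) per-window mean after two binary searches
        csum = np.concatenate([[0.0], np.cumsum(scores)])
        for start in range(1, length + 1, params.step):
            end = min(start + params.window_size - 1, length)
            i = int(np.searchsorted(mids, start, side="left"))
            j = int(np.searchsorted(mids, end, side="right"))
            n = j - i
            if n == 0:
                avg = None
            else:
                avg = float((csum[j] - csum[i]) / n)
            filtered = n < params.min_blocks
            significant = (not filtered) and avg is not None and avg > params.threshold
            windows.append(
                Window(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_blocks=n,
                    avg_neglog10p=avg,
                    significant=significant,
                    filtered=filtered,
                )
            )
    return windows


def call_candidate_regions(
    windows: Sequence[Window], params: ScanParams = ScanParams()
) -> List[CandidateRegion]:
    """Merge significant windows into candidate regions.

    Significant windows on the same chromosome that overlap or abut
    (next start <= current end + 1 in 1-based inclusive coordinates) are
    merged; each region records its peak window score and the number of
    contributing windows. Input order does not matter and the operation
    is idempotent. An empty window set yields an empty list.
    """
    sig = sorted(
        (w for w in windows if w.significant), key=lambda w: (w.chrom, w.start, w.end)
    )
    regions: List[CandidateRegion] = []
    for w in sig:
        if (
            regions
            and regions[-1].chrom == w.chrom
            and w.start <= regions[-1].end + 1
        ):
            last = regions[-1]
            regions[-1] = CandidateRegion(
                chrom=last.chrom,
                start=last.start,
                end=max(last.end, w.end),
                peak_score=max(last.peak_score, w.avg_neglog10p),
                n_windows=last.n_windows + 1,
            )
        else:
            regions.append(
                CandidateRegion(
                    chrom=w.chrom,
                    start=w.start,
                    end=w.end,
                    peak_score=w.avg_neglog10p,
                    n_windows=1,
                )
            )
    return regions
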