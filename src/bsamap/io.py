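"""Readers and writers for every on-disk artifact.

Formats
-------
* parent base-count TSV: ``chrom pos ref count_A count_C count_G count_T count_other``
* bulk allele-count TSV: ``chrom pos wt_allele mut_allele wt_count mut_count other_count``
* chromosome length TSV: ``chrom length``
* parent SNP TSV: ``chrom pos wt_allele mut_allele depth purity``
* window-score TSV: ``chrom start end n_blocks avg_neglog10p significant``
* BED (written): 0-based half-open intervals for candidate regions and
  origin segments

All TSVs are tab-separated UTF-8 with a mandatory header; ``.`` denotes a
missing value; lines starting with ``#`` are comments (used for
provenance headers) and are ignored on read. Files ending in ``.gz`` are
transparently (de)compressed. Internal coordinates are 1-based inclusive;
BED output converts to 0-based half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, IO, Iterable, Iterator, List, Optional, Sequence, Tuple

from .errors import FormatError, ValidationError
from .types import (
    BulkSiteCount,
    CandidateRegion,
    GenomeLayout,
    OriginSegment,
    ParentSnp,
    SiteBaseCount,
    Window,
)

MISSING = "."


def _open_text(path: str, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


def _rows(path: str, required: Sequence[str]) -> Iterator[Tuple[int, Dict[str, str]]]:
    """Yield (line_number, row dict) from a headered TSV, skipping comments."""
    with _open_text(path) as handle:
        lineno = 0
        header: Optional[List[str]] = None
        for raw in handle:
            lineno += 1
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in required if c not in header]
                if missing:
                    raise FormatError(
                        f"{path}: missing required column(s) {missing} in header (line {lineno})"
                    )
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, header has {len(header)}"
                )
            yield lineno, dict(zip(header, fields))
        if header is None:
            raise FormatError(f"{path}: empty file, header required")


def _int(row: Dict[str, str], col: str, path: str, lineno: int, minimum: Optional[int] = None) -> int:
    try:
        value = int(row[col])
    except ValueError:
        raise ValidationError(f"{path}: line {lineno}: column {col!r} is not an integer: {row[col]!r}")
    if minimum is not None and value < minimum:
        raise ValidationError(
            f"{path}: line {lineno}: column {col!r} must be >= {minimum}, got {value}"
        )
    return value


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------

def read_base_count_table(path: str) -> List[SiteBaseCount]:
    """Read a per-site base-count TSV into SiteBaseCount records (file order)."""
    required = ["chrom", "pos", "ref", "count_A", "count_C", "count_G", "count_T", "count_other"]
    out: List[SiteBaseCount] = []
    for lineno, row in _rows(path, required):
        try:
            out.append(
                SiteBaseCount(
                    chrom=row["chrom"],
                    pos=_int(row, "pos", path, lineno, minimum=1),
                    ref_base=row["ref"],
                    counts={b: _int(row, f"count_{b}", path, lineno, minimum=0) for b in "ACGT"},
                    other=_int(row, "count_other", path, lineno, minimum=0),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return out


def read_bulk_count_table(path: str) -> List[BulkSiteCount]:
    """Read a bulk parental-allele count TSV into BulkSiteCount records."""
    required = ["chrom", "pos", "wt_allele", "mut_allele", "wt_count", "mut_count", "other_count"]
    out: List[BulkSiteCount] = []
    for lineno, row in _rows(path, required):
        try:
            out.append(
                BulkSiteCount(
                    chrom=row["chrom"],
                    pos=_int(row, "pos", path, lineno, minimum=1),
                    wt_allele=row["wt_allele"],
                    mut_allele=row["mut_allele"],
                    wt_count=_int(row, "wt_count", path, lineno, minimum=0),
                    mut_count=_int(row, "mut_count", path, lineno, minimum=0),
                    other_count=_int(row, "other_count", path, lineno, minimum=0),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return out


def read_genome_layout(path: str) -> GenomeLayout:
    """Read a chromosome length table (columns chrom, length)."""
    pairs: List[Tuple[str, int]] = []
    for lineno, row in _rows(path, ["chrom", "length"]):
        pairs.append((row["chrom"], _int(row, "length", path, lineno, minimum=1)))
    return GenomeLayout.from_pairs(pairs)


def read_parent_snp_table(path: str) -> List[ParentSnp]:
    """Read a called parent-SNP TSV (columns chrom,pos,wt_allele,mut_allele,depth,purity)."""
    required = ["chrom", "pos", "wt_allele", "mut_allele", "depth", "purity"]
    out: List[ParentSnp] = []
    for lineno, row in _rows(path, required):
        try:
            out.append(
                ParentSnp(
                    chrom=row["chrom"],
                    pos=_int(row, "pos", path, lineno, minimum=1),
                    wt_allele=row["wt_allele"],
                    mut_allele=row["mut_allele"],
                    parent_depth=_int(row, "depth", path, lineno, minimum=0),
                    parent_purity=float(row["purity"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def _write_table(
    path: str,
    header: Sequence[str],
    rows: Iterable[Sequence[object]],
    header_lines: Optional[Sequence[str]] = None,
) -> None:
    with _open_text(path, "wt") as handle:
        for line in header_lines or ():
            handle.write(f"# {line}\n")
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def write_base_count_table(
    sites: Sequence[SiteBaseCount], path: str, header_lines: Optional[Sequence[str]] = None
) -> None:
    _write_table(
        path,
        ["chrom", "pos", "ref", "count_A", "count_C", "count_G", "count_T", "count_other"],
        (
            [s.chrom, s.pos, s.ref_base, s.counts["A"], s.counts["C"], s.counts["G"], s.counts["T"], s.other]
            for s in sites
        ),
        header_lines,
    )


def write_bulk_count_table(
    sites: Sequence[BulkSiteCount], path: str, header_lines: Optional[Sequence[str]] = None
) -> None:
    _write_table(
        path,
        ["chrom", "pos", "wt_allele", "mut_allele", "wt_count", "mut_count", "other_count"],
        (
            [s.chrom, s.pos, s.wt_allele, s.mut_allele, s.wt_count, s.mut_count, s.other_count]
            for s in sites
        ),
        header_lines,
    )


def write_genome_layout(
    layout: GenomeLayout, path: str, header_lines: Optional[Sequence[str]] = None
) -> None:
    _write_table(path, ["chrom", "length"], ([c, l] for c, l in layout), header_lines)


def write_parent_snp_table(
    snps: Sequence[ParentSnp], path: str, header_lines: Optional[Sequence[str]] = None
) -> None:
    _write_table(
        path,
        ["chrom", "pos", "wt_allele", "mut_allele", "depth", "purity"],
        (
            [s.chrom, s.pos, s.wt_allele, s.mut_allele, s.parent_depth, f"{s.parent_purity:.6g}"]
            for s in snps
        ),
        header_lines,
    )


def write_windows_tsv(
    windows: Sequence[Window], path: str, header_lines: Optional[Sequence[str]] = None
) -> None:
    """Write window scores; empty windows report '.' for the score."""
    _write_table(
        path,
        ["chrom", "start", "end", "n_blocks", "avg_neglog10p", "significant"],
        (
            [
                w.chrom,
                w.start,
                w.end,
                w.n_blocks,
                MISSING if w.avg_neglog10p is None else f"{w.avg_neglog10p:.6g}",
                int(w.significant),
            ]
            for w in windows
        ),
        header_lines,
    )


# ---------------------------------------------------------------------------
# BED output (0-based half-open)
# ---------------------------------------------------------------------------

def to_bed_interval(start: int, end: int) -> Tuple[int, int]:
    """Convert a 1-based inclusive interval [start, end] to BED (start-1, end)."""
    if start < 1 or end < start:
        raise ValidationError(f"invalid 1-based interval [{start}, {end}]")
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> Tuple[int, int]:
    """Convert a BED half-open interval to 1-based inclusive [start, end]."""
    if bed_start < 0 or bed_end <= bed_start:
        raise ValidationError(f"invalid BED interval ({bed_start}, {bed_end})")
    return bed_start + 1, bed_end


def write_regions_bed(
    regions: Sequence[CandidateRegion], path: str, header_lines: Optional[Sequence[str]] = None
) -> None:
    """Write candidate regions as 5-column BED sorted by (chrom, start)."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with _open_text(path, "wt") as handle:
        for line in header_lines or ():
            handle.write(f"# {line}\n")
        for i, region in enumerate(ordered, start=1):
            b0, b1 = to_bed_interval(region.start, region.end)
            handle.write(
                f"{region.chrom}\t{b0}\t{b1}\tregion_{i}\t{region.peak_score:.6g}\n"
            )


def write_segments_bed(
    segments: Sequence[OriginSegment], path: str, header_lines: Optional[Sequence[str]] = None
) -> None:
    """Write origin segments as 5-column BED sorted by (chrom, start)."""
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start, s.end))
    with _open_text(path, "wt") as handle:
        for line in header_lines or ():
            handle.write(f"# {line}\n")
        for i, seg in enumerate(ordered, start=1):
            b0, b1 = to_bed_interval(seg.start, seg.end)
            handle.write(f"{seg.chrom}\t{b0}\t{b1}\tsegment_{i}\t{seg.mean_purity:.6g}\n")


def read_regions_bed(path: str) -> List[CandidateRegion]:
    """Read a BED file back into CandidateRegion records (1-based inclusive).

    Only the first three columns are required; the score column, when
    present, populates ``peak_score`` (else 0). ``n_windows`` is not
    stored in BED and is read back as 1.
    """
    regions: List[CandidateRegion] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >= 3 columns")
            try:
                start, end = from_bed_interval(int(fields[1]), int(fields[2]))
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer BED coordinates")
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = 0.0
            regions.append(
                CandidateRegion(
                    chrom=fields[0], start=start, end=end,
                    peak_score=score, n_windows=1,
                )
            )
    return regions


# ---------------------------------------------------------------------------
# VCF entry point
# ---------------------------------------------------------------------------

@dataclass
class VcfImportSummary:
    """Bookkeeping for a VCF import: what was kept and why records were skipped."""

    n_retained: int = 0
    skipped: Dict[str, int] = field(default_factory=dict)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())

    def _skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1


def read_vcf_biallelic_snps(
    path: str, parent_sample: str, bulk_sample: str
) -> Tuple[List[ParentSnp], List[BulkSiteCount], VcfImportSummary]:
    """Import parent SNPs and bulk allele counts from a joint VCF.

    Only biallelic SNP records where the parent sample is homozygous for
    the alternate allele are retained; everything else is skipped and
    tallied in the summary. The bulk sample must carry per-allele depths
    (FORMAT/AD); the wild-type allele is REF, the mutant allele ALT.
    """
    import pysam

    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    for name in (parent_sample, bulk_sample):
        if name not in samples:
            raise FormatError(f"{path}: sample {name!r} not in VCF (has {samples})")
    if "AD" not in vcf.header.formats:
        raise FormatError(f"{path}: VCF lacks FORMAT/AD allele depths")

    snps: List[ParentSnp] = []
    bulk: List[BulkSiteCount] = []
    summary = VcfImportSummary()
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            summary._skip("not_biallelic")
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            summary._skip("not_snp")
            continue
        parent = rec.samples[parent_sample]
        gt = parent.get("GT")
        if gt is None or None in gt or set(gt) != {1}:
            summary._skip("parent_not_hom_alt")
            continue
        bulk_ad = rec.samples[bulk_sample].get("AD")
        if bulk_ad is None or len(bulk_ad) < 2 or any(x is None for x in bulk_ad[:2]):
            summary._skip("bulk_missing_AD")
            continue
        parent_ad = parent.get("AD")
        if parent_ad is not None and not any(x is None for x in parent_ad[:2]):
            depth = int(sum(x for x in parent_ad if x is not None))
            purity = (parent_ad[1] / depth) if depth > 0 else 0.0
        else:
            depth, purity = 0, 0.0
        snps.append(
            ParentSnp(
                chrom=rec.chrom, pos=rec.pos, wt_allele=ref, mut_allele=alt,
                parent_depth=depth, parent_purity=purity,
            )
        )
        bulk.append(
            BulkSiteCount(
                chrom=rec.chrom, pos=rec.pos, wt_allele=ref, mut_allele=alt,
                wt_count=int(bulk_ad[0]), mut_count=int(bulk_ad[1]),
                other_count=int(sum(x or 0 for x in bulk_ad[2:])),
            )
        )
        summary.n_retained += 1
    return snps, bulk, summary
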