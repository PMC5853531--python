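"""Domain types shared across the bsamap modules.

Coordinates are 1-based inclusive throughout the package (the pileup/VCF
convention); conversion to 0-based half-open happens only when writing BED
(:mod:`bsamap.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterator, Optional, Sequence, Tuple

from .errors import ValidationError

#: Canonical nucleotide order; ties in purity calls are broken in this order.
BASES: Tuple[str, str, str, str] = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# per-site evidence
# ---------------------------------------------------------------------------

@dataclass
class SiteBaseCount:
    """Read-base tally for one sample at one reference position.

    ``counts`` maps each of A/C/G/T to the number of reads carrying that
    base; ``other`` counts non-ACGT observations (ambiguity codes, deletions
    in reads, ...), which contribute to depth but can never be called.
    """

    chrom: str
    pos: int
    ref_base: str
    counts: Dict[str, int]
    other: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base not in BASES:
            raise ValidationError(f"ref_base must be one of A/C/G/T, got {self.ref_base!r}")
        counts = {b: int(self.counts.get(b, 0)) for b in BASES}
        for base, n in counts.items():
            if n < 0:
                raise ValidationError(f"negative count for base {base}: {n}")
        self.counts = counts
        if self.other < 0:
            raise ValidationError(f"negative other count: {self.other}")

    @property
    def depth(self) -> int:
        """Total observations at the site, including non-ACGT reads."""
        return sum(self.counts.values()) + self.other


@dataclass
class BulkSiteCount:
    """Parental-allele read tally for the bulk pool at one marker site.

    ``wt_count``/``mut_count`` are reads matching the wild-type and mutant
    parent allele respectively; ``other_count`` covers reads matching
    neither (sequencing error, third alleles).
    """

    chrom: str
    pos: int
    wt_allele: str
    mut_allele: str
    wt_count: int
    mut_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.wt_allele == self.mut_allele:
            raise ValidationError(
                f"wt_allele and mut_allele must differ, both are {self.wt_allele!r} "
                f"at {self.chrom}:{self.pos}"
            )
        for name in ("wt_count", "mut_count", "other_count"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative {name} at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        """Informative depth: wt + mut reads (``other`` excluded)."""
        return self.wt_count + self.mut_count

    @property
    def mut_fraction(self) -> float:
        """Mutant-allele read fraction among informative reads."""
        d = self.depth
        if d == 0:
            raise ValidationError(f"mut_fraction undefined at depth 0 ({self.chrom}:{self.pos})")
        return self.mut_count / d


@dataclass(frozen=True)
class ParentSnp:
    """A homozygous parent-vs-reference SNP: the marker unit of the scan.

    ``wt_allele`` is the reference (wild-type parent) base; ``mut_allele``
    the base fixed in the mutant parent. ``parent_depth``/``parent_purity``
    record the evidence the call was made from.
    """

    chrom: str
    pos: int
    wt_allele: str
    mut_allele: str
    parent_depth: int
    parent_purity: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.wt_allele == self.mut_allele:
            raise ValidationError(f"SNP alleles must differ at {self.chrom}:{self.pos}")
        if self.wt_allele not in BASES or self.mut_allele not in BASES:
            raise ValidationError(f"alleles must be A/C/G/T at {self.chrom}:{self.pos}")
        if self.parent_depth < 0:
            raise ValidationError("parent_depth must be >= 0")
        if not (0.0 <= self.parent_purity <= 1.0):
            raise ValidationError(f"parent_purity must be in [0,1], got {self.parent_purity}")


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", tuple((str(c), int(l)) for c, l in self.chromosomes))

    @classmethod
    def from_pairs(cls, pairs: Sequence[Tuple[str, int]]) -> "GenomeLayout":
        return cls(tuple(pairs))

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


# ---------------------------------------------------------------------------
# cross design
# ---------------------------------------------------------------------------

class CrossKind(str, enum.Enum):
    """Supported mapping-population designs."""

    BC1_TO_MUTANT = "bc1_mutant"
    F2_RECESSIVE = "f2_recessive"


@dataclass(frozen=True)
class CrossDesign:
    """Mapping-population model fixing the bulk allele-frequency null.

    In a backcross of the F1 to the mutant parent (BC1), every progeny
    carries one mutant-parent haplotype, so a bulk of phenotype-selected
    recessives has expected mutant-allele frequency 0.75 at unlinked loci
    and 1.0 at the causal locus. In an F2 recessive bulk the corresponding
    expectations are 0.5 and 1.0.
    """

    kind: CrossKind
    null_freq: float
    causal_freq: float = 1.0

    _EXPECTED_NULL = {CrossKind.BC1_TO_MUTANT: 0.75, CrossKind.F2_RECESSIVE: 0.5}

    def __post_init__(self) -> None:
        if not (0.0 < self.null_freq < self.causal_freq <= 1.0):
            raise ValidationError(
                f"require 0 < null_freq < causal_freq <= 1, got {self.null_freq}, {self.causal_freq}"
            )
        expected = self._EXPECTED_NULL[CrossKind(self.kind)]
        if abs(self.null_freq - expected) > 1e-12:
            raise ValidationError(
                f"{self.kind} implies null_freq {expected}, got {self.null_freq}"
            )

    @classmethod
    def bc1_to_mutant(cls) -> "CrossDesign":
        """BC1 (F1 x mutant parent) with a recessive-phenotype bulk."""
        return cls(CrossKind.BC1_TO_MUTANT, 0.75)

    @classmethod
    def f2_recessive(cls) -> "CrossDesign":
        """F2 with a homozygous-recessive bulk."""
        return cls(CrossKind.F2_RECESSIVE, 0.5)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

@dataclass
class Block:
    """A run of consecutive SNPs pooled to the minimum informative depth.

    Blocks are the unit on which the exact test is computed; ``p_value``
    is filled in by :func:`bsamap.blocks.block_p_value`.
    """

    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int
    mut_reads: int
    wt_reads: int
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValidationError(f"block start {self.start_pos} > end {self.end_pos}")
        if self.n_snps < 1:
            raise ValidationError("block must contain at least one SNP")
        if self.mut_reads < 0 or self.wt_reads < 0:
            raise ValidationError("negative read counts in block")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value must be in (0,1], got {self.p_value}")

    @property
    def depth(self) -> int:
        return self.mut_reads + self.wt_reads

    @property
    def midpoint(self) -> int:
        """Rounded-down mean of the first and last member SNP positions."""
        return (self.start_pos + self.end_pos) // 2


@dataclass(frozen=True)
class BlockParams:
    """Parameters for block construction and the block-level exact test."""

    min_block_depth: int = 20
    test: str = "binomial"          # {"fisher", "binomial"}
    sidedness: str = "two_sided"    # {"two_sided", "greater"}

    def __post_init__(self) -> None:
        if self.min_block_depth < 1:
            raise ValidationError("min_block_depth must be >= 1")
        if self.test not in ("fisher", "binomial"):
            raise ValidationError(f"unknown test {self.test!r}")
        if self.sidedness not in ("two_sided", "greater"):
            raise ValidationError(f"unknown sidedness {self.sidedness!r}")


# ---------------------------------------------------------------------------
# windows / regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """One sliding-window cell of the genome scan.

    ``avg_neglog10p`` is the arithmetic mean of -log10(P) over member
    blocks, or ``None`` for windows with no blocks (no evidence, which is
    distinct from evidence of no difference). ``filtered`` marks windows
    with fewer than the minimum number of blocks; they are never
    significant regardless of score.
    """

    chrom: str
    start: int
    end: int
    n_blocks: int
    avg_neglog10p: Optional[float]
    significant: bool
    filtered: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("window start > end")
        if self.n_blocks < 0:
            raise ValidationError("negative block count")
        if self.n_blocks == 0 and self.avg_neglog10p is not None:
            raise ValidationError("empty window must have undefined score")
        if self.avg_neglog10p is not None and self.avg_neglog10p < 0:
            raise ValidationError("avg_neglog10p must be >= 0")


@dataclass(frozen=True)
class ScanParams:
    """Sliding-window scan settings (2 Mb windows, 100 kb step by default)."""

    window_size: int = 2_000_000
    step: int = 100_000
    min_blocks: int = 5
    threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.step < 1:
            raise ValidationError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ValidationError("step must not exceed window_size")
        if self.min_blocks < 1:
            raise ValidationError("min_blocks must be >= 1")
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal union of overlapping/abutting significant windows."""

    chrom: str
    start: int
    end: int
    peak_score: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("region start > end")
        if self.n_windows < 1:
            raise ValidationError("region must contain at least one window")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# origin narrowing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OriginSegment:
    """A run of SNPs whose bulk reads derive (near-)exclusively from the mutant parent."""

    chrom: str
    start: int
    end: int
    n_snps: int
    mean_purity: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("segment start > end")
        if self.n_snps < 1:
            raise ValidationError("segment must contain at least one SNP")
        if not (0.0 <= self.mean_purity <= 1.0):
            raise ValidationError("mean_purity must be in [0,1]")


@dataclass(frozen=True)
class NarrowParams:
    """Thresholds for the sequence-origin narrowing step.

    ``tolerated_discordant_reads`` guards against single miscalled reads
    at pool-sequencing depth: an impure site only breaks a run when its
    wild-type read count exceeds this tolerance (a lone discordant read
    at ~10x is within the error model, two are evidence of a recombinant
    haplotype in the bulk).
    """

    min_purity: float = 0.95
    min_snps: int = 10
    min_site_depth: int = 5
    tolerated_discordant_reads: int = 1

    def __post_init__(self) -> None:
        if not (0.5 < self.min_purity <= 1.0):
            raise ValidationError("min_purity must be in (0.5, 1]")
        if self.min_snps < 1:
            raise ValidationError("min_snps must be >= 1")
        if self.min_site_depth < 1:
            raise ValidationError("min_site_depth must be >= 1")
        if self.tolerated_discordant_reads < 0:
            raise ValidationError("tolerated_discordant_reads must be >= 0")


# ---------------------------------------------------------------------------
# SNP calling parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpCallParams:
    """Homozygous-SNP calling thresholds: depth >= 10, major allele >= 90%."""

    min_depth: int = 10
    min_purity: float = 0.90

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
        if not (0.0 < self.min_purity <= 1.0):
            raise ValidationError("min_purity must be in (0, 1]")
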