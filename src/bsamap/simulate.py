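"""Synthetic genetic-cross and pooled-sequencing data generator.

The generator emulates the study design the scan statistics are built
for: a mutant line carrying a recessive allele is crossed to a wild-type
reference line; the F1 is backcrossed to the mutant parent (BC1) or
selfed (F2); progeny showing the recessive phenotype are bulked and the
pool is shotgun-sequenced at modest depth. Every step is driven by a
single seeded generator, so identical configurations produce
byte-identical output files.

Model summary
-------------
* Parental SNP markers are placed along each chromosome as a homogeneous
  Poisson process with the configured mean spacing.
* Each F1 gamete receives Poisson(recomb_rate x chromosome length)
  crossovers at uniform positions, alternating parental origin from a
  fair starting draw (no interference).
* BC1 progeny = F1 gamete + an intact mutant-parent haplotype; F2
  progeny = two independent F1 gametes. Phenotype is recessive: mutant
  iff the individual is homozygous mutant at the causal locus.
* Pooling weights every selected individual equally. Per-SNP read depth
  is Poisson(mean_depth); given the bulk's true mutant-allele frequency
  f, each read reports the mutant allele with probability
  f(1-e) + (1-f)e/3, the wild-type allele with (1-f)(1-e) + f e/3, and
  some other base otherwise, where e is the per-read miscall rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as bio
from .errors import InputError, ValidationError
from .types import BASES, BulkSiteCount, CrossDesign, CrossKind, GenomeLayout, ParentSnp

#: Mean mapped depth used for the simulated parent line, roughly the
#: deep-coverage parent sequencing the SNP map would come from.
PARENT_MEAN_DEPTH = 38


def default_layout() -> GenomeLayout:
    """Five 30 Mb chromosomes: a desk-scale stand-in for a large plant genome."""
    return GenomeLayout.from_pairs([(f"chr{i}", 30_000_000) for i in range(1, 6)])


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated mapping experiment.

    Defaults model a BC1 mapping population of 120 progeny from which a
    28-individual recessive bulk is drawn and pool-sequenced at 10x SNP
    depth with a 1% per-read miscall rate, over five 30 Mb chromosomes
    carrying one marker every 10 kb on average and a genome-wide
    recombination rate of 2 cM/Mb.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    snp_spacing: float = 10_000.0
    n_progeny: int = 120
    bulk_size: int = 28
    design: CrossDesign = field(default_factory=CrossDesign.bc1_to_mutant)
    causal_locus: Tuple[str, int] = ("chr3", 15_000_000)
    recomb_rate: float = 2e-8
    mean_depth: float = 10.0
    error_rate: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        if self.snp_spacing <= 0:
            raise ValidationError("snp_spacing must be positive")
        if self.n_progeny < 1 or self.bulk_size < 1:
            raise ValidationError("n_progeny and bulk_size must be >= 1")
        if not (0.0 <= self.error_rate <= 1.0) or not (0.0 <= self.recomb_rate <= 1.0):
            raise ValidationError("rates must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        chrom, pos = self.causal_locus
        if chrom not in self.layout:
            raise ValidationError(f"causal chromosome {chrom!r} not in layout")
        if not (1 <= pos <= self.layout.length_of(chrom)):
            raise ValidationError(f"causal position {pos} outside chromosome {chrom}")


@dataclass
class ProgenyGenotypes:
    """Genotypes (mutant-allele copies per SNP) and phenotypes of a cross."""

    chroms: np.ndarray        # SNP chromosome names, shape (n_snps,)
    positions: np.ndarray     # SNP positions, shape (n_snps,)
    genotypes: np.ndarray     # uint8 copies of the mutant allele, (n_progeny, n_snps)
    phenotype_mutant: np.ndarray  # bool, (n_progeny,)
    causal_index: int         # column index of the causal SNP

    @property
    def n_progeny(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, with ground truth."""

    config: SimConfig
    snps: List[ParentSnp]
    progeny: ProgenyGenotypes
    bulk_counts: List[BulkSiteCount]
    truth: pd.DataFrame  # columns chrom, pos, truth_freq, is_causal
    bulk_indices: np.ndarray


# ---------------------------------------------------------------------------
# marker placement
# ---------------------------------------------------------------------------

def place_snps(
    layout: GenomeLayout,
    snp_spacing: float,
    rng: np.random.Generator,
    parent_mean_depth: float = PARENT_MEAN_DEPTH,
) -> List[ParentSnp]:
    """Place parental SNP markers as a homogeneous process along each chromosome.

    Inter-marker gaps are exponential with the given mean spacing; allele
    pairs are drawn per SNP; the recorded parent evidence (depth, purity)
    models a clean deep-coverage homozygous call.
    """
    if snp_spacing <= 0:
        raise ValidationError("snp_spacing must be positive")
    snps: List[ParentSnp] = []
    for chrom, length in layout:
        pos = 0.0
        positions: List[int] = []
        while True:
            pos += rng.exponential(snp_spacing)
            ipos = int(np.ceil(pos))
            if ipos > length:
                break
            if positions and ipos <= positions[-1]:
                ipos = positions[-1] + 1
                if ipos > length:
                    break
            positions.append(ipos)
        for p in positions:
            wt = BASES[rng.integers(4)]
            mut = [b for b in BASES if b != wt][rng.integers(3)]
            depth = max(int(rng.poisson(parent_mean_depth)), 10)
            snps.append(
                ParentSnp(
                    chrom=chrom, pos=p, wt_allele=wt, mut_allele=mut,
                    parent_depth=depth, parent_purity=1.0,
                )
            )
    return snps


def _ensure_causal_snp(
    snps: List[ParentSnp], causal_locus: Tuple[str, int], rng: np.random.Generator
) -> List[ParentSnp]:
    """Guarantee a marker exactly at the causal position (the causal SNP itself)."""
    chrom, pos = causal_locus
    if any(s.chrom == chrom and s.pos == pos for s in snps):
        return snps
    wt = BASES[rng.integers(4)]
    mut = [b for b in BASES if b != wt][rng.integers(3)]
    causal = ParentSnp(
        chrom=chrom, pos=pos, wt_allele=wt, mut_allele=mut,
        parent_depth=max(int(rng.poisson(PARENT_MEAN_DEPTH)), 10), parent_purity=1.0,
    )
    merged = snps + [causal]
    order = GenomeLayoutOrder([s.chrom for s in merged])
    merged.sort(key=lambda s: (order.rank(s.chrom), s.pos))
    return merged


class GenomeLayoutOrder:
    """Stable chromosome ordering by first appearance."""

    def __init__(self, chroms: Sequence[str]) -> None:
        self._rank = {}
        for c in chroms:
            if c not in self._rank:
                self._rank[c] = len(self._rank)

    def rank(self, chrom: str) -> int:
        return self._rank[chrom]


# ---------------------------------------------------------------------------
# meiosis and progeny
# ---------------------------------------------------------------------------

def _f1_gamete_origins(
    positions: np.ndarray, length: int, recomb_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Mutant-parent origin (bool per SNP) of one F1 gamete for one chromosome.

    Crossovers are Poisson(recomb_rate * length) at uniform positions;
    parental origin alternates along the chromosome from a fair starting
    draw. With no crossovers the whole chromosome is one parental block.
    """
    n_xo = rng.poisson(recomb_rate * length)
    start_is_mut = bool(rng.integers(2))
    if n_xo == 0:
        return np.full(positions.shape, start_is_mut, dtype=bool)
    breaks = np.sort(rng.uniform(0, length, size=n_xo))
    crossings = np.searchsorted(breaks, positions, side="left")
    return (crossings % 2 == 0) == start_is_mut


def simulate_progeny(
    snps: Sequence[ParentSnp], config: SimConfig, rng: np.random.Generator
) -> ProgenyGenotypes:
    """Simulate the mapping population's genotypes at every marker SNP.

    Requires a marker at the causal position (``simulate_bsa_dataset``
    guarantees one); phenotype is recessive on the causal genotype.
    """
    chroms = np.array([s.chrom for s in snps])
    positions = np.array([s.pos for s in snps], dtype=np.int64)
    causal_chrom, causal_pos = config.causal_locus
    causal_matches = np.flatnonzero((chroms == causal_chrom) & (positions == causal_pos))
    if causal_matches.size == 0:
        raise InputError(
            f"no marker at the causal locus {causal_chrom}:{causal_pos}; "
            "include one (simulate_bsa_dataset does this automatically)"
        )
    causal_index = int(causal_matches[0])

    chrom_slices = []
    for chrom, length in config.layout:
        idx = np.flatnonzero(chroms == chrom)
        chrom_slices.append((idx, positions[idx].astype(float), length))

    n = config.n_progeny
    genotypes = np.zeros((n, positions.size), dtype=np.uint8)
    n_gametes = 1 if config.design.kind == CrossKind.BC1_TO_MUTANT else 2
    for i in range(n):
        copies = np.zeros(positions.size, dtype=np.uint8)
        for _ in range(n_gametes):
            for idx, pos_f, length in chrom_slices:
                origins = _f1_gamete_origins(pos_f, length, config.recomb_rate, rng)
                copies[idx] += origins.astype(np.uint8)
        if config.design.kind == CrossKind.BC1_TO_MUTANT:
            copies += 1  # the recurrent mutant-parent haplotype
        genotypes[i] = copies
    phenotype = genotypes[:, causal_index] == 2
    return ProgenyGenotypes(
        chroms=chroms, positions=positions, genotypes=genotypes,
        phenotype_mutant=phenotype, causal_index=causal_index,
    )


# ---------------------------------------------------------------------------
# pooling and sequencing
# ---------------------------------------------------------------------------

def make_bulk_counts(
    progeny: ProgenyGenotypes,
    snps: Sequence[ParentSnp],
    config: SimConfig,
    rng: np.random.Generator,
    selection: str = "mutant",
) -> Tuple[List[BulkSiteCount], pd.DataFrame, np.ndarray]:
    """Draw the bulk, compute truth frequencies, and sample pooled reads.

    ``selection`` is ``"mutant"`` (phenotype-selected bulk, the mapping
    design) or ``"random"`` (bulk drawn ignoring phenotype, the matched
    null experiment). Returns (bulk counts, truth table, bulk indices).
    """
    if selection not in ("mutant", "random"):
        raise InputError(f"selection must be 'mutant' or 'random', got {selection!r}")
    if selection == "mutant":
        candidates = np.flatnonzero(progeny.phenotype_mutant)
        if candidates.size < config.bulk_size:
            raise InputError(
                f"only {candidates.size} mutant progeny available for a bulk of "
                f"{config.bulk_size}; increase n_progeny"
            )
    else:
        candidates = np.arange(progeny.n_progeny)
    bulk_idx = np.sort(rng.choice(candidates, size=config.bulk_size, replace=False))

    copies = progeny.genotypes[bulk_idx].astype(np.int64)
    freq = copies.sum(axis=0) / (2 * config.bulk_size)

    e = config.error_rate
    p_mut = freq * (1 - e) + (1 - freq) * (e / 3)
    p_wt = (1 - freq) * (1 - e) + freq * (e / 3)
    p_other = np.clip(1.0 - p_mut - p_wt, 0.0, 1.0)

    depth = rng.poisson(config.mean_depth, size=freq.size)
    mut_reads = rng.binomial(depth, p_mut)
    rest = depth - mut_reads
    denom = p_wt + p_other
    with np.errstate(invalid="ignore", divide="ignore"):
        p_wt_given_rest = np.where(denom > 0, p_wt / denom, 1.0)
    wt_reads = rng.binomial(rest, p_wt_given_rest)
    other_reads = rest - wt_reads

    bulk: List[BulkSiteCount] = []
    for i, snp in enumerate(snps):
        bulk.append(
            BulkSiteCount(
                chrom=snp.chrom, pos=snp.pos,
                wt_allele=snp.wt_allele, mut_allele=snp.mut_allele,
                wt_count=int(wt_reads[i]), mut_count=int(mut_reads[i]),
                other_count=int(other_reads[i]),
            )
        )
    causal_chrom, causal_pos = config.causal_locus
    truth = pd.DataFrame(
        {
            "chrom": progeny.chroms,
            "pos": progeny.positions,
            "truth_freq": freq,
            "is_causal": (progeny.chroms == causal_chrom)
            & (progeny.positions == causal_pos),
        }
    )
    return bulk, truth, bulk_idx


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

def simulate_bsa_dataset(
    config: SimConfig = SimConfig(),
    out_dir: Optional[str] = None,
    selection: str = "mutant",
) -> SimulatedDataset:
    """Run the whole generator and optionally write the four input files.

    When ``out_dir`` is given, writes ``snps.tsv``, ``bulk_counts.tsv``,
    ``genome.tsv`` and ``truth.tsv`` in the package's own formats.
    Identical configuration (including seed) yields byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    snps = place_snps(config.layout, config.snp_spacing, rng)
    snps = _ensure_causal_snp(snps, config.causal_locus, rng)
    progeny = simulate_progeny(snps, config, rng)
    bulk, truth, bulk_idx = make_bulk_counts(progeny, snps, config, rng, selection)
    dataset = SimulatedDataset(
        config=config, snps=snps, progeny=progeny,
        bulk_counts=bulk, truth=truth, bulk_indices=bulk_idx,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bio.write_parent_snp_table(snps, str(out / "snps.tsv"))
        bio.write_bulk_count_table(bulk, str(out / "bulk_counts.tsv"))
        bio.write_genome_layout(config.layout, str(out / "genome.tsv"))
        truth_out = truth.copy()
        truth_out["is_causal"] = truth_out["is_causal"].astype(int)
        truth_out.to_csv(out / "truth.tsv", sep="\t", index=False)
    return dataset


def config_from_dict(data: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (YAML-friendly).

    Recognised keys mirror the SimConfig fields; ``layout`` is a list of
    ``[chrom, length]`` pairs, ``design`` one of ``bc1_mutant`` /
    ``f2_recessive``, ``causal_locus`` a ``[chrom, pos]`` pair.
    """
    kwargs = dict(data)
    if "layout" in kwargs:
        kwargs["layout"] = GenomeLayout.from_pairs([(c, int(l)) for c, l in kwargs["layout"]])
    if "design" in kwargs and not isinstance(kwargs["design"], CrossDesign):
        kind = CrossKind(kwargs["design"])
        kwargs["design"] = (
            CrossDesign.bc1_to_mutant()
            if kind == CrossKind.BC1_TO_MUTANT
            else CrossDesign.f2_recessive()
        )
    if "causal_locus" in kwargs:
        chrom, pos = kwargs["causal_locus"]
        kwargs["causal_locus"] = (str(chrom), int(pos))
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise InputError(f"unknown simulator config keys: {sorted(unknown)}")
    return SimConfig(**kwargs)
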