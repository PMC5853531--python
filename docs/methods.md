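# Methods

## Overview

`bsamap` maps recessive loci by bulked segregant analysis with pooled
whole-genome sequencing (BSA-seq). The experimental design it models: a
mutant line is crossed to a wild-type reference line; the F1 is either
backcrossed to the mutant parent (BC1) or selfed (F2); progeny showing the
recessive phenotype are pooled in equal ratio and sequenced as one sample,
alongside deep sequencing of the mutant parent. Around the causal locus
every selected individual carries the mutant-parent haplotype, so the
pool's mutant-allele read fraction is pulled toward 1; everywhere else it
segregates at the design null. The pipeline is:

1. **Marker discovery** — homozygous parent-vs-reference SNPs from
   per-site base counts (`snp_calling`).
2. **Block construction and exact testing** — consecutive SNPs pooled to a
   minimum bulk depth, each block tested against the design null allele
   frequency (`blocks`).
3. **Sliding-window scan** — average −log10(P) over blocks per window;
   windows above threshold merged into candidate regions (`windows`).
4. **Sequence-origin narrowing** — runs of SNPs whose bulk reads are
   (near-)exclusively mutant-parent inside candidate regions (`narrowing`).
5. **Simulation** — a seeded generator of the whole design with ground
   truth (`simulate`), used for end-to-end validation.

## Cross designs and the null

For a BC1 to the mutant parent, progeny are ½ Mm and ½ MM at any locus;
selecting recessives fixes the causal locus (bulk frequency 1.0) and
leaves unlinked loci at E[f] = 0.75. For an F2 recessive bulk the
corresponding values are 1.0 and 0.5. `CrossDesign` pins these constants;
`genetics.expected_bulk_allele_freq` exposes them.

At a locus at physical distance d from the causal gene, with crossovers a
homogeneous Poisson process of rate ρ per bp (no interference), the
recombination fraction is Haldane's r(d) = (1 − e^(−2ρd))/2 and the
expected BC1 bulk frequency is f(d) = 1 − r(d)/2. Note f(d) approaches
0.75 only asymptotically: at 1 Morgan it is still ≈0.78. The simulator
tests therefore validate "unlinked" expectations on chromosomes that do
not carry the causal locus, and validate the linked decay against the
closed form above.

## Marker calling

A site is called a homozygous parent SNP iff depth ≥ `min_depth`
(default 10), the major base is at least `min_purity` (default 0.90,
inclusive) of **all** observations at the site (non-ACGT reads included in
the denominator), and the major base differs from the reference. Ties
between equally frequent bases break in the fixed order A<C<G<T for
determinism. Only substitutions are called.

## Blocks and exact tests

At ~10× pool depth single SNPs are underpowered, so consecutive SNPs are
pooled greedily left-to-right until the informative depth (wt + mut reads;
reads matching neither parental allele are excluded) reaches
`min_block_depth` (default 20). A trailing run that never reaches the
minimum is discarded and reported. Blocks never span chromosomes and the
partition conserves reads.

Two exact tests of the pooled counts against the design null frequency
are provided:

* **binomial** (default): the exact binomial test of `mut_reads` out of
  `depth` at `null_freq`; two-sided p-values use the minimum-likelihood
  convention (sum of outcome probabilities not exceeding the observed
  one). Backed by `scipy.stats.binomtest`.
* **fisher**: the two-sided Fisher exact test of the observed (mut, wt)
  counts against the rounded (half-up) expected counts at `null_freq`
  over the same depth, computed in-package by exhaustive hypergeometric
  enumeration with exact integer tie comparison — p is the sum of the
  probabilities of all tables sharing the margins whose probability is at
  most the observed table's, with no floating-point epsilon in the tie
  rule.

The binomial default is a deliberate design choice. Conditioning the
Fisher test on a doubled table (observed row plus an expected row of the
same depth) roughly halves the effective information per block: on the
default simulated scenario a pure-mutant block of depth ~24 scores
−log10(p) ≈ 1.5 under the Fisher construction versus ≈ 2.5 under the
binomial test, so with the fixed window threshold of 2 only the binomial
variant separates causal windows (scores ≈ 2.7–3.0) from the null floor
(≈ 0.4). Both tests are exposed (`BlockParams.test`, CLI `--test`)
because the window threshold, not the block test, is the calibrated
quantity. One-sided ("greater", mutant enrichment) variants are available;
the two-sided default follows the convention of the named tests.

p-values are floored at 1e-300 before log transforms; this guards −inf
only and cannot affect any threshold decision.

## Window scan

Windows of `window_size` (default 2 Mb) tile each chromosome from
position 1 with `step` (default 100 kb); final windows truncate at the
chromosome end. A block belongs to a window iff its midpoint (rounded-down
mean of first/last member SNP positions) lies inside — this prevents
double counting of blocks straddling window edges. The window score is
the arithmetic mean of −log10(P) over member blocks. Windows with fewer
than `min_blocks` (default 5) blocks are filtered as noise regardless of
score; remaining windows are significant iff score **strictly** exceeds
`threshold` (default 2.0). Windows with no blocks report an undefined
score (written as `.`), never 0: no evidence is not evidence of no
difference. Significant windows that overlap or abut merge into candidate
regions carrying the peak score.

Truncated windows at chromosome ends average over fewer blocks and are
noisier; occasionally a sub-window-size end region clears the threshold
by chance. Such calls are narrow (≲ step size) and carry few windows —
a known edge effect left to the user's judgement rather than masked.

## Sequence-origin narrowing

Within a candidate region, stretches where the bulk contains essentially
no wild-type-parent reads pinpoint the locus more finely than window
averages. The per-SNP mutant read fraction is profiled at sites with
informative depth ≥ `min_site_depth` (default 5); maximal runs of
consecutive profiled SNPs with purity ≥ `min_purity` (default 0.95) and
length ≥ `min_snps` (default 10) are reported with their mean purity.

Two robustness rules matter at pool depth:

* under-depth sites are *skipped*, not zeroed — missing data does not
  break a run;
* an impure site breaks a run only when its wild-type read count exceeds
  `tolerated_discordant_reads` (default 1). At 10× depth a single
  miscalled read gives purity 0.9 and would otherwise split runs roughly
  every 30 SNPs — including, often enough to matter, at the causal SNP
  itself. One discordant read is within a 1% error model; two or more
  are treated as evidence of a recombinant haplotype.

## Segregation statistics and coverage

`chi_square_gof` is the plain Pearson goodness-of-fit statistic with
expected counts `total × ratio_k / Σratio`, **no continuity correction**,
df = classes − 1, upper-tail p from the χ² distribution. The
no-correction choice is pinned by reproducing the published
mapping-population values (BC1 218:194 vs 1:1 → χ² = 1.398; F2 1661:503
vs 3:1 → χ² = 3.559, both at 3 decimals). Reported statistics round
half-up: 3 decimals for χ², 1 decimal for fold coverage
(`fold_coverage(94.7 Gb, 2.5 Gb) = 37.9`).

## Simulator

`SimConfig` defaults define the reference scenario: five 30 Mb
chromosomes, mean marker spacing 10 kb (homogeneous Poisson placement),
120 BC1 progeny, a 28-individual recessive bulk pooled in equal ratio,
mean mapped pool depth 10× at marker sites, per-read miscall rate 1%
(uniform to the three other bases, so the observed mutant-read
probability is f(1−e) + (1−f)e/3), recombination 2×10⁻⁸ crossovers per
bp per meiosis (2 cM/Mb, a typical plant genome-wide order of magnitude),
causal locus at chr3:15,000,000. Gametes receive Poisson(ρL) crossovers
at uniform positions with no interference. A marker is guaranteed at the
causal position so the bulk truth frequency there is exactly 1.0 under
phenotype selection. Depth is Poisson per site, independent across sites.
All randomness flows from the single config seed through one
`numpy.random.Generator`; identical configs give byte-identical output
files.

Scale note: the five 30 Mb chromosomes are a deliberate desk-scale model
of a large plant genome — large enough that windows, blocks and linkage
decay behave as in the full-size problem, small enough that a full
simulate–scan replicate runs in seconds.

What the generator does **not** model: read-level artifacts (mapping
bias, duplicates, base-quality structure), depth autocorrelation along
the genome, segregation distortion, crossover interference, DNA-quantity
variation between pooled individuals, and multiplexed multi-trait bulks.
Passing end-to-end tests therefore demonstrate the statistical machinery
under the stated design, not robustness to alignment pathology in real
data.

## Validation summary

The test suite checks, among others: exact agreement of the Fisher
implementation with an exhaustive exact-rational enumeration oracle over
every 2×2 table with total ≤ 30; the binomial test against a direct
summation oracle; window scores against brute-force recomputation on
random block sets; read conservation of the block partition; and, on the
default scenario, recovery of the planted causal locus by the full
pipeline in ≥9 of 10 seeded replicates with no regions called in
phenotype-ignorant null bulks in ≥8 of 10. `scripts/acceptance.py`
recomputes all of these from scratch.

## Known limitations

* The Fisher-vs-expected construction is underpowered at default depth
  (see above); it is retained for comparability, not recommended.
* Region boundaries are window-quantized (±step) and deliberately
  generous; the narrowing step, not the scan, provides fine localization.
* The segregation χ² uses the asymptotic distribution; with class counts
  in the hundreds this is amply justified, but no exact multinomial test
  is provided.
* `read_vcf_biallelic_snps` requires FORMAT/AD and skips multi-allelic
  records rather than splitting them, because the method is defined on
  exactly two parental alleles.
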