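import numpy as np
import pytest

from bsamap import (
    CrossDesign,
    GenomeLayout,
    InputError,
    SimConfig,
    make_bulk_counts,
    place_snps,
    simulate_bsa_dataset,
    simulate_progeny,
)
from conftest import small_config


class TestPlaceSnps:
    def test_marker_count_matches_placement_process(self, rng):
        layout = GenomeLayout.from_pairs([("chr1", 10_000_000)])
        snps = place_snps(layout, 10_000.0, rng)
        expected = 1000
        sigma = expected**0.5
        assert abs(len(snps) - expected) <= 3 * sigma
        positions = [s.pos for s in snps]
        assert positions == sorted(positions)
        assert len(set(positions)) == len(positions)

    def test_same_seed_gives_identical_map(self):
        layout = GenomeLayout.from_pairs([("chr1", 1_000_000)])
        a = place_snps(layout, 5_000.0, np.random.default_rng(3))
        b = place_snps(layout, 5_000.0, np.random.default_rng(3))
        assert a == b

    def test_spacing_beyond_chromosome_may_give_empty_map(self):
        layout = GenomeLayout.from_pairs([("chr1", 1_000)])
        snps = place_snps(layout, 1e9, np.random.default_rng(0))
        assert snps == []


class TestSimulateProgeny:
    def test_no_recombination_gives_whole_chromosome_haplotypes(self):
        cfg = small_config(recomb_rate=0.0, n_progeny=200)
        ds = simulate_bsa_dataset(cfg)
        geno = ds.progeny.genotypes
        chroms = ds.progeny.chroms
        for chrom in ("chr1", "chr2"):
            cols = np.flatnonzero(chroms == chrom)
            sub = geno[:, cols]
            # every BC1 individual is uniformly Mm (1) or MM (2) per chromosome
            assert np.all((sub.min(axis=1) == sub.max(axis=1)))
        hom = (geno[:, 0] == 2).mean()
        assert abs(hom - 0.5) <= 3 * np.sqrt(0.25 / 200)

    def test_bc1_phenotype_ratio_is_one_to_one(self):
        cfg = small_config(n_progeny=400, seed=2)
        ds = simulate_bsa_dataset(cfg)
        frac = ds.progeny.phenotype_mutant.mean()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 400)

    def test_f2_phenotype_ratio_is_three_to_one(self):
        cfg = small_config(n_progeny=400, seed=2, design=CrossDesign.f2_recessive())
        ds = simulate_bsa_dataset(cfg)
        frac = ds.progeny.phenotype_mutant.mean()
        assert abs(frac - 0.25) <= 3 * np.sqrt(0.25 * 0.75 / 400)

    def test_missing_causal_marker_is_an_error(self):
        cfg = small_config()
        rng = np.random.default_rng(0)
        snps = place_snps(cfg.layout, 500_000.0, rng)
        snps = [s for s in snps if not (s.chrom == "chr2" and s.pos == 4_000_000)]
        with pytest.raises(InputError):
            simulate_progeny(snps, cfg, rng)


class TestMakeBulkCounts:
    def test_truth_frequency_exactly_one_at_causal(self, small_dataset):
        truth = small_dataset.truth
        causal = truth[truth.is_causal]
        assert len(causal) == 1
        assert causal.truth_freq.iloc[0] == 1.0

    def test_unlinked_truth_mean_near_design_null(self):
        # chr1 carries no causal locus; its mean frequency fluctuates with
        # sd ~ sqrt(bulk/4)/(2*bulk) per seed, so average over seeds
        means = []
        for seed in range(1, 7):
            ds = simulate_bsa_dataset(small_config(seed=seed))
            truth = ds.truth
            means.append(truth[truth.chrom == "chr1"].truth_freq.mean())
        se = np.sqrt(28 * 0.25) / 56 / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.75) <= 3 * se

    def test_f2_unlinked_truth_mean_near_half(self):
        cfg = small_config(design=CrossDesign.f2_recessive(), n_progeny=200, seed=3)
        ds = simulate_bsa_dataset(cfg)
        unlinked = ds.truth[ds.truth.chrom == "chr1"]
        assert abs(unlinked.truth_freq.mean() - 0.5) < 0.05

    def test_observed_mutant_fraction_tracks_error_model(self):
        """At the causal SNP, E[mut read fraction] = f(1-e) + (1-f)e/3 with f=1."""
        fracs = []
        for seed in range(1, 16):
            ds = simulate_bsa_dataset(small_config(seed=seed, mean_depth=40.0))
            causal = [
                s for s in ds.bulk_counts
                if (s.chrom, s.pos) == ds.config.causal_locus
            ][0]
            fracs.append(causal.mut_count / (causal.mut_count + causal.wt_count + 0.0))
        e = 0.01
        expected = 1 * (1 - e) + 0 * e / 3  # = 0.99 (other-base reads excluded here)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)

    def test_truth_frequency_decay_matches_haldane_expectation(self):
        """Averaged over seeds, linkage decays monotonically toward the
        null and tracks the closed form f(d) = 1 - r(d)/2 with Haldane
        r(d) = (1 - exp(-2 * rate * d)) / 2 for a BC1 recessive bulk."""
        layout = GenomeLayout.from_pairs([("chr1", 20_000_000)])
        rate = 2e-8
        bins = np.linspace(0, 10_000_000, 6)
        sums = np.zeros(5)
        counts = np.zeros(5)
        for seed in range(1, 21):
            cfg = SimConfig(
                layout=layout, causal_locus=("chr1", 10_000_000),
                n_progeny=100, recomb_rate=rate, seed=seed,
            )
            ds = simulate_bsa_dataset(cfg)
            dist = np.abs(ds.truth.pos.to_numpy() - 10_000_000)
            which = np.digitize(dist, bins[1:], right=True)
            for k in range(5):
                mask = which == k
                sums[k] += ds.truth.truth_freq.to_numpy()[mask].sum()
                counts[k] += mask.sum()
        profile = sums / counts
        centers = (bins[:-1] + bins[1:]) / 2
        expected = 1 - (1 - np.exp(-2 * rate * centers)) / 4
        assert profile[0] > 0.95
        assert all(a >= b - 0.02 for a, b in zip(profile, profile[1:]))
        assert np.allclose(profile, expected, atol=0.03)

    def test_insufficient_mutant_progeny_is_instructive_error(self):
        cfg = small_config(n_progeny=30, seed=1)
        ds_rng = np.random.default_rng(cfg.seed)
        snps = place_snps(cfg.layout, cfg.snp_spacing, ds_rng)
        from bsamap.simulate import _ensure_causal_snp

        snps = _ensure_causal_snp(snps, cfg.causal_locus, ds_rng)
        progeny = simulate_progeny(snps, cfg, ds_rng)
        with pytest.raises(InputError, match="n_progeny"):
            make_bulk_counts(progeny, snps, cfg, ds_rng)

    def test_random_selection_ignores_phenotype(self):
        ds = simulate_bsa_dataset(small_config(seed=9), selection="random")
        causal = ds.truth[ds.truth.is_causal]
        # a random bulk essentially never fixes the causal allele
        assert causal.truth_freq.iloc[0] < 1.0


class TestDatasetDeterminism:
    def test_same_seed_same_files(self, tmp_path):
        cfg = small_config(seed=13)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_bsa_dataset(cfg, out_dir=str(a))
        simulate_bsa_dataset(cfg, out_dir=str(b))
        for name in ("snps.tsv", "bulk_counts.tsv", "genome.tsv", "truth.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_different_seed_different_data(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_bsa_dataset(small_config(seed=1), out_dir=str(a))
        simulate_bsa_dataset(small_config(seed=2), out_dir=str(b))
        assert (a / "bulk_counts.tsv").read_bytes() != (b / "bulk_counts.tsv").read_bytes()
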