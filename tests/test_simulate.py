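"""F2 pool-seq simulator: meiosis, segregation, pooling, depth sampling,
and VCF round-trips."""

import math

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from virescue.genome import Chromosome, CrossDesign, GenomeModel, SeqModel
from virescue.io import read_vcf, write_vcf
from virescue.pipeline import simulate_variant_table
from virescue.simulate import (
    build_pools,
    simulate_f2_population,
    simulate_gamete,
)


def _het_parent(n_markers):
    return (
        np.zeros(n_markers, dtype=np.int8),
        np.ones(n_markers, dtype=np.int8),
    )


class TestGamete:
    def test_zero_map_length_returns_a_parental_haplotype(self, rng):
        a, b = _het_parent(20)
        cm = np.zeros(20)
        picks = set()
        for _ in range(200):
            g = simulate_gamete(a, b, cm, 0.0, rng)
            assert (g == a).all() or (g == b).all()
            picks.add(int(g[0]))
        assert picks == {0, 1}  # both strands get chosen

    def test_negative_map_length_rejected(self, rng):
        a, b = _het_parent(5)
        with pytest.raises(ValueError):
            simulate_gamete(a, b, np.zeros(5), -1.0, rng)

    def test_crossover_count_mean_matches_poisson(self, rng):
        # 100 cM chromosome => Poisson mean 1.0 crossovers per meiosis.
        # Strand switches along a dense marker grid count the crossovers
        # (adjacent-marker double crossovers are negligible at 0.05 cM).
        n = 2000
        a, b = _het_parent(n)
        cm = np.linspace(0.05, 100, n)
        switches = [
            int(np.sum(np.abs(np.diff(simulate_gamete(a, b, cm, 100.0, rng)))))
            for _ in range(10_000)
        ]
        mean = np.mean(switches)
        se = np.std(switches, ddof=1) / math.sqrt(len(switches))
        assert abs(mean - 1.0) <= 3 * se

    def test_recombinant_fraction_matches_haldane(self, rng):
        # Two markers 50 cM apart: r = (1 - exp(-2*0.5)) / 2 ~= 0.3161
        a, b = _het_parent(2)
        cm = np.array([0.0, 50.0])
        rec = [
            int(g[0] != g[1])
            for g in (
                simulate_gamete(a, b, cm, 50.0, rng) for _ in range(10_000)
            )
        ]
        r_hat = np.mean(rec)
        r_exp = (1 - math.exp(-1.0)) / 2
        se = math.sqrt(r_exp * (1 - r_exp) / len(rec))
        assert abs(r_hat - r_exp) <= 3 * se


@pytest.fixture(scope="module")
def big_population(tiny_genome):
    rng = np.random.default_rng(7)
    design = CrossDesign(n_f2=10_000, pool_size=15)
    return simulate_f2_population(tiny_genome, design, rng)


class TestF2Population:
    def test_segregation_is_three_to_one(self, big_population):
        from virescue.inheritance import segregation_chi_square

        n_yellow = sum(1 for i in big_population if i.phenotype == "yellow")
        n_green = len(big_population) - n_yellow
        res = segregation_chi_square((n_green, n_yellow), (3, 1))
        assert res.p_value > 0.001

    def test_yellow_individuals_are_homozygous_mutant(
        self, big_population, tiny_genome
    ):
        idx = tiny_genome.causal_index()
        for ind in big_population:
            if ind.phenotype == "yellow":
                assert ind.dosage("chr1")[idx] == 2

    def test_green_class_mutant_allele_frequency_near_one_third(
        self, big_population, tiny_genome
    ):
        idx = tiny_genome.causal_index()
        dosages = np.array(
            [
                ind.dosage("chr1")[idx]
                for ind in big_population
                if ind.phenotype == "green"
            ]
        )
        freq = dosages.mean() / 2
        # green class is 1/3 AA + 2/3 Aa => allele frequency 1/3
        se = np.std(dosages / 2, ddof=1) / math.sqrt(len(dosages))
        assert abs(freq - 1 / 3) <= 3 * se


class TestPools:
    def test_pools_are_disjoint_and_exact_size(self, tiny_genome, rng):
        design = CrossDesign(n_f2=200, pool_size=15)
        pop = simulate_f2_population(tiny_genome, design, rng)
        g_pool, y_pool = build_pools(pop, design, rng)
        assert len(g_pool) == len(y_pool) == 15
        assert all(i.phenotype == "green" for i in g_pool)
        assert all(i.phenotype == "yellow" for i in y_pool)
        ids = {id(i) for i in g_pool} | {id(i) for i in y_pool}
        assert len(ids) == 30

    def test_insufficient_class_raises_naming_the_class(self, tiny_genome, rng):
        design = CrossDesign(n_f2=200, pool_size=15)
        pop = simulate_f2_population(tiny_genome, design, rng)
        yellows = [i for i in pop if i.phenotype == "yellow"][:10]
        greens = [i for i in pop if i.phenotype == "green"]
        with pytest.raises(ValueError, match="yellow"):
            build_pools(greens + yellows, design, rng)

    def test_yellow_pool_fixed_for_mutant_allele_at_causal_locus(
        self, tiny_genome, rng
    ):
        design = CrossDesign(n_f2=200, pool_size=15)
        pop = simulate_f2_population(tiny_genome, design, rng)
        _, y_pool = build_pools(pop, design, rng)
        idx = tiny_genome.causal_index()
        counts = sum(i.dosage("chr1")[idx] for i in y_pool)
        assert counts == 2 * 15  # every chromosome carries the mutant allele


class TestPoolDepths:
    def test_mean_depth_matches_poisson(self):
        genome = GenomeModel(
            chromosomes=(Chromosome("chr1", 50_000_000, 50.0),),
            marker_spacing_bp=5_000,  # 10,000 sites
            causal_chrom="chr1",
            causal_pos=25_000_000,
        )
        seq = SeqModel(mean_coverage_g=95, mean_coverage_y=75, error_rate=0.01)
        _, _, table = simulate_variant_table(genome, CrossDesign(), seq, seed=3)
        depth_y = (table.y_ref + table.y_alt).to_numpy()
        se = depth_y.std(ddof=1) / math.sqrt(len(depth_y))
        assert abs(depth_y.mean() - 75) <= 3 * se

    def test_causal_site_fixed_in_yellow_pool_without_error(self, genome):
        seq = SeqModel(error_rate=0.0)
        _, _, table = simulate_variant_table(genome, CrossDesign(), seq, seed=5)
        row = table[(table.chrom == "chr3") & (table.pos == 34_500_000)].iloc[0]
        assert row.y_ref == 0 and row.y_alt > 0

    def test_unlinked_sites_have_symmetric_pool_frequencies(self):
        # E[f_G - f_Y] = 0 on a chromosome unlinked to the causal locus.
        # Within one replicate all sites share the pools' composition, so the
        # mean is taken over independent replicates (5,000 site values in
        # total) with the SE computed across replicate means.
        genome = GenomeModel(
            chromosomes=(
                Chromosome("chr1", 1_000_000, 10.0),
                Chromosome("chr2", 1_000_000, 10.0),
            ),
            marker_spacing_bp=10_000,  # 100 unlinked sites per replicate
            causal_chrom="chr2",
            causal_pos=500_000,
        )
        design = CrossDesign(n_f2=150, pool_size=15)
        rep_means = []
        for seed in range(50):
            _, _, table = simulate_variant_table(
                genome, design, SeqModel(), seed=3000 + seed
            )
            table = table[table.chrom == "chr1"]
            diff = (
                table.g_alt / (table.g_ref + table.g_alt)
                - table.y_alt / (table.y_ref + table.y_alt)
            ).to_numpy()
            rep_means.append(diff.mean())
        rep_means = np.array(rep_means)
        se = rep_means.std(ddof=1) / math.sqrt(len(rep_means))
        assert abs(rep_means.mean()) <= 3 * se

    def test_fixed_seed_reproduces_table_exactly(self, genome):
        _, _, t1 = simulate_variant_table(genome, CrossDesign(), SeqModel(), 42)
        _, _, t2 = simulate_variant_table(genome, CrossDesign(), SeqModel(), 42)
        pdt.assert_frame_equal(t1, t2)

    def test_allele_frequency_decays_toward_half_with_distance(self):
        # Yellow-pool frequency is 1 at the causal site and decays toward 0.5
        # with genetic distance; binned means over 50 replicates must be
        # monotone decreasing.
        genome = GenomeModel(
            chromosomes=(Chromosome("chr1", 20_000_000, 65.0),),
            marker_spacing_bp=500_000,
            causal_chrom="chr1",
            causal_pos=500_000,
        )
        seq = SeqModel(mean_coverage_g=500, mean_coverage_y=500, error_rate=0.0)
        freqs = []
        for seed in range(50):
            _, _, table = simulate_variant_table(
                genome, CrossDesign(), seq, seed=1000 + seed
            )
            freqs.append(
                (table.y_alt / (table.y_ref + table.y_alt)).to_numpy()
            )
        mean_f = np.mean(freqs, axis=0)
        dist_mb = (genome.marker_positions("chr1") - 500_000) / 1e6
        bins = np.array([0, 5, 10, 15, 20])
        binned = [
            mean_f[(dist_mb >= lo) & (dist_mb < hi)].mean()
            for lo, hi in zip(bins[:-1], bins[1:])
        ]
        assert all(a > b for a, b in zip(binned[:-1], binned[1:]))
        assert binned[-1] > 0.5  # decays toward, not past, 1/2


class TestVcfRoundTrip:
    def test_table_round_trips_losslessly(self, default_sim, tmp_path):
        _, _, table = default_sim
        path = tmp_path / "sim.vcf"
        write_vcf(table.head(100), path)
        back = read_vcf(path)
        pdt.assert_frame_equal(
            back, table.head(100).reset_index(drop=True), check_dtype=False
        )

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf(pd.DataFrame(columns=["chrom", "pos", "ref", "alt",
                                        "g_ref", "g_alt", "y_ref", "y_alt"]),
                  path, contig_lengths={"chr1": 1000})
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert len(read_vcf(path)) == 0

    def test_one_based_coordinate_preserved(self, tmp_path):
        table = pd.DataFrame(
            [("chr3", 34_500_000, "A", "T", 10, 20, 0, 30)],
            columns=["chrom", "pos", "ref", "alt",
                     "g_ref", "g_alt", "y_ref", "y_alt"],
        )
        path = tmp_path / "one.vcf"
        write_vcf(table, path)
        assert read_vcf(path).pos.iloc[0] == 34_500_000


class TestValidation:
    def test_pool_size_exceeding_expected_class_rejected(self):
        with pytest.raises(ValueError):
            CrossDesign(n_f2=40, pool_size=15)

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            SeqModel(error_rate=0.5)

    def test_causal_locus_must_sit_on_marker_grid(self):
        with pytest.raises(ValueError):
            GenomeModel(
                chromosomes=(Chromosome("chr1", 1_000_000, 10.0),),
                marker_spacing_bp=200_000,
                causal_chrom="chr1",
                causal_pos=123_456,
            )
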