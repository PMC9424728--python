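#!/usr/bin/env python
"""Simulate the default F2 pool-seq experiment and write its variant table.

Generates an F2 of 150 from a fully heterozygous F1, checks the 3:1
green:yellow segregation, draws two 15-individual extreme-phenotype pools,
and samples pooled read depths (95x green / 75x yellow, 1% error) at ~4,400
markers over seven chromosomes with the causal locus at chr3:34.5 Mb.

Writes results/sim.vcf and results/sim.population.tsv.
"""

from pathlib import Path

from virescue.genome import CrossDesign, SeqModel, default_genome
from virescue.inheritance import segregation_chi_square
from virescue.io import write_vcf
from virescue.pipeline import simulate_variant_table
from virescue.simulate import write_population_tsv

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    genome = default_genome()
    population, pools, table = simulate_variant_table(
        genome, CrossDesign(), SeqModel(), seed=SEED
    )
    n_yellow = sum(1 for i in population if i.phenotype == "yellow")
    n_green = len(population) - n_yellow
    res = segregation_chi_square((n_green, n_yellow), (3, 1))
    print(f"simulated F2: {n_green} green, {n_yellow} yellow "
          f"({res.display()} against 3:1)")
    contigs = {c.name: c.length_bp for c in genome.chromosomes}
    write_vcf(table, RESULTS / "sim.vcf", contigs)
    write_population_tsv(population, genome, RESULTS / "sim.population.tsv")
    print(f"wrote {len(table)} sites to {RESULTS / 'sim.vcf'}")


if __name__ == "__main__":
    main()
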