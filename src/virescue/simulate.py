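"""F2 population and pooled-sequencing simulation.

Meiosis follows the Haldane (no-interference) model: crossover counts are
Poisson with mean equal to the map length in Morgans, crossover positions are
uniform on the genetic map, and the starting parental strand is chosen with
probability 1/2.  Founder parents are fixed for opposite alleles at every
marker, so the F1 is fully heterozygous and an F2 individual is the union of
two independent F1 gametes.

Allele coding: 0 = wild-type (reference) allele, 1 = mutant (alternate)
allele.  An individual's phenotype is yellow iff it carries two mutant copies
at the causal marker (single recessive nuclear locus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CrossDesign, GenomeModel, SeqModel

__all__ = [
    "F2Individual",
    "simulate_gamete",
    "simulate_f2_population",
    "build_pools",
    "simulate_pool_depths",
    "write_population_tsv",
]

GREEN = "green"
YELLOW = "yellow"


@dataclass
class F2Individual:
    """Two haplotypes per chromosome (dict name -> (2, n_markers) array) plus
    a phenotype class."""

    haplotypes: dict[str, np.ndarray]
    phenotype: str

    def dosage(self, chrom: str) -> np.ndarray:
        """Mutant-allele copy number in {0,1,2} at each marker."""
        return self.haplotypes[chrom].sum(axis=0)


def simulate_gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    marker_cm: np.ndarray,
    genetic_length_cm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product of a parent with haplotypes ``hap_a``/``hap_b``.

    ``marker_cm`` gives each marker's genetic position; crossovers are drawn
    Poisson(genetic_length_cm / 100) with uniform positions, and the gamete
    alternates between the two parental strands at each crossover.
    """
    if genetic_length_cm < 0:
        raise ValueError("genetic length must be >= 0")
    if hap_a.shape != hap_b.shape or hap_a.shape != marker_cm.shape:
        raise ValueError("haplotypes and marker map must have equal length")
    n_xo = rng.poisson(genetic_length_cm / 100.0)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return (hap_a if start == 0 else hap_b).copy()
    xo_pos = np.sort(rng.uniform(0.0, genetic_length_cm, size=n_xo))
    # Strand at a marker = start + number of crossovers to its left, mod 2.
    strand = (start + np.searchsorted(xo_pos, marker_cm)) % 2
    return np.where(strand == 0, hap_a, hap_b)


def simulate_f2_population(
    genome: GenomeModel,
    design: CrossDesign,
    rng: np.random.Generator,
) -> list[F2Individual]:
    """Simulate ``design.n_f2`` F2 individuals from a fully heterozygous F1."""
    chrom_maps = {
        c.name: (genome.marker_cm(c.name), c.length_cm)
        for c in genome.chromosomes
    }
    f1 = {
        name: (
            np.zeros(len(cm), dtype=np.int8),
            np.ones(len(cm), dtype=np.int8),
        )
        for name, (cm, _) in chrom_maps.items()
    }
    causal_idx = genome.causal_index()
    population = []
    for _ in range(design.n_f2):
        haps = {}
        for name, (cm, length_cm) in chrom_maps.items():
            a, b = f1[name]
            g1 = simulate_gamete(a, b, cm, length_cm, rng)
            g2 = simulate_gamete(a, b, cm, length_cm, rng)
            haps[name] = np.stack([g1, g2])
        if design.phenotype_model == "recessive":
            dosage = haps[genome.causal_chrom][:, causal_idx].sum()
            phenotype = YELLOW if dosage == 2 else GREEN
        else:  # null model: 3:1 independent of genotype
            phenotype = YELLOW if rng.random() < 0.25 else GREEN
        population.append(F2Individual(haps, phenotype))
    return population


def build_pools(
    population: list[F2Individual],
    design: CrossDesign,
    rng: np.random.Generator,
) -> tuple[list[F2Individual], list[F2Individual]]:
    """Sample disjoint green and yellow pools of ``design.pool_size`` each.

    Pools are drawn uniformly within phenotype class; the study's "extremely"
    green/yellow selection is modelled as random within class since the
    phenotype is discrete under a single recessive locus.
    """
    green = [i for i in population if i.phenotype == GREEN]
    yellow = [i for i in population if i.phenotype == YELLOW]
    for name, cls in ((GREEN, green), (YELLOW, yellow)):
        if len(cls) < design.pool_size:
            raise ValueError(
                f"not enough {name} individuals: have {len(cls)}, "
                f"need pool_size={design.pool_size}"
            )
    g_idx = rng.choice(len(green), size=design.pool_size, replace=False)
    y_idx = rng.choice(len(yellow), size=design.pool_size, replace=False)
    return [green[i] for i in g_idx], [yellow[i] for i in y_idx]


def _pool_allele_counts(pool: list[F2Individual], chrom: str) -> np.ndarray:
    """Mutant-allele count over the pool's 2*pool_size chromosomes per marker."""
    return np.sum([ind.dosage(chrom) for ind in pool], axis=0)


def simulate_pool_depths(
    pools: tuple[list[F2Individual], list[F2Individual]],
    genome: GenomeModel,
    seq: SeqModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pooled sequencing read depths at every marker.

    Per site and pool, total depth is Poisson(mean coverage).  Each read
    samples one of the pool's ``2 * pool_size`` chromosomes uniformly and its
    allele flips with probability ``error_rate``; the alternate-read count is
    therefore Binomial(depth, p) with p = (c/2N)(1-e) + (1 - c/2N)e, which is
    sampled directly.

    Returns a variant table with columns
    ``chrom, pos, ref, alt, g_ref, g_alt, y_ref, y_alt`` (1-based positions).
    """
    g_pool, y_pool = pools
    e = seq.error_rate
    frames = []
    for chrom in genome.chromosomes:
        name = chrom.name
        positions = genome.marker_positions(name)
        n = len(positions)
        n_chr_g = 2 * len(g_pool)
        n_chr_y = 2 * len(y_pool)
        rows = {"chrom": np.repeat(name, n), "pos": positions}
        for tag, pool, n_chr, cov in (
            ("g", g_pool, n_chr_g, seq.mean_coverage_g),
            ("y", y_pool, n_chr_y, seq.mean_coverage_y),
        ):
            freq = _pool_allele_counts(pool, name) / n_chr
            p_alt = freq * (1 - e) + (1 - freq) * e
            depth = rng.poisson(cov, size=n)
            alt = rng.binomial(depth, p_alt)
            rows[f"{tag}_ref"] = depth - alt
            rows[f"{tag}_alt"] = alt
        frames.append(pd.DataFrame(rows))
    table = pd.concat(frames, ignore_index=True)
    table.insert(2, "ref", "A")
    table.insert(3, "alt", "T")
    return table[
        ["chrom", "pos", "ref", "alt", "g_ref", "g_alt", "y_ref", "y_alt"]
    ]


def write_population_tsv(
    population: list[F2Individual],
    genome: GenomeModel,
    path,
) -> None:
    """Write per-individual causal-locus genotype and phenotype (for
    segregation tests)."""
    idx = genome.causal_index()
    chrom = genome.causal_chrom
    records = [
        {
            "individual": i,
            "phenotype": ind.phenotype,
            "causal_dosage": int(ind.haplotypes[chrom][:, idx].sum()),
        }
        for i, ind in enumerate(population)
    ]
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
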