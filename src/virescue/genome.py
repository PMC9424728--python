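"""Genome layout, cross design, and sequencing models for F2 pool-seq simulation.

The default layout mimics a seven-chromosome cucumber genome with a recessive
causal locus on chromosome 3, placed inside the 33.54-35.66 Mb interval where
the virescent-leaf locus maps.  Markers sit on a regular physical grid; genetic
positions interpolate linearly between 0 and the chromosome's map length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Chromosome",
    "GenomeModel",
    "CrossDesign",
    "SeqModel",
    "default_genome",
]


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical length in bp and genetic length in cM."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: physical length must be > 0")
        if self.length_cm < 0:
            raise ValueError(f"{self.name}: genetic length must be >= 0")


@dataclass(frozen=True)
class GenomeModel:
    """Marker grid over a set of chromosomes, with one causal locus.

    Markers are placed deterministically at ``marker_spacing_bp, 2*spacing, ...``
    up to the chromosome length, so a fixed layout always yields the same grid.
    The causal locus must coincide with a grid marker (it is snapped on access
    only if it already lies on the grid; otherwise construction fails).
    """

    chromosomes: tuple[Chromosome, ...]
    marker_spacing_bp: int
    causal_chrom: str
    causal_pos: int

    def __post_init__(self) -> None:
        if self.marker_spacing_bp <= 0:
            raise ValueError("marker_spacing_bp must be > 0")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        chrom = self.chromosome(self.causal_chrom)
        if not (1 <= self.causal_pos <= chrom.length_bp):
            raise ValueError("causal locus outside its chromosome")
        if self.causal_pos % self.marker_spacing_bp != 0:
            raise ValueError(
                "causal locus must fall on the marker grid "
                f"(spacing {self.marker_spacing_bp} bp)"
            )

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def marker_positions(self, name: str) -> np.ndarray:
        """1-based physical marker positions on the regular grid."""
        chrom = self.chromosome(name)
        return np.arange(
            self.marker_spacing_bp,
            chrom.length_bp + 1,
            self.marker_spacing_bp,
            dtype=np.int64,
        )

    def marker_cm(self, name: str) -> np.ndarray:
        """Genetic positions of the markers, linear bp->cM interpolation."""
        chrom = self.chromosome(name)
        return self.marker_positions(name) / chrom.length_bp * chrom.length_cm

    def causal_index(self) -> int:
        pos = self.marker_positions(self.causal_chrom)
        idx = int(np.searchsorted(pos, self.causal_pos))
        assert pos[idx] == self.causal_pos
        return idx

    @property
    def n_markers(self) -> int:
        return int(
            sum(len(self.marker_positions(c.name)) for c in self.chromosomes)
        )


@dataclass(frozen=True)
class CrossDesign:
    """F2 design: population size, pool size, and the phenotype model.

    ``phenotype_model`` is ``"recessive"`` (yellow iff homozygous mutant at the
    causal locus) or ``"null"`` (phenotype drawn 3:1 independent of genotype;
    used for null calibration of the scan).
    """

    n_f2: int = 150
    pool_size: int = 15
    phenotype_model: str = "recessive"

    def __post_init__(self) -> None:
        if self.n_f2 <= 0 or self.pool_size <= 0:
            raise ValueError("n_f2 and pool_size must be > 0")
        if self.phenotype_model not in ("recessive", "null"):
            raise ValueError("phenotype_model must be 'recessive' or 'null'")
        # Recessive class expectation is n_f2/4; insist the pool fits it.
        if self.pool_size > self.n_f2 / 4:
            raise ValueError(
                "pool_size exceeds the expected size of the rarer phenotype "
                f"class (n_f2/4 = {self.n_f2 / 4:g})"
            )


@dataclass(frozen=True)
class SeqModel:
    """Pooled short-read sequencing: per-pool mean coverage and error rate.

    Defaults follow the study design this package emulates: ~95x for the
    green (wild-type) pool and ~75x for the yellow (mutant) pool, with a
    symmetric 1% per-read allele-flip error.
    """

    mean_coverage_g: float = 95.0
    mean_coverage_y: float = 75.0
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.mean_coverage_g <= 0 or self.mean_coverage_y <= 0:
            raise ValueError("mean coverage must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")


def default_genome(marker_spacing_bp: int = 50_000) -> GenomeModel:
    """Seven-chromosome desk-scale layout with the causal locus at chr3:34.5 Mb.

    Chromosomes are 30 Mb / 100 cM except chr3, which is 40 Mb / 130 cM so the
    causal locus at 34,500,000 bp sits inside the mapped 33.54-35.66 Mb
    interval.  At 50 kb spacing this yields ~4,400 markers genome-wide.
    """
    chroms = []
    for i in range(1, 8):
        if i == 3:
            chroms.append(Chromosome(f"chr{i}", 40_000_000, 130.0))
        else:
            chroms.append(Chromosome(f"chr{i}", 30_000_000, 100.0))
    return GenomeModel(
        chromosomes=tuple(chroms),
        marker_spacing_bp=marker_spacing_bp,
        causal_chrom="chr3",
        causal_pos=34_500_000,
    )
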