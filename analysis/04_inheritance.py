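#!/usr/bin/env python
"""Inheritance statistics and fine-mapping interval arithmetic from the
published counts and marker coordinates.

Tests both F2 populations against 3:1, computes SSR polymorphism rates, the
flanking-marker intervals of both populations, and their strict
intersection."""

from virescue.inheritance import (
    Marker,
    intersect_intervals,
    interval_from_markers,
    polymorphism_rate,
    segregation_chi_square,
)


def main() -> None:
    for label, counts in [("F2-A", (59, 18)), ("F2-B", (73, 20))]:
        res = segregation_chi_square(counts, (3, 1))
        print(f"{label}: {counts[0]} green / {counts[1]} yellow -> "
              f"{res.display()}")

    print(f"F2-A SSR polymorphism: {polymorphism_rate(18, 220)}% of 220")
    print(f"F2-B SSR polymorphism: {polymorphism_rate(64, 220)}% of 220")

    a = interval_from_markers(
        Marker("UW083999", "chr3", 32_156_194),
        Marker("UW071654", "chr3", 35_644_875),
    )
    b = interval_from_markers(
        Marker("UW084839", "chr3", 33_536_014),
        Marker("SSR15124", "chr3", 35_661_331),
    )
    print(f"F2-A interval {a.left.name}-{a.right.name}: "
          f"{a.length_bp:,} bp = {a.display_mb(2)} Mb")
    print(f"F2-B interval {b.left.name}-{b.right.name}: "
          f"{b.length_bp:,} bp = {b.display_mb(1)} Mb")
    both = intersect_intervals(a, b)
    print(f"strict intersection: {both.chrom}:{both.start:,}-{both.end:,} "
          f"({both.display_mb(2)} Mb)")


if __name__ == "__main__":
    main()
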