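"""Reading and writing the pipeline's on-disk formats.

Variant tables travel as minimal VCF 4.2 with two samples, ``G`` (green /
wild-type pool) and ``Y`` (yellow / mutant pool), carrying per-pool allelic
depths in the standard ``AD`` FORMAT field.  Positions are 1-based throughout;
BED export converts to 0-based half-open.
"""

from __future__ import annotations

import pandas as pd
import pysam

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "g_ref",
    "g_alt",
    "y_ref",
    "y_alt",
]


def write_vcf(table: pd.DataFrame, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a variant table as minimal VCF 4.2 (samples G and Y, FORMAT AD).

    ``contig_lengths`` populates ##contig headers; when absent, contigs are
    declared from the table with the max observed position as length.
    """
    if contig_lengths is None:
        if len(table):
            contig_lengths = (
                table.groupby("chrom", sort=False)["pos"].max().to_dict()
            )
        else:
            contig_lengths = {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=virescue\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={int(length)}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tG\tY\n"
        )
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\t"
                f"PASS\t.\tAD\t{int(row.g_ref)},{int(row.g_alt)}\t"
                f"{int(row.y_ref)},{int(row.y_alt)}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a two-sample (G, Y) VCF with AD depths into a variant table.

    Multi-allelic records are dropped with a count noted on the returned
    frame's ``attrs['n_multiallelic']``; only biallelic SNP/indel records with
    one ALT allele are retained.
    """
    rows = []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if samples != ["G", "Y"]:
            raise ValueError(f"expected samples ['G', 'Y'], got {samples}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            g_ad = rec.samples["G"]["AD"]
            y_ad = rec.samples["Y"]["AD"]
            rows.append(
                (
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alts[0],
                    int(g_ad[0]),
                    int(g_ad[1]),
                    int(y_ad[0]),
                    int(y_ad[1]),
                )
            )
    table = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if not len(table):
        table = table.astype(
            {c: "int64" for c in VARIANT_COLUMNS if c not in ("chrom", "ref", "alt")}
            | {"chrom": "object", "ref": "object", "alt": "object"}
        )
    table.attrs["n_multiallelic"] = n_multi
    return table


def read_variant_tsv(path) -> pd.DataFrame:
    """Read the equivalent TSV form of the variant table."""
    table = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    return table[list(table.columns)]


def write_regions_bed(regions, path) -> None:
    """Write region calls as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.peak_fitted:.6g}\n")


def write_regions_tsv(regions, path) -> None:
    """Write region calls as 1-based inclusive TSV."""
    pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "peak_pos": r.peak_pos,
                "peak_fitted": r.peak_fitted,
                "n_sites": r.n_sites,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "peak_pos", "peak_fitted", "n_sites"],
    ).to_csv(path, sep="\t", index=False)
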