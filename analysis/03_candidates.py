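#!/usr/bin/env python
"""Screen candidate SNPs in the mapped region and intersect with DEGs.

Annotates the simulated variant table (the planted causal SNP is
nonsynonymous in gene_causal; everything else intergenic), applies the four
screening conditions inside the top scanned region (in region; green pool
het; yellow pool homozygous non-reference; protein-affecting effect),
intersects surviving genes with a small synthetic DEG table, and checks the
2 kb promoter window of the surviving gene.

Writes results/candidates.tsv."""

from pathlib import Path

import numpy as np
import pandas as pd

from virescue.bsa import scan
from virescue.candidates import (
    GeneModel,
    deg_intersection,
    filter_candidate_snps,
    promoter_scan,
)
from virescue.io import read_vcf

RESULTS = Path(__file__).resolve().parents[1] / "results"

# synthetic transcriptome outcome: the causal gene is differentially
# expressed; two bystanders are not (q or fold-change fails)
DEGS = pd.DataFrame(
    {
        "gene_id": ["gene_causal", "gene_flat", "gene_weak"],
        "fold_change": [2.4, 1.1, 1.8],
        "q_value": [0.003, 0.6, 0.07],
    }
)


def main() -> None:
    table = read_vcf(RESULTS / "sim.vcf")
    _, regions, _ = scan(table)
    top = max(regions, key=lambda r: r.peak_fitted)
    print(f"screening {top.chrom}:{top.start:,}-{top.end:,}")

    annotated = table.copy()
    causal = (annotated.chrom == "chr3") & (annotated.pos == 34_500_000)
    annotated["effect"] = np.where(causal, "nonsynonymous", "intergenic")
    annotated["gene_id"] = np.where(causal, "gene_causal", "")
    cands, report = filter_candidate_snps(annotated, top)
    print("screening report:", report)
    cands.to_csv(RESULTS / "candidates.tsv", sep="\t", index=False)
    print(f"{len(cands)} candidate SNP(s):",
          list(zip(cands.chrom, cands.pos, cands.gene_id)))

    genes = deg_intersection(
        [g for g in cands.gene_id.unique() if g], DEGS
    )
    print("DEG intersection:", genes or "(none)")

    gene = GeneModel("gene_causal", "chr3", 34_490_000, 34_510_000, "+")
    upstream = promoter_scan(cands, gene, upstream_bp=2000)
    print(f"screening-passing SNPs in the 2 kb promoter window: "
          f"{len(upstream)} (differential expression not promoter-driven)"
          if len(upstream) == 0 else upstream)


if __name__ == "__main__":
    main()
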