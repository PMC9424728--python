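# Methods

## Study design being emulated

A spontaneous recessive virescent-leaf mutation in a cucumber inbred line,
mapped in two F2 populations. The package reproduces the analysis chain:
3:1 segregation tests; SSR-based fine mapping summarised as flanking-marker
intervals; BSA-Seq on two pools of 15 extreme-phenotype F2 individuals
(green/wild-type pool ≈95× coverage, yellow/mutant pool ≈75×) scanned with
the squared Euclidean-distance statistic; candidate-SNP screening inside the
mapped region intersected with differentially expressed genes; and the leaf
physiology (pigment contents, PAM fluorescence) used to characterise the
mutant. Raw-read processing (alignment, variant calling, effect annotation,
RNA-Seq quantification) is out of scope: variant tables with per-pool `AD`
depths, effect annotations, and DEG tables are inputs.

## Simulator

**Genetics.** Founder parents are fixed for opposite alleles at every
marker, so the F1 is fully heterozygous; each F2 individual is two
independent F1 gametes. Meiosis follows the Haldane model — crossover
counts Poisson with mean equal to the chromosome's map length in Morgans,
positions uniform on the genetic map, no interference — the standard
minimal choice when no genetic-map model is given. Genetic positions
interpolate linearly between bp and cM. Phenotype is yellow iff the
individual is homozygous mutant at the causal marker; a `null` phenotype
model (3:1 independent of genotype) supports null calibration.

**Default genome.** Seven chromosomes of 30 Mb/100 cM, except chr3 =
40 Mb/130 cM with the causal locus at 34,500,000 bp — inside the
33.54–35.66 Mb interval where the real locus maps. Markers every 50 kb
(~4,400 sites genome-wide): desk-scale but dense enough for Mb-resolution
region calls.

**Population and pools.** Default F2 size 150 with pools of 15 per
phenotype class. 150 keeps the yellow class (expected n/4) comfortably
above the pool size in essentially every replicate; the real F2-A had 77
plants, where the yellow class can fall below 15. Pools are drawn uniformly
within phenotype class: under a single fully penetrant recessive locus,
"extremely" green/yellow carries no extra genotype information.

**Sequencing.** Per site and pool, total depth is Poisson(mean coverage);
each read samples one of the pool's `2×15` chromosomes uniformly and its
allele flips with probability `error_rate` (default 0.01). The
implementation draws the alternate count directly as
`Binomial(depth, (c/2N)(1−e) + (1−c/2N)e)`, the exact distribution of that
per-read scheme. No mapping bias, indels, duplicates, or base-quality
structure — sufficient for the noise structure the ED statistic sees, but
real pool-seq has overdispersion beyond Poisson/Binomial, so passing tests
here bound statistical, not bioinformatic, behaviour.

**Determinism.** All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn` in a fixed stage order (population,
pooling, sequencing); identical config + seed gives byte-identical outputs.

## ED scan

Sites need ≥10 reads in *both* pools (default `min_depth`; bounds per-pool
frequency noise at roughly 0.16 SD) — this also makes zero-depth division
impossible. ED = √2·|f_G − f_Y| for biallelic sites; the association value
is ED². Multi-allelic records are dropped with a count.

**LOESS.** Degree-1 locally weighted regression per chromosome: a site's
neighbourhood is its `ceil(span·n)` nearest sites by genomic distance
(minimum 2), tricube weights with the farthest neighbour as bandwidth, no
robustness iterations, span 0.1 by default (resolves Mb-scale peaks at
50 kb spacing). Local linear fits reproduce constants and are exact on
linear data for any span. The implementation is written in-package so the
neighbourhood/weight conventions are pinned; tests verify it against an
independently coded brute-force weighted-least-squares oracle at 1e-8 and
against `statsmodels` lowess. Degenerate cases: <2 sites on a chromosome →
raw values with a warning; zero bandwidth (coincident positions) → local
mean.

**Windows and threshold.** 1 Mb windows every 100 kb from position 1; empty
windows are missing and excluded. The threshold is the genome-wide
linear-interpolation 0.99 quantile of window means ("top 1%" read as a
global filter); selection is `≥` so threshold ties are included. Runs of
selected windows separated by <100 kb merge into regions (start/end =
min/max of member windows, peak = best window). An option thresholds on
fitted site values instead, since the published description does not pin
which quantity the top-1% filter applied to. Coordinates are 1-based
inclusive internally (VCF convention); BED export is 0-based half-open.

**Expected behaviour.** With a recessive locus, f_Y = 1 and E[f_G] = 1/3 at
the causal site, so E[ED²] → 8/9 as coverage grows; tests confirm the
empirical mean at 500× over 50 seeds within 3 SE. Under the default design
the top-1% region set contains the planted causal position in roughly
85–90% of replicates: with 15-individual pools the green-pool frequency
drifts smoothly along the chromosome (SD ≈ 0.06 from pool composition
alone), so the smoothed ED² ridge often peaks 1–2 Mb from the causal base
pair, and only ~2–3 Mb of the ridge clears a genome-wide top-1% cut. This
localisation jitter is intrinsic to the pool size and statistic, not to the
implementation; the null model shows no reproducible peak chromosome.

## Candidate screening

Pooled "genotypes" are frequency bands, not hard calls: het = f ∈
[0.2, 0.8], homozygous alt = f ≥ 0.9 (hom ref symmetric), depth <10 or
between-band frequencies → ambiguous; bands are validated not to overlap
and are configurable. The four screening conditions — inside the mapped
region; green pool het; yellow pool homozygous for the non-reference
allele; effect ∈ {nonsynonymous, splice_site, inframe_indel} — are applied
with per-criterion drop counts. "In-frame mutations" is interpreted as
in-frame indels. DEG intersection uses strict inequalities (q < 0.05,
fold change > 1.5, either direction), keeping the smallest q on duplicate
ids. The promoter window is 2 kb 5′ of the gene start (strand-aware,
boundary inclusive at `start − upstream_bp`); no published distance exists,
so 2 kb follows common plant-promoter practice and is a parameter.

## Inheritance statistics

Pearson chi-square against an integer ratio without continuity correction —
the printed value for 59:18 (0.11) is only reproduced uncorrected (Yates
gives ≈0.04). p is the chi-square upper tail with df = k−1. The published report lists
p = 0.74 for both χ² = 0.11 and χ² = 0.61; the second is arithmetically
≈0.44 and is treated as a transcription slip — this package
always reports the computed tail. Interval lengths are end − start in bp
(markers auto-ordered); the strict intersection of the two populations'
intervals is [33,536,014, 35,644,875], slightly narrower on the right than
the published "final" interval (35,661,331), which is not a strict
intersection; the op returns the strict result. Display rounding: χ² and p
to 2 decimals, Mb to the displayed precision; raw values are retained.

## Physiology

The pigment equations circulate in a parenthesis-free printed form; the
only dimensionally consistent reading of these Lichtenthaler-style forms
is (linear OD combination, mg/L) × V/(1000·M),
with the carotenoid equation consuming the chlorophyll *concentrations*
before volume/mass scaling. Negative contents (possible near zero) are
flagged, never clipped. The fluorometer reports the saturation-pulse parameters without printing
formulas, so the standard definitions are adopted and documented: Genty
Y(II) = (Fm′−Ft)/Fm′; NPQ = (Fm−Fm′)/Fm′; qN = 1−(Fm′−Fo′)/(Fm−Fo); puddle
qP = (Fm′−Ft)/(Fm′−Fo′); lake qL = qP·Fo′/Ft; Kramer partition
Y(NPQ) = Ft/Fm′ − Ft/Fm, Y(NO) = Ft/Fm (so Y(II)+Y(NPQ)+Y(NO) ≡ 1);
Oxborough–Baker Fo′ = Fo/(Fv/Fm + Fo/Fm′) when unmeasured; ETR =
0.5·0.84·PAR·Y(II). All are overridable inputs, and Fm′ ≤ Fo′ flags qP/qL
rather than failing. Published Fv/Fo means are means of per-plant ratios,
so the Fv/Fo ↔ Fv/Fm identity is asserted on printed means only where the
deviation is small (<0.3% for the wild-type rows). Treatment comparisons
report percent change and a Welch t-test.

## Problem sizes

The default genome (~4,400 markers), F2 of 150, and 20–50-seed replicate
batches make every stage run in seconds on one CPU; statistical tests use
3-SE tolerances around exact expectations (Poisson/binomial/Haldane) so
they are stable at these sizes.

## Known limitations

Biallelic SNPs only; no read-level artifacts, reference bias, or indel
realignment effects; effect annotation is consumed, not computed; the
simulator's pools are random within phenotype class; localisation of the
top-1% region set carries the Mb-scale jitter described above, which is a
property of 15+15 pool designs rather than a tunable defect.
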