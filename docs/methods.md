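# Methods

## Scope and data model

`isotriad` starts downstream of alignment and transcript assignment. Its
atomic input is a read record: a cell barcode, a UMI, a gene assignment,
an optional isoform assignment, and an ordered chain of aligned exon
blocks on a known strand. Cluster labels place each barcode in a study
grid with three phenotypic axes — brain region, developmental age and
cell subtype — plus replicate and a broad → cell-type → subtype
hierarchy. All internal coordinates are 0-based half-open; GTF (1-based
inclusive) and BED dialects are converted at the I/O boundary. Multi-base
BED peaks are anchored at their midpoint, since end-site assignment is a
point-to-point distance test.

UMI deduplication collapses reads sharing (barcode, UMI, gene) to a
single molecule. The key includes the gene deliberately: a barcode+UMI
collision across genes is overwhelmingly two distinct molecules, not a
duplicate. Among copies, the record with the greatest total aligned
length is kept (the most complete observation of the molecule), ties
broken by smallest read id; the operation is idempotent.

## Exon support and Ψ

For each candidate internal exon (exons appearing as internal blocks in
reads, united with annotated internal exons), each gene read falls in
exactly one category:

* **in** — a block equals the exon exactly and both flanking splice
  junctions are observed;
* **out** — one read gap fully contains the exon and both gap-flanking
  aligned blocks span ≥ 50 bases (`skip_flank`). We read the "≥ 50 bases
  on both sides" requirement as a minimum on the flanking aligned blocks;
  the alternative (gap margin beyond the exon) is not exposed because the
  two coincide for full blocks;
* **acc_in / don_in** — a truncated read whose terminal block is anchored
  at the exon's acceptor (strand-aware 3' splice site) or donor and ends
  within the exon. These classes rescue inclusion evidence from 5'/3'
  degraded molecules;
* **ambiguous** — span overlap matching no category (e.g. read-through
  across a boundary, or a skip with short flanks); counts toward `X_tot`
  only;
* **none** — no span overlap.

`X_tot` counts all span-overlapping gene reads, which makes the
informative-fraction filter (below) sensitive to ambiguous overlap.

Ψ variants follow the formulas in the README. Keep filters run on
pseudo-bulk counts first: non-annotated exons with at least one annotated
splice-site boundary and ≥ 70 bases outside every annotated exon of the
gene are excluded as intron-retention or alternative-acceptor/donor
artifacts; surviving exons are kept iff **all three** Ψ variants lie in
[0.05, 0.95] (inclusive — we read the window conjunctively over the
variants) and (X_in+X_acc_in+X_don_in+X_out)/X_tot ≥ 0.8. Per-group
Ψ_overall is reported only where the group's X_tot ≥ 10.

The triad matrix aggregates counts over replicates (and subtypes) within
each (age, region, cell type) triad *before* computing Ψ; counts are
summed, which weights replicates by depth. A `replicate_combine="mean"`
switch instead computes per-replicate Ψ and averages the defined values,
for users who prefer equal replicate weighting; the default is count
summation.

### A known property: inclusion bias under truncation

Truncation is asymmetric for this estimator. A truncated *including* read
keeps counting (as acc_in/don_in) until the target exon itself is
clipped, whereas a truncated *skipping* read drops out of `X_out` as soon
as a gap-flanking block falls under 50 bases or is removed. Under the
generator's default truncation (probability 0.25 per end, clipping 1–2
whole terminal exons plus a uniform partial overhang) this inflates Ψ by
roughly +0.03 to +0.07 for short (5-exon) genes, shrinking with exon
count and truncation rate. The planted-Ψ recovery benchmark therefore
sits near its ±0.05 budget; simulator-level checks of planted Ψ use the
molecule truth (binomial interval), which is unbiased.

## Tri-axial isoform variability

Within one cell type, Π of an isoform at a level of one axis is its read
fraction among the gene's isoform-assigned reads pooled over the other
two axes. A level qualifies only when the gene has ≥ 10 pooled reads
there (`min_gene_reads`; the published depth rule for Ψ is reused because
none is stated for Π). Raw variability per axis is max(Π) − min(Π) over
qualifying levels and is defined only with ≥ 2 such levels; the dominant
level is the one whose Π diverges most from the median (ties →
lexicographically smallest). If any axis is undefined the isoform is
*unplaced* — zero-filling would fabricate axis evenness. If max(raw) ≥
0.1 the triple is normalized to sum to 1; a vertex requires a normalized
value strictly > 0.5 (exactly 0.5 → center), so placement partitions.
Highly variable isoforms need raw ≥ 0.25 on some axis at a vertex, or on
all three axes in the center (a center isoform's variability is spread,
so one axis is weak evidence). The pseudo-bulk variant replaces the
subtype axis with the cell-type axis and pools over all cells.

## Differential usage (DIE) and end sites

Per gene and comparison, unit counts (isoforms, or TSS/polyA sites
assigned to the read's strand-aware terminus within ± 50 bp, nearest site
first, ties toward the upstream site; unassigned reads discarded) form a
≤ 11 × 2 matrix: the ten most abundant units by pooled count (ties →
lexicographic) plus an "other" row. Genes with < 25 reads in *either*
condition are untestable — the stricter reading of "25 reads per gene
category". The test is plain Pearson χ² without continuity correction,
mirroring the two-sample χ²-of-abundance framework; low expected counts
are logged, not patched. ΔΠ is the larger of the summed top-two positive
and top-two negative per-unit usage changes, which is symmetric in the
conditions and bounded by 1. BH runs per battery over testable genes;
significance requires q ≤ 0.05 and ΔΠ ≥ 0.1. One-vs-rest orchestration
tests each region against the pooled others and reports the threshold
sweep, per-gene region sharing and a gene × region status matrix.

## Exon programs

Four comparison lineages restrict triad pairs: developmental-time pairs
for a matched (cell type, developmental region); cell-type pairs at fixed
pre-adult timepoint and developmental region; region pairs at the
terminal age for a matched cell type; and cell-type pairs within each
region at the terminal age. hVEx = any lineage comparison with ΔΨ ≥ 0.25
(inclusive). The all-pairs ΔΨ matrix (n(n−1)/2 = 946 comparisons for 44
triads) drops exons with > 50 % missing comparisons (the published
NA rule states no number; 0.5 is configurable) and clusters rows with
complete linkage on NaN-tolerant Euclidean distances into four A-groups.

EVEx reduces each lineage to its maximal ΔΨ and requires ≥ 0.75 in some
column. E-groups are rule-based by default because the published grouping
procedure is a clustering with unstated parameters: with precedence
E4 > E3 > E1 > E5 > E2, E4 = region column extreme (adult brain-region
specialization), E3 = developmental *and* adult cell-type columns
extreme, E1 = developmental cell-type only, E5 = adult cell-type only,
E2 = developmental-time only. The precedence makes the rules a total
function on EVEx rows. A Ward-clustering mode (k = 5, clusters named by
applying the same rules to their mean profile) is available as the
alternative.

eVar at one (region, timepoint) is the Ψ range over cell types with ≥ 2
defined values. Modalities encode the three timepoint transitions as
`+` (ΔeVar > 0.1), `−` (< −0.1) or `0`, using the same 0.1 the invariable
rule states (the symmetric threshold is a choice; only the invariable
side is published), giving 27 codes; `000` is the invariable group G0 and
the nine most frequent non-zero codes are labeled G1–G9. Exons missing
eVar at any timepoint are skipped and counted.

Ψ-profile correlation uses Pearson on pairwise-complete observations with
≥ 20 shared exons per pair, and average linkage on 1 − r for ordering —
both unstated in the source and configurable.

## Coordination

For an exon pair of one gene (pairs never span genes — a single molecule
must be able to span both exons), only reads with definitive in/out
status for *both* exons enter the 2×2; truncated and ambiguous reads are
excluded. Pairs need ≥ 25 contributing reads (mirroring the DIE depth
rule; the published criterion is "sufficient depth" without a number).
Association is Pearson χ²; degenerate margins get p = 1. The odds ratio
replaces zero cells with 0.5 before the cross-product; the effect size is
|log₁₀(odds ratio)|; co-inclusion is in-in/total. BH runs over all tested
pairs and coordinated ⇔ q ≤ 0.05 (the published account states the test
but not the multiplicity handling).

## Synthetic-data generator

The generator models structure, not sequence: no base-level errors, no
FASTQ (splice sites arrive pre-corrected upstream). The default design
grid is the emulated study: 2 developmental regions × 4 ages × 2
replicates (16 samples) plus 3 adult-only regions × 2 replicates (6
samples), 4 major cell types × 2 subtypes, giving 44 triads and 946
pairwise comparisons. Depth defaults (20 cells/cluster, 25 reads/cell)
are desk-scale stand-ins for the real thousands of cells per sample;
benchmarks state their own sizes.

Gene models get 3–9 exons; ≥ 2 isoforms per gene are distinct inclusion
patterns over a set of alternative internal exons (the full pattern is
always present, so four-isoform genes over two alternative exons are
combination-complete — needed to realize arbitrary exon-pair joint
distributions). Genes optionally carry a second TSS/polyA anchor realized
by trimming the terminal exon's outer boundary by 60 bp in some isoforms.
Reads are sampled per cluster: molecule counts are Poisson with mean
cells × reads/cell, cells are assigned uniformly, genes by weight, and
isoforms from cluster-level Π. Effects modify Π deterministically:
isoform switches move ΔΠ mass from the most- to the least-used isoform
for clusters matching an axis level; exon effects rescale the
including/skipping isoform groups to hit a per-triad Ψ; coordination
effects replace isoform sampling by a two-exon joint inclusion state with
Plackett-copula cell probabilities solved from the target odds ratio
(target < 1 is rejected — plant the reciprocal by swapping labels).
Truncation clips 1–2 whole terminal exons plus a uniform partial overhang
into the newly terminal exon per flagged end (probability 0.25 per end by
default; rates are unpublished free parameters), so truncated reads
genuinely end on an exon with the adjacent junction intact. UMI
duplicates (rate 0.2) re-truncate independently from the full isoform, so
copies differ in aligned length and the dedup tie-break is exercised.
Barcodes (16 nt) and UMIs (12 nt) are resampled on collision, so the
deduplicated count equals the molecule truth exactly. All outputs are
byte-identical given a seed.

What the generator does not emulate: sequencing error and splice-site
miscorrection, expression differences between clusters (gene weights are
shared), ambient RNA/doublets, and length-dependent capture bias. Passing
recovery tests therefore demonstrates correctness of the statistics under
clean sampling noise, not robustness to upstream artifacts.

## Numerical choices and degenerate inputs

χ² is computed via `scipy.stats.chi2_contingency(correction=False)`; BH
via `statsmodels.stats.multitest.multipletests`. Usage matrices drop rows
with zero total in both conditions; a single expressed unit or an empty
condition yields p = 1 (no usage shift is measurable). Ψ variants with a
zero denominator are undefined and such exons are dropped conservatively
at the keep-filter step. In ternary assignment the normalizer cannot be
zero once the 0.1 gate passes (asserted). Empty site sets or clusters log
warnings and yield unassigned reads / skipped clusters rather than
errors. Pipeline stages validate the configuration before any compute and
write a manifest (config hash, seed, input and output checksums) for
reproducibility.

## Benchmark problem sizes

The packaged experiments (`isotriad.benchmarks`, reported by
`scripts/acceptance.py`) use: planted Ψ/ΔΠ recovery on a one-gene,
single-condition design with ≥ 1,000 informative reads per condition;
EVEx lineage recovery on the full 44-triad grid at ~250 reads per triad
across 50 seeded runs; DIE null calibration on 2,000 genes at 200 reads
per condition; coordination null on 1,000 pairs at 300 reads. These sizes
keep the full validation under a minute on one CPU while leaving the
binomial tolerances meaningful.

## Known limitations

Intron retention is excluded, not measured. The hVEx/EVEx grouping and
NA-filter parameters are reconstructions of unpublished choices and are
exposed as configuration. The Ψ estimator's truncation bias (above) is
inherent to the counting definitions; heavily truncated libraries will
overestimate inclusion. The per-read table schema is a reconstruction of
an upstream all-info-per-read export, not a published format.
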