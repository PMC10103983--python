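# isotriad

Exon inclusion, isoform variability and coordination analysis for
barcoded single-cell long-read transcriptomes.

Single-cell long-read sequencing assigns every cDNA molecule a cell
barcode, a UMI and (after upstream alignment and transcript assignment) a
gene, an isoform and a chain of aligned exon blocks. Given such a
per-read table, a gene annotation (GTF) and reference TSS/polyA site sets
(BED), `isotriad` quantifies how isoform and exon usage varies across
three phenotypic axes — developmental age, brain region and cell
(sub)type — the way a multi-region, multi-age mouse-brain atlas is
analysed: per-cell-type exon Ψ from full-length *and* truncated reads,
tri-axial isoform variability with ternary (triangle) assignment,
χ²-based differential isoform/TSS/polyA usage, highly and extremely
variable exon calling across four comparison lineages, developmental
variability modalities, and exon-pair coordination. A synthetic-data
generator with full ground truth emulates the study design
(2 developmental regions × 4 ages × 2 replicates, plus 3 adult-only
regions × 2 replicates; a broad → cell-type → subtype hierarchy) so every
statistic can be validated against planted effects.

## The statistics

For an internal exon, reads of the same gene are classified into support
categories: `X_in` (block matches the exon with both flanking junctions),
`X_out` (a gap skips the exon with ≥ 50 aligned bases on both sides),
`X_acc_in` / `X_don_in` (a truncated read confirms the acceptor/donor
junction and ends on the exon) and `X_tot` (any span overlap). Then

```
Ψ_overall  = (X_in + X_acc_in + X_don_in) / (X_in + X_acc_in + X_don_in + X_out)
Ψ_acceptor = (X_in + X_acc_in) / (X_in + X_acc_in + X_out)
Ψ_donor    = (X_in + X_don_in) / (X_in + X_don_in + X_out)
```

Exons are kept when 0.05 ≤ Ψ ≤ 0.95 for all three variants and the
informative fraction is ≥ 0.8; per-group Ψ requires `X_tot` ≥ 10.
Per-isoform percent inclusion Π along one axis pools reads over the other
two axes; raw variability per axis is max(Π) − min(Π), and triples whose
maximum reaches 0.1 are normalized to sum to 1 for ternary placement.
Differential usage builds a ≤ 11 × 2 unit-by-condition matrix (top ten
units plus "other"), tests it with Pearson's χ² (untestable below 25
reads per condition), measures ΔΠ as the top-two usage shift per
direction, and applies BH at FDR 5 %. Exon Ψ over (age, region, cell
type) *triads* feeds hVEx (ΔΨ ≥ 0.25 in any of four comparison lineages),
EVEx (per-lineage maxima, ΔΨ ≥ 0.75, groups E1–E5), and the 3³ = 27
developmental modality codes of cell-type variability eVar. Exon-pair
coordination tests the 2×2 in/out co-inclusion matrix with χ², reporting
the odds ratio (zero cells → 0.5) and |log₁₀(odds ratio)|.

## Worked example

```python
import isotriad as it

design = it.default_design(cells_per_cluster=5, reads_per_cell=10)
annotation, tss, polya = it.build_synthetic_annotation(5, isoforms_per_gene=(2, 4), seed=11)
table, truth = it.simulate_study(design, it.EffectSpec(), annotation, seed=11)
table = it.dedupe_umis(table)
matrix = it.build_triad_psi_matrix(table, annotation, design)
print(matrix.psi.shape)
```

prints `(6, 44)`: six alternative exons pass the keep filters, quantified
over the 44 (age, region, cell type) triads of the design. Running
`python examples/01_simulate_study.py` on this same configuration prints

```
design: 22 samples (16 developmental + 6 adult), 176 cell clusters, 44 triads
annotation: 5 genes, 12 transcripts, 6 TSS / 7 polyA reference sites
simulated 10639 reads from 8919 molecules; 8919 remain after UMI deduplication (duplicate rate 0.19)
```

— the deduplicated read count recovers the simulated molecule count
exactly, and the realized duplicate rate matches the configured 0.2. The
other scripts in `examples/` walk through each capability (Ψ, ternary
variability, differential usage, exon programs, coordination) with
planted effects and one-line interpretations; e.g.
`examples/06_coordination.py` plants an exon-pair odds ratio of 9 and
recovers 8.85 from 2,413 definitive reads.

A thin CLI wraps the same pipeline for shell use:

```bash
isotriad all --seed 17 --out run/          # simulate + every analysis stage
isotriad psi --config run.yaml --out run/  # one stage, config-driven
```

Each run writes TSV outputs plus a `manifest.json` recording the config
hash, seed and per-file checksums; re-running with the same seed and
config is byte-identical.

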