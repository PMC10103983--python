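"""Exon programs: plant a developmental Ψ ramp, call hVEx/EVEx, group it,
and encode its variability modality.

The planted exon ramps from Ψ = 0.1 (P14) to 0.9 (P56) in every region
and cell type, so only the developmental-time lineage carries a large ΔΨ.
"""

import isotriad as it

annotation, _, _ = it.build_synthetic_annotation(
    1, exons_per_gene=(5, 5), isoforms_per_gene=(2, 2), seed=21,
    alt_tss_fraction=0.0, alt_polya_fraction=0.0,
)
txs = annotation.transcripts_of("g0001")
chains = [set((e.start, e.end) for e in t.exons) for t in txs]
(alt_exon,) = set.union(*chains) - set.intersection(*chains)

design = it.default_design(cells_per_cluster=5, reads_per_cell=20)
psi_by_age = dict(zip(design.ages, (0.1, 0.37, 0.63, 0.9)))
effects = it.EffectSpec(
    exon_effects=[it.ExonEffect(
        gene_id="g0001", exon=alt_exon,
        psi_by_triad=tuple(
            ((age, region, ct), psi_by_age[age])
            for (region, age) in design.conditions() for ct in design.cell_types
        ),
    )],
    umi_duplication_rate=0.0,
)
table, _ = it.simulate_study(design, effects, annotation, seed=21)
matrix = it.build_triad_psi_matrix(it.dedupe_umis(table), annotation, design)

comparisons = it.enumerate_lineage_comparisons(matrix)
hvex = it.call_hvex(comparisons, threshold=0.25)
evex = it.classify_evex_groups(it.call_evex(comparisons, hvex=hvex, threshold=0.75))
eid = f"g0001:{alt_exon[0]}-{alt_exon[1]}"
print(f"hVEx called: {sorted(hvex)}")
print("per-lineage maximal ΔΨ for the planted exon:")
print(evex.values.loc[[eid]].round(3).to_string())
print(f"EVEx: {bool(evex.evex.loc[eid])}, group: {evex.groups.loc[eid]}")
# The time lineage (dev_same_celltype) holds the 0.8 range; with no
# region or cell-type extreme the exon falls in the time-specific group E2.

tbl = it.evar_table(matrix, "HIPP")
modality = it.classify_developmental_modality(tbl)
print("\ncell-type variability (eVar) per timepoint and its modality code:")
print(modality["records"].round(3).to_string())
# eVar stays small at every age (all cell types ramp together), so the
# exon encodes as an invariable (G0) trajectory despite its strong
# developmental inclusion change.
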