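"""Exon-pair coordination: plant an odds ratio of 9 between two exons of
one gene and recover it from the 2x2 in/out read counts.

The odds ratio uses the 0.5 zero-cell substitution; the effect size is
|log10(odds ratio)|; significance is χ² association with BH correction.
"""

import isotriad as it

annotation, _, _ = it.build_synthetic_annotation(
    1, exons_per_gene=(6, 6), isoforms_per_gene=(4, 4), seed=31,
    alt_tss_fraction=0.0, alt_polya_fraction=0.0,
)
txs = annotation.transcripts_of("g0001")
chains = [set((e.start, e.end) for e in t.exons) for t in txs]
alt = sorted(set.union(*chains) - set.intersection(*chains))

design = it.StudyDesign(
    dev_regions=("R",), ages=("A",), adult_regions=(), replicates=("r1",),
    cell_hierarchy={"B": {"CT": ("S",)}}, cells_per_cluster=40, reads_per_cell=60.0,
)
effects = it.EffectSpec(
    coordination_effects=[it.CoordinationEffect(
        gene_id="g0001", exon_a=alt[0], exon_b=alt[1], odds_ratio=9.0,
    )],
    truncation_5=0.0, truncation_3=0.0, umi_duplication_rate=0.0,
)
table, truth = it.simulate_study(design, effects, annotation, seed=31)

counts = it.count_pair_states(table, [("g0001", alt[0], alt[1])])
results = it.test_coordination(counts)
print(it.coordination_frame(results).round(4).to_string(index=False))
print(f"\nplanted odds ratio 9.0, estimated {results[0].odds_ratio:.2f}; "
      f"coordinated={results[0].coordinated}")
print("worked zero-cell example (10,0,0,10): odds ratio "
      f"{it.odds_ratio_half_corrected(10, 0, 0, 10):.0f} "
      "(0.5 substituted for the empty discordant cells)")
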