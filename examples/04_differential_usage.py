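"""Differential isoform and TSS usage, one region vs the pooled rest.

Per gene, an isoform-by-condition count matrix (<= 11 rows) is tested
with Pearson's χ²; ΔΠ sums the usage shift of the top two isoforms per
direction; BH correction at FDR 5% plus ΔΠ >= 0.1 defines significance.
"""

import isotriad as it

design = it.default_design(cells_per_cluster=8, reads_per_cell=20)
annotation, tss, _ = it.build_synthetic_annotation(4, isoforms_per_gene=(2, 3), seed=29)
effects = it.EffectSpec(
    isoform_switches=[it.IsoformSwitch("g0001", "region", ("THAL",), 0.4)],
)
table, _ = it.simulate_study(design, effects, annotation, seed=29)
table = it.dedupe_umis(table)

out = it.one_vs_rest_region_die(table, unit_kind="isoform")
print("THAL vs rest (isoform usage):")
print(it.die_results_frame(out["results"]["THAL"]).round(4).to_string(index=False))
print("\nsignificant genes per region and ΔΠ threshold:")
print(out["significant_fraction"].round(3).to_string(index=False))
# g0001 carries the planted ΔΠ = 0.4 switch and is significant in the
# THAL battery; counts fall as the ΔΠ threshold rises.

assigned = it.assign_end_sites(table, tss, window=50)
frac = assigned["site_id"].notna().mean()
print(f"\nTSS assignment: {frac:.0%} of reads land within 50 bp of a "
      "reference peak (5'-truncated reads are discarded)")
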