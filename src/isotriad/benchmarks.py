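"""Planted-effect recovery and calibration experiments on synthetic data.

Each function builds a synthetic dataset with a known effect, runs the
corresponding analysis module end to end, and reports how well the
planted parameter is recovered. They exist so that the package's
statistical behaviour (estimator accuracy, null calibration, detection
power) can be measured reproducibly from a single seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (
    CoordinationEffect,
    EffectSpec,
    ExonEffect,
    IsoformSwitch,
    StudyDesign,
    bh_adjust,
    build_die_matrix,
    build_synthetic_annotation,
    build_triad_psi_matrix,
    call_evex,
    call_hvex,
    compute_cell_type_variability,
    count_pair_states,
    dedupe_umis,
    default_design,
    die_test,
    enumerate_lineage_comparisons,
    simulate_study,
    test_coordination,
)


def _single_condition_design(cells=40, rpc=60.0) -> StudyDesign:
    return StudyDesign(
        dev_regions=("R",), ages=("A",), adult_regions=(), replicates=("r1",),
        cell_hierarchy={"B": {"CT": ("S",)}},
        cells_per_cluster=cells, reads_per_cell=rpc,
    )


def _two_isoform_gene(seed):
    ann, _, _ = build_synthetic_annotation(
        1, exons_per_gene=(5, 5), isoforms_per_gene=(2, 2), seed=seed,
        alt_tss_fraction=0.0, alt_polya_fraction=0.0,
    )
    txs = ann.transcripts_of("g0001")
    chains = [set((e.start, e.end) for e in t.exons) for t in txs]
    (alt_exon,) = set.union(*chains) - set.intersection(*chains)
    return ann, alt_exon


def planted_psi_recovery(seed: int, target: float = 0.5) -> dict:
    """Plant a triad Ψ and recover it through the Ψ engine.

    One gene whose two isoforms differ by a single internal exon; >= 1,000
    informative reads in the target triad.
    """
    ann, alt_exon = _two_isoform_gene(seed)
    design = _single_condition_design()
    eff = EffectSpec(
        exon_effects=[ExonEffect(gene_id="g0001", exon=alt_exon, default_psi=target)],
        umi_duplication_rate=0.0,
    )
    table, _ = simulate_study(design, eff, ann, seed=seed)
    m = build_triad_psi_matrix(table, ann, design)
    est = float(m.psi.loc[f"g0001:{alt_exon[0]}-{alt_exon[1]}", ("A", "R", "CT")])
    return {"planted": target, "estimated": est, "abs_error": abs(est - target),
            "n_reads": len(table)}


def planted_dpi_recovery(seed: int, delta_pi: float) -> dict:
    """Plant a region-specific isoform switch of size ΔΠ and read it back
    as raw region variability (>= 1,000 gene reads per region level)."""
    ann, _ = _two_isoform_gene(seed)
    design = StudyDesign(
        dev_regions=("HIPP", "VIS"), ages=("P14",), adult_regions=(),
        replicates=("rep1",), cell_hierarchy={"Glia": {"Astro": ("A1",)}},
        cells_per_cluster=40, reads_per_cell=40.0,
    )
    eff = EffectSpec(
        isoform_switches=[IsoformSwitch("g0001", "region", ("HIPP",), delta_pi)],
        umi_duplication_rate=0.0,
    )
    table, _ = simulate_study(design, eff, ann, seed=seed)
    vs = compute_cell_type_variability(dedupe_umis(table), "Astro")
    est = max(v.raw["region"] for v in vs if v.raw["region"] is not None)
    return {"planted": delta_pi, "estimated": float(est),
            "abs_error": abs(est - delta_pi), "n_reads": len(table)}


def evex_lineage_recovery(seed: int, n_runs: int = 50, delta_psi: float = 0.8) -> dict:
    """Plant a developmental-time Ψ ramp of range ΔΨ on one exon and count
    how often it is called EVEx with the time lineage as the dominant
    column, across seeded replicate simulations on the full study grid."""
    ann, alt_exon = _two_isoform_gene(seed)
    design = default_design(cells_per_cluster=4, reads_per_cell=16.0)
    lo = 0.1
    ages = design.ages
    ramp = np.linspace(lo, lo + delta_psi, len(ages))
    psi_by_age = dict(zip(ages, ramp))
    psi_by_triad = tuple(
        ((age, region, ct), float(psi_by_age[age]))
        for (region, age) in design.conditions() for ct in design.cell_types
    )
    eff = EffectSpec(
        exon_effects=[ExonEffect(gene_id="g0001", exon=alt_exon, psi_by_triad=psi_by_triad)],
        umi_duplication_rate=0.0,
    )
    eid = f"g0001:{alt_exon[0]}-{alt_exon[1]}"
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    n_hit = 0
    for rs in run_seeds:
        table, _ = simulate_study(design, eff, ann, seed=int(rs))
        m = build_triad_psi_matrix(table, ann, design)
        comp = enumerate_lineage_comparisons(m)
        em = call_evex(comp, hvex=call_hvex(comp))
        if eid in em.values.index and bool(em.evex.get(eid, False)):
            dominant = em.values.loc[eid].idxmax()
            if dominant == "dev_same_celltype":
                n_hit += 1
    return {"n_runs": n_runs, "n_recovered": n_hit, "rate": n_hit / n_runs}


def die_null_calibration(
    seed: int,
    n_genes: int = 2000,
    depth: int = 200,
    thresholds: tuple = (0.1, 0.2, 0.3, 0.4, 0.5),
) -> dict:
    """Null DIE calibration: identical isoform multinomials in both
    conditions. Reports the fraction of genes declared significant at
    BH q <= 0.05 and ΔΠ >= 0.1, plus the significant-gene count per ΔΠ
    threshold (which must be non-increasing)."""
    rng = np.random.default_rng(seed)
    results = []
    for g in range(n_genes):
        k = int(rng.integers(2, 6))
        probs = rng.dirichlet(np.full(k, 2.0))
        c1 = rng.multinomial(depth, probs)
        c2 = rng.multinomial(depth, probs)
        counts = {f"i{j}": (int(c1[j]), int(c2[j])) for j in range(k)}
        m = build_die_matrix(f"g{g}", counts)
        results.append(die_test(m))
    bh_adjust(results)
    fpr = float(np.mean([r.status == "significant" for r in results]))
    sweep = {
        thr: sum(
            1 for r in results
            if r.q_value is not None and r.q_value <= 0.05 and r.delta_pi >= thr
        )
        for thr in thresholds
    }
    counts_sorted = [sweep[t] for t in sorted(sweep)]
    return {
        "n_genes": n_genes, "false_positive_rate": fpr, "sweep": sweep,
        "monotone_non_increasing": all(
            a >= b for a, b in zip(counts_sorted, counts_sorted[1:])
        ),
    }


def coordination_null_rate(seed: int, n_pairs: int = 1000, depth: int = 300) -> dict:
    """Independent planted inclusion: the raw-p <= 0.05 rate should sit
    near the nominal 5%."""
    from .coordination import PairCounts
    from .model import GenomicInterval

    rng = np.random.default_rng(seed)
    ea = GenomicInterval("chrS", 1000, 1100, "+")
    eb = GenomicInterval("chrS", 2000, 2100, "+")
    counts = []
    for i in range(n_pairs):
        za = rng.random(depth) < 0.5
        zb = rng.random(depth) < 0.5
        counts.append(PairCounts(
            "g", ea, eb, (),
            int((za & zb).sum()), int((za & ~zb).sum()),
            int((~za & zb).sum()), int((~za & ~zb).sum()),
        ))
    results = test_coordination(counts)
    rate = float(np.mean([r.p_value <= 0.05 for r in results]))
    return {"n_pairs": n_pairs, "raw_p_rate": rate}


def coordination_or_recovery(seed: int, odds_ratio: float = 9.0) -> dict:
    """Plant an exon-pair odds ratio through the read simulator and
    recover it with the coordination test; reports whether the estimate
    falls inside the 99% CI of the log odds ratio."""
    ann, _, _ = build_synthetic_annotation(
        1, exons_per_gene=(6, 6), isoforms_per_gene=(4, 4), seed=seed,
        alt_tss_fraction=0.0, alt_polya_fraction=0.0,
    )
    txs = ann.transcripts_of("g0001")
    chains = [set((e.start, e.end) for e in t.exons) for t in txs]
    alt = sorted(set.union(*chains) - set.intersection(*chains))
    design = _single_condition_design(cells=40, rpc=60.0)
    eff = EffectSpec(
        coordination_effects=[CoordinationEffect(
            gene_id="g0001", exon_a=alt[0], exon_b=alt[1], odds_ratio=odds_ratio,
        )],
        truncation_5=0.0, truncation_3=0.0, umi_duplication_rate=0.0,
    )
    table, _ = simulate_study(design, eff, ann, seed=seed)
    counts = count_pair_states(table, [("g0001", alt[0], alt[1])])
    (res,) = test_coordination(counts)
    pc = res.pair
    se = float(np.sqrt(sum(
        1 / max(x, 0.5)
        for x in (pc.n_in_in, pc.n_in_out, pc.n_out_in, pc.n_out_out)
    )))
    within = abs(np.log(res.odds_ratio) - np.log(odds_ratio)) <= 2.576 * se
    return {
        "planted": odds_ratio, "estimated": float(res.odds_ratio),
        "within_99ci": bool(within), "coordinated": bool(res.coordinated),
        "n_reads": pc.total,
    }
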