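"""Synthetic-data generator: determinism, design enumeration and planted
parameter recovery."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import isotriad as it


def test_design_enumeration_matches_reference_grid(paper_design):
    e = it.enumerate_design(paper_design)
    assert len(e["developmental_samples"]) == 16
    assert len(e["adult_samples"]) == 6
    assert len(e["triads"]) == 44
    assert e["n_pairwise_triad_comparisons"] == 946


def test_design_enumeration_degenerate_grid():
    d = it.StudyDesign(
        dev_regions=("R1",), ages=("A1",), adult_regions=(), replicates=("r1",),
        cell_hierarchy={"B": {"CT": ("S1",)}},
    )
    e = it.enumerate_design(d)
    assert len(e["triads"]) == 1
    assert e["n_pairwise_triad_comparisons"] == 0


def test_duplicate_sample_keys_rejected():
    d = it.StudyDesign(
        dev_regions=("R1",), ages=("A1",), adult_regions=("R1",), replicates=("r1",),
        cell_hierarchy={"B": {"CT": ("S1",)}},
    )
    with pytest.raises(ValueError, match="duplicate"):
        d.samples()


def test_subtype_mapped_to_two_cell_types_rejected():
    with pytest.raises(ValueError, match="two cell types"):
        it.StudyDesign(
            dev_regions=("R1",), ages=("A1",), adult_regions=(), replicates=("r1",),
            cell_hierarchy={"B": {"CT1": ("S1",), "CT2": ("S1",)}},
        )


# ---------------------------------------------------------------------------
# annotation generation

def test_annotation_deterministic_given_seed(tmp_path):
    p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
    for p in (p1, p2):
        ann, _, _ = it.build_synthetic_annotation(3, exons_per_gene=(5, 5), seed=7)
        it.write_annotation_gtf(ann, p)
    assert p1.read_bytes() == p2.read_bytes()


def test_annotation_isoform_counts_and_structure():
    ann, tss, polya = it.build_synthetic_annotation(
        6, isoforms_per_gene=(2, 2), seed=1
    )
    for gid in ann.genes:
        txs = ann.transcripts_of(gid)
        assert len(txs) == 2
        # isoforms differ by >= 1 internal exon
        chains = {tuple((e.start, e.end) for e in t.exons) for t in txs}
        assert len(chains) == 2
        # no same-transcript exon overlap (enforced at construction, checked
        # exhaustively over the output here)
        for t in txs:
            for a, b in zip(t.exons, t.exons[1:]):
                assert a.end <= b.start
    assert len(tss.sites) >= len(ann.genes)
    assert len(polya.sites) >= len(ann.genes)


def test_annotation_infeasible_ranges_rejected():
    with pytest.raises(ValueError):
        it.build_synthetic_annotation(1, exons_per_gene=(3, 3), isoforms_per_gene=(8, 8), seed=0)
    with pytest.raises(ValueError):
        it.build_synthetic_annotation(1, exons_per_gene=(2, 2), seed=0)


# ---------------------------------------------------------------------------
# study simulation

def small_design(cells=4, rpc=8.0):
    return it.StudyDesign(
        dev_regions=("HIPP", "VIS"), ages=("P14", "P56"), adult_regions=(),
        replicates=("rep1",),
        cell_hierarchy={"Glia": {"Astro": ("A1",)}, "Neuron": {"Excit": ("E1",)}},
        cells_per_cluster=cells, reads_per_cell=rpc,
    )


def test_simulation_deterministic_given_seed(tmp_path):
    ann, _, _ = it.build_synthetic_annotation(3, seed=2)
    files = []
    for name in ("x.tsv", "y.tsv"):
        table, _ = it.simulate_study(small_design(), it.EffectSpec(), ann, seed=9)
        path = tmp_path / name
        it.write_read_table(table, path)
        files.append(path.read_bytes())
    assert files[0] == files[1]


def test_no_truncation_reads_match_an_isoform_exactly():
    ann, _, _ = it.build_synthetic_annotation(3, seed=2)
    eff = it.EffectSpec(truncation_5=0.0, truncation_3=0.0, umi_duplication_rate=0.0)
    table, _ = it.simulate_study(small_design(), eff, ann, seed=4)
    chains = {
        g: {tuple((e.start, e.end) for e in t.exons) for t in ann.transcripts_of(g)}
        for g in ann.genes
    }
    assert len(table) > 0
    for r in table.records:
        assert r.blocks in chains[r.gene_id]


def test_truncation_preserves_at_least_one_block_and_loses_junction():
    ann, _, _ = it.build_synthetic_annotation(3, seed=2)
    eff = it.EffectSpec(truncation_5=1.0, truncation_3=1.0, umi_duplication_rate=0.0)
    table, _ = it.simulate_study(small_design(), eff, ann, seed=4)
    full = {t.transcript_id: tuple((e.start, e.end) for e in t.exons) for t in ann.transcripts.values()}
    n_shorter = 0
    for r in table.records:
        assert len(r.blocks) >= 1
        if len(r.blocks) < len(full[r.isoform_id]):
            n_shorter += 1
    assert n_shorter > 0.9 * len(table)


def test_umi_duplication_rate_and_dedup_truth():
    ann, _, _ = it.build_synthetic_annotation(3, seed=2)
    eff = it.EffectSpec(umi_duplication_rate=0.2)
    table, truth = it.simulate_study(small_design(cells=20, rpc=25), eff, ann, seed=6)
    n_dup = len(table) - truth.n_molecules
    rate = n_dup / truth.n_molecules
    assert 0.15 < rate < 0.25
    assert len(it.dedupe_umis(table)) == truth.n_molecules


def test_cluster_pi_recovers_in_read_frequencies():
    """Marginal per-cluster isoform frequencies converge to the truth Π."""
    ann, _, _ = it.build_synthetic_annotation(1, isoforms_per_gene=(2, 2), seed=8)
    d = it.StudyDesign(
        dev_regions=("R",), ages=("A",), adult_regions=(), replicates=("r1",),
        cell_hierarchy={"B": {"CT": ("S",)}}, cells_per_cluster=50, reads_per_cell=200.0,
    )
    eff = it.EffectSpec(umi_duplication_rate=0.0)
    table, truth = it.simulate_study(d, eff, ann, seed=8)
    df = table.to_frame()
    n = len(df)
    observed = df["isoform_id"].value_counts(normalize=True)
    for row in truth.pi.itertuples(index=False):
        p = row.pi
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo / n <= observed.get(row.isoform_id, 0.0) <= hi / n


def test_planted_exon_psi_recovered():
    """A planted triad Ψ of 0.5 is realized in the sampled molecules within
    the central 99% binomial interval, and recovered by the Ψ engine within
    ±0.05 (truncation makes the engine's estimate slightly inclusion-biased,
    because clipped skipping reads lose their 50-base flanks more easily
    than clipped including reads lose their anchor junction)."""
    ann, _, _ = it.build_synthetic_annotation(
        1, exons_per_gene=(5, 5), isoforms_per_gene=(2, 2), seed=21,
        alt_tss_fraction=0.0, alt_polya_fraction=0.0,
    )
    gid = "g0001"
    txs = ann.transcripts_of(gid)
    chains = [set((e.start, e.end) for e in t.exons) for t in txs]
    (alt_exon,) = set.union(*chains) - set.intersection(*chains)
    d = it.StudyDesign(
        dev_regions=("R",), ages=("A",), adult_regions=(), replicates=("r1",),
        cell_hierarchy={"B": {"CT": ("S",)}}, cells_per_cluster=40, reads_per_cell=60.0,
    )
    eff = it.EffectSpec(
        exon_effects=[it.ExonEffect(gene_id=gid, exon=alt_exon, default_psi=0.5)],
        umi_duplication_rate=0.0,
    )
    table, _ = it.simulate_study(d, eff, ann, seed=21)
    includes = {
        t.transcript_id: any((e.start, e.end) == alt_exon for e in t.exons)
        for t in txs
    }
    realized = np.mean([includes[r.isoform_id] for r in table.records])
    n = len(table)
    lo, hi = stats.binom.interval(0.99, n, 0.5)
    assert lo / n <= realized <= hi / n
    m = it.build_triad_psi_matrix(table, ann, d)
    eid = f"{gid}:{alt_exon[0]}-{alt_exon[1]}"
    psi = m.psi.loc[eid, ("A", "R", "CT")]
    assert abs(psi - 0.5) <= 0.05


def test_planted_coordination_odds_ratio_recovered():
    """A planted odds ratio of 9 is recovered within the 99% CI of the
    log odds ratio at ~1,000 contributing reads."""
    ann, _, _ = it.build_synthetic_annotation(
        1, exons_per_gene=(6, 6), isoforms_per_gene=(4, 4), seed=31,
        alt_tss_fraction=0.0, alt_polya_fraction=0.0,
    )
    gid = "g0001"
    txs = ann.transcripts_of(gid)
    chains = [set((e.start, e.end) for e in t.exons) for t in txs]
    alt = sorted(set.union(*chains) - set.intersection(*chains))
    assert len(alt) == 2
    d = it.StudyDesign(
        dev_regions=("R",), ages=("A",), adult_regions=(), replicates=("r1",),
        cell_hierarchy={"B": {"CT": ("S",)}}, cells_per_cluster=40, reads_per_cell=60.0,
    )
    eff = it.EffectSpec(
        coordination_effects=[it.CoordinationEffect(
            gene_id=gid, exon_a=alt[0], exon_b=alt[1], odds_ratio=9.0,
        )],
        truncation_5=0.0, truncation_3=0.0, umi_duplication_rate=0.0,
    )
    table, truth = it.simulate_study(d, eff, ann, seed=31)
    pairs = [(gid, alt[0], alt[1])]
    counts = it.count_pair_states(table, pairs)
    assert len(counts) == 1
    pc = counts[0]
    results = it.test_coordination(counts)
    est = results[0].odds_ratio
    se = np.sqrt(sum(1 / max(x, 0.5) for x in
                     (pc.n_in_in, pc.n_in_out, pc.n_out_in, pc.n_out_out)))
    assert abs(np.log(est) - np.log(9.0)) <= 2.576 * se
    assert results[0].coordinated


def test_odds_ratio_below_one_rejected():
    with pytest.raises(ValueError, match="reciprocal"):
        it.CoordinationEffect("g1", (0, 1), (2, 3), odds_ratio=0.5)


def test_joint_inclusion_probs_match_target():
    p11, p10, p01, p00 = it.joint_inclusion_probs(0.4, 0.6, 9.0)
    assert p11 + p10 == pytest.approx(0.4)
    assert p11 + p01 == pytest.approx(0.6)
    assert (p11 * p00) / (p10 * p01) == pytest.approx(9.0)
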