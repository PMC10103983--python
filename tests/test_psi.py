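"""Exon support classification, X counting, keep filters and Ψ."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import isotriad as it
from isotriad.model import Gene, GenomicInterval, Transcript
from isotriad.psi import COUNT_COLUMNS, _nonexonic_bases

from conftest import make_read, make_table

EXON = GenomicInterval("chr1", 1000, 1100, "+")


# ---------------------------------------------------------------------------
# classification

@pytest.mark.parametrize(
    "blocks,strand,expected",
    [
        # full support: internal block matches exactly, junctions both sides
        ([(700, 800), (1000, 1100), (1300, 1400)], "+", "in"),
        ([(700, 800), (1000, 1100), (1300, 1400)], "-", "in"),
        # skipping: gap contains exon, flanks >= 50
        ([(700, 940), (1160, 1400)], "+", "out"),
        # skipping but a gap-flanking block < 50 bases -> ambiguous
        ([(900, 940), (1160, 1400)], "+", "ambiguous"),
        # acceptor junction present, read terminates within the exon
        ([(700, 800), (1000, 1050)], "+", "acc_in"),
        # ... terminating exactly at the exon end still lacks the donor junction
        ([(700, 800), (1000, 1100)], "+", "acc_in"),
        # donor junction present, 5'-truncated read starts within the exon
        ([(1020, 1100), (1300, 1400)], "+", "don_in"),
        # minus strand swaps acceptor/donor roles
        ([(700, 800), (1000, 1050)], "-", "don_in"),
        ([(1020, 1100), (1300, 1400)], "-", "acc_in"),
        # read-through across a boundary contradicts both sites
        ([(900, 1200)], "+", "ambiguous"),
        # single block equal to the exon: no junction evidence
        ([(1000, 1100)], "+", "ambiguous"),
        # exact match sitting at the read terminus with one junction only
        ([(700, 800), (1000, 1100), (1300, 1400), (1500, 1600)], "+", "in"),
        # no span overlap
        ([(200, 300), (400, 500)], "+", "none"),
        ([(1100, 1300)], "+", "none"),
    ],
)
def test_classification_definitions(blocks, strand, expected):
    read = make_read("r1", blocks, strand=strand)
    assert it.classify_read_exon_support(read, EXON) == expected


def test_classification_flank_parameter():
    read = make_read("r1", [(900, 960), (1160, 1400)])
    assert it.classify_read_exon_support(read, EXON, flank=50) == "out"
    assert it.classify_read_exon_support(read, EXON, flank=70) == "ambiguous"


@settings(max_examples=200, derandomize=True)
@given(st.data())
def test_classification_returns_exactly_one_label(data):
    """Classification is total and single-valued over random reads."""
    n_blocks = data.draw(st.integers(1, 4))
    pos = 0
    blocks = []
    for _ in range(n_blocks):
        pos += data.draw(st.integers(1, 200))
        length = data.draw(st.integers(1, 200))
        blocks.append((pos, pos + length))
        pos += length
    strand = data.draw(st.sampled_from("+-"))
    read = make_read("r", blocks, strand=strand)
    s = data.draw(st.integers(0, 800))
    e = s + data.draw(st.integers(1, 300))
    label = it.classify_read_exon_support(read, GenomicInterval("chr1", s, e, strand))
    assert label in {"in", "out", "acc_in", "don_in", "ambiguous", "none"}
    span_s, span_e = read.span
    if label == "none":
        assert e <= span_s or s >= span_e
    else:
        assert s < span_e and span_s < e


# ---------------------------------------------------------------------------
# brute-force oracle for the counting engine

def brute_force_counts(table, exons, flank=50):
    """Independent tally from first principles (junction-set formulation)."""
    acc = {}
    for read in table.records:
        for exon in exons.get(read.gene_id, []):
            span_s, span_e = read.blocks[0][0], read.blocks[-1][1]
            if not (span_s < exon.end and exon.start < span_e):
                continue
            key = (read.gene_id, exon.start, exon.end)
            row = acc.setdefault(key, dict.fromkeys(COUNT_COLUMNS, 0))
            row["x_tot"] += 1
            junctions = [
                (read.blocks[i][1], read.blocks[i + 1][0])
                for i in range(len(read.blocks) - 1)
            ]
            left = any(j[1] == exon.start for j in junctions)
            right = any(j[0] == exon.end for j in junctions)
            exact = any(b == (exon.start, exon.end) for b in read.blocks)
            if exact and left and right:
                row["x_in"] += 1
                continue
            skipped = any(
                a <= exon.start and b >= exon.end
                and read.blocks[i][1] - read.blocks[i][0] >= flank
                and read.blocks[i + 1][1] - read.blocks[i + 1][0] >= flank
                for i, (a, b) in enumerate(junctions)
            )
            if skipped:
                row["x_out"] += 1
                continue
            last = read.blocks[-1]
            first = read.blocks[0]
            ends_left_anchored = (
                left and last[0] == exon.start and last[1] <= exon.end
            )
            ends_right_anchored = (
                right and first[1] == exon.end and first[0] >= exon.start
            )
            if ends_left_anchored:
                row["x_acc_in" if read.strand == "+" else "x_don_in"] += 1
            elif ends_right_anchored:
                row["x_don_in" if read.strand == "+" else "x_acc_in"] += 1
    return acc


def test_counts_match_brute_force_oracle(sim_dataset):
    """Vectorized counting equals a per-read, per-exon brute-force loop on
    a ~500-read simulated fixture."""
    table = make_table(sim_dataset["table"].records[:500], deduplicated=True)
    exons = it.candidate_exons(table, sim_dataset["annotation"])
    counts = it.count_exon_support(table, exons)
    oracle = brute_force_counts(table, exons)
    assert len(counts) == len(oracle)
    for row in counts.itertuples(index=False):
        exp = oracle[(row.gene_id, row.exon_start, row.exon_end)]
        got = {c: getattr(row, c) for c in COUNT_COLUMNS}
        assert got == exp, (row.gene_id, row.exon_start, row.exon_end)


def test_count_invariant_sum_bound(sim_dataset):
    table = sim_dataset["table"]
    exons = it.candidate_exons(table, sim_dataset["annotation"])
    counts = it.count_exon_support(table, exons)
    informative = counts[["x_in", "x_out", "x_acc_in", "x_don_in"]].sum(axis=1)
    assert (informative <= counts["x_tot"]).all()
    assert (counts[COUNT_COLUMNS] >= 0).all().all()


def test_count_unknown_group_key_raises(sim_dataset):
    with pytest.raises(KeyError, match="nonsense"):
        it.count_exon_support(sim_dataset["table"], {}, group_by=("nonsense",))


# ---------------------------------------------------------------------------
# Ψ formulas and keep filters

def _counts_frame(x_in, x_out, x_acc, x_don, x_tot, gene="g1", start=1000, end=1100):
    return pd.DataFrame([{
        "gene_id": gene, "exon_start": start, "exon_end": end,
        "x_in": x_in, "x_out": x_out, "x_acc_in": x_acc, "x_don_in": x_don,
        "x_tot": x_tot,
    }])


def test_psi_formulas():
    df = it.psi_from_counts(_counts_frame(8, 2, 1, 1, 12), xtot_min=10)
    row = df.iloc[0]
    assert row.psi_overall == pytest.approx(10 / 12)
    assert row.psi_acceptor == pytest.approx(9 / 11)
    assert row.psi_donor == pytest.approx(9 / 11)


def test_psi_zero_inclusion_and_depth_gate():
    row = it.psi_from_counts(_counts_frame(0, 5, 0, 0, 10), xtot_min=10).iloc[0]
    assert row.psi_overall == 0.0
    row = it.psi_from_counts(_counts_frame(8, 2, 1, 1, 9), xtot_min=10).iloc[0]
    assert np.isnan(row.psi_overall)
    assert row.psi_acceptor == pytest.approx(9 / 11)  # variants gated only by denominator


def test_psi_variants_agree_without_truncated_reads():
    row = it.psi_from_counts(_counts_frame(6, 3, 0, 0, 10), xtot_min=10).iloc[0]
    assert row.psi_overall == row.psi_acceptor == row.psi_donor == pytest.approx(6 / 9)


@pytest.fixture()
def two_exon_annotation():
    exons = [
        GenomicInterval("chr1", 100, 200, "+"),
        GenomicInterval("chr1", 1000, 1100, "+"),
        GenomicInterval("chr1", 2000, 2100, "+"),
    ]
    t1 = Transcript("t1", "g1", tuple(exons))
    t2 = Transcript("t2", "g1", (exons[0], exons[2]))
    return it.Annotation([Gene("g1", "chr1", "+")], [t1, t2])


@pytest.mark.parametrize(
    "counts,kept",
    [
        ((8, 2, 1, 1, 12), True),     # Ψs ~0.82-0.83, ratio 1.0
        ((97, 3, 0, 0, 100), False),  # Ψ = 0.97 outside the window
        ((3, 97, 0, 0, 100), False),  # Ψ = 0.03 outside the window
        ((40, 39, 0, 0, 100), False), # informative ratio 0.79 < 0.8
        ((40, 40, 0, 0, 100), True),  # ratio exactly 0.8 kept (inclusive)
    ],
)
def test_keep_filter_rules(two_exon_annotation, counts, kept):
    df = _counts_frame(*counts)
    result = it.filter_alternative_exons(df, two_exon_annotation)
    assert (("g1", 1000, 1100) in result) is kept


def test_nonannotated_exon_exclusion(two_exon_annotation):
    # novel interval sharing the annotated acceptor at 1000, extending 170
    # bases into the intron: >= 70 non-exonic bases -> excluded
    novel = _counts_frame(8, 2, 1, 1, 12, start=1000, end=1270)
    assert it.filter_alternative_exons(novel, two_exon_annotation) == set()
    # same boundaries but only 30 non-exonic bases -> retained
    short = _counts_frame(8, 2, 1, 1, 12, start=1000, end=1130)
    assert it.filter_alternative_exons(short, two_exon_annotation) == {("g1", 1000, 1130)}
    # fully novel exon (no annotated splice site) is not excluded by the rule
    novel_free = _counts_frame(8, 2, 1, 1, 12, start=5000, end=5400)
    assert it.filter_alternative_exons(novel_free, two_exon_annotation) == {("g1", 5000, 5400)}


def test_nonexonic_bases_partial_overlap():
    exon = GenomicInterval("chr1", 1000, 1300, "+")
    annotated = [GenomicInterval("chr1", 1000, 1100, "+"), GenomicInterval("chr1", 1250, 1400, "+")]
    assert _nonexonic_bases(exon, annotated) == 150


# ---------------------------------------------------------------------------
# triad matrix

def test_triad_matrix_has_design_columns(sim_dataset):
    m = it.build_triad_psi_matrix(
        sim_dataset["table"], sim_dataset["annotation"], sim_dataset["design"]
    )
    assert m.psi.shape[1] == 44
    assert list(m.psi.columns.names) == ["age", "region", "cell_type"]
    vals = m.psi.to_numpy()
    finite = vals[~np.isnan(vals)]
    assert ((finite >= 0) & (finite <= 1)).all()


def test_triad_counts_are_replicate_additive(sim_dataset):
    """Summing per-replicate counts reproduces the triad-level counts."""
    table = sim_dataset["table"]
    exons = it.candidate_exons(table, sim_dataset["annotation"])
    triad = it.count_exon_support(table, exons, group_by=("age", "region", "cell_type"))
    per_rep = it.count_exon_support(
        table, exons, group_by=("age", "region", "cell_type", "replicate")
    )
    summed = (
        per_rep.groupby(["gene_id", "exon_start", "exon_end", "age", "region", "cell_type"])
        [COUNT_COLUMNS].sum().reset_index()
    )
    merged = triad.merge(
        summed, on=["gene_id", "exon_start", "exon_end", "age", "region", "cell_type"],
        suffixes=("", "_sum"),
    )
    assert len(merged) == len(triad)
    for c in COUNT_COLUMNS:
        assert (merged[c] == merged[f"{c}_sum"]).all()


def test_triad_matrix_requires_present_cell_type(sim_dataset):
    with pytest.raises(ValueError, match="absent"):
        it.build_triad_psi_matrix(
            sim_dataset["table"], sim_dataset["annotation"], sim_dataset["design"],
            cell_types=["NoSuchType"],
        )
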