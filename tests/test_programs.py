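"""hVEx/EVEx calling, E-grouping, developmental modalities and Ψ-profile
correlation."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import isotriad as it
from isotriad.programs import _lineage_triad_pairs, EvexMatrix
from isotriad.psi import TriadPsiMatrix


def make_matrix(design, values: dict, exons=("e1",)):
    """values: {(age, region, ct): psi or {exon: psi}}."""
    cols = pd.MultiIndex.from_tuples(design.triads(), names=["age", "region", "cell_type"])
    df = pd.DataFrame(np.nan, index=list(exons), columns=cols)
    for triad, v in values.items():
        if isinstance(v, dict):
            for exon, p in v.items():
                df.loc[exon, triad] = p
        else:
            df.loc[exons[0], triad] = v
    info = pd.DataFrame({"gene_id": "g1", "exon_start": 0, "exon_end": 1}, index=list(exons))
    return TriadPsiMatrix(psi=df, design=design, exon_info=info)


@pytest.fixture(scope="module")
def design():
    return it.default_design()


# ---------------------------------------------------------------------------
# lineage enumeration

def test_lineage_pair_counts_on_reference_grid(design):
    pairs = _lineage_triad_pairs(design)
    counts = pd.Series([p[0] for p in pairs]).value_counts().to_dict()
    # 4 cts x 2 dev regions x C(4,2) timepoint pairs
    assert counts["dev_same_celltype"] == 4 * 2 * 6
    # 3 pre-adult timepoints x 2 dev regions x C(4,2) ct pairs
    assert counts["celltype_within_region_dev"] == 3 * 2 * 6
    # 4 cts x C(5,2) region pairs at the terminal age
    assert counts["region_matched_celltype_adult"] == 4 * 10
    # 5 regions x C(4,2) ct pairs at the terminal age
    assert counts["celltype_within_region_adult"] == 5 * 6


def test_dev_celltype_lineage_excludes_terminal_age(design):
    pairs = _lineage_triad_pairs(design)
    for lineage, ta, tb in pairs:
        if lineage == "celltype_within_region_dev":
            assert ta[0] != design.terminal_age and tb[0] != design.terminal_age


def test_comparisons_skip_missing_psi(design):
    m = make_matrix(design, {
        ("P14", "HIPP", "Astro"): 0.9,
        ("P56", "HIPP", "Astro"): 0.2,
        # P21/P28 left missing
    })
    comp = it.enumerate_lineage_comparisons(m)
    assert len(comp) == 1
    assert comp.iloc[0].delta_psi == pytest.approx(0.7)
    assert comp.iloc[0].lineage == "dev_same_celltype"


def test_two_triads_give_one_comparison():
    d = it.StudyDesign(
        dev_regions=("R",), ages=("A1", "A2"), adult_regions=(), replicates=("r1",),
        cell_hierarchy={"B": {"CT": ("S",)}},
    )
    m = make_matrix(d, {("A1", "R", "CT"): 0.1, ("A2", "R", "CT"): 0.2})
    assert len(it.enumerate_lineage_comparisons(m)) == 1


# ---------------------------------------------------------------------------
# hVEx / pairwise matrix

@pytest.mark.parametrize("dpsi,is_hvex", [(0.25, True), (0.24, False)])
def test_hvex_threshold_inclusive(design, dpsi, is_hvex):
    m = make_matrix(design, {
        ("P14", "HIPP", "Astro"): 0.5,
        ("P56", "HIPP", "Astro"): 0.5 + dpsi,
    })
    comp = it.enumerate_lineage_comparisons(m)
    assert (("e1" in it.call_hvex(comp)) is is_hvex)


def test_hvex_all_missing_not_called(design):
    comp = it.enumerate_lineage_comparisons(make_matrix(design, {}))
    assert it.call_hvex(comp) == set()


def test_pairwise_matrix_has_946_columns_and_na_filter(design):
    rng = np.random.default_rng(0)
    cols = design.triads()
    values = {}
    for t in cols:
        values[t] = {"dense": rng.uniform(), "sparse": np.nan}
    for t in cols[:10]:
        values[t]["sparse"] = rng.uniform()
    m = make_matrix(design, values, exons=("dense", "sparse"))
    out = it.pairwise_dpsi_matrix(m, max_na_fraction=0.5)
    assert out["dpsi"].shape[1] == 946
    # sparse exon: only C(10,2)=45 of 946 comparisons defined -> dropped
    assert list(out["dpsi"].index) == ["dense"]
    out2 = it.pairwise_dpsi_matrix(m, max_na_fraction=1.0)
    assert set(out2["dpsi"].index) == {"dense", "sparse"}
    assert out2["groups"].notna().all()  # clustering partitions retained exons


# ---------------------------------------------------------------------------
# EVEx

def test_evex_per_lineage_maxima_and_threshold(design):
    m = make_matrix(design, {
        ("P14", "HIPP", "Astro"): 0.05,
        ("P21", "HIPP", "Astro"): 0.30,
        ("P56", "HIPP", "Astro"): 0.85,  # time lineage max = 0.80
        ("P56", "VIS", "Astro"): 0.80,   # region lineage max = 0.05
    })
    comp = it.enumerate_lineage_comparisons(m)
    em = it.call_evex(comp, hvex=it.call_hvex(comp))
    assert em.values.loc["e1", "dev_same_celltype"] == pytest.approx(0.80)
    assert em.values.loc["e1", "region_matched_celltype_adult"] == pytest.approx(0.05)
    assert bool(em.evex.loc["e1"])
    assert em.values.loc["e1"].isna().sum() == 2  # undefined lineages stay missing


def test_evex_boundary_below_threshold(design):
    m = make_matrix(design, {
        ("P14", "HIPP", "Astro"): 0.1,
        ("P56", "HIPP", "Astro"): 0.84,  # ΔΨ = 0.74
    })
    comp = it.enumerate_lineage_comparisons(m)
    em = it.call_evex(comp, hvex=it.call_hvex(comp))
    assert not bool(em.evex.loc["e1"])


def test_evex_subset_of_hvex(sim_dataset):
    m = it.build_triad_psi_matrix(
        sim_dataset["table"], sim_dataset["annotation"], sim_dataset["design"]
    )
    comp = it.enumerate_lineage_comparisons(m)
    hvex = it.call_hvex(comp)
    em = it.call_evex(comp, hvex=hvex)
    assert set(em.evex[em.evex].index) <= hvex


def _evex_matrix(rows: dict) -> EvexMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[
        "celltype_within_region_dev", "dev_same_celltype",
        "region_matched_celltype_adult", "celltype_within_region_adult",
    ])[list(it.LINEAGES)]
    return EvexMatrix(values=df, evex=(df >= 0.75).any(axis=1))


@pytest.mark.parametrize(
    "cols,group",
    [
        # (dev_ct, time, region, adult_ct)
        ((0.8, 0.2, 0.1, 0.1), "E1"),
        ((0.1, 0.8, 0.1, 0.1), "E2"),
        ((0.8, 0.3, 0.2, 0.8), "E3"),
        ((0.2, 0.2, 0.8, 0.8), "E4"),
        ((0.1, 0.1, 0.1, 0.8), "E5"),
        ((0.8, 0.8, 0.8, 0.8), "E4"),  # precedence: region beats the rest
    ],
)
def test_evex_group_rules(cols, group):
    em = _evex_matrix({"e": cols})
    out = it.classify_evex_groups(em, method="rules")
    assert out.groups.loc["e"] == group


def test_evex_hclust_mode_partitions():
    rng = np.random.default_rng(1)
    rows = {}
    for i in range(6):
        rows[f"a{i}"] = (0.8 + rng.uniform(-0.03, 0.03), 0.1, 0.1, 0.1)
        rows[f"b{i}"] = (0.1, 0.1, 0.8 + rng.uniform(-0.03, 0.03), 0.2)
    em = _evex_matrix(rows)
    out = it.classify_evex_groups(em, method="hclust", n_groups=2)
    labels = out.groups
    assert labels.loc[[f"a{i}" for i in range(6)]].nunique() == 1
    assert labels.loc["a0"] != labels.loc["b0"]
    assert labels.loc["a0"].startswith("E1")
    assert labels.loc["b0"].startswith("E4")


# ---------------------------------------------------------------------------
# eVar and modalities

def test_evar_range_rules(design):
    m = make_matrix(design, {
        ("P14", "HIPP", "Astro"): 0.9,
        ("P14", "HIPP", "Oligo"): 0.2,
        ("P14", "HIPP", "ExcitNeuron"): 0.5,
        # InhibNeuron missing
        ("P21", "HIPP", "Astro"): 0.4,
    })
    assert it.compute_evar(m, "HIPP", "P14").loc["e1"] == pytest.approx(0.7)
    assert np.isnan(it.compute_evar(m, "HIPP", "P21").loc["e1"])  # one cell type only
    assert np.isnan(it.compute_evar(m, "VIS", "P14").loc["e1"])


def test_evar_all_equal_is_zero(design):
    m = make_matrix(design, {
        ("P14", "HIPP", ct): 0.6 for ct in design.cell_types
    })
    assert it.compute_evar(m, "HIPP", "P14").loc["e1"] == 0.0


def test_modality_code_space_is_27():
    assert len(it.MODALITY_CODES) == 27
    assert len(set(it.MODALITY_CODES)) == 27
    assert all(len(c) == 3 and set(c) <= set("+-0") for c in it.MODALITY_CODES)


@pytest.mark.parametrize(
    "evars,code,group",
    [
        ((0.2, 0.25, 0.17, 0.19), "000", "G0"),  # all |ΔeVar| < 0.1
        ((0.1, 0.4, 0.2, 0.2), "+-0", None),
        ((0.0, 0.5, 0.9, 0.2), "++-", None),
    ],
)
def test_modality_encoding(evars, code, group):
    tbl = pd.DataFrame([evars], columns=["P14", "P21", "P28", "P56"], index=["e1"])
    out = it.classify_developmental_modality(tbl)
    rec = out["records"].loc["e1"]
    assert rec.code == code
    if group:
        assert rec.group == group


def test_modality_skips_incomplete_trajectories():
    tbl = pd.DataFrame(
        [[0.1, 0.2, 0.3, 0.4], [0.1, np.nan, 0.3, 0.4]],
        columns=["P14", "P21", "P28", "P56"], index=["full", "gappy"],
    )
    out = it.classify_developmental_modality(tbl)
    assert out["n_skipped"] == 1
    assert list(out["records"].index) == ["full"]


def test_modality_group_labels_rank_by_frequency():
    rows = {"a%d" % i: (0.0, 0.5, 0.5, 0.5) for i in range(5)}  # "+00" x5
    rows.update({"b%d" % i: (0.5, 0.0, 0.0, 0.0) for i in range(3)})  # "-00" x3
    rows["c"] = (0.2, 0.2, 0.2, 0.2)  # G0
    tbl = pd.DataFrame.from_dict(rows, orient="index")
    tbl.columns = ["P14", "P21", "P28", "P56"]
    out = it.classify_developmental_modality(tbl)
    freq = out["frequencies"]
    assert freq.loc["+00", "group"] == "G1"
    assert freq.loc["-00", "group"] == "G2"
    assert freq.loc["000", "group"] == "G0"


# ---------------------------------------------------------------------------
# Ψ-profile correlation

def test_correlation_identical_and_opposite_profiles():
    rng = np.random.default_rng(2)
    x = rng.uniform(size=30)
    df = pd.DataFrame({"a": x, "b": x, "c": 1 - x})
    out = it.correlate_psi_profiles(df, min_shared=20)
    corr = out["correlation"]
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)
    assert out["linkage"] is not None


def test_correlation_min_shared_filter():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.uniform(size=(30, 2)), columns=["a", "b"])
    df.iloc[10:, 1] = np.nan  # only 10 shared exons
    out = it.correlate_psi_profiles(df, min_shared=20)
    assert np.isnan(out["correlation"].loc["a", "b"])


def test_correlation_constant_column_missing():
    df = pd.DataFrame({"a": np.arange(25.0), "b": np.ones(25)})
    out = it.correlate_psi_profiles(df, min_shared=20)
    assert np.isnan(out["correlation"].loc["a", "b"])


def test_adjacent_and_cross_region_extraction(design):
    rng = np.random.default_rng(4)
    triads = design.triads()
    psi = pd.DataFrame(
        rng.uniform(size=(40, len(triads))),
        columns=pd.MultiIndex.from_tuples(triads, names=["age", "region", "cell_type"]),
    )
    out = it.correlate_psi_profiles(psi, min_shared=20)
    adj = it.adjacent_timepoint_correlations(out["correlation"], design)
    assert len(adj) == 2 * 4 * 3  # dev regions x cell types x transitions
    cross = it.cross_region_correlations(out["correlation"], design)
    assert len(cross) == 4 * 10  # cell types x region pairs at P56
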