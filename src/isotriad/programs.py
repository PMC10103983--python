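"""Exon splicing programs: highly / extremely variable exons across four
comparison lineages, developmental variability modalities, and Ψ-profile
correlation.

The four lineages restrict which triad pairs are compared:

1. ``dev_same_celltype`` — pairs of timepoints for a matched cell type in
   a developmentally sampled region (developmental-time changes);
2. ``celltype_within_region_dev`` — pairs of cell types at a fixed
   pre-adult timepoint and developmental region;
3. ``region_matched_celltype_adult`` — pairs of regions at the terminal
   age for a matched cell type;
4. ``celltype_within_region_adult`` — pairs of cell types within each
   region at the terminal age.

Exons with |ΔΨ| >= 0.25 in any lineage comparison are highly variable
(hVEx); reducing each lineage to its maximal ΔΨ and thresholding at 0.75
yields extremely variable exons (EVEx), grouped E1–E5 by which lineages
carry the extreme variability.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

from .design import StudyDesign
from .psi import TriadPsiMatrix

log = logging.getLogger(__name__)

LINEAGES = (
    "dev_same_celltype",
    "celltype_within_region_dev",
    "region_matched_celltype_adult",
    "celltype_within_region_adult",
)


# ---------------------------------------------------------------------------
# Lineage comparisons, hVEx, EVEx

def _lineage_triad_pairs(design: StudyDesign) -> list:
    """(lineage, triad_a, triad_b) pairs; triads are (age, region, cell_type)."""
    pairs = []
    term = design.terminal_age
    pre_adult = [a for a in design.ages if a != term]
    for ct in design.cell_types:
        for region in design.dev_regions:
            for a1, a2 in itertools.combinations(design.ages, 2):
                pairs.append(("dev_same_celltype", (a1, region, ct), (a2, region, ct)))
    for age in pre_adult:
        for region in design.dev_regions:
            for c1, c2 in itertools.combinations(design.cell_types, 2):
                pairs.append(("celltype_within_region_dev", (age, region, c1), (age, region, c2)))
    for ct in design.cell_types:
        for r1, r2 in itertools.combinations(design.all_regions, 2):
            pairs.append(("region_matched_celltype_adult", (term, r1, ct), (term, r2, ct)))
    for region in design.all_regions:
        for c1, c2 in itertools.combinations(design.cell_types, 2):
            pairs.append(("celltype_within_region_adult", (term, region, c1), (term, region, c2)))
    return pairs


def enumerate_lineage_comparisons(matrix: TriadPsiMatrix) -> pd.DataFrame:
    """All defined ΔΨ comparisons along the four lineages.

    Returns a long frame (exon_id, lineage, triad_a, triad_b, delta_psi);
    comparisons where either Ψ is missing are skipped (a debug log reports
    the count).
    """
    psi = matrix.psi
    rows = []
    n_skipped = 0
    for lineage, ta, tb in _lineage_triad_pairs(matrix.design):
        if ta not in psi.columns or tb not in psi.columns:
            continue
        d = (psi[ta] - psi[tb]).abs()
        defined = d.dropna()
        n_skipped += len(d) - len(defined)
        for exon, val in defined.items():
            rows.append((exon, lineage, ta, tb, float(val)))
    if n_skipped:
        log.debug("%d lineage comparisons skipped for missing Ψ", n_skipped)
    return pd.DataFrame(rows, columns=["exon_id", "lineage", "triad_a", "triad_b", "delta_psi"])


def call_hvex(comparisons: pd.DataFrame, threshold: float = 0.25) -> set:
    """Highly variable exons: any lineage comparison with ΔΨ >= threshold."""
    if comparisons.empty:
        return set()
    hit = comparisons[comparisons["delta_psi"] >= threshold]
    return set(hit["exon_id"].unique())


def pairwise_dpsi_matrix(
    matrix: TriadPsiMatrix,
    exons: set | None = None,
    max_na_fraction: float = 0.5,
    n_groups: int = 4,
    linkage_method: str = "complete",
) -> dict:
    """|ΔΨ| over all triad pairs (n(n-1)/2 comparisons) for the given exons.

    Exons with a missing-value fraction above ``max_na_fraction`` are
    dropped; the surviving rows are hierarchically clustered (Euclidean
    distance on pairwise-complete values, complete linkage) into
    ``n_groups`` exon groups.

    Returns {"dpsi": frame exons x comparisons, "groups": Series of group
    labels ("A1".."Ak"), "linkage": scipy linkage matrix}.
    """
    psi = matrix.psi
    if exons is not None:
        psi = psi.loc[psi.index.intersection(sorted(exons))]
    cols = list(psi.columns)
    pair_cols = {}
    for ta, tb in itertools.combinations(cols, 2):
        label = "|".join(["_".join(ta), "_".join(tb)])
        pair_cols[label] = (psi[ta] - psi[tb]).abs()
    dpsi = pd.DataFrame(pair_cols, index=psi.index)
    na_frac = dpsi.isna().mean(axis=1)
    dpsi = dpsi.loc[na_frac <= max_na_fraction]
    if dpsi.empty:
        raise ValueError("no exon survives the NA-fraction filter")
    if len(dpsi) >= 2:
        dist = nan_euclidean_distances(dpsi.to_numpy())
        np.fill_diagonal(dist, 0.0)
        dist = np.nan_to_num(dist, nan=float(np.nanmax(dist)) if np.isfinite(np.nanmax(dist)) else 0.0)
        Z = linkage(squareform(dist, checks=False), method=linkage_method)
        labels = fcluster(Z, t=min(n_groups, len(dpsi)), criterion="maxclust")
    else:
        Z = None
        labels = np.ones(len(dpsi), dtype=int)
    groups = pd.Series([f"A{i}" for i in labels], index=dpsi.index, name="group")
    return {"dpsi": dpsi, "groups": groups, "linkage": Z}


@dataclass
class EvexMatrix:
    """hVEx x lineage matrix of per-lineage maximal ΔΨ."""

    values: pd.DataFrame  # columns = LINEAGES
    evex: pd.Series  # boolean flag per exon
    groups: pd.Series | None = None  # E1..E5 labels for EVEx exons


def call_evex(
    comparisons: pd.DataFrame,
    hvex: set | None = None,
    threshold: float = 0.75,
) -> EvexMatrix:
    """Reduce each lineage to its maximal ΔΨ per exon and flag EVEx.

    An exon is extremely variable when any lineage column reaches
    ``threshold``; lineages with no defined comparison are missing and
    never exceed.
    """
    df = comparisons
    if hvex is not None:
        df = df[df["exon_id"].isin(hvex)]
    if df.empty:
        values = pd.DataFrame(columns=list(LINEAGES))
    else:
        values = (
            df.groupby(["exon_id", "lineage"])["delta_psi"].max().unstack("lineage")
            .reindex(columns=list(LINEAGES))
        )
    evex = (values >= threshold).any(axis=1)
    return EvexMatrix(values=values, evex=evex)


# E-group rule columns: which lineage carries the extreme variability
_E_COLS = {
    "dev_ct": "celltype_within_region_dev",
    "time": "dev_same_celltype",
    "region": "region_matched_celltype_adult",
    "adult_ct": "celltype_within_region_adult",
}


def _e_rule(row: pd.Series, high: float) -> str:
    def hi(col):
        v = row.get(_E_COLS[col])
        return (v is not None) and not pd.isna(v) and v >= high

    # precedence E4 > E3 > E1 > E5 > E2
    if hi("region"):
        return "E4"  # adult brain-region specific inclusion
    if hi("dev_ct") and hi("adult_ct"):
        return "E3"  # cell-type specific in development and adulthood
    if hi("dev_ct"):
        return "E1"  # cell-type specific during development only
    if hi("adult_ct"):
        return "E5"  # cell-type specificity acquired in adulthood
    if hi("time"):
        return "E2"  # developmental-time specific inclusion
    return "unassigned"


def classify_evex_groups(
    m: EvexMatrix,
    method: str = "rules",
    high: float = 0.75,
    n_groups: int = 5,
) -> EvexMatrix:
    """Assign E1–E5 group labels to EVEx exons.

    ``rules`` (default) applies threshold rules on the four lineage maxima
    with precedence E4 > E3 > E1 > E5 > E2; ``hclust`` Ward-clusters the
    lineage matrix into ``n_groups`` clusters and names each cluster by
    applying the same rules to its mean profile.
    """
    sub = m.values.loc[m.evex[m.evex].index] if len(m.values) else m.values
    if method == "rules":
        groups = sub.apply(_e_rule, axis=1, high=high) if len(sub) else pd.Series(dtype=object)
    elif method == "hclust":
        if len(sub) < 2:
            groups = sub.apply(_e_rule, axis=1, high=high) if len(sub) else pd.Series(dtype=object)
        else:
            filled = sub.fillna(0.0).to_numpy()
            Z = linkage(filled, method="ward")
            labels = fcluster(Z, t=min(n_groups, len(sub)), criterion="maxclust")
            names = {}
            for lab in np.unique(labels):
                mean = sub.iloc[labels == lab].mean()
                name = _e_rule(mean, high)
                if name in names.values():
                    name = f"{name}#{lab}"
                names[lab] = name
            groups = pd.Series([names[l] for l in labels], index=sub.index)
    else:
        raise ValueError(f"unknown method {method!r}")
    n_un = int((groups == "unassigned").sum()) if len(groups) else 0
    if n_un:
        log.info("%d EVEx exons matched no E-group rule", n_un)
    m.groups = groups.rename("group") if len(groups) else pd.Series(dtype=object, name="group")
    return m


# ---------------------------------------------------------------------------
# Developmental modalities of variability

MODALITY_CODES = tuple("".join(c) for c in itertools.product("+-0", repeat=3))


def compute_evar(
    matrix: TriadPsiMatrix,
    region: str,
    timepoint: str,
    cell_types: list | None = None,
) -> pd.Series:
    """Per-exon cell-type variability eVar = max(Ψ) - min(Ψ) at one
    (region, timepoint); missing when fewer than two cell types have Ψ."""
    cts = list(cell_types) if cell_types is not None else list(matrix.design.cell_types)
    cols = [(timepoint, region, ct) for ct in cts if (timepoint, region, ct) in matrix.psi.columns]
    if not cols:
        return pd.Series(np.nan, index=matrix.psi.index, name="evar")
    sub = matrix.psi[cols]
    defined = sub.notna().sum(axis=1)
    evar = sub.max(axis=1) - sub.min(axis=1)
    evar[defined < 2] = np.nan
    return evar.rename("evar")


def evar_table(
    matrix: TriadPsiMatrix,
    region: str,
    cell_types: list | None = None,
) -> pd.DataFrame:
    """Exon x timepoint table of eVar for one developmental region."""
    return pd.DataFrame({
        age: compute_evar(matrix, region, age, cell_types)
        for age in matrix.design.ages
    })


def classify_developmental_modality(
    evar_by_timepoint: pd.DataFrame,
    step_threshold: float = 0.1,
    n_report: int = 9,
) -> dict:
    """Encode each exon's eVar trajectory as a three-transition pattern.

    Each timepoint transition contributes ``+`` (ΔeVar > step_threshold),
    ``-`` (< -step_threshold) or ``0``, giving 3^3 = 27 possible codes;
    the all-constant code is the invariable group G0. Exons lacking eVar
    at any timepoint are skipped and counted. The ``n_report`` most
    frequent non-G0 codes are labeled G1..Gk.

    Returns {"records": frame with code/group per exon, "frequencies":
    code frequency table with group labels, "n_skipped": int}.
    """
    ages = list(evar_by_timepoint.columns)
    if len(ages) < 2:
        raise ValueError("need >= 2 timepoints for transitions")
    complete = evar_by_timepoint.dropna()
    n_skipped = len(evar_by_timepoint) - len(complete)
    deltas = complete.diff(axis=1).iloc[:, 1:]
    def encode(d):
        if d > step_threshold:
            return "+"
        if d < -step_threshold:
            return "-"
        return "0"
    codes = deltas.map(encode).agg("".join, axis=1)
    zero_code = "0" * deltas.shape[1]
    freq = codes.value_counts()
    ranked = [c for c in freq.index if c != zero_code]
    group_of = {zero_code: "G0"}
    for i, code in enumerate(ranked[:n_report], start=1):
        group_of[code] = f"G{i}"
    records = complete.copy()
    for i, col in enumerate(deltas.columns):
        records[f"delta_{ages[i]}_{ages[i + 1]}"] = deltas[col]
    records["code"] = codes
    records["group"] = codes.map(lambda c: group_of.get(c, "other"))
    freq_table = freq.rename("count").to_frame()
    freq_table["group"] = [group_of.get(c, "other") for c in freq_table.index]
    return {"records": records, "frequencies": freq_table, "n_skipped": n_skipped}


# ---------------------------------------------------------------------------
# Ψ-profile correlation

def correlate_psi_profiles(
    psi: pd.DataFrame | TriadPsiMatrix,
    min_shared: int = 20,
    linkage_method: str = "average",
) -> dict:
    """Pairwise Pearson correlation between Ψ columns over shared exons.

    Uses pairwise-complete observations; pairs with fewer than
    ``min_shared`` shared exons (or a constant column) are missing.
    Columns whose correlations are all defined are clustered by
    hierarchical linkage on 1 - r.

    Returns {"correlation": matrix, "linkage": scipy matrix or None,
    "clustered_columns": list}.
    """
    df = psi.psi if isinstance(psi, TriadPsiMatrix) else psi
    if df.shape[1] < 2:
        raise ValueError("need >= 2 columns to correlate")
    corr = df.corr(method="pearson", min_periods=min_shared)
    if corr.isna().any().any():
        log.warning("undefined correlations (constant column or < %d shared exons)", min_shared)
    complete = corr.index[corr.notna().all(axis=1)]
    Z = None
    if len(complete) >= 3:
        d = 1.0 - corr.loc[complete, complete].to_numpy()
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2, 0.0, None)
        Z = linkage(squareform(d, checks=False), method=linkage_method)
    return {"correlation": corr, "linkage": Z, "clustered_columns": list(complete)}


def adjacent_timepoint_correlations(corr: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Extract r between consecutive ages for matched (region, cell type)."""
    rows = []
    for region in design.dev_regions:
        for ct in design.cell_types:
            for a1, a2 in zip(design.ages, design.ages[1:]):
                ca, cb = (a1, region, ct), (a2, region, ct)
                if ca in corr.index and cb in corr.index:
                    rows.append((region, ct, a1, a2, corr.loc[[ca], [cb]].iloc[0, 0]))
    return pd.DataFrame(rows, columns=["region", "cell_type", "age_a", "age_b", "r"])


def cross_region_correlations(corr: pd.DataFrame, design: StudyDesign, age: str | None = None) -> pd.DataFrame:
    """Extract r between regions for matched (age, cell type)."""
    age = age if age is not None else design.terminal_age
    rows = []
    for ct in design.cell_types:
        for r1, r2 in itertools.combinations(design.all_regions, 2):
            ca, cb = (age, r1, ct), (age, r2, ct)
            if ca in corr.index and cb in corr.index:
                rows.append((ct, age, r1, r2, corr.loc[[ca], [cb]].iloc[0, 0]))
    return pd.DataFrame(rows, columns=["cell_type", "age", "region_a", "region_b", "r"])
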