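"""Tri-axial isoform variability: Π by axis level, variability triples,
ternary (triangle) assignment, highly-variable-isoform calls and the
pseudo-bulk variant.

For a fixed cell type, every cluster is a combination of brain region
(axis ``region``), age (axis ``age``) and cell subtype (axis ``subtype``).
The percent inclusion Π of an isoform at a level of one axis is its read
fraction among the gene's reads pooled over the other two axes. The raw
variability of an isoform along an axis is max(Π) - min(Π) over qualifying
levels (defined only with >= 2 qualifying levels). If the largest of the
three raw values reaches the gate (default 0.1) the triple is normalized
to sum to 1 and placed in a ternary diagram: the isoform is assigned to an
axis vertex if that normalized value exceeds 0.5, otherwise to the center.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ReadTable

AXES = ("age", "region", "subtype")
PSEUDOBULK_AXES = ("age", "region", "cell_type")


@dataclass
class PiProfile:
    """Per-isoform Π across the levels of one or more axes (one cell type)."""

    gene_id: str
    isoform_id: str
    cell_type: str
    pi_by_level: dict = field(default_factory=dict)  # axis -> {level: Π}
    counts_by_level: dict = field(default_factory=dict)  # axis -> {level: gene reads}


@dataclass
class TriAxialVariability:
    gene_id: str
    isoform_id: str
    cell_type: str
    raw: dict = field(default_factory=dict)  # axis -> value or None
    normalized: dict | None = None  # axis -> value, sums to 1
    triangle: str = "unplaced"  # axis name, "center" or "unplaced"
    dominant_level: dict = field(default_factory=dict)  # axis -> level


def _axis_pi(df: pd.DataFrame, axis_col: str, min_gene_reads: int) -> pd.DataFrame:
    """Long frame (gene_id, isoform_id, level, pi, gene_reads) for one axis.

    Levels qualify per gene when the pooled gene read count reaches
    ``min_gene_reads``; isoforms unseen at a qualifying level get Π = 0.
    """
    counts = (
        df.groupby(["gene_id", axis_col, "isoform_id"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    gene_level = counts.groupby(["gene_id", axis_col])["n"].sum().rename("gene_reads")
    counts = counts.join(gene_level, on=["gene_id", axis_col])
    counts = counts[counts["gene_reads"] >= min_gene_reads]
    gene_isoforms = {
        gid: sorted(grp.unique()) for gid, grp in df.groupby("gene_id")["isoform_id"]
    }
    rows = []
    for (gid, level), grp in counts.groupby(["gene_id", axis_col], sort=True):
        total = int(grp["gene_reads"].iloc[0])
        seen = dict(zip(grp["isoform_id"], grp["n"]))
        for iso in gene_isoforms[gid]:
            rows.append((gid, iso, level, seen.get(iso, 0) / total, total))
    return pd.DataFrame(rows, columns=["gene_id", "isoform_id", "level", "pi", "gene_reads"])


def compute_axis_pi(
    table: ReadTable,
    cell_type: str,
    axis: str,
    min_gene_reads: int = 10,
) -> list:
    """Π per isoform per level of one axis, within one cell type.

    Reads without an isoform assignment are dropped. Returns PiProfile
    objects with only the requested axis populated; merge profiles from
    several calls with :func:`merge_profiles` before computing variability.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
    df = table.to_frame()
    df = df[(df["cell_type"] == cell_type) & df["isoform_id"].notna()]
    pis = _axis_pi(df, axis, min_gene_reads)
    profiles: dict[tuple, PiProfile] = {}
    for row in pis.itertuples(index=False):
        key = (row.gene_id, row.isoform_id)
        prof = profiles.setdefault(
            key, PiProfile(gene_id=row.gene_id, isoform_id=row.isoform_id, cell_type=cell_type)
        )
        prof.pi_by_level.setdefault(axis, {})[row.level] = row.pi
        prof.counts_by_level.setdefault(axis, {})[row.level] = row.gene_reads
    return list(profiles.values())


def merge_profiles(profile_lists: list) -> list:
    """Merge per-axis PiProfile lists into one profile per (gene, isoform)."""
    merged: dict[tuple, PiProfile] = {}
    for profiles in profile_lists:
        for p in profiles:
            key = (p.gene_id, p.isoform_id, p.cell_type)
            tgt = merged.setdefault(
                key, PiProfile(gene_id=p.gene_id, isoform_id=p.isoform_id, cell_type=p.cell_type)
            )
            for axis, levels in p.pi_by_level.items():
                tgt.pi_by_level.setdefault(axis, {}).update(levels)
            for axis, levels in p.counts_by_level.items():
                tgt.counts_by_level.setdefault(axis, {}).update(levels)
    return list(merged.values())


def _dominant_level(levels: dict) -> str:
    med = float(np.median(list(levels.values())))
    # highest divergence from the median Π; ties -> lexicographically smallest
    return min(levels, key=lambda lv: (-abs(levels[lv] - med), lv))


def compute_triaxial_variability(profiles: list, axes: tuple = AXES) -> list:
    """Raw per-axis variability (max Π - min Π) for each isoform.

    An axis is defined only when the isoform's gene qualifies at >= 2
    levels of that axis; otherwise the raw value is None.
    """
    out = []
    for p in profiles:
        v = TriAxialVariability(gene_id=p.gene_id, isoform_id=p.isoform_id, cell_type=p.cell_type)
        for axis in axes:
            levels = p.pi_by_level.get(axis, {})
            if len(levels) >= 2:
                vals = list(levels.values())
                v.raw[axis] = max(vals) - min(vals)
                v.dominant_level[axis] = _dominant_level(levels)
            else:
                v.raw[axis] = None
        out.append(v)
    return out


def assign_triangle(v: TriAxialVariability, gate: float = 0.1) -> TriAxialVariability:
    """Normalize the raw triple and place the isoform in the ternary diagram.

    Unplaced if any axis is undefined or max(raw) < gate. A vertex requires
    a normalized value strictly greater than 0.5; an exact 0.5 goes to the
    center, so the assignment partitions placed isoforms.
    """
    axes = list(v.raw)
    if any(v.raw[a] is None for a in axes) or not axes:
        v.triangle = "unplaced"
        v.normalized = None
        return v
    vals = {a: float(v.raw[a]) for a in axes}
    if max(vals.values()) < gate:
        v.triangle = "unplaced"
        v.normalized = None
        return v
    total = sum(vals.values())
    assert total > 0, "gate passed but raw variabilities sum to zero"
    v.normalized = {a: vals[a] / total for a in axes}
    over = [a for a in axes if v.normalized[a] > 0.5]
    v.triangle = over[0] if over else "center"
    return v


def identify_highly_variable_isoforms(vs: list, threshold: float = 0.25) -> list:
    """Flag highly variable isoforms.

    Vertex-triangle isoforms qualify with raw variability >= threshold on
    any axis; center-triangle isoforms only if all three raw values reach
    the threshold (their variability is spread, so one large axis is not
    enough evidence).
    """
    flagged = []
    for v in vs:
        if v.triangle == "unplaced":
            continue
        raws = [r for r in v.raw.values() if r is not None]
        if v.triangle == "center":
            if raws and all(r >= threshold for r in raws):
                flagged.append(v)
        elif any(r >= threshold for r in raws):
            flagged.append(v)
    return flagged


def summarize_gene_triangle_span(vs: list) -> pd.DataFrame:
    """Distinct triangle labels per (gene, cell type), with a per-gene
    roll-up across cell types.

    Returns a frame with one row per (gene_id, cell_type): ``span`` is the
    number of distinct triangles among placed isoforms, ``triangles`` the
    sorted labels; per-gene columns ``max_span`` (max over cell types) and
    ``differs_between_cell_types`` (True when two cell types show different
    triangle-label sets).
    """
    per: dict[tuple, set] = {}
    for v in vs:
        if v.triangle == "unplaced":
            continue
        per.setdefault((v.gene_id, v.cell_type), set()).add(v.triangle)
    rows = [
        (g, ct, len(tri), ",".join(sorted(tri)))
        for (g, ct), tri in sorted(per.items())
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "cell_type", "span", "triangles"])
    if df.empty:
        df["max_span"] = pd.Series(dtype=int)
        df["differs_between_cell_types"] = pd.Series(dtype=bool)
        return df
    roll = df.groupby("gene_id").agg(
        max_span=("span", "max"),
        differs_between_cell_types=("triangles", lambda s: s.nunique() > 1),
    )
    return df.join(roll, on="gene_id")


def compute_cell_type_variability(
    table: ReadTable,
    cell_type: str,
    min_gene_reads: int = 10,
    gate: float = 0.1,
) -> list:
    """Full per-cell-type pipeline: Π on all three axes, variability and
    triangle assignment."""
    profiles = merge_profiles(
        [compute_axis_pi(table, cell_type, axis, min_gene_reads) for axis in AXES]
    )
    vs = compute_triaxial_variability(profiles, axes=AXES)
    return [assign_triangle(v, gate=gate) for v in vs]


def compute_pseudobulk_variability(
    table: ReadTable,
    min_gene_reads: int = 10,
    gate: float = 0.1,
) -> list:
    """Pseudo-bulk variant: the subtype axis is replaced by the cell-type
    axis and Π pools over all cells, not a single cell type."""
    df = table.to_frame()
    df = df[df["isoform_id"].notna()]
    profile_map: dict[tuple, PiProfile] = {}
    for axis in PSEUDOBULK_AXES:
        pis = _axis_pi(df, axis, min_gene_reads)
        for row in pis.itertuples(index=False):
            key = (row.gene_id, row.isoform_id)
            prof = profile_map.setdefault(
                key, PiProfile(gene_id=row.gene_id, isoform_id=row.isoform_id, cell_type="pseudobulk")
            )
            prof.pi_by_level.setdefault(axis, {})[row.level] = row.pi
            prof.counts_by_level.setdefault(axis, {})[row.level] = row.gene_reads
    vs = compute_triaxial_variability(list(profile_map.values()), axes=PSEUDOBULK_AXES)
    return [assign_triangle(v, gate=gate) for v in vs]


def ternary_coordinates(v: TriAxialVariability) -> tuple | None:
    """Barycentric (x, y) for plotting the normalized triple; None if unplaced."""
    if v.normalized is None:
        return None
    a, b, c = (v.normalized[axis] for axis in list(v.normalized))
    return (0.5 * (2 * b + c) / (a + b + c), (math.sqrt(3) / 2) * c / (a + b + c))


def variability_frame(vs: list) -> pd.DataFrame:
    """Tabular export of variability results (one row per isoform)."""
    rows = []
    for v in vs:
        axes = list(v.raw)
        raw = {f"raw_{a}": v.raw[a] for a in axes}
        norm = {f"norm_{a}": (v.normalized or {}).get(a) for a in axes}
        dom = {f"dominant_{a}": v.dominant_level.get(a) for a in axes}
        rows.append({
            "gene_id": v.gene_id, "isoform_id": v.isoform_id, "cell_type": v.cell_type,
            **raw, **norm, "triangle": v.triangle, **dom,
        })
    return pd.DataFrame(rows)
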