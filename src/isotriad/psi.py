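"""Exon percent-spliced-in (Ψ) from full-length and truncated long reads.

For each internal exon and each read of the same gene, the read is placed
in exactly one support category:

* ``in``      — a read block matches the exon exactly and both flanking
                splice junctions are present (X_in);
* ``out``     — a single read gap fully contains the exon, with the
                aligned blocks flanking that gap each spanning at least
                ``flank`` bases (X_out);
* ``acc_in``  — the junction into the exon's acceptor (strand-aware 3'
                splice site) is present and the read terminates within the
                exon (X_acc_in), as produced by 3'-truncated molecules;
* ``don_in``  — symmetric for the donor (X_don_in);
* ``ambiguous`` — the read's aligned span overlaps the exon but matches no
                category (counts toward X_tot only);
* ``none``    — no span overlap.

X_tot counts all gene reads whose aligned span overlaps the exon. From the
grouped counts,

    Ψ_overall  = (X_in + X_acc_in + X_don_in) / (X_in + X_acc_in + X_don_in + X_out)
    Ψ_acceptor = (X_in + X_acc_in) / (X_in + X_acc_in + X_out)
    Ψ_donor    = (X_in + X_don_in) / (X_in + X_don_in + X_out)

and Ψ_overall is reported for a group only when X_tot >= 10 there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StudyDesign
from .model import Annotation, GenomicInterval, ReadRecord, ReadTable, CLUSTER_COLUMNS

COUNT_COLUMNS = ["x_in", "x_out", "x_acc_in", "x_don_in", "x_tot"]
_LABEL_TO_COL = {"in": "x_in", "out": "x_out", "acc_in": "x_acc_in", "don_in": "x_don_in"}


def classify_read_exon_support(read: ReadRecord, exon: GenomicInterval, flank: int = 50) -> str:
    """Classify one read's support for one exon of its gene.

    Returns one of {"in", "out", "acc_in", "don_in", "ambiguous", "none"};
    the categories are mutually exclusive by construction.
    """
    blocks = read.blocks
    n = len(blocks)
    # full support: exact block match with junctions on both sides
    for i in range(1, n - 1):
        if blocks[i][0] == exon.start and blocks[i][1] == exon.end:
            return "in"
    # skipping: one gap contains the exon; both gap-flanking blocks >= flank
    for i in range(n - 1):
        gap_s, gap_e = blocks[i][1], blocks[i + 1][0]
        if gap_s <= exon.start and gap_e >= exon.end:
            left = blocks[i][1] - blocks[i][0]
            right = blocks[i + 1][1] - blocks[i + 1][0]
            if left >= flank and right >= flank:
                return "out"
            break  # the exon sits in this gap; short flanks -> ambiguous
    # truncated reads ending on the exon with one junction present
    if n > 1:
        s, e = blocks[-1]  # genomic-last block: junction on its left
        if s == exon.start and s < e <= exon.end:
            return "acc_in" if read.strand == "+" else "don_in"
        s, e = blocks[0]  # genomic-first block: junction on its right
        if e == exon.end and exon.start <= s < e:
            return "don_in" if read.strand == "+" else "acc_in"
    span_s, span_e = read.span
    if span_s < exon.end and exon.start < span_e:
        return "ambiguous"
    return "none"


def candidate_exons(table: ReadTable, annotation: Annotation) -> dict:
    """Candidate exon universe per gene: exons appearing as internal blocks
    in reads, united with annotated internal exons."""
    out: dict[str, set] = {}
    for gid, gene in annotation.genes.items():
        out[gid] = set(annotation.internal_exons(gid))
    for r in table.records:
        target = out.setdefault(r.gene_id, set())
        for s, e in r.blocks[1:-1]:
            target.add(GenomicInterval(r.chrom, s, e, r.strand))
    return {g: sorted(exons) for g, exons in out.items() if exons}


def count_exon_support(
    table: ReadTable,
    exons: dict,
    group_by: tuple = (),
    flank: int = 50,
) -> pd.DataFrame:
    """Tally the five X counts per (exon, group).

    Parameters
    ----------
    exons
        Mapping gene_id -> iterable of candidate GenomicIntervals.
    group_by
        Cluster attribute names to aggregate over (subset of
        ``("region", "age", "replicate", "broad", "cell_type", "subtype")``);
        empty for pseudo-bulk.

    Returns a sparse long-format frame (groups with no overlapping read for
    an exon are absent) with columns gene_id, exon_start, exon_end, the
    group columns, and the five X counts.
    """
    for key in group_by:
        if key not in CLUSTER_COLUMNS:
            raise KeyError(f"unknown grouping key {key!r}")
    acc: dict[tuple, np.ndarray] = {}
    by_gene = table.by_gene()
    for gid, gene_exons in exons.items():
        reads = by_gene.get(gid, [])
        for read in reads:
            gkey = tuple(getattr(read.cluster, k) for k in group_by)
            span_s, span_e = read.span
            for exon in gene_exons:
                if exon.start >= span_e or exon.end <= span_s:
                    continue  # no span overlap -> "none"
                label = classify_read_exon_support(read, exon, flank=flank)
                if label == "none":
                    continue
                row = acc.setdefault(
                    (gid, exon.start, exon.end) + gkey, np.zeros(5, dtype=np.int64)
                )
                row[4] += 1  # x_tot: span overlap
                col = _LABEL_TO_COL.get(label)
                if col is not None:
                    row[COUNT_COLUMNS.index(col)] += 1
    if not acc:
        return pd.DataFrame(
            columns=["gene_id", "exon_start", "exon_end", *group_by, *COUNT_COLUMNS]
        )
    keys = pd.DataFrame(
        list(acc.keys()), columns=["gene_id", "exon_start", "exon_end", *group_by]
    )
    counts = pd.DataFrame(np.vstack(list(acc.values())), columns=COUNT_COLUMNS)
    df = pd.concat([keys, counts], axis=1)
    return df.sort_values(["gene_id", "exon_start", "exon_end", *group_by]).reset_index(drop=True)


def psi_from_counts(df: pd.DataFrame, xtot_min: int = 10) -> pd.DataFrame:
    """Append psi_overall / psi_acceptor / psi_donor columns to a count frame.

    psi_overall is masked (NaN) where x_tot < xtot_min; acceptor/donor
    variants are NaN only where their denominator is zero.
    """
    out = df.copy()
    xin = df["x_in"].to_numpy(float)
    xout = df["x_out"].to_numpy(float)
    xacc = df["x_acc_in"].to_numpy(float)
    xdon = df["x_don_in"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = xin + xacc + xdon
        overall = np.where(num + xout > 0, num / (num + xout), np.nan)
        acc = np.where(xin + xacc + xout > 0, (xin + xacc) / (xin + xacc + xout), np.nan)
        don = np.where(xin + xdon + xout > 0, (xin + xdon) / (xin + xdon + xout), np.nan)
    overall = np.where(df["x_tot"].to_numpy() >= xtot_min, overall, np.nan)
    out["psi_overall"] = overall
    out["psi_acceptor"] = acc
    out["psi_donor"] = don
    return out


def compute_group_psi(counts: pd.DataFrame, xtot_min: int = 10) -> pd.DataFrame:
    """Per-group Ψ for exons that passed the keep filters (thin wrapper)."""
    return psi_from_counts(counts, xtot_min=xtot_min)


def _nonexonic_bases(exon: GenomicInterval, annotated: list) -> int:
    """Bases of `exon` lying outside every annotated exon of the gene."""
    covered = 0
    pos = exon.start
    for iv in sorted(annotated, key=lambda e: e.start):
        if iv.end <= pos or iv.start >= exon.end:
            continue
        s = max(iv.start, pos)
        e = min(iv.end, exon.end)
        if e > s:
            covered += e - s
            pos = e
    return len(exon) - covered


def filter_alternative_exons(
    counts: pd.DataFrame,
    annotation: Annotation,
    psi_window: tuple = (0.05, 0.95),
    informative_ratio: float = 0.8,
    nonannotated_exclusion: int = 70,
) -> set:
    """Select the alternative exons to carry forward, from pseudo-bulk counts.

    An exon is first *excluded* as a likely intron-retention or alternative
    acceptor/donor event if it is not an annotated exon of its gene, at
    least one of its boundaries matches an annotated splice site, and at
    least ``nonannotated_exclusion`` of its bases fall outside every
    annotated exon of the gene. A surviving exon is *kept* iff all three Ψ
    variants lie inside ``psi_window`` (inclusive) and the informative
    fraction (X_in + X_acc_in + X_don_in + X_out) / X_tot is at least
    ``informative_ratio``. Exons with an undefined Ψ variant are dropped.

    Returns a set of (gene_id, exon_start, exon_end) keys.
    """
    lo, hi = psi_window
    with_psi = psi_from_counts(counts, xtot_min=0)
    kept: set = set()
    for row in with_psi.itertuples(index=False):
        gid = row.gene_id
        gene = annotation.genes.get(gid)
        if gene is None:
            continue
        exon = GenomicInterval(gene.chrom, int(row.exon_start), int(row.exon_end), gene.strand)
        exset = annotation.exon_set(gid)
        if exon not in exset:
            sites = annotation.splice_sites(gid)
            n_annotated_boundaries = (exon.start in sites) + (exon.end in sites)
            if n_annotated_boundaries >= 1 and _nonexonic_bases(exon, list(exset)) >= nonannotated_exclusion:
                continue
        psis = (row.psi_overall, row.psi_acceptor, row.psi_donor)
        if any(pd.isna(p) for p in psis):
            continue
        if not all(lo <= p <= hi for p in psis):
            continue
        informative = row.x_in + row.x_out + row.x_acc_in + row.x_don_in
        if row.x_tot == 0 or informative / row.x_tot < informative_ratio:
            continue
        kept.add((gid, int(row.exon_start), int(row.exon_end)))
    return kept


@dataclass
class TriadPsiMatrix:
    """Exon x triad matrix of Ψ_overall with missing-value support.

    ``psi`` is indexed by exon id ("gene:start-end") with a column
    MultiIndex (age, region, cell_type) covering every triad of the design;
    ``exon_info`` maps exon id back to (gene_id, exon_start, exon_end).
    """

    psi: pd.DataFrame
    design: StudyDesign
    exon_info: pd.DataFrame


def build_triad_psi_matrix(
    table: ReadTable,
    annotation: Annotation,
    design: StudyDesign,
    cell_types: list | None = None,
    xtot_min: int = 10,
    flank: int = 50,
    psi_window: tuple = (0.05, 0.95),
    informative_ratio: float = 0.8,
    nonannotated_exclusion: int = 70,
    kept: set | None = None,
    replicate_combine: str = "sum",
) -> TriadPsiMatrix:
    """Ψ per (exon, triad), with replicate (and subtype) counts summed
    within each (age, region, cell type) triad before Ψ computation.

    Keep filters are evaluated on pseudo-bulk counts first; per-triad Ψ is
    computed only for kept exons and masked where X_tot < ``xtot_min``.
    ``replicate_combine="mean"`` switches to the alternative convention of
    computing Ψ per replicate and averaging the defined values.
    """
    if replicate_combine not in ("sum", "mean"):
        raise ValueError("replicate_combine must be 'sum' or 'mean'")
    cell_types = list(cell_types) if cell_types is not None else list(design.cell_types)
    present = set(r.cluster.cell_type for r in table.records)
    absent = [ct for ct in cell_types if ct not in present]
    if absent == cell_types:
        raise ValueError(f"requested cell types absent from data: {absent}")
    exons = candidate_exons(table, annotation)
    if kept is None:
        bulk = count_exon_support(table, exons, group_by=(), flank=flank)
        kept = filter_alternative_exons(
            bulk, annotation,
            psi_window=psi_window,
            informative_ratio=informative_ratio,
            nonannotated_exclusion=nonannotated_exclusion,
        )
    kept_exons = {}
    for gid, exs in exons.items():
        sel = [e for e in exs if (gid, e.start, e.end) in kept]
        if sel:
            kept_exons[gid] = sel
    sub = table.subset(lambda r: r.cluster.cell_type in set(cell_types))
    group = ("age", "region", "cell_type")
    if replicate_combine == "mean":
        group = group + ("replicate",)
    counts = count_exon_support(sub, kept_exons, group_by=group, flank=flank)
    triads = [t for t in design.triads() if t[2] in cell_types]
    cols = pd.MultiIndex.from_tuples(triads, names=["age", "region", "cell_type"])
    if counts.empty:
        psi = pd.DataFrame(index=pd.Index([], name="exon_id"), columns=cols, dtype=float)
        info = pd.DataFrame(columns=["gene_id", "exon_start", "exon_end"])
        return TriadPsiMatrix(psi=psi, design=design, exon_info=info)
    counts = psi_from_counts(counts, xtot_min=xtot_min)
    counts["exon_id"] = (
        counts["gene_id"] + ":" + counts["exon_start"].astype(str) + "-" + counts["exon_end"].astype(str)
    )
    psi = counts.pivot_table(
        index="exon_id", columns=["age", "region", "cell_type"],
        values="psi_overall", aggfunc="mean", dropna=False,
    )
    psi = psi.reindex(columns=cols)
    info = (
        counts[["exon_id", "gene_id", "exon_start", "exon_end"]]
        .drop_duplicates("exon_id")
        .set_index("exon_id")
    )
    return TriadPsiMatrix(psi=psi.sort_index(), design=design, exon_info=info)
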