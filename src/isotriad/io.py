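"""Readers/writers for GTF, BED site sets and the per-read table, plus UMI
deduplication.

The per-read table is the flat-file analogue of an upstream "all info per
long read" export: one row per barcoded, UMI-tagged read with its aligned
exon blocks, gene assignment and cluster labels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd

from .model import (
    Annotation,
    ClusterKey,
    Gene,
    GenomicInterval,
    ReadRecord,
    ReadTable,
    SiteSet,
    Transcript,
)

log = logging.getLogger(__name__)

READ_TABLE_COLUMNS = [
    "read_id", "barcode", "umi", "sample_id",
    "region", "age", "replicate", "broad", "cell_type", "subtype",
    "gene_id", "chrom", "strand", "block_starts", "block_ends", "isoform_id",
]


# ---------------------------------------------------------------------------
# GTF

def read_annotation_gtf(path: str | Path) -> Annotation:
    """Parse a GTF into an :class:`Annotation`.

    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention. Requires exon features with gene_id and
    transcript_id attributes; gene/transcript feature lines are optional.
    """
    path = str(path)
    try:
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"malformed GTF {path!r}: {exc}") from exc

    genes: dict[str, Gene] = {}
    tx_exons: dict[str, list] = {}
    tx_gene: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", [None])[0]
        txid = feat.attributes.get("transcript_id", [None])[0]
        if gid is None or txid is None:
            raise ValueError(
                f"GTF exon at {feat.seqid}:{feat.start} lacks gene_id/transcript_id"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        genes.setdefault(gid, Gene(gid, feat.seqid, feat.strand))
        tx_exons.setdefault(txid, []).append(iv)
        tx_gene[txid] = gid
    # declared transcripts without exons are a structural defect
    for feat in db.features_of_type("transcript"):
        txid = feat.attributes.get("transcript_id", [None])[0]
        if txid is not None and txid not in tx_exons:
            raise ValueError(f"transcript {txid} has no exon features")

    transcripts = [
        Transcript(txid, tx_gene[txid], tuple(sorted(exons, key=lambda e: e.start)))
        for txid, exons in tx_exons.items()
    ]
    return Annotation(genes.values(), transcripts)


def write_annotation_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write an :class:`Annotation` as GTF (deterministic ordering)."""
    lines = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        txs = sorted(annotation.transcripts_of(gid), key=lambda t: t.transcript_id)
        gstart = min(t.exons[0].start for t in txs)
        gend = max(t.exons[-1].end for t in txs)
        attrs = f'gene_id "{gid}";'
        lines.append(
            f"{gene.chrom}\tisotriad\tgene\t{gstart + 1}\t{gend}\t.\t{gene.strand}\t.\t{attrs}"
        )
        for tx in txs:
            tattrs = f'gene_id "{gid}"; transcript_id "{tx.transcript_id}";'
            span = tx.span
            lines.append(
                f"{gene.chrom}\tisotriad\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{tattrs}"
            )
            for e in tx.exons:
                lines.append(
                    f"{gene.chrom}\tisotriad\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED site sets

def read_site_bed(path: str | Path, kind: str) -> SiteSet:
    """Read TSS/polyA reference sites from BED3/BED6.

    Multi-base intervals are anchored at their midpoint; peaks are treated
    as points because assignment uses a point-to-point distance window.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: BED start >= end")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            anchor = (start + end) // 2
            rows.append((chrom, anchor, strand))
    if not rows:
        log.warning("empty site BED %s (kind=%s)", path, kind)
    return SiteSet(kind=kind, sites=tuple(dict.fromkeys(rows)))


def write_site_bed(sites: SiteSet, path: str | Path) -> None:
    lines = [
        f"{chrom}\t{pos}\t{pos + 1}\t{sites.kind}_{i}\t.\t{strand}"
        for i, (chrom, pos, strand) in enumerate(sorted(sites.sites))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Read table

def _parse_blocks(starts: str, ends: str, read_id: str) -> tuple:
    try:
        ss = [int(x) for x in str(starts).split(",") if x != ""]
        ee = [int(x) for x in str(ends).split(",") if x != ""]
    except ValueError as exc:
        raise ValueError(f"read {read_id}: unparseable block lists") from exc
    if len(ss) != len(ee) or not ss:
        raise ValueError(f"read {read_id}: block_starts/block_ends length mismatch")
    return tuple(zip(ss, ee))


def load_read_table(path: str | Path, annotation: Annotation) -> ReadTable:
    """Load the per-read TSV and validate against the annotation.

    Rows whose gene_id is absent from the annotation are rejected and
    counted (logged); malformed blocks raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in READ_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read table {path} missing columns: {missing}")
    records = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        if row.gene_id not in annotation:
            n_rejected += 1
            continue
        blocks = _parse_blocks(row.block_starts, row.block_ends, row.read_id)
        cluster = ClusterKey(
            region=row.region, age=row.age, replicate=row.replicate,
            broad=row.broad, cell_type=row.cell_type, subtype=row.subtype,
        )
        records.append(
            ReadRecord(
                read_id=row.read_id, barcode=row.barcode, umi=row.umi,
                cluster=cluster, gene_id=row.gene_id, chrom=row.chrom,
                strand=row.strand, blocks=blocks,
                isoform_id=None if row.isoform_id in ("", "NA") else row.isoform_id,
            )
        )
    if n_rejected:
        log.warning("%d reads rejected (unknown gene_id) loading %s", n_rejected, path)
    return ReadTable(records, source=str(path), deduplicated=False)


def write_read_table(table: ReadTable, path: str | Path) -> None:
    lines = ["\t".join(READ_TABLE_COLUMNS)]
    for r in table.records:
        c = r.cluster
        lines.append("\t".join([
            r.read_id, r.barcode, r.umi, c.sample_id,
            c.region, c.age, c.replicate, c.broad, c.cell_type, c.subtype,
            r.gene_id, r.chrom, r.strand,
            ",".join(str(s) for s, _ in r.blocks),
            ",".join(str(e) for _, e in r.blocks),
            r.isoform_id if r.isoform_id is not None else "NA",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def dedupe_umis(table: ReadTable) -> ReadTable:
    """Collapse UMI duplicates to one record per (barcode, UMI, gene).

    Reads sharing barcode+UMI within a gene are copies of one cDNA
    molecule. The retained copy is the one with the greatest total aligned
    length (the most complete observation), ties broken by smallest
    read_id. Idempotent.
    """
    best: dict[tuple, ReadRecord] = {}
    for r in table.records:
        key = (r.barcode, r.umi, r.gene_id)
        cur = best.get(key)
        if cur is None or (-r.aligned_length, r.read_id) < (-cur.aligned_length, cur.read_id):
            best[key] = r
    kept = [r for r in table.records if best[(r.barcode, r.umi, r.gene_id)] is r]
    return ReadTable(kept, source=table.source, deduplicated=True)
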