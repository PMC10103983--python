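"""Core domain types for barcoded single-cell long-read transcriptomes.

All genomic coordinates are 0-based, half-open. GTF/BED dialects are
converted at the I/O boundary (:mod:`isotriad.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


def exon_id(gene_id: str, exon: GenomicInterval) -> str:
    """Stable string identifier for an exon within a gene."""
    return f"{gene_id}:{exon.start}-{exon.end}"


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    exons: tuple  # tuple[GenomicInterval], sorted, non-overlapping

    def __post_init__(self) -> None:
        ex = self.exons
        if not ex:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} exons unsorted/overlapping"
                )

    @property
    def span(self) -> GenomicInterval:
        first = self.exons[0]
        return GenomicInterval(first.chrom, first.start, self.exons[-1].end, first.strand)

    def internal_exons(self) -> tuple:
        return self.exons[1:-1]


class Annotation:
    """Gene models: transcripts, exon sets and splice sites per gene.

    Splice sites are stored as the 0-based half-open boundary coordinates of
    annotated exons (a ``start`` is an exon's left boundary, an ``end`` its
    right boundary, irrespective of strand).
    """

    def __init__(self, genes: Iterable[Gene], transcripts: Iterable[Transcript]):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self.transcripts: dict[str, Transcript] = {}
        self._tx_by_gene: dict[str, list[str]] = {g: [] for g in self.genes}
        for tx in transcripts:
            if tx.gene_id not in self.genes:
                raise ValueError(f"transcript {tx.transcript_id} references unknown gene {tx.gene_id}")
            self.transcripts[tx.transcript_id] = tx
            self._tx_by_gene[tx.gene_id].append(tx.transcript_id)
        self._exon_set: dict[str, set] = {}
        self._internal: dict[str, set] = {}
        self._sites: dict[str, set] = {}
        for gid, txids in self._tx_by_gene.items():
            exons: set = set()
            internal: set = set()
            sites: set = set()
            for txid in txids:
                tx = self.transcripts[txid]
                for e in tx.exons:
                    exons.add(e)
                    sites.add(e.start)
                    sites.add(e.end)
                internal.update(tx.internal_exons())
            self._exon_set[gid] = exons
            self._internal[gid] = internal
            self._sites[gid] = sites

    def transcripts_of(self, gene_id: str) -> list:
        return [self.transcripts[t] for t in self._tx_by_gene[gene_id]]

    def exon_set(self, gene_id: str) -> set:
        return self._exon_set[gene_id]

    def internal_exons(self, gene_id: str) -> set:
        return self._internal[gene_id]

    def splice_sites(self, gene_id: str) -> set:
        return self._sites[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


@dataclass(frozen=True)
class SiteSet:
    """Anchored single-base reference sites (CAGE/TSS peaks or polyA sites)."""

    kind: str  # "tss" | "polya"
    sites: tuple  # tuple[(chrom, position, strand)]

    def __post_init__(self) -> None:
        if self.kind not in ("tss", "polya"):
            raise ValueError(f"kind must be 'tss' or 'polya', got {self.kind!r}")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate sites in SiteSet")


@dataclass(frozen=True, order=True)
class ClusterKey:
    """Cell-cluster label: where a barcode sits in the study design.

    (region, age, replicate) identifies a sample; the cell hierarchy is
    broad class -> cell type -> subtype.
    """

    region: str
    age: str
    replicate: str
    broad: str
    cell_type: str
    subtype: str

    @property
    def sample_id(self) -> str:
        return f"{self.region}_{self.age}_{self.replicate}"

    @property
    def cluster_id(self) -> str:
        return f"{self.sample_id}.{self.subtype}"


@dataclass(frozen=True)
class ReadRecord:
    """One barcoded, UMI-tagged long read with its aligned exon blocks."""

    read_id: str
    barcode: str
    umi: str
    cluster: ClusterKey
    gene_id: str
    chrom: str
    strand: str
    blocks: tuple  # tuple[(start, end)], sorted, non-overlapping
    isoform_id: str | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id} has no aligned blocks")
        prev_end = None
        for s, e in self.blocks:
            if s >= e:
                raise ValueError(f"read {self.read_id}: empty block [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"read {self.read_id}: blocks unsorted or overlapping")
            prev_end = e

    @property
    def span(self) -> tuple:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' terminal base."""
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1] - 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the read's 3' terminal base."""
        return self.blocks[-1][1] - 1 if self.strand == "+" else self.blocks[0][0]


CLUSTER_COLUMNS = ("region", "age", "replicate", "broad", "cell_type", "subtype")


@dataclass
class ReadTable:
    """A collection of reads plus provenance/deduplication state."""

    records: list
    source: str = "<memory>"
    deduplicated: bool = False
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Label-level view (no blocks), one row per read; cached."""
        if self._frame is None or len(self._frame) != len(self.records):
            rows = [
                (
                    r.read_id, r.barcode, r.umi,
                    r.cluster.region, r.cluster.age, r.cluster.replicate,
                    r.cluster.broad, r.cluster.cell_type, r.cluster.subtype,
                    r.gene_id, r.chrom, r.strand, r.isoform_id,
                )
                for r in self.records
            ]
            self._frame = pd.DataFrame(
                rows,
                columns=["read_id", "barcode", "umi", *CLUSTER_COLUMNS,
                         "gene_id", "chrom", "strand", "isoform_id"],
            )
        return self._frame

    def by_gene(self) -> Mapping[str, list]:
        out: dict[str, list] = {}
        for r in self.records:
            out.setdefault(r.gene_id, []).append(r)
        return out

    def subset(self, predicate) -> "ReadTable":
        return ReadTable(
            [r for r in self.records if predicate(r)],
            source=self.source,
            deduplicated=self.deduplicated,
        )
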