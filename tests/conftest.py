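"""Shared fixtures: small study designs and simulated datasets.

All fixtures are generated programmatically at test time; simulation
sizes are kept small enough for the whole suite to run in minutes.
"""

from __future__ import annotations

import pytest

import isotriad as it
from isotriad.model import ClusterKey, ReadRecord, ReadTable


@pytest.fixture(scope="session")
def paper_design():
    """The reference study grid at reduced per-cluster depth."""
    return it.default_design(cells_per_cluster=5, reads_per_cell=10)


@pytest.fixture(scope="session")
def sim_dataset(paper_design):
    """A deduplicated simulated dataset with default (no-effect) settings."""
    ann, tss, polya = it.build_synthetic_annotation(
        5, isoforms_per_gene=(2, 4), seed=11
    )
    table, truth = it.simulate_study(paper_design, it.EffectSpec(), ann, seed=11)
    return {
        "annotation": ann, "tss": tss, "polya": polya,
        "raw": table, "table": it.dedupe_umis(table), "truth": truth,
        "design": paper_design,
    }


def make_cluster(region="HIPP", age="P14", replicate="rep1", broad="Glia",
                 cell_type="Astro", subtype="AstroFib") -> ClusterKey:
    return ClusterKey(region=region, age=age, replicate=replicate,
                      broad=broad, cell_type=cell_type, subtype=subtype)


def make_read(read_id, blocks, strand="+", gene_id="g1", chrom="chr1",
              barcode="ACGT" * 4, umi="ACGTACGTACGT", isoform_id=None,
              cluster=None) -> ReadRecord:
    return ReadRecord(
        read_id=read_id, barcode=barcode, umi=umi,
        cluster=cluster or make_cluster(), gene_id=gene_id, chrom=chrom,
        strand=strand, blocks=tuple(blocks), isoform_id=isoform_id,
    )


def make_table(reads, deduplicated=False) -> ReadTable:
    return ReadTable(list(reads), deduplicated=deduplicated)
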