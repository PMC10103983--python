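"""Synthetic-data generator with ground truth.

Generates a gene annotation, TSS/polyA site sets and a per-read table
that emulate a barcoded single-cell long-read experiment over the study
grid: cluster-level isoform proportions with planted axis effects,
per-triad exon inclusion targets, exon-pair coordination with a target
odds ratio, 5'/3' read truncation (so truncated reads genuinely end on an
exon with one junction intact) and UMI duplication. Every planted
parameter is recorded in a truth object so downstream modules can be
checked for recovery. All outputs are deterministic given the seed.

The generator models structure, not sequence: reads are exon-block chains
sampled from isoform models, with multinomial sampling as the only noise
source. There is no base-level error model (splice sites arrive
pre-corrected upstream of this pipeline).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign
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

_BASES = np.array(list("ACGT"))
BARCODE_LENGTH = 16
UMI_LENGTH = 12


# ---------------------------------------------------------------------------
# Effect specification

@dataclass(frozen=True)
class IsoformSwitch:
    """Shift ΔΠ of usage mass between two isoforms of a gene for clusters
    whose ``axis`` (age/region/subtype) value is in ``levels``."""

    gene_id: str
    axis: str
    levels: tuple
    delta_pi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_pi <= 1.0:
            raise ValueError("delta_pi must be in (0, 1]")
        if self.axis not in ("age", "region", "subtype"):
            raise ValueError(f"unknown axis {self.axis!r}")


@dataclass(frozen=True)
class ExonEffect:
    """Pin the inclusion Ψ of one exon to given values per triad.

    ``psi_by_triad`` maps (age, region, cell_type) -> Ψ; ``default_psi``
    (if set) applies to every other triad.
    """

    gene_id: str
    exon: tuple  # (start, end)
    psi_by_triad: tuple = ()  # ((triad, psi), ...) for hashability
    default_psi: float | None = None

    def target_for(self, triad: tuple) -> float | None:
        for t, p in self.psi_by_triad:
            if t == triad:
                return p
        return self.default_psi


@dataclass(frozen=True)
class CoordinationEffect:
    """Couple the inclusion of two exons of one gene to a target odds
    ratio, with the given marginal inclusion probabilities."""

    gene_id: str
    exon_a: tuple
    exon_b: tuple
    odds_ratio: float
    p_a: float = 0.5
    p_b: float = 0.5

    def __post_init__(self) -> None:
        if self.odds_ratio < 1.0:
            raise ValueError(
                "target odds ratio must be >= 1; plant the reciprocal by swapping labels"
            )


@dataclass
class EffectSpec:
    isoform_switches: list = field(default_factory=list)
    exon_effects: list = field(default_factory=list)
    coordination_effects: list = field(default_factory=list)
    truncation_5: float = 0.25  # probability a molecule loses its 5'-terminal junction
    truncation_3: float = 0.25  # likewise for the 3' end
    umi_duplication_rate: float = 0.2

    def __post_init__(self) -> None:
        for p in (self.truncation_5, self.truncation_3, self.umi_duplication_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities")


@dataclass
class SimTruth:
    """Realized generator parameters, keyed to match downstream outputs."""

    pi: pd.DataFrame  # gene_id, cluster_id, isoform_id, pi
    exon_psi: pd.DataFrame  # gene_id, exon_start, exon_end, age, region, cell_type, psi
    coordination: pd.DataFrame  # gene_id, exons, odds_ratio, joint probs
    n_molecules: int = 0


# ---------------------------------------------------------------------------
# Annotation generation

def build_synthetic_annotation(
    n_genes: int,
    exons_per_gene: tuple = (6, 9),
    isoforms_per_gene: tuple = (2, 4),
    seed: int = 0,
    chrom: str = "chrS",
    exon_length: tuple = (100, 300),
    intron_length: tuple = (300, 1500),
    gene_spacing: int = 10000,
    alt_tss_fraction: float = 0.5,
    alt_polya_fraction: float = 0.5,
    end_offset: int = 60,
):
    """Generate gene models with alternative internal exons and ends.

    Every gene gets >= 2 isoforms that differ by at least one internal
    exon: a set of internal exons is marked alternative and each isoform
    is a distinct inclusion pattern over them (the full-inclusion pattern
    is always present, so combination-complete genes exist when
    ``isoforms_per_gene`` allows 2^n_alt isoforms). With the stated
    fractions a gene additionally carries a second TSS and/or polyA
    anchor, realized by trimming the outer boundary of the terminal exon
    by ``end_offset`` bases in some isoforms. Returns
    (Annotation, tss SiteSet, polya SiteSet); deterministic given seed.
    """
    if n_genes < 1 or exons_per_gene[0] < 3:
        raise ValueError("need >= 1 gene and >= 3 exons per gene")
    if isoforms_per_gene[0] < 2:
        raise ValueError("every gene needs >= 2 isoforms")
    rng = np.random.default_rng(seed)
    genes, transcripts = [], []
    tss_sites, polya_sites = [], []
    cursor = 1000
    for gi in range(n_genes):
        gid = f"g{gi + 1:04d}"
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        n_iso = int(rng.integers(isoforms_per_gene[0], isoforms_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        n_internal = n_ex - 2
        n_alt = min(n_internal, max(1, math.ceil(math.log2(n_iso))))
        if n_iso > 2 ** n_alt:
            raise ValueError(
                f"gene {gid}: {n_iso} isoforms need more alternative exons than "
                f"available ({n_alt} of {n_internal} internal)"
            )
        # exon scaffold
        starts, ends = [], []
        pos = cursor
        for _ in range(n_ex):
            length = int(rng.integers(exon_length[0], exon_length[1] + 1))
            starts.append(pos)
            ends.append(pos + length)
            pos += length + int(rng.integers(intron_length[0], intron_length[1] + 1))
        cursor = pos + gene_spacing
        alt_idx = sorted(rng.choice(np.arange(1, n_ex - 1), size=n_alt, replace=False).tolist())
        all_patterns = list(itertools.product((1, 0), repeat=n_alt))
        if n_iso == len(all_patterns):
            patterns = all_patterns
        else:
            rest = all_patterns[1:]
            pick = rng.choice(len(rest), size=n_iso - 1, replace=False)
            patterns = [all_patterns[0]] + [rest[i] for i in sorted(pick)]
        # alternative ends
        n_starts = 2 if rng.random() < alt_tss_fraction else 1
        n_ends = 2 if rng.random() < alt_polya_fraction else 1
        genes.append(Gene(gid, chrom, strand))
        gene_tss, gene_polya = set(), set()
        for ti, pattern in enumerate(patterns):
            txid = f"{gid}.t{ti + 1}"
            keep = [True] * n_ex
            for ai, inc in zip(alt_idx, pattern):
                keep[ai] = bool(inc)
            exs = [(starts[i], ends[i]) for i in range(n_ex) if keep[i]]
            # trim outer boundary of terminal exons for alternative ends
            use_alt_start = n_starts == 2 and ti % 2 == 1
            use_alt_end = n_ends == 2 and (ti // 2) % 2 == 1
            five_left = strand == "+"  # 5'-terminal exon is genomically first on +
            if use_alt_start:
                if five_left:
                    s, e = exs[0]
                    exs[0] = (s + end_offset, e)
                else:
                    s, e = exs[-1]
                    exs[-1] = (s, e - end_offset)
            if use_alt_end:
                if five_left:
                    s, e = exs[-1]
                    exs[-1] = (s, e - end_offset)
                else:
                    s, e = exs[0]
                    exs[0] = (s + end_offset, e)
            ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exs)
            transcripts.append(Transcript(txid, gid, ivs))
            five = exs[0][0] if strand == "+" else exs[-1][1] - 1
            three = exs[-1][1] - 1 if strand == "+" else exs[0][0]
            gene_tss.add((chrom, five, strand))
            gene_polya.add((chrom, three, strand))
        tss_sites.extend(sorted(gene_tss))
        polya_sites.extend(sorted(gene_polya))
    annotation = Annotation(genes, transcripts)
    return (
        annotation,
        SiteSet("tss", tuple(dict.fromkeys(tss_sites))),
        SiteSet("polya", tuple(dict.fromkeys(polya_sites))),
    )


# ---------------------------------------------------------------------------
# Study simulation

def joint_inclusion_probs(p_a: float, p_b: float, odds_ratio: float) -> tuple:
    """(p11, p10, p01, p00) with the given marginals and odds ratio
    (Plackett construction)."""
    if odds_ratio == 1.0:
        p11 = p_a * p_b
    else:
        s = 1.0 + (p_a + p_b) * (odds_ratio - 1.0)
        disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_a * p_b
        p11 = (s - math.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    p10, p01 = p_a - p11, p_b - p11
    p00 = 1.0 - p_a - p_b + p11
    probs = (p11, p10, p01, p00)
    if any(p < -1e-12 for p in probs):
        raise ValueError("infeasible marginals/odds ratio combination")
    return tuple(max(p, 0.0) for p in probs)


def _isoform_inclusion(tx: Transcript, exon: tuple) -> bool:
    return any(e.start == exon[0] and e.end == exon[1] for e in tx.exons)


def _random_tags(rng: np.random.Generator, n: int, length: int) -> list:
    idx = rng.integers(0, 4, size=(n, length))
    return ["".join(row) for row in _BASES[idx]]


def _truncate_blocks(blocks: tuple, strand: str, rng: np.random.Generator,
                     do5: bool, do3: bool) -> tuple:
    """Clip whole terminal exons (1-2) plus a uniform partial overhang into
    the newly terminal exon, per flagged end; >= 1 block always remains."""
    b = list(blocks)
    for which, flag in (("5", do5), ("3", do3)):
        if not flag or len(b) < 2:
            continue
        left_side = (strand == "+") == (which == "5")
        k = int(rng.integers(1, min(2, len(b) - 1) + 1))
        if left_side:
            b = b[k:]
            s, e = b[0]
            over = int(rng.integers(0, e - s))
            b[0] = (s + over, e)
        else:
            b = b[:-k]
            s, e = b[-1]
            over = int(rng.integers(0, e - s))
            b[-1] = (s, e - over)
    return tuple(b)


def _cluster_pi(
    gene_id: str,
    isoforms: list,
    base_pi: np.ndarray,
    cluster: ClusterKey,
    effects: EffectSpec,
) -> np.ndarray:
    pi = base_pi.copy()
    iso_ids = [t.transcript_id for t in isoforms]
    for sw in effects.isoform_switches:
        if sw.gene_id != gene_id:
            continue
        value = getattr(cluster, sw.axis)
        if value in sw.levels:
            donor = int(np.argmax(base_pi))
            recipient = int(np.argmin(base_pi))
            if pi[donor] < sw.delta_pi:
                raise ValueError(
                    f"switch on {gene_id}: donor isoform lacks {sw.delta_pi} usage mass"
                )
            pi[donor] -= sw.delta_pi
            pi[recipient] += sw.delta_pi
    triad = (cluster.age, cluster.region, cluster.cell_type)
    for ee in effects.exon_effects:
        if ee.gene_id != gene_id:
            continue
        target = ee.target_for(triad)
        if target is None:
            continue
        inc = np.array([_isoform_inclusion(t, ee.exon) for t in isoforms])
        if not inc.any() or inc.all():
            raise ValueError(
                f"exon effect on {gene_id}:{ee.exon} needs both including and "
                "skipping isoforms"
            )
        m_in = pi[inc].sum()
        m_out = pi[~inc].sum()
        pi[inc] = pi[inc] / m_in * target if m_in > 0 else target / inc.sum()
        pi[~inc] = pi[~inc] / m_out * (1 - target) if m_out > 0 else (1 - target) / (~inc).sum()
    total = pi.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        pi = pi / total
    return pi


def simulate_study(
    design: StudyDesign,
    effects: EffectSpec,
    annotation: Annotation,
    seed: int = 0,
    gene_weights: dict | None = None,
) -> tuple:
    """Sample a per-read table from the design grid and effect spec.

    Per cluster, the number of molecules is Poisson with mean
    cells_per_cluster x reads_per_cell, molecules are assigned to cells
    uniformly, genes are drawn by weight (uniform by default), and the
    isoform of each molecule follows the cluster-level Π (or, for
    coordination genes, the coupled joint inclusion distribution of the
    two target exons). Truncation and UMI duplication are applied last;
    duplicates re-truncate independently from the full isoform so copies
    differ in aligned length. Returns (ReadTable, SimTruth); the table is
    NOT deduplicated.
    """
    for ee in effects.exon_effects:
        if ee.gene_id not in annotation:
            raise ValueError(f"exon effect references unknown gene {ee.gene_id}")
    for ce in effects.coordination_effects:
        if ce.gene_id not in annotation:
            raise ValueError(f"coordination effect references unknown gene {ce.gene_id}")
    rng = np.random.default_rng(seed)
    gene_ids = sorted(annotation.genes)
    weights = np.array([
        (gene_weights or {}).get(g, 1.0) for g in gene_ids
    ], dtype=float)
    weights = weights / weights.sum()
    isoforms = {
        g: sorted(annotation.transcripts_of(g), key=lambda t: t.transcript_id)
        for g in gene_ids
    }
    base_pi = {
        g: rng.dirichlet(np.full(len(isoforms[g]), 2.0)) for g in gene_ids
    }
    coord_by_gene = {ce.gene_id: ce for ce in effects.coordination_effects}
    coord_truth_rows = []
    for ce in effects.coordination_effects:
        p11, p10, p01, p00 = joint_inclusion_probs(ce.p_a, ce.p_b, ce.odds_ratio)
        combos = {}
        for combo in ((1, 1), (1, 0), (0, 1), (0, 0)):
            members = [
                i for i, t in enumerate(isoforms[ce.gene_id])
                if (_isoform_inclusion(t, ce.exon_a), _isoform_inclusion(t, ce.exon_b))
                == (bool(combo[0]), bool(combo[1]))
            ]
            if not members:
                raise ValueError(
                    f"coordination on {ce.gene_id} needs an isoform for inclusion "
                    f"combo {combo}; regenerate the gene with combination-complete isoforms"
                )
            combos[combo] = members
        coord_truth_rows.append({
            "gene_id": ce.gene_id,
            "exon_a": f"{ce.exon_a[0]}-{ce.exon_a[1]}",
            "exon_b": f"{ce.exon_b[0]}-{ce.exon_b[1]}",
            "odds_ratio": ce.odds_ratio,
            "p11": p11, "p10": p10, "p01": p01, "p00": p00,
        })
        coord_by_gene[ce.gene_id] = (ce, (p11, p10, p01, p00), combos)

    clusters = design.clusters()
    used_barcodes: set = set()
    used_keys: set = set()
    records: list[ReadRecord] = []
    pi_rows = []
    read_counter = itertools.count(1)

    def fresh_tags(n, length, taken, extra_key=None):
        out = []
        while len(out) < n:
            for tag in _random_tags(rng, n - len(out), length):
                key = tag if extra_key is None else (extra_key, tag)
                if key in taken:
                    continue
                taken.add(key)
                out.append(tag)
        return out

    for cluster in clusters:
        n_cells = design.cells_per_cluster
        n_mol = int(rng.poisson(n_cells * design.reads_per_cell))
        if n_mol == 0:
            log.warning("cluster %s drew no molecules; skipped", cluster.cluster_id)
            continue
        barcodes = fresh_tags(n_cells, BARCODE_LENGTH, used_barcodes)
        cluster_pis = {}
        for g in gene_ids:
            pi = _cluster_pi(g, isoforms[g], base_pi[g], cluster, effects)
            cluster_pis[g] = pi
            for iso, p in zip(isoforms[g], pi):
                pi_rows.append((g, cluster.cluster_id, iso.transcript_id, p))
        gene_draws = rng.choice(len(gene_ids), size=n_mol, p=weights)
        cell_draws = rng.integers(0, n_cells, size=n_mol)
        order = np.argsort(gene_draws, kind="stable")
        for gi in np.unique(gene_draws):
            g = gene_ids[gi]
            sel = order[gene_draws[order] == gi]
            n_g = len(sel)
            if g in coord_by_gene and isinstance(coord_by_gene[g], tuple):
                ce, probs, combos = coord_by_gene[g]
                combo_list = ((1, 1), (1, 0), (0, 1), (0, 0))
                combo_draws = rng.choice(4, size=n_g, p=probs)
                iso_draws = np.empty(n_g, dtype=int)
                pi = cluster_pis[g]
                for ci, combo in enumerate(combo_list):
                    mask = combo_draws == ci
                    if not mask.any():
                        continue
                    members = combos[combo]
                    w = pi[members]
                    w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1 / len(members))
                    iso_draws[mask] = rng.choice(members, size=int(mask.sum()), p=w)
            else:
                iso_draws = rng.choice(len(isoforms[g]), size=n_g, p=cluster_pis[g])
            gene = annotation.genes[g]
            for mi, ii in zip(sel, iso_draws):
                tx = isoforms[g][ii]
                barcode = barcodes[cell_draws[mi]]
                umi = fresh_tags(1, UMI_LENGTH, used_keys, extra_key=(barcode, g))[0]
                full_blocks = tuple((e.start, e.end) for e in tx.exons)
                do5 = rng.random() < effects.truncation_5
                do3 = rng.random() < effects.truncation_3
                blocks = _truncate_blocks(full_blocks, gene.strand, rng, do5, do3)
                records.append(ReadRecord(
                    read_id=f"r{next(read_counter):08d}",
                    barcode=barcode, umi=umi, cluster=cluster,
                    gene_id=g, chrom=gene.chrom, strand=gene.strand,
                    blocks=blocks, isoform_id=tx.transcript_id,
                ))
    n_molecules = len(records)
    # UMI duplicates: independent re-truncation from the full isoform
    duplicates = []
    dup_flags = rng.random(n_molecules) < effects.umi_duplication_rate
    for r, flag in zip(list(records), dup_flags):
        if not flag:
            continue
        tx = annotation.transcripts[r.isoform_id]
        full_blocks = tuple((e.start, e.end) for e in tx.exons)
        do5 = rng.random() < effects.truncation_5
        do3 = rng.random() < effects.truncation_3
        blocks = _truncate_blocks(full_blocks, r.strand, rng, do5, do3)
        duplicates.append(ReadRecord(
            read_id=f"r{next(read_counter):08d}",
            barcode=r.barcode, umi=r.umi, cluster=r.cluster,
            gene_id=r.gene_id, chrom=r.chrom, strand=r.strand,
            blocks=blocks, isoform_id=r.isoform_id,
        ))
    records.extend(duplicates)

    exon_rows = []
    for ee in effects.exon_effects:
        for triad in design.triads():
            target = ee.target_for(triad)
            if target is not None:
                exon_rows.append((
                    ee.gene_id, ee.exon[0], ee.exon[1],
                    triad[0], triad[1], triad[2], target,
                ))
    truth = SimTruth(
        pi=pd.DataFrame(pi_rows, columns=["gene_id", "cluster_id", "isoform_id", "pi"]),
        exon_psi=pd.DataFrame(
            exon_rows,
            columns=["gene_id", "exon_start", "exon_end", "age", "region", "cell_type", "psi"],
        ),
        coordination=pd.DataFrame(
            coord_truth_rows,
            columns=["gene_id", "exon_a", "exon_b", "odds_ratio", "p11", "p10", "p01", "p00"],
        ),
        n_molecules=n_molecules,
    )
    return ReadTable(records, source=f"simulate_study(seed={seed})"), truth
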