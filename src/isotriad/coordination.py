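"""Exon-pair coordination: co-inclusion counting and the χ²/odds-ratio
association test.

For an exon pair of one gene, every read with a definitive in/out status
for both exons contributes to a 2x2 matrix (in-in, in-out, out-in,
out-out). Association is tested with Pearson's χ²; the odds ratio is
(in-in * out-out) / (in-out * out-in) with zero cells replaced by 0.5, and
the effect size is |log10(odds ratio)|. The co-inclusion score is
in-in / total. Pairs are tested at cell-type or pseudo-bulk level; BH
correction is applied over all tested pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .model import GenomicInterval, ReadTable, CLUSTER_COLUMNS
from .psi import classify_read_exon_support


@dataclass
class PairCounts:
    gene_id: str
    exon_a: GenomicInterval
    exon_b: GenomicInterval
    group: tuple
    n_in_in: int
    n_in_out: int
    n_out_in: int
    n_out_out: int

    @property
    def total(self) -> int:
        return self.n_in_in + self.n_in_out + self.n_out_in + self.n_out_out

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.n_in_in, self.n_in_out], [self.n_out_in, self.n_out_out]], dtype=float
        )


@dataclass
class CoordinationResult:
    pair: PairCounts
    p_value: float
    odds_ratio: float
    effect_size: float
    co_inclusion: float
    q_value: float | None = None
    coordinated: bool = False


def enumerate_exon_pairs(kept: set) -> list:
    """All within-gene pairs of kept exons, ordered by coordinate.

    ``kept`` holds (gene_id, start, end) keys as produced by
    filter_alternative_exons.
    """
    by_gene: dict[str, list] = {}
    for gid, s, e in kept:
        by_gene.setdefault(gid, []).append((s, e))
    pairs = []
    for gid in sorted(by_gene):
        for (s1, e1), (s2, e2) in itertools.combinations(sorted(by_gene[gid]), 2):
            pairs.append((gid, (s1, e1), (s2, e2)))
    return pairs


def count_pair_states(
    table: ReadTable,
    pairs: list,
    group_by: tuple = (),
    min_total: int = 25,
    flank: int = 50,
) -> list:
    """Tally 2x2 in/out matrices per exon pair and group.

    A read contributes only when its support status is definitive (``in``
    or ``out``) for both exons; truncated (acc_in/don_in) and ambiguous
    reads are excluded. Pairs with total < ``min_total`` in a group are
    dropped as insufficient depth. Pairs must lie within one gene.
    """
    for key in group_by:
        if key not in CLUSTER_COLUMNS:
            raise KeyError(f"unknown grouping key {key!r}")
    by_gene = table.by_gene()
    out = []
    for gid, (s1, e1), (s2, e2) in pairs:
        reads = by_gene.get(gid, [])
        counts: dict[tuple, np.ndarray] = {}
        exon_a = exon_b = None
        for read in reads:
            if exon_a is None:
                exon_a = GenomicInterval(read.chrom, s1, e1, read.strand)
                exon_b = GenomicInterval(read.chrom, s2, e2, read.strand)
            la = classify_read_exon_support(read, exon_a, flank=flank)
            if la not in ("in", "out"):
                continue
            lb = classify_read_exon_support(read, exon_b, flank=flank)
            if lb not in ("in", "out"):
                continue
            gkey = tuple(getattr(read.cluster, k) for k in group_by)
            m = counts.setdefault(gkey, np.zeros(4, dtype=np.int64))
            m[(la == "out") * 2 + (lb == "out")] += 1
        for gkey, m in sorted(counts.items()):
            if m.sum() < min_total:
                continue
            out.append(PairCounts(
                gene_id=gid, exon_a=exon_a, exon_b=exon_b, group=gkey,
                n_in_in=int(m[0]), n_in_out=int(m[1]),
                n_out_in=int(m[2]), n_out_out=int(m[3]),
            ))
    return out


def odds_ratio_half_corrected(n_in_in: int, n_in_out: int, n_out_in: int, n_out_out: int) -> float:
    """Cross-product odds ratio with zero cells replaced by 0.5."""
    a, b, c, d = (x if x > 0 else 0.5 for x in (n_in_in, n_in_out, n_out_in, n_out_out))
    return (a * d) / (b * c)


def test_coordination(counts: list, fdr: float = 0.05) -> list:
    """χ² association test per pair plus odds ratio, effect size and BH.

    A pair is ``coordinated`` when its BH q-value is <= ``fdr``. Tables
    with a degenerate margin (all-in or all-out for one exon) carry no
    association evidence and get p = 1.
    """
    results = []
    for pc in counts:
        m = pc.matrix
        if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
            p = 1.0
        else:
            _, p, _, _ = chi2_contingency(m, correction=False)
        orr = odds_ratio_half_corrected(pc.n_in_in, pc.n_in_out, pc.n_out_in, pc.n_out_out)
        results.append(CoordinationResult(
            pair=pc, p_value=float(p), odds_ratio=float(orr),
            effect_size=abs(math.log10(orr)),
            co_inclusion=pc.n_in_in / pc.total if pc.total else float("nan"),
        ))
    if results:
        _, q, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.coordinated = bool(qv <= fdr)
    return results


def coordination_frame(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        pc = r.pair
        rows.append({
            "gene_id": pc.gene_id,
            "exon_a": f"{pc.exon_a.start}-{pc.exon_a.end}",
            "exon_b": f"{pc.exon_b.start}-{pc.exon_b.end}",
            "inter_exon_distance": pc.exon_b.start - pc.exon_a.end,
            "group": "|".join(pc.group) if pc.group else "pseudobulk",
            "n_in_in": pc.n_in_in, "n_in_out": pc.n_in_out,
            "n_out_in": pc.n_out_in, "n_out_out": pc.n_out_out,
            "co_inclusion": r.co_inclusion, "p_value": r.p_value,
            "q_value": r.q_value, "odds_ratio": r.odds_ratio,
            "effect_size": r.effect_size, "coordinated": r.coordinated,
        })
    return pd.DataFrame(rows)
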