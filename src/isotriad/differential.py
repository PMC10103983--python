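"""Differential isoform / TSS / polyA usage between two cell categories.

The two-sample test follows the χ²-of-abundance framework: per gene, a
unit-by-condition count matrix (units = isoforms, TSS sites or polyA
sites) capped at 11 rows — the ten most abundant units plus an "other"
row — is tested with Pearson's χ². The effect size ΔΠ is the sum of the
usage-fraction changes of the top two units in the direction (gain or
loss) with the larger total shift. Genes where either condition has fewer
than 25 reads are untestable. BH correction is applied over testable genes
per comparison battery, and a gene is called significant when q <= 0.05
and ΔΠ exceeds the configured threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .model import ReadTable, SiteSet

log = logging.getLogger(__name__)

MAX_UNIT_ROWS = 10
OTHER_LABEL = "other"


@dataclass
class UsageMatrix:
    gene_id: str
    unit_kind: str  # "isoform" | "tss" | "polya"
    row_labels: list
    counts: np.ndarray  # rows x 2
    condition_labels: tuple

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.row_labels) or self.counts.shape[1] != 2:
            raise ValueError("counts must be len(row_labels) x 2")
        if self.counts.shape[0] > MAX_UNIT_ROWS + 1:
            raise ValueError("usage matrix exceeds 11 rows")


@dataclass
class DieResult:
    gene_id: str
    p_value: float | None = None
    q_value: float | None = None
    delta_pi: float | None = None
    driver_units: dict = field(default_factory=dict)  # {"up": [...], "down": [...]}
    status: str = "untestable"  # significant | not_significant | untestable


def build_die_matrix(
    gene_id: str,
    unit_counts: dict,
    condition_labels: tuple = ("cond1", "cond2"),
    unit_kind: str = "isoform",
    min_reads: int = 25,
) -> UsageMatrix | None:
    """Construct the (<=11) x 2 unit-by-condition matrix, or None if
    untestable.

    ``unit_counts`` maps unit id -> (count_cond1, count_cond2). Untestable
    when either condition total falls below ``min_reads``. Units are ranked
    by pooled count (ties -> lexicographic id); ranks beyond 10 collapse
    into an "other" row.
    """
    items = [(u, int(c1), int(c2)) for u, (c1, c2) in unit_counts.items()]
    tot1 = sum(c1 for _, c1, _ in items)
    tot2 = sum(c2 for _, _, c2 in items)
    if tot1 < min_reads or tot2 < min_reads:
        return None
    items.sort(key=lambda t: (-(t[1] + t[2]), t[0]))
    top, rest = items[:MAX_UNIT_ROWS], items[MAX_UNIT_ROWS:]
    labels = [u for u, _, _ in top]
    counts = [[c1, c2] for _, c1, c2 in top]
    if rest:
        labels.append(OTHER_LABEL)
        counts.append([sum(c1 for _, c1, _ in rest), sum(c2 for _, _, c2 in rest)])
    return UsageMatrix(
        gene_id=gene_id, unit_kind=unit_kind, row_labels=labels,
        counts=np.asarray(counts, dtype=np.int64), condition_labels=condition_labels,
    )


def die_test(m: UsageMatrix) -> DieResult:
    """Pearson χ² (no continuity correction) plus the top-two ΔΠ statistic.

    Rows with zero total across both conditions are dropped before
    testing. q_value is left unset; apply :func:`bh_adjust` per battery.
    """
    counts = m.counts[m.counts.sum(axis=1) > 0]
    labels = [l for l, row in zip(m.row_labels, m.counts) if row.sum() > 0]
    res = DieResult(gene_id=m.gene_id)
    if counts.shape[0] < 2:
        # a single expressed unit cannot shift usage
        res.p_value, res.delta_pi, res.status = 1.0, 0.0, "not_significant"
        return res
    col = counts.sum(axis=0)
    if (col == 0).any():
        res.p_value, res.delta_pi, res.status = 1.0, 0.0, "not_significant"
        return res
    expected = np.outer(counts.sum(axis=1), col) / counts.sum()
    if (expected == 0).any() or counts.sum(axis=1).min() == 0:
        p = 1.0
    else:
        if (expected < 5).any():
            log.debug("gene %s: expected counts < 5 in χ² table", m.gene_id)
        stat, p, _, _ = chi2_contingency(counts, correction=False)
    pi = counts / col  # per-condition usage fractions
    dpi = pi[:, 0] - pi[:, 1]
    order = np.argsort(dpi)
    pos = sorted(dpi[dpi > 0], reverse=True)[:2]
    neg = sorted((-d for d in dpi if d < 0), reverse=True)[:2]
    res.delta_pi = float(max(sum(pos), sum(neg), 0.0))
    res.driver_units = {
        "up": [labels[i] for i in order[::-1][:2] if dpi[i] > 0],
        "down": [labels[i] for i in order[:2] if dpi[i] < 0],
    }
    res.p_value = float(p)
    res.status = "tested"
    return res


def bh_adjust(
    results: list,
    fdr: float = 0.05,
    delta_pi_threshold: float = 0.1,
) -> list:
    """Benjamini–Hochberg step-up over testable genes of one battery.

    Untestable genes keep q unset. A gene is ``significant`` when
    q <= fdr and ΔΠ >= delta_pi_threshold, else ``not_significant``.
    """
    testable = [r for r in results if r.p_value is not None]
    if testable:
        _, q, _, _ = multipletests([r.p_value for r in testable], method="fdr_bh")
        for r, qv in zip(testable, q):
            r.q_value = float(qv)
            if r.q_value <= fdr and (r.delta_pi or 0.0) >= delta_pi_threshold:
                r.status = "significant"
            else:
                r.status = "not_significant"
    return results


# ---------------------------------------------------------------------------
# End-site (TSS / polyA) assignment

def assign_end_sites(table: ReadTable, sites: SiteSet, window: int = 50) -> pd.DataFrame:
    """Assign each read's strand-aware terminus to the nearest reference
    site within +-window bases (inclusive).

    For ``tss`` sets the 5' terminus is used; for ``polya`` the 3'
    terminus. Distance ties are broken toward the upstream site in
    transcript orientation. Returns the label-level read frame with
    ``site_id`` (NaN when unassigned) and ``site_distance`` columns; reads
    without an assignable site are retained in the frame but should be
    excluded from end-site counts.
    """
    by_key: dict[tuple, list] = {}
    for chrom, pos, strand in sites.sites:
        by_key.setdefault((chrom, strand), []).append(pos)
    index = {}
    for key, positions in by_key.items():
        arr = np.array(sorted(positions))
        index[key] = arr
    if not index:
        log.warning("empty %s site set: no reads assignable", sites.kind)
    ids, dists = [], []
    for r in table.records:
        end = r.five_prime if sites.kind == "tss" else r.three_prime
        arr = index.get((r.chrom, r.strand))
        if arr is None:
            arr = index.get((r.chrom, "."))
        if arr is None or len(arr) == 0:
            ids.append(None)
            dists.append(np.nan)
            continue
        i = np.searchsorted(arr, end)
        candidates = [j for j in (i - 1, i) if 0 <= j < len(arr)]
        # nearest within window; tie -> upstream in transcript orientation
        def tie_key(j):
            upstream = arr[j] if r.strand == "+" else -arr[j]
            return (abs(int(arr[j]) - end), upstream)
        best = min(candidates, key=tie_key)
        d = abs(int(arr[best]) - end)
        if d <= window:
            ids.append(f"{sites.kind}:{r.chrom}:{int(arr[best])}")
            dists.append(d)
        else:
            ids.append(None)
            dists.append(np.nan)
    df = table.to_frame().copy()
    df["site_id"] = ids
    df["site_distance"] = dists
    return df


# ---------------------------------------------------------------------------
# One-region-vs-rest orchestration

def _unit_column(df: pd.DataFrame, unit_kind: str) -> str:
    if unit_kind == "isoform":
        return "isoform_id"
    if unit_kind in ("tss", "polya"):
        if "site_id" not in df.columns:
            raise ValueError("tss/polya testing requires assign_end_sites output")
        return "site_id"
    raise ValueError(f"unknown unit_kind {unit_kind!r}")


def one_vs_rest_region_die(
    reads: pd.DataFrame | ReadTable,
    cell_type: str | None = None,
    unit_kind: str = "isoform",
    delta_pi_thresholds: tuple = (0.1, 0.2, 0.3, 0.4, 0.5),
    min_reads: int = 25,
    fdr: float = 0.05,
) -> dict:
    """Run one DIE battery per region (foreground vs the pooled rest).

    ``reads`` is a ReadTable or the frame from :func:`assign_end_sites`.
    Returns a dict with:

    * ``results``: {region: [DieResult, ...]} with BH applied per battery
      at the smallest threshold in ``delta_pi_thresholds``;
    * ``significant_fraction``: frame (region, threshold, n_testable,
      n_significant, fraction) — the threshold sweep;
    * ``sharing``: per-gene count of regions where it is significant;
    * ``status``: gene x region status frame.
    """
    df = reads.to_frame() if isinstance(reads, ReadTable) else reads
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    unit_col = _unit_column(df, unit_kind)
    df = df[df[unit_col].notna()]
    regions = sorted(df["region"].unique())
    if len(regions) < 2:
        raise ValueError("one-vs-rest testing needs >= 2 regions")
    base_threshold = min(delta_pi_thresholds)
    results: dict[str, list] = {}
    sweep_rows = []
    for region in regions:
        fg = df[df["region"] == region]
        if fg.empty:
            log.warning("region %s has no reads for cell type %s; battery skipped", region, cell_type)
            continue
        counts = (
            df.assign(cond=np.where(df["region"] == region, 0, 1))
            .groupby(["gene_id", unit_col, "cond"]).size().unstack("cond", fill_value=0)
            .reindex(columns=[0, 1], fill_value=0)
        )
        battery = []
        for gid, grp in counts.groupby(level="gene_id"):
            unit_counts = {
                u: (int(row[0]), int(row[1]))
                for (_, u), row in grp.iterrows()
            }
            m = build_die_matrix(
                gid, unit_counts, condition_labels=(region, "rest"),
                unit_kind=unit_kind, min_reads=min_reads,
            )
            battery.append(DieResult(gene_id=gid) if m is None else die_test(m))
        bh_adjust(battery, fdr=fdr, delta_pi_threshold=base_threshold)
        results[region] = battery
        n_testable = sum(1 for r in battery if r.p_value is not None)
        for thr in delta_pi_thresholds:
            n_sig = sum(
                1 for r in battery
                if r.q_value is not None and r.q_value <= fdr and (r.delta_pi or 0) >= thr
            )
            sweep_rows.append((region, thr, n_testable, n_sig,
                               n_sig / n_testable if n_testable else np.nan))
    sweep = pd.DataFrame(
        sweep_rows, columns=["region", "threshold", "n_testable", "n_significant", "fraction"]
    )
    status = pd.DataFrame({
        region: {r.gene_id: r.status for r in battery}
        for region, battery in results.items()
    }).fillna("untestable")
    sharing = (status == "significant").sum(axis=1).rename("n_regions_significant")
    return {"results": results, "significant_fraction": sweep, "sharing": sharing, "status": status}


def die_results_frame(results: list) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id, "p_value": r.p_value, "q_value": r.q_value,
            "delta_pi": r.delta_pi,
            "drivers_up": ",".join(r.driver_units.get("up", [])),
            "drivers_down": ",".join(r.driver_units.get("down", [])),
            "status": r.status,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
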