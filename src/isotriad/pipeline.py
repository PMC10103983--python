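"""Pipeline orchestration: run analysis stages in dependency order and
record a reproducibility manifest (config hash, seed, input checksums)."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import coordination as coord_mod
from . import differential as die_mod
from . import io as io_mod
from . import programs as prog_mod
from . import psi as psi_mod
from . import variability as var_mod
from .config import RunConfig
from .design import enumerate_design
from .simulate import EffectSpec, build_synthetic_annotation, simulate_study

log = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate", "psi", "variability", "die", "endsites",
    "hvex", "evex", "modality", "coordinate", "correlate",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.6g")


class _Context:
    """Lazy access to inputs, from config paths or earlier stage outputs."""

    def __init__(self, config: RunConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self._cache: dict = {}

    def _resolve(self, name: str, config_path: str | None, produced: str, stage: str) -> Path:
        if config_path:
            return Path(config_path)
        candidate = self.outdir / produced
        if candidate.exists():
            return candidate
        raise FileNotFoundError(
            f"{name} not available: provide it in the config or run stage {stage!r} first"
        )

    def annotation(self):
        if "annotation" not in self._cache:
            path = self._resolve("annotation", self.config.gtf, "annotation.gtf", "simulate")
            self._cache["annotation"] = io_mod.read_annotation_gtf(path)
        return self._cache["annotation"]

    def table(self):
        if "table" not in self._cache:
            path = self._resolve("read table", self.config.reads, "reads.tsv", "simulate")
            table = io_mod.load_read_table(path, self.annotation())
            self._cache["table"] = io_mod.dedupe_umis(table)
        return self._cache["table"]

    def sites(self, kind: str):
        key = f"sites_{kind}"
        if key not in self._cache:
            cfg_path = self.config.tss if kind == "tss" else self.config.polya
            path = self._resolve(f"{kind} sites", cfg_path, f"{kind}.bed", "simulate")
            self._cache[key] = io_mod.read_site_bed(path, kind)
        return self._cache[key]

    def triad_matrix(self):
        if "triad_matrix" not in self._cache:
            th = self.config.thresholds
            self._cache["triad_matrix"] = psi_mod.build_triad_psi_matrix(
                self.table(), self.annotation(), self.config.design,
                xtot_min=th.xtot_min, flank=th.skip_flank,
                psi_window=th.psi_window, informative_ratio=th.informative_ratio,
                nonannotated_exclusion=th.nonannotated_exclusion,
                replicate_combine=th.replicate_combine,
            )
        return self._cache["triad_matrix"]

    def kept_exons(self):
        if "kept" not in self._cache:
            th = self.config.thresholds
            exons = psi_mod.candidate_exons(self.table(), self.annotation())
            bulk = psi_mod.count_exon_support(self.table(), exons, group_by=(), flank=th.skip_flank)
            self._cache["bulk_counts"] = bulk
            self._cache["kept"] = psi_mod.filter_alternative_exons(
                bulk, self.annotation(), psi_window=th.psi_window,
                informative_ratio=th.informative_ratio,
                nonannotated_exclusion=th.nonannotated_exclusion,
            )
        return self._cache["kept"]

    def lineage_comparisons(self):
        if "comparisons" not in self._cache:
            self._cache["comparisons"] = prog_mod.enumerate_lineage_comparisons(self.triad_matrix())
        return self._cache["comparisons"]


def run_pipeline(config: RunConfig, stages: tuple = STAGE_ORDER) -> dict:
    """Execute the requested stages in dependency order; returns the run
    manifest (also written to ``<outdir>/manifest.json``)."""
    config.validate()
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Context(config, outdir)
    th = config.thresholds
    design = config.design
    executed = []

    for stage in [s for s in STAGE_ORDER if s in set(stages)]:
        log.info("stage %s", stage)
        if stage == "simulate":
            sim = config.simulate
            annotation, tss, polya = build_synthetic_annotation(
                n_genes=sim.n_genes, exons_per_gene=sim.exons_per_gene,
                isoforms_per_gene=sim.isoforms_per_gene, seed=config.seed,
            )
            effects = EffectSpec(
                truncation_5=sim.truncation_5, truncation_3=sim.truncation_3,
                umi_duplication_rate=sim.umi_duplication_rate,
            )
            table, truth = simulate_study(design, effects, annotation, seed=config.seed)
            io_mod.write_annotation_gtf(annotation, outdir / "annotation.gtf")
            io_mod.write_site_bed(tss, outdir / "tss.bed")
            io_mod.write_site_bed(polya, outdir / "polya.bed")
            io_mod.write_read_table(table, outdir / "reads.tsv")
            _write_tsv(truth.pi, outdir / "truth_pi.tsv")
            _write_tsv(truth.exon_psi, outdir / "truth_exon_psi.tsv")
            _write_tsv(truth.coordination, outdir / "truth_coordination.tsv")
        elif stage == "psi":
            matrix = ctx.triad_matrix()
            flat = matrix.psi.copy()
            flat.columns = ["|".join(c) for c in flat.columns]
            _write_tsv(flat, outdir / "psi_triad_matrix.tsv", index=True)
            _write_tsv(ctx._cache.get("bulk_counts", pd.DataFrame()) if "bulk_counts" in ctx._cache
                       else psi_mod.count_exon_support(
                           ctx.table(), psi_mod.candidate_exons(ctx.table(), ctx.annotation()),
                           group_by=(), flank=th.skip_flank),
                       outdir / "pseudobulk_counts.tsv")
        elif stage == "variability":
            frames = []
            for ct in design.cell_types:
                vs = var_mod.compute_cell_type_variability(
                    ctx.table(), ct, min_gene_reads=th.min_gene_reads, gate=th.ternary_gate,
                )
                frames.append(var_mod.variability_frame(vs))
            pb = var_mod.compute_pseudobulk_variability(
                ctx.table(), min_gene_reads=th.min_gene_reads, gate=th.ternary_gate,
            )
            frames.append(var_mod.variability_frame(pb))
            _write_tsv(pd.concat(frames, ignore_index=True), outdir / "variability.tsv")
        elif stage == "die":
            out = die_mod.one_vs_rest_region_die(
                ctx.table(), unit_kind="isoform",
                min_reads=th.die_min_reads, fdr=th.fdr,
            )
            frames = []
            for region, battery in out["results"].items():
                f = die_mod.die_results_frame(battery)
                f.insert(0, "region", region)
                frames.append(f)
            _write_tsv(pd.concat(frames, ignore_index=True), outdir / "die_isoform.tsv")
            _write_tsv(out["significant_fraction"], outdir / "die_isoform_sweep.tsv")
        elif stage == "endsites":
            for kind in ("tss", "polya"):
                assigned = die_mod.assign_end_sites(ctx.table(), ctx.sites(kind), window=th.site_window)
                out = die_mod.one_vs_rest_region_die(
                    assigned, unit_kind=kind, min_reads=th.die_min_reads, fdr=th.fdr,
                )
                frames = []
                for region, battery in out["results"].items():
                    f = die_mod.die_results_frame(battery)
                    f.insert(0, "region", region)
                    frames.append(f)
                _write_tsv(pd.concat(frames, ignore_index=True), outdir / f"die_{kind}.tsv")
        elif stage == "hvex":
            comparisons = ctx.lineage_comparisons()
            hvex = prog_mod.call_hvex(comparisons, threshold=th.hvex)
            pd.Series(sorted(hvex), name="exon_id").to_csv(
                outdir / "hvex.tsv", sep="\t", index=False)
            if hvex:
                dp = prog_mod.pairwise_dpsi_matrix(
                    ctx.triad_matrix(), exons=hvex, max_na_fraction=th.max_na_fraction,
                )
                _write_tsv(dp["dpsi"], outdir / "hvex_dpsi_matrix.tsv", index=True)
                _write_tsv(dp["groups"].to_frame(), outdir / "hvex_groups.tsv", index=True)
            ctx._cache["hvex"] = hvex
        elif stage == "evex":
            comparisons = ctx.lineage_comparisons()
            hvex = ctx._cache.get("hvex")
            if hvex is None:
                hvex = prog_mod.call_hvex(comparisons, threshold=th.hvex)
            m = prog_mod.call_evex(comparisons, hvex=hvex, threshold=th.evex)
            m = prog_mod.classify_evex_groups(m, high=th.evex)
            out = m.values.copy()
            out["evex"] = m.evex
            out = out.join(m.groups)
            _write_tsv(out, outdir / "evex.tsv", index=True)
        elif stage == "modality":
            frames = []
            for region in design.dev_regions:
                tbl = prog_mod.evar_table(ctx.triad_matrix(), region)
                res = prog_mod.classify_developmental_modality(tbl, step_threshold=th.evar_step)
                rec = res["records"].copy()
                rec.insert(0, "region", region)
                frames.append(rec)
            _write_tsv(pd.concat(frames), outdir / "modality.tsv", index=True)
        elif stage == "coordinate":
            pairs = coord_mod.enumerate_exon_pairs(ctx.kept_exons())
            counts = coord_mod.count_pair_states(
                ctx.table(), pairs, group_by=(), min_total=th.coordination_min_total,
                flank=th.skip_flank,
            )
            results = coord_mod.test_coordination(counts, fdr=th.fdr)
            _write_tsv(coord_mod.coordination_frame(results), outdir / "coordination.tsv")
        elif stage == "correlate":
            res = prog_mod.correlate_psi_profiles(
                ctx.triad_matrix(), min_shared=th.min_shared_exons,
            )
            corr = res["correlation"].copy()
            corr.index = ["|".join(c) for c in corr.index]
            corr.columns = ["|".join(c) for c in corr.columns]
            _write_tsv(corr, outdir / "psi_correlation.tsv", index=True)
        executed.append(stage)

    inputs = {}
    for name in ("gtf", "reads", "tss", "polya"):
        p = getattr(config, name)
        if p and Path(p).exists():
            inputs[name] = _sha256(Path(p))
    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": executed,
        "input_checksums": inputs,
        "design": {
            "n_samples": len(design.samples()),
            "n_triads": len(design.triads()),
        },
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
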