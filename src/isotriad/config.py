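"""Run configuration: thresholds, inputs, design and effect specs.

Defaults equal the published analysis constants: Ψ keep window
[0.05, 0.95], informative ratio 0.8, X_tot >= 10, hVEx ΔΨ >= 0.25,
EVEx ΔΨ >= 0.75, ternary gate 0.1, highly-variable-isoform threshold
0.25, DIE depth 25 reads/category with ΔΠ >= 0.1 at FDR 5%, 50-bp
end-site window, eVar step 0.1, 50-base skip flank, 70-base
non-annotated-exon exclusion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import StudyDesign, default_design


@dataclass
class Thresholds:
    psi_window: tuple = (0.05, 0.95)
    informative_ratio: float = 0.8
    xtot_min: int = 10
    hvex: float = 0.25
    evex: float = 0.75
    ternary_gate: float = 0.1
    hvg: float = 0.25
    die_min_reads: int = 25
    die_delta_pi: float = 0.1
    fdr: float = 0.05
    site_window: int = 50
    evar_step: float = 0.1
    skip_flank: int = 50
    nonannotated_exclusion: int = 70
    min_gene_reads: int = 10
    coordination_min_total: int = 25
    max_na_fraction: float = 0.5
    min_shared_exons: int = 20
    replicate_combine: str = "sum"

    def validate(self) -> None:
        lo, hi = self.psi_window
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError(f"psi_window must be ordered within [0,1], got {self.psi_window}")
        for name in ("informative_ratio", "hvex", "evex", "ternary_gate", "hvg",
                     "die_delta_pi", "fdr", "evar_step", "max_na_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("xtot_min", "die_min_reads", "site_window", "skip_flank",
                     "nonannotated_exclusion", "min_gene_reads",
                     "coordination_min_total", "min_shared_exons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.replicate_combine not in ("sum", "mean"):
            raise ValueError("replicate_combine must be 'sum' or 'mean'")


@dataclass
class SimulateConfig:
    n_genes: int = 20
    exons_per_gene: tuple = (6, 9)
    isoforms_per_gene: tuple = (2, 4)
    truncation_5: float = 0.25
    truncation_3: float = 0.25
    umi_duplication_rate: float = 0.2


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "isotriad_run"
    design: StudyDesign = field(default_factory=default_design)
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    # external inputs (alternatives to the simulate stage)
    gtf: str | None = None
    reads: str | None = None
    tss: str | None = None
    polya: str | None = None

    def validate(self) -> "RunConfig":
        self.thresholds.validate()
        self.design.samples()  # raises on duplicate sample keys
        return self

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "design": asdict(self.design),
            "thresholds": asdict(self.thresholds),
            "simulate": asdict(self.simulate),
            "inputs": {"gtf": self.gtf, "reads": self.reads, "tss": self.tss, "polya": self.polya},
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _design_from_dict(d: dict) -> StudyDesign:
    base = default_design()
    hierarchy = d.get("cell_hierarchy")
    return StudyDesign(
        dev_regions=tuple(d.get("dev_regions", base.dev_regions)),
        ages=tuple(d.get("ages", base.ages)),
        adult_regions=tuple(d.get("adult_regions", base.adult_regions)),
        replicates=tuple(d.get("replicates", base.replicates)),
        cell_hierarchy={
            broad: {ct: tuple(subs) for ct, subs in cts.items()}
            for broad, cts in hierarchy.items()
        } if hierarchy else base.cell_hierarchy,
        cells_per_cluster=int(d.get("cells_per_cluster", base.cells_per_cluster)),
        reads_per_cell=float(d.get("reads_per_cell", base.reads_per_cell)),
    )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; ``overrides`` (flag > config > default) are
    applied on top for top-level and threshold keys."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    overrides = overrides or {}
    cfg = RunConfig()
    if "design" in data:
        cfg.design = _design_from_dict(data["design"])
    th = {**data.get("thresholds", {})}
    for k, v in overrides.items():
        if hasattr(cfg.thresholds, k):
            th[k] = v
    for k, v in th.items():
        if not hasattr(cfg.thresholds, k):
            raise ValueError(f"unknown threshold {k!r}")
        current = getattr(cfg.thresholds, k)
        setattr(cfg.thresholds, k, tuple(v) if isinstance(current, tuple) else v)
    sim = data.get("simulate", {})
    for k, v in sim.items():
        if not hasattr(cfg.simulate, k):
            raise ValueError(f"unknown simulate option {k!r}")
        current = getattr(cfg.simulate, k)
        setattr(cfg.simulate, k, tuple(v) if isinstance(current, tuple) else v)
    for k in ("seed", "outdir", "gtf", "reads", "tss", "polya"):
        if k in overrides and overrides[k] is not None:
            setattr(cfg, k, overrides[k])
        elif k in data:
            setattr(cfg, k, data[k])
    return cfg.validate()
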