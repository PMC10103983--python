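"""Study-design grid: samples, clusters and triads.

The reference design mirrors a developmental grid (two telencephalic
regions sampled at four postnatal ages, two replicates each) plus three
additional regions sampled only at the terminal age (two replicates each).
Cells carry a three-level hierarchy: broad class -> cell type -> subtype.
A *triad* is an (age, region, cell type) condition with replicates (and
subtypes) collapsed; Ψ matrices are indexed by triads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .model import ClusterKey


@dataclass(frozen=True)
class StudyDesign:
    dev_regions: tuple  # regions sampled across development
    ages: tuple  # ordered developmental ages; last entry is terminal
    adult_regions: tuple  # regions sampled only at the terminal age
    replicates: tuple
    # broad -> {cell_type: (subtypes...)}
    cell_hierarchy: dict
    cells_per_cluster: int = 20
    reads_per_cell: float = 25.0

    def __post_init__(self) -> None:
        if not self.dev_regions or not self.ages or not self.replicates:
            raise ValueError("design grids must be non-empty")
        seen: dict[str, str] = {}
        for broad, cts in self.cell_hierarchy.items():
            for ct, subs in cts.items():
                for sub in subs:
                    if sub in seen:
                        raise ValueError(f"subtype {sub!r} mapped to two cell types")
                    seen[sub] = ct

    @property
    def terminal_age(self) -> str:
        return self.ages[-1]

    @property
    def all_regions(self) -> tuple:
        return tuple(self.dev_regions) + tuple(self.adult_regions)

    @property
    def cell_types(self) -> tuple:
        return tuple(ct for cts in self.cell_hierarchy.values() for ct in cts)

    def subtypes_of(self, cell_type: str) -> tuple:
        for cts in self.cell_hierarchy.values():
            if cell_type in cts:
                return tuple(cts[cell_type])
        raise KeyError(cell_type)

    def broad_of(self, cell_type: str) -> str:
        for broad, cts in self.cell_hierarchy.items():
            if cell_type in cts:
                return broad
        raise KeyError(cell_type)

    def conditions(self) -> list:
        """(region, age) sample conditions: dev grid plus adult-only regions."""
        dev = [(r, a) for r in self.dev_regions for a in self.ages]
        adult = [(r, self.terminal_age) for r in self.adult_regions]
        return dev + adult

    def samples(self) -> list:
        """(region, age, replicate) triples; duplicates are a config error."""
        out = [(r, a, rep) for (r, a) in self.conditions() for rep in self.replicates]
        if len(set(out)) != len(out):
            raise ValueError("duplicate sample keys in design")
        return out

    def clusters(self) -> list:
        """All ClusterKeys: samples x cell subtypes."""
        keys = []
        for region, age, rep in self.samples():
            for broad, cts in self.cell_hierarchy.items():
                for ct, subs in cts.items():
                    for sub in subs:
                        keys.append(ClusterKey(region, age, rep, broad, ct, sub))
        return keys

    def triads(self) -> list:
        """(age, region, cell_type) triads, replicates collapsed."""
        return [
            (age, region, ct)
            for (region, age) in self.conditions()
            for ct in self.cell_types
        ]


def enumerate_design(design: StudyDesign) -> dict:
    """Enumerate samples, clusters and triads of a design.

    Returns a dict with keys ``samples``, ``developmental_samples``,
    ``adult_samples``, ``clusters``, ``conditions``, ``triads`` and
    ``n_pairwise_triad_comparisons`` (= n(n-1)/2 over triads).
    """
    samples = design.samples()
    dev = [s for s in samples if s[0] in design.dev_regions]
    adult = [s for s in samples if s[0] in design.adult_regions]
    triads = design.triads()
    n = len(triads)
    return {
        "samples": samples,
        "developmental_samples": dev,
        "adult_samples": adult,
        "clusters": design.clusters(),
        "conditions": design.conditions(),
        "triads": triads,
        "n_pairwise_triad_comparisons": n * (n - 1) // 2,
    }


def default_design(cells_per_cluster: int = 20, reads_per_cell: float = 25.0) -> StudyDesign:
    """The reference mouse-brain grid: HIPP/VIS at P14-P56 (16 samples) plus
    adult STRI/THAL/CEREB (6 samples); 4 major cell types, 2 subtypes each."""
    return StudyDesign(
        dev_regions=("HIPP", "VIS"),
        ages=("P14", "P21", "P28", "P56"),
        adult_regions=("STRI", "THAL", "CEREB"),
        replicates=("rep1", "rep2"),
        cell_hierarchy={
            "Glia": {
                "Astro": ("AstroFib", "AstroProto"),
                "Oligo": ("OPC", "MOL"),
            },
            "Neuron": {
                "ExcitNeuron": ("L23IT", "CA1Pyr"),
                "InhibNeuron": ("Pvalb", "Sst"),
            },
        },
        cells_per_cluster=cells_per_cluster,
        reads_per_cell=reads_per_cell,
    )
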