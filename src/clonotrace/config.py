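"""Pipeline configuration: one schema holding every stage's parameters.

The configuration round-trips losslessly through YAML; unknown keys are
rejected so a run is fully reconstructible from its config file.  Every
default that fills a gap the upstream method descriptions leave open (QC
bounds, smoothing window, HMM transition probability, resistance threshold,
match score) lives here in one place.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SampleSpec, SimulationConfig

__all__ = ["PipelineConfig", "default_config", "acceptance_scenario_config"]


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class QCSection:
    min_umi: float = 500.0
    max_umi: float = float("inf")
    min_genes: float = 200.0
    max_genes: float = float("inf")
    max_mito: float = 0.15
    cluster_lowq_cutoff: float = 0.33


@dataclass
class ClusterSection:
    n_hvg: int = 2000
    variance_fraction: float = 0.015
    k: int = 15
    resolution: float = 1.0


@dataclass
class MalignantSection:
    expr_threshold: float = 1.0
    fraction_threshold: float = 0.5
    restriction_threshold: float = 1.0


@dataclass
class CNVSection:
    min_mean: float = 0.1
    clip: float = 3.0
    window: int = 101
    transition: float = 1e-6
    eps0: float = 0.05
    sigma_floor: float = 0.05


@dataclass
class ClonesSection:
    method: str = "leiden"
    k: int = 15
    resolution: float = 1.0
    n_clusters: int = 4
    min_cluster_size: int = 10
    theta: float = 0.8
    min_match_score: float = 0.5


@dataclass
class ConcordanceSection:
    bin_size: int = 100_000


@dataclass
class DESection:
    min_lfc: float = 0.25
    min_frac: float = 0.10
    max_adj_p: float = 0.05
    min_abs_l2fc: float = 0.8
    sig_min_frac: float = 0.25


@dataclass
class GSEASection:
    n_perm: int = 1000
    min_size: int = 5
    rank_min_l2fc: float = 0.25


@dataclass
class CycleSection:
    n_bins: int = 24
    n_control: int = 100


@dataclass
class SimulateSection:
    n_chromosomes: int = 22
    genes_per_chromosome: int = 300
    samples: dict = field(default_factory=dict)     # sample -> {timepoint, n_cells}
    subclones: list = field(default_factory=list)   # [{id, parent, proportions, events}]
    baseline_shape: float = 0.4
    baseline_scale: float = 1.0
    libsize_meanlog: float = math.log(5_000.0)
    libsize_sdlog: float = 0.35
    dispersion: float = 2.0
    alpha: float = 1.0
    eps0: float = 0.05
    marker_effect: float = 12.0
    light_chain_ratio: float = 20.0
    cycle_multiplier: float = 3.0
    s_fraction: float = 0.15
    g2m_fraction: float = 0.15
    low_quality_fraction: float = 0.0

    def simulation_config(self, seed: int) -> SimulationConfig:
        samples = {
            name: SampleSpec(
                timepoint=s["timepoint"], n_cells=dict(s["n_cells"]),
                s_fraction=s.get("s_fraction"), g2m_fraction=s.get("g2m_fraction"),
            )
            for name, s in self.samples.items()
        }
        return SimulationConfig(
            samples=samples,
            baseline_shape=self.baseline_shape,
            baseline_scale=self.baseline_scale,
            libsize_meanlog=self.libsize_meanlog,
            libsize_sdlog=self.libsize_sdlog,
            dispersion=self.dispersion,
            alpha=self.alpha,
            eps0=self.eps0,
            marker_effect=self.marker_effect,
            light_chain_ratio=self.light_chain_ratio,
            cycle_multiplier=self.cycle_multiplier,
            s_fraction=self.s_fraction,
            g2m_fraction=self.g2m_fraction,
            low_quality_fraction=self.low_quality_fraction,
            seed=seed,
        )


_SECTIONS = {
    "simulate": SimulateSection,
    "qc": QCSection,
    "cluster": ClusterSection,
    "malignant": MalignantSection,
    "cnv": CNVSection,
    "clones": ClonesSection,
    "concordance": ConcordanceSection,
    "de": DESection,
    "gsea": GSEASection,
    "cycle": CycleSection,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str | None = None   # load counts instead of simulating when set
    simulate: SimulateSection = field(default_factory=SimulateSection)
    qc: QCSection = field(default_factory=QCSection)
    cluster: ClusterSection = field(default_factory=ClusterSection)
    malignant: MalignantSection = field(default_factory=MalignantSection)
    cnv: CNVSection = field(default_factory=CNVSection)
    clones: ClonesSection = field(default_factory=ClonesSection)
    concordance: ConcordanceSection = field(default_factory=ConcordanceSection)
    de: DESection = field(default_factory=DESection)
    gsea: GSEASection = field(default_factory=GSEASection)
    cycle: CycleSection = field(default_factory=CycleSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for key, section_cls in _SECTIONS.items():
            if key in d:
                kwargs[key] = _from_dict(section_cls, d.pop(key))
        for key in ("seed", "input_dir"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(seed: int = 0) -> PipelineConfig:
    """A small default scenario exercising every stage quickly.

    The smoothing window shrinks with the genome so that a window never spans
    a whole chromosome.
    """
    cfg = acceptance_scenario_config(seed=seed, scale=0.3)
    cfg.cnv.window = 31
    return cfg


def acceptance_scenario_config(seed: int = 0, scale: float = 1.0) -> PipelineConfig:
    """The paired diagnosis/relapse scenario with a 1% resistant precursor.

    Diagnosis: 500 normal + 1500 malignant cells in subclones A/B/C at
    0.90/0.09/0.01; relapse: 500 normal + 1500 malignant at 0.04/0.06/0.90.
    Clone C's event set equals the dominant relapse profile; all events span
    well over 30 genes with |copy - 2| >= 1.  ``scale`` shrinks cell and gene
    counts proportionally for quick runs.
    """
    gpc = max(40, int(round(273 * scale)))
    n_norm = max(60, int(round(500 * scale)))
    n_mal = max(200, int(round(1500 * scale)))
    # normal compartment split across cell types, B-rich
    normals = {
        "B": int(n_norm * 0.4),
        "CD8T": int(n_norm * 0.3),
        "CD4T": int(n_norm * 0.15),
        "NK": max(1, int(n_norm * 0.1)),
        "Mono": max(1, int(n_norm * 0.05)),
    }

    def ev(chrom, g0, g1, cn, gpc=gpc):
        # events specified in gene-index units; converted to bp by the pipeline
        return {"chromosome": chrom, "gene_span": [g0, g1], "copy_number": cn}

    # truncal events shared by all clones; B and C add private events;
    # C (the resistant precursor) carries the dominant-relapse profile:
    # amplifications on chr19/chr22-like chromosomes plus a 6q-like deletion.
    subclones = [
        {"id": "cloneA", "parent": None,
         "proportions": {"Dg": 0.90, "Rel": 0.04},
         "events": [ev("chr1", 30, 190, 1), ev("chr11", 60, 220, 4)]},
        {"id": "cloneB", "parent": "cloneA",
         "proportions": {"Dg": 0.09, "Rel": 0.06},
         "events": [ev("chr8", 50, 230, 3)]},
        {"id": "cloneC", "parent": "cloneA",
         "proportions": {"Dg": 0.01, "Rel": 0.90},
         "events": [ev("chr6", 80, 260, 1), ev("chr19", 20, 200, 4),
                    ev("chr22", 40, 210, 3)]},
    ]
    sim = SimulateSection(
        n_chromosomes=22,
        genes_per_chromosome=gpc,
        samples={
            "Dg": {"timepoint": "diagnosis", "n_cells": {**normals, "malignant": n_mal}},
            "Rel": {"timepoint": "relapse", "n_cells": {**normals, "malignant": n_mal}},
        },
        subclones=subclones,
    )
    if scale < 1.0:
        # shrink gene spans with the genome so events keep their relative size
        f = gpc / 273.0
        for sc in sim.subclones:
            for e in sc["events"]:
                g0, g1 = e["gene_span"]
                e["gene_span"] = [max(1, int(g0 * f)), min(gpc, max(int(g1 * f), int(g0 * f) + 5))]
    return PipelineConfig(seed=seed, simulate=sim)
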