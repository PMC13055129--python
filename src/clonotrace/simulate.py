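"""Synthetic paired diagnosis/relapse single-cell experiments with planted CNV clones.

The generator emulates the structure of a mantle-cell-lymphoma style study:
each sample holds normal reference cells (B/T/NK/monocyte-like) plus malignant
cells partitioned into subclones, every subclone carrying truncal plus private
copy-number events, with a minor diagnostic subclone sharing the dominant
relapse clone's profile.  Counts follow a gamma-Poisson (negative binomial)
model in which a gene's mean scales with ``(c/2)**alpha`` for copy number
``c``.  Malignant cells express a CCND1-like marker highly and exactly one
immunoglobulin light chain (kappa- or lambda-like); normal B-like cells mix
both chains.  A configurable fraction of cells receives an S- or G2/M-phase
program (elevated expression of the respective gene set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeModel",
    "CNVEvent",
    "Subclone",
    "MarkerConfig",
    "SampleSpec",
    "SimulationConfig",
    "SimulatedExperiment",
    "build_genome",
    "plant_clonal_architecture",
    "simulate_counts",
    "truth_bulk_segments",
    "subclone_segment_table",
]

MALIGNANT_KEY = "malignant"
NORMAL_CELL_TYPES = ("B", "CD8T", "CD4T", "NK", "Mono")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes and genome-ordered gene intervals.

    ``genes`` is a DataFrame with columns gene/chromosome/start/end, sorted by
    (chromosome rank, start); row position is the genome-wide gene order index.
    Coordinates are 1-based closed.
    """

    chromosomes: tuple  # of (name, length)
    genes: pd.DataFrame

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        g = self.genes
        if g["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in genome model")
        for chrom, sub in g.groupby("chromosome", sort=False):
            if chrom not in lengths:
                raise ValueError(f"gene on unknown chromosome {chrom!r}")
            if (sub["end"] > lengths[chrom]).any() or (sub["start"] < 1).any():
                raise ValueError(f"gene interval outside chromosome {chrom!r}")
            if not sub["start"].is_monotonic_increasing or sub["start"].duplicated().any():
                raise ValueError(f"gene starts not strictly increasing on {chrom!r}")

    @property
    def chrom_lengths(self) -> dict:
        return dict(self.chromosomes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def chrom_rank(self, name: str) -> int:
        for i, (c, _) in enumerate(self.chromosomes):
            if c == name:
                return i
        raise KeyError(name)


def build_genome(n_chromosomes: int, genes_per_chromosome: int, seed: int = 0) -> GenomeModel:
    """Random but reproducible genome: non-overlapping ordered gene intervals."""
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ValueError("n_chromosomes and genes_per_chromosome must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = []
    rows = []
    for ci in range(n_chromosomes):
        name = f"chr{ci + 1}"
        gene_len = rng.integers(2_000, 20_000, size=genes_per_chromosome)
        gap = rng.integers(5_000, 50_000, size=genes_per_chromosome)
        starts = np.cumsum(gap) + np.concatenate([[0], np.cumsum(gene_len[:-1])]) + 1
        ends = starts + gene_len - 1
        length = int(ends[-1] + rng.integers(5_000, 50_000))
        chroms.append((name, length))
        for gi, (s, e) in enumerate(zip(starts, ends)):
            rows.append((f"{name}_g{gi + 1:04d}", name, int(s), int(e)))
    genes = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])
    return GenomeModel(chromosomes=tuple(chroms), genes=genes)


# ---------------------------------------------------------------------------
# clonal architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNVEvent:
    """A departure from the diploid baseline on one chromosome (1-based closed)."""

    chromosome: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self):
        if not (0 <= self.copy_number <= 6):
            raise ValueError("copy_number must lie in [0, 6]")
        if self.copy_number == 2:
            raise ValueError("copy_number 2 is the diploid baseline, not an event")
        if self.start >= self.end:
            raise ValueError("event start must be < end")


@dataclass
class Subclone:
    """A tumor subpopulation: private events layered over an ancestor's profile.

    ``segments`` maps chromosome -> list of (start, end, copy_number) runs
    tiling the chromosome (the effective profile after inheritance); filled by
    :func:`plant_clonal_architecture`.
    """

    id: str
    parent: Optional[str]
    events: tuple  # private CNVEvents
    proportions: Mapping[str, float]
    segments: dict = field(default_factory=dict)


def _apply_event(runs: list, ev: CNVEvent) -> list:
    """Overwrite a sorted run list (tiling a chromosome) with one event."""
    out = []
    for s, e, c in runs:
        if e < ev.start or s > ev.end:
            out.append((s, e, c))
            continue
        if s < ev.start:
            out.append((s, ev.start - 1, c))
        if e > ev.end:
            out.append((ev.end + 1, e, c))
    out.append((ev.start, ev.end, ev.copy_number))
    out.sort()
    # merge adjacent equal-copy runs
    merged = [out[0]]
    for s, e, c in out[1:]:
        ps, pe, pc = merged[-1]
        if c == pc and s == pe + 1:
            merged[-1] = (ps, e, c)
        else:
            merged.append((s, e, c))
    return merged


def plant_clonal_architecture(
    genome: GenomeModel,
    spec: Sequence[tuple],
) -> list:
    """Build subclones from (id, parent, private events, proportions) tuples.

    Parents must precede children; a child's effective profile is its parent's
    profile with the private events overwriting any overlapped interval.
    Per-sample proportions must sum to 1 over all subclones (tol 1e-9).
    """
    lengths = genome.chrom_lengths
    by_id: dict = {}
    out = []
    for sid, parent, events, proportions in spec:
        if parent is not None and parent not in by_id:
            raise ValueError(f"parent {parent!r} of {sid!r} not defined before child")
        for ev in events:
            if ev.chromosome not in lengths:
                raise ValueError(f"event on unknown chromosome {ev.chromosome!r}")
            if ev.end > lengths[ev.chromosome]:
                raise ValueError(f"event {ev} exceeds chromosome bounds")
        if parent is None:
            segs = {c: [(1, L, 2)] for c, L in genome.chromosomes}
        else:
            segs = {c: list(v) for c, v in by_id[parent].segments.items()}
        for ev in events:
            segs[ev.chromosome] = _apply_event(segs[ev.chromosome], ev)
        sub = Subclone(id=sid, parent=parent, events=tuple(events),
                       proportions=dict(proportions), segments=segs)
        by_id[sid] = sub
        out.append(sub)
    samples = set()
    for sub in out:
        samples.update(sub.proportions)
    for sample in samples:
        tot = sum(sub.proportions.get(sample, 0.0) for sub in out)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"proportions for sample {sample!r} sum to {tot}, not 1")
    return out


def subclone_segment_table(subclone: Subclone, events_only: bool = True) -> pd.DataFrame:
    """The subclone's effective profile as a segment table (1-based closed)."""
    rows = []
    for chrom, runs in subclone.segments.items():
        for s, e, c in runs:
            if events_only and c == 2:
                continue
            rows.append((chrom, s, e, float(c)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "copy_number"])


def copy_number_per_gene(genome: GenomeModel, subclone: Subclone) -> np.ndarray:
    """Integer copy number of every gene (by midpoint) in the subclone."""
    cn = np.full(genome.n_genes, 2, dtype=int)
    genes = genome.genes
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    chrom_arr = genes["chromosome"].to_numpy()
    for chrom, runs in subclone.segments.items():
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        m = mid[mask]
        vals = np.full(m.shape, 2, dtype=int)
        for s, e, c in runs:
            vals[(m >= s) & (m <= e)] = c
        cn[mask] = vals
    return cn


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MarkerConfig:
    """Gene ids carrying the marker structure of the simulated tissue."""

    malignant_marker: str
    kappa_gene: str
    lambda_gene: str
    s_genes: tuple
    g2m_genes: tuple
    mito_genes: tuple
    cell_type_markers: Mapping[str, tuple]


def default_marker_config(genome: GenomeModel, seed: int = 0) -> MarkerConfig:
    """Deterministically assign marker roles to genes spread over the genome.

    The malignancy marker is placed on the 11th chromosome when one exists,
    mirroring CCND1's 11q13 locus.
    """
    rng = np.random.default_rng(seed)
    genes = genome.genes
    chrom_names = [c for c, _ in genome.chromosomes]
    marker_chrom = "chr11" if "chr11" in chrom_names else chrom_names[0]
    pool = list(genes["gene"])
    taken: set = set()

    def take(candidates, n):
        chosen = []
        for g in candidates:
            if g not in taken:
                chosen.append(g)
                taken.add(g)
            if len(chosen) == n:
                break
        if len(chosen) < n:
            raise ValueError("genome too small for default marker assignment")
        return tuple(chosen)

    on_marker_chrom = list(genes.loc[genes["chromosome"] == marker_chrom, "gene"])
    malignant_marker = take(on_marker_chrom or pool, 1)[0]
    kappa, lam = take(pool, 2)
    n = len(pool)
    scattered = [pool[i] for i in rng.permutation(n)]
    # sizes mirror the canonical S / G2M scoring lists (~43 and ~54 genes)
    s_genes = take(scattered, min(50, max(10, n // 40)))
    g2m_genes = take(scattered, min(50, max(10, n // 40)))
    mito_genes = take(scattered, min(10, max(2, n // 500)))
    cell_type_markers = {t: take(scattered, min(5, max(1, n // 1000)))
                         for t in NORMAL_CELL_TYPES}
    return MarkerConfig(
        malignant_marker=malignant_marker,
        kappa_gene=kappa,
        lambda_gene=lam,
        s_genes=s_genes,
        g2m_genes=g2m_genes,
        mito_genes=mito_genes,
        cell_type_markers=cell_type_markers,
    )


@dataclass
class SampleSpec:
    """Cell counts for one sample: normal cell types plus a total malignant count.

    ``s_fraction``/``g2m_fraction`` override the global cycling fractions for
    this sample (to plant a diagnosis -> relapse phase shift).
    """

    timepoint: str  # "diagnosis" | "relapse"
    n_cells: Mapping[str, int]  # population (cell type or "malignant") -> count
    s_fraction: Optional[float] = None
    g2m_fraction: Optional[float] = None


@dataclass
class SimulationConfig:
    samples: Mapping[str, SampleSpec] = field(default_factory=dict)
    baseline_shape: float = 0.4       # gamma shape of baseline gene means
    baseline_scale: float = 1.0
    libsize_meanlog: float = math.log(5_000.0)  # median ~5000 UMIs
    libsize_sdlog: float = 0.35
    dispersion: float = 2.0           # NB size parameter, shared across genes
    alpha: float = 1.0                # dosage exponent: mean ~ (c/2)**alpha
    eps0: float = 0.05                # homozygous-deletion floor
    marker_effect: float = 12.0       # malignancy-marker fold in malignant cells
    light_chain_ratio: float = 20.0   # restricted:excluded chain mean ratio
    cycle_multiplier: float = 3.0     # S / G2M program fold in assigned cells
    s_fraction: float = 0.15
    g2m_fraction: float = 0.15
    low_quality_fraction: float = 0.0  # planted low-quality (tiny library, high mito) cells
    seed: int = 0
    markers: Optional[MarkerConfig] = None

    def validate(self, genome: GenomeModel) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        for name, spec in self.samples.items():
            for pop, n in spec.n_cells.items():
                if n <= 0:
                    raise ValueError(f"cell count for {pop!r} in {name!r} must be positive")
        if self.markers is not None:
            ids = set(genome.genes["gene"])
            mk = self.markers
            every = {mk.malignant_marker, mk.kappa_gene, mk.lambda_gene}
            every.update(mk.s_genes, mk.g2m_genes, mk.mito_genes)
            for ms in mk.cell_type_markers.values():
                every.update(ms)
            missing = every - ids
            if missing:
                raise ValueError(f"marker genes absent from genome: {sorted(missing)[:5]}")


@dataclass
class SimulatedExperiment:
    """Counts plus per-cell truth labels and ground-truth segment tables."""

    counts: sp.csr_matrix          # cells x genes, integer
    cells: pd.DataFrame            # cell_id, sample, timepoint, population, malignant, phase, low_quality
    genes: pd.DataFrame            # gene, chromosome, start, end, is_mito + marker flags
    genome: GenomeModel
    subclones: list
    config: SimulationConfig
    truth_segments: Mapping[str, pd.DataFrame]   # subclone id -> event segment table
    truth_bulk: Mapping[str, pd.DataFrame]       # sample id -> expected bulk segment table


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _gene_indexer(genome: GenomeModel) -> Mapping[str, int]:
    return {g: i for i, g in enumerate(genome.genes["gene"])}


def simulate_counts(
    genome: GenomeModel,
    subclones: Sequence[Subclone],
    config: SimulationConfig,
) -> SimulatedExperiment:
    """Draw NB counts for every configured cell.

    Mean for cell i, gene g is ``libsize_i * rel_g * (c/2)**alpha`` times the
    cell's marker/program multipliers, where ``c`` is the gene's copy number in
    the cell's clone (2 in normal cells; c=0 replaced by the floor ``eps0``).
    """
    config.validate(genome)
    clone_ids = {s.id for s in subclones}
    for sample, sspec in config.samples.items():
        clash = (set(sspec.n_cells) - {MALIGNANT_KEY}) & clone_ids
        if clash:
            raise ValueError(
                f"sample {sample!r}: population names collide with subclone ids {sorted(clash)}"
            )
    rng = np.random.default_rng(config.seed)
    markers = config.markers or default_marker_config(genome, seed=config.seed)
    cfg = replace(config, markers=markers)
    cfg.validate(genome)

    idx = _gene_indexer(genome)
    n_genes = genome.n_genes
    base = rng.gamma(cfg.baseline_shape, cfg.baseline_scale, size=n_genes)
    base = np.maximum(base, 1e-6)
    rel = base / base.sum()
    # pin marker-role genes to defined baselines (in units of the mean gene)
    # so marker rules are exercisable regardless of the random baseline draw:
    # the malignancy marker is low outside tumor cells, light chains are solid
    # B-lineage genes, cell-type markers moderate.
    mean_rel = 1.0 / n_genes
    rel[idx[markers.malignant_marker]] = 0.5 * mean_rel
    rel[idx[markers.kappa_gene]] = 5.0 * mean_rel
    rel[idx[markers.lambda_gene]] = 5.0 * mean_rel
    for genes_t in markers.cell_type_markers.values():
        for g in genes_t:
            rel[idx[g]] = 2.0 * mean_rel
    # cycle genes are robustly expressed proliferation markers, not tail
    # genes; spread them over a moderate-to-high expression range
    cyc = list(markers.s_genes) + list(markers.g2m_genes)
    cyc_levels = np.linspace(1.0, 4.0, len(cyc))
    for g, lev in zip(cyc, rng.permutation(cyc_levels)):
        rel[idx[g]] = lev * mean_rel
    rel = rel / rel.sum()

    # per-gene copy-dosage factor per subclone
    dosage = {}
    for sub in subclones:
        cn = copy_number_per_gene(genome, sub)
        eff = np.where(cn == 0, cfg.eps0, cn).astype(float)
        dosage[sub.id] = (eff / 2.0) ** cfg.alpha

    s_idx = np.array([idx[g] for g in markers.s_genes], dtype=int)
    g2m_idx = np.array([idx[g] for g in markers.g2m_genes], dtype=int)
    mito_idx = np.array([idx[g] for g in markers.mito_genes], dtype=int)
    mk_i = idx[markers.malignant_marker]
    kap_i = idx[markers.kappa_gene]
    lam_i = idx[markers.lambda_gene]

    # population-level relative-expression multipliers
    ratio = cfg.light_chain_ratio

    def pop_multiplier(pop: str) -> np.ndarray:
        m = np.ones(n_genes)
        if pop in dict((s.id, s) for s in subclones):
            m[mk_i] *= cfg.marker_effect
            m[kap_i] *= math.sqrt(ratio) * 2.0   # restricted chain high
            m[lam_i] *= 2.0 / math.sqrt(ratio)   # excluded chain low -> 20:1 ratio
        elif pop == "B":
            m[kap_i] *= 2.0
            m[lam_i] *= 2.0
            for g in markers.cell_type_markers.get("B", ()):
                m[idx[g]] *= cfg.marker_effect
        else:
            for g in markers.cell_type_markers.get(pop, ()):
                m[idx[g]] *= cfg.marker_effect
        return m

    sub_by_id = {s.id: s for s in subclones}
    blocks = []
    meta_rows = []
    cell_counter = 0
    r = cfg.dispersion
    for sample, sspec in cfg.samples.items():
        for pop, n_cells in sspec.n_cells.items():
            if pop == MALIGNANT_KEY:
                props = np.array([sub_by_id[s.id].proportions.get(sample, 0.0)
                                  for s in subclones])
                if props.sum() <= 0:
                    raise ValueError(f"no subclone proportions defined for sample {sample!r}")
                draws = rng.multinomial(n_cells, props / props.sum())
                pops = [(subclones[i].id, int(k)) for i, k in enumerate(draws) if k > 0]
            else:
                pops = [(pop, n_cells)]
            for pop_name, n in pops:
                malignant = pop_name in sub_by_id
                mult = pop_multiplier(pop_name)
                d = dosage[pop_name] if malignant else np.ones(n_genes)
                relpop = rel * mult * d

                lib = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog, size=n)
                lowq = rng.random(n) < cfg.low_quality_fraction
                lib = np.where(lowq, lib * 0.05, lib)

                s_frac = sspec.s_fraction if sspec.s_fraction is not None else cfg.s_fraction
                g2m_frac = sspec.g2m_fraction if sspec.g2m_fraction is not None else cfg.g2m_fraction
                phase = rng.choice(
                    ["G1", "S", "G2M"], size=n,
                    p=[1 - s_frac - g2m_frac, s_frac, g2m_frac],
                )
                mean = np.outer(lib, relpop)
                mean[np.ix_(phase == "S", s_idx)] *= cfg.cycle_multiplier
                mean[np.ix_(phase == "G2M", g2m_idx)] *= cfg.cycle_multiplier
                if lowq.any():
                    mean[np.ix_(lowq, mito_idx)] *= 10.0

                lam_mat = rng.gamma(r, mean / r)
                counts = rng.poisson(lam_mat)
                blocks.append(sp.csr_matrix(counts))
                for j in range(n):
                    meta_rows.append((
                        f"cell{cell_counter + j:06d}", sample, sspec.timepoint,
                        pop_name, malignant, phase[j], bool(lowq[j]),
                    ))
                cell_counter += n

    counts = sp.vstack(blocks, format="csr")
    cells = pd.DataFrame(meta_rows, columns=[
        "cell_id", "sample", "timepoint", "population", "malignant", "phase", "low_quality",
    ])

    genes = genome.genes.copy()
    genes["is_mito"] = genes["gene"].isin(markers.mito_genes)
    genes["is_malignant_marker"] = genes["gene"] == markers.malignant_marker
    genes["is_kappa"] = genes["gene"] == markers.kappa_gene
    genes["is_lambda"] = genes["gene"] == markers.lambda_gene
    genes["is_s_gene"] = genes["gene"].isin(markers.s_genes)
    genes["is_g2m_gene"] = genes["gene"].isin(markers.g2m_genes)

    truth_segments = {s.id: subclone_segment_table(s) for s in subclones}
    truth_bulk = {
        sample: truth_bulk_segments(genome, subclones, sample)
        for sample in cfg.samples
    }
    return SimulatedExperiment(
        counts=counts, cells=cells, genes=genes, genome=genome,
        subclones=list(subclones), config=cfg,
        truth_segments=truth_segments, truth_bulk=truth_bulk,
    )


def truth_bulk_segments(
    genome: GenomeModel,
    subclones: Sequence[Subclone],
    sample: str,
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Expected bulk copy profile of the malignant compartment of one sample.

    Per bin, expected copy number = sum over subclones of proportion times the
    subclone's copy number in the bin; constant-value runs are merged.
    """
    props = {s.id: s.proportions.get(sample) for s in subclones}
    if all(v is None for v in props.values()):
        raise ValueError(f"sample {sample!r} unknown to every subclone")
    props = {k: (v or 0.0) for k, v in props.items()}

    rows = []
    for chrom, length in genome.chromosomes:
        n_bins = (length + bin_size - 1) // bin_size
        expected = np.zeros(n_bins)
        for sub in subclones:
            p = props[sub.id]
            vals = np.full(n_bins, 2.0)
            for s, e, c in sub.segments.get(chrom, [(1, length, 2)]):
                b0 = (s - 1) // bin_size
                b1 = (e - 1) // bin_size
                # a run dominates a bin when it covers the bin midpoint
                for b in range(b0, b1 + 1):
                    mid = b * bin_size + bin_size // 2 + 1
                    if s <= mid <= e:
                        vals[b] = c
            expected += p * vals
        # merge constant runs
        start_bin = 0
        for b in range(1, n_bins + 1):
            if b == n_bins or not np.isclose(expected[b], expected[start_bin]):
                seg_start = start_bin * bin_size + 1
                seg_end = min(b * bin_size, length)
                rows.append((chrom, seg_start, seg_end, float(expected[start_bin])))
                start_bin = b
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "copy_number"])
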