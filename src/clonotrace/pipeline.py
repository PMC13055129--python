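"""End-to-end orchestration: simulate/load -> QC -> cluster -> malignant ->
CNV -> subclones -> concordance -> statistics.

Every stage persists its table artifacts to the output directory, a single
seed controls all stochastic stages, and two runs with the same config
produce byte-identical output tables.  Stage failures abort with the stage
name and context.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnvmod
from . import io as iomod
from .clones import (SubcloneClusterer, classify_resistance, composition_table,
                     match_precursor, validate_subclone_cnv)
from .concordance import bin_segments, normalize_baseline, spearman_concordance
from .config import PipelineConfig
from .malignant import call_malignant, score_cell_types
from .preprocess import (QCThresholds, SNNLeidenClustering, VariancePCA,
                         VSTGeneSelector, apply_thresholds, compute_qc,
                         drop_low_quality_clusters, log_normalize, scale_genes)
from .simulate import (CNVEvent, SimulatedExperiment, build_genome,
                       plant_clonal_architecture, simulate_counts)
from .stats import (assign_phase, module_score, phase_shift_test,
                    preranked_gsea, significant_genes, wilcoxon_de)

__all__ = ["StageError", "RunReport", "build_experiment", "run_pipeline"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """Per-stage record counts, parameter echo and headline results."""

    config: dict
    counts: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {"config": self.config, "counts": self.counts,
                   "results": self.results, "warnings": self.warnings}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def build_experiment(cfg: PipelineConfig) -> SimulatedExperiment:
    """Construct the configured synthetic experiment (genome, clones, counts)."""
    sim = cfg.simulate
    genome = build_genome(sim.n_chromosomes, sim.genes_per_chromosome, seed=cfg.seed)
    spec = []
    for sc in sim.subclones:
        events = []
        for e in sc["events"]:
            chrom = e["chromosome"]
            sub = genome.genes[genome.genes["chromosome"] == chrom]
            if "gene_span" in e:
                g0, g1 = e["gene_span"]
                start = int(sub.iloc[g0 - 1]["start"])
                end = int(sub.iloc[g1 - 1]["end"])
            else:
                start, end = int(e["start"]), int(e["end"])
            events.append(CNVEvent(chrom, start, end, int(e["copy_number"])))
        spec.append((sc["id"], sc.get("parent"), events, sc["proportions"]))
    subclones = plant_clonal_architecture(genome, spec)
    return simulate_counts(genome, subclones, sim.simulation_config(seed=cfg.seed))


def _mean_state_segments(states: np.ndarray, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean copy state as a gene-interval segment table."""
    mean_state = states.mean(axis=0)
    return pd.DataFrame({
        "chromosome": genes["chromosome"].to_numpy(),
        "start": genes["start"].to_numpy(),
        "end": genes["end"].to_numpy(),
        "copy_number": mean_state,
    })


def run_pipeline(cfg: PipelineConfig, out_dir) -> RunReport:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg.to_dict())
    rep_counts, rep_results = report.counts, report.results

    # ----- simulate or load ------------------------------------------------
    stage = "simulate"
    try:
        if cfg.input_dir:
            counts, genes, barcodes = iomod.read_counts_10x(cfg.input_dir)
            cells = pd.read_csv(Path(cfg.input_dir) / "cells.tsv", sep="\t")
            exp = None
            chrom_lengths = {
                c: int(genes.loc[genes["chromosome"] == c, "end"].max())
                for c in genes["chromosome"].unique()
            }
        else:
            exp = build_experiment(cfg)
            counts, genes, cells = exp.counts, exp.genes, exp.cells
            chrom_lengths = exp.genome.chrom_lengths
            iomod.write_counts_10x(out / "counts", counts, genes, cells["cell_id"])
            cells.to_csv(out / "counts" / "cells.tsv", sep="\t", index=False)
            for sid, seg in exp.truth_segments.items():
                iomod.write_segments(out / f"truth_subclone_{sid}.tsv", seg)
            for sample, seg in exp.truth_bulk.items():
                iomod.write_segments(out / f"truth_bulk_{sample}.tsv", seg)
        rep_counts["cells_in"] = int(counts.shape[0])
        rep_counts["genes_in"] = int(counts.shape[1])
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ----- QC --------------------------------------------------------------
    stage = "qc"
    try:
        thresholds = QCThresholds(
            min_umi=cfg.qc.min_umi, max_umi=cfg.qc.max_umi,
            min_genes=cfg.qc.min_genes, max_genes=cfg.qc.max_genes,
            max_mito=cfg.qc.max_mito, cluster_lowq_cutoff=cfg.qc.cluster_lowq_cutoff,
        )
        qc = apply_thresholds(compute_qc(counts, genes["is_mito"]), thresholds)
        if qc["low_quality"].all():
            raise ValueError("every cell fails the QC thresholds; check bounds")
        ok = ~qc["degenerate"].to_numpy()
        rep_counts["cells_after_degenerate"] = int(ok.sum())
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ----- normalize + cluster + low-quality-cluster rule ------------------
    stage = "cluster"
    try:
        counts_ok = counts[ok]
        cells_ok = cells.loc[ok].reset_index(drop=True)
        qc_ok = qc.loc[ok].reset_index(drop=True)
        norm = log_normalize(counts_ok)
        hvg = VSTGeneSelector(n_top=min(cfg.cluster.n_hvg, counts_ok.shape[1])).fit(counts_ok)
        scaled = scale_genes(norm[:, hvg.support_])
        emb = VariancePCA(variance_fraction=cfg.cluster.variance_fraction).fit_transform(scaled)
        labels = SNNLeidenClustering(
            k=cfg.cluster.k, resolution=cfg.cluster.resolution, seed=cfg.seed
        ).fit_predict(emb)
        keep = drop_low_quality_clusters(
            labels, qc_ok["low_quality"], cfg.qc.cluster_lowq_cutoff
        )
        rep_counts["cells_retained"] = int(keep.sum())
        if not keep.any():
            raise ValueError("no cells retained after the low-quality-cluster rule")
        cells_r = cells_ok.loc[keep].reset_index(drop=True)
        norm_r = norm[keep]
        labels_r = labels[keep]
        qc_out = pd.concat([cells_ok, qc_ok.drop(columns="degenerate")], axis=1)
        qc_out["cluster"] = labels
        qc_out["retained"] = keep
        qc_out.to_csv(out / "cells_qc.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ----- malignant-cell identification -----------------------------------
    stage = "malignant"
    try:
        if exp is not None:
            mk = exp.config.markers
            marker_map = {t: list(g) for t, g in mk.cell_type_markers.items()}
            marker_gene, kappa_gene, lambda_gene = (
                mk.malignant_marker, mk.kappa_gene, mk.lambda_gene)
        else:
            # loaded data: marker roles come from the features table flags
            marker_gene = genes.loc[genes["is_malignant_marker"], "gene"].iloc[0]
            kappa_gene = genes.loc[genes["is_kappa"], "gene"].iloc[0]
            lambda_gene = genes.loc[genes["is_lambda"], "gene"].iloc[0]
            marker_map = {"B": [kappa_gene, lambda_gene]}
        types = score_cell_types(norm_r, labels_r, marker_map, genes["gene"])
        calls = call_malignant(
            norm_r, labels_r, genes["gene"],
            marker_gene, kappa_gene, lambda_gene,
            expr_threshold=cfg.malignant.expr_threshold,
            fraction_threshold=cfg.malignant.fraction_threshold,
            restriction_threshold=cfg.malignant.restriction_threshold,
        )
        calls["cell_type"] = calls["cluster"].map(types)
        calls.to_csv(out / "malignant_calls.tsv", sep="\t", index=False)
        mal_clusters = set(calls.loc[calls["malignant"], "cluster"])
        mal_mask = np.isin(labels_r, list(mal_clusters))
        rep_counts["malignant_cells"] = int(mal_mask.sum())
        if mal_mask.sum() < 2:
            raise ValueError("fewer than 2 malignant cells called")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ----- CNV inference ----------------------------------------------------
    stage = "cnv"
    try:
        caller = cnvmod.CNVCaller(
            gene_chromosomes=genes["chromosome"].to_numpy(),
            min_mean=cfg.cnv.min_mean, clip=cfg.cnv.clip, window=cfg.cnv.window,
            transition=cfg.cnv.transition, eps0=cfg.cnv.eps0,
            sigma_floor=cfg.cnv.sigma_floor,
        )
        caller.fit(norm_r, ~mal_mask)
        smoothed = caller.transform(norm_r)
        mal_smoothed = smoothed[mal_mask]
        mal_states = caller.predict_from_smoothed(mal_smoothed)
        rep_counts["genes_kept_cnv"] = int(caller.kept_genes_.size)
        kept_genes = genes.iloc[caller.kept_genes_].reset_index(drop=True)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ----- subclones --------------------------------------------------------
    stage = "clones"
    try:
        mal_cells = cells_r.loc[mal_mask].reset_index(drop=True)
        clusterer = SubcloneClusterer(
            method=cfg.clones.method, k=cfg.clones.k,
            resolution=cfg.clones.resolution, n_clusters=cfg.clones.n_clusters,
            min_cluster_size=cfg.clones.min_cluster_size, seed=cfg.seed,
        )
        sub_labels = np.array([f"S{l}" for l in clusterer.fit_predict(mal_smoothed)])
        assignment = mal_cells[["cell_id", "sample", "timepoint"]].copy()
        assignment["subclone"] = sub_labels
        assignment.to_csv(out / "subclone_assignment.tsv", sep="\t", index=False)
        rep_counts["n_subclones"] = int(len(set(sub_labels)))

        comp = composition_table(sub_labels, mal_cells["sample"])
        timepoints = dict(zip(cells_r["sample"], cells_r["timepoint"]))
        resistance = classify_resistance(comp, timepoints, theta=cfg.clones.theta)
        comp = comp.merge(resistance[["subclone", "label", "ratio"]], on="subclone")
        comp.to_csv(out / "composition.tsv", sep="\t", index=False)
        resistance.to_csv(out / "resistance.tsv", sep="\t", index=False)

        seg_all = cnvmod.states_to_segments(mal_states, kept_genes, sub_labels)
        iomod.write_segments(out / "subclone_segments.tsv", seg_all)

        # per-timepoint binned profiles for precursor matching
        bin_size = cfg.concordance.bin_size
        dg_mask = (mal_cells["timepoint"] == "diagnosis").to_numpy()
        profiles = {}
        for tp_name, tp_mask in (("diagnosis", dg_mask), ("relapse", ~dg_mask)):
            for sub in np.unique(sub_labels[tp_mask]):
                m = tp_mask & (sub_labels == sub)
                if m.sum() < 3:
                    continue
                segs = _mean_state_segments(mal_states[m], kept_genes)
                profiles[(tp_name, sub)] = bin_segments(segs, chrom_lengths, bin_size)
        relapse_profiles = {s: p for (tp, s), p in profiles.items() if tp == "relapse"}
        rel_comp = comp[comp["sample"].map(timepoints) == "relapse"]
        dominant_relapse = rel_comp.groupby("subclone")["proportion"].mean().idxmax()
        matches = []
        for (tp, sub), prof in profiles.items():
            if tp != "diagnosis":
                continue
            m = match_precursor(prof, relapse_profiles,
                                min_score=cfg.clones.min_match_score)
            matches.append((sub, m.best_relapse_subclone, m.score, m.shared_bins, m.call))
        match_df = pd.DataFrame(matches, columns=[
            "diagnostic_subclone", "best_relapse_subclone", "score", "shared_bins", "call",
        ]).sort_values("diagnostic_subclone")
        match_df.to_csv(out / "precursor_matches.tsv", sep="\t", index=False)
        rep_results["dominant_relapse_subclone"] = str(dominant_relapse)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ----- concordance vs truth bulk ---------------------------------------
    stage = "concordance"
    try:
        conc_rows = []
        if exp is not None:
            # subclone-proportion-weighted inferred profile per sample:
            # majority-state profile of each subclone, weighted by its share
            # of the sample's malignant cells
            sub_binned = {}
            for sub in np.unique(sub_labels):
                segs = seg_all[seg_all["group"] == sub]
                sub_binned[sub] = bin_segments(
                    segs.drop(columns="group"), chrom_lengths, cfg.concordance.bin_size)
            for sample in exp.config.samples:
                m = (mal_cells["sample"] == sample).to_numpy()
                if m.sum() < 3:
                    continue
                weights = pd.Series(sub_labels[m]).value_counts(normalize=True)
                inferred_prof = sum(w * sub_binned[sub] for sub, w in weights.items())
                prof_inf = normalize_baseline(inferred_prof)
                prof_truth = normalize_baseline(
                    bin_segments(exp.truth_bulk[sample], chrom_lengths,
                                 cfg.concordance.bin_size))
                res = spearman_concordance(prof_inf, prof_truth)
                conc_rows.append((sample, res.rho, res.n_bins, res.defined))
                # validate inferred subclone events against the truth bulk
                for sub in np.unique(sub_labels[m]):
                    segs = seg_all[(seg_all["group"] == sub)
                                   & (seg_all["copy_number"] != 2)]
                    validated = validate_subclone_cnv(segs, exp.truth_bulk[sample], tol=0.05)
                    validated.to_csv(out / f"validated_{sample}_{sub}.tsv",
                                     sep="\t", index=False)
        conc = pd.DataFrame(conc_rows, columns=["sample", "rho", "n_bins", "defined"])
        conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
        if not conc.empty:
            rep_results["concordance_rho"] = {
                r["sample"]: r["rho"] for _, r in conc.iterrows()}
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ----- downstream statistics -------------------------------------------
    stage = "stats"
    try:
        res_subs = set(resistance.loc[resistance["label"] == "resistant", "subclone"])
        sen_subs = set(resistance.loc[resistance["label"] == "sensitive", "subclone"])
        dg_cells = (mal_cells["timepoint"] == "diagnosis").to_numpy()
        in_res = np.isin(sub_labels, list(res_subs)) & dg_cells
        in_sen = np.isin(sub_labels, list(sen_subs)) & dg_cells
        mal_norm = norm_r[mal_mask]
        de = pd.DataFrame()
        if in_res.sum() >= 3 and in_sen.sum() >= 3:
            de = wilcoxon_de(
                mal_norm, in_res, in_sen, gene_names=genes["gene"],
                min_lfc=cfg.de.min_lfc, min_frac=cfg.de.min_frac,
            )
            de["significant"] = de["gene"].isin(significant_genes(
                de, cfg.de.max_adj_p, cfg.de.min_abs_l2fc, cfg.de.sig_min_frac))
        de.to_csv(out / "de.tsv", sep="\t", index=False)
        rep_counts["genes_tested_de"] = int(len(de))
        rep_counts["genes_significant_de"] = int(de["significant"].sum()) if len(de) else 0

        enr = pd.DataFrame()
        if len(de) >= 10 and exp is not None:
            ranked = de.set_index("gene")["l2fc"]
            ranked = ranked[ranked.abs() > cfg.gsea.rank_min_l2fc]
            mk = exp.config.markers
            sets = {"S_PROGRAM": list(mk.s_genes), "G2M_PROGRAM": list(mk.g2m_genes)}
            if len(ranked) >= 2 * cfg.gsea.min_size:
                enr = preranked_gsea(ranked, sets, n_perm=cfg.gsea.n_perm,
                                     seed=cfg.seed, min_size=cfg.gsea.min_size)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        # cell-cycle scoring on all retained cells
        s_set = genes.loc[genes["is_s_gene"], "gene"].tolist()
        g2m_set = genes.loc[genes["is_g2m_gene"], "gene"].tolist()
        s_scores = module_score(norm_r, s_set, genes["gene"],
                                n_bins=cfg.cycle.n_bins,
                                n_control=cfg.cycle.n_control, seed=cfg.seed)
        g2m_scores = module_score(norm_r, g2m_set, genes["gene"],
                                  n_bins=cfg.cycle.n_bins,
                                  n_control=cfg.cycle.n_control, seed=cfg.seed + 1)
        phases = assign_phase(s_scores, g2m_scores)
        ph = cells_r[["cell_id", "sample", "timepoint"]].copy()
        ph["s_score"], ph["g2m_score"], ph["phase"] = s_scores, g2m_scores, phases
        ph.to_csv(out / "phases.tsv", sep="\t", index=False)

        mal_ph = ph.loc[mal_mask]
        tab = pd.crosstab(mal_ph["timepoint"], mal_ph["phase"])
        if set(tab.index) == {"diagnosis", "relapse"}:
            ordered = tab.reindex(index=["diagnosis", "relapse"]).fillna(0)
            shift = phase_shift_test({"patient": ordered.to_numpy()})
            shift.to_csv(out / "phase_shift.tsv", sep="\t", index=False)
            rep_results["phase_shift_p"] = float(shift["pvalue"].iloc[0])
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    report.to_json(out / "report.json")
    return report
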