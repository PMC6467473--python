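"""End-to-end orchestration of the capacitation trajectory analysis.

``run_pipeline`` executes, from one configuration: expressed-gene
filtering, variable-gene detection, the time-course DE union, per-cell-line
soft clustering with semantic labels, cluster correspondence between cell
lines, stage signatures and fractional identity against the embryo
reference, and the sample-level correlation/PCA summaries. Every
intermediate is written as TSV next to a machine-readable run manifest
(config hash, seed, gene/sample counts after every filter), so any number
in the final outputs is reproducible from the manifest alone.

``make_demo`` writes a complete synthetic input bundle with planted-truth
sidecars on which the pipeline runs end to end.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .correspondence import SCHEMES, dataset_correspondence
from .errors import ConfigError, LabelingError, PipelineStageError
from .expression_io import (
    ExpressionMatrix,
    filter_expressed,
    harmonize_orthologs,
    read_expression,
    read_gmt,
    read_ortholog_table,
    read_sample_sheet,
    to_log2,
    write_expression,
    write_gmt,
    write_ortholog_table,
    write_sample_sheet,
)
from .soft_clustering import (
    cluster_profiles,
    cluster_set_enrichment,
    elbow_select_k,
    label_clusters,
    standardize_profiles,
    write_membership,
)
from .stage_identity import build_signatures, identity_timecourse
from .synthetic_data import (
    generate_gene_sets,
    generate_ortholog_map,
    generate_stage_reference,
    generate_timecourse,
)
from .trajectory_stats import joint_projection, pca_project, sample_correlation
from .variable_genes import fit_cv2_trend, select_variable_genes, timecourse_de_union

log = logging.getLogger("capacitrack")

DEMO_TIMEPOINTS = ("d0", "d1", "d2", "d3", "d7", "d10")
DEMO_STAGES = ("ICM", "EPI", "post-E", "post-L")


def make_demo(seed: int, out_dir: str | Path = "demo") -> Path:
    """Write a synthetic input bundle: a two-cell-line bulk time course
    (6 timepoints x 3 replicates), a 4-stage embryo-like reference in its
    own gene namespace, a 90% 1-to-1 ortholog map, GMT gene sets enriched
    for one archetype, planted-truth sidecars and a ready config.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_genes = 1200
    matrix, sheet, truth = generate_timecourse(
        n_genes=n_genes, n_variable=400, timepoints=DEMO_TIMEPOINTS,
        n_replicates=3, n_cell_lines=2, noise_cv=0.15, seed=seed,
    )
    write_expression(matrix, out / "timecourse.tsv")
    write_sample_sheet(sheet, out / "samples.tsv")
    truth.to_json(out / "timecourse_truth.json")

    ref_genes = [f"MF_{g}" for g in matrix.gene_ids]
    reference, ref_sheet = generate_stage_reference(
        n_genes=n_genes, stages=DEMO_STAGES, cells_per_stage=15,
        separation=3.0, noise_cv=0.2, seed=seed + 1, gene_ids=ref_genes,
    )
    write_expression(reference, out / "reference.tsv")
    write_sample_sheet(ref_sheet, out / "reference_samples.tsv")

    orthologs = generate_ortholog_map(
        matrix.gene_ids, ref_genes, frac_one_to_one=0.9, seed=seed + 2
    )
    write_ortholog_table(orthologs, out / "orthologs.tsv")

    sets = generate_gene_sets(
        matrix.gene_ids, n_sets=5, set_size=40,
        enriched_cluster="early_down", gene_archetype=truth.gene_archetype,
        seed=seed + 3,
    )
    write_gmt(sets, out / "genesets.gmt")

    cfg = PipelineConfig(
        timecourse=str(out / "timecourse.tsv"),
        sample_sheet=str(out / "samples.tsv"),
        reference=str(out / "reference.tsv"),
        reference_sheet=str(out / "reference_samples.tsv"),
        orthologs=str(out / "orthologs.tsv"),
        gene_sets=str(out / "genesets.gmt"),
        out_dir=str(out / "run"),
        seed=seed,
    )
    cfg.to_yaml(out / "config.yaml")
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage failure raises :class:`PipelineStageError` carrying the stage
    name, after a partial manifest has been written.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": json.loads(json.dumps(config.__dict__, default=list)),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "counts": {},
        "stages_completed": [],
        "warnings": [],
    }

    def finish_stage(name: str) -> None:
        manifest["stages_completed"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    stage = "load"
    try:
        config.require_inputs("timecourse", "sample_sheet")
        matrix = read_expression(config.timecourse, unit="fpkm")
        sheet = read_sample_sheet(config.sample_sheet)
        sheet.check_matches(matrix)
        manifest["counts"]["genes_input"] = matrix.n_genes
        manifest["counts"]["samples_input"] = matrix.n_samples
        finish_stage(stage)

        stage = "filter_expressed"
        expressed = filter_expressed(matrix, config.min_fpkm, config.min_samples)
        manifest["counts"]["genes_expressed"] = expressed.n_genes
        log.info("expressed genes: %d / %d", expressed.n_genes, matrix.n_genes)
        finish_stage(stage)

        stage = "variable_genes"
        fit = fit_cv2_trend(expressed)
        hvg = select_variable_genes(fit, config.hvg_min_log2fpkm, config.hvg_min_excess)
        fit.table.to_csv(out / "cv2_fit.tsv", sep="\t", index_label="gene_id")
        pd.Series(hvg, name="gene_id").to_csv(out / "hvg.tsv", sep="\t", index=False)
        manifest["counts"]["genes_variable"] = len(hvg)
        manifest["cv2_fit"] = {"a0": fit.a0, "a1": fit.a1, "n_fitted": fit.n_fitted}
        finish_stage(stage)

        stage = "timecourse_de"
        de_genes = timecourse_de_union(expressed, sheet, config.alpha, config.min_fc)
        pd.Series(de_genes, name="gene_id").to_csv(out / "de_union.tsv", sep="\t", index=False)
        manifest["counts"]["genes_de_union"] = len(de_genes)
        log.info("DE union: %d genes", len(de_genes))
        finish_stage(stage)

        stage = "cluster"
        log2m = to_log2(expressed, config.pseudocount)
        cluster_genes = de_genes if de_genes else hvg
        log2_sub = log2m.subset_genes(cluster_genes)
        memberships = {}
        for line in sheet.cell_lines():
            prof = standardize_profiles(log2_sub, sheet, cell_line=line)
            if config.k == "auto":
                lo, hi = config.k_range
                elbow = elbow_select_k(
                    prof.profiles, range(lo, hi + 1), m=config.m,
                    n_starts=config.n_starts, seed=config.seed,
                )
                elbow.table.to_csv(out / f"elbow_{line}.tsv", sep="\t")
                k = elbow.k
                if elbow.low_confidence:
                    manifest["warnings"].append(f"elbow low-confidence for {line}")
            else:
                k = int(config.k)
            mm = cluster_profiles(
                prof.profiles, k, m=config.m, n_starts=config.n_starts,
                seed=config.seed,
            )
            if k == 5:
                try:
                    mm = label_clusters(mm)
                except LabelingError as e:
                    manifest["warnings"].append(f"labeling failed for {line}: {e}")
            write_membership(mm, out / f"membership_{line}.tsv",
                             out / f"centroids_{line}.tsv")
            manifest["counts"][f"genes_clustered_{line}"] = len(mm.gene_ids)
            manifest["counts"][f"k_{line}"] = k
            memberships[line] = mm
        finish_stage(stage)

        stage = "correspondence"
        lines = sheet.cell_lines()
        if len(lines) >= 2:
            scheme = SCHEMES.get(config.scheme)
            if scheme is None:
                raise ConfigError(f"unknown scheme preset {config.scheme!r}")
            res = dataset_correspondence(
                memberships[lines[0]], memberships[lines[1]], scheme
            )
            res.verdicts.to_csv(out / "correspondence_verdicts.tsv", sep="\t", index=False)
            manifest["correspondence"] = {
                "n_compared": res.n_compared,
                "frac_same": res.frac_same,
                "frac_same_or_similar": res.frac_same_or_similar,
            }
        finish_stage(stage)

        stage = "correlation_pca"
        corr = sample_correlation(log2m)
        corr.matrix.to_csv(out / "sample_correlation.tsv", sep="\t")
        pca_genes = [g for g in cluster_genes if g in set(log2m.gene_ids)]
        n_comp = min(3, len(pca_genes), log2m.n_samples - 1)
        pca = pca_project(log2m, gene_subset=pca_genes, n_components=n_comp)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample")
        manifest["pca_explained_variance"] = pca.explained_variance_ratio.tolist()
        finish_stage(stage)

        stage = "stage_identity"
        if config.reference:
            config.require_inputs("reference", "reference_sheet")
            reference = read_expression(config.reference, unit="fpkm")
            ref_sheet = read_sample_sheet(config.reference_sheet)
            if config.orthologs:
                table = read_ortholog_table(config.orthologs)
                tc_h, ref_h = harmonize_orthologs(matrix, reference, table)
            else:
                table = None
                shared = [g for g in matrix.gene_ids if g in set(reference.gene_ids)]
                tc_h, ref_h = matrix.subset_genes(shared), reference.subset_genes(shared)
            manifest["counts"]["genes_harmonized"] = tc_h.n_genes
            # harmonized rows are aligned pairwise; move the reference into
            # the time-course gene namespace once and for all
            ref_h = ExpressionMatrix(
                ref_h.values.set_axis(tc_h.values.index, axis=0), ref_h.unit
            )
            sig_genes = [g for g in tc_h.gene_ids if g in set(cluster_genes)]
            signatures = build_signatures(ref_h, ref_sheet, config.stages,
                                          genes=sig_genes)
            _, summary = identity_timecourse(tc_h, sheet, signatures)
            summary.to_csv(out / "stage_fractions.tsv", sep="\t", index=False)
            manifest["counts"]["genes_signature"] = len(signatures.gene_ids)

            log2_ref = to_log2(ref_h, config.pseudocount)
            log2_tc = to_log2(tc_h, config.pseudocount)
            joint = joint_projection(
                log2_tc, log2_ref, ortholog_table=None,
                gene_subset=sig_genes,
                n_components=min(3, log2_tc.n_samples + log2_ref.n_samples - 1,
                                 len(sig_genes)),
            )
            scores = joint.pca.scores.copy()
            scores["origin"] = joint.origin
            scores.to_csv(out / "joint_pca_scores.tsv", sep="\t", index_label="sample")
        finish_stage(stage)

        stage = "enrichment"
        if config.gene_sets:
            sets = read_gmt(config.gene_sets)
            line = sheet.cell_lines()[0]
            mm = memberships[line]
            enr = cluster_set_enrichment(mm, sets, universe=mm.gene_ids)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        finish_stage(stage)
    except PipelineStageError:
        raise
    except Exception as e:
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineStageError(stage, str(e)) from e

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
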