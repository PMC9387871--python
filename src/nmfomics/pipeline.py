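"""End-to-end pipeline: read inputs, preprocess, factorize, and run every
downstream stage, writing diff-able TSV tables (config hash + seed in a
'#'-header) to an output directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import feature_axis, mqtl, network, sample_axis
from .containers import CPG, GENE
from .io import (PipelineConfig, read_annotations, read_beta_matrix,
                 read_expression_matrix, read_gmt, read_sample_sheet, write_table)
from .nmf import nmf_fit
from .preprocess import (beta_to_m, concatenate_and_scale, mean_variance_filter,
                         normalize_expression)

log = logging.getLogger("nmfomics")

__all__ = ["run_pipeline", "PipelineError", "CORE_TABLES"]

CORE_TABLES = [
    "H.tsv", "W.tsv", "factor_tests.tsv", "auc_report.tsv", "clusters.tsv",
    "selections.tsv", "enrichment.tsv", "edges.tsv", "mqtl_summary.tsv",
    "replication.tsv",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


STAGES = ("read", "preprocess", "factorize", "samples", "features",
          "network", "replication", "mqtl")


def run_pipeline(config: PipelineConfig, inputs: dict, outdir,
                 upto: str = "mqtl") -> dict:
    """Run the stage chain (optionally stopping at ``upto``) and write tables.

    ``inputs`` maps: expression, beta, sheet, gene_bed, cpg_manifest and
    optionally gmt, validation_expression, validation_beta — all file paths.
    Returns a dict table-name -> path.  On failure an ``INCOMPLETE`` marker
    is left in ``outdir`` and a :class:`PipelineError` names the stage.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("pipeline running\n")
    header = {"config_hash": config.hash(), "seed": config.seed}
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = True):
        path = outdir / name
        write_table(df, path, header=header, index=index)
        written[name] = path

    try:
        _run(config, inputs, header, emit, upto)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("unknown", exc) from exc
    else:
        marker.unlink(missing_ok=True)
    return written


def _run(config: PipelineConfig, inputs: dict, header: dict, emit,
         upto: str = "mqtl") -> None:
    stop_after = STAGES.index(upto)

    def done(stage: str) -> bool:
        return STAGES.index(stage) >= stop_after

    # ---- read ------------------------------------------------------------ #
    @_stage("read")
    def _read():
        sheet = read_sample_sheet(inputs["sheet"])
        expr = read_expression_matrix(inputs["expression"])
        beta = read_beta_matrix(inputs["beta"], sheet=sheet)
        annot = read_annotations(inputs["gene_bed"], inputs["cpg_manifest"])
        samples = [s for s in sheet.samples if s in set(expr.samples) & set(beta.samples)]
        if len(samples) < 4:
            raise ValueError("fewer than 4 samples shared across inputs")
        return (expr.subset_samples(samples), beta.subset_samples(samples),
                sheet, annot)

    expr_counts, beta, sheet, annot = _read()
    if done("read"):
        return

    # ---- preprocess ------------------------------------------------------ #
    @_stage("preprocess")
    def _preprocess():
        expr_norm = normalize_expression(expr_counts)
        expr_f, rep_g = mean_variance_filter(expr_norm, config.mean_expr, config.var_expr)
        beta_f, rep_c = mean_variance_filter(beta, config.mean_meth, config.var_meth)
        A = concatenate_and_scale(expr_f, beta_f)
        report = pd.DataFrame([rep_g.__dict__, rep_c.__dict__]).set_index("modality")
        return expr_norm, expr_f, beta_f, A, report

    expr_norm, expr_f, beta_f, A, filter_report = _preprocess()
    emit("filter_report.tsv", filter_report)
    if done("preprocess"):
        emit("concatenated.tsv", A.data)
        emit("feature_index.tsv", A.modality.rename("modality").to_frame())
        return

    # ---- factorize ------------------------------------------------------- #
    @_stage("factorize")
    def _factorize():
        return nmf_fit(A, config.chosen_rank, objective=config.objective,
                       n_runs=config.n_runs, max_iter=config.max_iter,
                       tol=config.tol, seed=config.seed)

    model = _factorize()
    emit("W.tsv", model.W)
    emit("H.tsv", model.H)
    emit("losses.tsv", pd.DataFrame({"run": range(len(model.per_run_losses)),
                                     "final_loss": model.per_run_losses}), index=False)
    if done("factorize"):
        return

    # ---- sample axis ----------------------------------------------------- #
    @_stage("samples")
    def _samples():
        tests = sample_axis.mann_whitney_per_factor(model.H, sheet)
        tests_df = pd.DataFrame([t.__dict__ for t in tests]).set_index("factor")

        coef_all, auc_all = sample_axis.logistic_auc(model.H, sheet)
        sig = [t.factor for t in tests if t.p_value < 0.05]
        rows = [("all_factors", auc_all, len(model.H.index))]
        if len(sig) >= 1:
            _, auc_sig = sample_axis.logistic_auc(model.H, sheet, factor_subset=sig)
            rows.append(("significant_factors", auc_sig, len(sig)))
        auc_df = pd.DataFrame(rows, columns=["model", "auc", "n_factors"]).set_index("model")

        assign_frames, gain_rows = {}, []
        for k in config.kmeans_grid:
            res_lf = sample_axis.cluster_and_test(model.H, sheet, k, seed=config.seed)
            res_ex = sample_axis.cluster_and_test(expr_f.data, sheet, k,
                                                  seed=config.seed, use_pca=True)
            res_me = sample_axis.cluster_and_test(beta_f.data, sheet, k,
                                                  seed=config.seed, use_pca=True)
            assign_frames[f"k{k}"] = res_lf.assignments
            for name, res in (("latent", res_lf), ("expression_pc", res_ex),
                              ("methylation_pc", res_me)):
                gain_rows.append((k, name, res.information_gain, res.chi2, res.chi2_p))
        clusters_df = pd.DataFrame(assign_frames)
        gains_df = pd.DataFrame(
            gain_rows, columns=["k", "profile", "information_gain", "chi2", "chi2_p"]
        )
        return tests_df, coef_all, auc_df, clusters_df, gains_df

    tests_df, coef_df, auc_df, clusters_df, gains_df = _samples()
    emit("factor_tests.tsv", tests_df)
    emit("logistic_coefficients.tsv", coef_df)
    emit("auc_report.tsv", auc_df)
    emit("clusters.tsv", clusters_df)
    emit("information_gain.tsv", gains_df, index=False)
    if done("samples"):
        return

    # ---- feature axis ---------------------------------------------------- #
    @_stage("features")
    def _features():
        selections = {
            f: feature_axis.select_features(model.W, A.modality, f,
                                            q=config.selection_percentile)
            for f in model.factor_names
        }
        sel_rows = []
        for f, sel in selections.items():
            for g in sorted(sel.genes):
                sel_rows.append((f, g, GENE, model.W.at[g, f], sel.threshold_value))
            for c in sorted(sel.cpgs):
                sel_rows.append((f, c, CPG, model.W.at[c, f], sel.threshold_value))
        sel_df = pd.DataFrame(
            sel_rows, columns=["factor", "feature", "modality", "W", "threshold"]
        )

        m_values = beta_to_m(beta_f)
        assoc = feature_axis.differential_association(expr_f, m_values, sheet)

        enr_frames = []
        gmt_path = inputs.get("gmt")
        if gmt_path:
            gene_sets = read_gmt(gmt_path)
            universe = set(expr_f.features)
            for f, sel in selections.items():
                if sel.genes:
                    tab = feature_axis.set_enrichment(sel.genes, universe, gene_sets)
                    tab.insert(0, "factor", f)
                    enr_frames.append(tab)
        combined_cpgs = set().union(*(sel.cpgs for sel in selections.values()))
        reg_rows = []
        for category in ("promoter", "enhancer", "tfbs"):
            res = feature_axis.regulatory_enrichment(combined_cpgs, annot, category)
            a, b, c, d = res["table"]
            reg_rows.append((category, a, b, c, d, res["fold"], res["p"]))
        reg_df = pd.DataFrame(
            reg_rows,
            columns=["category", "sel_flag", "sel_noflag", "rest_flag", "rest_noflag",
                     "fold", "p"],
        )
        enr_df = (pd.concat(enr_frames, ignore_index=True) if enr_frames
                  else pd.DataFrame(columns=["factor", "term_id", "term_size",
                                             "overlap", "p", "fold", "q_fdr"]))
        return selections, sel_df, assoc, enr_df, reg_df

    selections, sel_df, assoc, enr_df, reg_df = _features()
    emit("selections.tsv", sel_df, index=False)
    emit("association.tsv", assoc)
    emit("enrichment.tsv", enr_df, index=False)
    emit("regulatory_enrichment.tsv", reg_df, index=False)
    if done("features"):
        return

    # ---- network --------------------------------------------------------- #
    @_stage("network")
    def _network():
        edge_frames, degree_frames, hub_rows = [], [], []
        for f, sel in selections.items():
            genes = sorted(sel.genes)
            cpgs = sorted(sel.cpgs)
            if not genes or not cpgs:
                continue
            edges = network.correlate_pairs(
                expr_f.subset_features(genes), beta_f.subset_features(cpgs),
                fdr=config.correlation_fdr, factor=f,
            )
            if len(edges.edges) == 0:
                continue
            _, degrees = network.build_network(edges)
            hubs = network.hub_extraction(
                degrees, assoc=assoc, W_column=model.W[f],
                hub_percentile=config.hub_percentile,
            )
            e = edges.edges.copy()
            e.insert(0, "factor", f)
            edge_frames.append(e)
            d = degrees.reset_index()
            d.insert(0, "factor", f)
            degree_frames.append(d)
            hub_rows.append((f, len(hubs["hubs"]), len(hubs["hubs_differential"]),
                             hubs["summary"].get("mean_W_genes", np.nan),
                             hubs["summary"].get("mean_W_hub_genes", np.nan),
                             hubs["summary"].get("mean_lfc_genes", np.nan),
                             hubs["summary"].get("mean_lfc_hub_genes", np.nan),
                             ";".join(sorted(hubs["hubs"]))))
        edges_df = (pd.concat(edge_frames, ignore_index=True) if edge_frames
                    else pd.DataFrame(columns=["factor", "gene_id", "cpg_id",
                                               "R", "p", "q_fdr"]))
        degrees_df = (pd.concat(degree_frames, ignore_index=True) if degree_frames
                      else pd.DataFrame(columns=["factor", "id", "modality", "degree"]))
        hubs_df = pd.DataFrame(
            hub_rows, columns=["factor", "n_hubs", "n_hubs_differential",
                               "mean_W_genes", "mean_W_hub_genes", "mean_lfc_genes",
                               "mean_lfc_hub_genes", "hub_genes"],
        )
        return edges_df, degrees_df, hubs_df

    edges_df, degrees_df, hubs_df = _network()
    emit("edges.tsv", edges_df, index=False)
    emit("degrees.tsv", degrees_df, index=False)
    emit("hubs.tsv", hubs_df, index=False)
    if done("network"):
        return

    # ---- replication ----------------------------------------------------- #
    @_stage("replication")
    def _replication():
        rows = []
        v_expr_path = inputs.get("validation_expression")
        v_beta_path = inputs.get("validation_beta")
        if v_expr_path and v_beta_path and len(edges_df):
            v_expr = normalize_expression(read_expression_matrix(v_expr_path))
            v_beta = read_beta_matrix(v_beta_path)
            for f in edges_df["factor"].unique():
                fe = network.EdgeList(
                    edges=edges_df[edges_df["factor"] == f].drop(columns="factor"),
                    factor=f,
                )
                rep = network.replicate_in_cohort(
                    fe, v_expr, v_beta,
                    r_discovery_min=config.replication_r_threshold,
                    criterion=config.replication_criterion,
                )
                rows.append((f, rep.n_discovery_pairs, rep.n_tested,
                             rep.n_replicated, rep.fraction))
        return pd.DataFrame(rows, columns=["factor", "n_discovery_pairs", "n_tested",
                                           "n_replicated", "fraction"])

    emit("replication.tsv", _replication(), index=False)
    if done("replication"):
        return

    # ---- mqtl ------------------------------------------------------------ #
    @_stage("mqtl")
    def _mqtl():
        rows = []
        bedpe_frames = []
        for f in selections:
            fe_df = edges_df[edges_df["factor"] == f]
            genes = set(fe_df["gene_id"].unique())
            candidates = mqtl.cis_window_pairs(genes, annot, config.mqtl_window_bp)
            cis = mqtl.mqtl_correlations(candidates, expr_f, beta_f,
                                         fdr=config.correlation_fdr,
                                         window_bp=config.mqtl_window_bp)
            fe = network.EdgeList(edges=fe_df.drop(columns="factor"), factor=f)
            summary = mqtl.compare_with_network(fe, cis, annot)
            rows.append((f, summary.n_nmf_pairs, summary.n_mqtl_pairs,
                         summary.n_shared, summary.fraction_unique_to_nmf,
                         summary.fraction_trans_nmf))
            if len(cis.pairs):
                bedpe_frames.append(mqtl.links_bedpe(cis.pairs, annot))
        summary_df = pd.DataFrame(
            rows, columns=["factor", "n_nmf_pairs", "n_mqtl_pairs", "n_shared",
                           "fraction_unique_to_nmf", "fraction_trans_nmf"],
        )
        bedpe = (pd.concat(bedpe_frames, ignore_index=True) if bedpe_frames
                 else pd.DataFrame(columns=["chrom1", "start1", "end1", "chrom2",
                                            "start2", "end2", "name", "score"]))
        return summary_df, bedpe

    mqtl_summary, bedpe = _mqtl()
    emit("mqtl_summary.tsv", mqtl_summary, index=False)
    emit("links.bedpe", bedpe, index=False)
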