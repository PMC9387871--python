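"""Writing a simulated cohort to disk in the pipeline's input formats,
and reading the ground-truth sidecar back for recovery scoring.

Layout written by :func:`write_cohort` (all plain text):

* ``expression.tsv`` / ``beta.tsv`` — feature x sample matrices
* ``samples.tsv`` — sample sheet (sample_id, group)
* ``genes.bed`` — BED6 gene coordinates (0-based half-open)
* ``cpgs.csv`` — manifest-style CpG annotation (1-based positions)
* ``gene_sets.gmt`` — optional planted gene-set collection
* ``validation_expression.tsv`` / ``validation_beta.tsv`` — optional
  replication cohort
* ``truth_W.tsv`` / ``truth_H.tsv`` / ``truth.json`` — planted factors and
  the sets/pairs sidecar (differential factors, planted pairs, cis pairs,
  hub gene and CpGs, enhancer-enriched CpG set)
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import AnnotationTable, GroundTruth, OmicsMatrix, SampleSheet
from .io import write_gmt, write_table

__all__ = ["write_cohort", "read_truth"]


def write_cohort(outdir, expression: OmicsMatrix, beta: OmicsMatrix,
                 sheet: SampleSheet, annot: AnnotationTable, truth: GroundTruth,
                 gene_sets: dict | None = None, validation=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "beta": outdir / "beta.tsv",
        "sheet": outdir / "samples.tsv",
        "gene_bed": outdir / "genes.bed",
        "cpg_manifest": outdir / "cpgs.csv",
    }
    write_table(expression.data, paths["expression"])
    write_table(beta.data, paths["beta"])
    write_table(sheet.table, paths["sheet"])

    g = annot.genes
    bed = pd.DataFrame({
        "chrom": g["chrom"],
        "start": [tss if s == "+" else max(tss - 1000, 0)
                  for tss, s in zip(g["tss"], g["strand"])],
        "end": [tss + 1000 if s == "+" else tss
                for tss, s in zip(g["tss"], g["strand"])],
        "name": g.index,
        "score": 0,
        "strand": g["strand"],
    })
    bed.to_csv(paths["gene_bed"], sep="\t", header=False, index=False)

    c = annot.cpgs
    manifest = pd.DataFrame({
        "probe_id": c.index,
        "chrom": c["chrom"],
        "pos": c["pos"].astype(int) + 1,  # back to 1-based manifest convention
        "is_promoter": c["is_promoter"].astype(int),
        "is_enhancer": c["is_enhancer"].astype(int),
        "is_tfbs": c["is_tfbs"].astype(int),
    })
    manifest.to_csv(paths["cpg_manifest"], index=False)

    if gene_sets is not None:
        paths["gmt"] = outdir / "gene_sets.gmt"
        write_gmt(gene_sets, paths["gmt"])
    if validation is not None:
        v_expr, v_beta, v_sheet = validation
        paths["validation_expression"] = outdir / "validation_expression.tsv"
        paths["validation_beta"] = outdir / "validation_beta.tsv"
        write_table(v_expr.data, paths["validation_expression"])
        write_table(v_beta.data, paths["validation_beta"])
        write_table(v_sheet.table, outdir / "validation_samples.tsv")

    write_table(truth.W_true, outdir / "truth_W.tsv")
    write_table(truth.H_true, outdir / "truth_H.tsv")
    sidecar = {
        "differential_factors": sorted(truth.differential_factors),
        "planted_pairs": [list(p) for p in truth.planted_pairs],
        "cis_pairs": [list(p) for p in truth.cis_pairs],
        "enriched_cpg_set": sorted(truth.enriched_cpg_set),
        "hub_gene": truth.hub_gene,
        "hub_cpgs": list(truth.hub_cpgs),
        "hub_factor": truth.hub_factor,
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return {k: str(v) for k, v in paths.items()}


def read_truth(outdir) -> GroundTruth:
    outdir = Path(outdir)
    W = pd.read_csv(outdir / "truth_W.tsv", sep="\t", index_col=0, comment="#")
    H = pd.read_csv(outdir / "truth_H.tsv", sep="\t", index_col=0, comment="#")
    side = json.loads((outdir / "truth.json").read_text())
    return GroundTruth(
        W_true=W,
        H_true=H,
        differential_factors=set(side["differential_factors"]),
        planted_pairs=[tuple(p) for p in side["planted_pairs"]],
        cis_pairs=[tuple(p) for p in side["cis_pairs"]],
        enriched_cpg_set=set(side["enriched_cpg_set"]),
        hub_gene=side["hub_gene"],
        hub_cpgs=side["hub_cpgs"],
        hub_factor=side["hub_factor"],
    )
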