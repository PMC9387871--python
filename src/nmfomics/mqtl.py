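"""The cis-mQTL contrast: correlate each selected gene with CpGs inside a
+/- window of its TSS (no genotypes — "mQTL" here is methylation-expression
correlation), FDR-filter, and quantify overlap and cis/trans geometry
against the factorization-derived network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationTable, OmicsMatrix
from .network import EdgeList, pearson_matrix

log = logging.getLogger("nmfomics")

__all__ = ["CisPairSet", "OverlapSummary", "cis_window_pairs",
           "mqtl_correlations", "compare_with_network", "links_bedpe"]


@dataclass
class CisPairSet:
    pairs: pd.DataFrame  # gene_id, cpg_id, distance_bp, R, p, q_fdr
    window_bp: int


@dataclass
class OverlapSummary:
    n_nmf_pairs: int
    n_mqtl_pairs: int
    n_shared: int
    fraction_unique_to_nmf: float
    fraction_trans_nmf: float


def cis_window_pairs(genes: set, annot: AnnotationTable, window_bp: int = 10_000) -> pd.DataFrame:
    """All (gene, CpG) pairs on the same chromosome with |pos - TSS| <= window.

    The interval is closed (a CpG exactly at the window edge counts) and the
    distance is signed by strand: negative = upstream of the TSS.
    Unannotated genes are skipped with a count in the log.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    known = [g for g in genes if g in annot.genes.index]
    n_missing = len(genes) - len(known)
    if n_missing:
        log.warning("%d gene(s) without annotation skipped in cis windows", n_missing)
    rows = []
    cpg = annot.cpgs
    for g in sorted(known):
        chrom = annot.genes.at[g, "chrom"]
        tss = int(annot.genes.at[g, "tss"])
        strand = annot.genes.at[g, "strand"]
        near = cpg[(cpg["chrom"] == chrom) & (abs(cpg["pos"] - tss) <= window_bp)]
        for probe, pos in near["pos"].items():
            dist = int(pos - tss)
            if strand == "-":
                dist = -dist
            rows.append((g, probe, dist))
    return pd.DataFrame(rows, columns=["gene_id", "cpg_id", "distance_bp"])


def mqtl_correlations(candidates: pd.DataFrame, expr: OmicsMatrix,
                      meth: OmicsMatrix, fdr: float = 0.05,
                      window_bp: int = 10_000) -> CisPairSet:
    """Pearson + BH-FDR over the candidate cis pairs only; retain q < fdr.

    Correlations use the same Pearson/t-transform implementation as the
    network module, so shared pairs have identical R there and here.
    """
    if len(candidates) == 0:
        return CisPairSet(
            pairs=pd.DataFrame(columns=["gene_id", "cpg_id", "distance_bp", "R", "p", "q_fdr"]),
            window_bp=window_bp,
        )
    if list(expr.samples) != list(meth.samples):
        raise ValueError("expression and methylation samples must align")
    have = candidates["gene_id"].isin(expr.features) & candidates["cpg_id"].isin(meth.features)
    cand = candidates[have].reset_index(drop=True)
    X = expr.data.loc[cand["gene_id"]].to_numpy(dtype=float)
    Y = meth.data.loc[cand["cpg_id"]].to_numpy(dtype=float)
    # pairwise (row i of X with row i of Y): reuse the matrix routine row-block-wise
    R = np.empty(len(cand))
    P = np.empty(len(cand))
    for i in range(len(cand)):
        r, p = pearson_matrix(X[i:i + 1], Y[i:i + 1])
        R[i], P[i] = r[0, 0], p[0, 0]
    ok = np.isfinite(R)
    q = np.full(len(cand), np.nan)
    if ok.any():
        q[ok] = multipletests(P[ok], method="fdr_bh")[1]
    keep = ok & (q < fdr)
    pairs = cand[keep].copy()
    pairs["R"], pairs["p"], pairs["q_fdr"] = R[keep], P[keep], q[keep]
    # post-hoc window assertion, never assumed
    assert (pairs["distance_bp"].abs() <= window_bp).all(), "cis pair outside window"
    return CisPairSet(pairs=pairs.reset_index(drop=True), window_bp=window_bp)


def _trans_fraction(pairs: pd.DataFrame, annot: AnnotationTable) -> float:
    if len(pairs) == 0:
        return float("nan")
    g_chrom = annot.genes["chrom"].reindex(pairs["gene_id"]).to_numpy()
    c_chrom = annot.cpgs["chrom"].reindex(pairs["cpg_id"]).to_numpy()
    return float(np.mean(g_chrom != c_chrom))


def compare_with_network(nmf_edges: EdgeList, cis: CisPairSet,
                         annot: AnnotationTable) -> OverlapSummary:
    """Overlap and geometry contrast between network edges and cis pairs."""
    nmf_keys = set(zip(nmf_edges.edges["gene_id"], nmf_edges.edges["cpg_id"]))
    cis_keys = set(zip(cis.pairs["gene_id"], cis.pairs["cpg_id"]))
    shared = nmf_keys & cis_keys
    n_nmf = len(nmf_keys)
    return OverlapSummary(
        n_nmf_pairs=n_nmf,
        n_mqtl_pairs=len(cis_keys),
        n_shared=len(shared),
        fraction_unique_to_nmf=1.0 - len(shared) / n_nmf if n_nmf else float("nan"),
        fraction_trans_nmf=_trans_fraction(nmf_edges.edges, annot),
    )


def links_bedpe(pairs: pd.DataFrame, annot: AnnotationTable) -> pd.DataFrame:
    """Paired-interval (BEDPE) export of gene-CpG links: chrom1 start1 end1
    chrom2 start2 end2 name score.  Gene anchored at its TSS."""
    rows = []
    for _, row in pairs.iterrows():
        g, c = row["gene_id"], row["cpg_id"]
        if g not in annot.genes.index or c not in annot.cpgs.index:
            continue
        tss = int(annot.genes.at[g, "tss"])
        pos = int(annot.cpgs.at[c, "pos"])
        score = float(row["R"]) if "R" in row else 0.0
        rows.append((annot.genes.at[g, "chrom"], tss, tss + 1,
                     annot.cpgs.at[c, "chrom"], pos, pos + 1,
                     f"{g}|{c}", score))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                       "start2", "end2", "name", "score"])
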