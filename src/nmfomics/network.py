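"""Bipartite gene-CpG correlation networks for the selected features of each
latent factor: all-pairs Pearson correlation with BH-FDR edge filtering,
node degrees, hub extraction, shared-CpG subnetworks, random-pair background
comparison, and validation-cohort replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

from .containers import CPG, GENE, OmicsMatrix

log = logging.getLogger("nmfomics")

__all__ = [
    "EdgeList",
    "ReplicationReport",
    "pearson_matrix",
    "correlate_pairs",
    "background_comparison",
    "build_network",
    "hub_extraction",
    "shared_cpg_subnetwork",
    "replicate_in_cohort",
]


@dataclass
class EdgeList:
    edges: pd.DataFrame  # columns gene_id, cpg_id, R, p, q_fdr
    factor: str = ""


@dataclass
class ReplicationReport:
    n_discovery_pairs: int
    n_tested: int
    n_replicated: int

    @property
    def fraction(self) -> float:
        return self.n_replicated / self.n_tested if self.n_tested else float("nan")


def pearson_matrix(X: np.ndarray, Y: np.ndarray):
    """Row-by-row Pearson R between X (a x n) and Y (b x n) plus two-sided p
    from the t transform t = R sqrt((n-2)/(1-R^2)).  Rows with zero variance
    yield NaN."""
    n = X.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples for correlation p-values")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ Yc.T) / np.outer(xn, yn)
    R = np.clip(R, -1.0, 1.0)
    R[xn == 0, :] = np.nan
    R[:, yn == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R ** 2))
    p = 2.0 * ss.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(R), 1.0), 0.0, p)
    return R, p


def correlate_pairs(expr_selected: OmicsMatrix, meth_selected: OmicsMatrix,
                    fdr: float = 0.05, factor: str = "") -> EdgeList:
    """All gene x CpG Pearson correlations with BH-FDR; keep q < fdr.

    FDR is applied across every candidate pair of this factor.  Pairs
    involving a constant feature are excluded (counted in the log).
    """
    if list(expr_selected.samples) != list(meth_selected.samples):
        raise ValueError("expression and methylation samples must align")
    X = expr_selected.data.to_numpy(dtype=float)
    Y = meth_selected.data.to_numpy(dtype=float)
    R, p = pearson_matrix(X, Y)
    gi, ci = np.meshgrid(np.arange(X.shape[0]), np.arange(Y.shape[0]), indexing="ij")
    flatR, flatp = R.ravel(), p.ravel()
    ok = np.isfinite(flatR)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("excluded %d pairs with a constant feature", n_dropped)
    q = np.full(flatp.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(flatp[ok], method="fdr_bh")[1]
    keep = ok & (q < fdr)
    edges = pd.DataFrame(
        {
            "gene_id": expr_selected.features.to_numpy()[gi.ravel()[keep]],
            "cpg_id": meth_selected.features.to_numpy()[ci.ravel()[keep]],
            "R": flatR[keep],
            "p": flatp[keep],
            "q_fdr": q[keep],
        }
    )
    return EdgeList(edges=edges.reset_index(drop=True), factor=str(factor))


def background_comparison(edges: EdgeList, expr_all: OmicsMatrix,
                          meth_all: OmicsMatrix, n_random_pairs: int = 10_000,
                          seed: int = 0) -> dict:
    """Mean R of the selected-pair edges vs random gene-CpG pairs drawn from
    the full (unselected) feature universe."""
    rng = np.random.default_rng(seed)
    gidx = rng.integers(0, expr_all.shape[0], size=n_random_pairs)
    cidx = rng.integers(0, meth_all.shape[0], size=n_random_pairs)
    X = expr_all.values[gidx]
    Y = meth_all.values[cidx]
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_random = np.einsum("ij,ij->i", Xc, Yc) / denom
    r_random = r_random[np.isfinite(r_random)]
    r_selected = edges.edges["R"].to_numpy()
    return {
        "mean_R_selected": float(np.mean(r_selected)) if len(r_selected) else np.nan,
        "mean_R_random": float(np.mean(r_random)) if len(r_random) else np.nan,
        "selected_R": r_selected,
        "random_R": r_random,
    }


def build_network(edges: EdgeList):
    """Bipartite graph and per-node degree table; handshake enforced."""
    df = edges.edges
    if df.duplicated(subset=["gene_id", "cpg_id"]).any():
        raise ValueError("duplicate (gene, cpg) edges")
    if (df["gene_id"] == df["cpg_id"]).any():
        raise ValueError("self-pair in bipartite edge list (data corruption)")
    G = nx.Graph()
    G.add_nodes_from(df["gene_id"].unique(), modality=GENE)
    G.add_nodes_from(df["cpg_id"].unique(), modality=CPG)
    G.add_weighted_edges_from(df[["gene_id", "cpg_id", "R"]].itertuples(index=False),
                              weight="R")
    rows = [(node, G.nodes[node]["modality"], G.degree[node]) for node in G.nodes]
    degrees = pd.DataFrame(rows, columns=["id", "modality", "degree"]).set_index("id")
    gsum = degrees.loc[degrees["modality"] == GENE, "degree"].sum()
    csum = degrees.loc[degrees["modality"] == CPG, "degree"].sum()
    assert gsum == csum == len(df), "bipartite handshake violated"
    return G, degrees


def hub_extraction(degrees: pd.DataFrame, assoc: pd.DataFrame | None = None,
                   W_column: pd.Series | None = None,
                   hub_percentile: float = 90.0, sig_q: float = 0.05) -> dict:
    """Hub genes: gene nodes with degree at or above the percentile cut.

    Returns the hub set, its intersection with significantly differential
    genes (q < sig_q in ``assoc``), and mean-W / mean-LFC summaries of hubs
    vs all gene nodes when the annotations are supplied.  Ties at the cut
    are included; an all-tied degree table makes every gene a hub (warned).
    """
    gene_deg = degrees.loc[degrees["modality"] == GENE, "degree"]
    if gene_deg.empty:
        log.warning("no gene nodes in network; empty hub set")
        return {"hubs": set(), "hubs_differential": set(), "summary": {}}
    cut = float(np.percentile(gene_deg.to_numpy(), hub_percentile))
    hubs = set(gene_deg.index[gene_deg >= cut])
    if len(hubs) == len(gene_deg):
        log.warning("all gene degrees tie; every gene is a hub")
    hubs_diff = set()
    if assoc is not None:
        sig = set(assoc.index[(assoc["modality"] == GENE) & (assoc["q_fdr"] < sig_q)])
        hubs_diff = hubs & sig
    summary = {}
    if W_column is not None:
        all_genes = [g for g in gene_deg.index if g in W_column.index]
        hub_in = [g for g in hubs if g in W_column.index]
        summary["mean_W_genes"] = float(W_column.loc[all_genes].mean()) if all_genes else np.nan
        summary["mean_W_hub_genes"] = float(W_column.loc[hub_in].mean()) if hub_in else np.nan
    if assoc is not None:
        lfc = assoc["log2_fold_change"]
        all_genes = [g for g in gene_deg.index if g in lfc.index]
        hub_in = [g for g in hubs if g in lfc.index]
        summary["mean_lfc_genes"] = float(lfc.loc[all_genes].mean()) if all_genes else np.nan
        summary["mean_lfc_hub_genes"] = float(lfc.loc[hub_in].mean()) if hub_in else np.nan
    return {"hubs": hubs, "hubs_differential": hubs_diff, "summary": summary,
            "degree_cut": cut}


def shared_cpg_subnetwork(edges: EdgeList, gene_subset: set,
                          min_shared_degree: int = 2, r_min: float = 0.7) -> pd.DataFrame:
    """Edges with R > r_min touching ``gene_subset``, restricted to CpGs
    linked to at least ``min_shared_degree`` of those genes."""
    df = edges.edges
    sub = df[(df["gene_id"].isin(gene_subset)) & (df["R"] > r_min)]
    cpg_counts = sub.groupby("cpg_id")["gene_id"].nunique()
    keep_cpgs = set(cpg_counts.index[cpg_counts >= min_shared_degree])
    return sub[sub["cpg_id"].isin(keep_cpgs)].reset_index(drop=True)


def replicate_in_cohort(discovery_edges: EdgeList, validation_expr: OmicsMatrix,
                        validation_meth: OmicsMatrix,
                        r_discovery_min: float = 0.7,
                        criterion: str = "p_sign",
                        r_validation_min: float = 0.7,
                        alpha: float = 0.05) -> ReplicationReport:
    """Re-test strong discovery edges in an independent cohort.

    Pairs with discovery R > r_discovery_min whose two features are present
    in the validation matrices are recomputed there.  Replication criterion:
    ``p_sign`` (default) — validation p < alpha with the same R sign;
    ``r_threshold`` — validation R above r_validation_min (sign-matched).
    """
    if validation_expr.shape[1] < 4:
        raise ValueError("validation cohort needs >= 4 samples")
    if list(validation_expr.samples) != list(validation_meth.samples):
        raise ValueError("validation matrices must share samples")
    strong = discovery_edges.edges[discovery_edges.edges["R"] > r_discovery_min]
    have = strong["gene_id"].isin(validation_expr.features) & strong[
        "cpg_id"
    ].isin(validation_meth.features)
    tested = strong[have]
    n_rep = 0
    if len(tested):
        X = validation_expr.data.loc[tested["gene_id"]].to_numpy(dtype=float)
        Y = validation_meth.data.loc[tested["cpg_id"]].to_numpy(dtype=float)
        n = X.shape[1]
        Xc = X - X.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(Yc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_val = np.einsum("ij,ij->i", Xc, Yc) / denom
        r_val = np.clip(r_val, -1, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r_val * np.sqrt((n - 2) / (1 - r_val ** 2))
        p_val = 2.0 * ss.t.sf(np.abs(t), df=n - 2)
        same_sign = np.sign(r_val) == np.sign(tested["R"].to_numpy())
        if criterion == "p_sign":
            ok = (p_val < alpha) & same_sign
        elif criterion == "r_threshold":
            ok = (np.abs(r_val) > r_validation_min) & same_sign
        else:
            raise ValueError(f"unknown replication criterion {criterion!r}")
        n_rep = int(np.nansum(ok))
    return ReplicationReport(
        n_discovery_pairs=len(strong), n_tested=len(tested), n_replicated=n_rep
    )
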