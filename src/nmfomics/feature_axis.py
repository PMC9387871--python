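"""Analyses of the basis matrix W: percentile feature selection, overlaps,
set enrichment with FDR, random-selection controls, regulatory-category
enrichment, and the simplified per-feature differential tests that annotate
selections downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

from .containers import CPG, GENE, AnnotationTable, OmicsMatrix, SampleSheet

log = logging.getLogger("nmfomics")

__all__ = [
    "FeatureSelection",
    "select_features",
    "selection_overlap",
    "set_enrichment",
    "random_selection_control",
    "regulatory_enrichment",
    "differential_association",
]


@dataclass
class FeatureSelection:
    factor: str
    percentile: float
    threshold_value: float
    genes: set
    cpgs: set

    @property
    def n_sig_genes(self) -> int:  # populated by annotate step when used
        return len(self.genes)

    @property
    def features(self) -> set:
        return self.genes | self.cpgs


def select_features(W: pd.DataFrame, modality: pd.Series, factor,
                    q: float = 90.0) -> FeatureSelection:
    """Features whose loading on ``factor`` reaches the q-th percentile.

    The threshold is the q-th percentile (linear interpolation) of the FULL W
    column across both modalities — one joint cut, so per-factor gene+CpG
    counts sum to ~(1-q/100) of all features.  Ties at the threshold are
    included.  A constant column selects everything, with a warning.
    """
    if not 0 < q < 100:
        raise ValueError("percentile must lie in (0, 100)")
    col = W[factor].to_numpy(dtype=float)
    if col.max() == col.min():
        log.warning("factor %s has a constant W column; selecting all features", factor)
        threshold = float(col[0])
        mask = np.ones(len(col), dtype=bool)
    else:
        threshold = float(np.percentile(col, q))  # type-7 linear interpolation
        mask = col >= threshold
    ids = W.index[mask]
    tags = modality.loc[ids]
    return FeatureSelection(
        factor=str(factor),
        percentile=q,
        threshold_value=threshold,
        genes=set(ids[tags == GENE]),
        cpgs=set(ids[tags == CPG]),
    )


def selection_overlap(selections: list) -> pd.DataFrame:
    """Pairwise raw-intersection and Jaccard overlaps between selections."""
    rows = []
    for i, a in enumerate(selections):
        for b in selections[i + 1:]:
            sa, sb = a.features, b.features
            inter = len(sa & sb)
            union = len(sa | sb)
            rows.append(
                (a.factor, a.percentile, b.factor, b.percentile, inter,
                 inter / union if union else np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["factor_a", "q_a", "factor_b", "q_b", "intersection", "jaccard"],
    )


def set_enrichment(selected_genes: set, universe: set, gene_sets: dict) -> pd.DataFrame:
    """Over-representation of each gene set in the selection.

    One-sided hypergeometric (upper tail) per term after intersecting terms
    with the universe; BH-FDR across terms;
    fold = (overlap/|selected|) / (term_size/|universe|).
    """
    if not universe or not selected_genes:
        raise ValueError("selection and universe must be non-empty")
    if not selected_genes <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected_genes)
    rows = []
    for term, members in gene_sets.items():
        members = members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected_genes)
        p = float(ss.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term, K, k, p, fold))
    df = pd.DataFrame(rows, columns=["term_id", "term_size", "overlap", "p", "fold"])
    if len(df):
        df["q_fdr"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values("p").reset_index(drop=True)
    else:
        df["q_fdr"] = []
    return df


def random_selection_control(W: pd.DataFrame, modality: pd.Series, factor,
                             gene_sets: dict, q: float = 90.0,
                             n_repeats: int = 3, seed: int = 0) -> list:
    """Size- and modality-matched random selections run through enrichment.

    Returns one enrichment table per repeat; the minimum q over terms per
    repeat is the headline control statistic.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    sel = select_features(W, modality, factor, q)
    genes_all = list(modality.index[modality == GENE])
    universe = set(genes_all)
    empty = pd.DataFrame(columns=["term_id", "term_size", "overlap", "p",
                                  "fold", "q_fdr"])
    if not sel.genes:
        log.warning("factor %s selected no genes; control tables are empty", factor)
        return [empty.copy() for _ in range(n_repeats)]
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_repeats):
        draw = set(rng.choice(genes_all, size=min(len(sel.genes), len(genes_all)),
                              replace=False))
        tables.append(set_enrichment(draw, universe, gene_sets))
    return tables


def regulatory_enrichment(selected_cpgs: set, annot: AnnotationTable,
                          category: str) -> dict:
    """One-sided Fisher's exact test of a regulatory flag in the selection.

    2x2 table: (selected vs rest) x (flagged vs not);
    fold = (flagged/selected) / (flagged_rest/rest).
    """
    col = {"promoter": "is_promoter", "enhancer": "is_enhancer", "tfbs": "is_tfbs"}[category]
    flags = annot.cpgs[col]
    missing = selected_cpgs - set(flags.index)
    if missing:
        raise ValueError(f"selected CpGs missing from annotation: {sorted(missing)[:5]}")
    sel = flags.index.isin(selected_cpgs)
    a = int((flags[sel]).sum())            # selected & flagged
    b = int(len(flags[sel]) - a)           # selected & not
    c = int((flags[~sel]).sum())           # rest & flagged
    d = int(len(flags[~sel]) - c)          # rest & not
    if a + c == 0:
        log.warning("no CpG carries the %s flag; fold undefined", category)
        return {"category": category, "table": (a, b, c, d), "fold": None, "p": 1.0}
    _, p = ss.fisher_exact([[a, b], [c, d]], alternative="greater")
    sel_rate = a / (a + b) if a + b else 0.0
    rest_rate = c / (c + d) if c + d else 0.0
    fold = sel_rate / rest_rate if rest_rate > 0 else np.inf
    return {"category": category, "table": (a, b, c, d), "fold": fold, "p": float(p)}


def differential_association(expr_norm: OmicsMatrix, m_values: OmicsMatrix,
                             sheet: SampleSheet) -> pd.DataFrame:
    """Simplified per-feature case/control tests used for annotation.

    Genes: log2 fold change of group means on the normalised log scale with a
    Welch t-test.  CpGs: group mean difference of M-values with a Welch
    t-test.  BH-FDR per modality.  Zero-variance features in both groups get
    p = 1.
    """
    sheet.require_two_per_group()
    case_ids, ctrl_ids = sheet.split()
    frames = []
    for mat, tag in ((expr_norm, GENE), (m_values, CPG)):
        if mat is None:
            continue
        case = mat.data[case_ids].to_numpy(dtype=float)
        ctrl = mat.data[ctrl_ids].to_numpy(dtype=float)
        lfc = case.mean(axis=1) - ctrl.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = ss.ttest_ind(case, ctrl, axis=1, equal_var=False)
        degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
        p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
        q = multipletests(p, method="fdr_bh")[1]
        frames.append(pd.DataFrame(
            {"log2_fold_change": lfc, "p": p, "q_fdr": q, "modality": tag},
            index=mat.features,
        ))
    return pd.concat(frames)
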