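"""Synthetic paired expression + methylation cohorts with planted structure.

The generator emulates a two-group (case/control) cohort profiled on both
RNA-seq and a 450K-style methylation array:

* a shared low-rank signal ``W_true @ H_true`` (K latent factors) drives both
  modalities; each factor loads on a sparse subset of genes and CpGs, so
  gene-CpG pairs sharing a factor are positively correlated across samples;
* selected factors are *differential*: case samples receive a positive shift
  on those rows of H, which is what the encoding-matrix group tests and the
  classifier are meant to detect;
* expression is count-like — ``round(s_j * exp(signal + noise))`` with
  log-normal library-size factors ``s_j`` — and methylation is a logistic
  squashing of the noised signal, so beta values lie strictly in (0, 1);
* genomic geometry spans 22 synthetic chromosomes: genes live on the first
  half, most CpGs on the second half (trans by construction), and
  ``n_cis_pairs`` CpGs are placed within ``cis_max_dist`` of a gene's TSS and
  share a factor with that gene, giving the cis-mQTL contrast ground truth;
* one *hub* gene co-loads with ``n_hub_cpgs`` CpGs on a dedicated factor at
  high amplitude, planting a high-degree node for the network analysis;
* CpGs in the top decile of factor loading receive enhancer flags at
  ``enhancer_enrichment_odds``-fold higher odds than background, planting the
  regulatory-category enrichment.

What it deliberately does not emulate: probe-type chemistry, batch effects,
cell-type composition, negative-binomial dispersion, or realistic linkage
between neighbouring CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import CPG, GENE, AnnotationTable, GroundTruth, OmicsMatrix, SampleSheet

__all__ = ["SimulationDesign", "simulate_cohort", "simulate_validation",
           "make_gene_sets", "truth_factor_match"]

N_CHROMOSOMES = 22
CHROM_LENGTH = 50_000_000


@dataclass
class SimulationDesign:
    """Knobs of the synthetic cohort (defaults are the desk-scale study)."""

    n_case: int = 33
    n_control: int = 24
    n_genes: int = 500
    n_cpgs: int = 2000
    true_rank: int = 5
    differential_factors: frozenset = frozenset({0, 3})   # 0-based factor indices
    factor_effect: float = 1.0
    loading_sparsity: float = 0.12
    housekeeping_level: float = 20.0
    loading_low: float = 0.8
    loading_high: float = 1.5
    meth_offset: float = 2.5
    h_shape: float = 2.5
    h_scale: float = 0.5
    expr_scale: float = 1.4
    enhancer_percentile: float = 94.0
    noise_sd_expr: float = 0.3
    noise_sd_meth: float = 0.2
    n_cis_pairs: int = 50
    cis_max_dist: int = 10_000
    enhancer_enrichment_odds: float = 3.0
    enhancer_base_rate: float = 0.05
    n_hub_cpgs: int = 50
    hub_loading: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        n_samples = self.n_case + self.n_control
        m = self.n_genes + self.n_cpgs
        if not 0 < self.true_rank < min(n_samples, m):
            raise ValueError("true_rank must satisfy 0 < K < min(n_samples, n_features)")
        if not 0 < self.loading_sparsity <= 1:
            raise ValueError("loading_sparsity must lie in (0, 1]")
        if min(self.n_case, self.n_control, self.n_genes, self.n_cpgs) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_cis_pairs > self.n_cpgs:
            raise ValueError("n_cis_pairs cannot exceed n_cpgs")
        if self.enhancer_enrichment_odds < 1:
            raise ValueError("enhancer_enrichment_odds must be >= 1")
        if not set(self.differential_factors) <= set(range(self.true_rank)):
            raise ValueError("differential_factors must be subset of 0..K-1")


# --------------------------------------------------------------------------- #
# internals
# --------------------------------------------------------------------------- #
def _draw_basis(design: SimulationDesign, rng: np.random.Generator):
    """Sparse non-negative W_true plus the planted hub block."""
    m = design.n_genes + design.n_cpgs
    K = design.true_rank
    W = np.zeros((m, K))
    n_support = max(2, round(design.loading_sparsity * m))
    # supports are drawn disjointly while features remain (factors then
    # overlap only through the cis-pair co-loadings), which keeps the planted
    # factors identifiable; once the pool is exhausted supports are re-drawn
    # from the full feature set
    # the last factor is the hub block: exactly one gene co-loading with
    # n_hub_cpgs CpGs at high amplitude, planting a high-degree network node;
    # the remaining K-1 factors draw disjoint supports while features remain
    hub_factor = K - 1
    pool = rng.permutation(m)
    for k in range(K - 1):
        if len(pool) >= n_support:
            support, pool = pool[:n_support], pool[n_support:]
        else:
            support = rng.choice(m, size=n_support, replace=False)
        W[support, k] = rng.uniform(design.loading_low, design.loading_high,
                                    size=n_support)

    hub_gene_idx = int(rng.integers(design.n_genes))
    hub_cpg_idx = design.n_genes + rng.choice(
        design.n_cpgs, size=min(design.n_hub_cpgs, design.n_cpgs), replace=False
    )
    W[hub_gene_idx, :] = 0.0
    W[hub_gene_idx, hub_factor] = design.hub_loading
    W[hub_cpg_idx, :] = 0.0
    W[hub_cpg_idx, hub_factor] = rng.uniform(1.5, 2.5, size=len(hub_cpg_idx))
    return W, hub_gene_idx, hub_cpg_idx, hub_factor


def _draw_encodings(design: SimulationDesign, rng: np.random.Generator):
    n = design.n_case + design.n_control
    H = rng.gamma(shape=design.h_shape, scale=design.h_scale,
                  size=(design.true_rank, n))
    case_cols = np.arange(design.n_case)          # cases first
    for k in design.differential_factors:
        H[k, case_cols] += design.factor_effect
    return H


def _expression_from_signal(signal, rng, design):
    """Counts = round(s_j * exp(log-signal + noise)) with log-normal library
    sizes s_j.  Genes without any factor loading are housekeeping background:
    constant moderate expression (zero-free across samples), which gives the
    median-of-ratios normalisation an unchanged reference set, as in real
    cohorts where most genes are not differential."""
    size_factors = rng.lognormal(mean=0.0, sigma=0.2, size=signal.shape[1])
    background = ~(signal > 0).any(axis=1)
    # housekeeping genes are stably expressed: tighter noise keeps them below
    # the variance filter so they inform normalisation but not factorization
    sd = np.where(background, 0.35 * design.noise_sd_expr, design.noise_sd_expr)
    noise = rng.normal(0.0, 1.0, size=signal.shape) * sd[:, None]
    log_level = np.where(background, np.log(design.housekeeping_level), 0.0)
    counts = np.rint(size_factors[None, :]
                     * np.exp(log_level[:, None] + design.expr_scale * signal + noise))
    return np.maximum(counts, 0.0), size_factors


def _beta_from_signal(signal, rng, design):
    noise = rng.normal(0.0, design.noise_sd_meth, size=signal.shape)
    beta = 1.0 / (1.0 + np.exp(-(signal - design.meth_offset + noise)))
    return np.clip(beta, 1e-6, 1.0 - 1e-6)  # strictly inside (0, 1)


def _place_coordinates(design, W, gene_ids, cpg_ids, rng):
    """Genes on chromosomes 1-11; non-cis CpGs on 12-22 (trans by design);
    cis CpGs placed within the window of a gene's TSS, sharing a factor."""
    half = N_CHROMOSOMES // 2
    gene_chrom = rng.integers(1, half + 1, size=design.n_genes)
    margin = design.cis_max_dist + 1
    gene_tss = rng.integers(margin, CHROM_LENGTH - margin, size=design.n_genes)
    strand = rng.choice(["+", "-"], size=design.n_genes)

    cpg_chrom = rng.integers(half + 1, N_CHROMOSOMES + 1, size=design.n_cpgs)
    cpg_pos = rng.integers(0, CHROM_LENGTH, size=design.n_cpgs)

    cis_cpg_idx = rng.choice(design.n_cpgs, size=design.n_cis_pairs, replace=False)
    cis_gene_idx = rng.integers(0, design.n_genes, size=design.n_cis_pairs)
    cis_pairs = []
    for c_idx, g_idx in zip(cis_cpg_idx, cis_gene_idx):
        cpg_chrom[c_idx] = gene_chrom[g_idx]
        offset = int(rng.integers(-design.cis_max_dist, design.cis_max_dist + 1))
        cpg_pos[c_idx] = gene_tss[g_idx] + offset
        # cis CpG shares a factor with its gene so the pair is detectable
        g_row = W[g_idx]
        loaded = np.flatnonzero(g_row)
        if len(loaded) == 0:
            k = int(rng.integers(design.true_rank))
            W[g_idx, k] = rng.uniform(0.8, 1.2)
            loaded = np.array([k])
        k = int(rng.choice(loaded))
        W[design.n_genes + c_idx, k] = rng.uniform(0.8, 1.2)
        cis_pairs.append((gene_ids[g_idx], cpg_ids[c_idx]))

    genes = pd.DataFrame(
        {"chrom": [f"chr{c}" for c in gene_chrom], "tss": gene_tss, "strand": strand},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cpgs = pd.DataFrame(
        {"chrom": [f"chr{c}" for c in cpg_chrom], "pos": cpg_pos},
        index=pd.Index(cpg_ids, name="probe_id"),
    )
    return genes, cpgs, cis_pairs


def _plant_enhancers(design, W, rng):
    """CpGs with high factor loading get enhancer flags at elevated odds.

    "High loading" mirrors the pipeline's selection rule: per factor, a high
    percentile of the full W column (genes and CpGs jointly); the enriched
    set is the union of per-factor cuts restricted to CpGs.  The percentile
    sits slightly above the pipeline's 90 because the pipeline selects among
    variance-filtered features — a smaller universe — so this keeps the
    planted set nested inside the recovered selection.
    """
    W_cpg = W[design.n_genes:]
    high = np.zeros(design.n_cpgs, dtype=bool)
    for k in range(W.shape[1]):
        cutoff = np.percentile(W[:, k], design.enhancer_percentile)
        high |= (W_cpg[:, k] >= cutoff) & (W_cpg[:, k] > 0)
    p0 = design.enhancer_base_rate
    odds0 = p0 / (1.0 - p0)
    odds1 = odds0 * design.enhancer_enrichment_odds
    p1 = odds1 / (1.0 + odds1)
    prob = np.where(high, p1, p0)
    is_enhancer = rng.uniform(size=len(prob)) < prob
    is_promoter = rng.uniform(size=len(prob)) < 0.10
    is_tfbs = rng.uniform(size=len(prob)) < 0.10
    return is_enhancer, is_promoter, is_tfbs, high


# --------------------------------------------------------------------------- #
# public API
# --------------------------------------------------------------------------- #
def simulate_cohort(design: SimulationDesign):
    """Generate one cohort.

    Returns ``(expression, beta, sheet, annotations, truth)`` with matrices of
    shape (n_genes, n) and (n_cpgs, n); cases come first in the sample order.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_case + design.n_control
    gene_ids = [f"g{i:05d}" for i in range(design.n_genes)]
    cpg_ids = [f"cg{i:06d}" for i in range(design.n_cpgs)]
    sample_ids = [f"case{i:03d}" for i in range(design.n_case)] + [
        f"ctrl{i:03d}" for i in range(design.n_control)
    ]

    W, hub_gene_idx, hub_cpg_idx, hub_factor = _draw_basis(design, rng)
    genes_coord, cpgs_coord, cis_pairs = _place_coordinates(
        design, W, gene_ids, cpg_ids, rng
    )
    H = _draw_encodings(design, rng)
    signal = W @ H

    counts, _ = _expression_from_signal(signal[: design.n_genes], rng, design)
    beta = _beta_from_signal(signal[design.n_genes:], rng, design)

    is_enh, is_prom, is_tfbs, high = _plant_enhancers(design, W, rng)
    cpgs_coord = cpgs_coord.assign(
        is_promoter=is_prom, is_enhancer=is_enh, is_tfbs=is_tfbs
    )

    expression = OmicsMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), GENE
    )
    beta_m = OmicsMatrix(pd.DataFrame(beta, index=cpg_ids, columns=sample_ids), CPG)
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": ["case"] * design.n_case + ["control"] * design.n_control},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    annot = AnnotationTable(genes=genes_coord, cpgs=cpgs_coord)

    # planted positively-correlated gene-CpG pairs: shared-factor co-loading
    planted_pairs = []
    for k in range(design.true_rank):
        g_idx = [i for i in np.flatnonzero(W[: design.n_genes, k])][:20]
        c_idx = [i for i in np.flatnonzero(W[design.n_genes:, k])][:20]
        planted_pairs += [
            (gene_ids[g], cpg_ids[c], +1) for g, c in zip(g_idx, c_idx)
        ]

    feature_ids = gene_ids + cpg_ids
    truth = GroundTruth(
        W_true=pd.DataFrame(
            W, index=feature_ids, columns=[f"F{k + 1}" for k in range(design.true_rank)]
        ),
        H_true=pd.DataFrame(
            H, index=[f"F{k + 1}" for k in range(design.true_rank)], columns=sample_ids
        ),
        differential_factors=set(design.differential_factors),
        planted_pairs=planted_pairs,
        cis_pairs=cis_pairs,
        enriched_cpg_set={cpg_ids[i] for i in np.flatnonzero(high)},
        hub_gene=gene_ids[hub_gene_idx],
        hub_cpgs=[cpg_ids[i - design.n_genes] for i in hub_cpg_idx],
        hub_factor=hub_factor,
    )
    return expression, beta_m, sheet, annot, truth


def simulate_validation(truth: GroundTruth, design: SimulationDesign, seed: int):
    """An independent cohort sharing W_true (feature structure) with fresh
    samples and noise — the replication cohort for network edges."""
    rng = np.random.default_rng(seed)
    design_v = replace(design, seed=seed)
    H = _draw_encodings(design_v, rng)
    W = truth.W_true.to_numpy()
    signal = W @ H
    counts, _ = _expression_from_signal(signal[: design.n_genes], rng, design_v)
    beta = _beta_from_signal(signal[design.n_genes:], rng, design_v)
    sample_ids = [f"vcase{i:03d}" for i in range(design.n_case)] + [
        f"vctrl{i:03d}" for i in range(design.n_control)
    ]
    gene_ids = list(truth.W_true.index[: design.n_genes])
    cpg_ids = list(truth.W_true.index[design.n_genes:])
    expression = OmicsMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), GENE
    )
    beta_m = OmicsMatrix(pd.DataFrame(beta, index=cpg_ids, columns=sample_ids), CPG)
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": ["case"] * design.n_case + ["control"] * design.n_control},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return expression, beta_m, sheet


def make_gene_sets(truth: GroundTruth, n_genes: int, n_random_terms: int = 20,
                   seed: int = 0, max_term_size: int = 80) -> dict:
    """A GMT-style collection with one term per planted factor (its gene
    support) plus size-matched random terms, for enrichment recovery tests."""
    rng = np.random.default_rng(seed)
    gene_ids = list(truth.W_true.index[:n_genes])
    W_gene = truth.W_true.to_numpy()[:n_genes]
    sets: dict[str, set] = {}
    for k in range(W_gene.shape[1]):
        loaded = np.flatnonzero(W_gene[:, k])
        order = np.argsort(-W_gene[loaded, k])
        members = [gene_ids[i] for i in loaded[order][:max_term_size]]
        if len(members) >= 5:
            sets[f"factor_term_{k + 1}"] = set(members)
    sizes = [len(s) for s in sets.values()] or [40]
    for j in range(n_random_terms):
        size = int(rng.choice(sizes))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        sets[f"random_term_{j + 1}"] = set(members)
    return sets


def truth_factor_match(W_est: pd.DataFrame, truth: GroundTruth,
                       scale_rows: bool = False) -> pd.DataFrame:
    """Match estimated factors to planted ones by maximum-cosine assignment.

    Cosines are computed between W_est columns and W_true columns over the
    features present in ``W_est`` (rectangular assignment when ranks differ;
    a zero-norm column scores 0).  With ``scale_rows=True`` the true basis is
    first divided row-wise by the row maxima of the planted signal
    ``W_true @ H_true`` — the space the pipeline's max-norm scaling puts the
    estimated basis in.
    """
    W_true = truth.W_true.loc[W_est.index].to_numpy().astype(float).copy()
    if scale_rows:
        signal = truth.W_true.to_numpy() @ truth.H_true.to_numpy()
        rowmax = signal.max(axis=1)
        rowmax[rowmax == 0] = 1.0
        scale = pd.Series(rowmax, index=truth.W_true.index).loc[W_est.index].to_numpy()
        W_true = W_true / scale[:, None]
    E = W_est.to_numpy().astype(float)

    def _unit(M):
        norms = np.linalg.norm(M, axis=0)
        safe = np.where(norms == 0, 1.0, norms)
        return M / safe, norms == 0

    Eu, e_zero = _unit(E)
    Tu, t_zero = _unit(W_true)
    C = Eu.T @ Tu
    C[e_zero, :] = 0.0
    C[:, t_zero] = 0.0
    ei, ti = linear_sum_assignment(-C)
    return pd.DataFrame(
        {
            "est_factor": [W_est.columns[i] for i in ei],
            "true_factor": [truth.W_true.columns[j] for j in ti],
            "cosine": C[ei, ti],
        }
    )
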