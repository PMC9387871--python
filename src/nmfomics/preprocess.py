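"""Normalisation, filtering and concatenation ahead of the factorization.

The joint factorization consumes a single non-negative matrix: library-size
normalised log2 expression stacked on top of raw beta values, each feature
row rescaled to unit maximum ('max' norm) so the two modalities are
commensurable.  M-values are computed only for differential methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

log = logging.getLogger("nmfomics")

__all__ = [
    "FilterReport",
    "ConcatenatedMatrix",
    "normalize_expression",
    "beta_to_m",
    "mean_variance_filter",
    "concatenate_and_scale",
]


@dataclass
class FilterReport:
    modality: str
    n_before: int
    n_after: int
    mean_threshold: float
    var_threshold: float


@dataclass
class ConcatenatedMatrix:
    """Row-stacked gene+CpG matrix with every feature row scaled to max 1."""

    data: pd.DataFrame
    modality: pd.Series

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


def normalize_expression(counts: OmicsMatrix) -> OmicsMatrix:
    """Median-of-ratios depth normalisation followed by log2(x+1).

    Size factor of sample j is the median over reference genes (genes with a
    strictly positive geometric mean across samples) of count[g,j] / geomean_g.
    If no gene is zero-free, upper-quartile size factors are used instead.
    """
    X = counts.values.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 samples for depth normalisation")
    with np.errstate(divide="ignore"):
        logX = np.log(X)
    ref = np.all(X > 0, axis=1)
    if ref.any():
        geomean = np.exp(logX[ref].mean(axis=1))
        ratios = X[ref] / geomean[:, None]
        size = np.median(ratios, axis=0)
    else:
        log.warning("every gene contains a zero; falling back to upper-quartile size factors")
        uq = np.array([np.percentile(col[col > 0], 75) if (col > 0).any() else 1.0 for col in X.T])
        size = uq / np.exp(np.mean(np.log(uq)))
    norm = np.log2(X / size[None, :] + 1.0)
    return OmicsMatrix(
        pd.DataFrame(norm, index=counts.features, columns=counts.samples),
        counts.modality,
    )


def beta_to_m(beta: OmicsMatrix, epsilon: float = 1e-6) -> OmicsMatrix:
    """Logit transform of beta values: M = log2((b+eps)/(1-b+eps)).

    Used only for differential methylation; the factorization consumes beta
    values directly (they are already non-negative).  Returned as a plain
    DataFrame-backed object; note M-values are signed, so this output must
    never feed the NMF.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    b = beta.values
    M = np.log2((b + epsilon) / (1.0 - b + epsilon))
    df = pd.DataFrame(M, index=beta.features, columns=beta.samples)
    out = object.__new__(OmicsMatrix)  # bypass non-negativity check: M is signed
    out.data = df
    out.modality = beta.modality
    return out


def mean_variance_filter(
    m: OmicsMatrix, mean_min: float, var_min: float
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep features with row mean > mean_min AND unbiased variance > var_min.

    Strict inequalities, so constant rows fall out even at var_min = 0.
    """
    if mean_min < 0 or var_min < 0:
        raise ValueError("filter thresholds must be >= 0")
    X = m.values
    keep = (X.mean(axis=1) > mean_min) & (X.var(axis=1, ddof=1) > var_min)
    modality = m.modality.iloc[0] if len(m.modality) else "gene"
    report = FilterReport(
        modality=str(modality),
        n_before=X.shape[0],
        n_after=int(keep.sum()),
        mean_threshold=mean_min,
        var_threshold=var_min,
    )
    if report.n_after == 0:
        raise ValueError(
            f"mean/variance filter removed all {report.n_before} {report.modality} features "
            f"(mean > {mean_min}, var > {var_min})"
        )
    log.info(
        "%s filter: %d -> %d features (mean > %g, var > %g)",
        report.modality, report.n_before, report.n_after, mean_min, var_min,
    )
    return m.subset_features(m.features[keep]), report


def concatenate_and_scale(expr: OmicsMatrix, meth: OmicsMatrix) -> ConcatenatedMatrix:
    """Stack genes over CpGs and scale every feature row to unit maximum."""
    if list(expr.samples) != list(meth.samples):
        diff = set(expr.samples) ^ set(meth.samples)
        raise ValueError(f"sample sets differ between modalities: {sorted(diff)[:10] or 'order mismatch'}")
    data = pd.concat([expr.data, meth.data], axis=0)
    if not data.index.is_unique:
        raise ValueError("gene and CpG feature ids collide")
    X = data.to_numpy().astype(float)
    if (X < 0).any():
        raise ValueError("concatenation input must be non-negative")
    rowmax = X.max(axis=1)
    zero = rowmax == 0
    if zero.any():
        raise ValueError(f"all-zero feature row(s): {list(data.index[zero][:5])}")
    scaled = X / rowmax[:, None]
    modality = pd.concat([expr.modality, meth.modality])
    return ConcatenatedMatrix(
        pd.DataFrame(scaled, index=data.index, columns=data.columns), modality
    )
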