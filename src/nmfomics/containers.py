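"""Core in-memory containers shared across the pipeline.

The pipeline's matrices follow the omics convention of *features x samples*
(genes or CpG probes on the rows, patients on the columns).  ``OmicsMatrix``
is a thin wrapper over a :class:`pandas.DataFrame` that additionally carries a
per-feature modality tag (``"gene"`` or ``"cpg"``) so downstream stages can
split joint selections back into the two data types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE = "gene"
CPG = "cpg"

__all__ = [
    "GENE",
    "CPG",
    "OmicsMatrix",
    "SampleSheet",
    "AnnotationTable",
    "GroundTruth",
]


@dataclass
class OmicsMatrix:
    """Non-negative features x samples matrix with modality tags.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id, columns are sample ids.
    modality:
        Either a single tag applied to every feature or a Series aligned to
        ``data.index`` with per-feature tags.
    """

    data: pd.DataFrame
    modality: pd.Series

    def __init__(self, data: pd.DataFrame, modality) -> None:
        if not data.index.is_unique:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if not data.columns.is_unique:
            raise ValueError("duplicate sample ids")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("matrix contains non-numeric cells")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[r, c]} at feature {data.index[r]!r}, "
                f"sample {data.columns[c]!r}"
            )
        if isinstance(modality, str):
            modality = pd.Series(modality, index=data.index)
        else:
            modality = pd.Series(modality)
            if not modality.index.equals(data.index):
                modality = modality.reindex(data.index)
                if modality.isna().any():
                    raise ValueError("modality tags do not cover every feature")
        bad = set(modality.unique()) - {GENE, CPG}
        if bad:
            raise ValueError(f"unknown modality tags: {sorted(bad)}")
        self.data = data
        self.modality = modality

    # -- convenience accessors -------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, ids) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[ids], self.modality.loc[ids])

    def subset_samples(self, ids) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(ids)], self.modality)


@dataclass
class SampleSheet:
    """Case/control design: one row per sample."""

    table: pd.DataFrame  # index sample_id; column "group" in {case, control}

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError("duplicate sample ids in sample sheet")
        if "group" not in self.table.columns:
            raise ValueError("sample sheet needs a 'group' column")
        bad = set(self.table["group"].unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    def split(self) -> tuple[pd.Index, pd.Index]:
        g = self.table["group"]
        return self.table.index[g == "case"], self.table.index[g == "control"]

    def require_two_per_group(self) -> None:
        case, control = self.split()
        if len(case) < 2 or len(control) < 2:
            raise ValueError(
                f"need >= 2 samples per group, got {len(case)} case / {len(control)} control"
            )


@dataclass
class AnnotationTable:
    """Genomic coordinates for genes (TSS) and CpG probes, plus regulatory flags.

    ``genes``: index gene_id, columns chrom, tss (0-based), strand.
    ``cpgs``: index probe_id, columns chrom, pos (0-based, converted from the
    1-based manifest at read time), is_promoter, is_enhancer, is_tfbs (bool).
    """

    genes: pd.DataFrame
    cpgs: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "tss", "strand"):
            if col not in self.genes.columns:
                raise ValueError(f"gene annotation missing column {col!r}")
        for col in ("chrom", "pos", "is_promoter", "is_enhancer", "is_tfbs"):
            if col not in self.cpgs.columns:
                raise ValueError(f"CpG annotation missing column {col!r}")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery scoring."""

    W_true: pd.DataFrame          # features x K, non-negative
    H_true: pd.DataFrame          # K x samples, non-negative
    differential_factors: set = field(default_factory=set)   # 0-based factor indices
    planted_pairs: list = field(default_factory=list)        # (gene_id, cpg_id, sign)
    cis_pairs: list = field(default_factory=list)            # (gene_id, cpg_id)
    enriched_cpg_set: set = field(default_factory=set)       # CpGs flagged enhancer-enriched
    hub_gene: str | None = None
    hub_cpgs: list = field(default_factory=list)
    hub_factor: int | None = None

    def __post_init__(self) -> None:
        if (self.W_true.to_numpy() < 0).any() or (self.H_true.to_numpy() < 0).any():
            raise ValueError("ground-truth factors must be non-negative")
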