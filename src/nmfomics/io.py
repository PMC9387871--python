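"""Readers and writers for the pipeline's on-disk formats.

Expression matrices are TSV (or MatrixMarket) with a header row of sample ids
and gene ids in the first column; methylation beta matrices are TSV with the
same layout; gene annotations are BED6 (0-based half-open, TSS = start on "+"
and end on "-"); CpG manifests are CSV with 1-based positions (Illumina
convention, converted to 0-based at this boundary); gene sets are GMT.

All result tables are plain TSV with '#'-prefixed metadata header lines
(config hash, seed) so runs diff cleanly.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .containers import GENE, CPG, AnnotationTable, OmicsMatrix, SampleSheet

log = logging.getLogger("nmfomics")

__all__ = [
    "PipelineConfig",
    "read_expression_matrix",
    "read_beta_matrix",
    "read_sample_sheet",
    "read_annotations",
    "read_gmt",
    "write_gmt",
    "write_matrix",
    "write_table",
    "read_table",
]


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #
@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline, serializable to/from YAML.

    Defaults: 90th-percentile feature selection on W, a +/-10 kb cis window
    around the TSS, BH-FDR 0.05 on correlation edges, and a 30-restart
    factorization at a fixed seed for stable, reproducible fits.
    """

    mean_expr: float = 1.25
    var_expr: float = 0.1
    mean_meth: float = 0.05
    var_meth: float = 0.005
    rank_grid: list = field(default_factory=lambda: list(range(2, 11)))
    chosen_rank: int = 5
    n_runs: int = 30
    runs_per_rank: int = 5
    seed: int = 111223
    objective: str = "kl"
    max_iter: int = 2000
    tol: float = 1e-6
    selection_percentile: float = 90.0
    correlation_fdr: float = 0.05
    mqtl_window_bp: int = 10_000
    hub_percentile: float = 90.0
    replication_r_threshold: float = 0.7
    replication_criterion: str = "p_sign"   # or "r_threshold"
    scale_axis: str = "feature"             # 'max' norm over feature rows
    drop_threshold: float = 0.01
    kmeans_grid: list = field(default_factory=lambda: [4, 5, 6, 7])

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        grid = list(self.rank_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])) or (grid and grid[0] < 2):
            raise ValueError("rank_grid must be strictly increasing with min >= 2")
        if grid and self.chosen_rank not in grid:
            raise ValueError(f"chosen_rank {self.chosen_rank} not in rank_grid")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.selection_percentile < 100:
            raise ValueError("selection_percentile must lie in (0, 100)")
        if not 0 < self.correlation_fdr < 1:
            raise ValueError("correlation_fdr must lie in (0, 1)")
        if self.mqtl_window_bp <= 0:
            raise ValueError("mqtl_window_bp must be positive")
        if self.objective not in ("kl", "frobenius"):
            raise ValueError("objective must be 'kl' or 'frobenius'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# --------------------------------------------------------------------------- #
# matrix readers
# --------------------------------------------------------------------------- #
def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def read_expression_matrix(path, format: str = "tsv") -> OmicsMatrix:
    """Read a gene x sample count/expression matrix (TSV or MatrixMarket)."""
    path = Path(path)
    if format == "tsv":
        df = _read_tsv_matrix(path)
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        mat = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        rows = pd.read_csv(path.with_suffix(".rows"), header=None)[0]
        cols = pd.read_csv(path.with_suffix(".cols"), header=None)[0]
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    m = OmicsMatrix(df, GENE)
    log.info("read expression matrix %s: %d genes x %d samples", path, *m.shape)
    return m


def read_beta_matrix(path, sheet: SampleSheet | None = None) -> OmicsMatrix:
    """Read a CpG x sample beta-value matrix; values must lie in [0, 1]."""
    df = _read_tsv_matrix(path)
    values = df.to_numpy()
    bad = (values < 0) | (values > 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value {values[r, c]} outside [0,1] at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if sheet is not None and not set(df.columns) <= set(sheet.samples):
        extra = sorted(set(df.columns) - set(sheet.samples))
        raise ValueError(f"beta matrix samples not in sample sheet: {extra[:5]}")
    m = OmicsMatrix(df, CPG)
    log.info("read beta matrix %s: %d probes x %d samples", path, *m.shape)
    return m


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return SampleSheet(df)


# --------------------------------------------------------------------------- #
# annotations
# --------------------------------------------------------------------------- #
def read_annotations(gene_path, cpg_path) -> AnnotationTable:
    """Read gene BED6 and CpG manifest CSV into one annotation table.

    BED is 0-based half-open: TSS = start for "+" strand, end for "-".
    Manifest positions are 1-based and converted to 0-based here, once.
    """
    bed = pd.read_csv(
        gene_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if bed[["chrom", "start", "end", "name", "strand"]].isna().any().any():
        raise ValueError(f"{gene_path}: missing coordinate or name field")
    bad = set(bed["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"{gene_path}: unknown strand symbol(s) {sorted(bad)}")
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"])
    genes = pd.DataFrame(
        {"chrom": bed["chrom"].values, "tss": tss, "strand": bed["strand"].values},
        index=pd.Index(bed["name"], name="gene_id"),
    )

    man = pd.read_csv(cpg_path, comment="#")
    required = {"probe_id", "chrom", "pos", "is_promoter", "is_enhancer", "is_tfbs"}
    if not required <= set(man.columns):
        raise ValueError(f"{cpg_path}: missing columns {sorted(required - set(man.columns))}")
    if man[["chrom", "pos"]].isna().any().any():
        raise ValueError(f"{cpg_path}: missing coordinate")
    cpgs = pd.DataFrame(
        {
            "chrom": man["chrom"].values,
            "pos": man["pos"].astype(int).values - 1,  # 1-based manifest -> 0-based
            "is_promoter": man["is_promoter"].astype(bool).values,
            "is_enhancer": man["is_enhancer"].astype(bool).values,
            "is_tfbs": man["is_tfbs"].astype(bool).values,
        },
        index=pd.Index(man["probe_id"], name="probe_id"),
    )
    return AnnotationTable(genes=genes, cpgs=cpgs)


# --------------------------------------------------------------------------- #
# gene sets (GMT)
# --------------------------------------------------------------------------- #
def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


# --------------------------------------------------------------------------- #
# result tables
# --------------------------------------------------------------------------- #
def write_matrix(m: OmicsMatrix | pd.DataFrame, path, header: dict | None = None) -> None:
    df = m.data if isinstance(m, OmicsMatrix) else m
    write_table(df, path, header=header, index=True)


def write_table(df: pd.DataFrame, path, header: dict | None = None, index: bool = True) -> None:
    """Write a TSV with '#key=value' metadata lines, full float precision."""
    buf = _io.StringIO()
    for key, val in (header or {}).items():
        buf.write(f"#{key}={val}\n")
    df.to_csv(buf, sep="\t", index=index, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#",
                       float_precision="round_trip")
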