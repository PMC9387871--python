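"""Multiplicative-update non-negative matrix factorization with multi-start
selection and rank-scan diagnostics.

The model is A ~ W H with A the concatenated (features x samples) omics
matrix, W >= 0 the basis (feature loadings per latent factor) and H >= 0 the
encoding (sample weights per factor).  Two objectives are available:

* ``kl`` (default) — generalized Kullback-Leibler divergence
  D(A||WH) = sum A log(A/WH) - A + WH, minimised by the Lee-Seung updates
  in the form popularised by Brunet et al.;
* ``frobenius`` — squared error sum (A - WH)^2.

Both updates are monotone (the objective never increases), which the test
suite verifies property-style.  Reproducibility follows from seeding: each of
the ``n_runs`` random restarts draws its init from an independent substream of
one seed, and the run with the lowest final loss wins.

After fitting, W columns are rescaled to unit maximum with the inverse scale
absorbed into H; the product W H is unchanged, and percentile thresholds on W
become comparable across factors and runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import ConcatenatedMatrix

log = logging.getLogger("nmfomics")

EPS = 1e-12

__all__ = ["JointNMF", "FactorModel", "RankScanResult", "nmf_fit", "rank_scan",
           "choose_rank", "correlate_factor_models"]


# --------------------------------------------------------------------------- #
# numerics
# --------------------------------------------------------------------------- #
def _loss(A: np.ndarray, W: np.ndarray, H: np.ndarray, objective: str) -> float:
    V = W @ H
    if objective == "frobenius":
        return float(((A - V) ** 2).sum())
    Vc = np.maximum(V, EPS)
    pos = A > 0
    return float(np.sum(A[pos] * np.log(A[pos] / Vc[pos])) - A.sum() + V.sum())


def _update_kl(A, W, H):
    V = np.maximum(W @ H, EPS)
    H *= (W.T @ (A / V)) / np.maximum(W.sum(axis=0)[:, None], EPS)
    V = np.maximum(W @ H, EPS)
    W *= ((A / V) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
    return W, H


def _update_frobenius(A, W, H):
    H *= (W.T @ A) / np.maximum(W.T @ W @ H, EPS)
    W *= (A @ H.T) / np.maximum(W @ (H @ H.T), EPS)
    return W, H


def _fit_single(A, r, objective, rng, max_iter, tol):
    m, n = A.shape
    W = rng.uniform(EPS, 1.0, size=(m, r))
    H = rng.uniform(EPS, 1.0, size=(r, n))
    update = _update_kl if objective == "kl" else _update_frobenius
    trace = [_loss(A, W, H, objective)]
    for _ in range(max_iter):
        W, H = update(A, W, H)
        cur = _loss(A, W, H, objective)
        trace.append(cur)
        if not np.isfinite(cur):
            raise FloatingPointError("non-finite loss")
        prev = trace[-2]
        if abs(prev - cur) <= tol * max(abs(prev), EPS):
            break
    return W, H, np.asarray(trace)


def _normalize_columns(W, H):
    """Scale W columns to unit max, absorb the inverse into H (WH invariant)."""
    scale = W.max(axis=0)
    scale[scale == 0] = 1.0
    return W / scale[None, :], H * scale[:, None]


# --------------------------------------------------------------------------- #
# estimator
# --------------------------------------------------------------------------- #
class JointNMF(BaseEstimator, TransformerMixin):
    """Scikit-learn style NMF estimator over features x samples matrices.

    Unlike :class:`sklearn.decomposition.NMF` this estimator keeps the omics
    orientation (rows = features, columns = samples), runs ``n_runs`` random
    restarts and retains the best final loss, and exposes the KL objective in
    the multiplicative form used for joint omics factorizations.

    Parameters
    ----------
    rank : number of latent factors r (1 <= r < min(m, n)).
    objective : 'kl' or 'frobenius'.
    n_runs : random restarts; the run with the lowest final loss is kept.
    max_iter, tol : per-run iteration budget and relative-change stop.
    random_state : seed; every restart uses an independent substream.

    Attributes (after ``fit``)
    --------------------------
    W_ : (m, rank) basis, columns rescaled to unit max.
    H_ : (rank, n) encodings.
    best_run_loss_, per_run_losses_, loss_trace_, n_iter_, reconstruction_rss_.
    """

    def __init__(self, rank=5, objective="kl", n_runs=30, max_iter=2000,
                 tol=1e-6, random_state=0):
        self.rank = rank
        self.objective = objective
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, ConcatenatedMatrix):
            X = X.data
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        A = np.asarray(X, dtype=float)
        if A.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if not np.isfinite(A).all() or (A < 0).any():
            raise ValueError("input must be finite and non-negative")
        return A

    def fit(self, X, y=None):
        A = self._as_array(X)
        m, n = A.shape
        if not 1 <= self.rank < min(m, n):
            raise ValueError(f"rank {self.rank} out of range for {m}x{n} matrix")
        if self.objective not in ("kl", "frobenius"):
            raise ValueError("objective must be 'kl' or 'frobenius'")
        streams = np.random.SeedSequence(self.random_state).spawn(self.n_runs)
        best = None
        losses = []
        for i, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            try:
                W, H, trace = _fit_single(A, self.rank, self.objective, rng,
                                          self.max_iter, self.tol)
            except FloatingPointError:
                log.warning("run %d diverged (non-finite loss); skipped", i)
                losses.append(np.nan)
                continue
            losses.append(float(trace[-1]))
            if best is None or trace[-1] < best[2][-1]:
                best = (W, H, trace)
        if best is None:
            raise RuntimeError("all factorization runs failed")
        W, H, trace = best
        self.W_, self.H_ = _normalize_columns(W, H)
        self.loss_trace_ = trace
        self.per_run_losses_ = losses
        self.best_run_loss_ = float(np.nanmin(losses))
        self.n_iter_ = len(trace) - 1
        self.reconstruction_rss_ = float(((A - self.W_ @ self.H_) ** 2).sum())
        return self

    def transform(self, X):
        """Encode new samples (columns) against the fitted basis W_."""
        A = self._as_array(X)
        if A.shape[0] != self.W_.shape[0]:
            raise ValueError("feature dimension mismatch with fitted basis")
        rng = np.random.default_rng(np.random.SeedSequence(self.random_state).spawn(1)[0])
        H = rng.uniform(EPS, 1.0, size=(self.rank, A.shape[1]))
        W = self.W_
        for _ in range(self.max_iter):
            if self.objective == "kl":
                V = np.maximum(W @ H, EPS)
                Hn = H * (W.T @ (A / V)) / np.maximum(W.sum(axis=0)[:, None], EPS)
            else:
                Hn = H * (W.T @ A) / np.maximum(W.T @ W @ H, EPS)
            if np.abs(Hn - H).max() <= self.tol * max(H.max(), EPS):
                H = Hn
                break
            H = Hn
        return H

    def fit_transform(self, X, y=None):
        return self.fit(X).H_


# --------------------------------------------------------------------------- #
# labelled front-end
# --------------------------------------------------------------------------- #
@dataclass
class FactorModel:
    W: pd.DataFrame            # features x r, columns LF1..LFr
    H: pd.DataFrame            # r x samples
    rank: int
    objective: str
    best_run_loss: float
    per_run_losses: list
    seed: int
    n_iter_used: int
    loss_trace: np.ndarray = field(repr=False, default=None)
    rss: float = float("nan")
    evar: float = float("nan")

    @property
    def factor_names(self) -> list:
        return list(self.W.columns)


def nmf_fit(A: ConcatenatedMatrix, r: int, objective: str = "kl", n_runs: int = 30,
            max_iter: int = 2000, tol: float = 1e-6, seed: int = 111223) -> FactorModel:
    """Fit a rank-r factorization of the concatenated matrix (best of n_runs)."""
    est = JointNMF(rank=r, objective=objective, n_runs=n_runs, max_iter=max_iter,
                   tol=tol, random_state=seed).fit(A)
    names = [f"LF{i + 1}" for i in range(r)]
    if isinstance(A, ConcatenatedMatrix):
        features, samples = A.features, A.samples
        tss = float((A.values ** 2).sum())
    else:
        arr = JointNMF._as_array(A)
        features = pd.RangeIndex(arr.shape[0])
        samples = pd.RangeIndex(arr.shape[1])
        tss = float((arr ** 2).sum())
    return FactorModel(
        W=pd.DataFrame(est.W_, index=features, columns=names),
        H=pd.DataFrame(est.H_, index=names, columns=samples),
        rank=r,
        objective=objective,
        best_run_loss=est.best_run_loss_,
        per_run_losses=est.per_run_losses_,
        seed=seed,
        n_iter_used=est.n_iter_,
        loss_trace=est.loss_trace_,
        rss=est.reconstruction_rss_,
        evar=1.0 - est.reconstruction_rss_ / tss,
    )


@dataclass
class RankScanResult:
    table: pd.DataFrame  # index rank; columns rss, evar, delta_evar

    @property
    def ranks(self) -> list:
        return list(self.table.index)


def rank_scan(A: ConcatenatedMatrix, ranks, runs_per_rank: int = 5,
              seed: int = 111223, objective: str = "kl", max_iter: int = 2000,
              tol: float = 1e-6) -> RankScanResult:
    """Fit every rank in ``ranks`` and record RSS / explained variance.

    evar = 1 - RSS / sum(A^2) with the uncentered total sum of squares;
    delta_evar is the gain over the previous scanned rank (null for the
    first).  A rank whose fit fails is recorded as missing and the scan
    continues.
    """
    rows = []
    for r in ranks:
        try:
            model = nmf_fit(A, r, objective=objective, n_runs=runs_per_rank,
                            max_iter=max_iter, tol=tol, seed=seed)
            rows.append((r, model.rss, model.evar))
        except Exception as exc:  # noqa: BLE001 - record and continue
            log.warning("rank %d failed: %s", r, exc)
            rows.append((r, np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["rank", "rss", "evar"]).set_index("rank")
    df["delta_evar"] = df["evar"].diff()
    return RankScanResult(df)


def choose_rank(scan: RankScanResult, drop_threshold: float = 0.01) -> int:
    """Advisory elbow rule on delta explained variance.

    Returns the largest rank whose own evar gain is still >= drop_threshold
    (the minimum scanned rank counts by convention) while the next rank's
    gain falls below it.  When no rank qualifies, the minimum rank is
    returned with a warning — the choice is advisory and a configured rank
    overrides it, just as the original analysis chose its rank by inspection.
    """
    df = scan.table
    if len(df) < 2:
        raise ValueError("rank scan needs at least 2 ranks")
    ranks = list(df.index)
    delta = df["delta_evar"]
    candidates = []
    for i, r in enumerate(ranks[:-1]):
        own_ok = (i == 0) or (pd.notna(delta.loc[r]) and delta.loc[r] >= drop_threshold)
        nxt = ranks[i + 1]
        if own_ok and pd.notna(delta.loc[nxt]) and delta.loc[nxt] < drop_threshold:
            candidates.append(r)
    if not candidates:
        log.warning("no rank satisfies the delta-evar drop rule; returning min rank %d", ranks[0])
        return ranks[0]
    return max(candidates)


def correlate_factor_models(models: list, cluster_model: int = -1):
    """Pearson correlations between H rows of every model pair.

    Returns a long-format table (model_i, factor_i, model_j, factor_j, R)
    with null R for constant factors, plus the average-linkage hierarchical
    leaf order of the ``cluster_model``-th model's factors (distance
    1 - correlation between its H rows).
    """
    samples = list(models[0].H.columns)
    for m in models:
        if list(m.H.columns) != samples:
            raise ValueError("models must share the sample set and order")
    rows = []
    for i, mi in enumerate(models):
        for j, mj in enumerate(models):
            if j < i:
                continue
            for fi in mi.H.index:
                x = mi.H.loc[fi].to_numpy()
                for fj in mj.H.index:
                    if i == j and list(mi.H.index).index(fj) < list(mi.H.index).index(fi):
                        continue
                    y = mj.H.loc[fj].to_numpy()
                    if x.std() == 0 or y.std() == 0:
                        r = np.nan
                    else:
                        r = float(np.corrcoef(x, y)[0, 1])
                    rows.append((i, fi, j, fj, r))
    table = pd.DataFrame(rows, columns=["model_i", "factor_i", "model_j", "factor_j", "R"])

    Hc = models[cluster_model].H
    order = list(Hc.index)
    if len(order) > 2:
        C = np.corrcoef(Hc.to_numpy())
        C = np.nan_to_num(C, nan=0.0)
        dist = 1.0 - C[np.triu_indices(len(order), k=1)]
        link = sch.linkage(np.maximum(dist, 0.0), method="average")
        order = [order[k] for k in sch.leaves_list(link)]
    return table, order
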