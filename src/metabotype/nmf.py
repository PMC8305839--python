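"""Consensus non-negative matrix factorization and rank selection.

Subtypes are discovered by factorizing the preprocessed (auto-scaled)
patient matrix.  Because auto-scaled data contain negative entries while
NMF requires non-negativity, the matrix is first *folded*: the positive
and negative parts are stacked along the feature axis, which doubles the
features but preserves sign information symmetrically.

For each candidate rank k the factorization is repeated from many random
initializations; each replicate assigns every sample to the coefficient
row with the largest weight, and the sample x sample *consensus matrix*
records how often each pair co-clusters.  Rank selection combines the
cophenetic correlation of the consensus matrix (higher = more stable),
the mean silhouette width under the consensus distance, and the
proportion of ambiguous clustering (PAC; lower = more stable).  Final
labels come from average-linkage hierarchical clustering of the chosen
rank's consensus matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

_EPS = 1e-12


# ---------------------------------------------------------------------------
# folding


def fold_nonnegative(X: np.ndarray) -> np.ndarray:
    """Stack positive and negative parts of a feature x sample matrix.

    Returns ``[max(X, 0); max(-X, 0)]`` (2F x S).  The original matrix is
    recovered by :func:`unfold`.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("fold_nonnegative requires a finite matrix")
    return np.vstack([np.maximum(X, 0.0), np.maximum(-X, 0.0)])


def unfold(V: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fold_nonnegative` (top block minus bottom block)."""
    V = np.asarray(V, dtype=float)
    f2 = V.shape[0]
    if f2 % 2:
        raise ValueError("folded matrix must have an even number of rows")
    f = f2 // 2
    return V[:f] - V[f:]


# ---------------------------------------------------------------------------
# single NMF fit (Lee-Seung multiplicative updates, Frobenius objective)


@dataclass
class NMFFit:
    """One NMF replicate: V ~ W @ H with non-negative factors."""

    W: np.ndarray
    H: np.ndarray
    mse: float
    n_iter: int
    seed: int
    objective_trace: np.ndarray = field(repr=False, default=None)


def nmf_fit(
    V: np.ndarray,
    k: int,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFFit:
    """Multiplicative-update minimization of ||V - WH||^2_F.

    W and H are initialized uniform-random in (0, 1]; the Lee-Seung update
    rules make the objective non-increasing at every iteration.  Stops at
    `max_iter` iterations or when the relative objective change drops
    below `tol`.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("nmf_fit requires a non-negative matrix")
    n_feat, n_samp = V.shape
    if not 1 <= k <= min(n_feat, n_samp):
        raise ValueError(f"rank k={k} must lie in 1..min{V.shape}")
    rng = np.random.default_rng(seed)
    W = 1.0 - rng.random((n_feat, k))  # uniform in (0, 1]
    H = 1.0 - rng.random((k, n_samp))

    trace = []
    prev = np.linalg.norm(V - W @ H) ** 2
    trace.append(prev)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = np.linalg.norm(V - W @ H) ** 2
        trace.append(obj)
        if prev > 0 and (prev - obj) / max(prev, _EPS) < tol:
            prev = obj
            break
        prev = obj
    mse = prev / V.size
    return NMFFit(W=W, H=H, mse=float(mse), n_iter=n_iter, seed=seed, objective_trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# consensus machinery


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Correlation between consensus distances and dendrogram cophenetic
    distances under average linkage; 1 for a perfectly stable consensus."""
    D = 1.0 - np.asarray(consensus, dtype=float)
    np.fill_diagonal(D, 0.0)
    y = squareform(D, checks=False)
    if np.std(y) == 0:
        warnings.warn("constant consensus distances; cophenetic undefined", stacklevel=2)
        return float("nan")
    Z = average(y)
    c, _ = cophenet(Z, y)
    return float(c)


def pac(consensus: np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal
    consensus entries strictly inside (u1, u2)."""
    if not 0.0 <= u1 < u2 <= 1.0:
        raise ValueError("require 0 <= u1 < u2 <= 1")
    C = np.asarray(consensus, dtype=float)
    iu = np.triu_indices_from(C, k=1)
    vals = C[iu]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > u1) & (vals < u2)))


def silhouette_consensus(consensus: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width under the consensus distance 1 - C."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = 1.0 - np.asarray(consensus, dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return float(silhouette_score(D, labels, metric="precomputed"))


def cluster_consensus(consensus: np.ndarray, k: int) -> np.ndarray:
    """Final labels: average-linkage clustering of 1 - consensus, cut at k.

    Cluster ids are relabelled 1..k by increasing cluster size, so
    subtype 1 is the smallest cluster (mirroring cohort conventions where
    the rare subtype is listed first).
    """
    C = np.asarray(consensus, dtype=float)
    n = C.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    raw = fcluster(Z, t=k, criterion="maxclust")
    ids, sizes = np.unique(raw, return_counts=True)
    order = ids[np.argsort(sizes, kind="stable")]
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.asarray([remap[r] for r in raw], dtype=int)


@dataclass
class RankDiagnostics:
    """Consensus diagnostics for one candidate rank."""

    k: int
    consensus: np.ndarray
    cophenetic: float
    silhouette: float
    pac: float
    labels: np.ndarray
    best_fit: NMFFit


@dataclass
class ConsensusResult:
    """Consensus-NMF result across the rank range."""

    ranks: dict[int, RankDiagnostics]
    chosen_k: int
    labels: pd.Series  # sample -> subtype id (1-based, size-ascending)
    sample_ids: list[str]

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = [
            {"k": d.k, "cophenetic": d.cophenetic, "silhouette": d.silhouette, "pac": d.pac}
            for d in self.ranks.values()
        ]
        return pd.DataFrame(rows).set_index("k").sort_index()


def select_rank(diagnostics: Mapping[int, tuple[float, float, float]] | Mapping[int, RankDiagnostics]) -> int:
    """Choose the rank with the highest cophenetic coefficient.

    Ties are broken by higher silhouette, then lower PAC, then smaller k.
    Ranks whose cophenetic coefficient is NaN are ignored; all-NaN input
    is an error.
    """
    rows = []
    for k, d in diagnostics.items():
        if isinstance(d, RankDiagnostics):
            coph, sil, p = d.cophenetic, d.silhouette, d.pac
        else:
            coph, sil, p = d
        if np.isnan(coph):
            continue
        rows.append((k, coph, sil, p))
    if not rows:
        raise ValueError("no rank has a defined cophenetic coefficient")
    rows.sort(key=lambda r: (-r[1], -r[2], r[3], r[0]))
    return rows[0][0]


def _replicate_labels(fit: NMFFit) -> np.ndarray:
    # resolve the W/H scale ambiguity before reading cluster assignments:
    # scale each coefficient row by its basis column norm
    scale = np.linalg.norm(fit.W, axis=0)
    return np.argmax(fit.H * scale[:, None], axis=0)


def consensus_nmf(
    V: np.ndarray,
    k_range: Iterable[int] = range(3, 7),
    n_replicates: int = 100,
    seed: int = 0,
    max_iter: int = 100,
    sample_ids: Sequence[str] | None = None,
) -> ConsensusResult:
    """Consensus NMF over a rank range with seeded random restarts.

    Per replicate, each sample is assigned to the argmax coefficient row;
    ``consensus[i, j]`` is the fraction of replicates co-assigning samples
    i and j.  Degenerate replicates (with empty clusters) are kept.  The
    replicate with the lowest reconstruction error is retained per rank
    for loading inspection, but final labels are read from the consensus
    matrix, which is more stable than any single replicate.
    """
    if n_replicates < 2:
        raise ValueError("consensus requires at least 2 replicates")
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    ks = sorted(set(int(k) for k in k_range))
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(len(ks), n_replicates))

    ranks: dict[int, RankDiagnostics] = {}
    for ki, k in enumerate(ks):
        co = np.zeros((n, n))
        best: NMFFit | None = None
        for r in range(n_replicates):
            fit = nmf_fit(V, k, max_iter=max_iter, seed=int(rep_seeds[ki, r]))
            lab = _replicate_labels(fit)
            co += lab[:, None] == lab[None, :]
            if best is None or fit.mse < best.mse:
                best = fit
        C = co / n_replicates
        np.fill_diagonal(C, 1.0)
        labels_k = cluster_consensus(C, k)
        if len(np.unique(labels_k)) < k:
            warnings.warn(f"k={k}: final clustering produced empty clusters", stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coph = cophenetic_coefficient(C)
        sil = silhouette_consensus(C, labels_k) if len(np.unique(labels_k)) > 1 else float("nan")
        ranks[k] = RankDiagnostics(
            k=k, consensus=C, cophenetic=coph, silhouette=sil, pac=pac(C), labels=labels_k, best_fit=best
        )

    chosen = select_rank(ranks)
    labels = pd.Series(ranks[chosen].labels, index=pd.Index(list(sample_ids), name="sample_id"), name="subtype")
    return ConsensusResult(ranks=ranks, chosen_k=chosen, labels=labels, sample_ids=list(sample_ids))


def subtype_study(
    X: pd.DataFrame,
    k_range: Iterable[int] = range(3, 7),
    n_replicates: int = 100,
    seed: int = 0,
    max_iter: int = 100,
) -> ConsensusResult:
    """Convenience wrapper: fold an auto-scaled sample x metabolite frame
    and run consensus NMF over it."""
    V = fold_nonnegative(X.to_numpy(dtype=float).T)
    return consensus_nmf(
        V,
        k_range=k_range,
        n_replicates=n_replicates,
        seed=seed,
        max_iter=max_iter,
        sample_ids=list(X.index),
    )
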