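"""Correlation-network metabolic programs (weighted co-abundance modules).

The auto-scaled patient matrix is turned into a signed weighted network:
pairwise Pearson correlations are mapped to ``((1 + r) / 2) ** beta``
with the soft-threshold power ``beta`` chosen for approximate scale-free
topology.  The topological overlap measure (TOM) smooths the adjacency
by shared neighbourhoods; average-linkage clustering of ``1 - TOM`` with
a static cut yields modules, small clusters fall into the grey module 0.
Each module is summarized by its eigen-metabolite (first principal
component across samples); modules with highly correlated eigen-profiles
are merged into *metabolic programs*.  Programs are then related to
subtypes by correlating eigen-profiles with subtype indicators, members
are scored by module membership (kME, the correlation of a metabolite
with an eigen-profile), hubs are the top-kME members, and pathway
over-representation is tested per module with the hypergeometric tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationNetwork:
    """Soft-thresholded weighted adjacency over metabolites."""

    adjacency: pd.DataFrame
    beta: float
    fit_r2: float
    signed: bool = True


@dataclass
class TraitCorrelation:
    """Module-subtype Pearson correlations with exact t-transform p-values."""

    r: pd.DataFrame  # module x subtype
    p: pd.DataFrame


@dataclass
class ModuleSet:
    """Module assignment and derived summaries.

    ``assignment`` maps every metabolite to a module id; 0 is the grey
    module of unassigned metabolites.  Remaining fields are filled in by
    the corresponding operations.
    """

    assignment: pd.Series
    eigen: pd.DataFrame | None = None  # samples x modules
    kme: pd.DataFrame | None = None  # metabolites x modules
    trait_cor: TraitCorrelation | None = None
    enrichment: pd.DataFrame | None = None
    merged_from: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.unique()) - {0})

    def members(self, module: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


# ---------------------------------------------------------------------------
# network construction


def _correlation(X: pd.DataFrame) -> np.ndarray:
    cor = np.corrcoef(X.to_numpy(dtype=float).T)
    if np.any(np.isnan(cor)):
        raise ValueError("correlation undefined (constant metabolite profile?)")
    return np.clip(cor, -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) on log10(mean connectivity) over bins.

    The connectivity distribution is histogrammed into `n_bins` bins;
    empty bins are dropped and the squared Pearson correlation of the
    log-log relationship is returned (0 when fewer than 3 usable bins).
    """
    k = np.asarray(connectivity, dtype=float)
    if k.max() <= 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    centers, freqs = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        centers.append(k[sel].mean())
        freqs.append(sel.mean())
    centers, freqs = np.asarray(centers), np.asarray(freqs)
    usable = centers > 0
    if usable.sum() < 3:
        return 0.0
    res = stats.linregress(np.log10(centers[usable]), np.log10(freqs[usable]))
    return float(res.rvalue**2)


def adjacency(X: pd.DataFrame, beta: float, signed: bool = True) -> CorrelationNetwork:
    """Soft-thresholded adjacency: signed ``((1 + r)/2)^beta`` or
    unsigned ``|r|^beta``, zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = _correlation(X)
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    adj = pd.DataFrame(a, index=X.columns, columns=X.columns)
    k = a.sum(axis=0)
    return CorrelationNetwork(adjacency=adj, beta=float(beta), fit_r2=scale_free_fit(k), signed=signed)


def pick_power(
    X: pd.DataFrame,
    powers: range = range(1, 21),
    target_r2: float = 0.8,
    signed: bool = True,
) -> tuple[int, float]:
    """Smallest soft-threshold power reaching the scale-free fit target.

    Returns ``(beta, fit_r2)``.  Strongly modular (block-structured) data
    are not scale-free, so the target is often unreachable; in that case
    the conventional default power for the network type (12 signed, 6
    unsigned) is used, with a warning.  The fit landscape over powers is
    too noisy on modular data for an argmax fallback to be stable.
    """
    if X.shape[0] < 20:
        raise ValueError("pick_power needs at least 20 samples")
    cor = _correlation(X)
    base = (1.0 + cor) / 2.0 if signed else np.abs(cor)
    fallback = 12 if signed else 6
    for beta in powers:
        a = base**beta
        np.fill_diagonal(a, 0.0)
        r2 = scale_free_fit(a.sum(axis=0))
        if r2 >= target_r2:
            return int(beta), float(r2)
    a = base**fallback
    np.fill_diagonal(a, 0.0)
    fallback_r2 = scale_free_fit(a.sum(axis=0))
    warnings.warn(
        f"no power reached scale-free fit {target_r2}; using the "
        f"{'signed' if signed else 'unsigned'} convention beta={fallback} "
        f"(R^2={fallback_r2:.3f})",
        stacklevel=2,
    )
    return fallback, float(fallback_r2)


def tom(network: CorrelationNetwork) -> pd.DataFrame:
    """Topological overlap: ``(l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``l_ij = sum_u a_iu a_uj``; symmetric, in [0, 1], diagonal 1."""
    A = network.adjacency.to_numpy(dtype=float)
    L = A @ A
    k = A.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(T, index=network.adjacency.index, columns=network.adjacency.columns)


# ---------------------------------------------------------------------------
# module detection and summaries


def _relabel_by_size(raw: np.ndarray, grey: np.ndarray) -> np.ndarray:
    """Relabel cluster ids 1..M by decreasing size; grey positions get 0."""
    out = np.zeros(len(raw), dtype=int)
    kept = raw[~grey]
    ids, sizes = np.unique(kept, return_counts=True)
    order = ids[np.argsort(-sizes, kind="stable")]
    remap = {old: new for new, old in enumerate(order, start=1)}
    out[~grey] = [remap[r] for r in kept]
    return out


def detect_modules(tom_matrix: pd.DataFrame, min_size: int = 5, cut_height: float = 0.96) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than `min_size` are sent to the grey module 0;
    surviving modules are numbered 1..M by decreasing size.
    """
    T = tom_matrix.to_numpy(dtype=float)
    D = 1.0 - T
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    raw = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    grey = np.asarray([sizes[r] < min_size for r in raw])
    labels = _relabel_by_size(raw, grey)
    if (labels == 0).all():
        warnings.warn("all metabolites fell into the grey module", stacklevel=2)
    return ModuleSet(assignment=pd.Series(labels, index=tom_matrix.index, name="module"))


def eigen_metabolite(X: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First principal-component profile per module (unit variance).

    The sign is oriented so the mean correlation with member profiles is
    non-negative; a single-metabolite module's eigen-profile is that
    metabolite's standardized profile.
    """
    modules = sorted(set(assignment.unique()) - {0})
    if not modules:
        raise ValueError("no non-grey modules to summarize")
    cols = {}
    for mod in modules:
        members = assignment.index[assignment == mod]
        sub = X[members].to_numpy(dtype=float)
        sub = sub - sub.mean(axis=0)
        if sub.shape[1] == 1:
            score = sub[:, 0]
        else:
            u, s, _ = np.linalg.svd(sub, full_matrices=False)
            score = u[:, 0] * s[0]
        sd = score.std(ddof=1)
        if sd == 0:
            raise ValueError(f"module {mod} has a constant eigen-profile")
        score = score / sd
        corrs = np.array([np.corrcoef(score, X[m].to_numpy(dtype=float))[0, 1] for m in members])
        if corrs.mean() < 0:
            score = -score
        cols[mod] = score
    return pd.DataFrame(cols, index=X.index)


def kme(X: pd.DataFrame, eigen: pd.DataFrame) -> pd.DataFrame:
    """Module membership: correlation of each metabolite with each
    eigen-profile (metabolites x modules, in [-1, 1])."""
    Xv = X.to_numpy(dtype=float)
    Ev = eigen.to_numpy(dtype=float)
    Xc = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0, ddof=1)
    Ec = (Ev - Ev.mean(axis=0)) / Ev.std(axis=0, ddof=1)
    K = Xc.T @ Ec / (len(X) - 1)
    return pd.DataFrame(np.clip(K, -1.0, 1.0), index=X.columns, columns=eigen.columns)


def merge_modules(modules: ModuleSet, X: pd.DataFrame, merge_height: float = 0.25) -> ModuleSet:
    """Merge modules whose eigen-profiles are highly correlated.

    Average-linkage clustering of ``1 - cor(eigen_i, eigen_j)`` cut at
    `merge_height` (default 0.25, i.e. eigen correlation above 0.75
    merges).  Eigen-profiles and kME are recomputed for the merged
    programs; the merge history is recorded.  Idempotent at a fixed
    height.
    """
    eigen = modules.eigen if modules.eigen is not None else eigen_metabolite(X, modules.assignment)
    old_ids = list(eigen.columns)
    if len(old_ids) <= 1:
        groups = [tuple(old_ids)] if old_ids else []
    else:
        cor = np.corrcoef(eigen.to_numpy(dtype=float).T)
        D = np.clip(1.0 - cor, 0.0, None)
        np.fill_diagonal(D, 0.0)
        Z = average(squareform(D, checks=False))
        raw = fcluster(Z, t=merge_height, criterion="distance")
        groups = [
            tuple(mid for mid, r in zip(old_ids, raw) if r == g) for g in np.unique(raw)
        ]
    assignment = modules.assignment.copy()
    sizes = []
    for group in groups:
        members = assignment.index[assignment.isin(group)]
        sizes.append((len(members), group))
    sizes.sort(key=lambda t: (-t[0], t[1]))
    new_assignment = pd.Series(0, index=assignment.index, dtype=int, name="module")
    merged_from: dict[int, tuple[int, ...]] = {}
    for new_id, (_, group) in enumerate(sizes, start=1):
        new_assignment[assignment.isin(group)] = new_id
        merged_from[new_id] = group
    new_eigen = eigen_metabolite(X, new_assignment)
    return ModuleSet(
        assignment=new_assignment,
        eigen=new_eigen,
        kme=kme(X, new_eigen),
        merged_from=merged_from,
    )


def module_trait_cor(eigen: pd.DataFrame, labels: pd.Series) -> TraitCorrelation:
    """Pearson correlation of eigen-profiles with subtype 0/1 indicators.

    p-values use the exact t-transform ``t = r sqrt((n - 2) / (1 - r^2))``
    with n - 2 degrees of freedom.
    """
    labels = labels.loc[eigen.index]
    subtypes = sorted(labels.unique())
    n = len(labels)
    r = pd.DataFrame(index=eigen.columns, columns=subtypes, dtype=float)
    p = pd.DataFrame(index=eigen.columns, columns=subtypes, dtype=float)
    for s in subtypes:
        ind = (labels == s).to_numpy(dtype=float)
        for mod in eigen.columns:
            e = eigen[mod].to_numpy(dtype=float)
            if e.std() == 0 or ind.std() == 0:
                r.loc[mod, s], p.loc[mod, s] = np.nan, np.nan
                continue
            rv = float(np.corrcoef(e, ind)[0, 1])
            r.loc[mod, s] = rv
            if abs(rv) >= 1.0:
                p.loc[mod, s] = 0.0
            else:
                t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
                p.loc[mod, s] = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return TraitCorrelation(r=r, p=p)


def hub_metabolites(kme_table: pd.DataFrame, assignment: pd.Series, n: int = 3) -> dict[int, list[str]]:
    """Top-n members of each module by own-module kME (whole module when
    smaller than n)."""
    hubs: dict[int, list[str]] = {}
    for mod in kme_table.columns:
        members = assignment.index[assignment == mod]
        ranked = kme_table.loc[members, mod].sort_values(ascending=False)
        hubs[mod] = list(ranked.index[:n])
    return hubs


def module_enrichment(assignment: pd.Series, annotation) -> pd.DataFrame:
    """Hypergeometric pathway over-representation per module.

    The urn is the set of assigned (non-grey) metabolites; for each
    module and each pathway with at least one assigned member, the
    one-sided tail probability of drawing at least the observed overlap
    is computed, with BH correction across pathways within each module.
    """
    urn = list(assignment.index[assignment > 0])
    N = len(urn)
    members_by_pathway = annotation.pathway_members(restrict_to=urn)
    rows = []
    for mod in sorted(set(assignment.unique()) - {0}):
        mod_members = set(assignment.index[assignment == mod])
        n_mod = len(mod_members)
        block = []
        for pathway, mets in sorted(members_by_pathway.items()):
            K = len(mets)
            if K == 0:
                continue
            overlap = len(mod_members.intersection(mets))
            pval = float(stats.hypergeom.sf(overlap - 1, N, K, n_mod))
            block.append(
                {
                    "module": mod,
                    "pathway": pathway,
                    "n_module": n_mod,
                    "n_pathway": K,
                    "overlap": overlap,
                    "p": pval,
                }
            )
        if block:
            fdr = multipletests([b["p"] for b in block], method="fdr_bh")[1]
            for b, q in zip(block, fdr):
                b["fdr"] = float(q)
            rows.extend(block)
    return pd.DataFrame(rows, columns=["module", "pathway", "n_module", "n_pathway", "overlap", "p", "fdr"])


def significant_modules(enrichment: pd.DataFrame, trait_cor: TraitCorrelation, alpha: float = 0.05) -> list[int]:
    """Modules with both a pathway enriched at fdr < alpha and a subtype
    correlation at p < alpha."""
    enriched = set(enrichment.loc[enrichment["fdr"] < alpha, "module"])
    correlated = set(trait_cor.p.index[(trait_cor.p < alpha).any(axis=1)])
    return sorted(enriched & correlated)


# ---------------------------------------------------------------------------
# orchestration


def fit_programs(
    X: pd.DataFrame,
    annotation=None,
    labels: pd.Series | None = None,
    beta: int | None = 12,
    target_r2: float = 0.8,
    min_size: int = 5,
    cut_height: float = 0.96,
    merge_height: float = 0.25,
    signed: bool = True,
) -> tuple[ModuleSet, CorrelationNetwork]:
    """Full program pipeline: adjacency, TOM, detect, merge, summarize.

    ``beta=None`` selects the soft-threshold power by scale-free fit
    (:func:`pick_power`); the default is the fixed signed-network
    convention power 12, which is stable on strongly modular data where
    the scale-free criterion is ill-posed.
    """
    if beta is None:
        beta, _ = pick_power(X, target_r2=target_r2, signed=signed)
    net = adjacency(X, beta, signed=signed)
    T = tom(net)
    modules = detect_modules(T, min_size=min_size, cut_height=cut_height)
    if not modules.module_ids():
        return modules, net
    modules.eigen = eigen_metabolite(X, modules.assignment)
    modules = merge_modules(modules, X, merge_height=merge_height)
    if labels is not None:
        modules.trait_cor = module_trait_cor(modules.eigen, labels)
    if annotation is not None:
        modules.enrichment = module_enrichment(modules.assignment, annotation)
    return modules, net
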