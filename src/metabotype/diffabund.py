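"""Differential metabolite analysis across subtypes.

Given the auto-scaled patient matrix and subtype labels, this module
computes per-metabolite Welch two-sample t-tests for every
subtype-versus-rest and subtype-pair contrast with Benjamini-Hochberg
FDR control, selects per-subtype classifier metabolites, summarizes
significant changes by lipid subclass, scores pathways with the
differential abundance score

    DAS = (n_up - n_down) / (n_up + n_down)

over a pathway's significantly changed member metabolites (+1: all
members increased; -1: all decreased), checks subtype independence from
clinical covariates, and builds a simple metabolite-pathway bipartite
network whose metabolite projection is clustered by connected components.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DIFF_COLUMNS = ("contrast", "metabolite", "mean_diff", "p", "fdr", "direction")


def _welch_frame(A: pd.DataFrame, B: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Welch t-test per metabolite between two sample groups."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance metabolites yield nan
        t, p = stats.ttest_ind(
            A.to_numpy(dtype=float), B.to_numpy(dtype=float), axis=0, equal_var=False
        )
    mean_diff = A.mean(axis=0).to_numpy() - B.mean(axis=0).to_numpy()
    p = np.where(np.isnan(p), 1.0, p)  # both groups constant -> no evidence
    fdr = multipletests(p, method="fdr_bh")[1]
    direction = np.where(mean_diff > 0, "up", np.where(mean_diff < 0, "down", "none"))
    return pd.DataFrame(
        {
            "contrast": contrast,
            "metabolite": A.columns,
            "mean_diff": mean_diff,
            "p": p,
            "fdr": fdr,
            "direction": direction,
        }
    )


def _check_groups(labels: pd.Series) -> list:
    counts = labels.value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        warnings.warn(
            f"skipping subtypes {small} with fewer than 2 samples", stacklevel=3
        )
    usable = sorted(counts.index[counts >= 2])
    if len(usable) < 2:
        raise ValueError("need at least 2 subtypes with >= 2 samples each")
    return usable


def one_vs_rest(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Each subtype versus all other patients, per metabolite.

    Returns a long frame with columns contrast, metabolite, mean_diff
    (difference of auto-scaled means, subtype minus rest), p (two-sided
    Welch), fdr (BH within contrast) and direction.
    """
    labels = labels.loc[X.index]
    out = []
    for s in _check_groups(labels):
        in_s = labels == s
        if (~in_s).sum() < 2:
            raise ValueError(f"rest group for subtype {s} has fewer than 2 samples")
        out.append(_welch_frame(X.loc[in_s], X.loc[~in_s], f"subtype{s}_vs_rest"))
    return pd.concat(out, ignore_index=True)


def pairwise(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Every subtype pair (a < b), per metabolite; mean_diff is a minus b."""
    labels = labels.loc[X.index]
    uniq = _check_groups(labels)
    out = []
    for a, b in itertools.combinations(uniq, 2):
        out.append(
            _welch_frame(X.loc[labels == a], X.loc[labels == b], f"subtype{a}_vs_subtype{b}")
        )
    return pd.concat(out, ignore_index=True)


def select_classifiers(diff: pd.DataFrame, n: int = 30, alpha: float = 0.05) -> pd.DataFrame:
    """Top-n classifier metabolites per subtype-versus-rest contrast.

    Among metabolites significant at ``fdr < alpha``, the `n` with the
    largest absolute mean difference, in decreasing |effect| order.
    """
    rows = []
    for contrast, block in diff.groupby("contrast", sort=True):
        if not contrast.endswith("_vs_rest"):
            continue
        sig = block[block["fdr"] < alpha].copy()
        if sig.empty:
            warnings.warn(f"{contrast}: no significant metabolites", stacklevel=2)
            continue
        sig["abs_effect"] = sig["mean_diff"].abs()
        sig = sig.sort_values(["abs_effect", "metabolite"], ascending=[False, True]).head(n)
        sig["rank"] = np.arange(1, len(sig) + 1)
        rows.append(sig[["contrast", "rank", "metabolite", "mean_diff", "fdr"]])
    if not rows:
        return pd.DataFrame(columns=["contrast", "rank", "metabolite", "mean_diff", "fdr"])
    return pd.concat(rows, ignore_index=True)


def das(diff: pd.DataFrame, annotation, alpha: float = 0.05) -> pd.DataFrame:
    """Differential abundance score per contrast and pathway.

    Counts the pathway's member metabolites significantly increased
    (``n_up``) and decreased (``n_down``) at ``fdr < alpha`` and scores
    ``(n_up - n_down) / (n_up + n_down)``; NaN when no member changes.
    Pathways without any measured member are omitted.
    """
    rows = []
    for contrast, block in diff.groupby("contrast", sort=True):
        block = block.set_index("metabolite")
        members = annotation.pathway_members(restrict_to=list(block.index))
        sig = block[block["fdr"] < alpha]
        for pathway, mets in sorted(members.items()):
            if not mets:
                continue
            sig_members = sig.loc[sig.index.intersection(mets)]
            n_up = int((sig_members["direction"] == "up").sum())
            n_down = int((sig_members["direction"] == "down").sum())
            score = (n_up - n_down) / (n_up + n_down) if (n_up + n_down) else float("nan")
            rows.append(
                {
                    "contrast": contrast,
                    "pathway": pathway,
                    "n_measured": len(mets),
                    "n_up": n_up,
                    "n_down": n_down,
                    "das": score,
                }
            )
    return pd.DataFrame(rows)


def subclass_summary(diff: pd.DataFrame, annotation, alpha: float = 0.05) -> pd.DataFrame:
    """Significant up/down counts per lipid subclass and subtype contrast.

    Also reports the median signed effect among the significant members
    of each cell.  Use :func:`prominent_subclasses` for the subclasses
    with the most changes overall.
    """
    sub = annotation.subclass_of()
    lipid = sub[sub != ""]
    rows = []
    for contrast, block in diff.groupby("contrast", sort=True):
        if not contrast.endswith("_vs_rest"):
            continue
        block = block.set_index("metabolite")
        for subclass in sorted(lipid.unique()):
            mets = lipid.index[lipid == subclass]
            cell = block.loc[block.index.intersection(mets)]
            sig = cell[cell["fdr"] < alpha]
            rows.append(
                {
                    "contrast": contrast,
                    "subclass": subclass,
                    "n_up": int((sig["direction"] == "up").sum()),
                    "n_down": int((sig["direction"] == "down").sum()),
                    "median_effect": float(sig["mean_diff"].median()) if len(sig) else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def prominent_subclasses(summary: pd.DataFrame, n: int = 5) -> list[str]:
    """The `n` lipid subclasses with the most significant changes overall."""
    totals = (
        summary.assign(total=summary["n_up"] + summary["n_down"])
        .groupby("subclass")["total"]
        .sum()
        .sort_values(ascending=False)
    )
    return list(totals.index[:n])


def covariate_independence(labels: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Test each covariate for association with the subtype labels.

    Continuous covariates: Kruskal-Wallis across subtypes; categorical
    covariates: chi-square test of independence.  A constant covariate is
    reported with p = 1.
    """
    labels = labels.loc[covariates.index]
    rows = []
    for name in covariates.columns:
        col = covariates[name]
        continuous = pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        )
        if col.nunique(dropna=True) <= 1:
            test = "kruskal-wallis" if continuous else "chi-square"
            rows.append({"covariate": name, "test": test, "statistic": 0.0, "p": 1.0})
            continue
        if continuous:
            groups = [col[labels == s].dropna().to_numpy() for s in sorted(labels.unique())]
            stat, p = stats.kruskal(*groups)
            rows.append({"covariate": name, "test": "kruskal-wallis", "statistic": float(stat), "p": float(p)})
        else:
            table = pd.crosstab(labels, col)
            stat, p, _, _ = stats.chi2_contingency(table)
            rows.append({"covariate": name, "test": "chi-square", "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class PathwayNetwork:
    """Bipartite significant-metabolite/pathway graph and its projection."""

    bipartite: nx.Graph
    projection: nx.Graph  # metabolite-metabolite, weight = shared pathways
    components: dict[str, int]  # metabolite -> component id (1-based, by size)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in self.projection.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


def pathway_network(diff: pd.DataFrame, annotation, alpha: float = 0.05) -> PathwayNetwork:
    """Bipartite network of significant metabolites and their pathways.

    Metabolites significant at ``fdr < alpha`` in any contrast become one
    node set, their pathways the other.  The metabolite-metabolite
    projection weights each edge by the number of shared pathways; node
    clusters are the connected components of the projection, numbered by
    decreasing size.
    """
    sig_mets = sorted(diff.loc[diff["fdr"] < alpha, "metabolite"].unique())
    B = nx.Graph()
    B.add_nodes_from(sig_mets, bipartite=0)
    members = annotation.pathway_members(restrict_to=sig_mets)
    for pathway, mets in sorted(members.items()):
        B.add_node(pathway, bipartite=1)
        B.add_edges_from((m, pathway) for m in mets)

    proj = nx.Graph()
    proj.add_nodes_from(sig_mets)
    for pathway, mets in members.items():
        for a, b in itertools.combinations(sorted(mets), 2):
            if proj.has_edge(a, b):
                proj[a][b]["weight"] += 1
            else:
                proj.add_edge(a, b, weight=1)

    comps = sorted(nx.connected_components(proj), key=lambda c: (-len(c), sorted(c)))
    membership = {m: i for i, comp in enumerate(comps, start=1) for m in comp}
    return PathwayNetwork(bipartite=B, projection=proj, components=membership)
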