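"""CIMP classification by hierarchical clustering of the most variable loci.

Samples are clustered on Euclidean distance over the top-k loci by standard
deviation (k = 2000 by default, SD with n-1 denominator, ties broken by probe
id).  The dendrogram is cut at its top split into two major clusters and each
major cluster is cut again at its own top split into two sub-clusters,
mirroring the major/sub structure used for CIMP assignment: the major cluster
with the higher mean beta over the selected loci is CIMP+, the other CIMP-.

Paired-lesion retention: a pair retains its CIMP status when early and late
lesions carry the same label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from .model import BetaMatrix, SampleSheet

LINKAGE_METHODS = ("single", "complete", "average", "ward")


@dataclass
class CimpResult:
    selected_probes: list
    linkage_tree: np.ndarray
    sample_order: list
    major_assignment: dict          # sample -> 1 | 2  (1 = lower-mean cluster)
    sub_assignment: dict            # sample -> '1a' | '1b' | '2a' | '2b'
    cluster_means: dict             # '1', '2', '1a', ... -> mean beta
    anova_f_major: float
    anova_p_major: float
    anova_f_sub: float
    anova_p_sub: float
    cimp_label: dict = field(default_factory=dict)   # sample -> 'CIMP+' | 'CIMP-'
    degenerate_anova: bool = False


@dataclass
class RetentionTable:
    per_pair: pd.DataFrame          # pair_id, early/late label, retained, similar_profile
    retained_fraction: float
    similar_profile_fraction: float


def select_most_variable(beta: BetaMatrix | pd.DataFrame, k: int = 2000) -> list:
    """Top-k probes by across-sample SD (n-1), descending; ties by probe id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = beta.beta if isinstance(beta, BetaMatrix) else beta
    sd = df.std(axis=1, ddof=1)
    order = sorted(df.index, key=lambda p: (-sd[p], p))
    return order[: min(k, len(order))]


def hierarchical_cluster(beta_subset: pd.DataFrame, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering of samples (columns) on Euclidean distance.

    Returns the scipy linkage matrix; leaves are column positions in
    ``beta_subset.columns``.
    """
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    if beta_subset.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    x = beta_subset.to_numpy(dtype=float).T
    if np.isnan(x).any():
        raise ValueError("NaN in clustering input; failed probes must be removed upstream")
    return hierarchy.linkage(x, method=linkage, metric="euclidean")


def _subtree_leaves(tree: hierarchy.ClusterNode) -> list:
    return tree.pre_order(lambda node: node.id)


def cut_major_and_sub(linkage_tree: np.ndarray, sample_ids) -> tuple[dict, dict]:
    """Cut the dendrogram into 2 major clusters at the top split, then each
    major cluster at its own top split into 2 sub-clusters.

    Major labels are assigned deterministically: the cluster containing the
    lexicographically smallest sample id is numbered first, then renumbered
    by mean later in :func:`assign_cimp` via cluster means.  Sub-clusters are
    '<major>a' / '<major>b' with 'a' the larger (ties: the one holding the
    smallest sample id).  Singleton sub-clusters are permitted with a warning.
    """
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    root = hierarchy.to_tree(linkage_tree)
    if n < 4:
        warnings.warn("<4 samples: major cut only")
    if root.is_leaf():
        raise ValueError("cannot cut a single-leaf tree")

    majors = [root.left, root.right]
    # deterministic ordering of the two majors by smallest member sample id
    majors.sort(key=lambda t: min(sample_ids[i] for i in _subtree_leaves(t)))
    major_assignment: dict = {}
    sub_assignment: dict = {}
    for number, subtree in zip((1, 2), majors):
        leaves = _subtree_leaves(subtree)
        for i in leaves:
            major_assignment[sample_ids[i]] = number
        if n < 4:
            continue
        if subtree.is_leaf():
            warnings.warn(f"major cluster {number} is a singleton; no sub-split")
            sub_assignment[sample_ids[subtree.id]] = f"{number}a"
            continue
        children = [subtree.left, subtree.right]
        children.sort(
            key=lambda t: (-len(_subtree_leaves(t)),
                           min(sample_ids[i] for i in _subtree_leaves(t)))
        )
        for letter, child in zip("ab", children):
            child_leaves = _subtree_leaves(child)
            if len(child_leaves) == 1:
                warnings.warn(f"sub-cluster {number}{letter} is a singleton")
            for i in child_leaves:
                sub_assignment[sample_ids[i]] = f"{number}{letter}"
    return major_assignment, sub_assignment


def cluster_mean_beta(assignment: dict, beta_subset: pd.DataFrame) -> dict:
    """Unweighted mean beta over all (probe, sample) cells of each cluster."""
    out = {}
    clusters = sorted({str(v) for v in assignment.values()})
    for c in clusters:
        members = [s for s, v in assignment.items() if str(v) == c]
        present = [s for s in members if s in beta_subset.columns]
        if not present or len(present) < len(members):
            raise ValueError(f"cluster {c!r} is empty or has samples without data")
        out[c] = float(beta_subset[present].to_numpy().mean())
    return out


def anova_cluster_means(per_sample_mean: pd.Series, assignment: dict):
    """One-way fixed-effects ANOVA of per-sample mean beta across clusters.

    Returns (F, p, degenerate): when the within-group variance is exactly
    zero and group means differ, p is reported as 0.0 with the degenerate
    flag set.
    """
    clusters = sorted({str(v) for v in assignment.values()})
    groups = []
    for c in clusters:
        members = [s for s, v in assignment.items() if str(v) == c]
        if not members:
            raise ValueError(f"cluster {c!r} is empty")
        groups.append(per_sample_mean[members].to_numpy(dtype=float))
    if len(groups) < 2 or sum(len(g) for g in groups) < 3:
        raise ValueError("ANOVA needs >=2 groups and >=3 observations")
    pooled = np.concatenate(groups)
    total_ss = ((pooled - pooled.mean()) ** 2).sum()
    within_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within_ss <= 1e-12 * max(total_ss, 1e-300):
        means = [g.mean() for g in groups]
        if max(means) > min(means):
            return float("inf"), 0.0, True
        return 0.0, 1.0, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = f_oneway(*groups)
    return float(f), float(p), False


def assign_cimp(major_assignment: dict, cluster_means: dict) -> dict:
    """Label the higher-mean major cluster CIMP+, the other CIMP-."""
    majors = sorted({str(v) for v in major_assignment.values()})
    if len(majors) != 2:
        raise ValueError("CIMP assignment requires exactly 2 major clusters")
    m1, m2 = (cluster_means[m] for m in majors)
    if m1 == m2:
        raise ValueError("degenerate: equal major-cluster means")
    positive = majors[0] if m1 > m2 else majors[1]
    return {
        s: ("CIMP+" if str(v) == positive else "CIMP-")
        for s, v in major_assignment.items()
    }


def run_cimp(beta: BetaMatrix, samples=None, k: int = 2000,
             linkage: str = "average", anova_unit: str = "sample") -> CimpResult:
    """Select loci, cluster, cut, compute means/ANOVA and assign CIMP labels.

    ``anova_unit='sample'`` (default) runs the ANOVA on per-sample mean beta —
    one value per sample — avoiding pseudo-replication; ``'cell'`` uses every
    (probe, sample) cell.
    """
    df = beta.beta if samples is None else beta.beta[list(samples)]
    selected = select_most_variable(BetaMatrix(beta=df.clip(0, 1)), k)
    sub = df.loc[selected]
    tree = hierarchical_cluster(sub, linkage)
    major, subc = cut_major_and_sub(tree, list(sub.columns))
    means = cluster_mean_beta(major, sub)
    # renumber majors so cluster 1 is the lower-mean (CIMP-) cluster
    if means["1"] > means["2"]:
        major = {s: 3 - v for s, v in major.items()}
        subc = {s: f"{3 - int(lab[0])}{lab[1]}" for s, lab in subc.items()}
        means = cluster_mean_beta(major, sub)
    all_means = dict(means)
    if subc:
        all_means.update(cluster_mean_beta(subc, sub))

    if anova_unit == "sample":
        unit_major = sub.mean(axis=0)
        unit_sub = unit_major
        major_for_anova, sub_for_anova = major, subc
    elif anova_unit == "cell":
        stacked = sub.melt(var_name="sample", value_name="beta")
        unit_major = pd.Series(
            stacked["beta"].to_numpy(),
            index=pd.Index([f"{s}#{i}" for i, s in enumerate(stacked["sample"])]),
        )
        major_for_anova = {
            f"{s}#{i}": major[s] for i, s in enumerate(stacked["sample"])
        }
        sub_for_anova = {
            f"{s}#{i}": subc[s] for i, s in enumerate(stacked["sample"])
        } if subc else {}
        unit_sub = unit_major
    else:
        raise ValueError("anova_unit must be 'sample' or 'cell'")

    f_major, p_major, deg1 = anova_cluster_means(unit_major, major_for_anova)
    if sub_for_anova:
        f_sub, p_sub, deg2 = anova_cluster_means(unit_sub, sub_for_anova)
    else:
        f_sub, p_sub, deg2 = float("nan"), float("nan"), False

    labels = assign_cimp(major, means)
    return CimpResult(
        selected_probes=selected,
        linkage_tree=tree,
        sample_order=list(sub.columns),
        major_assignment=major,
        sub_assignment=subc,
        cluster_means=all_means,
        anova_f_major=f_major,
        anova_p_major=p_major,
        anova_f_sub=f_sub,
        anova_p_sub=p_sub,
        cimp_label=labels,
        degenerate_anova=deg1 or deg2,
    )


def score_retention(cimp_label: dict, sheet: SampleSheet,
                    beta_subset: pd.DataFrame | None = None,
                    similarity_quantile: float = 0.25) -> RetentionTable:
    """Per-pair CIMP retention and (optionally) profile similarity.

    A pair is retained when early and late lesions share a CIMP label.  When
    ``beta_subset`` (samples as columns, selected loci as rows) is given, a
    pair is additionally flagged profile-similar when its early-late
    Euclidean distance falls below the ``similarity_quantile`` of all
    inter-sample distances over the same loci.
    """
    cutoff = None
    dist = None
    if beta_subset is not None:
        order = list(beta_subset.columns)
        dmat = squareform(pdist(beta_subset.to_numpy(dtype=float).T))
        dist = pd.DataFrame(dmat, index=order, columns=order)
        cutoff = float(np.quantile(squareform(dmat, checks=False), similarity_quantile))

    rows = []
    for pid, (early, late) in sorted(sheet.pairs().items()):
        if early not in cimp_label or late not in cimp_label:
            warnings.warn(f"pair {pid!r}: missing CIMP label; excluded")
            continue
        retained = cimp_label[early] == cimp_label[late]
        similar = bool(dist.loc[early, late] < cutoff) if dist is not None else None
        rows.append({
            "pair_id": pid, "early_label": cimp_label[early],
            "late_label": cimp_label[late], "retained": retained,
            "similar_profile": similar,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no complete pairs to score")
    retained_fraction = float(table["retained"].mean())
    similar_fraction = (
        float(table["similar_profile"].mean()) if dist is not None else float("nan")
    )
    return RetentionTable(
        per_pair=table,
        retained_fraction=retained_fraction,
        similar_profile_fraction=similar_fraction,
    )


def linkage_to_newick(linkage_tree: np.ndarray, labels) -> str:
    """Export a scipy linkage matrix as a Newick string."""
    labels = list(labels)
    root = hierarchy.to_tree(linkage_tree)

    def _render(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _render(node.left, node.dist)
        right = _render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _render(root, root.dist) + ";"
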