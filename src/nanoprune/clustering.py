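"""Descriptor redundancy removal by rank-correlation hierarchical clustering.

Descriptors computed from the same underlying physics (e.g. the many
per-atom-type potential-energy averages) are strongly rank-correlated
and carry no independent information for regression.  The module
clusters concentration-independent descriptors with average-linkage
hierarchical clustering on the distance ``1 - |Spearman rho|``, cuts
the dendrogram with the inconsistency coefficient (default 0.8,
roughly a one-sigma level), validates the tree against the original
distances via the cophenetic correlation, and nominates one
representative per cluster — preferring names commonly studied in the
toxicity literature when a priority list is given.

Absolute correlation is used as similarity: an anticorrelated pair is
just as redundant for model building as a correlated one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from nanoprune.core_data import DescriptorMatrix

__all__ = [
    "LinkageTree",
    "ClusterResult",
    "spearman_matrix",
    "cluster_descriptors",
    "nominate_representatives",
]


@dataclass
class LinkageTree:
    """A scipy-format linkage matrix plus its leaf names."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage
    leaves: list[str]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (branch lengths = merge heights)."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{parent_height:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        return rec(tree, tree.dist).rsplit(":", 1)[0] + ";"


@dataclass
class ClusterResult:
    partition: dict[str, int]  # column name -> cluster id (1-based)
    representatives: dict[int, str] = field(default_factory=dict)
    cophenetic: float = float("nan")
    inconsistency_threshold: float = float("nan")
    constant_columns: list[str] = field(default_factory=list)
    mean_within_abs_rho: dict[int, float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition.values()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(c for c, k in self.partition.items() if k == cluster_id)


def spearman_matrix(m: DescriptorMatrix, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlation of descriptor columns (mid-rank ties).

    Constant columns get correlation 0 against everything (with a
    warning) and 1 on the diagonal.
    """
    cols = columns if columns is not None else m.column_names
    X = m.data[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >=3 rows for a rank correlation")
    const = [c for c, v in zip(cols, X.T) if np.ptp(v) == 0]
    if const:
        warnings.warn(
            f"constant columns have undefined rank correlation, reported as 0: {const}",
            stacklevel=2,
        )
    if len(cols) == 1:
        rho = np.ones((1, 1))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, _ = spearmanr(X)
        if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 columns
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=cols, columns=cols)


def cluster_descriptors(
    m: DescriptorMatrix,
    inconsistency: float = 0.8,
    depth: int = 2,
    columns: list[str] | None = None,
    max_distance: float = 0.8,
) -> tuple[LinkageTree, ClusterResult]:
    """Cluster descriptors on distance 1 - |Spearman rho|, average linkage.

    The tree is cut where the inconsistency coefficient (computed at
    ``depth`` 2) exceeds ``inconsistency``, or where the merge distance
    reaches ``max_distance`` (default 0.8, i.e. |rho| <= 0.2): columns
    that are not even weakly rank-correlated are not redundant and must
    not be forced into a cluster, which the inconsistency statistic
    alone cannot guarantee (it is scale-free, so a forest of mutually
    independent columns would otherwise merge consistently).  Constant
    columns are excluded before clustering and reported separately.
    The cophenetic coefficient between tree and original distances
    validates the clustering.
    """
    cols = columns if columns is not None else m.column_names
    if len(cols) < 2:
        raise ValueError("need >=2 columns to cluster")
    X = m.data[cols]
    constant = [c for c in cols if np.ptp(X[c].to_numpy(dtype=float)) == 0]
    if constant:
        warnings.warn(
            f"constant columns excluded from clustering: {constant}", stacklevel=2
        )
    active = [c for c in cols if c not in constant]
    if len(active) < 2:
        raise ValueError("fewer than 2 non-constant columns to cluster")

    rho = spearman_matrix(m, active).to_numpy()
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)

    Z = hierarchy.linkage(condensed, method="average")
    if len(active) > 2:
        coph, _ = hierarchy.cophenet(Z, condensed)
    else:
        coph = 1.0  # a single pairwise distance is represented exactly

    # cut criterion: inconsistency > threshold OR merge beyond the
    # redundancy ceiling; propagated as a subtree maximum so fcluster's
    # monocrit cut is well defined
    crit = hierarchy.inconsistent(Z, depth)[:, 3].copy()
    crit[Z[:, 2] >= max_distance] = np.inf
    n_leaves = len(active)
    for i in range(Z.shape[0]):
        for child in Z[i, :2]:
            ci = int(child) - n_leaves
            if ci >= 0:
                crit[i] = max(crit[i], crit[ci])
    labels = hierarchy.fcluster(Z, t=inconsistency, criterion="monocrit", monocrit=crit)

    partition = {c: int(k) for c, k in zip(active, labels)}
    # constant columns become their own singleton clusters
    next_id = max(partition.values(), default=0)
    for c in constant:
        next_id += 1
        partition[c] = next_id

    rho_df = pd.DataFrame(rho, index=active, columns=active)
    within: dict[int, float] = {}
    for k in sorted(set(partition.values())):
        members = [c for c in active if partition[c] == k]
        if len(members) > 1:
            sub = np.abs(rho_df.loc[members, members].to_numpy())
            within[k] = float(sub[np.triu_indices_from(sub, k=1)].mean())

    result = ClusterResult(
        partition=partition,
        cophenetic=float(coph),
        inconsistency_threshold=inconsistency,
        constant_columns=constant,
        mean_within_abs_rho=within,
    )
    result = nominate_representatives(result, priority=[], rho=rho_df)
    return LinkageTree(linkage=Z, leaves=active), result


def nominate_representatives(
    result: ClusterResult,
    priority: list[str],
    rho: pd.DataFrame | None = None,
) -> ClusterResult:
    """Pick one representative column per cluster.

    The highest-priority member wins; without a priority match, the
    member with the highest mean |rho| to its cluster mates; remaining
    ties break lexicographically.
    """
    reps: dict[int, str] = {}
    for k in sorted(set(result.partition.values())):
        members = result.members(k)
        chosen = None
        for name in priority:
            if name in members:
                chosen = name
                break
        if chosen is None:
            if rho is not None and len(members) > 1 and all(c in rho.index for c in members):
                sub = np.abs(rho.loc[members, members].to_numpy())
                np.fill_diagonal(sub, np.nan)
                scores = np.nanmean(sub, axis=1)
                best = np.nanmax(scores)
                chosen = sorted(mc for mc, s in zip(members, scores) if s >= best - 1e-12)[0]
            else:
                chosen = members[0]  # lexicographic
        reps[k] = chosen
    return ClusterResult(
        partition=result.partition,
        representatives=reps,
        cophenetic=result.cophenetic,
        inconsistency_threshold=result.inconsistency_threshold,
        constant_columns=result.constant_columns,
        mean_within_abs_rho=result.mean_within_abs_rho,
    )
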