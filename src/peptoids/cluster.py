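"""Ward hierarchical clustering of the descriptor matrix into families.

The library is grouped into K structural families by agglomerative Ward
clustering on the column-standardized descriptor matrix: at each step the
pair of clusters whose merge minimally increases the total within-cluster
sum of squares is joined (Lance-Williams update on squared Euclidean
distances). Merge heights are reported on the distance scale (the "D2"
convention, as used by scipy): two singletons merge at their Euclidean
distance. Labels, not heights, are the tested contract.

The default K is 12, which subdivides a ~221-member library into
relatively even groups; smaller K tends to produce one dominant cluster
and larger K many singletons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import ValidationError


@dataclass
class ClusterAssignment:
    """Family labels (1..k), merge heights, and the features used."""

    labels: np.ndarray
    k: int
    merge_heights: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValidationError(
                f"labels must cover 1..{self.k}, got {sorted(present)}")


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    return X, tuple(f"x{j}" for j in range(X.shape[1]))


def standardize(X):
    """Column-standardize to mean 0 and sample (n-1) standard deviation 1.

    Constant columns carry no clustering information; they are dropped
    with a warning. A DataFrame input returns a DataFrame.
    """
    arr, names = _as_matrix(X)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("standardize requires at least 2 rows")
    if np.isnan(arr).any():
        raise ValidationError("standardize: missing values not allowed")
    sd = arr.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("standardize: all columns are constant")
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
    Z = (arr[:, keep] - arr[:, keep].mean(axis=0)) / sd[keep]
    kept = tuple(n for n, k in zip(names, keep) if k)
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(Z, columns=list(kept), index=X.index)
    return Z


class WardFamilies(ClusterMixin, BaseEstimator):
    """Ward agglomerative clustering cut at ``n_clusters`` families.

    Parameters
    ----------
    n_clusters : int, default 12
        Number of families to cut the tree into.
    standardize_input : bool, default False
        Column-standardize X before clustering. The library pipeline
        standardizes explicitly, so the default is off.

    Attributes
    ----------
    labels_ : ndarray of int
        Family label per row, in 1..k (every label occurs).
    merge_heights_ : ndarray
        The n-1 nondecreasing merge costs on the distance scale.
    assignment_ : ClusterAssignment
    """

    def __init__(self, n_clusters: int = 12, standardize_input: bool = False):
        self.n_clusters = n_clusters
        self.standardize_input = standardize_input

    def fit(self, X, y=None):
        arr, names = _as_matrix(X)
        n = arr.shape[0]
        k = self.n_clusters
        if k < 1:
            raise ValidationError(f"n_clusters must be >= 1, got {k}")
        if k > n:
            raise ValidationError(f"n_clusters={k} exceeds n rows={n}")
        if self.standardize_input:
            Z = standardize(pd.DataFrame(arr, columns=list(names)))
            arr, names = Z.to_numpy(), tuple(Z.columns)
        if n == 1:
            self.linkage_ = np.empty((0, 4))
            raw = np.ones(1, dtype=int)
        else:
            self.linkage_ = linkage(arr, method="ward")
            raw = fcluster(self.linkage_, t=k, criterion="maxclust")
        # relabel by first appearance for input-order determinism
        remap, labels = {}, np.empty(n, dtype=int)
        for i, lab in enumerate(raw):
            labels[i] = remap.setdefault(lab, len(remap) + 1)
        self.labels_ = labels
        self.merge_heights_ = self.linkage_[:, 2].copy()
        self.feature_names_ = names
        self.assignment_ = ClusterAssignment(
            labels=labels, k=k, merge_heights=self.merge_heights_,
            feature_names=names)
        return self


def ward_cluster(Z, k: int) -> ClusterAssignment:
    """Ward-cluster a (standardized) matrix and cut at k families."""
    return WardFamilies(n_clusters=k).fit(Z).assignment_


def cluster_profile(assignment: ClusterAssignment, X) -> pd.DataFrame:
    """Per-family member counts and feature means/ranges."""
    arr, names = _as_matrix(X)
    if arr.shape[0] != len(assignment.labels):
        raise ValidationError("label/row count mismatch")
    df = pd.DataFrame(arr, columns=list(names))
    df["label"] = assignment.labels
    g = df.groupby("label")
    out = pd.DataFrame({"label": sorted(g.groups), "n": g.size().values})
    for name in names:
        out[f"{name}_mean"] = g[name].mean().values
        out[f"{name}_min"] = g[name].min().values
        out[f"{name}_max"] = g[name].max().values
    return out


def select_representatives(assignment: ClusterAssignment, Z, m: int) -> list[int]:
    """Pick m members per family, nearest the family centroid first.

    Distances are Euclidean in the standardized space; ties break toward
    the lowest row index. Families smaller than m return all members.
    Returns row indices ordered by (family, proximity rank).
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    arr, _ = _as_matrix(Z)
    chosen: list[int] = []
    for lab in range(1, assignment.k + 1):
        idx = np.flatnonzero(assignment.labels == lab)
        centroid = arr[idx].mean(axis=0)
        d = np.linalg.norm(arr[idx] - centroid, axis=1)
        order = idx[np.lexsort((idx, d))]
        chosen.extend(order[:m].tolist())
    return chosen
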