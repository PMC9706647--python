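"""Hierarchical clustering of individuals from genotypes.

Distances are Euclidean over dosages with pairwise-complete handling of
missing calls: the squared distance over the markers non-missing in both
individuals is rescaled by M / M_ij (total markers over shared markers) so
that pairs with different missingness remain comparable.  Complete-linkage
agglomeration then builds the dendrogram used to verify that the two chicken
types (and the breeds within them) separate, and to flag outliers —
individuals whose flat cluster is dominated by a different breed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataio import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray  # symmetric, nonnegative, zero diagonal

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any() or not np.allclose(np.diag(m), 0):
            raise ValueError("distances must be nonnegative with zero diagonal")


@dataclass
class Dendrogram:
    """Complete-linkage merge tree in scipy linkage format (heights nondecreasing)."""

    sample_ids: list[str]
    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) from cutting the tree into k clusters."""
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def genotype_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise-complete Euclidean distances between individuals.

    d(i,j) = sqrt( sum over shared markers of (x_i - x_j)^2  *  M / M_ij )
    where M is the marker count and M_ij the number of markers non-missing in
    both individuals.  A pair sharing no markers is an error.
    """
    X = ds.dosage
    n, M = X.shape
    W = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X)
    B = A * A  # x^2 where observed, 0 elsewhere
    shared = W @ W.T
    off = ~np.eye(n, dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(
            f"samples {ds.samples['sample_id'][i]!r} and {ds.samples['sample_id'][j]!r} "
            "share no non-missing markers"
        )
    d2 = B @ W.T + W @ B.T - 2 * A @ A.T
    d2 = np.clip(d2, 0, None) * (M / shared)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(list(ds.samples["sample_id"]), np.sqrt(d2))


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with maximum (complete) linkage."""
    condensed = squareform(d.matrix, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(sample_ids=list(d.sample_ids), linkage=Z)


def flag_outliers(
    tree: Dendrogram, samples: pd.DataFrame, k: int | None = None
) -> list[str]:
    """Samples whose flat cluster is dominated by a different breed.

    The tree is cut into ``k`` clusters (default: the number of breeds).  A
    sample is an outlier when the majority breed of its cluster differs from
    its own label; clusters with a tied majority are excluded with a warning.
    """
    breeds = samples.set_index("sample_id")["breed"]
    if k is None:
        k = breeds.nunique()
    if k > len(tree.sample_ids):
        raise ValueError(f"k={k} exceeds the number of samples")
    labels = tree.cut(k)
    out: list[str] = []
    for cl in np.unique(labels):
        members = [sid for sid, lab in zip(tree.sample_ids, labels) if lab == cl]
        counts = breeds.loc[members].value_counts()
        top = counts[counts == counts.max()]
        if len(top) > 1:
            logger.warning("cluster %d has a tied majority breed; excluded from outlier calls", cl)
            continue
        majority = top.index[0]
        out.extend(sid for sid in members if breeds.loc[sid] != majority)
    return out
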