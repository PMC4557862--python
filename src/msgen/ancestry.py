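"""Genetic-ancestry extraction.

The chain is: genome-wide allele-sharing distance -> classical
(Torgerson) multidimensional scaling with 50 dimensions and/or Ward
hierarchical clustering -> reference-anchored population labels.
Case-control cohorts are labelled by cutting the Ward tree (default
three clusters: a large EUNW cluster, a small Ashkenazi cluster, and a
small third cluster); trio studies, whose internal relatedness distorts
tree cuts, are labelled by thresholding the first MDS coordinate (PC1)
with its sign anchored to the reference panel.  Cohort-level structure
is summarised by a Ward dendrogram over allele-frequency vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "MdsCoordinates",
    "allele_sharing_distance",
    "classical_mds",
    "ward_tree",
    "label_clusters",
    "classify_trio_members",
    "cohort_frequency_dendrogram",
    "tree_to_newick",
]

LABEL_AJ, LABEL_EUNW, LABEL_OTHER = "AJ", "EUNW", "OTHER"


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix in [0, 1] with zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if D.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length mismatch")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if D.min() < -1e-12 or D.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.values = D

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class MdsCoordinates:
    """Classical-MDS embedding: columns ordered by decreasing eigenvalue."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: list[str]
    pc1_anchored: bool = False

    def pc1(self) -> pd.Series:
        return pd.Series(self.coords[:, 0], index=self.sample_ids, name="PC1")


def allele_sharing_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """Mean per-site allele-sharing distance d(i,j) = mean |d_i - d_j| / 2.

    The average runs over sites non-missing in both individuals; it is 0
    for identical genotypes and 1 for opposite homozygotes everywhere.
    A deterministic stand-in for haplotype-sharing (IBD) distances: it
    preserves the within/between-population ordering the clustering and
    MDS stages consume.
    """
    if G.n_samples < 2 or G.n_variants < 1:
        raise ValueError("need at least 2 samples and 1 variant")
    X = G.dosages.astype(float)
    if not (G.dosages == MISSING).any():
        D = squareform(pdist(X, metric="cityblock")) / (2.0 * G.n_variants)
    else:
        X[G.dosages == MISSING] = np.nan
        mask = ~np.isnan(X)
        n = G.n_samples
        D = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(X[i] - X)
            shared = mask[i] & mask
            cnt = shared.sum(axis=1)
            if (cnt == 0).any():
                j = int(np.where(cnt == 0)[0][0])
                raise ValueError(
                    f"samples {G.sample_ids[i]!r} and {G.sample_ids[j]!r} "
                    "share no non-missing sites"
                )
            D[i] = np.nansum(np.where(shared, diff, 0.0), axis=1) / cnt / 2.0
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, list(G.sample_ids))


def classical_mds(D: DistanceMatrix, k: int = 50) -> MdsCoordinates:
    """Torgerson double-centering + eigendecomposition.

    Returns at most k dimensions, truncated to the number of positive
    eigenvalues (with a warning when fewer than k).  For a
    Euclidean-embeddable D the pairwise coordinate distances reproduce D
    exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = D.n
    d2 = D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-10 * abs(evals[0]) if evals.size else 0)
    n_pos = int(pos.sum())
    k_eff = min(k, n - 1, n_pos)
    if k_eff < k:
        logger.warning(
            "only %d positive MDS dimensions available (requested %d)",
            k_eff, k,
        )
    if k_eff == 0:
        coords = np.zeros((n, 1))
        return MdsCoordinates(coords, np.zeros(1), list(D.sample_ids))
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    return MdsCoordinates(coords, evals[:k_eff], list(D.sample_ids))


def ward_tree(D: DistanceMatrix) -> np.ndarray:
    """Agglomerative Ward linkage (Ward.D2 convention) on a distance matrix.

    Returns the scipy linkage matrix; merges are deterministic.
    """
    if D.n < 2:
        raise ValueError("need at least 2 samples to build a tree")
    return linkage(squareform(D.values, checks=False), method="ward")


def label_clusters(
    tree: np.ndarray,
    reference_labels: pd.Series,
    sample_ids: list[str],
    K: int = 3,
) -> pd.DataFrame:
    """Cut the Ward tree at K clusters and label them via the reference panel.

    The cluster holding the largest fraction of the reference-panel AJ
    samples becomes AJ; the largest remaining cluster becomes EUNW; the
    rest are OTHER.  ``reference_labels`` maps reference sample ids to
    their known population.  An even split of the AJ reference across
    clusters is ambiguous and raises.
    """
    ref_aj = [s for s, lab in reference_labels.items() if lab == LABEL_AJ]
    if not ref_aj:
        raise ValueError("reference panel contains no AJ samples")
    assignment = fcluster(tree, t=K, criterion="maxclust")
    clusters = pd.Series(assignment, index=sample_ids, name="cluster")

    in_panel = clusters.index.isin(ref_aj)
    aj_counts = clusters[in_panel].value_counts()
    if len(aj_counts) == 0:
        raise ValueError("no reference AJ sample present in the tree")
    if len(aj_counts) > 1 and aj_counts.iloc[0] == aj_counts.iloc[1]:
        raise ValueError(
            "reference AJ panel splits evenly across clusters; "
            "use a larger panel or a different K"
        )
    aj_cluster = int(aj_counts.index[0])

    sizes = clusters.value_counts()
    remaining = sizes.drop(index=aj_cluster)
    eunw_cluster = int(remaining.index[0]) if len(remaining) else None

    def lab(c: int) -> str:
        if c == aj_cluster:
            return LABEL_AJ
        if c == eunw_cluster:
            return LABEL_EUNW
        return LABEL_OTHER

    out = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cluster": clusters.to_numpy(),
            "label": [lab(c) for c in clusters],
            "provenance": f"ward-cut-K{K}",
        }
    )
    # reference samples keep their known label
    known = out["sample_id"].map(reference_labels)
    out.loc[known.notna(), "label"] = known[known.notna()]
    return out


def anchor_pc1(coords: MdsCoordinates, reference_labels: pd.Series) -> MdsCoordinates:
    """Fix the PC1 sign so the reference-AJ mean is positive."""
    pc1 = coords.pc1()
    ref_aj = [s for s, lab in reference_labels.items()
              if lab == LABEL_AJ and s in pc1.index]
    if not ref_aj:
        raise ValueError("cannot anchor PC1: no reference AJ sample in coords")
    if pc1.loc[ref_aj].mean() < 0:
        coords.coords = coords.coords.copy()
        coords.coords[:, 0] = -coords.coords[:, 0]
    coords.pc1_anchored = True
    return coords


def classify_trio_members(
    coords: MdsCoordinates,
    reference_labels: pd.Series,
    samples: pd.DataFrame,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label trio members as AJ/EUNW by PC1 and flag Ashkenazi trios.

    A member is AJ iff its anchored PC1 exceeds the threshold (default:
    midpoint of the reference-AJ and reference-EUNW PC1 means).  A trio
    is Ashkenazi iff at least one parent is AJ.  Trios with a missing
    parent are skipped with a log entry.

    Returns (per-member labels, per-trio flags).
    """
    coords = anchor_pc1(coords, reference_labels)
    pc1 = coords.pc1()
    if threshold is None:
        ref_aj = [s for s, lab in reference_labels.items()
                  if lab == LABEL_AJ and s in pc1.index]
        ref_eu = [s for s, lab in reference_labels.items()
                  if lab == LABEL_EUNW and s in pc1.index]
        if not ref_aj or not ref_eu:
            raise ValueError(
                "default threshold needs AJ and EUNW reference samples"
            )
        threshold = (pc1.loc[ref_aj].mean() + pc1.loc[ref_eu].mean()) / 2.0

    members = pd.DataFrame(
        {
            "sample_id": pc1.index,
            "pc1": pc1.to_numpy(),
            "label": np.where(pc1.to_numpy() > threshold, LABEL_AJ, LABEL_EUNW),
        }
    )
    lab = members.set_index("sample_id")["label"]

    trio_rows = []
    probands = samples[(samples["father_id"] != "0") & (samples["mother_id"] != "0")]
    for _, row in probands.iterrows():
        f, m = row["father_id"], row["mother_id"]
        if f not in lab.index or m not in lab.index:
            logger.info("trio of %s skipped: missing parent", row["sample_id"])
            continue
        aj = (lab[f] == LABEL_AJ) or (lab[m] == LABEL_AJ)
        trio_rows.append((row["sample_id"], f, m, aj))
    trios = pd.DataFrame(
        trio_rows, columns=["proband_id", "father_id", "mother_id", "aj_trio"]
    )
    return members, trios


def cohort_frequency_dendrogram(freq_table: pd.DataFrame) -> np.ndarray:
    """Ward tree over cohorts from genome-wide allele-frequency vectors.

    ``freq_table`` is cohorts x variants; distances are Euclidean scaled
    by 1/sqrt(m) so the height scale is per-site.  Cohorts must share the
    variant set (any all-NaN column is rejected).
    """
    if len(freq_table) < 2:
        raise ValueError("need at least 2 cohorts")
    if freq_table.isna().any().any():
        raise ValueError("cohorts must share the variant set (NaNs present)")
    X = freq_table.to_numpy(dtype=float)
    m = X.shape[1]
    return linkage(pdist(X) / np.sqrt(m), method="ward")


def tree_to_newick(tree: np.ndarray, leaf_names: list[str]) -> str:
    """Serialise a scipy linkage matrix to a Newick string."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(tree)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"
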