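"""Agglomerative hierarchical clustering of significant genes and samples.

Rows are standardized (mean 0, sd 1 per gene), the distance is
1 - Pearson correlation, and the linkage is average (UPGMA) by default —
the standard recipe for expression heatmaps. Both axes are clustered:
transcripts (rows) and samples (columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix, SampleDesign
from .preprocess import standardize_rows

logger = logging.getLogger(__name__)

_METRICS = {"correlation", "euclidean"}
_LINKAGES = {"average", "complete", "single"}


@dataclass
class Dendrogram:
    """A hierarchical clustering tree over labelled leaves."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge list
    labels: list[str]
    linkage: str
    distance: str

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Assign each leaf a cluster id by cutting into n_clusters groups."""
        flat = hierarchy.fcluster(self.linkage_matrix, t=n_clusters,
                                  criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            d_left = node.dist - node.get_left().dist
            d_right = node.dist - node.get_right().dist
            return f"({left}:{d_left:.10g},{right}:{d_right:.10g})"

        return walk(tree) + ";"


def _linkage(data: np.ndarray, metric: str, method: str) -> np.ndarray:
    if metric == "correlation":
        d = pdist(data, metric="correlation")
        d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    else:
        d = pdist(data, metric="euclidean")
    return hierarchy.linkage(d, method=method)


def cluster_bimodal(
    matrix: ExpressionMatrix,
    metric: str = "correlation",
    method: str = "average",
) -> tuple[Dendrogram, Dendrogram, ExpressionMatrix]:
    """Cluster genes (rows) and samples (columns) of a significant-gene
    matrix.

    Rows are standardized first; rows or columns that are constant (zero
    variance, undefined correlation) are excluded with a warning. Returns
    (gene dendrogram, sample dendrogram, standardized matrix reordered to
    both leaf orders).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if method not in _LINKAGES:
        raise ValueError(f"method must be one of {sorted(_LINKAGES)}")

    z = standardize_rows(matrix)
    data = z.data

    if metric == "correlation":
        row_sd = data.to_numpy().std(axis=1)
        keep_rows = row_sd > 0
        if not keep_rows.all():
            logger.warning("cluster_bimodal: excluding %d constant row(s)",
                           int((~keep_rows).sum()))
            data = data.loc[keep_rows]
        col_sd = data.to_numpy().std(axis=0)
        keep_cols = col_sd > 0
        if not keep_cols.all():
            logger.warning("cluster_bimodal: excluding %d constant column(s)",
                           int((~keep_cols).sum()))
            data = data.loc[:, keep_cols]
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need >= 2 non-constant rows and columns to cluster")

    gene_link = _linkage(data.to_numpy(), metric, method)
    sample_link = _linkage(data.to_numpy().T, metric, method)
    genes = Dendrogram(gene_link, list(data.index), method, metric)
    samples = Dendrogram(sample_link, list(data.columns), method, metric)
    ordered = data.loc[genes.leaf_order, samples.leaf_order]
    return genes, samples, ExpressionMatrix(ordered, scale="log2")


def tissue_genotype_separation(
    sample_tree: Dendrogram, design: SampleDesign
) -> dict:
    """Check whether samples split by tissue at 2 clusters and by
    tissue x genotype at 4.

    Returns a dict with booleans ``tissue_separated`` / ``cell_separated``
    and the confusion counts of each cut against the design factors.
    """
    design = design.aligned_to(sample_tree.labels)
    tissue = design.table["tissue"]
    cell = design.table["tissue"] + "/" + design.table["genotype"]

    def partition_matches(cut: dict[str, int], labels: pd.Series) -> bool:
        frame = pd.DataFrame({"cluster": pd.Series(cut), "label": labels})
        # exact match: each cluster holds exactly one label and vice versa
        by_cluster = frame.groupby("cluster")["label"].nunique()
        by_label = frame.groupby("label")["cluster"].nunique()
        return bool((by_cluster == 1).all() and (by_label == 1).all())

    cut2 = sample_tree.cut(2)
    n_tissues = tissue.nunique()
    if n_tissues < 2:
        tissue_sep = True  # single-tissue design separates trivially
    else:
        tissue_sep = partition_matches(cut2, tissue)
    cut4 = sample_tree.cut(min(4, len(sample_tree.labels)))
    cell_sep = partition_matches(cut4, cell) if cell.nunique() > 1 else True

    confusion2 = pd.crosstab(pd.Series(cut2, name="cluster"), tissue)
    confusion4 = pd.crosstab(pd.Series(cut4, name="cluster"), cell)
    return {
        "tissue_separated": tissue_sep,
        "cell_separated": cell_sep,
        "tissue_confusion": confusion2,
        "cell_confusion": confusion4,
    }
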