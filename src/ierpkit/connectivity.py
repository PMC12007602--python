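"""Effective-connectivity maps and clustering.

Inputs are region x region probabilities that single-pulse stimulation of
one region evokes a cortico-cortical potential in another (afferent or
efferent). The module thresholds these into edge sets (default: keep
probability >= 0.5), clusters each region's probability pattern with
agglomerative hierarchical clustering (Euclidean distance over rows with
the two self-connection entries masked, average linkage), and compares
afferent against efferent structure (element-wise correlation, thresholded
edge agreement, and whether the k = 4 partitions coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator

from .config import DEFAULT_CONFIG, AnalysisConfig
from .datatypes import ConnectivityMatrix


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    probability: float


@dataclass
class EdgeSet:
    direction: str
    threshold: float
    edges: list[Edge]

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}


@dataclass
class ClusterTree:
    """Binary dendrogram over regions (R - 1 merges)."""

    regions: list[str]
    linkage_matrix: np.ndarray  # scipy format, (R-1, 4)

    def cut(self, k: int) -> np.ndarray:
        """Flat partition into k clusters (labels 1..k, scipy convention)."""
        if not 1 <= k <= len(self.regions):
            raise ValueError(f"k must lie in [1, {len(self.regions)}]")
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with height-difference branches."""
        n = len(self.regions)
        heights = {i: 0.0 for i in range(n)}
        newick = {i: _quote(self.regions[i]) for i in range(n)}
        for m, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            node = n + m
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            newick[node] = (
                f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
            )
            heights[node] = h
        return newick[n + len(self.linkage_matrix) - 1] + ";"


def _quote(name: str) -> str:
    if any(c in name for c in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# thresholded edge maps
# ---------------------------------------------------------------------------


def threshold_edges(
    matrix: ConnectivityMatrix,
    config: AnalysisConfig = DEFAULT_CONFIG,
    strict_gt: bool = False,
) -> EdgeSet:
    """Keep supra-threshold off-diagonal connections.

    The boundary is inclusive (probability == threshold kept) unless
    ``strict_gt``; self-loops are always excluded.
    """
    thr = config.conn_threshold
    edges = []
    for i, src in enumerate(matrix.regions):
        for j, tgt in enumerate(matrix.regions):
            if i == j:
                continue
            p = float(matrix.prob[i, j])
            keep = p > thr if strict_gt else p >= thr
            if keep:
                edges.append(Edge(src, tgt, p))
    return EdgeSet(direction=matrix.direction, threshold=thr, edges=edges)


# ---------------------------------------------------------------------------
# hierarchical clustering of probability patterns
# ---------------------------------------------------------------------------


def _masked_row_distances(prob: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances between rows, self-columns masked.

    The distance between regions i and j ignores columns i and j, so a
    region's (meaningless) self-connection never influences the tree.
    """
    r = prob.shape[0]
    out = []
    for i in range(r):
        for j in range(i + 1, r):
            keep = np.ones(r, dtype=bool)
            keep[[i, j]] = False
            diff = prob[i, keep] - prob[j, keep]
            out.append(np.sqrt(np.dot(diff, diff)))
    return np.array(out)


class RegionClusterer(BaseEstimator):
    """Agglomerative clustering of connectivity-probability patterns.

    Fitted attributes: ``tree_`` (:class:`ClusterTree`) and ``labels_``
    (flat partition at ``n_clusters``). Deterministic for a given matrix;
    scipy breaks exact ties by cluster index order.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        metric: str = "euclidean",
        linkage_method: str = "average",
        binarize: bool = False,
        config: AnalysisConfig = DEFAULT_CONFIG,
    ):
        self.n_clusters = n_clusters
        self.metric = metric
        self.linkage_method = linkage_method
        self.binarize = binarize
        self.config = config

    def fit(self, matrix: ConnectivityMatrix, y=None):
        r = len(matrix.regions)
        if r < 2:
            raise ValueError("clustering needs at least 2 regions")
        prob = matrix.prob.astype(float)
        if self.binarize:
            prob = (prob >= self.config.conn_threshold).astype(float)
        if self.metric == "euclidean":
            condensed = _masked_row_distances(prob)
        else:
            from scipy.spatial.distance import pdist

            masked = prob.copy()
            np.fill_diagonal(masked, 0.0)
            condensed = pdist(masked, metric=self.metric)
        self.tree_ = ClusterTree(
            regions=list(matrix.regions),
            linkage_matrix=linkage(condensed, method=self.linkage_method),
        )
        self.labels_ = self.tree_.cut(min(self.n_clusters, r))
        return self

    def fit_predict(self, matrix: ConnectivityMatrix) -> np.ndarray:
        return self.fit(matrix).labels_


def cluster_regions(
    matrix: ConnectivityMatrix,
    metric: str = "euclidean",
    linkage_method: str = "average",
) -> ClusterTree:
    """Build the hierarchical binary cluster tree over region patterns."""
    return RegionClusterer(
        metric=metric, linkage_method=linkage_method
    ).fit(matrix).tree_


# ---------------------------------------------------------------------------
# afferent vs efferent comparison
# ---------------------------------------------------------------------------


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label vectors induce the same set partition."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    pairs_a = a[:, None] == a[None, :]
    pairs_b = b[:, None] == b[None, :]
    return bool(np.array_equal(pairs_a, pairs_b))


@dataclass
class DirectionComparison:
    correlation: float
    edge_agreement: float
    same_partition_k4: bool


def compare_directions(
    afferent: ConnectivityMatrix,
    efferent: ConnectivityMatrix,
    config: AnalysisConfig = DEFAULT_CONFIG,
    k: int = 4,
) -> DirectionComparison:
    """Quantify afferent/efferent similarity.

    Off-diagonal Pearson correlation; Jaccard agreement of the thresholded
    edge sets (1.0 when both are empty); and whether the two cluster trees
    induce the same flat partition at ``k`` clusters.
    """
    if afferent.regions != efferent.regions:
        raise ValueError("region order mismatch between directions")
    r = len(afferent.regions)
    off = ~np.eye(r, dtype=bool)
    a = afferent.prob[off]
    b = efferent.prob[off]
    with np.errstate(invalid="ignore"):
        corr = float(np.corrcoef(a, b)[0, 1])
    ea = threshold_edges(afferent, config).pairs()
    eb = threshold_edges(efferent, config).pairs()
    union = ea | eb
    agreement = 1.0 if not union else len(ea & eb) / len(union)
    la = RegionClusterer(n_clusters=k, config=config).fit_predict(afferent)
    lb = RegionClusterer(n_clusters=k, config=config).fit_predict(efferent)
    return DirectionComparison(
        correlation=corr,
        edge_agreement=agreement,
        same_partition_k4=same_partition(la, lb),
    )
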