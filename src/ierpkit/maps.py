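"""Continuous cortical maps from discrete lead statistics.

Each mesh node aggregates the leads whose 7-node footprints fall inside a
1-cm geodesic disk around it, with contributions down-weighted by a
logistic function of geodesic distance (unit amplitude, midpoint 7.5 mm,
steepness 2 per mm): nodes within ~5 mm contribute almost fully, those
between 5 and 10 mm fade out, avoiding hard disk-edge artefacts.

Three map kinds are produced: sampling density (leads per cm^2), overall
responsiveness (% of explored that respond) and relative responsiveness
(% of responding that are selective). Percentage maps are masked below a
10 % display threshold. Geodesics are shortest paths on the mesh edge
graph with Euclidean edge lengths — a few-percent overestimate of true
polyhedral geodesics that the soft kernel renders immaterial.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator

from .config import DEFAULT_CONFIG, AnalysisConfig
from .datatypes import CorticalMesh, NodeNeighbourhood, SurfaceMap

MAP_KINDS = ("density", "overall", "relative")


def _edge_graph(mesh: CorticalMesh):
    edges = mesh.edge_lengths()
    if not edges:
        raise ValueError("mesh has no edges")
    i, j = zip(*edges.keys())
    w = list(edges.values())
    n = mesh.n_nodes
    return coo_matrix((w + w, (i + j, j + i)), shape=(n, n)).tocsr()


def geodesic_distances(
    mesh: CorticalMesh, source_node: int, max_mm: float = np.inf
) -> dict[int, float]:
    """Shortest-path distances along mesh edges, truncated at ``max_mm``.

    Unreachable nodes (and nodes beyond the truncation radius) are absent
    from the result.
    """
    if not 0 <= source_node < mesh.n_nodes:
        raise ValueError(
            f"source node {source_node} out of range for "
            f"{mesh.n_nodes}-node mesh"
        )
    dist = dijkstra(
        _edge_graph(mesh), directed=False, indices=source_node, limit=max_mm
    )
    return {
        int(i): float(d) for i, d in enumerate(dist) if np.isfinite(d)
    }


def node_weight(
    d_mm: float | np.ndarray, config: AnalysisConfig = DEFAULT_CONFIG
) -> float | np.ndarray:
    """Logistic distance weight w(d) = 1 / (1 + exp(s * (d - midpoint)))."""
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    w = 1.0 / (
        1.0 + np.exp(config.kernel_steepness * (d - config.kernel_midpoint_mm))
    )
    return float(w) if np.isscalar(d_mm) else w


def build_neighbourhood(
    mesh: CorticalMesh, node: int, config: AnalysisConfig = DEFAULT_CONFIG
) -> NodeNeighbourhood:
    """Geodesic disk of ``map_radius_mm`` around ``node`` with weights."""
    dists = geodesic_distances(mesh, node, max_mm=config.map_radius_mm)
    members = np.array(sorted(dists), dtype=int)
    d = np.array([dists[m] for m in members])
    return NodeNeighbourhood(
        centre=node,
        members=members,
        distances_mm=d,
        weights=np.asarray(node_weight(d, config)),
    )


def _lead_counts_per_node(
    n_nodes: int,
    assignment: dict[str, np.ndarray],
    flags: pd.DataFrame | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node counts of explored / responsive / selective lead footprints."""
    explored = np.zeros(n_nodes)
    responsive = np.zeros(n_nodes)
    selective = np.zeros(n_nodes)
    for lead_id, nodes in assignment.items():
        nodes = np.asarray(nodes, dtype=int)
        explored[nodes] += 1
        if flags is not None and lead_id in flags.index:
            row = flags.loc[lead_id]
            if bool(row.get("responsive", False)):
                responsive[nodes] += 1
            if bool(row.get("selective", False)):
                selective[nodes] += 1
    return explored, responsive, selective


class SurfaceMapper(BaseEstimator):
    """Transform per-lead flags into a continuous per-node surface map.

    ``fit`` fixes the geometry (mesh plus lead -> node assignment) and
    precomputes the truncated geodesic weight structure; ``transform``
    turns a per-lead flag table (boolean ``responsive`` / ``selective``
    columns indexed by lead_id) into a :class:`SurfaceMap` of the
    requested kind.
    """

    def __init__(
        self,
        kind: str = "overall",
        config: AnalysisConfig = DEFAULT_CONFIG,
    ):
        self.kind = kind
        self.config = config

    def fit(self, mesh: CorticalMesh, assignment: dict[str, np.ndarray]):
        if self.kind not in MAP_KINDS:
            raise ValueError(
                f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}"
            )
        n = mesh.n_nodes
        for lead_id, nodes in assignment.items():
            nodes = np.asarray(nodes, dtype=int)
            if nodes.min() < 0 or nodes.max() >= n:
                raise ValueError(
                    f"lead {lead_id!r}: assigned node out of range"
                )
        dist = dijkstra(
            _edge_graph(mesh),
            directed=False,
            limit=self.config.map_radius_mm,
        )
        with np.errstate(over="ignore"):
            weights = 1.0 / (
                1.0
                + np.exp(
                    self.config.kernel_steepness
                    * (dist - self.config.kernel_midpoint_mm)
                )
            )
        weights[~np.isfinite(dist)] = 0.0
        self.mesh_ = mesh
        self.assignment_ = dict(assignment)
        self.weights_ = weights  # (centre, member) kernel weights
        return self

    def transform(self, flags: pd.DataFrame | None = None) -> SurfaceMap:
        explored, responsive, selective = _lead_counts_per_node(
            self.mesh_.n_nodes, self.assignment_, flags
        )
        if flags is not None:
            bad = (selective > 0) & (responsive == 0)
            if np.any(bad):
                raise ValueError(
                    "inconsistent flags: selective leads must be responsive"
                )
        w = self.weights_
        explored_w = w @ explored
        cfg = self.config
        if self.kind == "density":
            area_cm2 = np.pi * (cfg.map_radius_mm / 10.0) ** 2
            values = (explored_w / cfg.nodes_per_lead) / area_cm2
            return SurfaceMap("density", values, explored_w > 0)
        if flags is None:
            raise ValueError(f"{self.kind} maps need per-lead flags")
        responsive_w = w @ responsive
        if self.kind == "overall":
            with np.errstate(invalid="ignore", divide="ignore"):
                values = 100.0 * responsive_w / explored_w
            mask = explored_w > 0
        else:  # relative
            selective_w = w @ selective
            if not np.any(responsive_w > 0):
                warnings.warn(
                    "no responsive weight anywhere; relative map fully masked",
                    stacklevel=2,
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                values = 100.0 * selective_w / responsive_w
            mask = responsive_w > 0
        values = np.where(mask, values, 0.0)
        mask = mask & (values >= cfg.map_threshold_pct)
        return SurfaceMap(self.kind, values, mask)


def compute_map(
    kind: str,
    mesh: CorticalMesh,
    assignment: dict[str, np.ndarray],
    flags: pd.DataFrame | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> SurfaceMap:
    """One-shot convenience wrapper around :class:`SurfaceMapper`."""
    return SurfaceMapper(kind=kind, config=config).fit(
        mesh, assignment
    ).transform(flags)
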