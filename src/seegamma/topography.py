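"""Geodesic disks with sigmoid node weights; sampling-density and
relative-responsiveness surface maps.

Every cortical node owns a disk: the surrounding nodes within a 10-mm
geodesic (along-surface) distance, weighted by a decreasing logistic
function of distance with unit amplitude, steepness 2 per mm and midpoint
7.5 mm -- nodes within 5 mm contribute maximally, those between 5 and
10 mm progressively less.  Geodesics are edge-graph shortest paths
(Dijkstra), adequate at ~1-mm edge length.
"""
from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .types import (
    DISK_RADIUS_MM,
    NODES_PER_LEAD,
    WEIGHT_MIDPOINT_MM,
    WEIGHT_STEEPNESS_PER_MM,
    DiskWeights,
    LeadRecord,
    SurfaceMap,
    ToyMesh,
)

#: disks with a weighted density below this many lead-equivalents
#: (two leads = 14 nodes) are masked out
DENSITY_MASK_LEADS: float = 2.0


def mesh_graph(mesh: ToyMesh):
    """Sparse symmetric edge-length graph of the mesh (cached on the mesh)."""
    g = getattr(mesh, "_graph", None)
    if g is None:
        e = mesh.edges()
        w = mesh.edge_lengths()
        n = mesh.n_nodes
        g = coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([e[:, 0], e[:, 1]]),
              np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n)).tocsr()
        mesh._graph = g
    return g


def geodesic_distances(mesh: ToyMesh, origin: int,
                       cutoff: float = DISK_RADIUS_MM) -> dict[int, float]:
    """Shortest-path distance (mm) from ``origin`` along mesh edges,
    truncated at ``cutoff``; unreachable nodes are absent."""
    if not (0 <= origin < mesh.n_nodes):
        raise ValueError(f"origin {origin} not on mesh")
    d = dijkstra(mesh_graph(mesh), indices=origin, limit=cutoff)
    reach = np.flatnonzero(np.isfinite(d))
    return {int(i): float(d[i]) for i in reach}


def node_weight(distance_mm, steepness: float = WEIGHT_STEEPNESS_PER_MM,
                midpoint: float = WEIGHT_MIDPOINT_MM):
    """Logistic disk weight w(d) = 1 / (1 + exp(k (d - m))).

    Unit amplitude, strictly decreasing; w(7.5 mm) = 0.5 with the default
    steepness k = 2 per mm and midpoint m = 7.5 mm.
    """
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    w = 1.0 / (1.0 + np.exp(np.clip(steepness * (d - midpoint), -700, 700)))
    return float(w) if np.isscalar(distance_mm) else w


def disk_weights(mesh: ToyMesh, origin: int,
                 radius: float = DISK_RADIUS_MM) -> DiskWeights:
    """The geodesic disk around ``origin``: member nodes and their weights."""
    d = geodesic_distances(mesh, origin, cutoff=radius)
    return DiskWeights(origin=origin,
                       members={i: node_weight(x) for i, x in d.items()},
                       radius_mm=radius)


def _lead_node_weight_matrix(mesh: ToyMesh, leads: list[LeadRecord],
                             radius: float) -> np.ndarray:
    """(n_leads, n_nodes) weighted contribution of each lead's 7 nodes to
    each origin node's disk."""
    n = mesh.n_nodes
    out = np.zeros((len(leads), n))
    if not leads:
        return out
    all_nodes = np.concatenate([l.node_ids for l in leads])
    d = dijkstra(mesh_graph(mesh), indices=all_nodes, limit=radius)
    w = np.where(np.isfinite(d), node_weight(np.where(np.isfinite(d), d, 0.0)),
                 0.0)
    k = 0
    for li, lead in enumerate(leads):
        m = len(lead.node_ids)
        if m != NODES_PER_LEAD:
            raise ValueError(f"lead {lead.lead_id} has {m} nodes, "
                             f"expected {NODES_PER_LEAD}")
        out[li] = w[k:k + m].sum(axis=0)
        k += m
    return out


def sampling_density(mesh: ToyMesh, leads: list[LeadRecord],
                     radius: float = DISK_RADIUS_MM) -> SurfaceMap:
    """Weighted lead-equivalents per disk: sum of logistic node weights of
    all lead nodes within the disk, divided by 7.

    Nodes sampled by fewer than two lead-equivalents (14 weighted nodes)
    are masked out.
    """
    w = _lead_node_weight_matrix(mesh, leads, radius)
    density = w.sum(axis=0) / NODES_PER_LEAD
    return SurfaceMap(values=density, kind="density",
                      mask=density < DENSITY_MASK_LEADS)


def relative_responsiveness(mesh: ToyMesh, leads: list[LeadRecord],
                            classifications: dict[str, tuple[str, bool]],
                            lead_class: str,
                            radius: float = DISK_RADIUS_MM) -> SurfaceMap:
    """Per-disk percentage of overall-responsive lead weight carried by
    leads of ``lead_class``.

    ``classifications`` maps lead_id -> (class, overall_responsive).  The
    map is masked where the disk holds no responsive weight or where the
    sampling-density mask applies.
    """
    if lead_class not in ("doubly", "static", "task"):
        raise ValueError(f"unknown lead class {lead_class!r}")
    responsive = [l for l in leads
                  if classifications.get(l.lead_id, ("none", False))[1]]
    of_class = [l for l in responsive
                if classifications[l.lead_id][0] == lead_class]
    den = _lead_node_weight_matrix(mesh, responsive, radius).sum(axis=0)
    num = _lead_node_weight_matrix(mesh, of_class, radius).sum(axis=0)
    density_mask = sampling_density(mesh, leads, radius).mask
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 100.0 * num / den
    mask = (den <= 0) | density_mask
    values[mask] = np.nan
    return SurfaceMap(values=values, kind="relative_responsiveness", mask=mask)


__all__ = [
    "DENSITY_MASK_LEADS", "disk_weights", "geodesic_distances", "mesh_graph",
    "node_weight", "relative_responsiveness", "sampling_density",
]
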