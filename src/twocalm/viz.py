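"""Cluster visualisation exports: meshes and primary-cluster extraction.

Clusters are exported as ASCII PLY meshes in one of two styles: the
boundary surface of the 3D Delaunay complex of the cluster's points
(i.e. its convex hull triangles), or a packing of spheres centred at
each point with radius half the nearest-neighbour distance (the same
radius the bullet volume estimator uses).

Primary clusters — the dominant aggregates of a sample — are extracted
with DBSCAN using the Ripley H-function's maximising distance (the
radius of maximal aggregation) as the neighbourhood radius; their
density and curvature distributions can then be compared between
samples with the same two-sample tests the pipeline uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .features import cluster_curvature, cluster_density, cluster_volume
from .localizations import LocalizationCloud
from .preprocess import DBSCANParams, ROISet, extract_rois

__all__ = ["ClusterMesh", "cluster_mesh", "export_ply", "primary_clusters", "primary_cluster_features", "rank_by_density"]


@dataclass
class ClusterMesh:
    vertices: np.ndarray
    faces: np.ndarray
    cluster_id: int = 0
    mode: str = "delaunay"

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def _sphere_mesh(members: np.ndarray) -> ClusterMesh:
    pts = np.asarray(members, dtype=float)
    nn = cKDTree(pts).query(pts, k=2)[0][:, 1]
    spheres = []
    for c, r in zip(pts, nn / 2.0):
        s = trimesh.creation.icosphere(subdivisions=1, radius=max(r, 1e-9))
        s.apply_translation(c)
        spheres.append(s)
    combined = trimesh.util.concatenate(spheres)
    return ClusterMesh(vertices=np.asarray(combined.vertices), faces=np.asarray(combined.faces), mode="spheres")


def cluster_mesh(members: np.ndarray, mode: str = "delaunay") -> ClusterMesh:
    """Triangle mesh of one cluster.

    ``delaunay``: boundary triangles of the cluster's 3D Delaunay
    complex (needs >= 4 points in general position; degenerate input
    falls back to sphere mode with a warning).  ``spheres``: an
    icosphere per point, radius half the nearest-neighbour distance.
    """
    pts = np.asarray(members, dtype=float)
    if mode == "spheres":
        if len(pts) < 2:
            raise ValueError("sphere mode needs at least 2 points")
        return _sphere_mesh(pts)
    if mode != "delaunay":
        raise ValueError(f"unknown mesh mode {mode!r}")
    if len(pts) < 4:
        raise ValueError("delaunay mode needs at least 4 points")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("degenerate (coplanar) cluster; falling back to sphere mesh")
        return _sphere_mesh(pts)
    return ClusterMesh(vertices=pts, faces=hull.simplices, mode="delaunay")


def export_ply(mesh: ClusterMesh, path) -> None:
    """Write the mesh as ASCII PLY."""
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(mesh.to_trimesh(), encoding="ascii"))


def primary_clusters(cloud: LocalizationCloud, d_star: float, min_points: int = 10) -> ROISet:
    """Extract primary clusters: DBSCAN components at rho = d_star.

    ``d_star`` is normally the H-argmax radius of maximal aggregation.
    """
    if d_star is None or d_star <= 0:
        raise ValueError("d_star must be a positive radius (nm)")
    return extract_rois(cloud, DBSCANParams(rho=float(d_star), min_points=min_points), min_roi_points=min_points)


def primary_cluster_features(rois: ROISet, global_density: float, volume_mode: str = "bullet"):
    """(densities, curvatures) distributions over the primary clusters."""
    dens, curv = [], []
    for roi in rois.rois:
        v = cluster_volume(roi.points, mode=volume_mode)
        if v is not None and v > 0:
            dens.append(cluster_density(len(roi), v, global_density))
        if len(roi) >= 4:
            curv.append(cluster_curvature(roi.points))
    return np.asarray(dens), np.asarray(curv)


def rank_by_density(rois: ROISet, global_density: float, top: int | None = None, volume_mode: str = "bullet"):
    """Primary clusters sorted densest-first (optionally the top n)."""
    scored = []
    for roi in rois.rois:
        v = cluster_volume(roi.points, mode=volume_mode)
        if v is not None and v > 0:
            scored.append((cluster_density(len(roi), v, global_density), roi))
    scored.sort(key=lambda t: -t[0])
    if top is not None:
        scored = scored[:top]
    return [roi for _, roi in scored]
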