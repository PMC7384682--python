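"""Outlier filtering, ROI segmentation and drift correction.

Raw dSTORM localisation tables contain isolated spurious events
(unspecific binding, fitting errors).  Following common SMLM practice
they are removed with DBSCAN: points with fewer than ``min_points``
neighbours within radius ``rho`` that are not density-reachable from a
core point are classified as noise.  The same labelling, with a larger
radius, segments spatially well-separated signal domains into regions of
interest (ROIs).

The DBSCAN here is deterministic: points are expanded in index order and
a border point joins the first core cluster that reaches it, which fixes
the classical border-point ambiguity reproducibly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .localizations import EmptyInputError, LocalizationCloud

__all__ = ["DBSCANParams", "ROISet", "dbscan_label", "filter_outliers", "extract_rois", "apply_drift_hook"]

NOISE = -1


@dataclass(frozen=True)
class DBSCANParams:
    """DBSCAN neighbourhood radius ``rho`` (nm) and core threshold ``min_points``.

    The neighbourhood count includes the query point itself, so
    ``min_points=3`` means a point plus two neighbours within ``rho``.
    """

    rho: float
    min_points: int

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be positive (nm)")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class ROISet:
    """Disjoint ROI sub-clouds (ordered by size, largest first) plus leftover noise points."""

    rois: list
    noise: LocalizationCloud | None


def dbscan_label(cloud: LocalizationCloud, params: DBSCANParams) -> np.ndarray:
    """Label each point with its DBSCAN cluster id, or -1 for noise.

    Core point: at least ``min_points`` points (itself included) within
    ``rho``.  Clusters are the density-connected components of core
    points; border points join the cluster of the first core point that
    reaches them during index-ordered expansion.
    """
    pts = cloud.points
    n = len(pts)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=params.rho)
    is_core = np.fromiter((len(nb) >= params.min_points for nb in neighbors), dtype=bool, count=n)

    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if not is_core[i] or labels[i] != NOISE:
            continue
        labels[i] = cluster
        stack = [i]
        while stack:
            j = stack.pop()
            for k in sorted(neighbors[j]):
                if labels[k] == NOISE:
                    labels[k] = cluster
                    if is_core[k]:
                        stack.append(k)
        cluster += 1
    return labels


def filter_outliers(cloud: LocalizationCloud, params: DBSCANParams) -> LocalizationCloud:
    """Drop DBSCAN noise points; raises if everything would be removed."""
    labels = dbscan_label(cloud, params)
    keep = labels != NOISE
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyInputError("outlier filter removed every point")
    if removed:
        warnings.warn(f"outlier filter removed {removed} of {len(cloud)} points")
    return cloud.subset(keep)


def extract_rois(cloud: LocalizationCloud, params: DBSCANParams, min_roi_points: int) -> ROISet:
    """Segment the cloud into ROIs: DBSCAN components with >= ``min_roi_points`` points.

    ROIs are returned largest-first; everything else (noise and
    undersized components) goes to ``noise``.
    """
    labels = dbscan_label(cloud, params)
    rois = []
    kept = np.zeros(len(cloud), dtype=bool)
    ids, counts = np.unique(labels[labels != NOISE], return_counts=True)
    order = np.argsort(-counts, kind="stable")
    for cid in ids[order]:
        mask = labels == cid
        if mask.sum() >= min_roi_points:
            rois.append(cloud.subset(mask))
            kept |= mask
    if not rois:
        warnings.warn("no DBSCAN component reached min_roi_points; empty ROI set")
    noise = cloud.subset(~kept) if (~kept).any() else None
    return ROISet(rois=rois, noise=noise)


def apply_drift_hook(cloud: LocalizationCloud, drift_track: np.ndarray) -> LocalizationCloud:
    """Subtract per-frame drift offsets supplied by an external estimator.

    ``drift_track`` is an (n_frames, 3) array indexed by the cloud's
    integer ``frame`` metadata column.  Drift estimation itself
    (redundancy or fiducial based) is out of scope; this hook only
    applies a given track.
    """
    if cloud.meta is None or "frame" not in cloud.meta.columns:
        raise ValueError("drift correction requires a 'frame' metadata column")
    frames = cloud.meta["frame"].to_numpy(dtype=int)
    track = np.asarray(drift_track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 3:
        raise ValueError("drift_track must be (n_frames, 3)")
    if frames.min() < 0 or frames.max() >= len(track):
        raise ValueError("drift_track does not cover all frames present in the cloud")
    corrected = cloud.points - track[frames]
    return LocalizationCloud(corrected, meta=cloud.meta, dim_mode=cloud.dim_mode)
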