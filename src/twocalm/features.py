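"""Hierarchical cluster features: density and curvature over a dimension sweep.

The central descriptor of a localisation cloud is obtained by cutting a
single complete-linkage dendrogram at a sweep of "cluster dimensions"
d = size_min + i*step.  Complete linkage merges at the maximum pairwise
distance, so cutting the tree at height d guarantees every cluster's
diameter is at most d.  For each dimension two per-cluster features are
extracted:

* relative density — cluster points-per-volume divided by the whole
  sample's points-per-volume (dimensionless; volume from a bullet,
  convex-hull or bounding-box estimator), and
* curvature (surface variation) — tau = lambda1 / (lambda1+lambda2+lambda3)
  of the eigenvalues of the cluster's scatter matrix, in [0, 1/3];
  0 for flat or linear clusters, 1/3 for isotropic ones.

Clusters too small for a feature are excluded from its distribution and
counted: density needs n_k >= 2 (the bullet estimator needs a nearest
neighbour), curvature needs n_k >= 4 (any three points are coplanar, so
tau would be identically zero and bias the distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .localizations import LocalizationCloud, sample_global_density

__all__ = [
    "DimensionGrid",
    "ClusterSet",
    "ClusterFeatureSet",
    "make_grid",
    "hierarchical_cut",
    "cluster_volume",
    "cluster_density",
    "cluster_curvature",
    "feature_sweep",
]

SIZE_MAX_CAP_NM = 1000.0  # sweep cap; cluster scales beyond 1 um are not resolved
AUTO_FRACTION = 0.45  # auto size_max = 45% of the smaller sample's minimal box edge


@dataclass(frozen=True)
class DimensionGrid:
    """Ordered sweep of maximal cluster dimensions dim(i) = size_min + i*step."""

    size_min: float
    step: float
    L: int

    def __post_init__(self):
        if self.size_min <= 0 or self.step <= 0:
            raise ValueError("size_min and step must be positive (nm)")
        if self.L < 2:
            raise ValueError("similarity curves need at least 2 cluster dimensions")

    @property
    def dims(self) -> np.ndarray:
        return self.size_min + self.step * np.arange(1, self.L + 1)

    @property
    def size_max(self) -> float:
        return float(self.size_min + self.L * self.step)

    @property
    def d_interval(self) -> float:
        return self.size_max - self.size_min


def make_grid(
    cloud_pair_extents,
    size_min: float = 10.0,
    step: float = 10.0,
    size_max: float | str = "auto",
) -> DimensionGrid:
    """Build the dimension grid for a pair of samples.

    ``cloud_pair_extents`` is any iterable of bounding-box extent vectors
    (one per sample).  With ``size_max="auto"`` the sweep runs to 45% of
    the smallest box edge over both samples, capped at 1000 nm.
    """
    if size_max == "auto":
        min_edge = min(float(np.min(np.asarray(e, dtype=float))) for e in cloud_pair_extents)
        size_max = min(AUTO_FRACTION * min_edge, SIZE_MAX_CAP_NM)
    size_max = float(size_max)
    if size_min >= size_max:
        raise ValueError(f"size_min={size_min} must be < size_max={size_max}")
    L = int(np.floor((size_max - size_min) / step + 1e-9))
    if L < 2:
        raise ValueError("grid has fewer than 2 dimensions; reduce step or size_min")
    return DimensionGrid(size_min=size_min, step=step, L=L)


@dataclass
class ClusterSet:
    """A flat clustering of a point set at one cluster dimension."""

    dimension: float
    labels: np.ndarray  # per-point cluster id, 0..n_clusters-1

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def members(self, points: np.ndarray) -> list:
        order = np.argsort(self.labels, kind="stable")
        bounds = np.searchsorted(self.labels[order], np.arange(self.n_clusters + 1))
        return [points[order[bounds[i]: bounds[i + 1]]] for i in range(self.n_clusters)]


@dataclass
class ClusterFeatureSet:
    """Per-cluster features at one dimension, plus their averages."""

    dimension: float
    n_clusters: int
    densities: np.ndarray  # relative densities of clusters with a defined volume
    curvatures: np.ndarray  # tau of clusters with n_k >= 4
    av_density: float  # nan when no cluster qualifies
    av_curv: float
    n_excluded_density: int = 0
    n_excluded_curvature: int = 0
    volume_mode: str = "bullet"


def _complete_linkage(points: np.ndarray):
    """Complete-linkage dendrogram over lexicographically sorted points.

    Sorting first makes tie-breaking (and hence the whole partition)
    independent of the input row order.  Returns (linkage matrix, order)
    where ``order`` maps sorted rows back to original rows.
    """
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
    if len(points) == 1:
        return None, order
    Z = linkage(points[order], method="complete")
    return Z, order


def hierarchical_cut(points: np.ndarray, d: float) -> ClusterSet:
    """Cut the complete-linkage tree so every cluster's diameter is <= d."""
    points = np.asarray(points, dtype=float)
    if len(points) < 1:
        raise ValueError("need at least one point")
    if d <= 0:
        raise ValueError("cluster dimension d must be positive")
    Z, order = _complete_linkage(points)
    labels = np.zeros(len(points), dtype=int)
    if Z is not None:
        sorted_labels = fcluster(Z, t=d, criterion="distance") - 1
        labels[order] = sorted_labels
    return ClusterSet(dimension=float(d), labels=_canonical_labels(labels))


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance so ids are order-stable."""
    _, canon = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty_like(canon)
    nxt = 0
    for i, c in enumerate(canon):
        if c not in first:
            first[c] = nxt
            nxt += 1
        out[i] = first[c]
    return out


def cluster_volume(members: np.ndarray, mode: str = "bullet", box_clamp: float | None = None) -> float | None:
    """Volume (nm^3) of one cluster, or None when the estimator is undefined.

    bullet: sum of per-point spheres with radius half the within-cluster
    nearest-neighbour distance (needs n >= 2).  hull: convex-hull volume
    (needs >= 4 points in general position).  box: product of per-axis
    extents, with zero extents clamped to ``box_clamp`` when given.
    """
    pts = np.asarray(members, dtype=float)
    n = len(pts)
    if mode == "bullet":
        if n < 2:
            return None
        if n <= 64:
            dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(dm, np.inf)
            nn = dm.min(axis=1)
        else:
            nn = cKDTree(pts).query(pts, k=2)[0][:, 1]
        return float((4.0 / 3.0) * np.pi * np.sum((nn / 2.0) ** 3))
    if mode == "hull":
        if n < 4:
            return None
        try:
            hull = ConvexHull(pts)
        except QhullError:
            return None
        return float(hull.volume)
    if mode == "box":
        if n < 2:
            return None
        ext = pts.max(axis=0) - pts.min(axis=0)
        if box_clamp is not None:
            ext = np.maximum(ext, box_clamp)
        elif np.any(ext == 0):
            return None
        return float(np.prod(ext))
    raise ValueError(f"unknown volume mode {mode!r}")


def cluster_density(n_k: int, V_k: float, global_density: float) -> float:
    """Relative density (n_k/V_k) / density(sample); dimensionless."""
    if V_k is None or V_k <= 0:
        raise ValueError("cluster volume must be positive and defined")
    if global_density <= 0:
        raise ValueError("global density must be positive")
    return (n_k / V_k) / global_density


def cluster_curvature(members: np.ndarray) -> float:
    """Surface variation tau = lambda1/(lambda1+lambda2+lambda3) in [0, 1/3].

    Eigenvalues of the scatter matrix sum_j (p_j - centroid)(p_j - centroid)^T,
    sorted ascending.  Returns 0 for coincident points (zero trace).
    Requires at least 4 points (fewer are always coplanar).
    """
    pts = np.asarray(members, dtype=float)
    if len(pts) < 4:
        raise ValueError("curvature needs at least 4 points")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred
    lam = np.linalg.eigvalsh(cov)
    total = lam.sum()
    if total <= 0:
        return 0.0
    return float(np.clip(lam[0] / total, 0.0, 1.0 / 3.0))


def _bullet_volumes_per_cluster(pts: np.ndarray, labels: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Bullet volume of every cluster at once (nan where n_k < 2).

    Within-cluster nearest neighbours for all points are found with one
    KD-tree query in 4D: a fourth coordinate label*offset separates the
    clusters by far more than any spatial distance, so each point's
    nearest 4D neighbour is its nearest spatial neighbour in its own
    cluster.
    """
    multi = sizes[labels] >= 2
    if not multi.any():
        return np.full(len(sizes), np.nan)
    span = np.ptp(pts, axis=0).max() + 1.0
    coords4 = np.column_stack([pts[multi], labels[multi] * (10.0 * span)])
    nn = cKDTree(coords4).query(coords4, k=2)[0][:, 1]
    per_point = (4.0 / 3.0) * np.pi * (nn / 2.0) ** 3
    vols = np.where(sizes >= 2, 0.0, np.nan)
    np.add.at(vols, labels[multi], per_point)
    return vols


def _curvatures_per_cluster(pts: np.ndarray, labels: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """tau for every cluster with n_k >= 4 (nan elsewhere), batched."""
    nc = len(sizes)
    taus = np.full(nc, np.nan)
    big = sizes[labels] >= 4
    if not big.any():
        return taus
    lab = labels[big]
    p = pts[big]
    nc_idx = np.flatnonzero(sizes >= 4)
    sums = np.zeros((nc, 3))
    outer = np.zeros((nc, 3, 3))
    np.add.at(sums, lab, p)
    np.add.at(outer, lab, p[:, :, None] * p[:, None, :])
    ns = sizes[nc_idx][:, None]
    mu = sums[nc_idx] / ns
    cov = outer[nc_idx] - sizes[nc_idx][:, None, None] * (mu[:, :, None] * mu[:, None, :])
    lam = np.linalg.eigvalsh(cov)
    trace = lam.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(trace > 0, lam[:, 0] / trace, 0.0)
    taus[nc_idx] = np.clip(tau, 0.0, 1.0 / 3.0)
    return taus


def feature_sweep(
    cloud: LocalizationCloud,
    grid: DimensionGrid,
    volume_mode: str = "bullet",
    global_density: float | None = None,
) -> list[ClusterFeatureSet]:
    """Features at every grid dimension from one dendrogram, L cuts.

    ``global_density`` defaults to the cloud's own N/V; when comparing
    resamples the caller may pin it to the parent sample's density.
    """
    pts = cloud.points
    if global_density is None:
        global_density = sample_global_density(cloud)
    Z, order = _complete_linkage(pts)
    sorted_pts = pts[order]
    out = []
    for d in grid.dims:
        if Z is None:
            labels = np.zeros(1, dtype=int)
        else:
            labels = fcluster(Z, t=d, criterion="distance") - 1
        sizes = np.bincount(labels)
        nc = len(sizes)
        if volume_mode == "bullet":
            vols = _bullet_volumes_per_cluster(sorted_pts, labels, sizes)
        else:
            vols = np.full(nc, np.nan)
            cs = ClusterSet(dimension=float(d), labels=labels)
            clamp = grid.size_min if volume_mode == "box" else None
            for k, mem in enumerate(cs.members(sorted_pts)):
                v = cluster_volume(mem, mode=volume_mode, box_clamp=clamp)
                if v is not None:
                    vols[k] = v
        with np.errstate(invalid="ignore", divide="ignore"):
            dens = (sizes / vols) / global_density
        dens_ok = np.isfinite(dens) & (vols > 0)
        taus = _curvatures_per_cluster(sorted_pts, labels, sizes)
        tau_ok = np.isfinite(taus)
        out.append(
            ClusterFeatureSet(
                dimension=float(d),
                n_clusters=nc,
                densities=dens[dens_ok],
                curvatures=taus[tau_ok],
                av_density=float(dens[dens_ok].mean()) if dens_ok.any() else np.nan,
                av_curv=float(taus[tau_ok].mean()) if tau_ok.any() else np.nan,
                n_excluded_density=int(nc - dens_ok.sum()),
                n_excluded_curvature=int(nc - tau_ok.sum()),
                volume_mode=volume_mode,
            )
        )
    return out
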