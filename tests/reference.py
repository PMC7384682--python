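"""Brute-force reference implementations used as independent oracles.

Everything here is written for clarity, not speed: dense distance
matrices, explicit loops, no spatial indexing.  The fast implementations
in ``twocalm`` must agree with these on random instances.
"""

from __future__ import annotations

import numpy as np


def brute_dbscan(points: np.ndarray, rho: float, min_points: int) -> np.ndarray:
    """Dense-matrix DBSCAN with the package's deterministic border rule.

    Core: >= min_points within rho (self included).  Cluster ids are
    assigned to core connected components in index order; a border point
    joins the lowest-id cluster among its core neighbours.
    """
    n = len(points)
    dm = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    within = dm <= rho
    is_core = within.sum(axis=1) >= min_points

    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not is_core[i] or labels[i] != -1:
            continue
        comp = {i}
        frontier = {i}
        while frontier:  # connected component over core-core edges
            nxt = set()
            for j in frontier:
                for k in np.flatnonzero(within[j] & is_core):
                    if k not in comp:
                        comp.add(int(k))
                        nxt.add(int(k))
            frontier = nxt
        for j in comp:
            labels[j] = cluster
        cluster += 1
    for i in range(n):  # border points: lowest cluster id among core neighbours
        if labels[i] == -1 and not is_core[i]:
            neigh = np.flatnonzero(within[i] & is_core)
            if len(neigh):
                labels[i] = labels[neigh].min()
    return labels


def brute_complete_linkage_cut(points: np.ndarray, d: float) -> set:
    """Greedy agglomeration: merge the closest pair (complete linkage)
    while the merge distance is <= d.  Returns the partition as a set of
    frozensets of point indices."""
    clusters = [{i} for i in range(len(points))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = max(
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        if best[0] > d:
            break
        _, a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def brute_ripley_k(points: np.ndarray, dims: np.ndarray, correction: str, box_extents=None) -> np.ndarray:
    """Double-loop evaluation of K(d) over ordered pairs."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    ext = np.asarray(box_extents, float) if box_extents is not None else pts.max(0) - pts.min(0)
    V = float(np.prod(ext))
    K = np.zeros(len(dims))
    for idx, d in enumerate(dims):
        total = 0.0
        for k in range(n):
            for l in range(n):
                if l == k:
                    continue
                diff = pts[k] - pts[l]
                dist = float(np.linalg.norm(diff))
                if dist <= d:
                    if correction == "translation":
                        w = V / float(np.prod(ext - np.abs(diff)))
                    else:
                        w = 1.0
                    total += w
        K[idx] = (V / n**2) * total
    return K


def brute_peacock_d(a: np.ndarray, b: np.ndarray) -> float:
    """Triple-loop 2D KS statistic: all origins, all 4 quadrant orientations."""
    d = 0.0
    for origin in np.vstack([a, b]):
        ox, oy = origin
        for sx in (1, -1):
            for sy in (1, -1):
                fa = np.mean([(p[0] <= ox if sx == 1 else p[0] >= ox) and (p[1] <= oy if sy == 1 else p[1] >= oy) for p in a])
                fb = np.mean([(p[0] <= ox if sx == 1 else p[0] >= ox) and (p[1] <= oy if sy == 1 else p[1] >= oy) for p in b])
                d = max(d, abs(fa - fb))
    return float(d)


def labels_to_partition(labels: np.ndarray) -> set:
    """Cluster labels -> set of frozensets of indices (noise label -1 excluded)."""
    out = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        out.setdefault(lab, set()).add(i)
    return {frozenset(s) for s in out.values()}
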