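"""Per-shoot and per-canopy structural traits.

Shoot angle: elevation of the oriented-bounding-box major axis above the
horizontal plane, θ = arccos(AB·v / ‖AB‖‖v‖) with AB the base→tip major
axis and v its horizontal projection; θ ∈ [0°, 90°].

Shoot length: a base-to-tip skeleton polyline is built from the point
cloud and its consecutive node distances summed.  The reference skeleton
method bins points by geodesic distance from the lowest point on a
k-nearest-neighbor graph and takes per-bin centroids.

Canopy: total shoot length L, convex-hull volume V of the canopy cloud,
and the shoot length density D = L / V (m·m⁻³).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import ConvexHull, cKDTree

from .cloud import PointCloud
from .exceptions import DegenerateGeometryError
from .segmentation import ShootSegment

__all__ = [
    "ShootTraits",
    "CanopyTraits",
    "oriented_bbox",
    "shoot_angle",
    "skeletonize",
    "shoot_length",
    "convex_hull_volume",
    "length_density",
    "measure_segments",
    "canopy_summary",
    "regression_metrics",
]

DEFAULT_BIN_WIDTH = 0.02  # m geodesic bin for skeleton nodes
DEFAULT_KNN = 8           # neighbors in the geodesic graph


@dataclass
class ShootTraits:
    segment_id: int
    theta: float                  # degrees in [0, 90], elevation from horizontal
    length: float                 # m, skeleton polyline length
    chord: float                  # m, distance between skeleton endpoints
    n_points: int
    provenance: str = ""
    skeleton: np.ndarray | None = None  # (k, 3) ordered polyline nodes


@dataclass
class CanopyTraits:
    shoot_count: int
    total_length: float   # L (m)
    hull_volume: float    # V (m³)
    length_density: float  # D = L/V (m·m⁻³)
    mean_theta: float     # degrees


def oriented_bbox(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-oriented bounding box.

    Returns (axes, extents, center): axes are the covariance eigenvectors
    as rows, ordered by decreasing extent; extents are the projection
    ranges along each axis; center is the box center.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or len(points) < 2:
        raise DegenerateGeometryError("oriented_bbox: need at least 2 points")
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs.T[::-1]  # eigh returns ascending eigenvalues
    proj = centered @ axes.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    extents = hi - lo
    order = np.argsort(extents)[::-1]
    axes, extents = axes[order], extents[order]
    lo, hi = lo[order], hi[order]
    center = points.mean(axis=0) + axes.T @ ((lo + hi) / 2)
    return axes, extents, center


def shoot_angle(points: np.ndarray) -> float:
    """Elevation of the shoot's OBB major axis above the horizontal plane.

    The major axis AB is oriented so B (tip) has the higher z; v is the
    unit horizontal projection of AB; θ = arccos(AB·v/‖AB‖) in degrees.
    A vertical shoot (horizontal projection ~ 0) returns exactly 90.
    """
    axes, extents, _ = oriented_bbox(points)
    ab = axes[0] * extents[0]
    if np.linalg.norm(ab) < 1e-12:
        raise DegenerateGeometryError("shoot_angle: zero-length major axis")
    if ab[2] < 0:  # orient base→top
        ab = -ab
    horiz = np.array([ab[0], ab[1], 0.0])
    h_norm = np.linalg.norm(horiz)
    if h_norm < 1e-9 * np.linalg.norm(ab):
        return 90.0
    cosang = float(ab @ (horiz / h_norm) / np.linalg.norm(ab))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _knn_graph(points: np.ndarray, knn: int) -> csr_matrix:
    """Symmetric kNN graph with Euclidean weights; disconnected components
    are stitched via their closest point pair."""
    n = len(points)
    k = min(knn + 1, n)
    tree = cKDTree(points)
    dists, idx = tree.query(points, k=k)
    rows = np.repeat(np.arange(n), k - 1)
    cols = idx[:, 1:].ravel()
    vals = dists[:, 1:].ravel()
    g = csr_matrix((vals, (rows, cols)), shape=(n, n))
    g = g.maximum(g.T)
    n_comp, comp = connected_components(g, directed=False)
    while n_comp > 1:
        # bridge the main component to its nearest other component
        main = comp == comp[0]
        t_main = cKDTree(points[main])
        d_other, j_other = t_main.query(points[~main])
        best = int(np.argmin(d_other))
        main_idx = np.nonzero(main)[0]
        other_idx = np.nonzero(~main)[0]
        a, b = main_idx[j_other[best]], other_idx[best]
        g = g.tolil()
        g[a, b] = g[b, a] = max(d_other[best], 1e-12)
        g = g.tocsr()
        n_comp, comp = connected_components(g, directed=False)
    return g


def skeletonize(points: np.ndarray, method: str = "geodesic_bins",
                bin_width: float = DEFAULT_BIN_WIDTH,
                knn: int = DEFAULT_KNN) -> np.ndarray:
    """Base-to-tip ordered skeleton polyline of a shoot point cloud.

    ``geodesic_bins`` (reference method): root = lowest-z point; geodesic
    distances via shortest paths on the kNN graph; points binned by
    geodesic distance (``bin_width``); one node per bin at the bin
    centroid, ordered by bin index.  The exact root point and the farthest
    point cap the polyline so the basal and distal half-bins are not lost.

    ``laplacian``: iterative Laplacian contraction onto the local curve
    axis, then the contracted points are ordered and chained by the same
    geodesic binning — same contract, smoother nodes.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) == 0:
        raise DegenerateGeometryError("skeletonize: empty point set")
    if len(points) == 1:
        return points.copy()
    if method == "laplacian":
        work = _laplacian_contract(points, knn=knn)
    elif method == "geodesic_bins":
        work = points
    else:
        raise ValueError(f"unknown skeleton method {method!r}")
    root = int(np.argmin(points[:, 2]))
    g = _knn_graph(points, knn)
    geo = dijkstra(g, directed=False, indices=root)
    if not np.isfinite(geo).all():
        raise DegenerateGeometryError("skeletonize: geodesic graph not connected")
    bins = np.floor(geo / bin_width).astype(np.int64)
    nodes = [work[bins == b].mean(axis=0) for b in np.unique(bins)]
    if len(nodes) == 1:  # whole shoot inside one bin: a single node, length 0
        return np.asarray(nodes)
    tip = int(np.argmax(geo))
    polyline = [points[root]] + nodes + [points[tip]]
    return np.asarray(polyline)


def _laplacian_contract(points: np.ndarray, knn: int = DEFAULT_KNN,
                        iterations: int = 10, step: float = 0.5) -> np.ndarray:
    """Contract points toward the local neighborhood centroid (umbrella
    Laplacian), collapsing a tubular cloud onto its curve axis."""
    work = points.copy()
    for _ in range(iterations):
        tree = cKDTree(work)
        _, idx = tree.query(work, k=min(knn + 1, len(work)))
        centroids = work[idx[:, 1:]].mean(axis=1)
        work = work + step * (centroids - work)
    return work


def shoot_length(polyline: np.ndarray) -> float:
    """Sum of Euclidean distances between consecutive polyline nodes."""
    polyline = np.asarray(polyline, dtype=np.float64)
    if len(polyline) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(polyline, axis=0), axis=1).sum())


def convex_hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """3-D convex hull volume (Quickhull).  Returns (volume, degenerate);
    coplanar or too-few inputs give (0.0, True)."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 4:
        return 0.0, True
    try:
        hull = ConvexHull(points)
    except Exception:
        return 0.0, True
    return float(hull.volume), False


def length_density(total_length: float, volume: float) -> float:
    """Shoot length density D = L / V (m·m⁻³)."""
    if volume <= 0:
        raise ZeroDivisionError("length_density: hull volume must be positive")
    return total_length / volume


def measure_segments(segments: list[ShootSegment], method: str = "geodesic_bins",
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     knn: int = DEFAULT_KNN) -> list[ShootTraits]:
    """Angle + skeleton length for every segment; also fills the segment's
    ``length``/``theta`` fields in place."""
    traits = []
    for seg in segments:
        theta = shoot_angle(seg.points)
        skel = skeletonize(seg.points, method=method, bin_width=bin_width, knn=knn)
        length = shoot_length(skel)
        chord = float(np.linalg.norm(skel[-1] - skel[0]))
        seg.length, seg.theta = length, theta
        traits.append(ShootTraits(
            segment_id=seg.segment_id, theta=theta, length=length, chord=chord,
            n_points=len(seg.points), provenance=seg.provenance, skeleton=skel,
        ))
    return traits


def canopy_summary(traits: list[ShootTraits], hull_points: PointCloud) -> CanopyTraits:
    """Canopy-level totals: shoot count, total length L, hull volume V of
    the full canopy cloud, density D = L/V, and mean angle."""
    count = len(traits)
    total = float(sum(t.length for t in traits))
    volume, degenerate = convex_hull_volume(hull_points.points)
    if degenerate or volume <= 0:
        density = 0.0
    else:
        density = length_density(total, volume)
    mean_theta = float(np.mean([t.theta for t in traits])) if traits else float("nan")
    return CanopyTraits(
        shoot_count=count, total_length=total, hull_volume=volume,
        length_density=density, mean_theta=mean_theta,
    )


def regression_metrics(estimated, reference) -> tuple[float, float, float]:
    """R², RMSE, MAE of estimates against reference values.

    R² = 1 − SS_res/SS_tot about the reference mean; errors on the raw
    scale of the inputs.
    """
    est = np.asarray(estimated, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if est.shape != ref.shape or est.size < 2:
        raise ValueError("regression_metrics: need equal-length sequences, n >= 2")
    ss_tot = float(((ref - ref.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ZeroDivisionError("regression_metrics: zero-variance reference")
    resid = est - ref
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    rmse = float(np.sqrt((resid ** 2).mean()))
    mae = float(np.abs(resid).mean())
    return r2, rmse, mae
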