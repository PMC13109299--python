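"""Independent brute-force reference implementations.

These deliberately avoid the package's code paths (no KD-trees, no
sklearn): O(N²) distance matrices and literal textbook definitions, used
to cross-check the fast implementations on small instances.
"""

from __future__ import annotations

import numpy as np


def pairwise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))


def nn_rmse_brute(query: np.ndarray, reference: np.ndarray) -> float:
    d = pairwise(query, reference).min(axis=1)
    return float(np.sqrt((d ** 2).mean()))


def residual_brute(keep: np.ndarray, reference: np.ndarray,
                   threshold: float) -> np.ndarray:
    """Positions of keep-points whose NN distance to reference > threshold."""
    d = pairwise(keep, reference).min(axis=1)
    return np.nonzero(d > threshold)[0]


def sor_keep_brute(points: np.ndarray, k: int, std_mult: float) -> np.ndarray:
    """Positions kept by statistical outlier removal."""
    d = pairwise(points, points)
    np.fill_diagonal(d, np.inf)
    mean_knn = np.sort(d, axis=1)[:, :k].mean(axis=1)
    mu, sigma = mean_knn.mean(), mean_knn.std()
    return np.nonzero(mean_knn <= mu + std_mult * sigma)[0]


def dbscan_brute(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Labels per point (-1 = noise) from literal density reachability.

    Clusters are grown core-point-first by depth-first expansion in scan
    order — the classic deterministic tie-break for border points
    reachable from several clusters.  Neighborhoods come from a full
    pairwise distance matrix, independent of any spatial index.
    """
    n = len(points)
    d = pairwise(points, points)
    neighbors = [np.nonzero(d[i] <= eps)[0] for i in range(n)]  # self included
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for start in range(n):
        if not core[start] or labels[start] != -1:
            continue
        stack = [start]
        while stack:
            j = stack.pop()
            if labels[j] != -1:
                continue
            labels[j] = cluster
            if core[j]:
                for q in neighbors[j]:
                    if labels[q] == -1:
                        stack.append(q)
        cluster += 1
    return labels


def voxel_count_brute(points: np.ndarray, voxel: float) -> int:
    keys = np.floor(points / voxel).astype(np.int64)  # origin-anchored grid
    return len({tuple(k) for k in keys})


def layer_index_brute(z: np.ndarray, thickness: float) -> np.ndarray:
    return np.floor((z - z.min()) / thickness).astype(int)


def polyline_length_brute(nodes: np.ndarray) -> float:
    total = 0.0
    for a, b in zip(nodes[:-1], nodes[1:]):
        total += float(np.sqrt(((a - b) ** 2).sum()))
    return total


def hull_volume_monte_carlo(points: np.ndarray, hull_vertices: np.ndarray,
                            n_samples: int, seed: int) -> float:
    """Rejection-sampling estimate of the convex hull volume: sample the
    bounding box, count points inside every hull facet half-space."""
    from scipy.spatial import ConvexHull  # geometry only, not the volume

    hull = ConvexHull(points)
    rng = np.random.default_rng(seed)
    lo, hi = points.min(axis=0), points.max(axis=0)
    samples = rng.uniform(lo, hi, (n_samples, 3))
    # hull.equations: normal · x + offset <= 0 inside
    inside = np.all(samples @ hull.equations[:, :3].T
                    + hull.equations[:, 3] <= 1e-12, axis=1)
    box = float(np.prod(hi - lo))
    return box * inside.mean()


def r2_rmse_mae_brute(est: np.ndarray, ref: np.ndarray):
    resid = est - ref
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((ref - ref.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    rmse = float(np.sqrt((resid ** 2).mean()))
    mae = float(np.abs(resid).mean())
    return r2, rmse, mae
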