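"""Preprocessing chain for single-tree TLS scans: height crop, statistical
outlier removal (SOR), voxel subsampling.

The chain order is crop → SOR → voxel.  Every filter returns a cloud whose
ids are a subset of the input's ids; no new coordinates are synthesized
(the voxel filter keeps the real input point nearest each voxel centroid),
so downstream index-based set operations stay exact.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .exceptions import EmptyCloudError

__all__ = ["crop_height", "sor_filter", "voxel_downsample", "preprocess"]

DEFAULT_CROP = 0.05       # m above the cloud's own minimum z
DEFAULT_SOR_K = 10        # neighborhood size
DEFAULT_SOR_STD = 5.0     # standard-deviation multiplier
DEFAULT_VOXEL = 0.001     # m


def crop_height(cloud: PointCloud, z_min: float = DEFAULT_CROP) -> PointCloud:
    """Remove the basal slab: keep points with z >= min(z) + z_min.

    The threshold is measured from the cloud's own minimum z, not absolute
    elevation, since scans carry an arbitrary vertical datum.  Removes
    ground clutter and basal growth below ~5 cm by default.
    """
    cloud.require_nonempty("crop_height")
    keep = cloud.z >= cloud.z.min() + z_min
    if not keep.any():
        raise EmptyCloudError(f"crop_height: z_min={z_min} removed every point")
    return cloud.subset(keep)


def sor_filter(cloud: PointCloud, k: int = DEFAULT_SOR_K,
               std_mult: float = DEFAULT_SOR_STD) -> PointCloud:
    """Statistical outlier removal.

    For each point, compute the mean distance to its ``k`` nearest
    neighbors; drop points whose mean distance exceeds
    ``mu + std_mult * sigma``, where mu and sigma are the global mean and
    standard deviation of those per-point means.
    """
    n = len(cloud)
    if n <= k:
        raise ValueError(
            f"sor_filter: need more than k={k} points (have {n}); reduce k"
        )
    tree = cKDTree(cloud.points)
    # k+1 because the closest neighbor of a point is itself
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    mu, sigma = mean_d.mean(), mean_d.std()
    keep = mean_d <= mu + std_mult * sigma
    if not keep.any():
        raise EmptyCloudError("sor_filter removed every point")
    return cloud.subset(keep)


def voxel_downsample(cloud: PointCloud, voxel: float = DEFAULT_VOXEL) -> PointCloud:
    """Keep one representative point per occupied voxel.

    The representative is the input point nearest the voxel's point
    centroid, so output coordinates (and ids) are always real input
    points.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    cloud.require_nonempty("voxel_downsample")
    pts = cloud.points
    # grid anchored at the absolute origin so the operation is idempotent
    keys = np.floor(pts / voxel).astype(np.int64)
    # group points by voxel key
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    sorted_keys = keys[order]
    boundaries = np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)
    starts = np.concatenate([[0], np.nonzero(boundaries)[0] + 1, [len(pts)]])
    reps = np.empty(len(starts) - 1, dtype=np.int64)
    for g in range(len(starts) - 1):
        members = order[starts[g]:starts[g + 1]]
        centroid = pts[members].mean(axis=0)
        local = np.argmin(((pts[members] - centroid) ** 2).sum(axis=1))
        reps[g] = members[local]
    reps.sort()
    return cloud.subset(reps)


def preprocess(cloud: PointCloud, crop: float = DEFAULT_CROP,
               sor_k: int = DEFAULT_SOR_K, sor_std: float = DEFAULT_SOR_STD,
               voxel: float = DEFAULT_VOXEL) -> PointCloud:
    """Run the full chain in the fixed order crop → SOR → voxel."""
    out = crop_height(cloud, crop)
    out = sor_filter(out, sor_k, sor_std)
    return voxel_downsample(out, voxel)
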