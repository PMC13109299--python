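"""Pairwise rigid registration of two scans of the same tree.

Alignment is anchored on the trunk: a coarse translation matches the two
trunk centroids, then point-to-point ICP refines the transform on the
trunk clouds only (trunks barely change between scans, shoots do).  The
composed transform is applied to the full moving cloud, and the alignment
is scored by nearest-neighbor RMSE on the full trees, with a quality gate
that excludes badly aligned pairs from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .exceptions import DegenerateMatchError, EmptyCloudError
from .trunk import DEFAULT_LAMBDA, DEFAULT_THICKNESS, extract_trunk

__all__ = [
    "RigidTransform",
    "AlignmentResult",
    "coarse_align",
    "icp_refine",
    "apply_transform",
    "nn_rmse",
    "align_trees",
]

DEFAULT_MAX_ITER = 50
DEFAULT_TOL = 1e-6
DEFAULT_MAX_CORR_DIST = 0.1   # m; rejects cross-branch correspondences
DEFAULT_REFINE_CORR_DIST = 0.02  # m; tight gate for the full-cloud polish
DEFAULT_EXCLUDE_RMSE = 0.09   # m; quality gate


@dataclass
class RigidTransform:
    """p' = R @ p + t, with R orthonormal and det(R) = +1."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``first``, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ first.rotation,
            translation=self.rotation @ first.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        r_inv = self.rotation.T
        return RigidTransform(rotation=r_inv, translation=-r_inv @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()


@dataclass
class AlignmentResult:
    """Full-pair alignment outcome with quality gate."""

    transform: RigidTransform     # maps moving → fixed
    rmse_d: float                 # nearest-neighbor RMSE on the full trees (m)
    iterations: int               # ICP iterations used
    excluded: bool                # True when rmse_d > exclusion threshold
    moving_aligned: PointCloud | None = None


def coarse_align(moving: PointCloud, fixed: PointCloud) -> RigidTransform:
    """Pure translation matching the centroids of the two (trunk) clouds."""
    moving.require_nonempty("coarse_align: moving")
    fixed.require_nonempty("coarse_align: fixed")
    a = fixed.points.mean(axis=0) - moving.points.mean(axis=0)
    return RigidTransform(translation=a)


def _solve_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform src→dst via SVD of the cross-covariance."""
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    h = (src - c_src).T @ (dst - c_dst)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = c_dst - r @ c_src
    return RigidTransform(rotation=r, translation=t)


def icp_refine(moving: PointCloud, fixed: PointCloud,
               max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL,
               max_corr_dist: float = DEFAULT_MAX_CORR_DIST,
               ) -> tuple[RigidTransform, int]:
    """Point-to-point ICP with a closed-form SVD update.

    Each iteration matches every moving point to its nearest fixed point
    within ``max_corr_dist``, solves the least-squares rigid transform on
    the matched pairs, and applies it.  Stops when the relative change of
    the correspondence RMSE drops below ``tol``.  Deterministic: no random
    initialization; the caller provides the coarse starting pose.
    """
    if len(moving) < 3 or len(fixed) < 3:
        raise DegenerateMatchError("icp_refine: need at least 3 points per cloud")
    tree = cKDTree(fixed.points)
    current = moving.points.copy()
    total = RigidTransform.identity()
    prev_rmse = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        dists, nn = tree.query(current, distance_upper_bound=max_corr_dist)
        matched = np.isfinite(dists)
        if matched.sum() < 3:
            raise DegenerateMatchError(
                f"icp_refine: fewer than 3 correspondences within "
                f"max_corr_dist={max_corr_dist}"
            )
        step = _solve_rigid(current[matched], fixed.points[nn[matched]])
        current = step.apply(current)
        total = step.compose(total)
        rmse = float(np.sqrt(np.mean(dists[matched] ** 2)))
        if rmse < 1e-12:  # exact overlap: nothing left to refine
            break
        if prev_rmse < np.inf:
            denom = max(prev_rmse, 1e-30)
            if abs(prev_rmse - rmse) / denom < tol:
                break
        prev_rmse = rmse
    return total, iterations


def apply_transform(cloud: PointCloud, t: RigidTransform) -> PointCloud:
    """Rigidly move every point; ids and labels are untouched."""
    return PointCloud(points=t.apply(cloud.points), ids=cloud.ids.copy(),
                      labels={k: v.copy() for k, v in cloud.labels.items()})


def nn_rmse(query: PointCloud, reference: PointCloud) -> float:
    """RMSE of nearest-neighbor distances from every query point to the
    reference cloud.  Asymmetric by definition: the query is the smaller
    (after-pruning) cloud of a pair."""
    query.require_nonempty("nn_rmse: query")
    reference.require_nonempty("nn_rmse: reference")
    dists, _ = cKDTree(reference.points).query(query.points)
    return float(np.sqrt(np.mean(dists ** 2)))


def align_trees(moving: PointCloud, fixed: PointCloud, *,
                thickness: float = DEFAULT_THICKNESS, lam: float = DEFAULT_LAMBDA,
                max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL,
                max_corr_dist: float = DEFAULT_MAX_CORR_DIST,
                exclude_rmse: float = DEFAULT_EXCLUDE_RMSE,
                refine_full: bool = True,
                refine_corr_dist: float = DEFAULT_REFINE_CORR_DIST,
                keep_cloud: bool = True) -> AlignmentResult:
    """Full-tree alignment: trunk extraction → coarse + ICP on trunks →
    tight-gated ICP polish on the full clouds → RMSE gate.

    The trunk stage is what avoids ICP's local optima on canopies that
    changed between scans; but a trunk is nearly a surface of revolution,
    so yaw stays weakly determined by it.  The polish stage re-runs ICP on
    the full clouds from the trunk solution with a much tighter
    correspondence gate (``refine_corr_dist``): structure that changed
    between the scans (new or removed shoots) finds no matches inside the
    tight gate and cannot bias the pose, while the unchanged canopy
    provides long horizontal levers that lock yaw.

    The registration RMSE ``d`` is computed on the full trees after the
    transform, with the smaller cloud as the query (the pruned scan of a
    pair has fewer points).  Pairs with ``d`` above ``exclude_rmse`` are
    flagged excluded and must not feed shoot extraction.
    """
    if len(moving) == 0 and len(fixed) == 0:
        raise EmptyCloudError("align_trees: both clouds are empty")
    trunk_m = moving.by_ids(extract_trunk(moving, thickness, lam).trunk_ids)
    trunk_f = fixed.by_ids(extract_trunk(fixed, thickness, lam).trunk_ids)
    t_coarse = coarse_align(trunk_m, trunk_f)
    trunk_m_coarse = apply_transform(trunk_m, t_coarse)
    t_fine, iterations = icp_refine(trunk_m_coarse, trunk_f, max_iter, tol,
                                    max_corr_dist)
    t_total = t_fine.compose(t_coarse)
    moving_aligned = apply_transform(moving, t_total)
    if refine_full:
        t_polish, it2 = icp_refine(moving_aligned, fixed, max_iter, tol,
                                   refine_corr_dist)
        t_total = t_polish.compose(t_total)
        moving_aligned = apply_transform(moving, t_total)
        iterations += it2
    if len(moving_aligned) <= len(fixed):
        d = nn_rmse(moving_aligned, fixed)
    else:
        d = nn_rmse(fixed, moving_aligned)
    return AlignmentResult(
        transform=t_total,
        rmse_d=d,
        iterations=iterations,
        excluded=bool(d > exclude_rmse),
        moving_aligned=moving_aligned if keep_cloud else None,
    )
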