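"""Instance segmentation of residual shoot points with DBSCAN.

Residual AS/PS points form dense elongated clusters (one per shoot) plus
scattered registration noise; DBSCAN separates them without needing a
cluster count and discards the noise.  Defaults Eps = 0.02 m, MinPts = 20
suit voxel-subsampled TLS clouds at millimeter spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .cloud import PointCloud

__all__ = ["ShootSegment", "cluster_shoots", "filter_segments"]

DEFAULT_EPS = 0.02      # m neighborhood radius
DEFAULT_MIN_PTS = 20    # minimum neighbors (self included) for a core point


@dataclass
class ShootSegment:
    """One clustered shoot instance."""

    segment_id: int
    point_ids: np.ndarray     # ids in the source cloud
    points: np.ndarray        # (n, 3) coordinates
    provenance: str = ""      # AS, PS, AS∩PS, AS−PS or PS−AS
    length: float | None = None   # filled by the trait stage (m)
    theta: float | None = None    # filled by the trait stage (degrees)


def cluster_shoots(cloud: PointCloud, eps: float = DEFAULT_EPS,
                   min_pts: int = DEFAULT_MIN_PTS,
                   provenance: str = "") -> list[ShootSegment]:
    """Cluster a residual cloud into shoot instances; noise is dropped.

    Classic DBSCAN: a core point has >= min_pts neighbors within eps,
    counting itself; clusters are connected components of density
    reachability.  Labeling is deterministic — segments are renumbered by
    their lowest member id, so the partition is invariant to point order.
    """
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    if len(cloud) == 0:
        return []
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(cloud.points)
    segments = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        mask = labels == lab
        segments.append(ShootSegment(
            segment_id=-1,
            point_ids=cloud.ids[mask],
            points=cloud.points[mask],
            provenance=provenance,
        ))
    segments.sort(key=lambda s: int(s.point_ids.min()))
    for i, seg in enumerate(segments):
        seg.segment_id = i
    return segments


def filter_segments(segments: list[ShootSegment],
                    min_length: float = 0.0) -> list[ShootSegment]:
    """Drop segments whose measured length is below ``min_length``.

    Guards the trait stage against fragments; requires lengths already
    measured.  min_length = 0 disables the filter.
    """
    if min_length <= 0:
        return list(segments)
    kept = []
    for seg in segments:
        if seg.length is None:
            raise ValueError(
                f"segment {seg.segment_id} has no measured length; run the "
                "trait stage before filtering"
            )
        if seg.length >= min_length:
            kept.append(seg)
    return kept
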