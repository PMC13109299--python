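"""The point-cloud container shared by every pipeline stage.

A :class:`PointCloud` is an ordered set of 3-D points (meters, z-up) with
stable integer ids assigned at load time.  Ids survive filtering and rigid
transforms, which is what makes the downstream annual-shoot / pruned-shoot
set arithmetic exact rather than proximity-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyCloudError

__all__ = ["PointCloud"]


@dataclass
class PointCloud:
    """3-D points with stable ids and optional per-point label columns.

    Parameters
    ----------
    points : (N, 3) float array
        Coordinates in meters.
    ids : (N,) int array, optional
        Unique per-point identifiers; defaults to ``0..N-1``.
    labels : dict of str -> (N,) array, optional
        Per-point categorical or numeric tags (e.g. ``organ``, ``shoot_id``,
        ``status``).  Each column must align with ``points`` row-for-row.
    """

    points: np.ndarray
    ids: np.ndarray = None  # type: ignore[assignment]
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain non-finite coordinates")
        n = len(self.points)
        if self.ids is None:
            self.ids = np.arange(n, dtype=np.int64)
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)
        if len(self.ids) != n:
            raise ValueError("ids length does not match points")
        if len(np.unique(self.ids)) != n:
            raise ValueError("ids are not unique")
        for key, col in self.labels.items():
            col = np.asarray(col)
            if len(col) != n:
                raise ValueError(f"label column {key!r} length mismatch")
            self.labels[key] = col

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def subset(self, mask: np.ndarray) -> "PointCloud":
        """Select points by boolean mask or positional index array.

        Ids and labels follow the selection, so the result's ids are a
        subset of this cloud's ids.
        """
        mask = np.asarray(mask)
        return PointCloud(
            points=self.points[mask],
            ids=self.ids[mask],
            labels={k: v[mask] for k, v in self.labels.items()},
        )

    def by_ids(self, wanted: np.ndarray) -> "PointCloud":
        """Select the points whose ids are in ``wanted`` (cloud order kept)."""
        wanted = np.asarray(wanted, dtype=np.int64)
        return self.subset(np.isin(self.ids, wanted))

    def id_index(self) -> dict[int, int]:
        """Map id -> row position, for O(1) id lookups."""
        return {int(i): pos for pos, i in enumerate(self.ids)}

    def require_nonempty(self, context: str = "operation") -> "PointCloud":
        if len(self) == 0:
            raise EmptyCloudError(f"{context}: cloud has no points")
        return self

    def copy(self) -> "PointCloud":
        return PointCloud(
            points=self.points.copy(),
            ids=self.ids.copy(),
            labels={k: v.copy() for k, v in self.labels.items()},
        )
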