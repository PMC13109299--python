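"""Multi-temporal differencing: extract annual and pruned shoots as the
non-overlapping residual between aligned scans.

With a pair aligned to a common frame, duplicate points are those closer
than a threshold to the other scan; the threshold is 4 × d, where d is the
pair's nearest-neighbor registration RMSE.  Annual shoots (AS) are the
points present before the next pruning but absent after the previous one
(in BP_{i+1}, not in AP_i); pruned shoots (PS) are present before a
pruning but absent after it (in BP_{i+1}, not in AP_{i+1}).  Because both
subsets live in the same BP_{i+1} cloud, the AS∩PS / AS−PS / PS−AS
decomposition is exact index arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .exceptions import AlignmentExcludedError
from .registration import AlignmentResult, nn_rmse

__all__ = [
    "DiffResult",
    "remove_overlap",
    "extract_annual_shoots",
    "extract_pruned_shoots",
    "decompose_as_ps",
]

DEFAULT_K = 4.0  # threshold multiplier on the registration RMSE d


@dataclass
class DiffResult:
    """AS/PS id sets over one common source cloud (BP_{i+1})."""

    source_cloud: PointCloud
    as_ids: np.ndarray
    ps_ids: np.ndarray
    inter_ids: np.ndarray    # AS ∩ PS
    as_only_ids: np.ndarray  # AS − PS
    ps_only_ids: np.ndarray  # PS − AS
    d_as: float              # registration RMSE of the growth pair
    d_ps: float              # registration RMSE of the pruning pair
    k: float = DEFAULT_K


def remove_overlap(keep: PointCloud, reference: PointCloud,
                   threshold: float) -> np.ndarray:
    """Ids of ``keep`` points farther than ``threshold`` from ``reference``.

    This is the non-duplicate residual: duplicate points are those whose
    nearest-neighbor distance to the other (aligned) scan falls below the
    threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(reference) == 0:
        warnings.warn("remove_overlap: empty reference, nothing to subtract")
        return keep.ids.copy()
    dists, _ = cKDTree(reference.points).query(keep.points)
    return keep.ids[dists > threshold]


def _residual(keep: PointCloud, reference: PointCloud, k: float,
              alignment: AlignmentResult | None) -> tuple[np.ndarray, float]:
    if alignment is not None and alignment.excluded:
        raise AlignmentExcludedError(
            f"pair failed the registration gate (d={alignment.rmse_d:.4f} m); "
            "shoot extraction refused"
        )
    # d is defined on the pruned/smaller cloud as query
    if len(reference) <= len(keep):
        d = nn_rmse(reference, keep)
    else:
        d = nn_rmse(keep, reference)
    # identical clouds give d = 0; any strictly positive threshold then
    # yields the correct empty residual
    threshold = k * d if k * d > 0 else np.finfo(np.float64).tiny
    ids = remove_overlap(keep, reference, threshold)
    return ids, d


def extract_annual_shoots(ap_i: PointCloud, bp_next: PointCloud,
                          k: float = DEFAULT_K,
                          alignment: AlignmentResult | None = None,
                          ) -> tuple[np.ndarray, float]:
    """Annual shoots: points of BP_{i+1} absent from AP_i.

    Returns (ids into bp_next, d) where d = nn_rmse of the aligned pair and
    the residual threshold is k*d (default k=4).
    """
    return _residual(keep=bp_next, reference=ap_i, k=k, alignment=alignment)


def extract_pruned_shoots(bp_next: PointCloud, ap_next: PointCloud,
                          k: float = DEFAULT_K,
                          alignment: AlignmentResult | None = None,
                          ) -> tuple[np.ndarray, float]:
    """Pruned shoots: points of BP_{i+1} absent from AP_{i+1}."""
    return _residual(keep=bp_next, reference=ap_next, k=k, alignment=alignment)


def decompose_as_ps(as_ids: np.ndarray, ps_ids: np.ndarray,
                    source: PointCloud, d_as: float = float("nan"),
                    d_ps: float = float("nan"), k: float = DEFAULT_K,
                    ) -> DiffResult:
    """Exact index-set decomposition of AS and PS over their shared source.

    Both id sets must be subsets of the source cloud's ids (they were both
    extracted from the same BP_{i+1} scan); a violation signals that a
    transform broke point identity somewhere upstream.
    """
    as_ids = np.unique(np.asarray(as_ids, dtype=np.int64))
    ps_ids = np.unique(np.asarray(ps_ids, dtype=np.int64))
    source_set = source.ids
    for name, ids in (("as_ids", as_ids), ("ps_ids", ps_ids)):
        missing = np.setdiff1d(ids, source_set)
        if len(missing):
            raise ValueError(
                f"decompose_as_ps: {name} contains {len(missing)} ids absent "
                f"from the source cloud (first: {missing[0]})"
            )
    return DiffResult(
        source_cloud=source,
        as_ids=as_ids,
        ps_ids=ps_ids,
        inter_ids=np.intersect1d(as_ids, ps_ids),
        as_only_ids=np.setdiff1d(as_ids, ps_ids),
        ps_only_ids=np.setdiff1d(ps_ids, as_ids),
        d_as=d_as,
        d_ps=d_ps,
        k=k,
    )
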