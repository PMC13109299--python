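"""Distributional analysis of shoot traits and pruning-pattern fractions.

Shoot angles are approximately normal after a square-root transform
(θ' = √θ) and shoot lengths after a shifted log transform
(l' = log10(l + 0.1)).  Gaussian fits are performed on the transformed
scale and reported as back-transformed mean and mean ∓ SD interval.
Pruning patterns are summarized as the fraction of pruned shoots that are
annual (by count and by length) and the fraction of annual shoots that
were pruned (likewise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .diff import DiffResult
from .segmentation import ShootSegment

__all__ = [
    "DistributionFit",
    "PruningPatternSummary",
    "transform_values",
    "inverse_transform",
    "ks_normality",
    "gaussian_fit",
    "classify_segments",
    "pruning_fractions",
]

TRANSFORMS = ("sqrt", "log10_offset")
LOG_OFFSET = 0.1
MEMBERSHIP_THRESHOLD = 0.5  # a segment is "annual"/"pruned" when > 50% of its
                            # points belong to the corresponding id set


@dataclass
class DistributionFit:
    variable: str        # "angle" or "length"
    transform: str       # "sqrt" or "log10_offset"
    mu: float            # mean on the transformed scale
    sigma: float         # SD (ddof=1) on the transformed scale
    ks_p: float          # KS normality p-value of the transformed sample
    back_mean: float     # inverse-transformed mu
    back_lo: float       # inverse-transformed mu - sigma
    back_hi: float       # inverse-transformed mu + sigma
    n: int


@dataclass
class PruningPatternSummary:
    frac_ps_annual_count: float    # fraction of pruned shoots that are annual
    frac_ps_annual_length: float   # same, weighted by shoot length
    frac_as_pruned_count: float    # fraction of annual shoots that were pruned
    frac_as_pruned_length: float
    n_as_segments: int
    n_ps_segments: int
    undefined: bool = False        # a denominator was zero


def transform_values(values, kind: str) -> np.ndarray:
    """θ' = √θ (kind="sqrt") or l' = log10(l + 0.1) (kind="log10_offset")."""
    values = np.asarray(values, dtype=np.float64)
    if kind == "sqrt":
        bad = np.nonzero(values < 0)[0]
        if len(bad):
            raise ValueError(f"sqrt transform: negative values at indices {bad[:10].tolist()}")
        return np.sqrt(values)
    if kind == "log10_offset":
        bad = np.nonzero(values <= -LOG_OFFSET)[0]
        if len(bad):
            raise ValueError(
                f"log10_offset transform: values <= -{LOG_OFFSET} at indices {bad[:10].tolist()}"
            )
        return np.log10(values + LOG_OFFSET)
    raise ValueError(f"unknown transform {kind!r}")


def inverse_transform(values, kind: str) -> np.ndarray:
    """Inverse of :func:`transform_values`: θ = θ'², l = 10^l' − 0.1."""
    values = np.asarray(values, dtype=np.float64)
    if kind == "sqrt":
        return values ** 2
    if kind == "log10_offset":
        return 10.0 ** values - LOG_OFFSET
    raise ValueError(f"unknown transform {kind!r}")


def ks_normality(values) -> float:
    """One-sample Kolmogorov–Smirnov p-value against the normal.

    The sample is standardized with its own mean and SD and compared to
    the standard normal with the classical KS p-value.  With estimated
    parameters this convention is anti-conservative (p-values run high),
    which is acceptable for the descriptive normality screen used here.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 8:
        raise ValueError("ks_normality: need at least 8 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("ks_normality: constant sample")
    z = (values - values.mean()) / sd
    return float(sstats.kstest(z, "norm").pvalue)


def gaussian_fit(transformed, variable: str, transform: str) -> DistributionFit:
    """Gaussian fit on the transformed scale with back-transformed summary.

    mu and sigma are the sample mean and SD (ddof=1); back_mean/lo/hi are
    the inverse transform of mu and mu ∓ sigma.
    """
    x = np.asarray(transformed, dtype=np.float64)
    if x.size < 8:
        raise ValueError("gaussian_fit: need at least 8 values")
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    try:
        ks_p = ks_normality(x) if sigma > 0 else float("nan")
    except ValueError:
        ks_p = float("nan")
    lo, mid, hi = inverse_transform(np.array([mu - sigma, mu, mu + sigma]), transform)
    return DistributionFit(
        variable=variable, transform=transform, mu=mu, sigma=sigma, ks_p=ks_p,
        back_mean=float(mid), back_lo=float(lo), back_hi=float(hi), n=int(x.size),
    )


def _membership_fraction(segment: ShootSegment, id_set: np.ndarray) -> float:
    return float(np.isin(segment.point_ids, id_set).mean())


def classify_segments(segments: list[ShootSegment], id_set: np.ndarray,
                      threshold: float = MEMBERSHIP_THRESHOLD) -> np.ndarray:
    """Boolean flags: True where > threshold of a segment's points belong
    to ``id_set``."""
    return np.array([_membership_fraction(s, id_set) > threshold for s in segments])


def pruning_fractions(diff: DiffResult, as_segments: list[ShootSegment],
                      ps_segments: list[ShootSegment],
                      threshold: float = MEMBERSHIP_THRESHOLD,
                      ) -> PruningPatternSummary:
    """Pruning-pattern fractions from one tree's AS/PS decomposition.

    A PS segment counts as annual when more than half of its points carry
    AS membership in the shared source cloud, and symmetrically for AS
    segments counting as pruned.  Length fractions weight the same
    classification by measured shoot length (requires the trait stage).
    """
    ps_is_annual = classify_segments(ps_segments, diff.as_ids, threshold)
    as_is_pruned = classify_segments(as_segments, diff.ps_ids, threshold)

    def _frac(flags: np.ndarray, segments: list[ShootSegment]) -> tuple[float, float, bool]:
        n = len(segments)
        if n == 0:
            return float("nan"), float("nan"), True
        count_frac = float(flags.mean())
        lengths = np.array([s.length if s.length is not None else np.nan
                            for s in segments])
        total = np.nansum(lengths)
        if not np.isfinite(lengths).all() or total <= 0:
            return count_frac, float("nan"), True
        return count_frac, float(lengths[flags].sum() / total), False

    ps_count, ps_len, und1 = _frac(ps_is_annual, ps_segments)
    as_count, as_len, und2 = _frac(as_is_pruned, as_segments)
    return PruningPatternSummary(
        frac_ps_annual_count=ps_count,
        frac_ps_annual_length=ps_len,
        frac_as_pruned_count=as_count,
        frac_as_pruned_length=as_len,
        n_as_segments=len(as_segments),
        n_ps_segments=len(ps_segments),
        undefined=und1 or und2,
    )
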