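"""Synthetic orchard generator: labeled pear-tree point clouds with known
trunk/scaffold/shoot structure, pruning and growth events, scan noise and
rigid mis-registration.

Trees follow the three training architectures used in commercial pear
orchards — Y (2 scaffolds), "2+1" (2 arms + central leader) and "3+1"
(3 arms + leader).  Shoot angles are drawn normal on the √θ scale and
lengths normal on the log10(l+0.1) scale, echoing the distributions of
field-measured annual shoots; both models are configurable.  Shoot
centerlines are circular arcs, so every ground-truth length is an exact
closed-form arc length.

Every operation is deterministic given its seed (one numpy Generator per
event, documented draw order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .exceptions import SpecError
from .registration import RigidTransform

__all__ = [
    "TreeSpec",
    "GroundTruth",
    "SimulatedTriple",
    "generate_tree",
    "simulate_prune",
    "simulate_growth",
    "perturb_scan",
    "make_triple",
]

ARCHITECTURES = {
    # name -> (arm azimuths in degrees, has central leader)
    "Y": ((0.0, 180.0), False),
    "two_plus_one": ((0.0, 180.0), True),
    "three_plus_one": ((0.0, 120.0, 240.0), True),
}


@dataclass
class TreeSpec:
    """Geometry and statistical models of one synthetic tree."""

    architecture: str = "Y"
    trunk_height: float = 1.0        # m
    trunk_radius: float = 0.025      # m at the base
    trunk_taper: float = 0.7         # top radius / base radius
    trunk_ovality: float = 0.10      # elliptical cross-section amplitude (fraction of r)
    trunk_flute: float = 0.12        # bark fluting amplitude (fraction of r)
    trunk_flute_lobes: int = 9       # fluting lobes around the circumference
    trunk_lean: float = 1.5          # degrees of centerline lean
    scaffold_length: float = 1.2     # m
    scaffold_radius: float = 0.015   # m
    scaffold_elevation: float = 45.0  # degrees above horizontal
    leader_elevation: float = 80.0   # degrees, for 2+1 / 3+1 leaders
    n_shoots: int = 30
    angle_model: tuple[float, float] = (8.67, 1.2)    # (mu, sigma) on √θ scale
    length_model: tuple[float, float] = (-0.33, 0.25)  # (mu, sigma) on log10(l+0.1)
    shoot_radius: float = 0.004      # m
    curvature: float = 0.05          # max lateral bow as fraction of length
    point_spacing: float = 0.003     # m between sampled surface points
    attach_margin: float = 0.1       # shoots attach within [margin, 1-margin/2] of a scaffold
    min_attach_spacing: float = 0.0  # m along-scaffold spacing floor (0 = off)
    min_shoot_clearance: float = 0.0  # m pairwise shoot-tube clearance (0 = off);
                                      # set > DBSCAN eps for well-separated fixtures
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise SpecError(f"unknown architecture {self.architecture!r}")
        for name in ("trunk_radius", "scaffold_radius", "shoot_radius",
                     "trunk_height", "scaffold_length", "point_spacing"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        mu_l, _ = self.length_model
        mean_len = 10.0 ** mu_l - 0.1
        if mean_len > 10 * self.scaffold_length:
            raise SpecError("shoots longer than 10x the scaffold are infeasible")


@dataclass
class GroundTruth:
    """Per-point and per-shoot labels emitted alongside a generated cloud.

    ``per_point`` mirrors the cloud's label columns (indexed by point id);
    ``shoots`` has one row per shoot with the analytic chord angle and arc
    length of its generating centerline.
    """

    per_point: pd.DataFrame           # index: point id; organ, shoot_id, status
    shoots: pd.DataFrame              # shoot_id, true_angle, true_length, attach_*, status

    def copy(self) -> "GroundTruth":
        return GroundTruth(self.per_point.copy(), self.shoots.copy())


@dataclass
class SimulatedTriple:
    """One simulated pruning cycle: AP_i → growth → BP_{i+1} → AP_{i+1}."""

    ap_i: PointCloud
    bp_next: PointCloud
    ap_next: PointCloud
    truth_ap_i: GroundTruth
    truth_bp_next: GroundTruth      # statuses reflect the coming pruning
    truth_ap_next: GroundTruth
    true_as_ids: np.ndarray         # BP_{i+1} ids with annual status
    true_ps_ids: np.ndarray         # BP_{i+1} ids removed by the second pruning
    scan_transforms: dict[str, RigidTransform] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


# ------------------------------------------------------------------ geometry


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_to(u: np.ndarray, psi: float) -> np.ndarray:
    """A unit vector perpendicular to u, rotated by psi within u's normal plane."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(u @ helper) > 0.99:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    return np.cos(psi) * e1 + np.sin(psi) * e2


def _tube_points(centers: np.ndarray, tangents: np.ndarray, radius: float,
                 spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Sample the surface of a tube around a polyline of ring centers."""
    n_circ = max(4, int(round(2 * np.pi * radius / spacing)))
    gammas = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    out = []
    for c, t in zip(centers, tangents):
        e1 = _orthonormal_to(t, 0.0)
        e2 = np.cross(_unit(t), e1)
        phase = rng.uniform(0, 2 * np.pi)
        ring = c + radius * (np.cos(gammas + phase)[:, None] * e1
                             + np.sin(gammas + phase)[:, None] * e2)
        out.append(ring)
    return np.concatenate(out)


def _arc_centerline(attach: np.ndarray, u: np.ndarray, w: np.ndarray,
                    arc_length: float, bow_frac: float, spacing: float,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circular-arc centerline with exact arc length and chord along u.

    Returns (ring centers, unit tangents, arc-position fractions).  The
    chord runs from ``attach`` along ``u``; the bow of height
    ``bow_frac * arc_length`` points along ``w`` (w ⊥ u).
    """
    n = max(3, int(np.ceil(arc_length / spacing)) + 1)
    s_frac = np.linspace(0.0, 1.0, n)
    if bow_frac < 1e-6:
        centers = attach + np.outer(s_frac * arc_length, u)
        tangents = np.tile(u, (n, 1))
        return centers, tangents, s_frac
    # solve the half-angle alpha from sagitta/arc = (1 - cos a) / (2 a);
    # the ratio tops out at 1/π (a semicircle), so cap the bow below that
    f = min(bow_frac, 0.3)
    alpha = brentq(lambda a: (1 - np.cos(a)) / (2 * a) - f, 1e-9, np.pi - 1e-9)
    radius = arc_length / (2 * alpha)
    chord = 2 * radius * np.sin(alpha)
    phi = -alpha + 2 * alpha * s_frac
    xi = chord / 2 + radius * np.sin(phi)
    eta = radius * np.cos(phi) - radius * np.cos(alpha)
    centers = attach + np.outer(xi, u) + np.outer(eta, w)
    tangents = np.outer(np.cos(phi), u) - np.outer(np.sin(phi), w)
    return centers, tangents, s_frac


def _scaffolds(spec: TreeSpec) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
    """(origin, unit direction, length, radius) per scaffold — deterministic."""
    azimuths, leader = ARCHITECTURES[spec.architecture]
    top = np.array([spec.trunk_height * np.tan(np.radians(spec.trunk_lean)),
                    0.0, spec.trunk_height])
    out = []
    for az in azimuths:
        e = np.radians(spec.scaffold_elevation)
        a = np.radians(az)
        d = np.array([np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e)])
        out.append((top, d, spec.scaffold_length, spec.scaffold_radius))
    if leader:
        e = np.radians(spec.leader_elevation)
        d = np.array([np.cos(e), 0.0, np.sin(e)])
        out.append((top, d, spec.scaffold_length * 0.8, spec.scaffold_radius))
    return out


def _draw_angle(rng: np.random.Generator, model: tuple[float, float]) -> float:
    """θ = (normal draw on √ scale)², resampled into (0°, 90°]."""
    mu, sigma = model
    hi = np.sqrt(90.0)
    for _ in range(1000):
        d = rng.normal(mu, sigma)
        if 0.0 < d <= hi:
            return float(d ** 2)
    raise SpecError(f"angle model {model} never lands in (0, 90]")


def _draw_length(rng: np.random.Generator, model: tuple[float, float]) -> float:
    """l = 10^(normal draw) − 0.1, resampled into (0.02 m, ∞)."""
    mu, sigma = model
    for _ in range(1000):
        val = 10.0 ** rng.normal(mu, sigma) - 0.1
        if val > 0.02:
            return float(val)
    raise SpecError(f"length model {model} never yields a usable length")


def _make_shoots(spec: TreeSpec, n: int, rng: np.random.Generator,
                 first_shoot_id: int, status: str,
                 existing_attach: list[tuple[int, float]] | None = None,
                 ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray]:
    """Sample ``n`` shoots on the scaffolds.

    Returns (points, per-shoot table, per-point shoot ids, per-point arc
    fractions).  Draw order per shoot: scaffold, attach position, azimuth,
    angle, length, bow fraction, bow orientation, ring phases.
    """
    scaffolds = _scaffolds(spec)
    attach_used = list(existing_attach or [])
    accepted_tree = None
    accepted_pts: list[np.ndarray] = []
    pts_all, sid_all, arc_all, rows = [], [], [], []
    for j in range(n):
        shoot_id = first_shoot_id + j
        for _attempt in range(200):
            sc = int(rng.integers(len(scaffolds)))
            origin, d, length, _ = scaffolds[sc]
            t = float(rng.uniform(spec.attach_margin, 1 - spec.attach_margin / 2))
            if spec.min_attach_spacing > 0:
                ok = all(sc != s or abs(t - u) * length >= spec.min_attach_spacing
                         for s, u in attach_used)
                if not ok:
                    continue
            # shoots emerge radially from the branch surface, fanning
            # outward — the chord's horizontal azimuth follows the
            # emergence direction (with jitter), never running
            # longitudinally along the scaffold
            gamma = rng.uniform(0, 2 * np.pi)
            e1 = _orthonormal_to(d, 0.0)
            e2 = np.cross(d, e1)
            radial = np.cos(gamma) * e1 + np.sin(gamma) * e2
            attach = origin + t * length * d + spec.scaffold_radius * radial
            if np.hypot(radial[0], radial[1]) > 0.1:
                azim = float(np.arctan2(radial[1], radial[0])) \
                    + rng.uniform(-np.pi / 6, np.pi / 6)
            else:  # bud on top/bottom of the branch: any direction
                azim = rng.uniform(0, 2 * np.pi)
            theta = _draw_angle(rng, spec.angle_model)
            arc_len = _draw_length(rng, spec.length_model)
            e = np.radians(theta)
            u = np.array([np.cos(e) * np.cos(azim),
                          np.cos(e) * np.sin(azim), np.sin(e)])
            bow = rng.uniform(0, spec.curvature)
            w = _orthonormal_to(u, rng.uniform(0, 2 * np.pi))
            centers, tangents, s_frac = _arc_centerline(
                attach, u, w, arc_len, bow, spec.point_spacing)
            pts = _tube_points(centers, tangents, spec.shoot_radius,
                               spec.point_spacing, rng)
            if spec.min_shoot_clearance > 0 and accepted_tree is not None:
                gap, _ = accepted_tree.query(pts, k=1)
                if gap.min() < spec.min_shoot_clearance:
                    continue
            break
        attach_used.append((sc, t))
        if spec.min_shoot_clearance > 0:
            accepted_pts.append(pts)
            accepted_tree = cKDTree(np.concatenate(accepted_pts))
        n_circ = len(pts) // len(centers)
        pts_all.append(pts)
        sid_all.append(np.full(len(pts), shoot_id, dtype=np.int64))
        arc_all.append(np.repeat(s_frac, n_circ))
        rows.append({
            "shoot_id": shoot_id, "true_angle": theta, "true_length": arc_len,
            "attach_x": attach[0], "attach_y": attach[1], "attach_z": attach[2],
            "scaffold": sc, "status": status,
        })
    if not rows:
        empty = np.empty((0, 3))
        return empty, pd.DataFrame(columns=[
            "shoot_id", "true_angle", "true_length", "attach_x", "attach_y",
            "attach_z", "scaffold", "status"]), np.empty(0, np.int64), np.empty(0)
    return (np.concatenate(pts_all), pd.DataFrame(rows),
            np.concatenate(sid_all), np.concatenate(arc_all))


def _assemble(points_parts, organ_parts, sid_parts, arc_parts, status_parts,
              first_id: int = 0) -> PointCloud:
    points = np.concatenate(points_parts)
    n = len(points)
    return PointCloud(
        points=points,
        ids=np.arange(first_id, first_id + n, dtype=np.int64),
        labels={
            "organ": np.concatenate(organ_parts).astype("U10"),
            "shoot_id": np.concatenate(sid_parts),
            "status": np.concatenate(status_parts).astype("U10"),
            "arc_frac": np.concatenate(arc_parts),
        },
    )


def _truth_per_point(cloud: PointCloud) -> pd.DataFrame:
    return pd.DataFrame({
        "organ": cloud.labels["organ"],
        "shoot_id": cloud.labels["shoot_id"],
        "status": cloud.labels["status"],
    }, index=pd.Index(cloud.ids, name="point_id"))


def generate_tree(spec: TreeSpec) -> tuple[PointCloud, GroundTruth]:
    """Sample one labeled tree surface cloud from its spec.

    Deterministic given ``spec.seed``.  Draw order: trunk ring phases,
    scaffold ring phases (in scaffold order), then shoots (see
    ``_make_shoots``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    # trunk: tapered, slightly leaning tube with an oval, fluted (bark-like)
    # cross-section — old pear trunks are not smooth cylinders, and that
    # irregularity is exactly what makes trunk-anchored registration
    # observable in yaw
    n_rings = max(2, int(np.ceil(spec.trunk_height / spec.point_spacing)))
    zs = np.linspace(0.0, spec.trunk_height, n_rings)
    radii = spec.trunk_radius * (1 + (spec.trunk_taper - 1) * zs / spec.trunk_height)
    lean = np.radians(spec.trunk_lean)
    lean_az = 0.0  # lean along +x, deterministic so scaffolds line up
    oval_phase = rng.uniform(0, 2 * np.pi)
    flute_phase = rng.uniform(0, 2 * np.pi)
    trunk_pts = []
    for z, r in zip(zs, radii):
        n_circ = max(6, int(round(2 * np.pi * r / spec.point_spacing)))
        gam = np.linspace(0, 2 * np.pi, n_circ, endpoint=False) + rng.uniform(0, 2 * np.pi)
        r_eff = r * (1.0
                     + spec.trunk_ovality * np.cos(2 * (gam - oval_phase))
                     + spec.trunk_flute * np.cos(spec.trunk_flute_lobes * gam
                                                 + flute_phase))
        cx = z * np.tan(lean) * np.cos(lean_az)
        cy = z * np.tan(lean) * np.sin(lean_az)
        trunk_pts.append(np.column_stack([
            cx + r_eff * np.cos(gam), cy + r_eff * np.sin(gam),
            np.full(n_circ, z)]))
    trunk_pts = np.concatenate(trunk_pts)
    parts_p = [trunk_pts]
    parts_o = [np.full(len(trunk_pts), "trunk")]
    parts_s = [np.full(len(trunk_pts), -1, dtype=np.int64)]
    parts_a = [np.zeros(len(trunk_pts))]
    parts_st = [np.full(len(trunk_pts), "persistent")]
    # scaffolds
    for origin, d, length, radius in _scaffolds(spec):
        n_axis = max(2, int(np.ceil(length / spec.point_spacing)))
        s = np.linspace(0.0, length, n_axis)
        centers = origin + np.outer(s, d)
        tangents = np.tile(d, (n_axis, 1))
        taper = radius * (1 + (0.6 - 1) * s / length)
        pts = []
        for c, t, r in zip(centers, tangents, taper):
            pts.append(_tube_points(c[None, :], t[None, :], r,
                                    spec.point_spacing, rng))
        pts = np.concatenate(pts)
        parts_p.append(pts)
        parts_o.append(np.full(len(pts), "scaffold"))
        parts_s.append(np.full(len(pts), -1, dtype=np.int64))
        parts_a.append(np.zeros(len(pts)))
        parts_st.append(np.full(len(pts), "persistent"))
    # shoots
    shoot_pts, shoots_df, sids, arcs = _make_shoots(
        spec, spec.n_shoots, rng, first_shoot_id=0, status="persistent")
    if len(shoot_pts):
        parts_p.append(shoot_pts)
        parts_o.append(np.full(len(shoot_pts), "shoot"))
        parts_s.append(sids)
        parts_a.append(arcs)
        parts_st.append(np.full(len(shoot_pts), "persistent"))
    cloud = _assemble(parts_p, parts_o, parts_s, parts_a, parts_st)
    truth = GroundTruth(per_point=_truth_per_point(cloud), shoots=shoots_df)
    return cloud, truth


# ------------------------------------------------------------------- events


def _weighted_pick(rng: np.random.Generator, ids: np.ndarray,
                   weights: np.ndarray, m: int) -> np.ndarray:
    """Weighted sampling without replacement (exponential-key trick)."""
    if m >= len(ids):
        return ids.copy()
    keys = rng.exponential(size=len(ids)) / np.maximum(weights, 1e-12)
    return ids[np.argsort(keys)[:m]]


def simulate_prune(cloud: PointCloud, truth: GroundTruth,
                   target_fraction: float, angle_bias: float = 0.1,
                   thinning_fraction: float = 0.8,
                   annual_targeting: float | None = None,
                   seed: int = 0) -> tuple[PointCloud, GroundTruth]:
    """Remove a fraction of shoots, biased toward large angles.

    Shoots are sampled without replacement with weight
    logistic(angle_bias · (θ − 70°)) until ⌈target_fraction · n⌉ are
    removed.  Each removed shoot is thinned (all points deleted) with
    probability ``thinning_fraction``, else headed back (distal points
    beyond a cut at 20–60 % of its length deleted).  When
    ``annual_targeting`` is set, that fraction of the removals is drawn
    from annual-status shoots and the rest from older ones, making the
    annual share of the pruning controllable.

    Side effect: removed points get ``status = "pruned"`` in the *input*
    cloud's labels and truth (the pre-event state records what the event
    took); the returned pair is the post-event cloud and truth.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shoots = truth.shoots
    present = np.unique(cloud.labels["shoot_id"])
    present = present[present >= 0]
    live = shoots[shoots["shoot_id"].isin(present)]
    n = len(live)
    m = int(np.ceil(target_fraction * n))
    if n == 0 or m == 0:
        return cloud.copy(), truth.copy()
    theta = live["true_angle"].to_numpy()
    weights = 1.0 / (1.0 + np.exp(-angle_bias * (theta - 70.0)))
    sid = live["shoot_id"].to_numpy()
    if annual_targeting is None:
        chosen = _weighted_pick(rng, sid, weights, m)
    else:
        is_annual = (live["status"] == "annual").to_numpy()
        m_annual = min(int(round(annual_targeting * m)), int(is_annual.sum()))
        m_old = min(m - m_annual, int((~is_annual).sum()))
        m_annual = min(m - m_old, int(is_annual.sum()))
        chosen = np.concatenate([
            _weighted_pick(rng, sid[is_annual], weights[is_annual], m_annual),
            _weighted_pick(rng, sid[~is_annual], weights[~is_annual], m_old),
        ])
    remove_mask = np.zeros(len(cloud), dtype=bool)
    fully_removed = []
    for s in chosen:
        members = cloud.labels["shoot_id"] == s
        if rng.random() < thinning_fraction:
            remove_mask |= members
            fully_removed.append(s)
        else:
            cut = rng.uniform(0.2, 0.6)
            remove_mask |= members & (cloud.labels["arc_frac"] > cut)
    # record the event on the pre-event state
    cloud.labels["status"] = cloud.labels["status"].copy()
    cloud.labels["status"][remove_mask] = "pruned"
    truth.per_point.loc[cloud.ids[remove_mask], "status"] = "pruned"
    truth.shoots.loc[truth.shoots["shoot_id"].isin(chosen), "status"] = "pruned"
    pruned = cloud.subset(~remove_mask)
    new_truth = GroundTruth(
        per_point=_truth_per_point(pruned),
        shoots=truth.shoots[~truth.shoots["shoot_id"].isin(fully_removed)].copy(),
    )
    return pruned, new_truth


def simulate_growth(cloud: PointCloud, truth: GroundTruth, spec: TreeSpec,
                    n_new: int, seed: int = 0) -> tuple[PointCloud, GroundTruth]:
    """Add ``n_new`` annual shoots drawn from the spec's models.

    Existing points are unchanged; new points get fresh ids above the
    current maximum and ``status = "annual"``.
    """
    if n_new == 0:
        return cloud.copy(), truth.copy()
    rng = np.random.default_rng(seed)
    first_sid = int(max(truth.shoots["shoot_id"].max() if len(truth.shoots) else -1,
                        cloud.labels["shoot_id"].max()) + 1)
    pts, shoots_df, sids, arcs = _make_shoots(spec, n_new, rng, first_sid, "annual")
    new_cloud = _assemble(
        [cloud.points, pts],
        [cloud.labels["organ"], np.full(len(pts), "shoot")],
        [cloud.labels["shoot_id"], sids],
        [cloud.labels["arc_frac"], arcs],
        [cloud.labels["status"], np.full(len(pts), "annual")],
    )
    # keep the original ids for the pre-existing points
    new_ids = np.concatenate([cloud.ids,
                              np.arange(len(pts), dtype=np.int64) + cloud.ids.max() + 1])
    new_cloud = PointCloud(points=new_cloud.points, ids=new_ids,
                           labels=new_cloud.labels)
    new_truth = GroundTruth(
        per_point=_truth_per_point(new_cloud),
        shoots=pd.concat([truth.shoots, shoots_df], ignore_index=True),
    )
    return new_cloud, new_truth


def perturb_scan(cloud: PointCloud, yaw_deg: float = 0.0,
                 translation=(0.0, 0.0, 0.0), noise_sigma: float = 0.0,
                 dropout: float = 0.0, seed: int = 0,
                 ) -> tuple[PointCloud, RigidTransform]:
    """Emulate an independent scan: rigid offset + sensor noise + dropout.

    Applies a yaw rotation about the z axis (through the origin) then a
    translation, adds isotropic Gaussian noise, and deletes a random
    ``dropout`` fraction of points (occlusion proxy).  Surviving points
    keep their ids.  Returns the perturbed cloud and the applied rigid
    transform for use as a registration oracle.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    c, s = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t = RigidTransform(rotation=rot, translation=np.asarray(translation, float))
    pts = t.apply(cloud.points)
    if noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, size=pts.shape)
    out = PointCloud(points=pts, ids=cloud.ids.copy(),
                     labels={k: v.copy() for k, v in cloud.labels.items()})
    if dropout > 0:
        n_keep = int(np.ceil((1.0 - dropout) * len(out)))
        keep = np.sort(rng.choice(len(out), size=n_keep, replace=False))
        out = out.subset(keep)
    return out, t


def make_triple(spec: TreeSpec, prune1: dict | None = None,
                growth: dict | None = None, prune2: dict | None = None,
                scan: dict | None = None, seed: int = 0) -> SimulatedTriple:
    """Simulate one pruning cycle and scan it three times.

    The base tree is pruned (AP_i), grows annual shoots (BP_{i+1}), and is
    pruned again (AP_{i+1}); each state is scanned with an independent
    rigid offset, noise and dropout.  The manifest records the applied
    transforms and the true AS/PS id sets in BP_{i+1} for downstream
    evaluation.

    Default events: prune 80 % of shoots (thinning-dominated), grow
    ``spec.n_shoots`` new annual shoots, prune 80 % again.  Default scans:
    yaw up to ±3°, translation up to ±0.5 m, σ = 3 mm noise, 5 % dropout.
    """
    prune1 = dict(prune1 or {})
    growth = dict(growth or {})
    prune2 = dict(prune2 or {})
    scan = dict(scan or {})
    prune1.setdefault("target_fraction", 0.8)
    growth.setdefault("n_new", spec.n_shoots)
    prune2.setdefault("target_fraction", 0.8)
    scan.setdefault("yaw_max", 3.0)
    scan.setdefault("translation_max", 0.5)
    scan.setdefault("noise_sigma", 0.003)
    scan.setdefault("dropout", 0.05)
    rng = np.random.default_rng(seed)
    sub = [int(x) for x in rng.integers(0, 2 ** 31 - 1, size=8)]

    base_spec = replace(spec, seed=sub[0])
    tree0, truth0 = generate_tree(base_spec)
    ap_i_cloud, truth_ap_i = simulate_prune(tree0, truth0, seed=sub[1], **prune1)
    bp_cloud, truth_bp = simulate_growth(ap_i_cloud, truth_ap_i, base_spec,
                                         seed=sub[2], n_new=growth["n_new"])
    ap_next_cloud, truth_ap_next = simulate_prune(bp_cloud, truth_bp,
                                                  seed=sub[3], **prune2)
    # AS truth goes by shoot id (growth event membership): the second
    # pruning overwrote status="annual" with "pruned" on removed points.
    true_as = bp_cloud.ids[np.isin(bp_cloud.labels["shoot_id"],
                                   _annual_shoot_ids(truth_ap_i, truth_bp))]
    # PS truth: the pre-event BP state carries the prune2 marks.
    true_ps = bp_cloud.ids[bp_cloud.labels["status"] == "pruned"]

    scans = {}
    transforms = {}
    for name, c in (("ap_i", ap_i_cloud), ("bp_next", bp_cloud),
                    ("ap_next", ap_next_cloud)):
        yaw = float(rng.uniform(-scan["yaw_max"], scan["yaw_max"]))
        trans = rng.uniform(-scan["translation_max"], scan["translation_max"], 3)
        scans[name], transforms[name] = perturb_scan(
            c, yaw_deg=yaw, translation=trans,
            noise_sigma=scan["noise_sigma"], dropout=scan["dropout"],
            seed=int(rng.integers(0, 2 ** 31 - 1)))
    # evaluation frame = the BP_{i+1} *scan*: points lost to scan dropout
    # cannot be recovered by any method and are not part of the truth sets
    true_as = np.intersect1d(true_as, scans["bp_next"].ids)
    true_ps = np.intersect1d(true_ps, scans["bp_next"].ids)
    manifest = {
        "seed": seed,
        "event_seeds": sub[:4],
        "true_as_ids": np.sort(true_as).tolist(),
        "true_ps_ids": np.sort(true_ps).tolist(),
        "n_annual_shoots": int(growth["n_new"]),
    }
    return SimulatedTriple(
        ap_i=scans["ap_i"], bp_next=scans["bp_next"], ap_next=scans["ap_next"],
        truth_ap_i=truth_ap_i, truth_bp_next=truth_bp,
        truth_ap_next=truth_ap_next,
        true_as_ids=np.sort(true_as), true_ps_ids=np.sort(true_ps),
        scan_transforms=transforms, manifest=manifest,
    )


def _annual_shoot_ids(truth_before_growth: GroundTruth,
                      truth_after_growth: GroundTruth) -> np.ndarray:
    """Shoot ids added by the growth event."""
    before = set(truth_before_growth.shoots["shoot_id"])
    after = set(truth_after_growth.shoots["shoot_id"])
    return np.array(sorted(after - before), dtype=np.int64)
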