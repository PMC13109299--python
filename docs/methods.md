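# Methods

`shootdelta` quantifies orchard pruning by differencing repeat terrestrial
laser scans (TLS) of the same tree. This note describes the model behind
each stage, the parameters that matter, what the synthetic test bed does
and does not emulate, and the numerical choices made where the design was
open.

## Problem setting

A pear tree in its full bearing period is scanned at three moments of a
pruning cycle: after a dormant pruning (AP_i), before the next pruning a
season later (BP_{i+1}), and after that pruning (AP_{i+1}). Subtracting
aligned scans isolates two shoot populations:

- **Annual shoots (AS)** — points present in BP_{i+1} but absent from
  AP_i: the wood that grew during the season.
- **Pruned shoots (PS)** — points present in BP_{i+1} but absent from
  AP_{i+1}: the wood the pruner removed.

Both are subsets of the *same* BP_{i+1} cloud, so AS∩PS (annual wood that
was pruned), AS−PS (annual wood retained) and PS−AS (older wood pruned)
are computed by exact integer index arithmetic, not by spatial proximity.
This is the package's central bookkeeping guarantee and the reason every
operation preserves stable per-point ids through filtering and rigid
transforms.

## Preprocessing

Scans are cropped 0.05 m above their own minimum z (scan datum is
arbitrary; the slab removes ground clutter and basal suckers), denoised
with statistical outlier removal (k = 10 neighbors, threshold
mean + 5·SD of the mean-kNN distances), and thinned to one point per
1 mm voxel. The voxel representative is the real input point nearest the
voxel centroid — never a synthesized coordinate — so ids survive. The
voxel grid is anchored at the absolute origin, which makes the operation
idempotent; the height crop, being defined relative to the cloud's own
base, is deliberately not idempotent.

## Trunk extraction (growing pipe)

The cloud is sliced into 0.02 m horizontal layers. Starting from the
lowest occupied layer (horizontal extents x_s, y_s), layers are
accumulated as trunk while their extent stays within x_s + λ and
y_s + λ, with λ = 0.05 m of allowed widening for lean and bend (~2×
trunk radius). The first violating layer — in practice the first
scaffold bifurcation — stops the pipe. Empty layers (occlusion gaps) are
skipped rather than treated as stops. If no layer ever violates the
test, the whole cloud is trunk and the result is flagged `reached_top`.
Layer thickness and λ were fixed once at values fine enough to localize
the bifurcation within a couple of layers; both are exposed as
configuration.

## Registration

Scans of the same tree carry a rigid offset of up to a meter and a few
degrees of yaw (GPS/placement error). Direct ICP on full canopies
converges to local optima because the canopy itself changed between
scans; the trunk barely changes, so alignment is anchored there:

1. **Coarse**: translate the moving trunk's centroid onto the fixed
   trunk's centroid.
2. **Fine**: point-to-point ICP on the trunk clouds (closed-form SVD
   update, correspondences gated at 0.1 m, stop at relative RMSE change
   < 1e-6 or 50 iterations). Deterministic — no random initialization.
3. **Polish**: one more ICP pass on the *full* clouds, initialized at
   the trunk solution, with a much tighter 0.02 m correspondence gate.
   A trunk is nearly a surface of revolution, so yaw stays weakly
   observable from it alone; the unchanged canopy supplies long
   horizontal levers that lock yaw, while structure that changed between
   scans finds no matches inside the tight gate and cannot bias the
   pose. Setting `refine_full=False` restores the trunk-only behavior.
4. The composed transform is applied to the whole moving cloud and the
   pair is scored by `d` = nearest-neighbor RMSE with the smaller
   (pruned) cloud as query. Pairs with d > 0.09 m are flagged excluded
   and refuse to feed shoot extraction; the pipeline reports them rather
   than dropping them silently.

On synthetic pairs (yaw ≤ 5°, translation ≤ 1 m, 3 mm noise) the
recovered pose is within ~0.02° and ~1 mm of truth and the residual sits
at the noise floor (d ≈ 0.004 m ≤ 2σ).

## Shoot extraction and decomposition

Duplicate points between an aligned pair are those closer than 4×d to
the other scan; the residual beyond that threshold is the shoot
population. The threshold scales with the pair's own registration
quality: d is computed per pair, so the growth pair and the pruning pair
may use different absolute thresholds. The multiplier k = 4 balances
removing overlap against fragmenting shoots; a sweep utility exposes the
trade-off but nothing re-optimizes it automatically. Because the shoot's
base necessarily sits on the parent branch, the basal ~4d of every shoot
is unavoidably classified as overlap; this is the dominant recall loss
(point recall ≈ 0.91–0.92, precision ≈ 1.0 on labeled synthetic
triples).

Residual points are clustered into shoot instances with DBSCAN
(eps = 0.02 m, MinPts = 20, suited to the 1 mm voxel density). Noise
points are discarded, never reassigned. Segment numbering is
deterministic (ordered by lowest member id). Shoots that physically
touch or cross merge into one cluster — the method's known failure mode;
on unconstrained synthetic canopies this undercounts shoots by roughly a
third, while trees whose shoots keep even ~0.015 m of mutual clearance
count to within 10 %.

## Trait measurement

- **Angle** θ: elevation of the shoot's PCA-oriented bounding-box major
  axis above the horizontal, θ = arccos(AB·v/‖AB‖‖v‖) with AB oriented
  base→tip (B the higher-z end) and v its horizontal projection;
  θ ∈ [0°, 90°], exactly 90° when the horizontal projection vanishes.
  A PCA box rather than a minimal-volume box: only the axis direction
  matters, and shoots are near-straight.
- **Length**: a base-to-tip skeleton polyline, summed segment-wise. The
  reference skeleton bins points by geodesic distance from the lowest
  point on an 8-NN graph (0.02 m bins, per-bin centroids, disconnected
  graph components bridged at their closest pair); the exact root and
  tip points cap the polyline so the basal and distal half-bins are not
  lost. An optional Laplacian-contraction variant collapses the tube
  onto its axis before the same binning — same contract, smoother nodes.
  Recovery on synthetic cohorts: angle MAE ≪ 1°, length error ~1–2 %
  (straight and curved).
- **Canopy**: total shoot length L, convex-hull volume V of the full
  canopy cloud (Quickhull), and shoot length density D = L/V, which
  satisfies D·V = L to 1e-9 by construction.
- **Evaluation metrics**: R² (about the reference mean), RMSE, MAE.

## Distribution analysis and pruning patterns

Shoot angles are near-normal after a square-root transform (θ' = √θ) and
lengths after a shifted log transform (l' = log10(l + 0.1)). Normality
is screened with a one-sample Kolmogorov–Smirnov test on standardized
values against the standard normal; with parameters estimated from the
sample this classical convention is anti-conservative, which is
acceptable for a descriptive screen and documented as such. Gaussian
fits report the transformed-scale mean and SD plus the back-transformed
mean ∓ SD interval.

A segment counts as "annual" when more than half of its points carry AS
membership (and symmetrically for "pruned") — a majority rule chosen
because per-point membership is exact while segment boundaries are not.
Cohort fractions are means of per-tree fractions, not pooled totals.
Four fractions summarize a pruning pattern: the share of pruned shoots
that are annual (by count and by length) and the share of annual shoots
that were pruned (likewise).

## Synthetic orchard generator

The generator is the test bed: every stage is validated against its
labels. One tree consists of:

- a tapered, slightly leaning trunk (1 m, base radius 0.025 m, taper
  0.7, lean 1.5°) with an oval (10 %), bark-fluted (12 %, 9 lobes)
  cross-section — mature pear trunks are not smooth cylinders, and that
  irregularity is what makes trunk-anchored yaw registration observable
  at all;
- 2–4 straight scaffolds per the Y / 2+1 / 3+1 training systems
  (length 1.2 m, radius 0.015 m, elevation 45°, leaders at 80°);
- a cohort of shoots (default 30) whose angles are drawn normal on the
  √θ scale (μ = 8.67, σ = 1.2 ≈ 75° mean, resampled into (0°, 90°])
  and lengths normal on the log10(l+0.1) scale (μ = −0.33, σ = 0.25
  ≈ 0.37 m mean). Shoots emerge radially from the branch surface
  (azimuth = emergence direction ± 30°), as buds do — never running
  longitudinally along their parent. Centerlines are circular arcs
  (bow up to 5 % of length), so every ground-truth length is an exact
  closed-form arc length; the chord elevation is the ground-truth angle.
  All surfaces are sampled at 3 mm spacing.

Events: pruning removes ⌈fraction·n⌉ shoots sampled without replacement
with weight logistic(bias·(θ − 70°)) — steep shoots go first — by
thinning (80 % of removals, whole shoot) or heading-back (cut at 20–60 %
of length). An optional `annual_targeting` dial fixes the share of
removals taken from annual shoots. Growth adds new annual shoots from
the same models. Scans apply a rigid yaw/translation offset, isotropic
Gaussian noise (default σ = 3 mm), and exact-count random dropout (5 %),
and return the applied transform for oracle use. Everything is
deterministic given a seed, with a documented draw order.

What the generator does **not** emulate: view-dependent occlusion (the
dropout is uniform), leaves and buds, wind deformation between scans,
multi-station merging artifacts, intensity/color, and bark texture
beyond the low-order trunk harmonics. Passing tests therefore show the
algorithms are correct under realistic geometry and sensor noise — not
that field scans with heavy occlusion will reach the same accuracy.

With the default angle model (mean near 75°), the 90° cap truncates the
√-scale normal noticeably (the +1 SD point back-transforms past 90°), so the
generator's distributional self-test uses a model whose truncation mass
is negligible; the default model is kept for realism.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest problem sizes, stated
here as the package's own choices: registration/trunk/trait checks use
trees sampled at 5 mm spacing with 12–20 shoots (~20k points); the
differencing chain is always exercised at the native 3 mm spacing
(~40–70k points per scan) because the 4×d threshold scales with sampling
density; cohort statistics use n = 5000 draws. Other numerics: ICP
declares convergence below 1e-6 relative RMSE change or at an absolute
floor of 1e-12 m (exact overlap); DBSCAN border points between two
clusters follow scan order; circular-arc bows are capped at 0.3 of arc
length (a semicircle is the geometric maximum 1/π); degenerate hulls
(< 4 points or coplanar) report zero volume with a flag rather than
raising; zero-denominator pruning fractions are flagged undefined rather
than raising.

## Known limitations

- Touching/crossing shoots merge into one DBSCAN cluster (undercounts
  crowded canopies); no skeleton-topology splitting is attempted.
- The basal ~4d of every shoot is invisible to the differencing, which
  also truncates measured lengths of extracted (as opposed to labeled)
  shoots.
- The trunk pipe assumes the tree is upright in the sensor frame; trunk
  lean is tolerated via λ but not tracked.
- Branch diameter is out of scope, as is splitting PS−AS wood into
  branch types.
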