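# shootdelta

Multi-temporal terrestrial-laser-scan (TLS) analysis of orchard pruning:
align repeat scans of the same fruit tree, extract the shoots that grew
or were cut between scans, measure them, and quantify the pruning
pattern.

## Who this is for

Plant phenotyping and precision-orchard researchers working with
tripod-LiDAR point clouds of individual trees (pear and similar
deciduous fruit trees), and anyone developing automated pruning
strategies who needs quantitative answers to "what did the pruner
actually remove, and how does it relate to last season's growth?".

## The method

Scans of one tree at three moments of a pruning cycle — after a pruning
(AP_i), before the next (BP_{i+1}), after it (AP_{i+1}) — are aligned
pairwise by a trunk-anchored rigid registration: the trunk is isolated
by a growing-pipe layer test (accumulate 0.02 m layers upward while
their horizontal extent stays within the base extent + λ), a coarse
centroid translation plus point-to-point ICP aligns the trunks, and a
tight-gated ICP polish on the full clouds locks the pose; pairs with
nearest-neighbor RMSE d > 0.09 m are excluded.

Shoots are the points of BP_{i+1} farther than **4×d** from the other
aligned scan:

- annual shoots **AS** = BP_{i+1} \ AP_i (season's growth),
- pruned shoots **PS** = BP_{i+1} \ AP_{i+1} (what pruning removed),

with AS∩PS, AS−PS, PS−AS computed by exact point-index arithmetic on the
shared BP_{i+1} cloud. DBSCAN (eps = 0.02 m, MinPts = 20) splits the
residual into shoot instances. Per shoot, the angle is the elevation of
the oriented-bounding-box major axis, θ = arccos(AB·v/‖AB‖‖v‖) ∈ [0°, 90°],
and the length is the sum over a geodesic-bin skeleton polyline. Canopy
shoot length density is D = L/V with V the convex-hull volume. Angle
cohorts are fit Gaussian on the √θ scale, lengths on the log10(l+0.1)
scale, and the pruning pattern is summarized by the fraction of pruned
shoots that are annual (by count/length) and of annual shoots that were
pruned.

A fully labeled synthetic orchard generator (trunk + scaffolds +
arc-shaped shoots with known angles and exact arc lengths, pruning and
growth events, scan noise and mis-registration) makes every stage
testable without field data.

## Worked example

```python
import shootdelta as sd

spec = sd.TreeSpec(architecture="Y", n_shoots=20, seed=7)
triple = sd.make_triple(spec, seed=7)            # AP_i, BP_next, AP_next scans
report = sd.run_triple(triple.ap_i, triple.bp_next, triple.ap_next,
                       preprocess_inputs=False)
```

Inspecting the report prints:

```
growth pair rmse_d = 0.0029 m, pruning pair rmse_d = 0.0029 m
AS points = 25040, PS points = 22877, AS∩PS = 21104
AS segments = 13, PS segments = 13
AS angle fit: back-transformed mean = 61.8 deg (49.2-76.0)
pruned shoots that are annual: 92.31% by count, 95.81% by length
annual shoots that were pruned: 84.62% by count, 86.83% by length
```

Reading: both scan pairs aligned to ~3 mm residual (well under the
0.09 m exclusion gate), ~25k residual points were identified as annual
growth and ~23k as pruned wood, of which 21k are the same points — this
tree's pruning overwhelmingly removed the season's shoots (92 % of
pruned shoots by count, 96 % by length), while 85 % of the annual shoots
were pruned off. The angle fit is the back-transformed mean ∓ SD
interval of the √-scale Gaussian.

The same pipeline runs from the shell on PLY/PCD/xyz files:

```bash
shootdelta simulate --seed 7 --out-dir sim/        # or bring your own scans
shootdelta run --config cfg.yaml                   # preprocess→…→stats, JSON report
shootdelta align --moving BP.ply --fixed AP.ply --out BP_aligned.ply --report align.json
```

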