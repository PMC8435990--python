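# Methods

## Problem and model

A cylindrical metal specimen (gauge radius r₀, nominally 1500 µm) corrodes in
two superimposed modes: a roughly uniform radial thinning and localized pits.
The input is a binarized micro-CT stack — one boolean cross-section per axial
layer, `True` = remaining metal core, isotropic voxels (15 µm in the reference
protocol). The degradation layer around the core is assumed to carry no load
and is excluded by the binarization itself.

The analysis separates the two modes per slice: the fitted radius r₁
represents the uniformly corroded surface, and pit depth is measured from r₁,
not from r₀. Two depth fields therefore coexist:

* **total penetration** `r₀ − dist(θ)` — loss from the original surface; feeds
  the unrolled-surface heatmap and the pitting factor;
* **pit depth** `d(θ) = max(0, r₁ − dist(θ))` — loss below the uniformly
  corroded surface; feeds all pit statistics.

The method is radial: each of 180 rays (2° apart) sees only the outermost
metal crossing. Re-entrant (undercutting) pit morphologies are invisible by
construction — an inherent property of radial profilometry, not a bug.

## Processing chain and key parameters

| parameter | default | meaning |
|---|---|---|
| `r0_um` | 1500 | initial gauge radius; the fixed reference for penetration |
| `voxel_size_um` | 15 | isotropic voxel edge; also the slice thickness and the radius-reduction step |
| `angular_step_deg` | 2 | circumferential sampling; 180 bins, bin k along 2k° from +x |
| `material_ratio` | 0.20 | fraction of directions that must intersect metal at r₁ |
| `on_threshold_um` | 0 | pit mask: depth strictly greater than this marks a pit cell |
| `min_pit_depth_um` | 50 | 3D severity filter, strict `>`; applied after bonding |
| `min_overlap` | 1 | shared angle indices required to bond segments in adjacent layers |
| `center_slices` | 1 | end slices averaged for the axis fit |
| `rho_mg` | 1.84 g/cm³ | alloy density (WE43); used in mass/rate conversions |
| `rho_h2_g_per_l` | 0.0823 | H₂ density at 25 °C/1 atm; `hydrogen_density_ideal_gas` gives other conditions |

The material-ratio criterion, the 2° step, r₀, and the 50 µm filter follow
the reference protocol; the pit statistics are sensitive to these values, so
every run logs the configuration actually used.

**Axis correction.** Only the first and last slices anchor the axis; centres
are interpolated with step `s = (x₂−x₁)/(n−1)` so the line passes through
both fitted endpoints (a divisor of n would stop the interpolant one step
short of the far centre, defeating the correction's purpose). The per-slice
centre is the centre of the *minimum enclosing circle* of the outer contour —
governed by the intact rim and hence robust to inward pits, where a centroid
would drift toward the remaining material. The enclosing circle is computed
with Welzl's algorithm (deterministic fixed-seed shuffle over convex-hull
vertices). Vertical axis lines (x₁ = x₂) fall back to direct interpolation
of y.

**Fitted radius.** Starting from the greatest centre-to-contour distance, the
candidate radius decreases in one-voxel steps until ≥ 20 % of the 180
directions still reach it; the per-direction material test uses the same 2°
ray discretisation as the depth sampling (the continuous-circumference
alternative differs only below the step size). r₁ is therefore quantized to
one voxel — visible as a ~0.5-voxel downward bias of r₁ and correspondingly
small upward bias of R̄L, well inside the stated voxel-level tolerances.

**Depth sampling.** Rays are marched outward on the bilinearly interpolated
mask at 0.25-voxel radial steps, taking the outermost 0.5-crossing with
linear refinement. The binary mask is first smoothed with a small Gaussian
(σ = 0.8 voxel): the raw indicator's 0.5 iso-level zigzags ±0.4 voxel around
a smooth surface (marching-squares staircase), while the smoothed level set
localizes it to ~±0.35 voxel worst-case with a negligible curvature bias
(~σ²/2r ≈ 0.005 voxel at these radii). This residual is the information
floor of binarized data; sub-voxel precision matters because the 50 µm
severity filter is only ~3 voxels. A ray that meets no metal at all is
assigned full depth r₁ and flagged in the report. Only the largest connected
component of a slice is profiled; detached fragments count toward volume
loss only.

**Pit tracking.** Pit cells form maximal circular runs per slice (wrapping
across the 358°→0° seam — without the wrap a pit crossing the seam would be
split in two). Runs in adjacent layers sharing ≥ `min_overlap` angle indices
bond into one 3D pit; bonding is transitive, so a pit that splits and rejoins
(or two pits that coalesce) is a single object, matching how small pits merge
into larger ones over time. Deepest-point ties break deterministically to the
lowest layer, then lowest angle index.

**Pit geometry.** Each (layer, angle) cell spans an arc element
`Δθ·r₁(layer)` by one slice thickness. Opening area sums arc elements at r₁;
volume sums `depth × arc` with the arc taken at the mid-depth radius
`r₁ − depth/2`, a second-order correction for the inward taper of a wedge
(`mid_depth_arc=False` selects the plain rectangle rule at r₁).

**Parameter record.** The pitting factor uses total penetration from r₀
(the pitting-factor definition references the original metal surface),
averaged over all 180·n samples — not only pitted ones; the all-sample choice
makes PF = 1 exact for uniform corrosion. On a pristine surface the average
penetration is below half a voxel and PF is reported as NaN with a warning
rather than an error. d_min pairs each ray with the ray 90 index positions
(180°) across, i.e. the width through the corrected centre — the dotted-line
construction of the protocol — not the true minimal chord. VL counts core
voxels against the analytic initial cylinder π·r₀²·L; ML normalizes the
hydrogen-derived mass to the initial gauge mass ρ·π·r₀²·L. d̄₁₀ averages all
pits when fewer than ten exist. All standard deviations use the n−1
denominator. Mass loss (ML) and corrosion rate need immersion measurements
(hydrogen volume, exposed area, time); they are NaN when those are not
supplied.

**Regression.** The exponential model is fitted by nonlinear least squares in
original space (initialized from the log-linear fit, or from a flat curve
when responses are non-positive), so its R² is computed on the same scale as
the linear model's and the two are comparable; a pure log-space fit would
down-weight large responses. The linear fit reports the slope's F-test
p-value; no further inference machinery is provided. Constant predictors or
responses are rejected per fit and flagged (not fatal) in the cohort report.

## The phantom generator

`pitscan.phantom` emulates exactly the geometry the chain assumes: a
voxelized cylinder (centre-of-voxel inclusion, anti-aliasing deliberately
off so the input matches binarized segmentation output), optional linear
axis tilt (pure per-slice translation, carved in the local frame so tilt and
pitting commute), uniform radial loss, and pits as radial indentation
profiles in the unrolled (arc, axial) surface frame — spherical-cap profiles
(opening half-width ≥ depth so the rim is continuous) or half-ellipsoids.
Overlapping indentations carve as their pointwise maximum (union of carved
regions) and are marked as one merged group in the truth record.

Truth values are exact for this geometry: per-pit volume has the closed form
`V_planar − ∫f²dA/(2r)` (planar cap/half-ellipsoid volume minus the
cylindrical-taper correction), the deepest point is the prescribed apex, and
the remaining volume is the analytic cylinder minus carved volumes.

The battery (`make_suite`) covers pristine, uniform-only, single-pit, three
disjoint pits, a seam-crossing pit, a single sub-50 µm pit and a coalescing
pair, each also tilted by (2, 1) voxels; the seed jitters the single-pit
azimuth. Suite phantoms are 60 slices (900 µm) — long enough for every pit
plus margins — keeping the full battery under ~10 s. Ellipsoidal pits use a
90 µm axial half-length so that even the shallowest pit's depth falls by at
least half a voxel within two layers of its apex; flatter pits leave the
deepest *layer* fundamentally unresolvable in 15 µm binarized data (the broad
spherical cap in the battery is flat to < 2 µm over ±5 layers, so its
deepest-point check is location-within-flat-bottom rather than ±1 layer).

What the phantoms do **not** emulate, and hence what passing tests do not
show: grayscale CT artifacts (beam hardening, rings, noise — inputs here are
perfectly binarized), real pit morphology (undercuts, intergranular paths,
rough surfaces), corrosion kinetics, and segmentation error from the manual
thresholding step. Recovery tolerances achieved on phantoms are therefore a
lower bound on real-data error.

## Degenerate inputs and numerical conventions

* Slices are ordered by ascending natural filename sort; layer 0 is the first
  image. Stacks with at most two distinct values load as binary (metal = the
  maximal value); anything else is grayscale and needs an explicit threshold
  (the core/degradation contrast is scan-specific; no automatic rule is
  assumed, and out-of-range thresholds simply yield all-true/all-false).
* Gaussian preprocessing of grayscale stacks is 2D per cross-section
  (σ = 2 px default). Pure thresholding (σ = 0) is exactly idempotent on
  binary input; with smoothing, repeated application only erodes a one-pixel
  boundary band (corner rounding).
* Empty slices raise a detection error; a slice whose material ratio is never
  reached before the radius hits zero raises a degenerate-slice error; slices
  with > 90 % radius loss produce warnings, not failures.
* `analyze` is fully deterministic — no randomness anywhere in the chain —
  and removes partial outputs when a stage fails, naming the stage.
* In-plane points are (x, y) = (column, row); angle bin k points along 2k°
  from the +x axis toward +y. Heatmap rows are layers (ascending), columns
  angle bins.

## Known limitations

* Radial ray casting cannot see undercut pit walls or measure pit shape
  classes; pits narrower than the 2° arc (~50 µm at full radius) may be
  sampled by no ray.
* All sub-voxel localisation is bounded by the binarization: ±0.35 voxel
  (~5 µm at 15 µm voxels) worst case. Quantities built on extremes of the
  depth field (PF, d_max, d_min) inherit this as a small positive/negative
  bias; on a uniform-corrosion phantom the measured PF is ≈ 1.05 rather than
  exactly 1.
* The axis model is a straight line through two anchor slices; bent specimens
  violate it by construction.
* The fitted radius assumes a roughly convex, roughly circular cross-section;
  square bars or heavily fragmented cores are out of scope.
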