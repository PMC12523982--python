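# Methods

This note records the measurement model, the conventions every number in the
output tables follows, the numerical choices that differ from the most obvious
implementation (and why), and the known limits of the synthetic generator.

## 1. Measurement model

A quantitative phase image stores, per pixel, the optical path difference

    OPD(x, y) = Δn · t(x, y)        [µm]

where `t` is the physical thickness of cellular material along the optical
axis and `Δn = n_object − n_medium` is the refractive-index contrast. With
the default optics (`OpticsConfig`):

| parameter   | symbol | default | units  |
|-------------|--------|---------|--------|
| wavelength  | λ      | 0.640   | µm     |
| pixel size  | p      | 0.5     | µm     |
| medium RI   | n_m    | 1.337   | —      |
| object RI   | n_o    | 1.377   | —      |
| refractive increment | α | 0.18 | µm³/pg |

Derived per-object quantities (module `morphometry`, one `CellRecord` per
gated object):

- **area** `A = N · p²` (µm²), N = pixel count of the labelled object.
- **dry mass** `m = Σ OPD · p² / α` (pg) over the object's pixels. Because the
  sum is linear in OPD, mass is exactly additive over objects and invariant
  to segmentation errors that only move *zero-OPD* pixels.
- **optical thickness** — mean and max of `OPD / Δn` (µm) over the object.
- **sphericity** ψ = `2π r_eq² / S` with `r_eq = (3V / 2π)^(1/3)`: the ratio
  of the surface area of the *equal-volume hemisphere* to the measured upper
  surface area `S = Σ √(1 + |∇t|²) · p²`. A hemisphere scores exactly 1;
  flatter objects score lower; the scale is dimensionless and size-free.
- **length/width ratio** — major/minor axis lengths of the equivalent
  ellipse (second image moments), always ≥ 1.
- **fluorescence mean** — mean of a co-registered fluorescence channel over
  the object's pixels after zeroing pixels at or below the background
  threshold (default 50 AU).

Gating: objects with area strictly greater than 400 µm² are cells, the rest
is debris (`apply_size_gate`, `strict=True` by default). The
`GateSummary.debris_percent` is `100 · n_debris / n_total`. Populations can
be split at sphericity 0.25 (`split_by_sphericity`) into spread versus
rounded cells.

### Sensitivity to Δn

Dry mass does not depend on Δn (it is computed from OPD and α directly), but
*thickness* — and through it sphericity — scales as 1/Δn. A relative error δ
in Δn scales all thicknesses by 1/(1+δ); for flat objects (|∇t| ≪ 1) the
measured surface `S ≈ A + ½Σ|∇t|²p²` is dominated by the footprint, so
ψ ∝ V^(2/3) changes by roughly −(2/3)δ. The default Δn = 0.04 is a typical cytoplasmic
contrast; analyses comparing sphericities across
conditions are robust to a wrong Δn (common factor), absolute values are not.

## 2. Segmentation

`segment(image)`:

1. **Threshold on the raw OPD** using the triangle method, not Otsu, and not
   on a smoothed copy. On sparse dark-background phase images Otsu places the
   cut mid-bump and erodes object rims (in validation it shrank hemisphere
   footprints ~20% and biased flat-cap sphericity from 0.24 to 0.34);
   thresholding a Gaussian-smoothed image instead *grows* halos (+50% area).
   The triangle threshold on the raw image recovered phantom areas, masses
   (≤ 0.04% error) and sphericities within tolerance across all phantom
   shapes, so it is the default; an explicit `threshold=` overrides it.
2. Fill holes, drop fragments below 4 px (unreliable-metric threshold).
3. **Watershed split** of touching cells: markers are local maxima of the
   Gaussian-smoothed OPD (σ = `smoothing_scale` µm, default 2) separated by at
   least `min_seed_separation` (default 10 µm); the watershed runs on the
   negated smoothed image, constrained to the binary mask. Components that
   received no marker are rescued as single objects.

Objects touching the frame are measured but flagged `touches_border`;
objects under 4 px are flagged `unreliable`.

## 3. Tube networks

`make_tube_mask` binarises (same triangle-on-raw rule), fills holes below
200 µm² and drops regions below 400 µm². `skeletonize_and_graph`:

- skeletonise (scikit-image), classify skeleton pixels by 8-neighbour count
  (1 → endpoint, ≥ 3 → junction pixel);
- merge 8-connected junction-pixel clusters, then merge junction nodes closer
  than `junction_merge_radius` (default 5 µm) — a wide crossing thins into
  two nearby Y-points that are one biological junction;
- trace maximal degree-2 chains into edges; a closed chain with no node
  becomes a single self-contained loop segment (`u = v = None`);
- iteratively prune spur edges shorter than `prune_length` (default 15 µm),
  dissolving any junction that drops to degree 2 by merging its two edges;
- **edge length** is the Euclidean length of the chain resampled with chords
  every 8 pixels. Counting 8-connected steps (1 or √2 per step) systematically
  *overestimates* length of straight lines at intermediate angles by up to
  8% (chamfer bias), which broke a 3% accuracy requirement on Y-phantoms;
  8-pixel chords keep the error ≤ 0.6% on straight runs and ≈ 1–2% on curved
  phantom networks while following genuine curvature.

`network_metrics` reports segment/junction/extremity/branch counts (a branch
is an edge with at least one extremity endpoint), total and median segment
length. `flag_boundary_branches` marks — never deletes — edges entering a
margin band (default 2 px) at the frame edge, because a clipped tube's
skeleton endpoint retracts about half a tube-width from the frame and is
not a true extremity. `normalize_timecourse` expresses every metric as % of
the baseline frame (default 1 h); a zero baseline yields NaN, not ∞.

## 4. Pharmacology

The three-parameter logistic (Hill slope fixed at 1), X in log₁₀ molar:

    Y = Bottom + (Top − Bottom) / (10^(LogEC50 − X) + 1)

`fit_3pl` parameterises as (bottom, span ≥ 0, LogEC50) so Top ≥ Bottom by
construction, runs `scipy.optimize.least_squares` from data-driven initials
with up to five LogEC50 jitters (0, ±1, ±0.5), and reports standard errors
from the Jacobian (`cov = (JᵀJ)⁻¹ · rss/dof`; `se(top)` includes the
bottom–span covariance). Flat data is declared non-converged with infinite
`se(log_ec50)` rather than returning an arbitrary midpoint. At least 3
distinct concentrations are required. `derive_potency_table` aggregates
per-experiment fits into mean ± SEM of pEC50 (= −LogEC50) and span; a single
experiment yields NaN SEMs and a `single_experiment` flag.
`normalize_to_vehicle` rescales responses so the vehicle mean is 100%.

## 5. Phantom generator: scope and exactness

Cell phantoms are solids of three models over an elliptical footprint with
semi-axes (a, b) and apex height h:

- `spherical_cap` (a = b): cap of the sphere of radius `(a² + h²) / 2h`;
- `ellipsoidal_cap`: upper half-ellipsoid, `t = h·√(1 − ρ²)`;
- `gaussian_bump`: `t = h·exp(−(3ρ)²/2)` truncated at 3σ (ρ = elliptical
  radius ∈ [0, 1]).

Truth values are analytic: closed forms for volumes; cap sphericity in the
scale-free form `ψ(k) = 2·(k(3+k²)/4)^(2/3) / (1+k²)`, k = h/a, inverted by
Brent's method for "render at sphericity ψ" requests; other surfaces by
Gauss–Legendre quadrature with a ρ = sin φ substitution that removes the rim
singularity of `√(1+t′²)` (verified to 1.4·10⁻⁵ against the hemisphere).
When `dry_mass` is given, the rendered OPD raster is rescaled so the
*discrete* pixel sum equals the target exactly — and the truth record is
computed on the correspondingly height-scaled solid, since the rescale
changes the shape. Fields place objects by seeded rejection sampling with a
minimum gap; placement failure raises with the achieved density rather than
silently overlapping. Network phantoms paint constant-OPD capsules along
seed-graph edges; the seed graph supplies exact counts and polyline lengths.
Dose–response tables evaluate the logistic directly with optional Gaussian
noise; timelapse phantoms drift length/width ratio and height/radius ratio
linearly at constant footprint area, so frame truths follow in closed form.

### Known limits

- **Surface underestimation at near-vertical rims.** The measured surface
  `Σ √(1+|∇t|²) p²` uses finite-difference gradients; where the true profile
  approaches vertical (a full hemisphere's rim) the discrete gradient is
  finite and the rim band's area is undercounted. At 0.5 µm/px and radius
  15 µm the hemisphere still measures ψ = 1.000 because the volume term is
  similarly discretised, but very steep *and small* objects (radius ≲ 8 px)
  lose accuracy; keep phantoms above ~10 px radius for 2% shape accuracy.
- Phantoms are ideal: no shot noise, no background tilt, no halo artefacts,
  no partially-overlapping cells (fields enforce a gap). The segmentation
  defaults are therefore tuned to faithful images; noisy real data may need
  an explicit threshold or different smoothing.
- Mixed-height populations share one global threshold, so very flat cells
  next to very tall ones lose a thin rim (sphericity biased up by a few
  percent). Per-object thresholds are out of scope.
- The 3-parameter logistic fixes the Hill slope at 1; data with genuinely
  steeper slopes will show lack-of-fit rather than a slope estimate.
- Skeleton-based lengths are accurate to ~2–3% on 12 µm-wide tubes; below
  ~6 px tube width, skeletonisation itself becomes unstable.

## 6. Determinism

All stochastic code takes explicit integer seeds (`numpy` Generators); the
pipeline writes CSVs with a fixed float format (`%.10g`), so repeated runs
with the same configuration and seeds are byte-identical, and each run writes
a manifest with SHA-256 hashes of its outputs.
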