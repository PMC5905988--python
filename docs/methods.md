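# Methods

This note documents the measurement model, the tunable parameters and their
defaults, the synthetic data the package validates itself on, and the
numerical and design choices made where the method left room.

## Pipeline

1. **Centerlines.** The binary vessel mask is thinned with 8-connected
   morphological thinning (Zhang–Suen family). Bifurcation and crossover
   pixels — any skeleton pixel with ≥ 3 true 8-neighbors — are removed in a
   single pass, leaving components that are simple paths or closed loops.
   Loops and isolated pixels are discarded (loops with a warning; vessels are
   endpoint-bounded). Terminal segments shorter than 10 pixels (strict) are
   pruned as thinning spurs; "length" is the point count of the 8-connected
   path, which differs from Euclidean arclength by at most a factor √2.
   Coordinates are 0-based (row, col) with pixel centers on the integer grid.

2. **Segment smoothing.** Each segment is approximated by a planar
   least-squares cubic spline under centripetal parametrization (parameter
   increments proportional to the square root of chord length). The number
   of polynomial pieces is the segment point count divided by 20 px, rounded
   half-up with a floor of 1; interior knots sit at parameter quantiles,
   which keeps the Schoenberg–Whitney conditions satisfied on ordered path
   data. Exact duplicate consecutive points are dropped first. Endpoints are
   treated like all other points (pure least squares, no clamping). The unit
   tangent comes from the spline derivative at each original point's
   parameter; the normal is the tangent rotated +90°. Profiles are sampled
   symmetrically about the centerline, so the normal's sign convention has no
   effect on any measurement.

3. **Profiles.** Intensity profiles are sampled on the green channel
   (normalized to [0, 1] by the image bit depth) along the normals, 1 px
   spacing, bilinear interpolation, symmetric about the centerline point.
   The initial half-length is `ceil(1.5 × max distance-transform value)` of
   the mask — 1.5 times the largest inscribed vessel radius — so the widest
   vessel is always covered. Samples falling outside the image take the
   nearest-edge value and are flagged; profiles with more than 25 % flagged
   samples are excluded from length statistics.

4. **Vessel extent.** For each centerline point, the mean of the 11
   neighboring profiles (5 per side, truncated at segment ends) is smoothed
   with a Savitzky–Golay filter (order 2; window = smallest odd integer
   ≥ max(5, profile length / 4)) and its interior extrema are located, with
   plateaus reported at their midpoints. A CLR region — central maximum, two
   flanking minima, two limiting maxima — is searched first, under validity
   rules (below). If none containing the profile center passes, a plain
   region (central minimum with adjacent maxima) is searched, with mirroring
   of a missing or too-close side and iterative outward search when both
   limits crowd the center. If both searches fail the full profile stands in
   (overestimation only widens the fitting window; underestimation would
   discard vessel signal). The extent is
   `prof_length = 2 × mean(|x_maxL − x_c|, |x_maxR − x_c|)` with `x_c` the
   CLR peak (CLR branch) or the central minimum (plain branch). The
   per-segment length is the median over the segment's profiles (even
   counts: mean of the middle two); profiles are then cut symmetrically to
   that length and the straightened segment is smoothed with an anisotropic
   Gaussian, σ = 0.1 × prof_length across the profile and 1.5 × prof_length
   along the vessel (reflection at borders), so wider vessels are smoothed
   more.

5. **Model fitting.** One of three profile models (Hermite, DoG-L7, DoG-L8;
   see README) is fitted per centerline point to the pooled points of the 11
   neighboring smoothed profiles by bounded Trust-Region-Reflective least
   squares (the 2D model surface is independent of the along-vessel
   coordinate, so pooling into one plane is equivalent to fitting the
   extruded surface). Solver failures are reported (`converged=False`), not
   raised.

6. **Width regression and evaluation.** A random forest (bagged regression
   trees with random predictor selection at each split) learns the mapping
   from the N best-fit parameters to the annotated diameter. Annotated and
   detected center points are matched greedily in ascending distance, each
   point used at most once, pairs accepted only below 5 px (strict).
   Precision is `sigma_error`, the n−1-normalized standard deviation of the
   per-profile errors χᵢ = ωᵢ − ψᵢ; the success rate is the percentage of
   annotated profiles measured. Validation is 10-fold cross-validation at
   profile level (seeded shuffle) or leave-one-segment-out; segment
   similarity is summarized by pairwise correlations of segment mean
   profiles, aligned at their maxima and normalized by the larger
   autocorrelation over the aligned overlap, so an exact integer shift
   scores 1.

## Tunable parameters

All of the following live in `PipelineConfig` / `ClrRuleConfig` /
`RegressorConfig` and a single YAML file; a run is reproducible from its
config and one seed.

| parameter | default | meaning |
|---|---|---|
| `min_minima_separation` | 3 px | CLR minima closer than this are a false reflex |
| `max_bump_depth_ratio` | 0.5 | max relative difference of the two CLR bump depths (depth = limit max − adjacent min) |
| `max_limit_distance_difference` | 0.5 | max relative difference of the two center-to-limit distances |
| `max_limit_distance` | 0.8 × initial half-length | limits farther out are rejected (one-sided failure → mirror the valid side) |
| `center_value_tolerance` | 0.1 × dynamic range | CLR-center override: "close in value to the lowest maximum" |
| `max_center_offset_fraction` | 0.25 × profile length | CLR-center override: "not too far from the center" |
| `min_limit_center_distance` | 1.5 px | plain-branch limits closer than this are "too close" |
| `neighbors_per_side` | 5 | profiles pooled per side for means and 2D fits |
| `sigma_across/along_factor` | 0.1 / 1.5 | anisotropic smoothing spreads as fractions of prof_length |
| `match_max_dist` | 5 px | ground-truth association radius (strict) |
| `n_trees`, `predictors_per_split`, `min_leaf` | 100, round(N/3), 5 | forest hyperparameters, seeded |

The extent-rule thresholds are engineering defaults chosen once from the
geometry they guard (e.g. a reflex narrower than 3 px is unresolvable at
1 px sampling); none is derived from annotated data.

**Fit bounds and initialization** are data-driven per profile: background
`t ∈ [0, 2·max]` starting at the outermost sample; main depth
`h1 ∈ [−2·range, 0]` starting at −range; center within ±length/4 of the
profile center, starting at the profile minimum; spreads in
[0.5, length/2] starting at length/6 (main) and length/12 (CLR); line slope
in ±0.1 starting at 0; `mu2` within ±length/8. Because a profile whose
reflex displaces the minimum off-center puts the single default start in the
wrong basin, the fitter tries a small fixed set of data-driven starts (dip
centroid; CLR-peak starts at the interior local maximum nearest the center
with several depth/spread combinations; a wide-dip variant) and keeps the
lowest final cost. Tolerances are 1e-10 (function, step and gradient) with
at most 400 iterations' worth of evaluations per start.

**Gaussian convention.** The models are defined with
`exp(-((x-mu)/(2 sigma))^2)`, which differs from the standard
`exp(-(x-mu)^2/(2 sigma^2))` by √2 in the effective spread. Both
parameterizations span the same curve family (only `sigma` rescales), so
fitted curves and widths are unchanged; `gaussian_convention: standard`
switches the convention for sensitivity checks.

## Synthetic data

`synthetic.render_vessel_image` draws tubes of constant diameter D along a
line, sine or circular arc. The green-channel intensity at distance d from
the centerline is `background − contrast·g1(d) + clr_depth·g2(d)` with

* `g1(d) = exp(-(d/(2 σv))²) − 0.35·exp(-((|d|−D/2)/(2·1.0))²)`, σv = D/6:
  a Gaussian dip with a bright rim at the tube boundary,
* `g2(d) = exp(-(d/(2 σc))²)`, σc = 0.4·D/4: the CLR ridge.

The rim emulates the vessel-wall brightness transition that gives real
profiles their limiting maxima; a bare Gaussian dip on a constant background
has no flanking peaks, and every profile would fall back to its full length.
Its amplitude (0.35 × contrast) and spread (1 px) were set so the rim
survives the Savitzky–Golay smoothing of step 4 without its peak drifting
outward on the dip's slope — with a weaker or narrower rim the detected
extent of wide vessels biases several pixels high. The CLR ridge defaults
(width fraction 0.4, depth 0.6 × contrast when present) place the reflex
minima ≳ 0.36·D apart, which is resolvable for D ≥ 13 px — consistent with
CLR being a feature of larger arterioles; the study generator therefore adds
CLR only to vessels of at least 13 px. Noise is additive Gaussian on the
[0, 1] intensity scale (the default sd 0.02 matches the end-to-end study
conditions); red/blue channels are scaled copies of green. The mask is the
exact tube (d ≤ D/2) and ground-truth edge points sit at ±D/2 along the
normals at ~1 px arclength spacing, so the annotated width is exactly D.

The study population (`make_validation_specs`) is 32 vessels, diameters
uniform on [4, 20] px, mixed line/sine/arc geometry, noise sd 0.02, a quarter
of the wide vessels carrying a CLR. One 160×160 image is rendered per vessel
and every third centerline point is fitted (~1400 measured profiles).

**What passing on this data does and does not show.** The generator covers
curved dark vessels with and without reflex, subpixel edge geometry, and
per-pixel noise; it does not emulate uneven illumination, the optic disc or
lesions, vessel branching, contrast that varies along a vessel, or observer
disagreement in the annotations (the ground truth here is geometric and
exact, so cross-validated `sigma_error` on synthetic data is substantially
smaller than on observer-annotated photographs; on this generator's output
the 10-fold CV run yields `sigma_error` ≈ 0.12–0.15 px). Relative statements
— LOSO being less precise than CV, flexibility ordering of the three models,
branch selection accuracy — are the transferable results.

## Numerical choices and degenerate inputs

* Rounding at .5 ties (spline pieces, profile cutting) is half-up, to avoid
  the platform's round-half-even surprises.
* Plateau extrema report their midpoint; the plateau's own value is read at
  the floor index.
* The extent fallback returns length `n − 1` (first-to-last sample span),
  which is exactly the two-limits-at-the-ends value of the extent formula.
* A flat profile (zero dynamic range) cannot be fitted (bounds degenerate)
  and raises; the pipeline logs and skips such points.
* The CLR elevation rule compares the CLR peak against the *lower* of the
  two limiting maxima.
* In greedy center matching, ties are resolved globally by ascending
  distance with stable ordering, making the matching deterministic.
* LOSO groups by (dataset, segment); k-fold shuffles at profile level with
  the run seed, so consecutive (correlated) profiles can land in different
  folds — exactly the optimism LOSO is there to expose.

## Known limitations

* The extent rules assume at most one neighboring vessel per side; dense
  parallel vasculature can still fool the CLR override.
* Widths below ~4 px leave the reflex and rim structure unresolved at 1 px
  sampling; the regressor then leans on the spread parameters alone.
* The regression trees cannot extrapolate: widths outside the training range
  are clipped toward it, which shows up in LOSO on the extreme-diameter
  segments.
* Skeleton erosion at segment tips means the first/last few annotated points
  of a segment are never measured; crossings are deliberately unmeasured
  (junction removal), lowering the success rate in crowded frames.
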