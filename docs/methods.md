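# Methods

This note records the models, conventions and numerical choices behind
trilomorph, and what the synthetic data do and do not establish.

## Scope and model of the data

The package models the measurement chain of an optical surface roughness
meter (OSRM) applied to small fossil surfaces: the instrument scans a
5 × 5 mm window at 1500 lines per axis with ~1.5 µm vertical accuracy and
emits a text point cloud in scan-window (relative) coordinates. Everything
downstream — absolute-coordinate conversion, gridding to a digital elevation
model (DEM), profile extraction, landmarking, shape statistics — is
reimplemented here with open conventions, since the original chain ran
through closed instrument software and a commercial GIS.

Units are mm throughout (cell sizes, elevations, centroid sizes); shape
quantities (Procrustes distances, tangent coordinates) are dimensionless
because configurations are scaled to unit centroid size.

## Gridding and profiles

- `grid_point_cloud` grids onto cell centers over the cloud's bounding box.
  Default cell size 5/1500 mm emulates the instrument raster. Default method
  is Delaunay-based linear interpolation (TIN); `nearest` and `idw` (power
  2, 8 neighbours) are alternatives. Cells outside the convex hull stay
  nodata — the package never invents relief beyond the scanned area.
  Collinear clouds are rejected for TIN rather than silently degraded.
- DEM interchange is the ESRI ASCII grid: a six-key text header plus row
  data, top row first on disk; in memory row 0 is the *bottom* row (y up).
  Nodata sentinel −9999 on disk, NaN in memory.
- `extract_profile` samples a straight line at n equally spaced positions
  (default 1500, one per instrument line) by bilinear interpolation on the
  4 surrounding cell centers. Samples touching nodata are dropped, not
  imputed. Within the outer half-cell band coordinates are clamped to the
  center lattice (the interpolant degenerates to the edge value there).
- The sagittal line defaults to the window's vertical midline; the
  exsagittal line is parallel, offset by 15 % of the window width (the
  offset used in the original design is unrecorded; this is a configurable
  default, not a claim).
- Relief is per-profile max − min elevation; population summaries use
  linear-interpolation (Tukey inclusive) quartiles.

## Landmark detection and sharpness

Profiles are landmarked automatically so the pipeline is reproducible;
manually digitized TPS files override detection wherever supplied, because
expert placement remains the reference practice in this field.

The rule: smooth with a centered moving average (window = 2 % of samples);
take the 4 most prominent local maxima (scipy `find_peaks` prominence) as
lobes L4..L1; take the deepest point between consecutive lobes as a furrow
provided it sits at least `min_prominence` below both flanking crests.
Default `min_prominence` is 3 µm = 2× instrument accuracy, so measurement
noise cannot create a furrow. Alternation and strictly increasing positions
hold by construction. Anything failing the rule raises
`InsufficientReliefError` carrying the counts found — this is the "effaced
furrow" preservation state, a result in its own right, not a crash.

Sharpness: a quadratic is fit over ±half_window (default 5 % of profile
length) at each landmark; the proxy is its second derivative (1/mm),
negative at crests, positive in furrows. The sharp/rounded threshold
defaults to the median |curvature| of the landmarks being scored —
data-adaptive because no quantitative boundary between the two published
preservation styles exists — and is echoed in the report so users can fix
it explicitly. The landmark u-coordinate is horizontal distance along the
profile line, not arc length.

## Procrustes conventions

- Full Procrustes fit = GPA: center, scale to unit centroid size, rotate by
  the SVD of the cross-covariance with det +1 enforced (no reflections:
  profiles have a fixed anatomical orientation), iterate align → re-average
  → rescale until the consensus moves < 1e-10 (Frobenius), max 1000
  iterations (high-dispersion batches converge only linearly; typical
  biological dispersions converge in < 5). The first configuration seeds
  the consensus; afterwards the consensus is rotated to its principal axes
  (half-turn sign fixed) so results do not depend on how the input batch
  happened to be oriented.
- Distances are partial Procrustes distances (root summed squares between
  unit-size optimally rotated configurations), the convention of mainstream
  morphometrics software.
- Tangent coordinates: orthogonal projection at the consensus,
  `t = x − (x·m)m`. Centering, unit scale and optimal rotation make exactly
  4 directions vanish, so rank ≤ 2k − 4 = 10 holds to machine precision.

## Statistics

- PCA is an eigendecomposition of the tangent covariance matrix (ddof 1);
  components below 1e-12 × λ₁ are dropped and percentages are over the
  retained spectrum.
- Goodall's F is computed with Euclidean norms on aligned Procrustes
  coordinates — the standard linearized partition. This choice makes the
  two-group multi-sample ANOVA *identical* to the pairwise test (an exact
  algebraic identity used as a test oracle); with the small dispersions of
  real landmark data it agrees with the curved-space version to high order.
  df: (g−1)(2k−4) over (n−g)(2k−4); parametric p from the F distribution,
  and a resampled p from random reassignment of specimens to groups. The
  published description calls this a bootstrap but describes label
  randomization; permutation is implemented as primary, bootstrap over the
  pooled sample as an option.
- p-values use the add-one convention p = (1 + #{T* ≥ T}) / (1 + N), never
  exactly zero at finite N. A statistic that ignores labels yields p = 1
  with a degenerate-null flag.
- CVA: tangent data are projected onto PCs with eigenvalue > 1e-12 × λ₁,
  capped at n − g dimensions so the pooled within-group covariance is
  invertible (groups smaller than 3 force an extra rank cut, with a
  warning). Canonical axes solve the whitened between-group eigenproblem;
  at most g − 1 axes. Pairwise Mahalanobis distances use the pooled
  within-group covariance *of that pair* — the same quantity the
  permutation null recomputes, keeping observed statistic and null
  distribution consistent. Procrustes distances between group mean shapes
  are permuted the same way. Default 10 000 rounds.
- Pairwise Goodall tests are reported unadjusted (matching the published
  tables' practice); a clearly labeled Bonferroni column is also emitted.

## Synthetic data: what it emulates, what it does not

`simulate_glabella_dem` builds an axial elevation function: a flat-topped
super-Gaussian dome (height ~0.35 mm, half-width 0.75 × glabellar length)
carrying four Gaussian lobe bumps and three Gaussian furrow grooves, times a
cross-axis envelope, plus white Gaussian noise at 1.5 µm. Two deliberate
geometric choices:

- the dome is flat-topped so its slope does not compete with the grooves for
  the interior extrema (a plain Gaussian dome's flanks can erase the outer
  lobe crests);
- lobe bumps are wider than half their spacing (default σ = 0.6 × L/4), so
  adjacent lobes merge into a smooth crest unless a furrow groove separates
  them. Effacing a furrow (depth 0) therefore genuinely removes the
  corresponding extrema — as in the fossils — rather than leaving a residual
  dip between free-standing bumps.

Ground truth is the set of extrema of the noise-free axial function located
on a fine grid and returned alongside the DEM.

`simulate_study` emits the study design: three populations of sizes
19 (China), 18 (Siberia), 16 (USA); glabellar length uniform on 1.5–5 mm
with all vertical scales proportional to length; regimes — USA deep furrows
(0.045–0.07 × L/3) with wide ("rounded") features; Siberia shallow furrows
(0.025–0.04) with narrow ("sharp") features, a 25 % chance of TF3/TF2 being
fully effaced, and a narrow relief factor (N(0.80, 0.04)); China an even
mixture of both styles with the widest relief spread (N(1.25, 0.20)). These
depths and factors are the generator's definition of the qualitative
published contrasts (deep/rounded vs shallow/sharp/effaced vs mixed; Siberia
narrowest relief range) — chosen once as plausible magnitudes, since no
quantitative values were published.

What passing tests on this generator do *not* show: real scans have
spatially correlated roughness, ornamentation, cracks and tilt, none of
which are simulated (noise is white); real landmarking is manual; and the
published tables derive from real profiles, so synthetic statistics match
the published design (sample sizes, df, permutation machinery), not the
published values. The quantitative comparison against those values runs
only when the original profile dataset is supplied locally
(`data/published_profiles/`).

## Numerical details and degenerate inputs

- Zero-size (coincident-landmark) configurations, collinear clouds for TIN,
  all-nodata rasters, profile lines through pure nodata, landmark windows
  off the profile, and TPS records with LM ≠ 7 all raise typed errors.
- Within-furrow ties in detection resolve to the first minimum (argmin);
  detection is invariant to elevation offsets and to rescaling of the
  distance axis.
- Infinite F (zero within-group variance) is flagged, with the permutation
  p still defined.
- Problem sizes in the test suite are chosen to exercise the contracts at
  small cost: calibration uses 200 replicate null datasets × 499 resamples
  at n = 15 per group (binomial SE ≈ 0.015 on a 0.05 rate, against a ±0.03
  acceptance band); the end-to-end recovery check runs one full
  1500 × 1500-cell scan; the oracle comparison uses a 0.001° exhaustive
  rotation grid on 100 random shape pairs.

## Known limitations

- 2-D profile landmarks only; no 3-D configurations, semilandmarks or
  sliding, and no thin-plate-spline warp visualizations (landmark
  displacement vectors are exportable instead).
- The `.MAP` dialect implemented is a documented stand-in (whitespace x y z,
  window-relative); proprietary binary variants are out of scope.
- The exsagittal offset, the sharp/rounded threshold and the CVA input space
  (tangent coordinates vs a PC subset) are all conventions the original
  publication leaves unstated; each is a configurable default here, and
  distance values can shift with the CVA rank choice on rank-deficient data.
- No smoothing/denoising or hole-filling is applied to DEMs; what was
  scanned is what is analysed.
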