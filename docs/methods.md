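# Methods

## Blastocyst arc geometry and the BSCR

The outer epiblast layer of a peri-implantation mouse blastocyst
(E4.25–E4.50) is treated as a shallow circular arc. From the chord width
*w* and cap height *h* (µm):

- arc radius r = w²/(8h) + h/2 (µm) — the circumradius of the chord
  endpoints (±w/2, 0) and apex (0, h);
- curvature κ = 1000/r (mm⁻¹) — all lengths in the package are µm and all
  curvatures mm⁻¹, so the conversion factor 1000 appears exactly once;
- arc length = 2r·arcsin(w/2r) (µm); linear cell density = cells / arc
  length when a count is available.

`bscr_from_measurements` pools per-embryo curvatures into the BSCR
interval. The default bound mode is **min/max** over the measurements,
with mean ± k·sd as an option: the published interval (15–62 mm⁻¹)
brackets the published mean ± sd (31 ± 8 mm⁻¹) far wider than one
standard deviation, so extremes are the consistent reading. The package
default `DEFAULT_BSCR` is the 15–62 mm⁻¹ interval itself.

The 59 × 21 µm mean epiblast gives r = 31.22 µm, κ = 32.03 mm⁻¹ — inside
the interval, as it must be for the construction to be self-consistent.

## Scaled three-point directional curvature

Surfaces are 2.5D height maps: one height per lateral position, extracted
from binary micro-CT occupancy stacks as (topmost occupied voxel index +
1) × voxel size, or read directly from TIFF/CSV rasters. Overhanging
(multivalued) surfaces are out of scope.

At a point A, for each of D = 18 directions θᵢ = i·180°/D, the surface is
sampled at C = A + s·(cos θᵢ, sin θᵢ) and E = A − s·(cos θᵢ, sin θᵢ)
with half-span s = 30 µm (scale length CE = 60 µm, chosen to match the
epiblast width; both are parameters). The directional curvature is the
reciprocal circumradius of the planar triangle {(−s, z_E), (0, z_A),
(+s, z_C)}, signed by the sagitta z_C + z_E − 2z_A: positive = the point
dips below its flanks = concave. Directions span [0°, 180°) only: each
probe uses both flanks, so opposite headings are redundant.

Classification:

- motif from the mean ⟨κ⟩ over the D directions: concave ⟨κ⟩ ≥ +2.5,
  convex ⟨κ⟩ ≤ −2.5, flat otherwise. Boundaries are inclusive on the
  curved side so the three classes partition the line; the band
  half-width (2.5 mm⁻¹) is a parameter.
- BSCR membership from the individual κᵢ: the count is the number of
  directions with 15 < κᵢ < 62 mm⁻¹ (strict interior), BSCR+ means
  count ≥ 1, and the count is binned into thirds of D: none (0), low
  (1–6), med (7–12), hi (13–18) for D = 18.

The mixed convention — strict interval, inclusive motif boundary — keeps
both classifications total; both interval endpoints and the band are
configurable where a user needs a different convention.

### Numerical choices

- **Interpolation**: bilinear (exact on planes); a nearest-neighbour mode
  is retained for voxel-faithful checks. On a 1 µm grid the bilinear
  error on spheres of radius 16–80 µm stays below 1% per direction;
  chord endpoints that land exactly on grid nodes are exact to ~1e-9.
- **Collinearity**: |sagitta| < 1e-9 µm returns exactly κ = 0, which
  prevents sign flapping at machine precision on flat regions.
- **Borders**: points whose chord star leaves the valid raster are marked
  invalid rather than computed from truncated chords — truncation would
  bias κ, and no edge rule is defensible a priori. A margin of width s is
  therefore always invalid.
- **Coordinates**: x rightward (columns), y downward (rows), origin at
  the top-left pixel centre, position (µm) = index × pixel size.
  Registration of microscopy frames assumes the same convention.
- **Order independence**: per-pixel evaluation is independent; the
  vectorized whole-map path (scipy `map_coordinates`, order 1) and the
  per-point path agree, which the tests check directly.
- Constant height offsets leave all integer outputs (motif labels, BSCR
  counts) unchanged; the scalar κ is offset-invariant to ~1e-12 relative
  (exact invariance is impossible in floating point). Height negation
  negates κ exactly and swaps convex/concave fractions exactly.

## Overlay analysis

- **Registration**: least-squares affine from ≥ 3 non-collinear landmark
  pairs, replacing manual image overlay; the RMS residual (µm) is
  reported as the registration quality figure.
- **Naive calling**: threshold = max (live GFP tracking), mean
  (fixed-stain MFI) or mean + k·sd of the plain-substrate control
  population, per experiment type; a cell is naive-hi when its intensity
  is *strictly* above the threshold. The control statistic is computed
  over cells, not pixels.
- **Assignment**: each cell takes the motif/BSCR state of the single
  pixel under its (registered) centroid — the simplest faithful overlay;
  cells off the raster or on invalid pixels are excluded and counted.
- **Region statistics**: per stratum (motif, BSCR flag or BSCR category)
  and time point: cell count, stratum area (pixel count × pixel size²),
  density in cells·mm⁻² (area-normalised; a per-field normalisation is a
  user-side choice), naive fraction, MFI. Empty strata yield missing
  values, never 0, so time averages are not biased.
- **Tracks**: per interval between retained samples (optionally
  subsampled to a fixed frame interval): straight-line displacement, path
  length, and a border event classified from the BSCR flag at the two
  endpoints only (stay_in / stay_out / in_to_out / out_to_in). Continuous
  path–border intersection is deliberately not attempted at 60–90 min
  frame spacings.
- **Imaging helpers**: max-intensity projection; nuclei detection by
  Gaussian smoothing → Otsu or fixed threshold → connected components
  with a minimum area (default 10 µm²); hi/positive area ratio inside a
  mask (missing when no positive pixels).

## Synthetic data

The generators stand in for micro-CT and microscopy and define the
conditions the tests run under.

**Surfaces.** Spherical-cap microbowl lattices and cylindrical
microgroove arrays are exact analytic geometry (cap depth
R − √(R² − a²) for aperture radius a; infeasible caps a > R are
rejected), so their curvature at feature bottoms is known (1000/R across
the curved section). The `random_bms` kind sums lognormally sized
Gaussian pits and bumps and low-pass filters them — an emulation of
spark-eroded mould surfaces with randomly varied motifs. Defaults
(25 features per 500 µm square, amplitude ~8 µm, lateral extent ~35 µm,
5 µm smoothing) produce BSCR+ area fractions of a few percent with the
count histogram peaking at small counts, the qualitative regime of real
moulded substrates; they were chosen once as plausible and are not
calibrated to any measured surface.

**Cells.** Agents seed uniformly over valid pixels in the primed state.
Per step dt (default 1 h): a primed cell reverts with probability
logistic(β₀ + β₁·count) at its current pixel (defaults β₀ = −4,
β₁ = 0.25 per count unit — chosen for testability, not as a biological
rate claim); cells divide as Bernoulli events at rate g (naive 0.03 h⁻¹ ≥
primed 0.02 h⁻¹, naive cells proliferate faster), the daughter placed
within one cell diameter (5 µm); positions take reflected Gaussian steps
of scale σ√dt (default σ = 1 µm·h^−1/2, which keeps ~88% of 24 h net
displacements under 10 µm — the limited-migration regime); fluorescence
is drawn per observation from state-specific lognormals (log-means
ln 100 vs ln 1000, log-sd 0.3 — clearly separated states). Reversion is
irreversible by default (an optional relapse rate models inhibitor
washout); apoptosis is not modelled, so cell count ≡ n₀ + divisions.

With σ = 0 and equal division rates the naive fraction at horizon T for
cells on count c has the closed form 1 − (1 − q_c)^(T/dt),
q_c = logistic(β₀ + β₁·c); `expected_naive_fraction` exposes it and the
end-to-end tests compare recovered per-category fractions against it
inside a family-wise 95% band (Bonferroni z = 2.50 across the four
categories, plus a 0.01 allowance for control-threshold
misclassification).

**Images.** Cells render as Gaussian spots (default; a point source under
a diffraction-limited optic, for peak-detection fixtures) or as uniform
disks of equal radius (for area-occupancy metrics: the thresholded area
of a Gaussian spot grows with log amplitude, so only equal-footprint
rendering makes the hi/positive area ratio equal the hi cell fraction).
Additive Gaussian noise, clipped at zero; deterministic given the seed.

**What passing tests do and do not show.** The synthetic surfaces are
noise-free and exactly band-limited, cells are independent points without
contact inhibition or segmentation errors, and fluorescence states are
well separated. Passing therefore demonstrates that the analysis chain is
mathematically correct and statistically unbiased under its own model —
not that real micro-CT noise, registration error, cell crowding or
marker-distribution overlap are handled; those enter through the
pixel-size, registration-residual and threshold parameters and must be
judged per dataset.

## Pipeline

`run_pipeline` executes surface → map → cells → overlay → report from a
single YAML config; flags override config keys. All randomness flows from
one root seed; the manifest records config, package version, seed and
SHA-256 checksums of every artifact, and re-running from the manifest's
config reproduces byte-identical tables. Pre-flight validation (stage
names, input existence, parameter sanity) runs before any output is
created.

Problem sizes in the shipped demo and test suite (400–500 µm rasters at
1–2 µm pixels, 400–5000 cells, 6–24 h horizons, 100-replicate sign
recovery) were chosen so the whole suite exercises every contract at
desk scale; all generators accept larger extents and populations
unchanged.

## Auxiliary quantifications

ChIP enrichment: percent input = 10 × 2^(CT_input,10% − CT_ChIP),
optionally normalised to the total-H3 percent input; values stay on the
percent scale (10 = 10%). Teratoma volume: width² × length / 2 (cm³,
caliper convention width ≤ length). Both are strictly monotone in their
arguments and scale as expected (one extra ChIP cycle halves enrichment;
isotropic size scaling cubes the volume).

## Known limitations

- 2.5D only: no principal-curvature/shape-operator analysis of meshes and
  no overhangs.
- Per-cell motif assignment uses the single pixel under the centroid
  (a neighbourhood-majority option exists in the design space but only
  the centroid rule is implemented).
- Border-crossing is endpoint-based; fast cells can cross and return
  within one frame unobserved.
- The simulator's hazard model is a testing device: it encodes the
  qualitative structure (reversion increasing with BSCR count, faster
  naive proliferation, limited migration) with convenient parametric
  forms, not measured kinetics.
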