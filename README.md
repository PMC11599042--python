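# bscrmap

Curvature-resolved analysis of micro-structured cell culture substrates
against the **blastocyst-scaled curvature range (BSCR)** — the interval of
interface curvatures, 15–62 mm⁻¹, that naive pluripotent stem cells
experience at the epiblast–trophectoderm boundary of a peri-implantation
mouse blastocyst. Substrates whose local topography reproduces this range
can revert primed pluripotent stem cells towards naivety; `bscrmap`
provides the geometric and correlative machinery to quantify that link:

1. **Blastocyst geometry** — from measured epiblast chord width *w* and cap
   height *h* (µm), the arc radius follows the sagitta relation
   *r = w²/(8h) + h/2*, curvature *κ = 1000/r* (mm⁻¹), arc length
   *2r·arcsin(w/2r)*; pooling curvatures over embryos yields the BSCR.
2. **Directional surface curvature** — on a 2.5D height map *z(x, y)*, each
   point A is probed in *D* = 18 directions with a scaled three-point
   approach: the surface is sampled at the two flanking points C, E a
   half-span *s* = 30 µm away (60 µm chord, the epiblast width), and
   *κ = sign(z_C + z_E − 2z_A) · 1000 / R*, with *R* the circumradius of
   {(−s, z_E), (0, z_A), (+s, z_C)}. Positive *κ* is concave (bowl-like).
   The mean ⟨κ⟩ classifies the point into a motif (convex ⟨κ⟩ ≤ −2.5,
   flat, concave ⟨κ⟩ ≥ +2.5 mm⁻¹); a point is **BSCR+** when at least one
   directional κ lies strictly inside (15, 62) mm⁻¹, and the **BSCR
   count** (0–18, binned none / low 1–6 / med 7–12 / hi 13–18) grades how
   omnidirectional the match is.
3. **Correlative overlay** — cell tables (positions, times, fluorescence)
   are registered onto the maps with a landmark affine fit, called
   naive-high against a plain-substrate control threshold (strictly above
   the control max or mean), and summarised per motif / BSCR stratum:
   counts, densities (mm⁻²), naive fractions, MFI, plus track
   displacement and BSCR-border-crossing metrics and GFP-hi/GFP+ area
   ratios.
4. **Synthetic ground truth** — analytic microbowl/microgroove/random
   surfaces and an agent-based cell simulator (logistic reversion hazard
   in the local BSCR count, state-specific division, reflected random
   walk) make every stage testable without any imaging data.

Intended users: groups doing mechanobiology / topography-guided stem-cell
culture who have height maps (micro-CT, profilometry) and cell
observations, and want reproducible curvature maps and per-motif
statistics instead of manual image overlays.

## Worked example

The built-in demo builds a 400×400 µm lattice of spherical microbowls
(sphere radius 32 µm ⇒ κ = 31.25 mm⁻¹, inside the BSCR), maps it, and
simulates a primed population whose reversion hazard grows with the local
BSCR count:

```sh
bscrmap run --seed 1 --out-dir demo
```

prints

```
final naive fraction per stratum:
  none: 0.3832
  low: 0.8333
  med: 0.9574
  hi: 1.0
manifest: demo/manifest.json
```

The recovered naive fraction increases monotonically with the BSCR count
category — cells sitting where many probe directions fall inside the
blastocyst curvature range revert most — which is exactly the ground
truth the simulator encodes (per-step hazard logistic(−4 + 0.25·count)
over 24 h). The map summary in `demo/manifest.json` reports the motif
area fractions (convex 0.576 / flat 0.132 / concave 0.292 for this
lattice) and the BSCR+ area fraction (0.282); `region_stats.csv` holds
the full per-stratum time course.

Library use mirrors the CLI:

```python
import bscrmap as b

g = b.epi_geometry(b.BlastocystMeasurement(width=59, height=21))
g.curvature                      # 32.03 mm^-1, inside DEFAULT_BSCR (15-62)

hm, _ = b.make_surface(b.SurfaceSpec(kind="microbowl_array", radius=32.0))
motif, bscr, summary = b.map_surface(hm, b.CurvatureParams())
summary["frac_bscr_positive"]    # fraction of valid pixels that are BSCR+
```

Other subcommands: `geometry` (blastocyst tables → arc geometry + BSCR),
`map` (height map → motif/BSCR rasters), `simulate surface`, `overlay`,
`tracks`, `quant chip|teratoma`.

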