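# Methods

## Scope and model

`petripath` models a fused-filament printer (Ultimaker-Original class,
Marlin/RepRap g-code) printing PLA walls directly onto tissue-culture
plastic inside 35 mm Petri dishes. The package is organised around one
invariant representation: a `GCodeCollection` (an ordered command list) that
can be parsed from and serialized to g-code text, and a kinematic simulator
that resolves it into `ToolpathSegment`s — start/end positions, extrusion
delta and feed. Every higher-level claim in the package (structure
dimensions, batch safety, repair post-conditions) is checked on simulated
segments, never on raw text.

Machine conventions: origin at the front-left of the stage, z = 0 at the
configured start height, lengths in mm, angles in degrees CCW from +x,
feeds in mm/min. The extruder axis is absolute (M82 convention) and reset
with `G92 E0` between objects; a negative extruder delta is a retraction
and is classified as non-depositing. Arc g-codes (G2/G3) are not emitted;
curves are segmented into chords.

A fully specified absolute move issued before the position is known (no
homing, no start state) defines the position without emitting a segment:
there is no physical start point to report. A partially specified move in
that situation is an error. This lets bare object collections — which always
begin with a travel carrying X, Y and Z — be simulated standalone while
still rejecting genuinely ill-posed programs.

## Print settings

| parameter | default | unit | rationale |
|---|---|---|---|
| temperature | 230 | °C | PLA hotend temperature for dish printing |
| feed_print | 400 | mm/min | mid of the 300–500 mm/min working range |
| feed_travel | 1500 | mm/min | non-depositing moves; not geometry-critical |
| extrusion_rate | 0.034 | filament-mm per path-mm | mid of the 0.027–0.041 working range |
| nozzle_diameter | 0.4 | mm | hardware |
| layer_height | 0.12 | mm | one deposited PLA layer on culture plastic |

## Curve segmentation and validation

Arcs and circles are polygonized by bounding the chord sagitta
`s = r(1 − cos θ/2)`; the default tolerance 0.01 mm is 40× below the nozzle
diameter, so segmentation error is invisible in the print. Vertices are
placed exactly on the curve, which makes the validation bound achievable by
construction: the validator extracts every simulated move endpoint and
computes the exact planar distance to the ideal curve — closed form for
lines (infinite line through the two points) and circles, and for ellipses
a 721-point coarse scan followed by safeguarded Newton iteration on the
stationarity condition of the squared distance. Newton converges
quadratically to machine precision; the generic bounded 1-D minimizer is
kept only as a cross-check for non-trivial distances because its internal
`sqrt(eps)` relative x-tolerance floor (~1e-7 rad) is too coarse for the
1e-12 mm convergence target. Ellipse vertex counts are chosen from the
worst-case curvature bound `max(a/b², b/a²)`; a circle-degenerate ellipse
(a = b) delegates to the arc code so the vertex sets are identical.

Serialization is fixed-point with 9 decimals. Five decimals would be ample
for the printer (half-ulp 5 µm ≪ 12 µm z-resolution), but the package
promises that a serialize/parse round trip preserves the toolpath to
1e-9 mm, and that requires half-ulp ≤ 5e-10 mm. Nine decimals keep the
output deterministic and byte-stable through one parse/serialize cycle.

## Structures

All generators emit one extrusion perimeter per layer (no infill, no
multiple perimeters — these walls are single-bead), with layer z values at
strictly increasing integer multiples of the layer height. Layer count is
`ceil(height / layer_height)` with a 1e-9 slack term so binary-float
artefacts (1.8/0.12 = 15.000000000000002) do not add a phantom layer.
Heights that are not multiples of the layer height get a final layer above
the nominal height with the radius clamped at the structure top.

- **Ring**: 6 mm diameter × 1.8 mm (15 layers) — a cell-spreading barrier.
  The toolpath radius is the nominal diameter/2 (centerline convention).
- **Conical well**: constant radius for z ≤ wall height (3 mm), then radius
  growing linearly at `tan(apex/2)` per mm over the 1 mm cone. `apex_angle`
  is the full cone opening angle (default 100°, i.e. walls tilted 50° from
  vertical); the angle is recoverable from consecutive layer radii as
  `2·atan(Δr/Δz)`. The base diameter default (7 mm) is chosen so seven
  wells — top radius 3.5 + tan 50° ≈ 4.69 mm — pack in a 35 mm dish.
- **Seven-well dish**: one central well plus six at 60° spacing on the
  largest circle that keeps footprints disjoint and inside the dish,
  `ring radius = dish radius − top radius` (12.81 mm at defaults), valid
  when that is ≥ 2 × top radius.
- **Double ring**: the default inner ring is the 6 × 1.8 mm barrier; the
  outer medium wall (28 mm ⌀ × 4.2 mm) is a package default chosen to fit a
  35 mm dish with margin — only its ordering constraints (larger, taller)
  are inherent.
- **Sorter grid**: a 7 × 6 lattice of 1 mm pitch with the four corner cells
  omitted — 38 cells. Cell walls are emitted edge-by-edge with each shared
  edge drawn once, all at a single z (one PLA layer).

`count_enclosed_cells` nodes the planar extrusion segments and polygonizes
the arrangement (shapely), returning the number of bounded faces. The test
suite cross-checks it with an independent raster flood-fill oracle
(rasterize walls at 20 px/mm, 4-connected labelling, count regions not
touching the border) on randomized sub-lattices including interior holes.

## Batch planning

Dish (row, column) centres sit at `(column · column_distance,
row · row_distance)`. Each object is translated rigidly by the dish centre
in xy and by the dish's probed surface height in z (fallback: the layout's
`start_height`, with a warning — so batches can be planned without the
probe hardware). The probe map is a CSV of `row,column,z_mm`; duplicates
keep the last value with a warning. Safe travel height is
`start_height + dish_wall_height + clearance` (defaults 0 + 10 + 5 mm);
the planner enters and leaves every dish vertically at its centre at that
height, resets the extruder axis per dish, and visits dishes row-major
(deterministic) unless the greedy nearest-neighbour flag is set.
`check_safe_travel` classifies a segment as inter-dish unless both
endpoints are inside the same dish footprint, and flags inter-dish
non-extruding segments whose z dips below the safe height — by
construction the planner's own output is violation-free.

## Travel repair

A travel move is hazardous when its xy-projection crosses the protected
region's interior while the nozzle is below the region's `z_ceiling` over
the crossed portion (z interpolated linearly along the move). Purely
vertical moves are exempt: the hazard modelled is dragging threads *across*
the culture surface, and descending at a point is inherent to printing
there. This rule makes the z-hop repair self-certifying — lift and lower
are vertical, the crossing happens at the ceiling.

The detour repair walks the region boundary inflated by the nozzle
diameter plus a 0.05 mm chord margin, entering and leaving at the original
segment's boundary intersections and taking the shorter boundary arc (ties
counter-clockwise). The extra margin guarantees the polyline chords between
boundary vertices never dip inside the nozzle-inflated region (the region
the tests sample at 0.05 mm resolution). z is interpolated along the detour
arc length. A detour whose endpoint lies inside the inflated region is
refused with an error — the destination itself is in the protected area and
only a z-hop makes sense there. Circular regions are represented as
256-gon shapely polygons; the approximation error (~1e-4 relative) is far
below the nozzle-diameter inflation that pads every decision.

Both repairs leave the multiset of extrude-moves byte-identical and are
idempotent (a second pass finds nothing to fix). Interactive editing is
reduced to its primitive: `move_control_point` relocates a single move
target and nothing else.

## Contrast score

The score of a well image is the mean 3×3 Sobel gradient magnitude
`√(gx² + gy²)` over cell pixels: pixels inside the elliptical well ROI
whose Sobel response exceeds a threshold. Borders are handled by edge
replication, so a constant image scores exactly zero and a unit intensity
step responds with magnitude 4 in the two columns flanking the edge. The
threshold defaults to Otsu's value computed on the Sobel image within the
ROI; tests and examples use fixed thresholds for determinism. An empty mask
scores 0 with a warning (not an error) so batch scoring degrades
gracefully. The score is invariant to constant intensity offsets and
jointly homogeneous: doubling intensities and the threshold doubles it.

The synthetic generator emulates adherent cells in phase contrast: dark
circular bodies (default 60 units below a background of 120) ringed by
bright halo annuli (+40 units, radius 1.0–1.6 cell radii), placed without
overlap by seeded rejection sampling, plus Gaussian noise, then a Gaussian
blur applied last so defocus degrades both edges and noise — the synthetic
analog of meniscus-induced image degradation. It does **not** model mosaic
stitching seams, illumination gradients, cell shape irregularity or
confluent sheets; passing tests therefore demonstrate the metric's ordinal
behaviour (blur monotonically lowers the score), not absolute score values
on real micrographs, which depend on the unreported normalization and
threshold of any particular acquisition pipeline.

## Problem sizes and numerics

The test suite and the acceptance script run on desk-scale inputs: default
structures (hundreds to a few thousand commands), 2×2 to 3×5 dish grids,
128–256 px synthetic images, and 20-seed Monte-Carlo panels for the blur
trend — enough for every property to be decided at its stated tolerance
with seconds of compute. Key tolerances: 1e-9 mm for toolpath equality and
isometries, 1e-8 mm for on-curve vertex placement (the validator's
certification bound), 1e-12 mm for ellipse nearest-point convergence,
0.1° for apex-angle recovery from layer radii.

## Known limitations

- No arc (G2/G3) or Bézier emission; no STL slicing — third-party slicer
  output is consumed as g-code only.
- Curves and the deviation validator are planar; 3D space curves beyond
  stacked layers are out of scope.
- The detour router assumes one protected region at a time and refuses
  endpoints inside the inflated region.
- The contrast score is a quality metric, not a cell segmenter; its
  absolute values are pipeline-specific.
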