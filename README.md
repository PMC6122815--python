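# petripath

Toolpath generation, batch planning and repair for 3D-printed cell-culture
structures in Petri dishes — with a Sobel-based phase-contrast image-quality
score.

Fused-filament printing of PLA micro-structures directly onto tissue-culture
plastic lets a lab turn plain 35 mm dishes into multi-well plates, cell
confinement rings or clone-sorting grids, with far better phase-contrast
optics than standard multiwell plates. Doing that reliably is a toolpath
problem, not a slicing problem: the structures are single-perimeter walls a
fraction of a millimetre wide, printed into dishes whose surface heights vary
by ~0.2 mm between runs — more than one 0.12 mm layer — and whose culture
surfaces must never be crossed by a stringing travel move. `petripath` is a
headless library for that workflow:

- **`petripath.gcode`** — a typed g-code model (Marlin/RepRap dialect:
  G0/G1/G4/G28/G90/G91/G92/M104/M109) with a parser, deterministic
  serializer, rigid translation and a kinematic simulator that resolves every
  program into continuous `ToolpathSegment`s with exact extrusion accounting.
- **`petripath.geometry`** — curve primitives (lines, arcs, circles,
  ellipses) polygonized with a sagitta bound `s = r(1 − cos θ/2) ≤ tol` and
  vertices placed *exactly on the curve*, plus a validator that measures the
  exact point-to-curve distance of every move endpoint (closed form for lines
  and circles, Newton-refined nearest point for ellipses).
- **`petripath.structures`** — parametric generators: confinement rings
  (6 mm ⌀ × 1.8 mm), conical wells (3 mm cylindrical wall flaring 1 mm at a
  100° apex angle, so the radius grows as `tan(apex/2)` per mm of height),
  a seven-well 35 mm dish, a double-ring dish, and a single-layer sorter grid
  enclosing 38 one-mm² mini-wells — plus a bounded-face counter over the
  planar arrangement of extrusion segments.
- **`petripath.batch`** — the multi-dish planner: per-dish probe-map z
  compensation, row-major (or greedy nearest-neighbour) visit order,
  extruder reset at each dish, and collision-safe inter-dish travel at
  `start_height + wall_height + clearance`, with a checker that certifies it.
- **`petripath.path_edit`** — hazard detection and automatic repair of
  travel moves crossing a protected culture region, by z-hop or by planar
  detour around the region inflated by the nozzle diameter; deposition
  commands pass through byte-identical.
- **`petripath.contrast`** — the image-quality score: Sobel gradient
  magnitude, threshold (fixed or Otsu) inside an elliptical well ROI, score =
  mean edge magnitude over cell pixels; plus a seeded synthetic
  phase-contrast image generator for testing the metric.

## Worked example

```sh
python examples/generate_structures.py
```

```
ring: diameter 6.000 mm, 15 layers, top z 1.80 mm, filament used 9.60 mm
conical well: base radius 3.50 mm grows to 4.692 mm over the 1.0 mm cone (apex angle 100.0 deg, wall slope 50.0 deg from vertical)
seven-well dish: 7 wells, max radial extent 17.50 mm (fits the 17.5 mm dish radius)
sorter grid: 38 enclosed 1 mm^2 mini-wells in a single printed layer
```

The ring stacks fifteen 0.12 mm layers to 1.8 mm; the conical well's top
radius is `3.5 + 1.0·tan(50°) ≈ 4.692` mm; the seven wells pack hexagonally
to exactly the 17.5 mm dish radius; and the sorter grid's extrusion
segments, polygonized, enclose 38 bounded faces of 1 mm² each.

`examples/score_contrast.py` shows the optics side — the contrast score of
synthetic wells dropping monotonically (≈153 → 39) as meniscus-like blur
grows from 0 to 4 px — and `examples/batch_print.py`, `repair_travels.py`
and `validate_gcode.py` walk the planner, the travel repair and the
curve validator.

There is also a thin CLI over the same functions:

```sh
petripath generate --spec ring.yaml --out ring.gcode
petripath validate --gcode ring.gcode --curve circle:0,0,3 --tol 1e-8
petripath batch --layout layout.yaml --assign assign.yaml --probe probe.csv --out batch.gcode
petripath reroute --gcode in.gcode --region circle:0,0,3 --mode zhop --out out.gcode
petripath score --image well.png --roi ellipse:64,64,50,50 --threshold 30
```

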