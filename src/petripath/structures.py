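"""Parametric generators for PLA culture-dish structures.

Each generator emits a layered toolpath for one structure placed with its
footprint centred on (0, 0): cell-confinement rings, conical wells whose
sloped walls preserve phase-contrast optics, a seven-well 35 mm dish, a
double-ring (spreading barrier + medium wall) dish, and a single-layer
cell-sorter grid of ~1 mm^2 mini-wells.

Every wall is a single extrusion perimeter per layer (no infill), layer z
values are strictly increasing integer multiples of the layer height, and
ring/well perimeters are closed polylines with vertices exactly on the
nominal circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from shapely.geometry import LineString
from shapely.ops import polygonize, unary_union

from .gcode import GCodeCollection, MachineState, Position, PrintSettings, simulate
from .geometry import CurveDescriptor, SegmentationTolerance, ToolpathBuilder, arc_path


class StructureError(ValueError):
    """Invalid structure specification or layout."""


def _n_layers(height: float, layer_height: float) -> int:
    # 1e-9 slack so e.g. 1.8 / 0.12 rounds to exactly 15 layers
    return max(1, math.ceil(height / layer_height - 1e-9))


@dataclass(frozen=True)
class RingSpec:
    """A circular confinement ring (printed wall)."""

    diameter: float = 6.0  # mm
    height: float = 1.8  # mm
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not self.diameter > 0 or not self.height > 0:
            raise StructureError("ring diameter and height must be > 0")


@dataclass(frozen=True)
class ConicalWellSpec:
    """A cylindrical well flaring into an outward-leaning cone.

    ``apex_angle`` is the full cone opening angle; the wall tilts
    ``apex_angle / 2`` from vertical, so the radius grows by
    ``tan(apex_angle / 2)`` per mm of height in the conical section.
    """

    base_diameter: float = 7.0  # mm; chosen so seven wells pack in a 35 mm dish
    wall_height: float = 3.0  # mm, cylindrical section
    cone_height: float = 1.0  # mm, conical section
    apex_angle: float = 100.0  # degrees, full opening angle

    def __post_init__(self):
        if not 0.0 < self.apex_angle < 180.0:
            raise StructureError("apex_angle must lie in (0, 180) degrees")
        if self.base_diameter <= 0 or self.wall_height <= 0 or self.cone_height <= 0:
            raise StructureError("well dimensions must be > 0")

    @property
    def base_radius(self) -> float:
        return self.base_diameter / 2.0

    @property
    def top_radius(self) -> float:
        return self.base_radius + self.cone_height * math.tan(math.radians(self.apex_angle / 2.0))

    @property
    def total_height(self) -> float:
        return self.wall_height + self.cone_height

    def radius_at(self, z: float) -> float:
        """Wall radius at height z (clamped to the top radius above the cone)."""
        if z <= self.wall_height:
            return self.base_radius
        dz = min(z, self.total_height) - self.wall_height
        return self.base_radius + dz * math.tan(math.radians(self.apex_angle / 2.0))


@dataclass(frozen=True)
class MultiWellDishSpec:
    """Several independent conical wells in one dish, centred hexagonally."""

    n_wells: int = 7
    dish_diameter: float = 35.0  # mm
    well: ConicalWellSpec = field(default_factory=ConicalWellSpec)

    def __post_init__(self):
        if not 1 <= self.n_wells <= 7:
            raise StructureError("centred hexagonal arrangement supports 1-7 wells")
        if not self.dish_diameter > 0:
            raise StructureError("dish_diameter must be > 0")

    def well_centers(self) -> list[tuple[float, float]]:
        """One central well plus up to six at 60 degree spacing, on the largest
        circle that keeps footprints disjoint and inside the dish."""
        top_r = self.well.top_radius
        dish_r = self.dish_diameter / 2.0
        centers = [(0.0, 0.0)]
        if self.n_wells > 1:
            ring_r = dish_r - top_r
            if ring_r < 2.0 * top_r - 1e-9:
                raise StructureError(
                    f"wells of top radius {top_r:.3f} mm do not fit disjointly "
                    f"in a {self.dish_diameter:.1f} mm dish"
                )
            for k in range(self.n_wells - 1):
                ang = math.radians(60.0 * k)
                centers.append((ring_r * math.cos(ang), ring_r * math.sin(ang)))
        return centers


@dataclass(frozen=True)
class DoubleRingSpec:
    """Inner spreading-limit ring plus a higher, larger-diameter medium wall."""

    inner: RingSpec = field(default_factory=RingSpec)
    outer: RingSpec = field(default_factory=lambda: RingSpec(diameter=28.0, height=4.2))

    def __post_init__(self):
        if self.outer.diameter <= self.inner.diameter:
            raise StructureError("outer ring must have the larger diameter")
        if self.outer.height <= self.inner.height:
            raise StructureError("outer ring must be the taller one")
        if self.outer.center != self.inner.center:
            raise StructureError("rings must be concentric")


@dataclass(frozen=True)
class GridSpec:
    """A single-layer lattice of square mini-wells (the cell-sorter grid)."""

    columns: int = 7
    rows: int = 6
    pitch: float = 1.0  # mm; nominal cell area = pitch^2
    omit_corners: bool = True
    layers: int = 1

    def __post_init__(self):
        if self.columns < 1 or self.rows < 1:
            raise StructureError("grid needs at least one row and column")
        if not self.pitch > 0:
            raise StructureError("pitch must be > 0")
        if self.layers < 1:
            raise StructureError("layers must be >= 1")

    def cells(self) -> list[tuple[int, int]]:
        """(column, row) indices of retained cells."""
        corners = set()
        if self.omit_corners:
            corners = {
                (0, 0),
                (self.columns - 1, 0),
                (0, self.rows - 1),
                (self.columns - 1, self.rows - 1),
            }
        return [
            (c, r)
            for r in range(self.rows)
            for c in range(self.columns)
            if (c, r) not in corners
        ]


# ---------------------------------------------------------------------------
# generators

_TOL = SegmentationTolerance()


def _stack_circles(
    builder: ToolpathBuilder,
    center: tuple[float, float],
    radius_of_z,
    n_layers: int,
) -> None:
    lh = builder.settings.layer_height
    for k in range(1, n_layers + 1):
        z = k * lh
        r = radius_of_z(z)
        builder.extrude_polyline(arc_path(CurveDescriptor.circle(center[0], center[1], r, z=z), _TOL))


def build_ring(spec: RingSpec, s: PrintSettings = PrintSettings()) -> GCodeCollection:
    """Stacked closed circular layers forming one confinement ring."""
    if spec.diameter < s.nozzle_diameter:
        raise StructureError("ring diameter smaller than the nozzle diameter")
    b = ToolpathBuilder(s, name="ring")
    b.comment(f"ring d={spec.diameter} h={spec.height}")
    _stack_circles(b, spec.center, lambda z: spec.diameter / 2.0, _n_layers(spec.height, s.layer_height))
    return b.collection


def build_conical_well(
    spec: ConicalWellSpec = ConicalWellSpec(),
    s: PrintSettings = PrintSettings(),
    center: tuple[float, float] = (0.0, 0.0),
    name: str = "conical-well",
) -> GCodeCollection:
    """Cylindrical wall expanding into a cone of the given apex angle.

    Layers sit at integer multiples of the layer height; the radius is
    constant up to ``wall_height`` and then grows linearly with slope
    ``tan(apex_angle / 2)`` until the cone top (clamped above it).
    """
    b = ToolpathBuilder(s, name=name)
    b.comment(
        f"conical well base_d={spec.base_diameter} wall={spec.wall_height} "
        f"cone={spec.cone_height} apex={spec.apex_angle}"
    )
    _stack_circles(b, center, spec.radius_at, _n_layers(spec.total_height, s.layer_height))
    return b.collection


def build_seven_well_dish(
    spec: MultiWellDishSpec = MultiWellDishSpec(), s: PrintSettings = PrintSettings()
) -> GCodeCollection:
    """Independent conical wells in one 35 mm dish (default: seven)."""
    centers = spec.well_centers()
    top_r = spec.well.top_radius
    dish_r = spec.dish_diameter / 2.0
    for i, (xi, yi) in enumerate(centers):
        if math.hypot(xi, yi) + top_r > dish_r + 1e-9:
            raise StructureError("well footprint exceeds the dish")
        for xj, yj in centers[i + 1 :]:
            if math.hypot(xi - xj, yi - yj) < 2.0 * top_r - 1e-9:
                raise StructureError("well footprints overlap")
    b = ToolpathBuilder(s, name="multi-well-dish")
    b.comment(f"{spec.n_wells} conical wells in a {spec.dish_diameter} mm dish")
    n = _n_layers(spec.well.total_height, s.layer_height)
    for cx, cy in centers:
        _stack_circles(b, (cx, cy), spec.well.radius_at, n)
    return b.collection


def build_double_ring(
    spec: DoubleRingSpec = DoubleRingSpec(), s: PrintSettings = PrintSettings()
) -> GCodeCollection:
    """Concentric ring pair: low spreading barrier inside a taller medium wall."""
    b = ToolpathBuilder(s, name="double-ring")
    b.comment(
        f"double ring inner d={spec.inner.diameter} h={spec.inner.height}; "
        f"outer d={spec.outer.diameter} h={spec.outer.height}"
    )
    _stack_circles(
        b,
        spec.inner.center,
        lambda z: spec.inner.diameter / 2.0,
        _n_layers(spec.inner.height, s.layer_height),
    )
    _stack_circles(
        b,
        spec.outer.center,
        lambda z: spec.outer.diameter / 2.0,
        _n_layers(spec.outer.height, s.layer_height),
    )
    return b.collection


def build_sorter_grid(
    spec: GridSpec = GridSpec(), s: PrintSettings = PrintSettings()
) -> GCodeCollection:
    """Orthogonal lattice of extruded walls enclosing square mini-wells.

    The default 7 x 6 cell lattice with the four corner cells omitted encloses
    38 cells of nominal 1 mm^2 each, printed as a single PLA layer.  Walls are
    emitted edge-by-edge, each shared edge exactly once.
    """
    if spec.pitch < s.nozzle_diameter:
        raise StructureError("pitch smaller than the nozzle diameter")
    p = spec.pitch
    x0 = -spec.columns * p / 2.0
    y0 = -spec.rows * p / 2.0
    edges: set[tuple[tuple[float, float], tuple[float, float]]] = set()
    for c, r in spec.cells():
        xl, xr = x0 + c * p, x0 + (c + 1) * p
        yb, yt = y0 + r * p, y0 + (r + 1) * p
        for edge in (
            ((xl, yb), (xr, yb)),
            ((xr, yb), (xr, yt)),
            ((xl, yt), (xr, yt)),
            ((xl, yb), (xl, yt)),
        ):
            edges.add(edge)
    b = ToolpathBuilder(s, name="sorter-grid")
    b.comment(f"sorter grid {spec.columns}x{spec.rows} pitch={spec.pitch}")
    for k in range(1, spec.layers + 1):
        z = k * s.layer_height
        for (ax, ay), (bx, by) in sorted(edges):
            b.extrude_polyline([Position(ax, ay, z), Position(bx, by, z)])
    return b.collection


# ---------------------------------------------------------------------------
# face counting


def count_enclosed_cells(c: GCodeCollection) -> int:
    """Bounded faces of the planar subdivision induced by the extrusion path.

    Requires a planar (single-z) extrusion toolpath; raises
    :class:`StructureError` otherwise.  Faces are computed by noding the
    extrusion segments and polygonizing the arrangement.
    """
    segments = [s for s in simulate(c, MachineState.at_origin()) if s.is_extrusion]
    if not segments:
        raise StructureError("no extrusion path to analyse")
    zs = {round(s.start.z, 9) for s in segments} | {round(s.end.z, 9) for s in segments}
    if len(zs) != 1:
        raise StructureError(f"extrusion path is not planar: z values {sorted(zs)}")
    lines = [
        LineString([(s.start.x, s.start.y), (s.end.x, s.end.y)])
        for s in segments
        if s.xy_length > 1e-12
    ]
    return len(list(polygonize(unary_union(lines))))
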