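"""Repair of hazardous travel moves over protected culture regions.

When a slicer's travel moves cross the area where cells are expected to
adhere, the hot nozzle can drag thin PLA threads onto the culture surface.
This module finds such travels and repairs them automatically, either by
hopping over the region at a safe height (``zhop``) or by routing around the
region boundary in the plane (``detour``).  Deposition is never touched:
extrude-moves pass through byte-identical.

A travel is hazardous when its xy-projection crosses the region interior
while the nozzle is below the region's ``z_ceiling`` over the crossed
portion.  Purely vertical moves are exempt — descending at a point does not
drag threads across the surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring

from .gcode import (
    CommandKind,
    GCodeCollection,
    MachineCommand,
    MachineState,
    Position,
    PrintSettings,
    simulate,
)


class RerouteError(ValueError):
    """Travel repair is impossible for this geometry."""


_CIRCLE_QUAD_SEGS = 64  # boundary discretization of circular regions


@dataclass(frozen=True)
class ProtectedRegion:
    """A planar no-fly zone with a z ceiling.

    Travels at or above ``z_ceiling`` are exempt; the default matches a
    typical dish wall height, the clearance concern that motivates the rule.
    """

    polygon: Polygon
    z_ceiling: float = 10.0

    @classmethod
    def circle(cls, cx: float, cy: float, r: float, z_ceiling: float = 10.0) -> "ProtectedRegion":
        if not r > 0:
            raise ValueError("radius must be > 0")
        return cls(Point(cx, cy).buffer(r, quad_segs=_CIRCLE_QUAD_SEGS), z_ceiling)

    @classmethod
    def from_vertices(
        cls, vertices: list[tuple[float, float]], z_ceiling: float = 10.0
    ) -> "ProtectedRegion":
        poly = Polygon(vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("polygon must be simple, closed and non-degenerate")
        return cls(poly, z_ceiling)


def _crossing_z_range(seg, poly: Polygon) -> tuple[float, float] | None:
    """z range of the nozzle while the segment's xy-projection is inside poly."""
    line = LineString([(seg.start.x, seg.start.y), (seg.end.x, seg.end.y)])
    if line.length < 1e-12:
        return None  # vertical move: no dragging across the surface
    inter = line.intersection(poly)
    if inter.is_empty or inter.length < 1e-12:
        return None
    geoms = getattr(inter, "geoms", [inter])
    zmin, zmax = math.inf, -math.inf
    for g in geoms:
        for x, y in getattr(g, "coords", []):
            t = line.project(Point(x, y)) / line.length
            z = seg.start.z + t * (seg.end.z - seg.start.z)
            zmin, zmax = min(zmin, z), max(zmax, z)
    if zmin is math.inf:
        return None
    return zmin, zmax


def find_travel_violations(
    c: GCodeCollection, region: ProtectedRegion, start: MachineState | None = None
) -> list[int]:
    """Indices (into the simulated toolpath) of hazardous travel segments."""
    if start is None:
        start = MachineState.at_origin()
    bad: list[int] = []
    for i, seg in enumerate(simulate(c, start)):
        if seg.is_extrusion:
            continue
        zr = _crossing_z_range(seg, region.polygon)
        if zr is not None and zr[0] < region.z_ceiling - 1e-9:
            bad.append(i)
    return bad


def _detour_points(
    seg, region: ProtectedRegion, inflate: float, margin: float
) -> list[tuple[float, float]]:
    """Planar waypoints around the inflated region boundary.

    The route follows the boundary inflated by ``inflate + margin`` so the
    polyline chords between boundary vertices never dip inside the
    ``inflate``-buffered region.  Shorter boundary arc wins; ties go
    counter-clockwise.
    """
    a = (seg.start.x, seg.start.y)
    b = (seg.end.x, seg.end.y)
    route_poly = region.polygon.buffer(inflate + margin, quad_segs=_CIRCLE_QUAD_SEGS)
    if route_poly.covers(Point(a)) or route_poly.covers(Point(b)):
        raise RerouteError(
            "travel endpoint lies inside the protected clearance; use zhop instead"
        )
    line = LineString([a, b])
    if not line.intersects(route_poly):
        return [b]
    ext = route_poly.exterior  # CCW by shapely convention
    total = ext.length
    # entry/exit = first/last intersection of the segment with the route boundary
    hits = line.intersection(ext)
    pts = []
    for g in getattr(hits, "geoms", [hits]):
        pts.extend(getattr(g, "coords", []))
    if len(pts) < 2:
        # grazing contact only; the straight segment is fine
        return [b]
    pts.sort(key=lambda p: line.project(Point(p)))
    entry, exit_ = pts[0], pts[-1]
    s1 = ext.project(Point(entry))
    s2 = ext.project(Point(exit_))
    forward = (s2 - s1) % total
    backward = total - forward
    if forward <= backward + 1e-12:  # tie -> CCW (forward along exterior)
        if s2 >= s1:
            walk = list(substring(ext, s1, s2).coords)
        else:
            walk = list(substring(ext, s1, total).coords) + list(substring(ext, 0.0, s2).coords)
    else:
        if s1 >= s2:
            walk = list(substring(ext, s1, s2).coords)
        else:
            walk = list(substring(ext, s1, 0.0).coords) + list(substring(ext, total, s2).coords)
    out: list[tuple[float, float]] = []
    for p in [entry, *walk, exit_, b]:
        if not out or math.hypot(p[0] - out[-1][0], p[1] - out[-1][1]) > 1e-9:
            out.append((p[0], p[1]))
    return out


def reroute_travel(
    c: GCodeCollection,
    region: ProtectedRegion,
    mode: str = "zhop",
    settings: PrintSettings = PrintSettings(),
    start: MachineState | None = None,
) -> GCodeCollection:
    """Replace hazardous travels so no travel crosses the region.

    ``zhop``: lift to the region's z ceiling, cross, lower at the destination
    (xy-projection of the endpoints preserved).  ``detour``: stay in plane and
    walk around the region boundary inflated by the nozzle diameter.  All
    extrude-moves pass through untouched; applying the repair twice equals
    applying it once.
    """
    if mode not in ("zhop", "detour"):
        raise ValueError(f"mode must be zhop or detour, got {mode!r}")
    if start is None:
        start = MachineState.at_origin()
    segments = simulate(c, start)
    violations = find_travel_violations(c, region, start)
    if not violations:
        return GCodeCollection(name=c.name, commands=list(c.commands))
    seg_by_cmd = {segments[i].command_index: segments[i] for i in violations}
    out = GCodeCollection(name=c.name)
    for idx, cmd in enumerate(c.commands):
        seg = seg_by_cmd.get(idx)
        if seg is None:
            out.append(cmd)
            continue
        feed = cmd.feed if cmd.feed is not None else settings.feed_travel
        if mode == "zhop":
            zc = region.z_ceiling
            out.append(
                MachineCommand(
                    CommandKind.TRAVEL, target=Position(seg.start.x, seg.start.y, zc), feed=feed
                )
            )
            out.append(
                MachineCommand(
                    CommandKind.TRAVEL, target=Position(seg.end.x, seg.end.y, zc), feed=feed
                )
            )
            out.append(
                MachineCommand(
                    CommandKind.TRAVEL,
                    target=Position(seg.end.x, seg.end.y, seg.end.z),
                    feed=feed,
                )
            )
        else:
            waypoints = _detour_points(seg, region, settings.nozzle_diameter, margin=0.05)
            # distribute z linearly along the detour arc length
            xy = [(seg.start.x, seg.start.y), *waypoints]
            lengths = [
                math.hypot(q[0] - p[0], q[1] - p[1]) for p, q in zip(xy[:-1], xy[1:])
            ]
            total = sum(lengths) or 1.0
            acc = 0.0
            for (x, y), L in zip(waypoints, lengths):
                acc += L
                z = seg.start.z + (acc / total) * (seg.end.z - seg.start.z)
                out.append(
                    MachineCommand(CommandKind.TRAVEL, target=Position(x, y, z), feed=feed)
                )
    return out


def move_control_point(
    c: GCodeCollection, command_index: int, new: Position
) -> GCodeCollection:
    """Relocate one move command's target; every other command is untouched."""
    if not 0 <= command_index < len(c.commands):
        raise IndexError(f"command index {command_index} out of range (0..{len(c.commands) - 1})")
    cmd = c.commands[command_index]
    if not cmd.is_move:
        raise ValueError(f"command {command_index} is a {cmd.kind.value}, not a move")
    commands = list(c.commands)
    commands[command_index] = replace(cmd, target=new)
    return GCodeCollection(name=c.name, commands=commands)
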