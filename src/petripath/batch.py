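"""Batch planner: distribute printed objects across a grid of Petri dishes.

Each dish position gets one object, translated to the dish centre and to the
dish's measured surface height (from a microswitch probe map); travel between
dishes happens at a safe height above the dish walls so the hot nozzle never
crosses a wall.  The print-by-print variation of dish surface heights is
around 0.2 mm — more than one layer — which is why per-dish z compensation
matters.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from .gcode import (
    CommandKind,
    GCodeCollection,
    MachineCommand,
    MachineState,
    Position,
    PrintSettings,
    ToolpathSegment,
    simulate,
    translate,
)


class BatchError(ValueError):
    """Invalid layout, assignment or probe data."""


class ProbeMapWarning(UserWarning):
    """Duplicate or missing probe entries (planner falls back gracefully)."""


@dataclass(frozen=True)
class DishLayout:
    """Geometry of the dish grid on the printer stage.

    ``start_height`` is the nominal z of the dish surfaces; the safe travel
    plane sits ``dish_wall_height + clearance`` above it.
    """

    rows: int
    columns: int
    row_distance: float = 40.0  # mm between dish centres along y
    column_distance: float = 40.0  # mm between dish centres along x
    start_height: float = 0.0  # mm, nominal dish surface z
    dish_diameter: float = 35.0  # mm
    dish_wall_height: float = 10.0  # mm
    clearance: float = 5.0  # mm above the wall for inter-dish travel

    def __post_init__(self):
        if self.rows < 1 or self.columns < 1:
            raise BatchError("layout needs at least one row and column")
        if self.row_distance <= self.dish_diameter or self.column_distance <= self.dish_diameter:
            raise BatchError("dish spacing must exceed the dish diameter")
        if not self.clearance > 0:
            raise BatchError("clearance must be > 0")

    def center(self, row: int, column: int) -> tuple[float, float]:
        if not (0 <= row < self.rows and 0 <= column < self.columns):
            raise BatchError(f"dish position ({row}, {column}) outside the layout")
        return (column * self.column_distance, row * self.row_distance)

    @property
    def safe_z(self) -> float:
        return self.start_height + self.dish_wall_height + self.clearance

    def dish_at(self, x: float, y: float) -> tuple[int, int] | None:
        """Dish whose footprint contains (x, y), or None."""
        c = round(x / self.column_distance)
        r = round(y / self.row_distance)
        if not (0 <= r < self.rows and 0 <= c < self.columns):
            return None
        cx, cy = c * self.column_distance, r * self.row_distance
        if math.hypot(x - cx, y - cy) <= self.dish_diameter / 2.0 + 1e-9:
            return (r, c)
        return None


@dataclass
class ProbeMap:
    """Measured surface z per dish position."""

    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def get(self, row: int, column: int, fallback: float) -> float:
        return self.entries.get((row, column), fallback)

    def __len__(self) -> int:
        return len(self.entries)


def load_probe_map(source: str | Path | TextIO) -> ProbeMap:
    """Load a probe map from CSV rows ``row,column,z_mm``.

    Blank lines and a ``row,column,...`` header are ignored.  Duplicate
    positions keep the last value and emit a :class:`ProbeMapWarning`.
    Non-numeric z raises :class:`BatchError`.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return load_probe_map(fh)
    pm = ProbeMap()
    for lineno, rec in enumerate(csv.reader(source), start=1):
        if not rec or not "".join(rec).strip():
            continue
        if rec[0].strip().lower() == "row":
            continue
        if len(rec) < 3:
            raise BatchError(f"probe row {lineno}: expected row,column,z")
        try:
            r, c, z = int(rec[0]), int(rec[1]), float(rec[2])
        except ValueError as exc:
            raise BatchError(f"probe row {lineno}: {exc}") from None
        if (r, c) in pm.entries:
            warnings.warn(
                f"duplicate probe entry for dish ({r}, {c}); keeping the last value",
                ProbeMapWarning,
                stacklevel=2,
            )
        pm.entries[(r, c)] = z
    return pm


@dataclass
class BatchAssignment:
    """Which object is printed in which dish."""

    mapping: dict[tuple[int, int], GCodeCollection] = field(default_factory=dict)

    def assign(self, row: int, column: int, obj: GCodeCollection) -> None:
        self.mapping[(row, column)] = obj


def object_bounding_radius(c: GCodeCollection) -> float:
    """Largest xy distance of any toolpath point from the object origin."""
    segs = simulate(c, MachineState.at_origin())
    r = 0.0
    for s in segs:
        if s.is_extrusion:
            r = max(r, math.hypot(s.start.x, s.start.y), math.hypot(s.end.x, s.end.y))
    return r


def _travel(x=None, y=None, z=None, feed=None) -> MachineCommand:
    return MachineCommand(CommandKind.TRAVEL, target=Position(x, y, z), feed=feed)


def plan_batch(
    a: BatchAssignment,
    layout: DishLayout,
    probe: ProbeMap | None = None,
    s: PrintSettings = PrintSettings(),
    nearest_neighbor: bool = False,
) -> GCodeCollection:
    """Assemble the full batch program.

    Preamble (home, heat-and-wait), then per dish: travel at the safe height
    to the dish centre, reset the extruder axis, run the object translated by
    (dish centre, probed surface z), lift back to the safe height.  Dishes are
    visited row-major by default; ``nearest_neighbor=True`` greedily shortens
    the tour instead.  A missing probe entry falls back to the layout's
    ``start_height`` with a warning.
    """
    probe = probe or ProbeMap()
    order = sorted(a.mapping)
    if nearest_neighbor and order:
        remaining = set(order)
        tour = [min(remaining)]
        remaining.discard(tour[0])
        while remaining:
            hx, hy = layout.center(*tour[-1])
            nxt = min(
                remaining,
                key=lambda rc: math.hypot(layout.center(*rc)[0] - hx, layout.center(*rc)[1] - hy),
            )
            tour.append(nxt)
            remaining.discard(nxt)
        order = tour

    out = GCodeCollection(name="batch")
    out.append(MachineCommand(CommandKind.COMMENT, text=f"batch of {len(order)} dishes"))
    out.append(MachineCommand(CommandKind.HOME))
    out.append(MachineCommand(CommandKind.SET_MODE, mode="absolute"))
    out.append(MachineCommand(CommandKind.WAIT_TEMP, temperature=s.temperature))
    dish_r = layout.dish_diameter / 2.0
    for r, c in order:
        obj = a.mapping[(r, c)]
        if object_bounding_radius(obj) > dish_r + 1e-9:
            raise BatchError(f"object {obj.name!r} does not fit inside a dish at ({r}, {c})")
        if (r, c) not in probe.entries:
            warnings.warn(
                f"no probe entry for dish ({r}, {c}); using start_height",
                ProbeMapWarning,
                stacklevel=2,
            )
        z_surf = probe.get(r, c, layout.start_height)
        cx, cy = layout.center(r, c)
        out.append(MachineCommand(CommandKind.COMMENT, text=f"dish {r},{c} surface z={z_surf:g}"))
        out.append(_travel(z=layout.safe_z, feed=s.feed_travel))
        out.append(_travel(x=cx, y=cy, feed=s.feed_travel))
        out.append(MachineCommand(CommandKind.RESET_E, e_value=0.0))
        out.extend(translate(obj, (cx, cy, z_surf)).commands)
        out.append(_travel(z=layout.safe_z, feed=s.feed_travel))
    out.append(MachineCommand(CommandKind.SET_TEMP, temperature=0.0))
    out.append(MachineCommand(CommandKind.COMMENT, text="end of batch"))
    return out


def check_safe_travel(
    c: GCodeCollection, layout: DishLayout, start: MachineState | None = None
) -> list[int]:
    """Indices of toolpath segments that travel between dishes too low.

    A segment is inter-dish unless both endpoints lie inside the same dish
    footprint; inter-dish travels must stay at or above the layout's safe
    height.  Extrusion segments and intra-dish moves are exempt.
    """
    segments = simulate(c, start)
    bad: list[int] = []
    threshold = layout.safe_z
    for i, seg in enumerate(segments):
        if seg.is_extrusion:
            continue
        d1 = layout.dish_at(seg.start.x, seg.start.y)
        d2 = layout.dish_at(seg.end.x, seg.end.y)
        if d1 is not None and d1 == d2:
            continue
        if min(seg.start.z, seg.end.z) < threshold - 1e-9:
            bad.append(i)
    return bad
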