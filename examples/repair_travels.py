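"""Find and repair travel moves that cross a protected culture region.

A travel move dragging over the area where cells will adhere can deposit
thin PLA threads on the culture surface.  This example builds a toolpath
whose travel crosses a circular protected region, then repairs it by z-hop
and by planar detour, showing that deposition is untouched either way.
"""

from petripath import (
    CommandKind,
    MachineState,
    Position,
    PrintSettings,
    ProtectedRegion,
    ToolpathBuilder,
    find_travel_violations,
    reroute_travel,
    simulate,
)

b = ToolpathBuilder(PrintSettings())
b.travel_to(Position(-10, 0.5, 1.0))
b.extrude_polyline([Position(-10, 0.5, 1.0), Position(-8, 0.5, 1.0)])
b.travel_to(Position(10, 0.5, 1.0))  # crosses the culture area!
b.extrude_polyline([Position(10, 0.5, 1.0), Position(12, 0.5, 1.0)])
path = b.collection

region = ProtectedRegion.circle(0.0, 0.0, 3.0, z_ceiling=8.0)
start = MachineState(position=Position(-10, 0.5, 1.0))

bad = find_travel_violations(path, region, start)
print(f"hazardous travel segments: {bad}")

for mode in ("zhop", "detour"):
    fixed = reroute_travel(path, region, mode=mode, start=start)
    after = find_travel_violations(fixed, region, start)
    extrudes_same = [c for c in fixed.commands if c.kind is CommandKind.EXTRUDE] == [
        c for c in path.commands if c.kind is CommandKind.EXTRUDE
    ]
    travel_len = sum(s.length for s in simulate(fixed, start) if not s.is_extrusion)
    print(f"{mode}: violations after repair = {len(after)}, "
          f"deposition unchanged = {extrudes_same}, travel length {travel_len:.1f} mm")
# zhop clears the region vertically (lift to the z ceiling, cross, lower);
# detour stays in plane and walks around the region inflated by the nozzle.
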