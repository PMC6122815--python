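"""Generate the stock culture-dish structures and report their geometry.

Builds each parametric structure with its defaults, simulates the toolpath
and prints the dimensions a microscope user cares about: ring diameter and
height, conical-well wall slope, well count, and the number of enclosed
mini-wells in the sorter grid.
"""

import math

from petripath import (
    ConicalWellSpec,
    GridSpec,
    MachineState,
    MultiWellDishSpec,
    PrintSettings,
    RingSpec,
    build_conical_well,
    build_ring,
    build_seven_well_dish,
    build_sorter_grid,
    count_enclosed_cells,
    simulate,
    total_extrusion,
)

settings = PrintSettings()

ring = build_ring(RingSpec(), settings)
segs = simulate(ring, MachineState.at_origin())
radius = max(math.hypot(s.end.x, s.end.y) for s in segs if s.is_extrusion)
layers = {round(s.end.z, 9) for s in segs if s.is_extrusion}
print(f"ring: diameter {2 * radius:.3f} mm, {len(layers)} layers, "
      f"top z {max(layers):.2f} mm, filament used {total_extrusion(segs):.2f} mm")

spec = ConicalWellSpec()
well = build_conical_well(spec, settings)
print(f"conical well: base radius {spec.base_radius:.2f} mm grows to "
      f"{spec.top_radius:.3f} mm over the {spec.cone_height} mm cone "
      f"(apex angle {spec.apex_angle} deg, wall slope {spec.apex_angle / 2} deg from vertical)")

dish = build_seven_well_dish(MultiWellDishSpec(), settings)
dsegs = simulate(dish, MachineState.at_origin())
extent = max(math.hypot(s.end.x, s.end.y) for s in dsegs if s.is_extrusion)
print(f"seven-well dish: 7 wells, max radial extent {extent:.2f} mm "
      f"(fits the 17.5 mm dish radius)")

grid = build_sorter_grid(GridSpec(), settings)
print(f"sorter grid: {count_enclosed_cells(grid)} enclosed 1 mm^2 mini-wells "
      f"in a single printed layer")

# The cell counts and radial extents above are the printable-geometry
# counterparts of what calipers and a microscope would measure on the dish.
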