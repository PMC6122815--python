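import math

import numpy as np
import pytest
from scipy import ndimage

from petripath import MachineState, PrintSettings, Position, simulate


@pytest.fixture(scope="session")
def settings():
    return PrintSettings()


@pytest.fixture()
def origin_state():
    return MachineState.at_origin()


def toolpath(collection, start=None):
    """Simulated toolpath from the machine origin (test shorthand)."""
    return simulate(collection, start or MachineState.at_origin())


def extrusion_segments(collection, start=None):
    return [s for s in toolpath(collection, start) if s.is_extrusion]


def raster_enclosed_regions(segments, px_per_mm=20):
    """Independent flood-fill oracle for bounded faces of a planar lattice.

    Rasterizes the xy extrusion segments onto a padded boolean grid and counts
    connected open regions that do not touch the border (4-connectivity).
    """
    xs = [v for s in segments for v in (s.start.x, s.end.x)]
    ys = [v for s in segments for v in (s.start.y, s.end.y)]
    x0, y0 = min(xs), min(ys)
    w = int(math.ceil((max(xs) - x0) * px_per_mm)) + 1
    h = int(math.ceil((max(ys) - y0) * px_per_mm)) + 1
    pad = 3
    wall = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    for s in segments:
        n = max(2, int(s.xy_length * px_per_mm * 4) + 1)
        for t in np.linspace(0.0, 1.0, n):
            x = s.start.x + t * (s.end.x - s.start.x)
            y = s.start.y + t * (s.end.y - s.start.y)
            wall[int(round((y - y0) * px_per_mm)) + pad, int(round((x - x0) * px_per_mm)) + pad] = True
    labels, n = ndimage.label(~wall)  # default structure = 4-connectivity
    border = set(labels[0, :]) | set(labels[-1, :]) | set(labels[:, 0]) | set(labels[:, -1])
    return sum(1 for lab in range(1, n + 1) if lab not in border)


def layer_radii(collection):
    """Map layer z -> max radial extent of extrusion endpoints about (0,0)."""
    radii: dict[float, float] = {}
    for s in extrusion_segments(collection):
        z = round(s.end.z, 9)
        radii[z] = max(radii.get(z, 0.0), math.hypot(s.end.x, s.end.y), math.hypot(s.start.x, s.start.y))
    return radii


def square_polyline(x0, y0, size, z):
    return [
        Position(x0, y0, z),
        Position(x0 + size, y0, z),
        Position(x0 + size, y0 + size, z),
        Position(x0, y0 + size, z),
        Position(x0, y0, z),
    ]
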