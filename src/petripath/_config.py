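"""Structured-text (YAML) configuration loading for the CLI.

Structure spec files name a kind plus parameters, e.g.::

    kind: ring
    diameter: 6.0
    height: 1.8

Layout files carry the dish-grid geometry, assignment files map ``"r,c"``
positions to structure spec files, and print settings may be overridden with
a ``settings:`` block in any of them.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .batch import BatchAssignment, DishLayout
from .gcode import GCodeCollection, PrintSettings
from .structures import (
    ConicalWellSpec,
    DoubleRingSpec,
    GridSpec,
    MultiWellDishSpec,
    RingSpec,
    build_conical_well,
    build_double_ring,
    build_ring,
    build_seven_well_dish,
    build_sorter_grid,
)

_BUILDERS = {
    "ring": (RingSpec, build_ring),
    "conical_well": (ConicalWellSpec, build_conical_well),
    "seven_well": (MultiWellDishSpec, build_seven_well_dish),
    "double_ring": (DoubleRingSpec, build_double_ring),
    "sorter_grid": (GridSpec, build_sorter_grid),
}


def load_settings(data: dict | None) -> PrintSettings:
    return PrintSettings(**(data or {}))


def _coerce(cls, data: dict):
    if cls is MultiWellDishSpec and "well" in data:
        data = {**data, "well": ConicalWellSpec(**data["well"])}
    if cls is DoubleRingSpec:
        data = {
            **data,
            **{k: RingSpec(**v) for k, v in data.items() if k in ("inner", "outer")},
        }
    if cls is RingSpec and "center" in data:
        data = {**data, "center": tuple(data["center"])}
    return cls(**data)


def build_structure_from_file(path: str | Path) -> tuple[GCodeCollection, PrintSettings]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kind = data.pop("kind", None)
    if kind not in _BUILDERS:
        raise ValueError(f"unknown structure kind {kind!r}; choose from {sorted(_BUILDERS)}")
    settings = load_settings(data.pop("settings", None))
    cls, builder = _BUILDERS[kind]
    spec = _coerce(cls, data)
    return builder(spec, settings), settings


def load_layout(path: str | Path) -> tuple[DishLayout, PrintSettings]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    settings = load_settings(data.pop("settings", None))
    return DishLayout(**data), settings


def load_assignment(path: str | Path) -> BatchAssignment:
    """Assignment file: mapping from "row,column" keys to structure spec files
    (relative paths resolved against the assignment file's directory)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    a = BatchAssignment()
    for key, spec_file in data.items():
        r, c = (int(v) for v in str(key).split(","))
        spec_path = Path(spec_file)
        if not spec_path.is_absolute():
            spec_path = path.parent / spec_path
        obj, _ = build_structure_from_file(spec_path)
        a.assign(r, c, obj)
    return a
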