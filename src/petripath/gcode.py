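"""In-memory model, parser, serializer and kinematic simulator for g-code.

The dialect is the Marlin/RepRap subset spoken by an Ultimaker Original:
``G0`` travel, ``G1`` move/extrude, ``G4`` dwell, ``G28`` home, ``G90``/``G91``
positioning mode, ``G92`` extruder reset, ``M104``/``M109`` hotend temperature,
``;`` comments.  The extruder axis is absolute (M82 convention) and is reset
explicitly with ``G92 E0`` between objects; a negative extruder delta
(retraction) is classified as non-depositing.

Simulation resolves every move against a running :class:`MachineState` and
yields :class:`ToolpathSegment` objects — the universal test surface for the
rest of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence


class GCodeError(Exception):
    """Base class for g-code model errors."""


class GCodeParseError(GCodeError):
    """Raised on a malformed g-code line; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class SimulationError(GCodeError):
    """Raised when a move is issued before the position is fully defined."""


class TranslateError(GCodeError):
    """Raised when a collection cannot be rigidly translated."""


class CommandKind(str, Enum):
    TRAVEL = "travel-move"
    EXTRUDE = "extrude-move"
    SET_TEMP = "set-temperature"
    WAIT_TEMP = "wait-temperature"
    HOME = "home-axes"
    SET_MODE = "set-mode"
    RESET_E = "reset-extruder"
    DWELL = "dwell"
    COMMENT = "comment"


MOVE_KINDS = (CommandKind.TRAVEL, CommandKind.EXTRUDE)


@dataclass(frozen=True)
class Position:
    """Machine Cartesian coordinates in mm; ``None`` means "unchanged"."""

    x: float | None = None
    y: float | None = None
    z: float | None = None

    def __post_init__(self):
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    @property
    def is_full(self) -> bool:
        return self.x is not None and self.y is not None and self.z is not None

    def shifted(self, dx: float, dy: float, dz: float) -> "Position":
        """Shift the *present* components; absent ones stay absent."""
        return Position(
            None if self.x is None else self.x + dx,
            None if self.y is None else self.y + dy,
            None if self.z is None else self.z + dz,
        )

    def distance_to(self, other: "Position") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))


@dataclass(frozen=True)
class MachineCommand:
    kind: CommandKind
    target: Position | None = None
    e_value: float | None = None  # absolute extruder axis, filament-mm
    feed: float | None = None  # mm/min
    temperature: float | None = None  # degC
    text: str = ""
    mode: str | None = None  # "absolute" | "relative" for SET_MODE
    seconds: float | None = None  # dwell time

    def __post_init__(self):
        if self.feed is not None and not self.feed > 0:
            raise ValueError(f"feed must be > 0, got {self.feed}")
        if self.temperature is not None and not 0.0 <= self.temperature <= 300.0:
            raise ValueError(f"temperature out of [0, 300] degC: {self.temperature}")
        if self.kind is CommandKind.EXTRUDE and self.e_value is None:
            raise ValueError("extrude-move must carry an e_value")
        if self.kind is CommandKind.SET_MODE and self.mode not in ("absolute", "relative"):
            raise ValueError(f"set-mode requires mode absolute|relative, got {self.mode!r}")

    @property
    def is_move(self) -> bool:
        return self.kind in MOVE_KINDS


@dataclass
class GCodeCollection:
    """An ordered, executable sequence of machine commands."""

    name: str = "object"
    commands: list[MachineCommand] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.commands)

    def __iter__(self):
        return iter(self.commands)

    def append(self, cmd: MachineCommand) -> None:
        self.commands.append(cmd)

    def extend(self, cmds: Iterable[MachineCommand]) -> None:
        self.commands.extend(cmds)


@dataclass
class MachineState:
    """Fully resolved machine state used to interpret relative moves."""

    position: Position = field(default_factory=Position)
    mode: str = "absolute"
    e_accum: float = 0.0
    feed: float | None = None
    temperature: float = 25.0

    @classmethod
    def at_origin(cls) -> "MachineState":
        return cls(position=Position(0.0, 0.0, 0.0))


@dataclass(frozen=True)
class ToolpathSegment:
    """One simulated machine movement."""

    start: Position
    end: Position
    is_extrusion: bool
    e_delta: float  # filament-mm (negative = retraction)
    feed: float | None = None
    command_index: int | None = None  # index of the generating command

    @property
    def length(self) -> float:
        return self.start.distance_to(self.end)

    @property
    def xy_length(self) -> float:
        return math.hypot(self.end.x - self.start.x, self.end.y - self.start.y)


@dataclass(frozen=True)
class PrintSettings:
    """Machine/material settings for PLA printing into culture dishes.

    Defaults follow the Ultimaker Original setup this package targets:
    230 degC hotend, 0.4 mm nozzle, 300-500 mm/min print feed,
    0.027-0.041 filament-mm extruded per path-mm, 0.12 mm layers.
    """

    temperature: float = 230.0
    feed_print: float = 400.0
    feed_travel: float = 1500.0
    extrusion_rate: float = 0.034  # filament-mm per path-mm
    nozzle_diameter: float = 0.4
    layer_height: float = 0.12

    def __post_init__(self):
        for name in (
            "temperature",
            "feed_print",
            "feed_travel",
            "extrusion_rate",
            "nozzle_diameter",
            "layer_height",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# parsing

_FMT = "{:.9f}"  # fixed-point, locale independent; half-ulp 5e-10 mm keeps
# parse/serialize round trips within the 1e-9 mm toolpath equality bound


def _fmt(v: float) -> str:
    return _FMT.format(v)


def _parse_words(body: str, lineno: int) -> dict[str, float]:
    words: dict[str, float] = {}
    for token in body.split():
        letter = token[0].upper()
        try:
            value = float(token[1:])
        except ValueError:
            raise GCodeParseError(f"malformed numeric field {token!r}", lineno) from None
        words[letter] = value
    return words


def _target_from_words(words: dict[str, float]) -> Position:
    return Position(words.get("X"), words.get("Y"), words.get("Z"))


def parse(text: str, name: str = "parsed") -> GCodeCollection:
    """Parse g-code text into a :class:`GCodeCollection`.

    Recognized words map one-to-one onto commands; unrecognized lines are
    preserved, in order, as comments.  A malformed numeric field raises
    :class:`GCodeParseError` with the offending line number.
    """
    out = GCodeCollection(name=name)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        code, _, comment = line.partition(";")
        code = code.strip()
        if not code:
            out.append(MachineCommand(CommandKind.COMMENT, text=comment.strip()))
            continue
        words = _parse_words(code, lineno)
        head = code.split()[0].upper()
        if head in ("G0", "G00"):
            out.append(
                MachineCommand(
                    CommandKind.TRAVEL, target=_target_from_words(words), feed=words.get("F")
                )
            )
        elif head in ("G1", "G01"):
            kind = CommandKind.EXTRUDE if "E" in words else CommandKind.TRAVEL
            out.append(
                MachineCommand(
                    kind,
                    target=_target_from_words(words),
                    e_value=words.get("E"),
                    feed=words.get("F"),
                )
            )
        elif head == "G4":
            seconds = words.get("S", words.get("P", 0.0) / 1000.0)
            out.append(MachineCommand(CommandKind.DWELL, seconds=seconds))
        elif head == "G28":
            out.append(MachineCommand(CommandKind.HOME))
        elif head == "G90":
            out.append(MachineCommand(CommandKind.SET_MODE, mode="absolute"))
        elif head == "G91":
            out.append(MachineCommand(CommandKind.SET_MODE, mode="relative"))
        elif head == "G92":
            out.append(MachineCommand(CommandKind.RESET_E, e_value=words.get("E", 0.0)))
        elif head == "M104":
            out.append(MachineCommand(CommandKind.SET_TEMP, temperature=words.get("S")))
        elif head == "M109":
            out.append(MachineCommand(CommandKind.WAIT_TEMP, temperature=words.get("S")))
        else:
            out.append(MachineCommand(CommandKind.COMMENT, text=line))
    return out


# ---------------------------------------------------------------------------
# serialization


def _emit_move(cmd: MachineCommand) -> str:
    head = "G0" if cmd.kind is CommandKind.TRAVEL else "G1"
    parts = [head]
    t = cmd.target or Position()
    for letter, v in (("X", t.x), ("Y", t.y), ("Z", t.z)):
        if v is not None:
            parts.append(f"{letter}{_fmt(v)}")
    if cmd.e_value is not None and cmd.kind is CommandKind.EXTRUDE:
        parts.append(f"E{_fmt(cmd.e_value)}")
    if cmd.feed is not None:
        parts.append(f"F{_fmt(cmd.feed)}")
    return " ".join(parts)


def serialize(
    c: GCodeCollection,
    settings: PrintSettings | None = None,
    preamble: Sequence[str] = (),
    postamble: Sequence[str] = (),
) -> str:
    """Serialize a collection to g-code text.

    Deterministic: equal inputs give byte-identical output.  Coordinates are
    written fixed-point with 5 decimals.  ``preamble``/``postamble`` are
    literal lines framing the command block (empty by default).
    """
    lines = list(preamble)
    for cmd in c.commands:
        if cmd.kind in MOVE_KINDS:
            lines.append(_emit_move(cmd))
        elif cmd.kind is CommandKind.DWELL:
            lines.append(f"G4 S{_fmt(cmd.seconds or 0.0)}")
        elif cmd.kind is CommandKind.HOME:
            lines.append("G28")
        elif cmd.kind is CommandKind.SET_MODE:
            lines.append("G90" if cmd.mode == "absolute" else "G91")
        elif cmd.kind is CommandKind.RESET_E:
            lines.append(f"G92 E{_fmt(cmd.e_value or 0.0)}")
        elif cmd.kind is CommandKind.SET_TEMP:
            lines.append(f"M104 S{_fmt(cmd.temperature or 0.0)}")
        elif cmd.kind is CommandKind.WAIT_TEMP:
            lines.append(f"M109 S{_fmt(cmd.temperature or 0.0)}")
        elif cmd.kind is CommandKind.COMMENT:
            lines.append(f"; {cmd.text}" if cmd.text else ";")
    lines.extend(postamble)
    return "\n".join(lines) + "\n" if lines else ""


# ---------------------------------------------------------------------------
# simulation


def simulate(c: GCodeCollection, start: MachineState | None = None) -> list[ToolpathSegment]:
    """Resolve a command sequence into a continuous toolpath.

    ``start=None`` begins with an undefined position (absolute mode, E=0);
    homing or a first fully-specified absolute move then defines it.  A
    fully-specified absolute move from an undefined position produces no
    segment — there is no known start point — while a partially specified one
    raises :class:`SimulationError`.
    """
    if start is None:
        st = MachineState()
    else:
        st = MachineState(
            position=start.position,
            mode=start.mode,
            e_accum=start.e_accum,
            feed=start.feed,
            temperature=start.temperature,
        )
    segments: list[ToolpathSegment] = []
    for index, cmd in enumerate(c.commands):
        if cmd.kind in MOVE_KINDS:
            if cmd.feed is not None:
                st.feed = cmd.feed
            t = cmd.target or Position()
            if st.mode == "relative":
                if not st.position.is_full:
                    raise SimulationError(
                        f"command {index}: relative move before position is defined"
                    )
                new = Position(
                    st.position.x + (t.x or 0.0),
                    st.position.y + (t.y or 0.0),
                    st.position.z + (t.z or 0.0),
                )
            else:
                new = Position(
                    t.x if t.x is not None else st.position.x,
                    t.y if t.y is not None else st.position.y,
                    t.z if t.z is not None else st.position.z,
                )
                if not new.is_full:
                    raise SimulationError(
                        f"command {index}: move before position is fully defined"
                    )
            e_delta = 0.0
            if cmd.kind is CommandKind.EXTRUDE and cmd.e_value is not None:
                e_delta = cmd.e_value - st.e_accum
                st.e_accum = cmd.e_value
            if st.position.is_full:
                segments.append(
                    ToolpathSegment(
                        start=st.position,
                        end=new,
                        is_extrusion=e_delta > 0.0,
                        e_delta=e_delta,
                        feed=st.feed,
                        command_index=index,
                    )
                )
            st.position = new
        elif cmd.kind is CommandKind.HOME:
            st.position = Position(0.0, 0.0, 0.0)
            st.mode = "absolute"
        elif cmd.kind is CommandKind.SET_MODE:
            st.mode = cmd.mode
        elif cmd.kind is CommandKind.RESET_E:
            st.e_accum = cmd.e_value or 0.0
        elif cmd.kind in (CommandKind.SET_TEMP, CommandKind.WAIT_TEMP):
            if cmd.temperature is not None:
                st.temperature = cmd.temperature
    return segments


def total_extrusion(segments: Iterable[ToolpathSegment]) -> float:
    """Filament deposited (sum of positive e_delta) over a toolpath."""
    return sum(s.e_delta for s in segments if s.e_delta > 0)


def toolpaths_allclose(
    a: Sequence[ToolpathSegment], b: Sequence[ToolpathSegment], tol: float = 1e-9
) -> bool:
    """Segment-by-segment positional equality within ``tol`` mm."""
    if len(a) != len(b):
        return False
    for sa, sb in zip(a, b):
        if sa.start.distance_to(sb.start) > tol or sa.end.distance_to(sb.end) > tol:
            return False
        if sa.is_extrusion != sb.is_extrusion:
            return False
    return True


# ---------------------------------------------------------------------------
# rigid translation


def translate(c: GCodeCollection, d: Position | tuple[float, float, float]) -> GCodeCollection:
    """Shift every move target by the offset ``d`` (rigid translation).

    The collection must be purely absolute: an offset is ambiguous for
    relative-mode programs, so any ``G91`` raises :class:`TranslateError`.
    Extruder values, feeds and temperatures are untouched and the command
    count is preserved.
    """
    if isinstance(d, Position):
        dx, dy, dz = d.x or 0.0, d.y or 0.0, d.z or 0.0
    else:
        dx, dy, dz = d
    for cmd in c.commands:
        if cmd.kind is CommandKind.SET_MODE and cmd.mode == "relative":
            raise TranslateError("cannot translate a relative-mode collection")
    out = GCodeCollection(name=c.name)
    for cmd in c.commands:
        if cmd.kind in MOVE_KINDS and cmd.target is not None:
            out.append(replace(cmd, target=cmd.target.shifted(dx, dy, dz)))
        else:
            out.append(cmd)
    return out
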