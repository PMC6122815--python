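"""g-code model: parsing, serialization, simulation and rigid translation."""

import math

import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from petripath import (
    CommandKind,
    GCodeCollection,
    GCodeParseError,
    MachineCommand,
    MachineState,
    Position,
    PrintSettings,
    SimulationError,
    TranslateError,
    parse,
    serialize,
    simulate,
    toolpaths_allclose,
    total_extrusion,
    translate,
)
from petripath.structures import RingSpec, build_ring

from conftest import toolpath


class TestParse:
    def test_extrude_move_words(self):
        c = parse("G1 X10 Y5 E0.5 F300")
        (cmd,) = c.commands
        assert cmd.kind is CommandKind.EXTRUDE
        assert (cmd.target.x, cmd.target.y, cmd.target.z) == (10.0, 5.0, None)
        assert cmd.e_value == 0.5
        assert cmd.feed == 300.0

    def test_wait_temperature(self):
        (cmd,) = parse("M109 S230").commands
        assert cmd.kind is CommandKind.WAIT_TEMP
        assert cmd.temperature == 230.0

    @pytest.mark.parametrize(
        "line,kind",
        [
            ("G0 X1 Y2", CommandKind.TRAVEL),
            ("G1 X1 Y2", CommandKind.TRAVEL),  # no E word -> non-depositing
            ("G4 S2", CommandKind.DWELL),
            ("G28", CommandKind.HOME),
            ("G90", CommandKind.SET_MODE),
            ("G91", CommandKind.SET_MODE),
            ("G92 E0", CommandKind.RESET_E),
            ("M104 S200", CommandKind.SET_TEMP),
            ("; hello", CommandKind.COMMENT),
            ("M82", CommandKind.COMMENT),  # unknown word preserved as comment
        ],
    )
    def test_line_to_command_kind(self, line, kind):
        (cmd,) = parse(line).commands
        assert cmd.kind is kind

    def test_order_preserved_one_command_per_line(self):
        text = "G28\nG90\nG1 X1 E0.1\nM104 S0\n"
        kinds = [c.kind for c in parse(text).commands]
        assert kinds == [
            CommandKind.HOME,
            CommandKind.SET_MODE,
            CommandKind.EXTRUDE,
            CommandKind.SET_TEMP,
        ]

    def test_malformed_numeric_reports_line_number(self):
        with pytest.raises(GCodeParseError, match="line 2"):
            parse("G28\nG1 Xabc\n")


class TestSerialize:
    def test_empty_collection_emits_only_framing(self):
        assert serialize(GCodeCollection()) == ""
        out = serialize(GCodeCollection(), preamble=["; start"], postamble=["; end"])
        assert out == "; start\n; end\n"

    def test_extrude_move_carries_all_words(self):
        cmd = MachineCommand(
            CommandKind.EXTRUDE, target=Position(10, 5, 0.2), e_value=0.5, feed=300
        )
        line = serialize(GCodeCollection(commands=[cmd])).strip()
        assert line.startswith("G1 ")
        for word in ("X10.", "Y5.", "Z0.2", "E0.5", "F300."):
            assert word in line

    def test_serialize_parse_serialize_is_byte_identical(self):
        ring = build_ring(RingSpec())
        once = serialize(ring)
        twice = serialize(parse(once))
        assert once == twice

    def test_round_trip_preserves_toolpath(self):
        ring = build_ring(RingSpec())
        assert toolpaths_allclose(toolpath(ring), toolpath(parse(serialize(ring))), tol=1e-9)


class TestSimulate:
    def test_relative_moves_accumulate(self):
        c = parse("G28\nG91\nG0 X5\nG0 X5\n")
        segs = simulate(c)
        assert segs[-1].end.x == pytest.approx(10.0)

    def test_travel_then_extrude_flags(self, origin_state):
        c = parse("G0 X1 Y0 Z0\nG1 X2 Y0 Z0 E0.1\n")
        segs = simulate(c, origin_state)
        assert [s.is_extrusion for s in segs] == [False, True]

    def test_move_before_position_defined_raises(self):
        with pytest.raises(SimulationError):
            simulate(parse("G0 X5\n"))  # partial target, unknown start

    def test_relative_and_absolute_conversion_agree(self, origin_state):
        rel = parse("G91\nG0 X1 Y1\nG1 X1 Y0 E0.1\nG0 X0 Y-1\n")
        ab = parse("G90\nG0 X1 Y1 Z0\nG1 X2 Y1 Z0 E0.1\nG0 X2 Y0 Z0\n")
        assert toolpaths_allclose(simulate(rel, origin_state), simulate(ab, origin_state))

    def test_e_reset_splits_extrusion_accounting(self, origin_state):
        c = parse("G1 X10 Y0 Z0 E1\nG92 E0\nG1 X20 Y0 Z0 E1\n")
        segs = simulate(c, origin_state)
        assert [s.e_delta for s in segs] == [1.0, 1.0]

    def test_retraction_is_not_extrusion(self, origin_state):
        c = parse("G1 X10 Y0 Z0 E1\nG1 X10 Y0 Z0 E0.5\n")
        segs = simulate(c, origin_state)
        assert segs[1].e_delta == -0.5 and not segs[1].is_extrusion

    def test_segments_are_continuous(self):
        ring = build_ring(RingSpec())
        segs = toolpath(ring)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end.distance_to(b.start) <= 1e-9

    def test_extrusion_matches_rate_times_length(self):
        s = PrintSettings()
        ring = build_ring(RingSpec(), s)
        segs = toolpath(ring)
        length = sum(seg.length for seg in segs if seg.is_extrusion)
        assert total_extrusion(segs) == pytest.approx(s.extrusion_rate * length, rel=1e-9)


class TestTranslate:
    def test_zero_offset_is_identity(self):
        ring = build_ring(RingSpec())
        assert toolpaths_allclose(toolpath(translate(ring, (0, 0, 0))), toolpath(ring))

    def test_bounding_box_shifts_linearly(self):
        ring = build_ring(RingSpec())
        moved = translate(ring, (3.0, -2.0, 1.5))
        pts = [s.end for s in toolpath(ring)]
        mpts = [s.end for s in toolpath(translate(ring, (3.0, -2.0, 1.5)))]
        assert len(moved) == len(ring)
        assert max(p.x for p in mpts) == pytest.approx(max(p.x for p in pts) + 3.0)
        assert min(p.y for p in mpts) == pytest.approx(min(p.y for p in pts) - 2.0)
        assert max(p.z for p in mpts) == pytest.approx(max(p.z for p in pts) + 1.5)

    def test_translation_is_an_isometry(self):
        ring = build_ring(RingSpec())
        # skip the approach segment from the (untranslated) start state
        a = toolpath(ring)[1:]
        b = toolpath(translate(ring, (7.5, -1.25, 0.4)))[1:]
        for sa, sb in zip(a, b):
            assert sa.length == pytest.approx(sb.length, abs=1e-9)
        # inter-point distances across segments too
        for i in range(0, len(a) - 5, 7):
            assert a[i].end.distance_to(a[i + 5].end) == pytest.approx(
                b[i].end.distance_to(b[i + 5].end), abs=1e-9
            )

    def test_e_and_feed_untouched(self):
        ring = build_ring(RingSpec())
        moved = translate(ring, (1, 2, 3))
        for orig, m in zip(ring.commands, moved.commands):
            assert orig.e_value == m.e_value and orig.feed == m.feed

    def test_relative_collection_rejected(self):
        with pytest.raises(TranslateError):
            translate(parse("G91\nG0 X1\n"), (1, 0, 0))


_coord = st.floats(min_value=-100, max_value=100, allow_nan=False, allow_infinity=False)


@hyp_settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(_coord, _coord, _coord, st.booleans()), min_size=1, max_size=20))
def test_round_trip_toolpath_equality_random_programs(moves):
    """parse(serialize(C)) preserves the simulated toolpath for arbitrary
    absolute-move programs, including mixed travel/extrusion."""
    c = GCodeCollection()
    e = 0.0
    for x, y, z, ext in moves:
        if ext:
            e += 0.1
            c.append(
                MachineCommand(CommandKind.EXTRUDE, target=Position(x, y, z), e_value=e)
            )
        else:
            c.append(MachineCommand(CommandKind.TRAVEL, target=Position(x, y, z)))
    start = MachineState.at_origin()
    assert toolpaths_allclose(
        simulate(parse(serialize(c)), start), simulate(c, start), tol=1e-9
    )
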