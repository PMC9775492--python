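"""Tests for the fluidic chip model: gating, routing, separation, degas,
mixing, conservation and species integrity."""

import math

import pytest
from hypothesis import given, strategies as st

from valveflow.chip import (ChipError, ChipModel, ContaminationError,
                            FluidNode, MicrovalveState, build_glucose_chip,
                            degas_update, flow_update, load_blood,
                            mixing_update, reachable, valve_is_closed)

#: valve control pressures during the sequestered mixing phase (step vi):
#: everything activated except V3
MIXING_VALVES = {"V1": 25.0, "V2": 25.0, "V3": 0.0, "V4": 25.0,
                 "V5": 25.0, "V6": 25.0}


def brute_force_reachable(chip, valve_pressures, a, b):
    """Independent DFS oracle over the open edges (no graph library)."""
    adj = {}
    for u, v, d in chip.graph.edges(data=True):
        valve = d["valve"]
        is_open = valve is None or valve_pressures.get(valve, 0.0) < \
            chip.close_threshold
        if is_open:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
    stack, seen = [a], {a}
    while stack:
        node = stack.pop()
        if node == b:
            return True
        for nxt in adj.get(node, []):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


class TestValveGating:
    @pytest.mark.parametrize("pressure,closed", [
        (25.0, True),    # pressurized above threshold: activated/closed
        (0.0, False),    # atmospheric: deactivated/open
        (20.0, True),    # boundary: >= convention
        (19.99, False),
    ])
    def test_close_threshold(self, pressure, closed):
        assert valve_is_closed(MicrovalveState("V1", pressure)) is closed


class TestReachability:
    def test_all_open_graph_fully_connected(self, glucose_chip):
        open_vp = {v: 0.0 for v in MIXING_VALVES}
        nodes = [n.id for n in glucose_chip.nodes()]
        for other in nodes[1:]:
            assert reachable(glucose_chip, open_vp, nodes[0], other)

    def test_single_closed_valve_blocks_edge(self):
        chip = ChipModel()
        chip.add_node(FluidNode("a", "inlet", 100.0))
        chip.add_node(FluidNode("b", "outlet", 100.0))
        chip.add_edge("a", "b", valve="V1")
        assert reachable(chip, {"V1": 0.0}, "a", "b")
        assert not reachable(chip, {"V1": 25.0}, "a", "b")

    def test_unknown_node_errors(self, glucose_chip):
        with pytest.raises(ChipError):
            reachable(glucose_chip, {}, "psm", "nowhere")

    def test_mixing_config_isolates_units_vs_dfs_oracle(self, glucose_chip):
        """Under the sequestered mixing configuration no chamber of one
        unit reaches any chamber of another (exhaustive pair check,
        verified against an independent DFS)."""
        units = glucose_chip.analysis_units
        for ua, (sa, ra) in units.items():
            for ub, (sb, rb) in units.items():
                for a in (sa, ra):
                    for b in (sb, rb):
                        got = reachable(glucose_chip, MIXING_VALVES, a, b)
                        ref = brute_force_reachable(glucose_chip,
                                                    MIXING_VALVES, a, b)
                        assert got == ref
                        if ua != ub:
                            assert not got, f"{a} reaches {b}"

    def test_within_unit_mixing_path_open_when_v5_releases(self, glucose_chip):
        vp = dict(MIXING_VALVES, V5=0.0)
        for s, r in glucose_chip.analysis_units.values():
            assert reachable(glucose_chip, vp, s, r)


class TestFlowUpdate:
    def test_no_differential_no_change(self, separation_chip):
        load_blood(separation_chip, 8000.0)
        before = {n.id: dict(n.contents) for n in separation_chip.nodes()}
        flow_update(separation_chip, {"psm": 0.0, "vacuum_outlet": 0.0},
                    {}, 1.0)
        after = {n.id: dict(n.contents) for n in separation_chip.nodes()}
        assert before == after

    def test_plasma_separation_retains_cells(self, separation_chip):
        """8 uL whole blood at hematocrit 0.45, -1 psig for 120 s: the
        collection channel holds at most its 1 uL capacity of plasma and
        zero blood cells."""
        load_blood(separation_chip, 8000.0, 0.45)
        ports = {"psm": 0.0, "vacuum_outlet": -1.0}
        for _ in range(1200):
            flow_update(separation_chip, ports, {}, 0.1)
        col = separation_chip.node("collection")
        assert col.volume("plasma") <= 1000.0 + 1e-6
        assert col.volume("blood_cells") == 0.0
        assert separation_chip.node("vacuum_outlet").volume("blood_cells") == 0.0
        assert separation_chip.node("psm").volume("blood_cells") == \
            pytest.approx(3600.0)

    def test_chamber_fill_reaches_95_percent(self, glucose_chip):
        """Plasma pull then chamber fill: every sample and reagent chamber
        ends at >= 95% liquid fill."""
        load_blood(glucose_chip, 8000.0, 0.45)
        pull_vp = {"V1": 0.0, "V2": 25.0, "V3": 25.0, "V4": 25.0,
                   "V5": 25.0, "V6": 25.0}
        for _ in range(300):
            flow_update(glucose_chip, {"psm": 0.0, "vacuum_outlet": -1.0},
                        pull_vp, 0.1)
        fill_vp = {"V1": 25.0, "V2": 0.0, "V3": 0.0, "V4": 0.0,
                   "V5": 25.0, "V6": 0.0}
        ports = {"air_inlet": 1.0, "reagent_inlet": 1.0,
                 "vacuum_outlet": 0.0, "o1": 0.0, "o2": 0.0, "o3": 0.0,
                 "o4": 0.0}
        for _ in range(200):
            flow_update(glucose_chip, ports, fill_vp, 0.1)
        for _, (s, r) in glucose_chip.analysis_units.items():
            for cid in (s, r):
                node = glucose_chip.node(cid)
                assert node.liquid() / node.capacity >= 0.95

    def test_liquid_volume_conserved(self, glucose_chip):
        load_blood(glucose_chip, 8000.0, 0.45)
        total0 = glucose_chip.total_liquid()
        vp = {"V1": 0.0, "V2": 0.0, "V3": 0.0, "V4": 0.0, "V5": 0.0,
              "V6": 25.0}
        for _ in range(500):
            flow_update(glucose_chip, {"psm": 0.0, "vacuum_outlet": -1.0},
                        vp, 0.1)
        assert glucose_chip.total_liquid() == pytest.approx(total0)

    def test_dt_must_be_positive(self, separation_chip):
        with pytest.raises(ChipError):
            flow_update(separation_chip, {"psm": 0.0}, {}, 0.0)


@given(valve_seq=st.lists(
    st.tuples(st.sampled_from(["V1", "V2", "V3", "V4", "V5", "V6"]),
              st.sampled_from([0.0, 25.0])),
    min_size=1, max_size=12))
def test_blood_cells_never_cross_membrane(valve_seq):
    """Species integrity: whatever the valve actuation sequence, blood
    cells never appear downstream of the plasma-only membrane edge."""
    chip = build_glucose_chip()
    load_blood(chip, 8000.0, 0.45)
    vp = {v: 0.0 for v in ("V1", "V2", "V3", "V4", "V5", "V6")}
    ports = {"psm": 0.0, "vacuum_outlet": -1.0, "air_inlet": 1.0}
    for valve, pressure in valve_seq:
        vp[valve] = pressure
        for _ in range(20):
            flow_update(chip, ports, vp, 0.1)
        for node in chip.nodes():
            if node.id != "psm":
                assert node.volume("blood_cells") == 0.0


class TestDegas:
    def test_zero_time_is_identity(self):
        chip = ChipModel()
        chip.add_node(FluidNode("c", "chamber", 50.0, {"air": 10.0}))
        degas_update(chip, 4.0, 0.0)
        assert chip.node("c").volume("air") == 10.0

    def test_exponential_closed_form(self):
        """10 nL of trapped air, tau = 45 s, 180 s at 4 psig ->
        10*e^-4 ~ 0.183 nL (>= 97% removed over the published step)."""
        chip = ChipModel()
        chip.add_node(FluidNode("c", "chamber", 50.0, {"air": 10.0}))
        degas_update(chip, 4.0, 180.0)
        assert chip.node("c").volume("air") == pytest.approx(
            10.0 * math.exp(-4.0), rel=1e-9)
        assert chip.node("c").volume("air") <= 0.03 * 10.0

    def test_nonpositive_pressure_rejected(self):
        chip = ChipModel()
        chip.add_node(FluidNode("c", "chamber", 50.0, {"air": 10.0}))
        with pytest.raises(ChipError):
            degas_update(chip, 0.0, 10.0)

    def test_batching(self):
        a = ChipModel()
        a.add_node(FluidNode("c", "chamber", 50.0, {"air": 10.0}))
        b = ChipModel()
        b.add_node(FluidNode("c", "chamber", 50.0, {"air": 10.0}))
        degas_update(a, 4.0, 90.0)
        degas_update(a, 4.0, 90.0)
        degas_update(b, 4.0, 180.0)
        assert a.node("c").volume("air") == pytest.approx(
            b.node("c").volume("air"))


class TestMixing:
    def test_zero_cycles_zero_homogeneity(self, glucose_chip):
        mixing_update(glucose_chip, "unit1", 0)
        assert glucose_chip.mixing_state["unit1"] == 0.0

    def test_full_exchange_single_cycle(self, glucose_chip):
        glucose_chip.exchange_fraction = 1.0
        mixing_update(glucose_chip, "unit1", 1)
        assert glucose_chip.mixing_state["unit1"] == 1.0

    def test_closed_form(self, glucose_chip):
        glucose_chip.exchange_fraction = 0.3
        mixing_update(glucose_chip, "unit1", 10)
        assert glucose_chip.mixing_state["unit1"] == pytest.approx(
            1.0 - 0.7 ** 10)

    def test_default_regime_saturates(self, glucose_chip):
        """480 alternations at the default exchange fraction leave the
        unit essentially homogeneous (> 0.9999)."""
        mixing_update(glucose_chip, "unit1", 480)
        assert glucose_chip.mixing_state["unit1"] > 0.9999

    @given(n1=st.integers(0, 200), n2=st.integers(0, 200))
    def test_batching_invariance(self, n1, n2):
        a = build_glucose_chip()
        b = build_glucose_chip()
        mixing_update(a, "unit1", n1)
        mixing_update(a, "unit1", n2)
        mixing_update(b, "unit1", n1 + n2)
        assert a.mixing_state["unit1"] == pytest.approx(
            b.mixing_state["unit1"])

    def test_monotone_in_cycles(self, glucose_chip):
        last = 0.0
        for n in (1, 2, 5, 10, 50):
            chip = build_glucose_chip()
            mixing_update(chip, "unit1", n)
            assert chip.mixing_state["unit1"] >= last
            last = chip.mixing_state["unit1"]

    def test_contamination_guard(self, glucose_chip):
        open_vp = {v: 0.0 for v in ("V1", "V2", "V3", "V4", "V5", "V6")}
        with pytest.raises(ContaminationError):
            mixing_update(glucose_chip, "unit1", 1, open_vp)
        mixing_update(glucose_chip, "unit1", 1, MIXING_VALVES)  # fine


def test_chip_json_roundtrip(tmp_path, glucose_chip):
    load_blood(glucose_chip, 8000.0)
    path = tmp_path / "chip.json"
    glucose_chip.save(path)
    loaded = ChipModel.load(path)
    assert {n.id for n in loaded.nodes()} == \
        {n.id for n in glucose_chip.nodes()}
    assert loaded.analysis_units == glucose_chip.analysis_units
    for n in glucose_chip.nodes():
        assert loaded.node(n.id).contents == pytest.approx(n.contents)


def test_exactly_four_analysis_units_of_50_nl(glucose_chip):
    assert len(glucose_chip.analysis_units) == 4
    for s, r in glucose_chip.analysis_units.values():
        assert glucose_chip.node(s).capacity == 50.0
        assert glucose_chip.node(r).capacity == 50.0
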