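"""Declarative assay protocols, schedule compilation and execution.

A :class:`Protocol` is an ordered list of steps, each fixing the state of
all six on-chip microvalves, the pressure setpoints applied to the
pneumatic subsystems, which chip ports those subsystems reach, and a
duration.  The compiler expands a protocol into a timestamped
:class:`Schedule` of actuation events (solenoid switches, setpoint
changes, mixing alternations, terminal all-safe), and the executor
dispatches the schedule through a HAL, regulating pressures with
:class:`~valveflow.regulation.BangBangController` and, when a
:class:`~valveflow.chip.ChipModel` is attached, driving its flow, degas
and mixing updates.

Two built-in protocols transcribe the published workflows: the six-step
automated glucose assay (valve fill, plasma pull at -1 psig, chamber fill
at +1 psig, degas at +4 psig, sequestration, 8 min of active mixing) and
the two-step plasma separation (-1 psig pull, +1 psig push-out).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import pandas as pd

from . import chip as chipmod
from .hal import HALContract, pump_id, vent_id
from .pneumatics import HIGH, LOW_NEGATIVE, LOW_POSITIVE
from .regulation import BangBangController, PressureTrace, RegulatorConfig

SCHEMA_VERSION = 1

MICROVALVES = ("V1", "V2", "V3", "V4", "V5", "V6")

#: bijection between the six high-pressure solenoid stations and the
#: six on-chip microvalves they actuate
VALVE_SOLENOIDS = {f"V{i}": f"HP{i}" for i in range(1, 7)}

#: allowed setpoint ranges per subsystem (psig)
SUBSYSTEM_RANGES = {
    HIGH: (0.0, 25.0),
    LOW_POSITIVE: (-5.0, 5.0),
    LOW_NEGATIVE: (-5.0, 5.0),
}

PREPARATION = "preparation"
ASSAY = "assay"


class ProtocolError(ValueError):
    """Invalid protocol definition or compilation failure."""


@dataclass(frozen=True)
class ValveConfig:
    """Activation state (True = activated = closed) of all six microvalves."""

    states: dict[str, bool]

    def __post_init__(self) -> None:
        if set(self.states) != set(MICROVALVES):
            missing = set(MICROVALVES) - set(self.states)
            extra = set(self.states) - set(MICROVALVES)
            raise ProtocolError(
                f"valve config must assign exactly V1..V6 "
                f"(missing {sorted(missing)}, extra {sorted(extra)})")

    def __getitem__(self, valve: str) -> bool:
        return self.states[valve]

    @classmethod
    def all_activated(cls, except_for: tuple[str, ...] = ()) -> "ValveConfig":
        return cls({v: v not in except_for for v in MICROVALVES})

    @classmethod
    def all_deactivated(cls) -> "ValveConfig":
        return cls({v: False for v in MICROVALVES})

    def with_states(self, **kw: bool) -> "ValveConfig":
        states = dict(self.states)
        states.update(kw)
        return ValveConfig(states)


@dataclass(frozen=True)
class MixingSpec:
    """Alternating actuation of two microvalves at a fixed half-period."""

    valves: tuple[str, str] = ("V3", "V5")
    half_period: float = 1.0

    def __post_init__(self) -> None:
        if self.half_period <= 0:
            raise ProtocolError("mixing half_period must be > 0")


@dataclass(frozen=True)
class ProtocolStep:
    """One timed stage: valve configuration + setpoints + port routing.

    ``setpoints`` maps subsystem label to the regulated pressure (psig);
    an absent subsystem is unpressurized.  ``applied_ports`` maps a
    subsystem label (or the pseudo-label ``ambient`` for ports open to
    atmosphere) to chip port node ids.  ``chip_actions`` names the fluid
    processes active during the step (``flow``, ``degas``, ``mixing``).
    ``vent_all`` opens the flow-layer (low-pressure) vents so the
    reaction chambers fully depressurize; the high circuit keeps holding
    the microvalves.
    """

    name: str
    valve_config: ValveConfig
    duration: float
    phase: str = ASSAY
    setpoints: dict[str, float] = field(default_factory=dict)
    applied_ports: dict[str, tuple[str, ...]] = field(default_factory=dict)
    chip_actions: tuple[str, ...] = ()
    mixing: MixingSpec | None = None
    vent_all: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ProtocolError(f"step {self.name!r}: duration must be > 0")
        if self.phase not in (PREPARATION, ASSAY):
            raise ProtocolError(f"step {self.name!r}: unknown phase "
                                f"{self.phase!r}")
        for sub, sp in self.setpoints.items():
            if sub not in SUBSYSTEM_RANGES:
                raise ProtocolError(f"step {self.name!r}: unknown subsystem "
                                    f"{sub!r}")
            lo, hi = SUBSYSTEM_RANGES[sub]
            if not lo <= sp <= hi:
                raise ProtocolError(
                    f"step {self.name!r}: setpoint {sp} psig outside "
                    f"[{lo}, {hi}] for subsystem {sub}")
        for action in self.chip_actions:
            if action not in ("flow", "degas", "mixing"):
                raise ProtocolError(f"step {self.name!r}: unknown chip "
                                    f"action {action!r}")


@dataclass(frozen=True)
class Protocol:
    """Named, versioned, ordered list of steps."""

    name: str
    steps: tuple[ProtocolStep, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        if not self.steps:
            raise ProtocolError("protocol has no steps")
        seen_assay = False
        for step in self.steps:
            if step.phase == ASSAY:
                seen_assay = True
            elif seen_assay:
                raise ProtocolError(
                    f"step {step.name!r}: preparation steps must precede "
                    "all assay steps")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def step_dict(s: ProtocolStep) -> dict:
            d = {
                "name": s.name,
                "valve_config": dict(s.valve_config.states),
                "duration": s.duration,
                "phase": s.phase,
                "setpoints": dict(s.setpoints),
                "applied_ports": {k: list(v)
                                  for k, v in s.applied_ports.items()},
                "chip_actions": list(s.chip_actions),
                "vent_all": s.vent_all,
            }
            if s.mixing is not None:
                d["mixing"] = {"valves": list(s.mixing.valves),
                               "half_period": s.mixing.half_period}
            return d
        return {"schema_version": SCHEMA_VERSION, "name": self.name,
                "version": self.version,
                "steps": [step_dict(s) for s in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ProtocolError(
                f"unsupported schema_version {d.get('schema_version')!r}")
        steps = []
        for sd in d["steps"]:
            mixing = None
            if "mixing" in sd:
                mixing = MixingSpec(valves=tuple(sd["mixing"]["valves"]),
                                    half_period=sd["mixing"]["half_period"])
            steps.append(ProtocolStep(
                name=sd["name"],
                valve_config=ValveConfig(dict(sd["valve_config"])),
                duration=sd["duration"],
                phase=sd.get("phase", ASSAY),
                setpoints=dict(sd.get("setpoints", {})),
                applied_ports={k: tuple(v) for k, v
                               in sd.get("applied_ports", {}).items()},
                chip_actions=tuple(sd.get("chip_actions", [])),
                mixing=mixing,
                vent_all=sd.get("vent_all", False)))
        return cls(name=d["name"], steps=tuple(steps),
                   version=d.get("version", "1"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "Protocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Built-in protocols
# ---------------------------------------------------------------------------

def builtin_glucose_protocol(*, mixing_half_period: float = 1.0,
                             open_path_duration: float = 2.0,
                             depressurize_duration: float = 10.0,
                             include_preparation: bool = True) -> Protocol:
    """The automated plasma-separation + glucose-assay workflow.

    Preparation: all six microvalve lines pressurized to 25 psig for
    5 min to fill them with water, then a 10 min delay for loading
    reagents.  Assay: (i) open the PSM-to-vacuum path, (ii) pull plasma at
    -1 psig for 30 s, (iii) fill sample and reagent chambers at +1 psig
    for 20 s, (iv) degas at +4 psig for 3 min with the outlets sealed,
    (v) depressurize and sequester every reaction chamber (all valves
    activated except V3), (vi) actively mix by alternating V3/V5 for
    8 min, ending with all valves activated except V3.
    """
    steps: list[ProtocolStep] = []
    if include_preparation:
        steps += [
            ProtocolStep(
                name="valve_fill",
                valve_config=ValveConfig.all_activated(),
                duration=300.0, phase=PREPARATION,
                setpoints={HIGH: 25.0}),
            ProtocolStep(
                name="preparation_delay",
                valve_config=ValveConfig.all_activated(),
                duration=600.0, phase=PREPARATION),
        ]
    sequestered = ValveConfig.all_activated(except_for=("V3",))
    steps += [
        ProtocolStep(  # (i)
            name="open_psm_path",
            valve_config=ValveConfig.all_activated(except_for=("V1",)),
            duration=open_path_duration, phase=ASSAY,
            setpoints={HIGH: 25.0}),
        ProtocolStep(  # (ii)
            name="plasma_pull",
            valve_config=ValveConfig.all_activated(except_for=("V1",)),
            duration=30.0, phase=ASSAY,
            setpoints={HIGH: 25.0, LOW_NEGATIVE: -1.0},
            applied_ports={LOW_NEGATIVE: ("vacuum_outlet",),
                           "ambient": ("psm",)},
            chip_actions=("flow",)),
        ProtocolStep(  # (iii)
            name="chamber_fill",
            valve_config=ValveConfig.all_activated(
                except_for=("V2", "V3", "V4", "V6")),
            duration=20.0, phase=ASSAY,
            setpoints={HIGH: 25.0, LOW_POSITIVE: 1.0},
            applied_ports={LOW_POSITIVE: ("air_inlet", "reagent_inlet"),
                           "ambient": ("vacuum_outlet",
                                       "o1", "o2", "o3", "o4")},
            chip_actions=("flow",)),
        ProtocolStep(  # (iv)
            name="degas",
            valve_config=ValveConfig.all_activated(
                except_for=("V3", "V4", "V6")),
            duration=180.0, phase=ASSAY,
            setpoints={HIGH: 25.0, LOW_POSITIVE: 4.0},
            applied_ports={LOW_POSITIVE: ("air_inlet", "reagent_inlet")},
            chip_actions=("flow", "degas")),
        ProtocolStep(  # (v)
            name="depressurize_sequester",
            valve_config=sequestered,
            duration=depressurize_duration, phase=ASSAY,
            setpoints={HIGH: 25.0},
            vent_all=True),
        ProtocolStep(  # (vi)
            name="active_mixing",
            valve_config=sequestered,
            duration=480.0, phase=ASSAY,
            setpoints={HIGH: 25.0},
            mixing=MixingSpec(valves=("V3", "V5"),
                              half_period=mixing_half_period),
            chip_actions=("mixing",)),
    ]
    return Protocol(name="glucose_assay", steps=tuple(steps))


def builtin_separation_protocol(*, push_duration: float = 60.0) -> Protocol:
    """The two-step plasma separation and collection workflow:
    (1) -1 psig at the vacuum outlet for 2 min pulls plasma through the
    membrane into the collection microchannel; (2) +1 psig at the air
    inlet pushes the collected plasma out into the outlet tubing."""
    valves = ValveConfig.all_deactivated()
    steps = (
        ProtocolStep(
            name="pull_plasma",
            valve_config=valves,
            duration=120.0, phase=ASSAY,
            setpoints={LOW_NEGATIVE: -1.0},
            applied_ports={LOW_NEGATIVE: ("vacuum_outlet",),
                           "ambient": ("psm",)},
            chip_actions=("flow",)),
        ProtocolStep(
            name="push_out",
            valve_config=valves,
            duration=push_duration, phase=ASSAY,
            setpoints={HIGH: 25.0, LOW_POSITIVE: 1.0},
            applied_ports={LOW_POSITIVE: ("air_inlet",),
                           "ambient": ("vacuum_outlet",)},
            chip_actions=("flow",)),
    )
    return Protocol(name="plasma_separation", steps=steps)


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleEvent:
    """One timestamped scheduler action."""

    time: float
    kind: str          # step_start | valve | setpoint | vent_all | mix_toggle | all_safe
    step: str
    target: str = ""   # valve id or subsystem label
    value: object = None

    def __post_init__(self) -> None:
        if self.kind not in ("step_start", "valve", "setpoint", "vent_all",
                             "mix_toggle", "all_safe"):
            raise ProtocolError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Schedule:
    """Compiled, timestamped actuation plan.

    ``steps`` holds (name, phase, start time, duration) per step; the
    source :class:`Protocol` rides along so the executor can consult step
    details (chip actions, port routing) by name.
    """

    protocol_name: str
    events: tuple[ScheduleEvent, ...]
    steps: tuple[tuple[str, str, float, float], ...]  # (name, phase, t0, dur)
    protocol: Protocol

    def step(self, name: str) -> ProtocolStep:
        for s in self.protocol.steps:
            if s.name == name:
                return s
        raise ProtocolError(f"unknown step {name!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "time_s": e.time, "kind": e.kind, "step": e.step,
            "target": e.target, "value": e.value,
        } for e in self.events])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def duration(self) -> float:
        name, phase, t0, dur = self.steps[-1]
        return t0 + dur


def compile(protocol: Protocol,
            mixing_half_period: float | None = None) -> Schedule:
    """Expand a protocol into timestamped events.

    Each step emits its full valve configuration and setpoint changes at
    its start time (re-emitting unchanged states keeps steps
    self-contained and commands idempotent); a mixing step expands into
    one alternation event per half-period; the schedule ends with a
    terminal all-safe event (pumps off, vents open, solenoids released).
    Deterministic: compiling the same protocol twice gives equal
    schedules.
    """
    events: list[ScheduleEvent] = []
    steps_meta: list[tuple[str, str, float, float]] = []
    t = 0.0
    for step in protocol.steps:
        events.append(ScheduleEvent(t, "step_start", step.name))
        for valve in MICROVALVES:
            events.append(ScheduleEvent(t, "valve", step.name, valve,
                                        step.valve_config[valve]))
        for sub in SUBSYSTEM_RANGES:
            sp = step.setpoints.get(sub)
            events.append(ScheduleEvent(t, "setpoint", step.name, sub, sp))
        if step.vent_all:
            events.append(ScheduleEvent(t, "vent_all", step.name))
        if step.mixing is not None:
            half = (mixing_half_period if mixing_half_period is not None
                    else step.mixing.half_period)
            if half <= 0:
                raise ProtocolError("mixing half-period must be > 0")
            n_toggles = int(round(step.duration / half))
            a, b = step.mixing.valves
            for i in range(n_toggles):
                # phase A: first valve open, second closed; phase B swapped
                opened = a if i % 2 == 0 else b
                closed = b if i % 2 == 0 else a
                events.append(ScheduleEvent(t + i * half, "mix_toggle",
                                            step.name, f"{opened}/{closed}",
                                            (opened, closed)))
            # restore the step's base configuration at the end of mixing
            events.append(ScheduleEvent(t + step.duration - 1e-9, "valve",
                                        step.name, a, step.valve_config[a]))
            events.append(ScheduleEvent(t + step.duration - 1e-9, "valve",
                                        step.name, b, step.valve_config[b]))
        steps_meta.append((step.name, step.phase, t, step.duration))
        t += step.duration
    events.append(ScheduleEvent(t, "all_safe", "terminal"))
    return Schedule(protocol_name=protocol.name, events=tuple(events),
                    steps=tuple(steps_meta), protocol=protocol)


def total_duration(schedule: Schedule, phase: str = "all") -> float:
    """Summed step durations for ``preparation``, ``assay`` or ``all``."""
    if phase not in (PREPARATION, ASSAY, "all"):
        raise ProtocolError(f"unknown phase {phase!r}")
    return sum(dur for _, ph, _, dur in schedule.steps
               if phase == "all" or ph == phase)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

@dataclass
class RunLog:
    """Record of an executed schedule."""

    protocol_name: str
    events: list[dict] = field(default_factory=list)
    traces: dict[str, PressureTrace] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    step_snapshots: dict[str, dict] = field(default_factory=dict)
    peak_volumes: dict[tuple[str, str], float] = field(default_factory=dict)
    mixing_cycles: int = 0

    def log(self, time: float, description: str) -> None:
        self.events.append({"time_s": time, "event": description})

    def peak(self, node: str, species: str) -> float:
        return self.peak_volumes.get((node, species), 0.0)


def execute(schedule: Schedule, hal: HALContract,
            chip: chipmod.ChipModel | None = None, *,
            tick: float = 0.01,
            regulator_defaults: RegulatorConfig | None = None) -> RunLog:
    """Dispatch a schedule through a HAL, regulating and (optionally)
    driving an attached chip model.

    Pressure setpoints are maintained by one
    :class:`~valveflow.regulation.BangBangController` per subsystem,
    re-created whenever a step changes the setpoint.  With a chip
    attached, ``flow`` steps call
    :func:`~valveflow.chip.flow_update` each tick with the subsystems'
    live pressures at the step's ports, ``degas`` steps additionally
    decay trapped chamber air, and each mixing alternation applies one
    mixing cycle to every analysis unit.
    """
    log = RunLog(protocol_name=schedule.protocol_name)
    truth_of = getattr(hal, "true_pressure", None)

    valve_state: dict[str, bool] = {}
    setpoints: dict[str, float | None] = {s: None for s in SUBSYSTEM_RANGES}
    controllers: dict[str, BangBangController] = {}

    def subsystem_pressure(sub: str) -> float:
        if truth_of is not None:
            return truth_of(sub)
        return hal.read_pressure(sub)

    def make_controller(sp: float) -> BangBangController:
        base = regulator_defaults or RegulatorConfig(sp)
        return BangBangController(replace(base, setpoint=sp))

    def valve_pressures() -> dict[str, float]:
        p_high = subsystem_pressure(HIGH)
        return {v: (p_high if valve_state.get(v, False) else 0.0)
                for v in MICROVALVES}

    def record_peaks() -> None:
        for node in chip.nodes():
            for sp_name, vol in node.contents.items():
                if sp_name == "air":
                    continue
                key = (node.id, sp_name)
                if vol > log.peak_volumes.get(key, 0.0):
                    log.peak_volumes[key] = vol

    def dispatch(event: ScheduleEvent, now: float) -> None:
        if event.kind == "step_start":
            log.log(now, f"step {event.step} started")
        elif event.kind == "valve":
            energized = bool(event.value)
            if valve_state.get(event.target) != energized:
                hal.set_solenoid(VALVE_SOLENOIDS[event.target], energized)
            valve_state[event.target] = energized
            log.log(now, f"valve {event.target} "
                         f"{'activated' if energized else 'deactivated'}")
        elif event.kind == "setpoint":
            sub = event.target
            sp = event.value
            if sp is None:
                if setpoints[sub] is not None:
                    hal.set_pump(pump_id(sub), False)
                    hal.set_solenoid(vent_id(sub), False)
                setpoints[sub] = None
                controllers.pop(sub, None)
            else:
                if setpoints[sub] != sp:
                    controllers[sub] = make_controller(float(sp))
                setpoints[sub] = float(sp)
            log.log(now, f"setpoint {sub} = {sp}")
        elif event.kind == "vent_all":
            # depressurize the flow layer; the high circuit keeps holding
            # the microvalves closed
            for sub in (LOW_POSITIVE, LOW_NEGATIVE):
                setpoints[sub] = None
                controllers.pop(sub, None)
                hal.set_pump(pump_id(sub), False)
                hal.set_solenoid(vent_id(sub), True)
            log.log(now, "flow-layer subsystems venting")
        elif event.kind == "mix_toggle":
            opened, closed = event.value
            for valve, state in ((opened, False), (closed, True)):
                if valve_state.get(valve) != state:
                    hal.set_solenoid(VALVE_SOLENOIDS[valve], state)
                    valve_state[valve] = state
            if chip is not None:
                vp = valve_pressures()
                for unit in chip.analysis_units:
                    chipmod.mixing_update(chip, unit, 1, vp)
            log.mixing_cycles += 1
            log.log(now, f"mix toggle {event.target}")
        elif event.kind == "all_safe":
            for sub in SUBSYSTEM_RANGES:
                setpoints[sub] = None
                controllers.pop(sub, None)
                hal.set_pump(pump_id(sub), False)
                hal.set_solenoid(vent_id(sub), True)
            log.log(now, "terminal all-safe")

    events = sorted(schedule.events, key=lambda e: e.time)
    n_ticks = max(1, round(schedule.duration / tick))
    ei = 0
    active: ProtocolStep | None = None

    try:
        for k in range(n_ticks + 1):
            now = k * tick
            while ei < len(events) and events[ei].time <= now + tick / 2:
                ev = events[ei]
                if ev.kind == "step_start":
                    if chip is not None and active is not None:
                        log.step_snapshots[active.name] = chip.to_dict()
                    active = schedule.step(ev.step)
                dispatch(ev, now)
                ei += 1
            if k == n_ticks:
                break
            # regulation at the control tick
            for sub, sp in setpoints.items():
                if sp is None:
                    continue
                reading = hal.read_pressure(sub)
                pump, vent = controllers[sub].decide(reading)
                hal.set_pump(pump_id(sub), pump)
                hal.set_solenoid(vent_id(sub), vent)
                trace = log.traces.setdefault(sub, PressureTrace(sub))
                truth = truth_of(sub) if truth_of is not None else reading
                trace.append(now, reading, truth, pump, vent)
            # chip processes of the active step
            if chip is not None and active is not None:
                if "flow" in active.chip_actions:
                    ports: dict[str, float] = {}
                    for sub, port_ids in active.applied_ports.items():
                        p = 0.0 if sub == "ambient" else subsystem_pressure(sub)
                        for port in port_ids:
                            ports[port] = p
                    if ports:
                        chipmod.flow_update(chip, ports, valve_pressures(),
                                            tick)
                if "degas" in active.chip_actions:
                    p_pos = max((subsystem_pressure(s)
                                 for s in active.setpoints), default=0.0)
                    if p_pos > 0:
                        chipmod.degas_update(chip, p_pos, tick)
                record_peaks()
            hal.wait(tick)
        if chip is not None and active is not None:
            log.step_snapshots[active.name] = chip.to_dict()
    except Exception as exc:
        log.warnings.append(f"aborted: {exc}")
        exc.partial_log = log  # type: ignore[attr-defined]
        raise
    return log
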