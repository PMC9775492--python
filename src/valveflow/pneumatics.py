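"""Discrete-time physical model of the pneumatic plant.

The plant mirrors the architecture of a compact pneumatic control box for
microvalve-enabled microfluidic chips: a high-pressure circuit (diaphragm
pump -> accumulator -> solenoid manifold) that actuates on-chip membrane
valves, and a low-pressure circuit delivering positive and negative gauge
pressure to move liquids.  Each subsystem is a lumped isothermal gas
reservoir charged by a diaphragm pump with a linear pump curve and bled by
a solenoid vent with linear (laminar) conductance.  Digital pressure
sensors return the true reservoir pressure corrupted by Gaussian read
noise and quantization.

Units: gauge pressure in psig (0 = ambient, -14.7 = perfect vacuum),
volumes in mL, flows in standard cm^3/min (sccm), time in seconds.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np

#: Atmospheric pressure in psi; gauge pressure cannot go below -ATM_PSI.
ATM_PSI = 14.7

HIGH = "high"
LOW_POSITIVE = "low_positive"
LOW_NEGATIVE = "low_negative"


class ConfigurationError(ValueError):
    """Raised for invalid plant configuration or unknown actuator ids."""


# ---------------------------------------------------------------------------
# Component specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PumpSpec:
    """Diaphragm pump with a linear head-flow curve.

    ``free_flow`` is the volumetric flow at zero head (sccm) and
    ``stall_pressure`` the gauge head (psig) at which flow reaches zero.
    ``polarity`` selects whether the pump charges the reservoir
    (``pressurize``) or evacuates it (``evacuate``).
    """

    free_flow: float
    stall_pressure: float
    polarity: str = "pressurize"

    def __post_init__(self) -> None:
        if self.free_flow <= 0:
            raise ConfigurationError("pump free_flow must be > 0")
        if self.stall_pressure <= 0:
            raise ConfigurationError("pump stall_pressure must be > 0")
        if self.polarity not in ("pressurize", "evacuate"):
            raise ConfigurationError(f"unknown pump polarity {self.polarity!r}")


@dataclass(frozen=True)
class ReservoirSpec:
    """Gas reservoir (accumulator or, for the vacuum side, line volume)."""

    volume: float  # mL
    label: str = HIGH

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ConfigurationError("reservoir volume must be > 0")


@dataclass(frozen=True)
class VentSpec:
    """Solenoid vent valve with linear conductance (sccm per psi)."""

    conductance: float

    def __post_init__(self) -> None:
        if self.conductance <= 0:
            raise ConfigurationError("vent conductance must be > 0")


@dataclass(frozen=True)
class SensorSpec:
    """Digital pressure sensor: Gaussian read noise plus quantization."""

    noise_sd: float = 0.05       # psig
    sample_period: float = 0.01  # s
    quantization: float = 0.01   # psig; 0 disables rounding

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("sensor noise_sd must be >= 0")
        if self.sample_period <= 0:
            raise ConfigurationError("sensor sample_period must be > 0")
        if self.quantization < 0:
            raise ConfigurationError("sensor quantization must be >= 0")


@dataclass(frozen=True)
class SubsystemSpec:
    """One pneumatic circuit: pump + reservoir + vent + sensor."""

    pump: PumpSpec
    reservoir: ReservoirSpec
    vent: VentSpec
    sensor: SensorSpec = SensorSpec()


@dataclass(frozen=True)
class ActuatorCommand:
    """Switch one actuator: ``kind`` is pump | vent | solenoid."""

    target: str
    kind: str
    value: bool

    def __post_init__(self) -> None:
        if self.kind not in ("pump", "vent", "solenoid"):
            raise ConfigurationError(f"unknown actuator kind {self.kind!r}")


@dataclass
class PlantState:
    """Snapshot of all gauge pressures and actuator states at one instant."""

    time: float
    pressure: dict[str, float]
    pump_on: dict[str, bool]
    vent_open: dict[str, bool]
    solenoid_energized: dict[str, bool]

    def copy(self) -> "PlantState":
        return PlantState(
            time=self.time,
            pressure=dict(self.pressure),
            pump_on=dict(self.pump_on),
            vent_open=dict(self.vent_open),
            solenoid_energized=dict(self.solenoid_energized),
        )


# ---------------------------------------------------------------------------
# Plant configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantConfig:
    """Full plant: subsystems plus the solenoid -> subsystem wiring map."""

    subsystems: Mapping[str, SubsystemSpec]
    solenoids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sol, sub in self.solenoids.items():
            if sub not in self.subsystems:
                raise ConfigurationError(
                    f"solenoid {sol!r} wired to unknown subsystem {sub!r}")

    @staticmethod
    def pump_id(label: str) -> str:
        return f"pump_{label}"

    @staticmethod
    def vent_id(label: str) -> str:
        return f"vent_{label}"

    def to_dict(self) -> dict:
        return {
            "subsystems": {k: asdict(v) for k, v in self.subsystems.items()},
            "solenoids": dict(self.solenoids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantConfig":
        subs = {}
        for label, sd in d["subsystems"].items():
            subs[label] = SubsystemSpec(
                pump=PumpSpec(**sd["pump"]),
                reservoir=ReservoirSpec(**sd["reservoir"]),
                vent=VentSpec(**sd["vent"]),
                sensor=SensorSpec(**sd.get("sensor", {})),
            )
        return cls(subsystems=subs, solenoids=dict(d.get("solenoids", {})))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PlantConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_plant_config() -> PlantConfig:
    """The default three-circuit plant.

    The high side models a 2 slpm miniature diaphragm pump charging a
    100 mL accumulator (stall 30 psig).  The low circuits use small
    metering pumps (50 sccm, stall 8 psig): the positive side feeds a
    20 mL accumulator, the negative side has no accumulator, only ~5 mL
    of line volume.  Vent conductances are sized so a single 10 ms vent
    pulse moves the reservoir by much less than the regulation deadband.
    """
    subsystems = {
        HIGH: SubsystemSpec(
            pump=PumpSpec(free_flow=2000.0, stall_pressure=30.0),
            reservoir=ReservoirSpec(volume=100.0, label=HIGH),
            vent=VentSpec(conductance=100.0),
        ),
        LOW_POSITIVE: SubsystemSpec(
            pump=PumpSpec(free_flow=50.0, stall_pressure=8.0),
            reservoir=ReservoirSpec(volume=20.0, label=LOW_POSITIVE),
            vent=VentSpec(conductance=30.0),
        ),
        LOW_NEGATIVE: SubsystemSpec(
            pump=PumpSpec(free_flow=50.0, stall_pressure=8.0,
                          polarity="evacuate"),
            reservoir=ReservoirSpec(volume=5.0, label=LOW_NEGATIVE),
            vent=VentSpec(conductance=8.0),
        ),
    }
    # Six high-pressure solenoids drive the six on-chip microvalves; the
    # low-pressure manifold has three stations (air inlet, reagent inlets,
    # vacuum line).
    solenoids = {f"HP{i}": HIGH for i in range(1, 7)}
    solenoids.update({"LPA": LOW_POSITIVE, "LPR": LOW_POSITIVE,
                      "LPV": LOW_NEGATIVE})
    return PlantConfig(subsystems=subsystems, solenoids=solenoids)


# ---------------------------------------------------------------------------
# Physics
# ---------------------------------------------------------------------------

def pump_flow(head_pressure: float, spec: PumpSpec) -> float:
    """Pump delivery (sccm) at the given head, linear curve, never negative."""
    return spec.free_flow * max(0.0, 1.0 - head_pressure / spec.stall_pressure)


def vent_flow(pressure: float, spec: VentSpec) -> float:
    """Signed vent flow (sccm), positive outward; zero at ambient."""
    return spec.conductance * pressure


def _subsystem_rate(spec: SubsystemSpec, pressure: float,
                    pump_on: bool, vent_open: bool) -> float:
    """dP/dt (psi/s) for one reservoir under the current actuator states.

    Isothermal ideal gas: a standard flow Q (sccm) into volume V (mL)
    changes absolute pressure at Q/60 * ATM_PSI / V psi per second.
    """
    conv = ATM_PSI / (60.0 * spec.reservoir.volume)
    rate = 0.0
    if pump_on:
        if spec.pump.polarity == "pressurize":
            rate += pump_flow(pressure, spec.pump) * conv
        else:
            rate -= pump_flow(-pressure, spec.pump) * conv
    if vent_open:
        rate -= vent_flow(pressure, spec.vent) * conv
    return rate


def advance(state: PlantState, commands: Iterable[ActuatorCommand],
            dt: float, config: PlantConfig, rng=None) -> PlantState:
    """Apply ``commands`` then integrate the plant one explicit step of ``dt``.

    Pressures are clamped to [-ATM_PSI, stall] (a pump can never push a
    reservoir past its stall head, nor can any vent pull below vacuum).
    The update itself is deterministic; ``rng`` is accepted for signature
    symmetry with the sensor model but unused.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new = state.copy()
    for cmd in commands:
        _apply_command(new, cmd, config)
    for label, spec in config.subsystems.items():
        p = new.pressure[label]
        rate = _subsystem_rate(spec, p, new.pump_on[PlantConfig.pump_id(label)],
                               new.vent_open[PlantConfig.vent_id(label)])
        p += rate * dt
        if spec.pump.polarity == "pressurize":
            p = min(p, spec.pump.stall_pressure)
        else:
            p = max(p, -spec.pump.stall_pressure)
        p = max(p, -ATM_PSI)
        new.pressure[label] = p
    new.time = state.time + dt
    return new


def _apply_command(state: PlantState, cmd: ActuatorCommand,
                   config: PlantConfig) -> None:
    if cmd.kind == "pump":
        if cmd.target not in state.pump_on:
            raise ConfigurationError(f"unknown pump id {cmd.target!r}")
        state.pump_on[cmd.target] = bool(cmd.value)
    elif cmd.kind == "vent":
        if cmd.target not in state.vent_open:
            raise ConfigurationError(f"unknown vent id {cmd.target!r}")
        state.vent_open[cmd.target] = bool(cmd.value)
    else:
        if cmd.target not in state.solenoid_energized:
            raise ConfigurationError(f"unknown solenoid id {cmd.target!r}")
        state.solenoid_energized[cmd.target] = bool(cmd.value)


def read_sensor(state: PlantState, label: str, spec: SensorSpec,
                rng: np.random.Generator) -> float:
    """One sensor reading: truth + N(0, noise_sd), rounded to quantization."""
    if label not in state.pressure:
        raise ConfigurationError(f"unknown subsystem label {label!r}")
    value = state.pressure[label]
    if spec.noise_sd > 0:
        value += rng.normal(0.0, spec.noise_sd)
    if spec.quantization > 0:
        q = spec.quantization
        # round half away from zero so e.g. 24.97 -> 25.0 at q = 0.1
        value = math.copysign(math.floor(abs(value) / q + 0.5) * q, value)
    return value


# ---------------------------------------------------------------------------
# Stateful wrapper
# ---------------------------------------------------------------------------

class Plant:
    """Mutable plant simulation holding a :class:`PlantConfig` and state.

    ``step`` mutates in place (fast path used by the HAL); the module-level
    :func:`advance` provides the pure-functional update used in tests.
    """

    def __init__(self, config: PlantConfig | None = None, *,
                 initial_pressure: Mapping[str, float] | None = None):
        self.config = config if config is not None else default_plant_config()
        pressures = {label: 0.0 for label in self.config.subsystems}
        if initial_pressure:
            for k, v in initial_pressure.items():
                if k not in pressures:
                    raise ConfigurationError(f"unknown subsystem {k!r}")
                pressures[k] = float(v)
        self.state = PlantState(
            time=0.0,
            pressure=pressures,
            pump_on={PlantConfig.pump_id(l): False for l in self.config.subsystems},
            vent_open={PlantConfig.vent_id(l): False for l in self.config.subsystems},
            solenoid_energized={s: False for s in self.config.solenoids},
        )

    def apply(self, commands: Iterable[ActuatorCommand]) -> None:
        for cmd in commands:
            _apply_command(self.state, cmd, self.config)

    def step(self, dt: float) -> None:
        """In-place integration step under the current actuator states."""
        st = self.state
        for label, spec in self.config.subsystems.items():
            p = st.pressure[label]
            rate = _subsystem_rate(
                spec, p, st.pump_on[PlantConfig.pump_id(label)],
                st.vent_open[PlantConfig.vent_id(label)])
            p += rate * dt
            if spec.pump.polarity == "pressurize":
                p = min(p, spec.pump.stall_pressure)
            else:
                p = max(p, -spec.pump.stall_pressure)
            st.pressure[label] = max(p, -ATM_PSI)
        st.time += dt

    def pressure(self, label: str) -> float:
        return self.state.pressure[label]

    def read_sensor(self, label: str, rng: np.random.Generator) -> float:
        return read_sensor(self.state, label,
                           self.config.subsystems[label].sensor, rng)

    def snapshot(self) -> PlantState:
        return copy.deepcopy(self.state)
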