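"""Hardware abstraction layer (HAL).

The controller and protocol executor talk to the plant only through this
contract, so the same code can drive the simulator, a serial-attached
control box, or a stub.  Commands are idempotent; ``read_pressure`` may be
called at the sensor sample rate or faster.

Back-ends provided here:

``SimulatedHAL``
    wraps a :class:`~valveflow.pneumatics.Plant`; ``wait`` integrates the
    plant forward with the currently latched actuator states.
``SerialLineHAL``
    speaks a line-oriented text protocol (``P <id> <0|1>``, ``V <id> <0|1>``,
    ``R <label>``) over any transport with write/readline.  Only the
    loopback transport (backed by a :class:`SimulatedHAL`) is exercised in
    tests; a pyserial transport can be dropped in for real hardware.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .pneumatics import ActuatorCommand, Plant, PlantConfig


@runtime_checkable
class HALContract(Protocol):
    """Operations any back-end must expose."""

    def set_solenoid(self, solenoid_id: str, energized: bool) -> None: ...

    def set_pump(self, pump_id: str, on: bool) -> None: ...

    def read_pressure(self, label: str) -> float: ...

    def now(self) -> float: ...

    def wait(self, seconds: float) -> None: ...


class HALError(RuntimeError):
    """Raised when a back-end cannot complete an operation."""


class SimulatedHAL:
    """HAL back-end over the pneumatic plant simulator.

    Vent valves are physically solenoid valves, so ``set_solenoid`` accepts
    vent ids (``vent_<subsystem>``) as well as manifold solenoid ids.
    ``true_pressure`` exposes noiseless plant truth for tracing; it is not
    part of the contract and hardware back-ends do not have it.
    """

    def __init__(self, plant: Plant | None = None, *, seed: int = 0,
                 plant_dt: float = 0.001):
        if plant_dt <= 0:
            raise ValueError("plant_dt must be > 0")
        self.plant = plant if plant is not None else Plant()
        self.plant_dt = plant_dt
        self.rng = np.random.default_rng(seed)

    # -- contract ---------------------------------------------------------
    def set_solenoid(self, solenoid_id: str, energized: bool) -> None:
        kind = "vent" if solenoid_id in self.plant.state.vent_open else "solenoid"
        self.plant.apply([ActuatorCommand(solenoid_id, kind, energized)])

    def set_pump(self, pump_id: str, on: bool) -> None:
        self.plant.apply([ActuatorCommand(pump_id, "pump", on)])

    def read_pressure(self, label: str) -> float:
        return self.plant.read_sensor(label, self.rng)

    def now(self) -> float:
        return self.plant.state.time

    def wait(self, seconds: float) -> None:
        if seconds <= 0:
            return
        n = max(1, round(seconds / self.plant_dt))
        dt = seconds / n
        for _ in range(n):
            self.plant.step(dt)

    # -- extras for tracing ----------------------------------------------
    def true_pressure(self, label: str) -> float:
        return self.plant.pressure(label)


class LoopbackTransport:
    """In-process transport that answers the serial text protocol from a
    :class:`SimulatedHAL`.  Stands in for a pyserial connection in tests."""

    def __init__(self, hal: SimulatedHAL):
        self.hal = hal
        self._responses: list[str] = []

    def write(self, line: str) -> None:
        parts = line.strip().split()
        if not parts:
            return
        op = parts[0]
        if op == "P" and len(parts) == 3:
            self.hal.set_pump(parts[1], parts[2] == "1")
            self._responses.append("OK")
        elif op == "V" and len(parts) == 3:
            self.hal.set_solenoid(parts[1], parts[2] == "1")
            self._responses.append("OK")
        elif op == "R" and len(parts) == 2:
            self._responses.append(f"{self.hal.read_pressure(parts[1]):.6f}")
        elif op == "T" and len(parts) == 1:
            self._responses.append(f"{self.hal.now():.6f}")
        elif op == "W" and len(parts) == 2:
            self.hal.wait(float(parts[1]))
            self._responses.append("OK")
        else:
            self._responses.append(f"ERR bad command: {line.strip()}")

    def readline(self) -> str:
        if not self._responses:
            raise HALError("no pending response")
        return self._responses.pop(0)


class SerialLineHAL:
    """HAL speaking the line protocol over a transport (loopback or serial)."""

    def __init__(self, transport):
        self.transport = transport

    def _ask(self, line: str) -> str:
        self.transport.write(line)
        reply = self.transport.readline().strip()
        if reply.startswith("ERR"):
            raise HALError(reply)
        return reply

    def set_solenoid(self, solenoid_id: str, energized: bool) -> None:
        self._ask(f"V {solenoid_id} {1 if energized else 0}")

    def set_pump(self, pump_id: str, on: bool) -> None:
        self._ask(f"P {pump_id} {1 if on else 0}")

    def read_pressure(self, label: str) -> float:
        return float(self._ask(f"R {label}"))

    def now(self) -> float:
        return float(self._ask("T"))

    def wait(self, seconds: float) -> None:
        self._ask(f"W {seconds:.9g}")


def pump_id(label: str) -> str:
    return PlantConfig.pump_id(label)


def vent_id(label: str) -> str:
    return PlantConfig.vent_id(label)
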