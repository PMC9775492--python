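"""Bang-bang pressure regulation with hysteresis.

The regulator reproduces the feedback loop of the hardware it models: a
diaphragm pump charges the accumulator toward the setpoint while a vent
solenoid releases excess pressure, with a deadband around the setpoint to
prevent chatter.  Negative setpoints run the identical algorithm on the
pressure magnitude with sign bookkeeping, so the vacuum side is regulated
in the same manner as the positive circuits.

The decision rule itself (:func:`regulator_step`) is a memoryless
three-zone bang-bang: pump below the band, vent above it, hold inside.
The execution loop around it has to cope with a sensor whose read noise
(0.05 psig by default) is an order of magnitude larger than the deadband
at the smallest setpoints.  It does so in two regimes:

* **slew** -- far from the setpoint, actuate continuously on a short
  moving average of the readings (classic bang-bang);
* **settle-and-measure** -- near the setpoint, hold both actuators
  closed while accumulating readings.  With everything closed the
  reservoir is strictly conservative, so the accumulated mean is an
  unbiased estimate of the true pressure whose standard error shrinks as
  1/sqrt(n).  Once enough samples confirm that the pressure sits outside
  the deadband (beyond a few standard errors), the regulator fires a
  short actuation *burst* sized from the estimated per-period response,
  then returns to measuring.  Because pump and vent rates both decrease
  toward the target, bursts systematically undershoot and convergence is
  monotone.

This is the kind of firmware loop a microcontroller actually runs for
"pump to setpoint, vent the excess" regulation; a per-sample bang-bang on
raw readings would chatter on noise, and a long linear filter would
limit-cycle on its own lag.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hal import HALContract, SimulatedHAL, pump_id, vent_id
from .pneumatics import Plant, PlantConfig, default_plant_config


@dataclass(frozen=True)
class RegulatorConfig:
    """Setpoint plus deadband and measurement parameters.

    ``relative_deadband`` scales with |setpoint|; ``min_deadband`` is an
    absolute floor so near-zero setpoints keep a finite band.
    ``settle_time`` is the window excluded from precision metrics after
    the trace first reaches the deadband.  ``sensor_noise_sd`` is the
    controller's knowledge of the sensor read noise (psig), used to size
    confidence margins; ``confirm_samples`` is the minimum number of
    readings averaged before a near-setpoint correction is allowed, and
    ``margin_sigma`` the number of standard errors by which the averaged
    reading must clear the deadband before the regulator acts on it.
    ``coarse_band_factor`` (in deadbands) separates the continuous slew
    regime from settle-and-measure; ``coarse_window`` is the short moving
    average used while slewing.
    """

    setpoint: float
    relative_deadband: float = 0.005
    min_deadband: float = 0.005
    settle_time: float = 5.0
    sensor_noise_sd: float = 0.05
    confirm_samples: int = 200
    margin_sigma: float = 2.0
    coarse_band_factor: float = 20.0
    coarse_window: int = 8
    max_burst: int = 1000
    burst_caution: float = 1.5
    control_band_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.relative_deadband <= 0:
            raise ValueError("relative_deadband must be > 0")
        if self.min_deadband <= 0:
            raise ValueError("min_deadband must be > 0")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")
        if self.confirm_samples < 1:
            raise ValueError("confirm_samples must be >= 1")

    @property
    def deadband(self) -> float:
        return max(self.relative_deadband * abs(self.setpoint),
                   self.min_deadband)


def regulator_step(reading: float, config: RegulatorConfig,
                   previous: tuple[bool, bool] | None = None
                   ) -> tuple[bool, bool]:
    """One bang-bang decision: returns ``(pump_on, vent_open)``.

    Below the band (toward atmosphere) the pump runs; beyond the band the
    vent opens; inside the band both actuators are closed (hold).  The
    two outputs are mutually exclusive by construction.  For a negative
    setpoint "toward the setpoint" means more negative.  ``previous`` is
    accepted for API symmetry but the decision is memoryless.
    """
    sign = -1.0 if config.setpoint < 0 else 1.0
    magnitude = sign * reading
    target = abs(config.setpoint)
    delta = config.deadband
    if magnitude < target - delta:
        return True, False
    if magnitude > target + delta:
        return False, True
    return False, False


@dataclass
class PressureTrace:
    """Regulation trace: per-sample reading, truth and actuator states."""

    subsystem: str
    times: list[float] = field(default_factory=list)
    readings: list[float] = field(default_factory=list)
    true_pressures: list[float] = field(default_factory=list)
    pump_on: list[bool] = field(default_factory=list)
    vent_open: list[bool] = field(default_factory=list)

    def append(self, t: float, reading: float, truth: float,
               pump: bool, vent: bool) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("trace times must be strictly increasing")
        self.times.append(t)
        self.readings.append(reading)
        self.true_pressures.append(truth)
        self.pump_on.append(pump)
        self.vent_open.append(vent)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "subsystem": self.subsystem,
            "pressure_psig": self.true_pressures,
            "reading_psig": self.readings,
            "pump_on": self.pump_on,
            "vent_open": self.vent_open,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self, config: RegulatorConfig) -> dict:
        """Max- and mean-based precision over the post-settle window."""
        dev = _post_settle_deviation(self, config)
        target = abs(config.setpoint)
        return {
            "subsystem": self.subsystem,
            "setpoint_psig": config.setpoint,
            "n_samples": len(self),
            "precision_max_pct": 100.0 * float(np.max(dev)) / target,
            "precision_mean_abs_pct": 100.0 * float(np.mean(dev)) / target,
        }


def _post_settle_deviation(trace: PressureTrace,
                           config: RegulatorConfig) -> np.ndarray:
    """|true - setpoint| over the post-settle window.

    The settle clock starts when the true pressure first enters the
    deadband (the standard settling-time definition) and the window opens
    ``settle_time`` later, so charge transients and the first corrective
    bursts are excluded regardless of how long the initial slew takes.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    t = np.asarray(trace.times)
    p = np.asarray(trace.true_pressures)
    err = np.abs(p - config.setpoint)
    in_band = err <= config.deadband
    if not in_band.any():
        raise ValueError("trace never reached the deadband")
    t_enter = t[int(np.argmax(in_band))]
    window = t >= t_enter + config.settle_time
    if not window.any():
        raise ValueError("no samples after the settle window")
    return err[window]


def precision(trace: PressureTrace, config: RegulatorConfig) -> float:
    """Worst-case post-settle deviation as percent of the setpoint."""
    if config.setpoint == 0:
        raise ValueError("relative precision undefined at zero setpoint")
    dev = _post_settle_deviation(trace, config)
    return 100.0 * float(np.max(dev)) / abs(config.setpoint)


class BangBangController:
    """Stateful execution of the bang-bang loop, one decision per period.

    Wraps :func:`regulator_step` with the slew / settle-and-measure /
    burst machinery described in the module docstring.  ``decide`` takes
    the latest sensor reading and returns the ``(pump_on, vent_open)``
    command to latch for the coming sample period.  The class is
    back-end agnostic; callers own the HAL interaction.
    """

    def __init__(self, config: RegulatorConfig):
        self.config = config
        self._delta = config.deadband
        self._ctrl_config = replace(
            config,
            relative_deadband=(config.relative_deadband
                               * config.control_band_fraction),
            min_deadband=config.min_deadband * config.control_band_fraction)
        self._ctrl_delta = self._ctrl_config.deadband
        self._coarse_limit = config.coarse_band_factor * self._delta
        self._sign = -1.0 if config.setpoint < 0 else 1.0
        self._target = abs(config.setpoint)
        self._confirm = 1 if config.sensor_noise_sd == 0 else config.confirm_samples
        self._coarse: deque[float] = deque(maxlen=config.coarse_window)
        self._acc_sum = 0.0
        self._acc_n = 0
        self._burst_left = 0
        self._burst_cmd = (False, False)
        self._burst_n = 0
        self._burst_start_mag: float | None = None
        self._slewing = True
        self._current = (False, False)
        # per-period response estimates (psi per period), learned from bursts
        self._q_hat = {"pump": 2.0 * self._delta, "vent": 2.0 * self._delta}
        self._learn = {"pump": [0.0, 0], "vent": [0.0, 0]}

    def decide(self, reading: float) -> tuple[bool, bool]:
        cfg = self.config
        self._coarse.append(reading)
        if self._burst_left > 0:
            self._burst_left -= 1
            self._current = self._burst_cmd
        elif not self._slewing and self._current != (False, False):
            # burst just finished: close and let the plant sit for one
            # boundary period before measuring resumes
            self._current = (False, False)
        elif self._slewing:
            coarse_mean = sum(self._coarse) / len(self._coarse)
            if abs(self._sign * coarse_mean - self._target) > self._coarse_limit:
                # slew regime: continuous bang-bang on the short average
                self._current = regulator_step(coarse_mean, cfg)
            else:
                self._slewing = False
                self._current = (False, False)
                self._acc_sum, self._acc_n = reading, 1
        else:
            self._current = (False, False)
            self._acc_sum += reading
            self._acc_n += 1
            if self._acc_n >= self._confirm:
                self._measure_and_maybe_burst()
        assert not (self._current[0] and self._current[1])
        return self._current

    def _measure_and_maybe_burst(self) -> None:
        cfg = self.config
        mean = self._acc_sum / self._acc_n
        mag = self._sign * mean
        if self._burst_start_mag is not None and self._burst_n > 0:
            moved = abs(mag - self._burst_start_mag)
            kind = "pump" if self._burst_cmd[0] else "vent"
            # accumulate movement over bursts and learn the per-period
            # response once the total is resolvable above measurement
            # noise; never let one update change the estimate by more
            # than 3x
            self._learn[kind][0] += moved
            self._learn[kind][1] += self._burst_n
            resolvable = (4.0 * math.sqrt(2.0) * cfg.sensor_noise_sd
                          / math.sqrt(self._confirm))
            if self._learn[kind][0] > resolvable:
                q_new = self._learn[kind][0] / self._learn[kind][1]
                self._q_hat[kind] = min(max(q_new, self._q_hat[kind] / 3.0),
                                        self._q_hat[kind] * 3.0)
                self._learn[kind] = [0.0, 0]
            self._burst_start_mag = None
        margin = cfg.margin_sigma * cfg.sensor_noise_sd / math.sqrt(self._acc_n)
        # regulate into a band tighter than the reported one so a landing
        # marginally outside the control band is still comfortably inside
        # the deadband
        pump, vent = regulator_step(mean, self._ctrl_config)
        err = abs(mag - self._target)
        if (pump or vent) and err > self._ctrl_delta + margin:
            # size the burst toward the setpoint, derated by burst_caution:
            # actuator rates fall toward the target, so with the derating a
            # burst only crosses the band if the mean estimate was off by
            # more than a third of the true distance
            q = self._q_hat["pump" if pump else "vent"]
            self._burst_n = int(min(cfg.max_burst,
                                    max(1, math.ceil(err / (q * cfg.burst_caution)))))
            self._burst_cmd = (pump, vent)
            self._burst_left = self._burst_n - 1  # this period is the first
            self._burst_start_mag = mag
            self._current = (pump, vent)
            self._acc_sum, self._acc_n = 0.0, 0


def run_regulation(hal: HALContract, subsystem: str, config: RegulatorConfig,
                   duration: float, *, period: float = 0.01) -> PressureTrace:
    """Regulate ``subsystem`` through ``hal`` for ``duration`` seconds.

    Evaluates the bang-bang decision once per sensor sample period and
    latches commands through the HAL; works identically for the
    simulator, a serial-attached box, or a stub (the loop contains no
    simulator-specific calls).  On a HAL failure the trace collected so
    far is attached to the raised exception.
    """
    trace = PressureTrace(subsystem=subsystem)
    n_steps = max(1, round(duration / period))
    controller = BangBangController(config)
    pid, vid = pump_id(subsystem), vent_id(subsystem)
    truth_of = getattr(hal, "true_pressure", None)
    latched: tuple[bool, bool] | None = None

    def command(pump: bool, vent: bool) -> None:
        nonlocal latched
        if (pump, vent) != latched:
            hal.set_pump(pid, pump)
            hal.set_solenoid(vid, vent)
            latched = (pump, vent)

    try:
        command(False, False)
        for _ in range(n_steps):
            reading = hal.read_pressure(subsystem)
            pump, vent = controller.decide(reading)
            command(pump, vent)
            truth = truth_of(subsystem) if truth_of is not None else reading
            trace.append(hal.now(), reading, truth, pump, vent)
            hal.wait(period)
        command(False, False)
    except Exception as exc:
        exc.partial_trace = trace  # type: ignore[attr-defined]
        raise
    return trace


def simulate_regulation(subsystem: str, setpoint: float, duration: float,
                        *, seed: int = 0,
                        plant_config: PlantConfig | None = None,
                        regulator: RegulatorConfig | None = None,
                        plant_dt: float = 0.001
                        ) -> tuple[PressureTrace, RegulatorConfig]:
    """Convenience wrapper: build plant + simulated HAL and regulate.

    Returns the trace and the regulator config used (so callers can feed
    both to :func:`precision`).
    """
    cfg = regulator if regulator is not None else RegulatorConfig(setpoint)
    plant = Plant(plant_config if plant_config is not None
                  else default_plant_config())
    hal = SimulatedHAL(plant, seed=seed, plant_dt=plant_dt)
    period = plant.config.subsystems[subsystem].sensor.sample_period
    trace = run_regulation(hal, subsystem, cfg, duration, period=period)
    return trace, cfg
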