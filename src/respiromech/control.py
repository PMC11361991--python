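"""Bang-bang (on-off) pneumatic pressure control simulation and metrics.

The actuator pressure is regulated by two solenoid valves — a supply valve
and an exhaust valve — switched by a dead-band controller: when the
measured pressure falls below target minus threshold, the supply valve
opens to inflate; above target plus threshold, the exhaust valve opens to
vent; within the band, both valves close and the pressure holds. The
pneumatic chamber is modelled as a first-order element with separate fill
and vent time constants.

Metrics cover the standard step-response quantities (rise time, settling
time relative to a +/-10%-of-target band, overshoot) and the mean absolute
tracking error against a commanded waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ControllerConfig",
    "PlantParams",
    "ValveCommand",
    "control_step",
    "simulate_pneumatics",
    "step_metrics",
    "tracking_mae",
]

#: Fraction of the target defining the error band for rise/settling time.
SETTLING_BAND_FRACTION = 0.1


@dataclass(frozen=True)
class ControllerConfig:
    """Reference trace (or constant, kPa), dead-band half-width, loop period."""

    target: float | np.ndarray
    threshold: float
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise ValueError("threshold must be positive")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class PlantParams:
    """First-order pneumatic chamber: fill/vent time constants and supply.

    Chosen so the simulated full-scale (0 -> 50 kPa) step settles well
    within a breath cycle with negligible overshoot.
    """

    tau_fill: float = 0.25
    tau_vent: float = 0.35
    P_supply: float = 100.0

    def __post_init__(self) -> None:
        if not (self.tau_fill > 0 and self.tau_vent > 0 and self.P_supply > 0):
            raise ValueError("plant parameters must all be positive")


@dataclass(frozen=True)
class ValveCommand:
    supply: bool
    exhaust: bool

    def __post_init__(self) -> None:
        if self.supply and self.exhaust:
            raise ValueError("supply and exhaust valves cannot both be open")


def control_step(measured: float, target: float, threshold: float) -> ValveCommand:
    """One dead-band decision: inflate, vent, or hold."""
    if not (threshold > 0):
        raise ValueError("threshold must be positive")
    if not math.isfinite(measured):
        raise ValueError(f"non-finite measured pressure: {measured!r}")
    if measured < target - threshold:
        return ValveCommand(supply=True, exhaust=False)
    if measured > target + threshold:
        return ValveCommand(supply=False, exhaust=True)
    return ValveCommand(supply=False, exhaust=False)


def simulate_pneumatics(
    plant: PlantParams,
    config: ControllerConfig,
    duration: float,
    p0: float = 0.0,
    return_commands: bool = False,
):
    """Closed-loop pressure trace (kPa) under bang-bang valve control.

    The controller is evaluated every ``config.dt``; between evaluations
    the chamber follows its first-order dynamics exactly:
    filling toward the supply pressure with ``tau_fill``, venting toward
    atmosphere with ``tau_vent``, or holding when both valves are closed.

    Returns ``(t, pressure)``; with ``return_commands=True`` also the list
    of ValveCommand issued at each step.
    """
    dt = config.dt
    if duration < dt:
        raise ValueError("duration must cover at least one control period")
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    target = np.asarray(config.target, dtype=float)
    if target.ndim == 0:
        target = np.full(n, float(target))
    elif target.size != n:
        raise ValueError(f"target trace length {target.size} != number of steps {n}")
    if np.any(target >= plant.P_supply):
        raise ValueError("supply pressure must exceed every commanded target")

    fill_gain = 1.0 - math.exp(-dt / plant.tau_fill)
    vent_gain = math.exp(-dt / plant.tau_vent)

    p = float(p0)
    out = np.empty(n)
    out[0] = p
    commands = []
    for i in range(1, n):
        cmd = control_step(p, target[i - 1], config.threshold)
        if cmd.supply:
            p = p + (plant.P_supply - p) * fill_gain
        elif cmd.exhaust:
            p = p * vent_gain
        if return_commands:
            commands.append(cmd)
        out[i] = p
    if return_commands:
        return t, out, commands
    return t, out


def step_metrics(trace, target: float, dt: float) -> dict:
    """Step-response metrics for a 0 -> target experiment.

    ``rise_time_s``: first time the trace is within 10% of the target;
    ``settling_time_s``: first time after which it never leaves the
    +/-10%-of-target band; ``overshoot_kPa``: peak excess over the target,
    floored at zero. Times are NaN when the band is never reached.
    """
    trace = np.asarray(trace, dtype=float)
    if not (target > 0 and dt > 0):
        raise ValueError("target and dt must be positive")
    band = SETTLING_BAND_FRACTION * target
    inside = np.abs(trace - target) <= band
    overshoot = max(0.0, float(np.max(trace)) - target)
    if not np.any(inside):
        return {"rise_time_s": math.nan, "settling_time_s": math.nan,
                "overshoot_kPa": overshoot}
    rise = float(np.argmax(inside)) * dt
    outside = np.nonzero(~inside)[0]
    settle = 0.0 if outside.size == 0 else float(outside[-1] + 1) * dt
    if outside.size and outside[-1] == trace.size - 1:
        settle = math.nan  # still outside the band at the end of the record
    return {"rise_time_s": rise, "settling_time_s": settle, "overshoot_kPa": overshoot}


def tracking_mae(trace, reference) -> float:
    """Mean absolute tracking error (kPa) between measured and commanded."""
    trace = np.asarray(trace, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if trace.shape != reference.shape:
        raise ValueError(f"length mismatch: {trace.shape} vs {reference.shape}")
    return float(np.mean(np.abs(trace - reference)))
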