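"""Muscle drive and robotic pressurization waveform generators.

Muscle pressures are half-rectified sines active during the inspiratory
window of each breath cycle; the robot pressurizes its origami actuators
during expiration (default 3 s inflation) with a square, triangle, or
(half-)sine program, and deflates during inhalation. The actuator set
pressure is specified in kPa and transmitted to the abdominal wall as an
effective cmH2O pressure through an explicit actuator-to-abdomen gain
``k_transmission`` (default 0.1 cmH2O/kPa, so a 30 kPa program yields the
reference 3 cmH2O effective robotic pressure). The robot trace is
negative-signed: it drives the diaphragm cranially during expiration.

Also includes the Yoshimura origami closure-condition helper relating the
trapezoid base angle, facet count, and pre-folding angle of the actuator's
fold pattern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .mechanics import DriveSignals

__all__ = [
    "BreathPattern",
    "RobotPressureProgram",
    "OrigamiClosure",
    "muscle_wave",
    "robot_wave",
    "actuator_reference",
    "build_drives",
    "yoshimura_prefold_angle",
    "pattern_program_to_yaml",
    "pattern_program_from_yaml",
]

ROBOT_SHAPES = ("square", "triangle", "sine")

#: Typical adult respiratory cycle range in seconds.
TYPICAL_PERIOD_RANGE = (3.0, 6.0)


@dataclass(frozen=True)
class BreathPattern:
    """Breath timing and muscle amplitudes.

    ``T``: breath period (s); ``f_insp``: inspiratory fraction of the
    cycle; ``A_rc`` / ``A_dim``: rib-cage and diaphragm muscle pressure
    amplitudes (cmH2O).
    """

    T: float = 6.0
    f_insp: float = 0.5
    A_rc: float = 1.0
    A_dim: float = 2.5

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError("breath period must be positive")
        if not (0.0 < self.f_insp < 1.0):
            raise ValueError("f_insp must lie in (0, 1)")
        if self.A_rc < 0 or self.A_dim < 0:
            raise ValueError("muscle amplitudes must be non-negative")
        lo, hi = TYPICAL_PERIOD_RANGE
        if not (lo <= self.T <= hi):
            warnings.warn(
                f"breath period {self.T} s outside the typical {lo}-{hi} s range",
                stacklevel=2,
            )

    @property
    def t_insp(self) -> float:
        """Inspiratory window duration (s)."""
        return self.f_insp * self.T

    def replace(self, **kwargs) -> "BreathPattern":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RobotPressureProgram:
    """Robotic pressurization program for the expiratory phase.

    ``shape``: square, triangle, or sine; ``level_kPa``: actuator set
    pressure; ``k_transmission``: actuator-to-abdomen gain (cmH2O/kPa);
    ``t_inflate``: inflation duration within expiration (s).
    """

    shape: str = "square"
    level_kPa: float = 30.0
    k_transmission: float = 0.1
    t_inflate: float = 3.0

    def __post_init__(self) -> None:
        if self.shape not in ROBOT_SHAPES:
            raise ValueError(f"shape must be one of {ROBOT_SHAPES}, got {self.shape!r}")
        if self.level_kPa < 0:
            raise ValueError("level_kPa must be non-negative")
        if not (self.t_inflate > 0):
            raise ValueError("t_inflate must be positive")
        if self.k_transmission < 0:
            raise ValueError("k_transmission must be non-negative")

    @property
    def p_rex_magnitude(self) -> float:
        """Peak effective abdominal pressure magnitude, cmH2O."""
        return self.k_transmission * self.level_kPa

    def replace(self, **kwargs) -> "RobotPressureProgram":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class OrigamiClosure:
    """A closed Yoshimura origami configuration (angles in degrees)."""

    gamma: float
    M: int
    theta: float

    def residual(self) -> float:
        """Closure-condition residual tan(gamma)*cos(theta/2) - tan(pi/M)."""
        g = math.radians(self.gamma)
        return math.tan(g) * math.cos(math.radians(self.theta) / 2.0) - math.tan(math.pi / self.M)


def _unit_shape(shape: str, u: np.ndarray) -> np.ndarray:
    """Unit-amplitude profile over normalized inflation phase u in [0, 1)."""
    if shape == "square":
        return np.ones_like(u)
    if shape == "triangle":
        return 1.0 - np.abs(2.0 * u - 1.0)
    if shape == "sine":
        return np.sin(np.pi * u)
    raise ValueError(f"unknown shape {shape!r}")


def muscle_wave(pattern: BreathPattern, t_grid, channel: str) -> np.ndarray:
    """Muscle pressure trace (cmH2O): half-sine during inspiration.

    ``channel`` selects the rib-cage (``"rc"``) or diaphragm (``"di"``)
    amplitude. The wave peaks at mid-inspiration and is zero throughout
    expiration; periodic with the breath period.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if channel == "rc":
        amp = pattern.A_rc
    elif channel == "di":
        amp = pattern.A_dim
    else:
        raise ValueError(f"channel must be 'rc' or 'di', got {channel!r}")
    phase = np.mod(t, pattern.T)
    insp = phase < pattern.t_insp
    out = np.zeros_like(t)
    out[insp] = amp * np.sin(np.pi * phase[insp] / pattern.t_insp)
    return out


def actuator_reference(program: RobotPressureProgram, pattern: BreathPattern, t_grid) -> np.ndarray:
    """Commanded actuator pressure trace in kPa (non-negative).

    Active over the inflation window at the start of expiration, zero
    during inspiration; this is the reference the pneumatic controller
    tracks.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    t_exp = (1.0 - pattern.f_insp) * pattern.T
    if program.t_inflate > t_exp * (1 + 1e-12):
        raise ValueError(
            f"t_inflate={program.t_inflate} s exceeds the expiratory window {t_exp} s"
        )
    phase = np.mod(t, pattern.T)
    u = (phase - pattern.t_insp) / program.t_inflate
    active = (u >= 0.0) & (u < 1.0)
    out = np.zeros_like(t)
    out[active] = program.level_kPa * _unit_shape(program.shape, u[active])
    return out


def robot_wave(program: RobotPressureProgram, pattern: BreathPattern, t_grid) -> np.ndarray:
    """Effective robotic abdominal pressure trace (cmH2O, signed).

    Negative during the expiratory inflation window — the robot compresses
    the abdomen inward, displacing the diaphragm cranially — and zero
    during inspiration while the actuators deflate.
    """
    return -program.k_transmission * actuator_reference(program, pattern, t_grid)


def build_drives(
    pattern: BreathPattern,
    t_grid,
    program: RobotPressureProgram | None = None,
) -> DriveSignals:
    """Assemble muscle (and optional robotic) drives on a shared grid."""
    t = np.asarray(t_grid, dtype=float)
    p_rex = np.zeros_like(t) if program is None else robot_wave(program, pattern, t)
    return DriveSignals(
        t=t,
        P_rcmus=muscle_wave(pattern, t, "rc"),
        P_dimus=muscle_wave(pattern, t, "di"),
        P_rex=p_rex,
    )


def yoshimura_prefold_angle(gamma: float, M: int) -> float:
    """Pre-folding angle (degrees) closing a Yoshimura origami tube.

    Solves the closure condition ``tan(gamma) * cos(theta/2) = tan(pi/M)``
    for theta, given the trapezoid base angle ``gamma`` (degrees) and the
    number of horizontal trapezoids ``M``.
    """
    if not (0.0 < gamma < 90.0):
        raise ValueError("gamma must lie in (0, 90) degrees")
    if not (isinstance(M, (int, np.integer)) and M >= 3):
        raise ValueError("M must be an integer >= 3")
    ratio = math.tan(math.pi / M) / math.tan(math.radians(gamma))
    if ratio > 1.0:
        raise ValueError(
            f"no closed solution: tan(pi/{M}) exceeds tan({gamma} deg)"
        )
    return math.degrees(2.0 * math.acos(ratio))


def pattern_program_to_yaml(
    pattern: BreathPattern, program: RobotPressureProgram | None = None
) -> str:
    """Serialize a breath pattern and optional robot program to YAML."""
    doc: dict = {
        "breath": {"T": pattern.T, "f_insp": pattern.f_insp,
                   "A_rc": pattern.A_rc, "A_dim": pattern.A_dim},
    }
    if program is not None:
        doc["robot"] = {
            "shape": program.shape, "level_kPa": program.level_kPa,
            "k_transmission": program.k_transmission, "t_inflate": program.t_inflate,
        }
    return yaml.safe_dump(doc, sort_keys=True)


def pattern_program_from_yaml(text: str) -> tuple[BreathPattern, RobotPressureProgram | None]:
    doc = yaml.safe_load(text)
    pattern = BreathPattern(**doc["breath"])
    program = RobotPressureProgram(**doc["robot"]) if "robot" in doc else None
    return pattern, program
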