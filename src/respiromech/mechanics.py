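"""Coupled human-robot two-compartment respiratory mechanics.

The chest wall is modelled as two compartments — rib cage and abdomen —
separated by the diaphragm and coupled to the lung through the pleural
cavity. Each compartment is a first-order resistance-compliance element
driven by a pressure: the rib-cage inspiratory muscles (``P_rcmus``), the
diaphragm muscle (``P_dimus``), and the extracorporeal robotic pressure
applied to the abdominal wall (``P_rex``), which adds to the diaphragm
drive::

    R_rc dV_rc/dt + V_rc / C_rc = P_rcmus
    R_ab dV_ab/dt + V_ab / C_ab = P_dimus + P_rex
    P_pl = (V_ab + V_rc) / C_pl
    R_l  dV_l/dt  + V_l / C_l  = P_pl

Volumes are deviations from the end-expiratory (functional residual
capacity) baseline, in litres; pressures in cmH2O; time in seconds.
Cranio-caudal diaphragm displacement follows from the displaced abdominal
volume over the body cross-sectional area ``A_di``:
``x_di = V_ab / A_di`` (with explicit L -> m^3 and m -> cm conversions).

Robotic expiratory assistance is encoded as a *negative* ``P_rex`` trace
during the expiratory phase: the robot compresses the abdominal wall
inward, pushing the diaphragm cranially (negative ``V_ab``), while the
additive structure of the abdominal driving pressure is kept intact.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MechanicalParameters",
    "DriveSignals",
    "StateTrajectory",
    "compartment_derivatives",
    "simulate",
    "diaphragm_displacement",
    "pleural_pressure",
    "abdominal_pressure",
    "step_response_closed_form",
]

#: Reference simulation constants of the respiratory model (healthy adult).
TABLE_DEFAULTS = {
    "R_rc": 1.0,
    "R_ab": 1.0,
    "R_l": 2.0,
    "C_rc": 0.2,
    "C_ab": 0.4,
    "C_l": 0.2,
    "C_pl": 0.25,
    "A_di": 0.08,
}


@dataclass(frozen=True)
class MechanicalParameters:
    """Resistances, compliances and body area of the coupled model.

    Units: resistances cmH2O/(L*s); compliances L/cmH2O; ``A_di`` m^2
    (body cross-sectional area, approximately weight over height).
    Defaults are the reference simulation values for a healthy adult.
    """

    R_rc: float = TABLE_DEFAULTS["R_rc"]
    R_ab: float = TABLE_DEFAULTS["R_ab"]
    R_l: float = TABLE_DEFAULTS["R_l"]
    C_rc: float = TABLE_DEFAULTS["C_rc"]
    C_ab: float = TABLE_DEFAULTS["C_ab"]
    C_l: float = TABLE_DEFAULTS["C_l"]
    C_pl: float = TABLE_DEFAULTS["C_pl"]
    A_di: float = TABLE_DEFAULTS["A_di"]

    def __post_init__(self) -> None:
        for name in ("R_rc", "R_ab", "R_l", "C_rc", "C_ab", "C_l", "C_pl", "A_di"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"parameter {name} must be strictly positive, got {value!r}")

    def replace(self, **kwargs) -> "MechanicalParameters":
        return replace(self, **kwargs)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class DriveSignals:
    """Time-aligned muscle and robotic pressure traces on a uniform grid.

    ``t`` in s; ``P_rcmus``, ``P_dimus``, ``P_rex`` in cmH2O. All four
    sequences share a length of at least two, and ``t`` must be strictly
    increasing with a constant step.
    """

    t: np.ndarray
    P_rcmus: np.ndarray
    P_dimus: np.ndarray
    P_rex: np.ndarray

    def __post_init__(self) -> None:
        t = _as_1d(self.t, "t")
        object.__setattr__(self, "t", t)
        for name in ("P_rcmus", "P_dimus", "P_rex"):
            arr = _as_1d(getattr(self, name), name)
            if arr.shape != t.shape:
                raise ValueError(f"{name} length {arr.size} does not match t length {t.size}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        if t.size < 2:
            raise ValueError("drive signals need at least two samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("t must be strictly increasing")
        h = steps[0]
        if not np.allclose(steps, h, rtol=1e-9, atol=0.0):
            raise ValueError("t must have a constant step")

    @property
    def dt(self) -> float:
        """Grid step in seconds."""
        return float(self.t[1] - self.t[0])

    def __add__(self, other: "DriveSignals") -> "DriveSignals":
        if not np.array_equal(self.t, other.t):
            raise ValueError("drive grids differ")
        return DriveSignals(
            self.t,
            self.P_rcmus + other.P_rcmus,
            self.P_dimus + other.P_dimus,
            self.P_rex + other.P_rex,
        )

    def to_csv(self, path_or_buf) -> None:
        _write_csv(
            path_or_buf,
            {"t": self.t, "P_rcmus": self.P_rcmus, "P_dimus": self.P_dimus, "P_rex": self.P_rex},
            units="s, cmH2O, cmH2O, cmH2O",
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "DriveSignals":
        df = pd.read_csv(path_or_buf, comment="#")
        return cls(df["t"].to_numpy(), df["P_rcmus"].to_numpy(),
                   df["P_dimus"].to_numpy(), df["P_rex"].to_numpy())


@dataclass(frozen=True)
class StateTrajectory:
    """Simulated compartment volumes and derived pressures/displacement.

    ``V_rc``, ``V_ab``, ``V_l`` are volume deviations from baseline (L);
    ``P_pl`` pleural pressure and ``P_ab`` abdominal driving pressure
    (cmH2O); ``x_di`` diaphragm displacement (cm, positive = caudal).
    """

    t: np.ndarray
    V_rc: np.ndarray
    V_ab: np.ndarray
    V_l: np.ndarray
    P_pl: np.ndarray
    P_ab: np.ndarray
    x_di: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_csv(self, path_or_buf) -> None:
        _write_csv(
            path_or_buf,
            {
                "t": self.t, "V_rc": self.V_rc, "V_ab": self.V_ab, "V_l": self.V_l,
                "P_pl": self.P_pl, "P_ab": self.P_ab, "x_di": self.x_di,
            },
            units="s, L, L, L, cmH2O, cmH2O, cm",
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "StateTrajectory":
        df = pd.read_csv(path_or_buf, comment="#")
        return cls(*(df[c].to_numpy() for c in ("t", "V_rc", "V_ab", "V_l", "P_pl", "P_ab", "x_di")))


def _write_csv(path_or_buf, columns: dict, units: str) -> None:
    # repr-level precision so round trips are lossless well past 12 digits
    df = pd.DataFrame(columns)
    buf = io.StringIO()
    buf.write(f"# units: {units}\n")
    df.to_csv(buf, index=False, float_format="%.17g")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def _check_finite_scalar(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value for {name}: {value!r}")
    return value


def compartment_derivatives(
    v_rc: float,
    v_ab: float,
    v_l: float,
    p_rcmus: float,
    p_dimus: float,
    p_rex: float,
    params: MechanicalParameters,
) -> tuple[float, float, float]:
    """Instantaneous volume rates (L/s) of the three compartments.

    Evaluates the first-order balance of each compartment: drive pressure
    minus elastic recoil, over the resistance. The lung is driven by the
    pleural pressure generated by the combined rib-cage and abdominal
    volume displacement.
    """
    v_rc = _check_finite_scalar(v_rc, "v_rc")
    v_ab = _check_finite_scalar(v_ab, "v_ab")
    v_l = _check_finite_scalar(v_l, "v_l")
    p_rcmus = _check_finite_scalar(p_rcmus, "p_rcmus")
    p_dimus = _check_finite_scalar(p_dimus, "p_dimus")
    p_rex = _check_finite_scalar(p_rex, "p_rex")
    d_rc = (p_rcmus - v_rc / params.C_rc) / params.R_rc
    d_ab = (p_dimus + p_rex - v_ab / params.C_ab) / params.R_ab
    d_l = ((v_ab + v_rc) / params.C_pl - v_l / params.C_l) / params.R_l
    return d_rc, d_ab, d_l


def diaphragm_displacement(v_ab, a_di: float):
    """Cranio-caudal diaphragm displacement (cm) from abdominal volume (L).

    The inward/outward motion of the ventral abdominal wall displaces an
    equal diaphragmatic volume, so displacement is the displaced volume
    over the body cross-sectional area: explicit conversions take litres
    to cubic metres (1e-3) and metres to centimetres (100).
    """
    if not (a_di > 0):
        raise ValueError(f"a_di must be positive, got {a_di!r}")
    return 100.0 * (np.asarray(v_ab, dtype=float) * 1e-3) / a_di


def pleural_pressure(v_rc, v_ab, c_pl: float):
    """Pleural pressure (cmH2O) from the combined chest-wall displacement."""
    if not (c_pl > 0):
        raise ValueError(f"c_pl must be positive, got {c_pl!r}")
    return (np.asarray(v_ab, dtype=float) + np.asarray(v_rc, dtype=float)) / c_pl


def abdominal_pressure(p_dimus, p_rex):
    """Total abdominal driving pressure: diaphragm muscle plus robot (cmH2O)."""
    a = np.asarray(p_dimus, dtype=float)
    b = np.asarray(p_rex, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("abdominal_pressure requires finite inputs")
    return a + b


def step_response_closed_form(R: float, C: float, P0: float, t):
    """Analytic first-order step response ``C*P0*(1 - exp(-t/(R*C)))`` in L.

    Serves as the independent oracle for the rib-cage and abdominal
    compartments under a constant drive.
    """
    if not (R > 0 and C > 0):
        raise ValueError("R and C must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return C * P0 * (1.0 - np.exp(-t / (R * C)))


def simulate(
    params: MechanicalParameters,
    drives: DriveSignals,
    init: tuple[float, float, float] = (0.0, 0.0, 0.0),
    dt: float = 1e-3,
) -> StateTrajectory:
    """Integrate the coupled compartment ODEs with classical RK4.

    Drives are interpolated linearly between grid points; integration uses
    a fixed step of at most ``dt`` chosen to divide the drive grid step
    evenly, and the trajectory is returned on the drive grid. The system
    is linear with time constants well above a millisecond, so the default
    1 ms step resolves it to well below measurement precision.
    """
    if not (dt > 0):
        raise ValueError(f"dt must be positive, got {dt!r}")
    h = drives.dt
    if dt > h * (1 + 1e-9):
        raise ValueError(f"dt={dt} exceeds the drive grid step {h}")
    for i, name in enumerate(("V_rc", "V_ab", "V_l")):
        _check_finite_scalar(init[i], f"init {name}")

    n_sub = max(1, int(math.ceil(h / dt - 1e-9)))
    step = h / n_sub
    n_grid = drives.t.size

    # drives on the fine grid; linear interpolation makes midpoints averages
    if n_sub == 1:
        u_rc = drives.P_rcmus
        u_ab = drives.P_dimus + drives.P_rex
    else:
        fine_t = drives.t[0] + step * np.arange((n_grid - 1) * n_sub + 1)
        u_rc = np.interp(fine_t, drives.t, drives.P_rcmus)
        u_ab = np.interp(fine_t, drives.t, drives.P_dimus + drives.P_rex)

    r_rc, r_ab, r_l = params.R_rc, params.R_ab, params.R_l
    c_rc, c_ab, c_l, c_pl = params.C_rc, params.C_ab, params.C_l, params.C_pl

    v_rc, v_ab, v_l = float(init[0]), float(init[1]), float(init[2])
    out_rc = np.empty(n_grid)
    out_ab = np.empty(n_grid)
    out_l = np.empty(n_grid)
    out_rc[0], out_ab[0], out_l[0] = v_rc, v_ab, v_l

    u_rc_l = u_rc.tolist()
    u_ab_l = u_ab.tolist()
    half = step / 2.0
    sixth = step / 6.0
    idx = 0
    for g in range(1, n_grid):
        for _ in range(n_sub):
            ur0, ua0 = u_rc_l[idx], u_ab_l[idx]
            ur1, ua1 = u_rc_l[idx + 1], u_ab_l[idx + 1]
            urm, uam = 0.5 * (ur0 + ur1), 0.5 * (ua0 + ua1)

            k1_rc = (ur0 - v_rc / c_rc) / r_rc
            k1_ab = (ua0 - v_ab / c_ab) / r_ab
            k1_l = ((v_ab + v_rc) / c_pl - v_l / c_l) / r_l

            y_rc = v_rc + half * k1_rc
            y_ab = v_ab + half * k1_ab
            y_l = v_l + half * k1_l
            k2_rc = (urm - y_rc / c_rc) / r_rc
            k2_ab = (uam - y_ab / c_ab) / r_ab
            k2_l = ((y_ab + y_rc) / c_pl - y_l / c_l) / r_l

            y_rc = v_rc + half * k2_rc
            y_ab = v_ab + half * k2_ab
            y_l = v_l + half * k2_l
            k3_rc = (urm - y_rc / c_rc) / r_rc
            k3_ab = (uam - y_ab / c_ab) / r_ab
            k3_l = ((y_ab + y_rc) / c_pl - y_l / c_l) / r_l

            y_rc = v_rc + step * k3_rc
            y_ab = v_ab + step * k3_ab
            y_l = v_l + step * k3_l
            k4_rc = (ur1 - y_rc / c_rc) / r_rc
            k4_ab = (ua1 - y_ab / c_ab) / r_ab
            k4_l = ((y_ab + y_rc) / c_pl - y_l / c_l) / r_l

            v_rc += sixth * (k1_rc + 2.0 * (k2_rc + k3_rc) + k4_rc)
            v_ab += sixth * (k1_ab + 2.0 * (k2_ab + k3_ab) + k4_ab)
            v_l += sixth * (k1_l + 2.0 * (k2_l + k3_l) + k4_l)
            idx += 1
        out_rc[g], out_ab[g], out_l[g] = v_rc, v_ab, v_l

    return StateTrajectory(
        t=drives.t.copy(),
        V_rc=out_rc,
        V_ab=out_ab,
        V_l=out_l,
        P_pl=pleural_pressure(out_rc, out_ab, c_pl),
        P_ab=abdominal_pressure(drives.P_dimus, drives.P_rex),
        x_di=diaphragm_displacement(out_ab, params.A_di),
    )
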