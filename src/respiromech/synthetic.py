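"""Synthetic cohorts, recordings, and M-mode-style images.

Emulates the measurement structure of a robotic-ventilation study on a
small healthy cohort: each participant is a set of respiratory mechanics
parameters (lognormal inter-individual variability around the reference
values) with a breath pattern; a session simultaneously records a noisy
diaphragm-displacement trace (ultrasound surrogate) and an airflow trace
(spirometer surrogate) under the spontaneous or robot-assisted condition.
The noiseless simulated trajectory is retained as ground truth for
oracle testing only.

Amplitude calibration reproduces printed single-subject reference values
(spontaneous excursion and tidal volume); assist calibration scales the
robot's effective pressure and the assisted rib-cage amplitude so the
cohort reaches prescribed assisted/spontaneous fold changes — an explicit
calibration knob emulating the study aggregates, not a model prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import metrics
from .mechanics import MechanicalParameters, StateTrajectory, simulate
from .waveforms import BreathPattern, RobotPressureProgram, build_drives

__all__ = [
    "ParticipantProfile",
    "SessionRecording",
    "ImageSpec",
    "sample_cohort",
    "calibrate_amplitudes",
    "calibrate_assist",
    "generate_session",
    "render_mmode",
]

#: Default additive measurement noise SDs for the two surrogate channels.
DEFAULT_NOISE_DISP_CM = 0.05
DEFAULT_NOISE_FLOW_LPS = 0.02

#: Default shared sampling rate of a session recording (Hz).
DEFAULT_FS = 50.0

#: Muscle amplitude search bounds for calibration, cmH2O.
AMPLITUDE_BOUNDS = (0.0, 50.0)

#: Spontaneous reference values of the typical participant: per-breath
#: diaphragm excursion (cm) and tidal volume (L).
REFERENCE_SPONT_EXCURSION_CM = 1.14
REFERENCE_SPONT_VT_L = 0.83

#: Cohort-average assisted/spontaneous fold changes used as calibration
#: targets for displacement and tidal volume.
REFERENCE_DISP_RATIO = 1.95
REFERENCE_VT_RATIO = 2.14


@dataclass(frozen=True)
class ParticipantProfile:
    """A synthetic participant: mechanics, breath pattern, noise levels."""

    params: MechanicalParameters = field(default_factory=MechanicalParameters)
    pattern: BreathPattern = field(default_factory=BreathPattern)
    noise_disp: float = DEFAULT_NOISE_DISP_CM
    noise_flow: float = DEFAULT_NOISE_FLOW_LPS
    id: str = "P0"

    def __post_init__(self) -> None:
        if self.noise_disp < 0 or self.noise_flow < 0:
            raise ValueError("noise SDs must be non-negative")

    def replace_pattern(self, **kwargs) -> "ParticipantProfile":
        from dataclasses import replace
        return replace(self, pattern=self.pattern.replace(**kwargs))


@dataclass(frozen=True)
class SessionRecording:
    """A synthetic measured session on a shared uniform grid.

    ``displacement`` (cm) and ``flow`` (L/s) carry measurement noise;
    ``truth`` is the noiseless simulated trajectory, retained for oracle
    testing only and never fed back into the analysis pipeline. The
    breath pattern and robot program document the experimental protocol
    (timing is known to the experimenter; muscle amplitudes are not
    observable and must be estimated).
    """

    condition: str
    t: np.ndarray
    displacement: np.ndarray
    flow: np.ndarray
    pattern: BreathPattern
    truth: StateTrajectory | None = None
    program: RobotPressureProgram | None = None
    subject_id: str = "P0"

    def __post_init__(self) -> None:
        if self.condition not in ("spontaneous", "assisted"):
            raise ValueError("condition must be 'spontaneous' or 'assisted'")
        if not (self.t.shape == self.displacement.shape == self.flow.shape):
            raise ValueError("displacement and flow must share the time grid")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def sample_cohort(n: int, seed: int, cv: float = 0.2) -> list[ParticipantProfile]:
    """Draw ``n`` synthetic participants around the reference mechanics.

    Each resistance and compliance is the reference value times an
    independent unit-mean lognormal factor with coefficient of variation
    ``cv`` (multiplicative variability keeps every parameter positive);
    breath periods are uniform over the typical 3-6 s adult range.
    Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(cv)
    mu = -0.5 * sigma * sigma  # unit-mean lognormal
    names = ("R_rc", "R_ab", "R_l", "C_rc", "C_ab", "C_l", "C_pl")
    base = MechanicalParameters()
    profiles = []
    for i in range(n):
        factors = rng.lognormal(mean=mu, sigma=sigma, size=len(names))
        params = base.replace(**{k: getattr(base, k) * f for k, f in zip(names, factors)})
        T = float(rng.uniform(3.0, 6.0))
        profiles.append(
            ParticipantProfile(
                params=params,
                pattern=BreathPattern(T=T, f_insp=0.5),
                id=f"P{i + 1}",
            )
        )
    return profiles


def generate_session(
    profile: ParticipantProfile,
    condition: str,
    program: RobotPressureProgram | None = None,
    n_breaths: int = 6,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    dt: float | None = None,
    pattern: BreathPattern | None = None,
) -> SessionRecording:
    """Simulate one measured session for a participant.

    Builds the muscle drives (plus the robot program when assisted),
    integrates the mechanics model, derives flow as the first difference
    of lung volume over the sampling step, and adds independent zero-mean
    Gaussian noise to each channel. ``dt`` defaults to the sampling step
    itself (fourth-order integration at these time constants is accurate
    to ~1e-5 relative at a 20 ms step). Deterministic given the seed.
    """
    if n_breaths < 3:
        raise ValueError("need at least 3 breath cycles per session")
    if condition == "assisted" and program is None:
        raise ValueError("assisted condition requires a robot program")
    if condition == "spontaneous":
        program = None
    pat = pattern if pattern is not None else profile.pattern
    h = 1.0 / fs
    n = int(round(n_breaths * pat.T * fs)) + 1
    t = h * np.arange(n)
    drives = build_drives(pat, t, program)
    truth = simulate(profile.params, drives, dt=(dt if dt is not None else h))
    flow = np.empty(n)
    flow[0] = 0.0
    flow[1:] = np.diff(truth.V_l) / h
    rng = np.random.default_rng(seed)
    disp = truth.x_di + rng.normal(0.0, profile.noise_disp, n)
    flow_noisy = flow + rng.normal(0.0, profile.noise_flow, n)
    return SessionRecording(
        condition=condition,
        t=t,
        displacement=disp,
        flow=flow_noisy,
        truth=truth,
        pattern=pat,
        program=program,
        subject_id=profile.id,
    )


def _noiseless(profile: ParticipantProfile) -> ParticipantProfile:
    from dataclasses import replace
    return replace(profile, noise_disp=0.0, noise_flow=0.0)


def _spont_summary(
    profile: ParticipantProfile, pattern: BreathPattern, n_breaths: int, fs: float
) -> dict:
    rec = generate_session(
        _noiseless(profile), "spontaneous", n_breaths=n_breaths, fs=fs, pattern=pattern
    )
    return metrics.session_summary(rec.displacement, rec.flow, rec.dt, pattern.T)


def calibrate_amplitudes(
    profile: ParticipantProfile,
    target_VT: float = REFERENCE_SPONT_VT_L,
    target_excursion: float = REFERENCE_SPONT_EXCURSION_CM,
    n_breaths: int = 6,
    fs: float = DEFAULT_FS,
    clamp: bool = False,
) -> tuple[float, float]:
    """Muscle amplitudes (A_rc, A_dim) reproducing spontaneous targets.

    The diaphragm amplitude is set directly from the excursion target via
    the linear abdominal-channel gain (excursion is exactly proportional
    to A_dim in a spontaneous breath); the rib-cage amplitude is then
    found by a one-dimensional root search so the measured mean tidal
    volume matches its target. Raises when the targets are unattainable
    within the amplitude bounds, unless ``clamp`` is set, in which case
    the nearest attainable rib-cage amplitude is returned (a sampled
    participant whose diaphragm-driven tidal volume already exceeds the
    target gets A_rc = 0).
    """
    if not (target_VT > 0 and target_excursion > 0):
        raise ValueError("targets must be positive")
    lo, hi = AMPLITUDE_BOUNDS

    unit = _spont_summary(profile, profile.pattern.replace(A_dim=1.0, A_rc=0.0), n_breaths, fs)
    a_dim = target_excursion / unit["mean_excursion_cm"]
    if not (lo <= a_dim <= hi):
        raise ValueError(f"excursion target needs A_dim={a_dim:.2f} outside bounds {AMPLITUDE_BOUNDS}")

    def vt_gap(a_rc: float) -> float:
        s = _spont_summary(profile, profile.pattern.replace(A_dim=a_dim, A_rc=a_rc), n_breaths, fs)
        return s["mean_vt_L"] - target_VT

    g_lo, g_hi = vt_gap(lo), vt_gap(hi)
    if g_lo > 0:
        if clamp:
            return lo, a_dim
        raise ValueError("VT target below the diaphragm-only tidal volume: unattainable")
    if g_hi < 0:
        if clamp:
            return hi, a_dim
        raise ValueError("VT target unattainable within amplitude bounds")
    a_rc = float(brentq(vt_gap, lo, hi, xtol=1e-8, rtol=1e-12))
    return a_rc, a_dim


def calibrate_assist(
    profile: ParticipantProfile,
    program: RobotPressureProgram,
    target_disp_ratio: float = REFERENCE_DISP_RATIO,
    target_vt_ratio: float | None = REFERENCE_VT_RATIO,
    n_breaths: int = 6,
    fs: float = DEFAULT_FS,
) -> tuple[RobotPressureProgram, BreathPattern]:
    """Scale the robot program and assisted rib-cage amplitude to targets.

    Two decoupled one-dimensional searches: the effective robotic pressure
    (via ``k_transmission``) sets the assisted/spontaneous excursion fold
    change — excursion depends only on the abdominal channel — and the
    assisted-condition rib-cage amplitude then sets the tidal-volume fold
    change (skipped, leaving the rib-cage amplitude unchanged, when
    ``target_vt_ratio`` is None). Returns the scaled program and the
    assisted breath pattern.
    """
    pat = profile.pattern
    # synchronize the robot with the participant's rhythm: the inflation
    # cannot outlast this subject's expiratory window
    t_exp = (1.0 - pat.f_insp) * pat.T
    if program.t_inflate > t_exp:
        program = program.replace(t_inflate=t_exp)
    base = _spont_summary(profile, pat, n_breaths, fs)
    e0, v0 = base["mean_excursion_cm"], base["mean_vt_L"]

    def assisted_summary(prog: RobotPressureProgram, pattern: BreathPattern) -> dict:
        rec = generate_session(
            _noiseless(profile), "assisted", prog, n_breaths=n_breaths, fs=fs, pattern=pattern
        )
        return metrics.session_summary(rec.displacement, rec.flow, rec.dt, pattern.T)

    def disp_gap(scale: float) -> float:
        prog = program.replace(k_transmission=program.k_transmission * scale)
        return assisted_summary(prog, pat)["mean_excursion_cm"] / e0 - target_disp_ratio

    if disp_gap(0.0) > 0:
        raise ValueError("displacement ratio target below 1: unattainable with assistance")
    hi = 50.0
    if disp_gap(hi) < 0:
        raise ValueError("displacement ratio target unattainable within transmission bounds")
    scale = float(brentq(disp_gap, 0.0, hi, xtol=1e-8, rtol=1e-12))
    prog_cal = program.replace(k_transmission=program.k_transmission * scale)

    if target_vt_ratio is None:
        return prog_cal, pat

    lo_a, hi_a = AMPLITUDE_BOUNDS

    def vt_gap(a_rc: float) -> float:
        return assisted_summary(prog_cal, pat.replace(A_rc=a_rc))["mean_vt_L"] / v0 - target_vt_ratio

    if vt_gap(lo_a) > 0:
        raise ValueError("VT ratio target below the zero-ribcage assisted ratio: unattainable")
    if vt_gap(hi_a) < 0:
        raise ValueError("VT ratio target unattainable within amplitude bounds")
    a_rc_assist = float(brentq(vt_gap, lo_a, hi_a, xtol=1e-8, rtol=1e-12))
    return prog_cal, pat.replace(A_rc=a_rc_assist)


# --- M-mode image synthesis -------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Geometry and intensity of a synthetic M-mode rendering.

    Depth spans ``depth_min``..``depth_max`` cm over ``pixels_depth``
    rows (row 0 shallowest, depth increasing downward); the diaphragm
    appears as a Gaussian-profile bright band of full-width-half-maximum
    ``band_width`` cm on a darker speckle-free background. Positive
    displacement (toward the probe) shifts the band to shallower depth
    from ``baseline_depth`` (defaults to mid-range).
    """

    depth_min: float = 0.0
    depth_max: float = 6.0
    pixels_depth: int = 256
    band_width: float = 0.4
    background_level: int = 30
    band_level: int = 220
    baseline_depth: float | None = None

    def __post_init__(self) -> None:
        if not (self.depth_max > self.depth_min):
            raise ValueError("depth_max must exceed depth_min")
        if self.pixels_depth < 2:
            raise ValueError("pixels_depth must be >= 2")
        if not (self.band_width > 0):
            raise ValueError("band_width must be positive")
        if not (0 <= self.background_level < self.band_level <= 255):
            raise ValueError("need 0 <= background_level < band_level <= 255")

    @property
    def pixel_size(self) -> float:
        """Depth extent of one pixel row, cm."""
        return (self.depth_max - self.depth_min) / self.pixels_depth

    @property
    def baseline(self) -> float:
        if self.baseline_depth is not None:
            return self.baseline_depth
        return 0.5 * (self.depth_min + self.depth_max)

    def row_depths(self) -> np.ndarray:
        """Depth (cm) at each pixel-row center."""
        return self.depth_min + (np.arange(self.pixels_depth) + 0.5) * self.pixel_size

    def depth_to_row(self, depth) -> np.ndarray:
        return (np.asarray(depth, dtype=float) - self.depth_min) / self.pixel_size - 0.5


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def render_mmode(displacement, spec: ImageSpec) -> np.ndarray:
    """Render a displacement trace as an 8-bit grayscale M-mode image.

    One image column per time sample; each column carries a Gaussian
    bright band centered at the depth corresponding to that sample's
    displacement. Returns an array of shape (pixels_depth, n_samples).
    """
    disp = np.asarray(displacement, dtype=float)
    if disp.ndim != 1 or disp.size == 0:
        raise ValueError("displacement must be a non-empty 1-D trace")
    depth = spec.baseline - disp
    if np.any(depth < spec.depth_min) or np.any(depth > spec.depth_max):
        raise ValueError("displacement exceeds the image depth range")
    sigma = spec.band_width * _FWHM_TO_SIGMA
    rows = spec.row_depths()[:, None]
    profile = np.exp(-((rows - depth[None, :]) ** 2) / (2.0 * sigma * sigma))
    img = spec.background_level + (spec.band_level - spec.background_level) * profile
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
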