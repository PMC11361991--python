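"""Measurement and evaluation procedures for breathing recordings.

Implements the study-style processing chain: breath-cycle segmentation,
tidal volume by numerical integration of spirometer flow over the
inspiratory phase, per-breath diaphragm excursion (peak-to-trough
displacement), phase-normalized cycle averaging (20 points per cycle over
3 consecutive cycles), amplitude error and range-normalized RMSE between
simulated and observed traces, displacement-volume correlation, and the
paired spontaneous-vs-assisted comparison (exact Wilcoxon signed-rank).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "BreathSegmentation",
    "ComparisonResult",
    "segment_breaths",
    "tidal_volumes",
    "excursions",
    "normalize_cycles",
    "amplitude_error",
    "nrmse",
    "displacement_volume_correlation",
    "paired_ratio_test",
    "session_summary",
]

#: Hysteresis half-band for flow zero-crossing detection, fraction of peak.
FLOW_HYSTERESIS_FRACTION = 0.02


@dataclass(frozen=True)
class BreathSegmentation:
    """Cycle-start sample indices; consecutive boundaries bound one cycle."""

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=int)
        object.__setattr__(self, "boundaries", b)
        if b.size < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("segmentation needs >= 2 strictly increasing boundaries")

    @property
    def n_cycles(self) -> int:
        return self.boundaries.size - 1

    def cycles(self):
        """Iterate (start, stop) index pairs, stop inclusive of the boundary."""
        b = self.boundaries
        for k in range(self.n_cycles):
            yield int(b[k]), int(b[k + 1])


def segment_breaths(
    trace,
    kind: str,
    dt: float,
    nominal_period: float | None = None,
) -> BreathSegmentation:
    """Locate breath-cycle starts in a flow or displacement trace.

    Flow: negative-to-positive zero crossings with a hysteresis band of
    +/-2% of the peak magnitude; consecutive crossings closer than half
    the nominal period (when given) are treated as chatter of a single
    crossing and ignored. Displacement: local minima separated by at least
    half the nominal period, located on a lightly smoothed copy so that
    sample-level noise does not split minima.
    """
    trace = np.asarray(trace, dtype=float)
    if not (dt > 0):
        raise ValueError("dt must be positive")
    if nominal_period is not None and nominal_period > 0:
        if trace.size * dt <= nominal_period:
            raise ValueError("trace shorter than one nominal period")
    if np.ptp(trace) == 0.0:
        raise ValueError("no complete cycle: constant trace")

    if kind == "flow":
        peak = float(np.max(np.abs(trace)))
        h = FLOW_HYSTERESIS_FRACTION * peak
        refractory = 0
        if nominal_period is not None and nominal_period > 0:
            refractory = int(round(0.5 * nominal_period / dt))
        boundaries = []
        armed = False
        last = -10**9
        for i, v in enumerate(trace):
            if v < -h:
                armed = True
            elif armed and v > h:
                if i - last >= refractory:
                    boundaries.append(i)
                    last = i
                armed = False
        if len(boundaries) < 2:
            raise ValueError("no complete cycle found in flow trace")
        return BreathSegmentation(np.asarray(boundaries))

    if kind == "displacement":
        if nominal_period is None or nominal_period <= 0:
            raise ValueError("displacement segmentation requires a nominal period")
        distance = max(1, int(round(0.5 * nominal_period / dt)))
        sigma = max(1.0, 0.05 * nominal_period / dt)
        smooth = gaussian_filter1d(trace, sigma, mode="nearest")
        minima, _ = _sig.find_peaks(-smooth, distance=distance)
        if minima.size < 2:
            raise ValueError("no complete cycle found in displacement trace")
        return BreathSegmentation(minima)

    raise ValueError(f"kind must be 'flow' or 'displacement', got {kind!r}")


def tidal_volumes(flow, seg: BreathSegmentation, dt: float) -> np.ndarray:
    """Per-breath tidal volume (L): trapezoidal integral of inspiratory flow."""
    if not (dt > 0):
        raise ValueError("dt must be positive")
    flow = np.asarray(flow, dtype=float)
    insp = np.clip(flow, 0.0, None)
    return np.array([np.trapezoid(insp[a:b + 1], dx=dt) for a, b in seg.cycles()])


def excursions(displacement, seg: BreathSegmentation) -> np.ndarray:
    """Per-breath excursion (cm): peak-to-trough displacement per cycle."""
    displacement = np.asarray(displacement, dtype=float)
    return np.array([np.ptp(displacement[a:b + 1]) for a, b in seg.cycles()])


def normalize_cycles(
    trace, seg: BreathSegmentation, n_points: int = 20, n_cycles: int = 3
) -> np.ndarray:
    """Phase-normalized average curve over consecutive cycles.

    Each cycle is linearly resampled to ``n_points`` values over the
    normalized phase [0, 1), then the first ``n_cycles`` cycles are
    averaged pointwise.
    """
    trace = np.asarray(trace, dtype=float)
    if seg.n_cycles < n_cycles:
        raise ValueError(f"segmentation has {seg.n_cycles} cycles, need {n_cycles}")
    phase = np.arange(n_points) / n_points
    rows = []
    for k, (a, b) in enumerate(seg.cycles()):
        if k >= n_cycles:
            break
        xs = a + phase * (b - a)
        rows.append(np.interp(xs, np.arange(trace.size), trace))
    return np.mean(rows, axis=0)


def amplitude_error(sim_amplitude: float, obs_amplitude: float) -> float:
    """Relative amplitude error in percent: 100*|sim - obs|/obs."""
    if not (obs_amplitude > 0):
        raise ValueError("observed amplitude must be positive")
    return 100.0 * abs(sim_amplitude - obs_amplitude) / obs_amplitude


def nrmse(sim, obs) -> float:
    """RMSE normalized by the observed peak-to-peak range, in percent."""
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("traces must have equal length")
    rng = float(np.ptp(obs))
    if rng == 0.0:
        raise ValueError("observed trace has zero range")
    return 100.0 * math.sqrt(float(np.mean((sim - obs) ** 2))) / rng


def displacement_volume_correlation(pairs) -> dict:
    """Pearson correlation between excursion and tidal volume pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (excursion, VT) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero-variance input")
    res = _stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue)}


@dataclass(frozen=True)
class ComparisonResult:
    """Paired spontaneous-vs-assisted comparison over a cohort.

    ``ratio_means`` is mean(assisted)/mean(spontaneous);
    ``mean_of_ratios`` averages per-subject ratios instead — both are
    reported because either convention is defensible for a cohort-level
    fold change.
    """

    ratio_means: float
    mean_of_ratios: float
    p_value: float
    per_subject_pairs: list

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def paired_ratio_test(spont, assisted) -> ComparisonResult:
    """Cohort fold change plus exact two-sided Wilcoxon signed-rank test.

    The exact null distribution is used for cohorts of up to 25 subjects
    (no normality assumption); identical paired values yield p = 1.
    """
    spont = np.asarray(spont, dtype=float)
    assisted = np.asarray(assisted, dtype=float)
    if spont.shape != assisted.shape or spont.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    mean_spont = float(np.mean(spont))
    if mean_spont == 0.0:
        raise ValueError("zero spontaneous mean")
    diffs = assisted - spont
    if np.all(diffs == 0.0):
        p = 1.0
    else:
        method = "exact" if spont.size <= 25 else "auto"
        try:
            res = _stats.wilcoxon(assisted, spont, alternative="two-sided", method=method)
        except ValueError:
            res = _stats.wilcoxon(assisted, spont, alternative="two-sided")
        p = float(res.pvalue)
    return ComparisonResult(
        ratio_means=float(np.mean(assisted)) / mean_spont,
        mean_of_ratios=float(np.mean(assisted / spont)),
        p_value=p,
        per_subject_pairs=[(float(s), float(a)) for s, a in zip(spont, assisted)],
    )


#: Default low-pass width (s) applied to measured channels before
#: per-breath amplitude measurement. Breathing content lies well below
#: 1 Hz, while peak-to-trough statistics on raw noisy samples carry an
#: extreme-value bias; the same smoothing is applied wherever sessions
#: are measured (calibration, analysis, fit scoring) so the procedure is
#: self-consistent.
SESSION_SMOOTH_S = 0.15


def session_summary(
    displacement, flow, dt: float, nominal_period: float,
    smooth_s: float = SESSION_SMOOTH_S,
) -> dict:
    """Mean per-breath excursion and tidal volume of one recording.

    Convenience wrapper used by calibration and the analysis pipeline:
    low-passes both channels (Gaussian, width ``smooth_s`` seconds), then
    segments the displacement (minima) and flow (zero crossings) channels
    independently and averages the per-breath measures.
    """
    displacement = np.asarray(displacement, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if smooth_s > 0:
        sigma = smooth_s / dt
        displacement = gaussian_filter1d(displacement, sigma, mode="nearest")
        flow = gaussian_filter1d(flow, sigma, mode="nearest")
    seg_d = segment_breaths(displacement, "displacement", dt, nominal_period)
    seg_f = segment_breaths(flow, "flow", dt, nominal_period)
    exc = excursions(displacement, seg_d)
    vt = tidal_volumes(flow, seg_f, dt)
    return {
        "mean_excursion_cm": float(np.mean(exc)),
        "mean_vt_L": float(np.mean(vt)),
        "excursions_cm": exc,
        "tidal_volumes_L": vt,
    }
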