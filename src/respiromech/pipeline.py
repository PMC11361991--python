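"""End-to-end reproducible runs: cohort -> sessions -> metrics -> fits.

A run is fully described by a validated configuration (unknown keys
rejected) and a seed; rerunning the same configuration reproduces every
numeric output exactly. Each run directory receives the resolved config,
per-session CSVs, a cohort manifest, a metrics/fit report in JSON, a
manifest of SHA-256 digests of every output, and a structured log with
per-stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__, metrics
from .fitting import FitSpec, fit
from .mechanics import MechanicalParameters
from .synthetic import (
    ParticipantProfile,
    SessionRecording,
    calibrate_amplitudes,
    calibrate_assist,
    generate_session,
    sample_cohort,
)
from .waveforms import BreathPattern, RobotPressureProgram

__all__ = ["RunConfig", "run_pipeline", "analyze_cohort", "load_manifest_sessions"]

REPORT_SCHEMA_VERSION = 1

#: Fit-quality threshold (percent amplitude error) counted as a good fit.
GOOD_FIT_AMPLITUDE_ERROR_PCT = 7.0


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortBlock(_Model):
    n: int = 8
    cv: float = 0.2


class RobotBlock(_Model):
    shape: str = "square"
    level_kPa: float = 30.0
    k_transmission: float = 0.1
    t_inflate: float = 3.0


class CalibrationBlock(_Model):
    target_excursion_cm: float = 1.14
    target_vt_L: float = 0.83
    disp_ratio: float = 1.95
    vt_ratio: float = 2.14


class NoiseBlock(_Model):
    disp_cm: float = 0.05
    flow_Lps: float = 0.02


class SessionBlock(_Model):
    n_breaths: int = 6
    fs: float = 50.0


class FitBlock(_Model):
    n_starts: int = 2
    free_spontaneous: tuple[str, ...] = ("A_dim", "A_rc")
    free_assisted: tuple[str, ...] = ("A_dim", "A_rc", "P_rex")


class StageBlock(_Model):
    metrics: bool = True
    fit: bool = True


class RunConfig(_Model):
    """Schema-validated description of one reproducible pipeline run."""

    seed: int = 42
    outdir: str = "runs/run"
    cohort: CohortBlock = CohortBlock()
    robot: RobotBlock = RobotBlock()
    calibration: CalibrationBlock = CalibrationBlock()
    noise: NoiseBlock = NoiseBlock()
    session: SessionBlock = SessionBlock()
    fit: FitBlock = FitBlock()
    stages: StageBlock = StageBlock()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _session_seed(seed: int, subject: int, condition: str) -> int:
    ss = np.random.SeedSequence([seed, subject, 0 if condition == "spontaneous" else 1])
    return int(ss.generate_state(1)[0] % 2**31)


def _write_session_csvs(rec: SessionRecording, outdir: Path) -> dict:
    stem = f"{rec.subject_id}_{rec.condition}"
    files = {}
    for channel, data, unit in (
        ("disp", rec.displacement, "cm"),
        ("flow", rec.flow, "L/s"),
    ):
        name = f"{stem}_{channel}.csv"
        df = pd.DataFrame({"t": rec.t, channel: data})
        with open(outdir / name, "w") as fh:
            fh.write(f"# units: s, {unit}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
        files[channel] = name
    return files


def _pattern_doc(p: BreathPattern) -> dict:
    return {"T": float(p.T), "f_insp": float(p.f_insp),
            "A_rc": float(p.A_rc), "A_dim": float(p.A_dim)}


def _program_doc(p: RobotPressureProgram | None) -> dict | None:
    if p is None:
        return None
    return {"shape": p.shape, "level_kPa": float(p.level_kPa),
            "k_transmission": float(p.k_transmission),
            "t_inflate": float(p.t_inflate)}


def load_manifest_sessions(manifest_path) -> list[dict]:
    """Rebuild per-subject SessionRecording pairs from a cohort manifest.

    Ground truth is not persisted, so the loaded recordings carry only the
    measured channels — exactly what the analysis stages are allowed to
    see.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    base = manifest_path.parent
    subjects = []
    for entry in doc["subjects"]:
        params = MechanicalParameters(**entry["params"])
        sessions = {}
        for condition, meta in entry["sessions"].items():
            disp = pd.read_csv(base / meta["disp_csv"], comment="#")
            flow = pd.read_csv(base / meta["flow_csv"], comment="#")
            sessions[condition] = SessionRecording(
                condition=condition,
                t=disp["t"].to_numpy(),
                displacement=disp["disp"].to_numpy(),
                flow=flow["flow"].to_numpy(),
                pattern=BreathPattern(**meta["pattern"]),
                program=(RobotPressureProgram(**meta["program"])
                         if meta["program"] else None),
                subject_id=entry["id"],
            )
        subjects.append({"id": entry["id"], "params": params, "sessions": sessions})
    return subjects


def analyze_cohort(subjects: list[dict], fit_block: FitBlock | None = None,
                   fit_seed: int = 0) -> dict:
    """Cohort-level report: per-subject measures, fold changes, fits.

    ``subjects`` is a list of dicts with keys ``id``, ``params``
    (MechanicalParameters) and ``sessions`` (condition ->
    SessionRecording). When ``fit_block`` is given, each session is fitted
    and per-session amplitude errors and NRMSEs are reported.
    """
    per_subject = []
    spont_exc, spont_vt, assist_exc, assist_vt = [], [], [], []
    corr_pairs = []
    for entry in subjects:
        row = {"id": entry["id"]}
        for condition, rec in entry["sessions"].items():
            s = metrics.session_summary(rec.displacement, rec.flow, rec.dt, rec.pattern.T)
            row[condition] = {
                "mean_excursion_cm": s["mean_excursion_cm"],
                "mean_vt_L": s["mean_vt_L"],
                "n_breaths_disp": int(s["excursions_cm"].size),
                "n_breaths_flow": int(s["tidal_volumes_L"].size),
            }
            corr_pairs.append((s["mean_excursion_cm"], s["mean_vt_L"]))
            if condition == "spontaneous":
                spont_exc.append(s["mean_excursion_cm"])
                spont_vt.append(s["mean_vt_L"])
            else:
                assist_exc.append(s["mean_excursion_cm"])
                assist_vt.append(s["mean_vt_L"])
        per_subject.append(row)

    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "per_subject": per_subject}
    if assist_exc and len(assist_exc) == len(spont_exc) and len(spont_exc) >= 2:
        cmp_exc = metrics.paired_ratio_test(spont_exc, assist_exc)
        cmp_vt = metrics.paired_ratio_test(spont_vt, assist_vt)
        report["displacement"] = {
            "ratio_means": cmp_exc.ratio_means,
            "mean_of_ratios": cmp_exc.mean_of_ratios,
            "p_value": cmp_exc.p_value,
        }
        report["tidal_volume"] = {
            "ratio_means": cmp_vt.ratio_means,
            "mean_of_ratios": cmp_vt.mean_of_ratios,
            "p_value": cmp_vt.p_value,
        }
    if len(corr_pairs) >= 3:
        report["excursion_vt_correlation"] = metrics.displacement_volume_correlation(corr_pairs)

    if fit_block is not None:
        fits = []
        good = 0
        total = 0
        for si, entry in enumerate(subjects):
            for condition, rec in entry["sessions"].items():
                free = (fit_block.free_spontaneous if condition == "spontaneous"
                        else fit_block.free_assisted)
                result = fit(rec, entry["params"], FitSpec(free=free),
                             seed=_session_seed(fit_seed, si, condition),
                             n_starts=fit_block.n_starts)
                total += 1
                ok = (result.amplitude_error_disp < GOOD_FIT_AMPLITUDE_ERROR_PCT
                      and result.amplitude_error_vol < GOOD_FIT_AMPLITUDE_ERROR_PCT)
                good += ok
                fits.append({
                    "id": entry["id"], "condition": condition,
                    "estimates": result.estimates,
                    "amplitude_error_disp_pct": result.amplitude_error_disp,
                    "amplitude_error_vol_pct": result.amplitude_error_vol,
                    "nrmse_disp_pct": result.nrmse_disp,
                    "nrmse_vol_pct": result.nrmse_vol,
                    "converged": result.converged,
                })
        report["fits"] = fits
        report["fit_quality"] = {
            "n_sessions": total,
            "fraction_good_amplitude": good / total if total else float("nan"),
            "max_nrmse_disp_pct": max(f["nrmse_disp_pct"] for f in fits),
            "max_nrmse_vol_pct": max(f["nrmse_vol_pct"] for f in fits),
        }
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write a reproducible run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t_start = time.perf_counter()

    def log(stage: str, t0: float, **info) -> None:
        extras = " ".join(f"{k}={v}" for k, v in info.items())
        log_lines.append(
            f"stage={stage} seed={config.seed} elapsed_s={time.perf_counter() - t0:.3f} {extras}".rstrip()
        )

    try:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.model_dump(), fh, sort_keys=True)

        # --- cohort generation and calibration
        t0 = time.perf_counter()
        cohort = sample_cohort(config.cohort.n, config.seed, config.cohort.cv)
        base_program = RobotPressureProgram(
            shape=config.robot.shape, level_kPa=config.robot.level_kPa,
            k_transmission=config.robot.k_transmission,
            t_inflate=config.robot.t_inflate,
        )
        subjects = []
        manifest_entries = []
        for si, prof in enumerate(cohort):
            prof = replace(prof, noise_disp=config.noise.disp_cm,
                           noise_flow=config.noise.flow_Lps)
            a_rc, a_dim = calibrate_amplitudes(
                prof, config.calibration.target_vt_L,
                config.calibration.target_excursion_cm,
                n_breaths=config.session.n_breaths, fs=config.session.fs,
                clamp=True,
            )
            prof = prof.replace_pattern(A_rc=a_rc, A_dim=a_dim)
            program, pattern_assist = calibrate_assist(
                prof, base_program, config.calibration.disp_ratio,
                config.calibration.vt_ratio,
                n_breaths=config.session.n_breaths, fs=config.session.fs,
            )
            sessions = {}
            session_meta = {}
            for condition, prog, pat in (
                ("spontaneous", None, prof.pattern),
                ("assisted", program, pattern_assist),
            ):
                rec = generate_session(
                    prof, condition, prog,
                    n_breaths=config.session.n_breaths,
                    seed=_session_seed(config.seed, si, condition),
                    fs=config.session.fs, pattern=pat,
                )
                sessions[condition] = rec
                files = _write_session_csvs(rec, outdir)
                session_meta[condition] = {
                    "disp_csv": files["disp"], "flow_csv": files["flow"],
                    "pattern": _pattern_doc(pat), "program": _program_doc(prog),
                }
            subjects.append({"id": prof.id, "params": prof.params, "sessions": sessions})
            manifest_entries.append({
                "id": prof.id,
                "params": {k: float(getattr(prof.params, k)) for k in
                           ("R_rc", "R_ab", "R_l", "C_rc", "C_ab", "C_l", "C_pl", "A_di")},
                "noise": {"disp_cm": float(prof.noise_disp),
                          "flow_Lps": float(prof.noise_flow)},
                "sessions": session_meta,
            })
        with open(outdir / "cohort.yaml", "w") as fh:
            yaml.safe_dump({"seed": config.seed, "n": config.cohort.n,
                            "cv": config.cohort.cv, "subjects": manifest_entries},
                           fh, sort_keys=True)
        log("cohort", t0, n=config.cohort.n)

        # --- metrics and fitting
        report = None
        if config.stages.metrics:
            t0 = time.perf_counter()
            report = analyze_cohort(
                subjects,
                fit_block=config.fit if config.stages.fit else None,
                fit_seed=config.seed,
            )
            with open(outdir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            log("metrics", t0, fit=config.stages.fit)

        # --- manifest with digests (log excluded: it carries wall times)
        t0 = time.perf_counter()
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "outputs": {
                p.name: _sha256(p)
                for p in sorted(outdir.iterdir())
                if p.is_file() and p.name not in ("manifest.json", "log.txt")
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log("manifest", t0, n_outputs=len(manifest["outputs"]))
        log_lines.append(f"run_complete total_s={time.perf_counter() - t_start:.3f}")
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    except Exception:
        (outdir / "FAILED").write_text("pipeline run did not complete\n")
        raise
    return outdir
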