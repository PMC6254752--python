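"""Synthetic subjects: ground-truth waveforms and rendered test images.

A subject is parameterized by a true wave speed ``c_true``.  Per beat, the
diameter rises from its diastolic value with a smoothed-ramp pulse (linear
mid-rise with cosine corners, chosen for closed-form onset truth) and decays
back; during the forward-wave window the velocity is exactly
``U = 2 * c_true * ln(D / D_d)``, so the early-systolic ln(D)U relation is
linear with slope ``2 * c_true`` by construction.  A delayed, scaled
reflected component is added to D and subtracted from U after
``reflection_delay``, breaking that proportionality the way returning
reflections do.

Diameter and velocity runs are generated with independently sampled
beat-to-beat cycle lengths (distinct RNG streams), emulating sequential
acquisition.  Renderers turn the waveforms into M-mode-like two-wall band
images and Doppler-like filled spectrograms with an embedded ECG strip, and
the fixtures are written in the text sidecar dialect of :mod:`.image_io`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import GeometryError
from .image_io import UltrasoundRecording, write_recording

__all__ = [
    "NoiseModel",
    "SyntheticSubject",
    "SyntheticRun",
    "generate_run",
    "generate_waveform_pair",
    "render_mmode",
    "render_doppler",
    "MModeRender",
    "DopplerRender",
    "write_subject_fixture",
    "write_waveform_fixture",
]


@dataclass
class NoiseModel:
    """Noise scales: grayscale SD for rendering, fractional SD for waveforms."""

    pixel: float = 0.0
    waveform: float = 0.0


@dataclass
class SyntheticSubject:
    c_true: float = 4.0  # m/s
    D_d: float = 2.6  # diastolic diameter, cm
    pulse_amplitude: float = 0.2  # cm
    heart_rate_mean: float = 65.0  # bpm
    heart_rate_cv: float = 0.03  # fractional beat-to-beat variability
    reflection_delay: float = 0.09  # s after upstroke onset
    reflection_magnitude: float = 0.15  # fraction of forward component
    onset_delay: float = 0.05  # s from R-peak to upstroke onset
    rise_time: float = 0.10  # s, upstroke duration
    corner_time: float = 0.022  # s, cosine corner width of the ramp
    decay_tau: float = 0.25  # s, diastolic decay constant
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_true <= 0 or self.D_d <= 0 or self.pulse_amplitude <= 0:
            raise ValueError("c_true, D_d and pulse_amplitude must be positive")
        if not 0 <= self.reflection_magnitude < 1:
            raise ValueError("reflection_magnitude must lie in [0, 1)")
        if self.heart_rate_cv < 0 or self.heart_rate_mean <= 0:
            raise ValueError("invalid heart rate parameters")
        if 2 * self.corner_time >= self.rise_time:
            raise ValueError("corner_time must be less than half the rise_time")


@dataclass
class SyntheticRun:
    """One generated acquisition run on a uniform time grid."""

    values: np.ndarray  # cm (diameter) or m/s (velocity)
    kind: str
    dt: float  # seconds per sample
    r_peaks: np.ndarray  # sample indices, length n_beats + 1
    ecg: np.ndarray  # normalized ECG amplitude per sample
    truth: dict


def _ramp(tau: np.ndarray, rise: float, corner: float) -> np.ndarray:
    """Unit smoothed ramp: cosine corners of width ``corner``, linear between.

    The shape is the normalized integral of a trapezoidal velocity profile
    with cosine-smoothed ends; it is 0 at tau<=0 and 1 at tau>=rise.
    """
    w, r = corner, rise
    out = np.zeros_like(tau, dtype=float)
    u = np.clip(tau, 0.0, r)
    a = np.where(
        u <= w,
        0.5 * (u - (w / np.pi) * np.sin(np.pi * np.clip(u, 0, w) / w)),
        np.where(
            u <= r - w,
            w / 2.0 + (u - w),
            w / 2.0 + (r - 2 * w)
            + 0.5 * ((u - (r - w)) + (w / np.pi) * np.sin(np.pi * np.clip(u - (r - w), 0, w) / w)),
        ),
    )
    out = a / (r - w)
    out[tau <= 0] = 0.0
    out[tau >= r] = 1.0
    return out


def _pulse(tau: np.ndarray, T: float, subject: SyntheticSubject, onset: float) -> np.ndarray:
    """Normalized single-beat pulse: smoothed-ramp upstroke, decay to 0 at T."""
    s = subject
    t_peak = onset + s.rise_time
    p = _ramp(tau - onset, s.rise_time, s.corner_time)
    decay_span = max(T - t_peak, 1e-6)
    u = np.clip(tau - t_peak, 0.0, None)
    tail = np.exp(-u / s.decay_tau) - np.exp(-decay_span / s.decay_tau) * (u / decay_span)
    return np.where(tau > t_peak, tail, p)


def _beat_durations(subject: SyntheticSubject, n_beats: int, rng: np.random.Generator) -> np.ndarray:
    mean_T = 60.0 / subject.heart_rate_mean
    z = np.clip(rng.standard_normal(n_beats), -2.5, 2.5)
    return np.maximum(mean_T * (1.0 + subject.heart_rate_cv * z), 0.4)


def _ecg_shape(tau: np.ndarray, T: float) -> np.ndarray:
    """Per-beat ECG: QRS spike of height 1 at tau=0 and a smaller T-wave."""
    qrs = np.maximum(0.0, 1.0 - np.abs(tau) / 0.02) + np.maximum(0.0, 1.0 - np.abs(tau - T) / 0.02)
    t_wave = 0.25 * np.exp(-0.5 * ((tau - 0.35 * T) / 0.04) ** 2)
    return 0.05 + qrs + t_wave


def generate_run(
    subject: SyntheticSubject,
    n_beats: int,
    kind: str,
    dt: float = 0.001,
    rng: np.random.Generator | None = None,
) -> SyntheticRun:
    """Generate one run of ``n_beats`` beats of diameter or velocity.

    Beat durations are snapped to the sample grid so that R-peaks fall on
    exact sample indices.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be at least 1")
    if kind not in ("diameter", "velocity"):
        raise ValueError(f"kind must be 'diameter' or 'velocity', got {kind!r}")
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    s = subject
    durations = _beat_durations(s, n_beats, rng)
    n_samples = np.maximum(np.round(durations / dt).astype(int), 2)
    durations = n_samples * dt  # snapped to the grid
    r_peaks = np.concatenate([[0], np.cumsum(n_samples)])
    values = np.empty(int(r_peaks[-1]) + 1)
    ecg = np.empty_like(values)
    onsets, refl_times = [], []
    amp = s.pulse_amplitude
    for i in range(n_beats):
        a, b = int(r_peaks[i]), int(r_peaks[i + 1])
        T = durations[i]
        tau = np.arange(b - a) * dt
        onset = s.onset_delay
        fwd = _pulse(tau, T, s, onset)
        refl = s.reflection_magnitude * _pulse(tau, T, s, onset + s.reflection_delay)
        if kind == "diameter":
            vals = s.D_d + amp * fwd + amp * refl
        else:
            u_fwd = 2.0 * s.c_true * np.log1p(amp * fwd / s.D_d)
            u_refl = 2.0 * s.c_true * np.log1p(amp * refl / s.D_d)
            vals = u_fwd - u_refl
        values[a:b] = vals
        ecg[a:b] = _ecg_shape(tau, T)
        onsets.append(a * dt + onset)
        refl_times.append(a * dt + onset + s.reflection_delay)
    # closing sample at the final R-peak
    values[-1] = values[0]
    ecg[-1] = _ecg_shape(np.array([0.0]), durations[-1])[0]
    if s.noise.waveform > 0:
        scale = amp if kind == "diameter" else 2.0 * s.c_true * np.log1p(amp / s.D_d)
        values = values + rng.normal(0.0, s.noise.waveform * scale, values.size)
        if kind == "diameter":
            values = np.maximum(values, 0.1 * s.D_d)
    truth = {
        "c_true": s.c_true,
        "kind": kind,
        "durations_s": durations.tolist(),
        "onset_times_s": onsets,
        "reflection_times_s": refl_times,
        "r_peak_indices": r_peaks.tolist(),
        "dt_s": dt,
    }
    return SyntheticRun(values=values, kind=kind, dt=dt, r_peaks=r_peaks, ecg=ecg, truth=truth)


def generate_waveform_pair(
    subject: SyntheticSubject,
    n_beats: int,
    dt: float = 0.001,
    run_index: int = 0,
    shared_timing: bool = False,
) -> tuple[SyntheticRun, SyntheticRun]:
    """One diameter run and one velocity run for the same subject.

    The two runs draw beat durations from distinct RNG sub-streams
    (sequential-acquisition realism); with ``shared_timing=True`` or zero
    heart-rate variability the timing coincides.
    """
    rng_d = np.random.default_rng([subject.seed, 101, run_index])
    rng_u = rng_d if shared_timing else np.random.default_rng([subject.seed, 202, run_index])
    d_run = generate_run(subject, n_beats, "diameter", dt=dt, rng=rng_d)
    if shared_timing:
        rng_u = np.random.default_rng([subject.seed, 101, run_index])
    u_run = generate_run(subject, n_beats, "velocity", dt=dt, rng=rng_u)
    return d_run, u_run


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


@dataclass
class MModeRender:
    rows: int = 340
    time_cal_ms: float = 3.5  # ms per pixel column
    value_cal: float = 0.016  # cm per pixel row
    centerline_row: int = 150
    wall_thickness: int = 4
    wall_intensity: float = 210.0
    background: float = 18.0
    ecg_band: tuple[int, int] = (300, 336)
    ecg_intensity: float = 250.0


@dataclass
class DopplerRender:
    rows: int = 340
    time_cal_ms: float = 2.5
    value_cal: float = 0.02  # m/s per pixel row
    baseline_row: int = 250
    background: float = 10.0
    band_max_intensity: float = 230.0
    band_min_intensity: float = 120.0
    ecg_band: tuple[int, int] = (300, 336)
    ecg_intensity: float = 250.0
    flow_side: str = "up"


def _column_grid(run: SyntheticRun, time_cal_ms: float) -> tuple[np.ndarray, np.ndarray]:
    total_s = (run.values.size - 1) * run.dt
    n_cols = int(np.floor(total_s * 1000.0 / time_cal_ms)) + 1
    t_cols = np.arange(n_cols) * time_cal_ms / 1000.0
    src_t = np.arange(run.values.size) * run.dt
    return t_cols, src_t


def _render_ecg(img: np.ndarray, run: SyntheticRun, t_cols, src_t, band, intensity) -> None:
    b0, b1 = band
    e = np.interp(t_cols, src_t, run.ecg)
    e = e / max(e.max(), 1e-9)
    row_f = (b1 - 2) - e * (b1 - b0 - 3)
    rows = np.clip(np.rint(row_f).astype(int), b0, b1 - 1)
    cols = np.arange(t_cols.size)
    img[rows, cols] = intensity
    img[np.clip(rows - 1, b0, b1 - 1), cols] = intensity


def _r_peak_columns(run: SyntheticRun, time_cal_ms: float) -> np.ndarray:
    return np.rint(run.r_peaks * run.dt * 1000.0 / time_cal_ms).astype(int)


def render_mmode(
    run: SyntheticRun,
    cfg: MModeRender | None = None,
    pixel_noise: float | None = None,
    rng: np.random.Generator | None = None,
    run_id: int | str = 1,
) -> tuple[UltrasoundRecording, dict]:
    """Render a diameter run as a two-wall M-mode image with ECG strip.

    Returns the recording and a truth record holding the float inner-edge
    rows per column and the R-peak columns.
    """
    if run.kind != "diameter":
        raise ValueError("render_mmode needs a diameter run")
    cfg = cfg or MModeRender()
    t_cols, src_t = _column_grid(run, cfg.time_cal_ms)
    d_cols = np.interp(t_cols, src_t, run.values)
    half = d_cols / (2.0 * cfg.value_cal)
    near_f = cfg.centerline_row - half  # inner edge of anterior wall
    far_f = cfg.centerline_row + half  # inner edge of posterior wall
    thick = cfg.wall_thickness
    if near_f.min() - thick + 1 < 0 or far_f.max() + thick - 1 >= cfg.ecg_band[0]:
        raise GeometryError("diameter range does not fit inside the image geometry")
    img = np.full((cfg.rows, t_cols.size), cfg.background)
    rows_idx = np.arange(cfg.rows)[:, None]
    near_in = np.rint(near_f)[None, :]
    far_in = np.rint(far_f)[None, :]
    near_mask = (rows_idx <= near_in) & (rows_idx > near_in - thick)
    far_mask = (rows_idx >= far_in) & (rows_idx < far_in + thick)
    img[near_mask | far_mask] = cfg.wall_intensity
    _render_ecg(img, run, t_cols, src_t, cfg.ecg_band, cfg.ecg_intensity)
    if rng is None:
        rng = np.random.default_rng(0)
    if pixel_noise and pixel_noise > 0:
        img = img + rng.normal(0.0, pixel_noise, img.shape)
    img = np.clip(np.rint(img), 0, 255)
    rec = UltrasoundRecording(
        pixels=img,
        modality="mmode",
        time_cal=cfg.time_cal_ms,
        value_cal=cfg.value_cal,
        ecg_band=cfg.ecg_band,
        run_id=run_id,
    )
    truth = {
        "near_rows": near_f,
        "far_rows": far_f,
        "r_peak_columns": _r_peak_columns(run, cfg.time_cal_ms),
        "run_truth": run.truth,
    }
    return rec, truth


def render_doppler(
    run: SyntheticRun,
    cfg: DopplerRender | None = None,
    pixel_noise: float | None = None,
    rng: np.random.Generator | None = None,
    run_id: int | str = 1,
) -> tuple[UltrasoundRecording, dict]:
    """Render a velocity run as a filled Doppler spectrogram with ECG strip.

    The spectral band fills from the baseline to the envelope row with
    intensity decaying toward the envelope edge.
    """
    if run.kind != "velocity":
        raise ValueError("render_doppler needs a velocity run")
    cfg = cfg or DopplerRender()
    t_cols, src_t = _column_grid(run, cfg.time_cal_ms)
    u_cols = np.maximum(np.interp(t_cols, src_t, run.values), 0.0)
    excursion = u_cols / cfg.value_cal
    if cfg.flow_side == "up":
        env_f = cfg.baseline_row - excursion
        if env_f.min() < 0:
            raise GeometryError("velocity envelope exceeds the top of the image")
    else:
        env_f = cfg.baseline_row + excursion
        if env_f.max() >= min(cfg.rows, cfg.ecg_band[0]):
            raise GeometryError("velocity envelope exceeds the bottom of the image")
    img = np.full((cfg.rows, t_cols.size), cfg.background)
    rows_idx = np.arange(cfg.rows)[:, None]
    env_in = np.rint(env_f)[None, :]
    base = cfg.baseline_row
    if cfg.flow_side == "up":
        inside = (rows_idx >= env_in) & (rows_idx <= base)
        frac = np.where(inside, (base - rows_idx) / np.maximum(base - env_in, 1), 0.0)
    else:
        inside = (rows_idx <= env_in) & (rows_idx >= base)
        frac = np.where(inside, (rows_idx - base) / np.maximum(env_in - base, 1), 0.0)
    band = cfg.band_max_intensity - (cfg.band_max_intensity - cfg.band_min_intensity) * frac
    img = np.where(inside, band, img)
    _render_ecg(img, run, t_cols, src_t, cfg.ecg_band, cfg.ecg_intensity)
    if rng is None:
        rng = np.random.default_rng(0)
    if pixel_noise and pixel_noise > 0:
        img = img + rng.normal(0.0, pixel_noise, img.shape)
    img = np.clip(np.rint(img), 0, 255)
    rec = UltrasoundRecording(
        pixels=img,
        modality="doppler",
        time_cal=cfg.time_cal_ms,
        value_cal=cfg.value_cal,
        ecg_band=cfg.ecg_band,
        baseline_row=cfg.baseline_row,
        run_id=run_id,
    )
    truth = {
        "envelope_rows": env_f,
        "r_peak_columns": _r_peak_columns(run, cfg.time_cal_ms),
        "run_truth": run.truth,
    }
    return rec, truth


# --------------------------------------------------------------------------
# Fixture writing
# --------------------------------------------------------------------------


def default_tracing_config(subject: SyntheticSubject, mmode: MModeRender, doppler: DopplerRender) -> dict:
    """Tracing config (ROIs and thresholds) consistent with the render geometry."""
    d_max = subject.D_d + subject.pulse_amplitude * (1 + subject.reflection_magnitude) + 0.05
    d_min = subject.D_d - 0.05
    half_max = d_max / (2 * mmode.value_cal)
    half_min = d_min / (2 * mmode.value_cal)
    t = mmode.wall_thickness
    near_roi = [int(mmode.centerline_row - half_max - t - 2), int(mmode.centerline_row - half_min + 2)]
    far_roi = [int(mmode.centerline_row + half_min - 2), int(mmode.centerline_row + half_max + t + 2)]
    wall_thr = float(0.5 * (mmode.background + mmode.wall_intensity))
    dop_thr = float(0.5 * (doppler.background + doppler.band_min_intensity))
    return {
        "near_roi": near_roi,
        "far_roi": far_roi,
        "near_threshold": wall_thr,
        "far_threshold": wall_thr,
        "doppler_threshold": dop_thr,
        "flow_side": doppler.flow_side,
    }


def write_subject_fixture(
    subject: SyntheticSubject,
    out_dir: str | Path,
    n_runs: int = 3,
    n_beats: int = 8,
    mmode_cfg: MModeRender | None = None,
    doppler_cfg: DopplerRender | None = None,
    frame_width: int = 256,
    frame_overlap: int = 0,
) -> Path:
    """Write image fixtures for one subject: n_runs D runs + n_runs U runs.

    Produces run directories ``d1..dN`` / ``u1..uN`` (sidecar dialect),
    ``truth.json`` and a ready-to-run pipeline ``config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmode_cfg = mmode_cfg or MModeRender()
    doppler_cfg = doppler_cfg or DopplerRender()
    runs_manifest, truths = [], {}
    for r in range(1, n_runs + 1):
        d_run, u_run = generate_waveform_pair(subject, n_beats, run_index=r)
        noise_rng = np.random.default_rng([subject.seed, 303, r])
        d_rec, d_truth = render_mmode(
            d_run, mmode_cfg, pixel_noise=subject.noise.pixel, rng=noise_rng, run_id=f"d{r}"
        )
        u_rec, u_truth = render_doppler(
            u_run, doppler_cfg, pixel_noise=subject.noise.pixel, rng=noise_rng, run_id=f"u{r}"
        )
        write_recording(d_rec, out_dir / f"d{r}", frame_width, frame_overlap)
        write_recording(u_rec, out_dir / f"u{r}", frame_width, frame_overlap)
        runs_manifest.append({"run_id": f"d{r}", "kind": "diameter", "source": "images", "path": f"d{r}"})
        runs_manifest.append({"run_id": f"u{r}", "kind": "velocity", "source": "images", "path": f"u{r}"})
        truths[f"d{r}"] = {k: v for k, v in d_truth.items() if k != "near_rows" and k != "far_rows"}
        truths[f"d{r}"]["r_peak_columns"] = d_truth["r_peak_columns"].tolist()
        truths[f"u{r}"] = {"r_peak_columns": u_truth["r_peak_columns"].tolist(), "run_truth": u_truth["run_truth"]}
    truths["c_true"] = subject.c_true
    (out_dir / "truth.json").write_text(json.dumps(truths, indent=1, sort_keys=True))
    config = {
        "runs": runs_manifest,
        "tracing": default_tracing_config(subject, mmode_cfg, doppler_cfg),
        "output_dir": "out",
    }
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return out_dir


def write_waveform_fixture(
    subject: SyntheticSubject,
    out_dir: str | Path,
    n_runs: int = 3,
    n_beats: int = 8,
    dt: float = 0.001,
) -> Path:
    """Write CSV waveform fixtures (time_ms,value) plus R-peak sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runs_manifest, truths = [], {}
    for r in range(1, n_runs + 1):
        d_run, u_run = generate_waveform_pair(subject, n_beats, dt=dt, run_index=r)
        for tag, run in (("d", d_run), ("u", u_run)):
            name = f"{tag}{r}"
            times_ms = np.arange(run.values.size) * run.dt * 1000.0
            lines = ["time_ms,value"] + [
                f"{t:.6f},{v:.9f}" for t, v in zip(times_ms, run.values)
            ]
            (out_dir / f"{name}.csv").write_text("\n".join(lines) + "\n")
            (out_dir / f"{name}_peaks.json").write_text(
                json.dumps({"r_peaks": run.r_peaks.tolist()})
            )
            runs_manifest.append(
                {
                    "run_id": name,
                    "kind": run.kind,
                    "source": "waveform",
                    "path": f"{name}.csv",
                    "r_peaks": f"{name}_peaks.json",
                }
            )
            truths[name] = run.truth
    truths["c_true"] = subject.c_true
    (out_dir / "truth.json").write_text(json.dumps(truths, indent=1, sort_keys=True))
    (out_dir / "config.yaml").write_text(
        yaml.safe_dump({"runs": runs_manifest, "output_dir": "out"}, sort_keys=True)
    )
    return out_dir
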