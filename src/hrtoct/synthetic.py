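"""Forward-model generator of coupled ECG traces and OCT B-scan stacks.

Every pipeline stage is testable against known ground truth: true R-peak
times, the true axial-velocity waveform, the true heart-retina delay, and the
per-frame rigid motion.  The model is deliberately minimal:

* the ECG is a parametric P-QRS-T template (sum of Gaussians with a dominant
  R spike) sampled at the monitor rate with sub-millisecond timestamp jitter
  and additive Gaussian noise at a configurable SNR;
* each heartbeat launches a pulse wave that reaches the retina
  ``true_hrt_ms`` later: a logistic rise (10-90 % within about one frame
  interval) followed by an exponential decay toward a diastolic baseline at
  25 % of the systolic peak;
* B-scans contain a layered speckled background, a circular vessel with
  hyperreflective walls and a shadow column, and a lumen whose normalised
  intensity follows the washout relation applied to the true velocity.

Two rendering details make the forward model exactly invertible in the
noise-free case.  First, a static 3x3 "reference scatterer" patch sits inside
the 7x7 analysis window at the no-washout intensity level, pinning the
peak-pixel reference SNR; the remaining window pixels are compensated so the
window mean equals ``lumen_level * snr_drop`` exactly.  Second, the first ten
frames carry no motion (the subject settles into fixation), so the
first-ten-frame average used as the registration reference is sharp and the
recorded per-frame transforms are directly comparable to the registration
output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .ecg import ECGTrace, PeakTrain, write_ecg_csv
from .errors import InvalidInputError
from .stack import (
    BScanStack,
    RigidTransform,
    ScanParams,
    VesselTrack,
    apply_rigid,
    save_stack,
    write_annotations,
)
from .washout import WashoutParams, forward_washout

#: The OCT acquisition starts this long after the ECG recording begins (ms),
#: leaving room for the 10 s pre-padding of the cross-correlation window.
OCT_START_MS = 11_000.0

# P-QRS-T template: (centre offset from R in ms, sigma in ms, amplitude).
_ECG_WAVES = (
    (-200.0, 25.0, 0.12),  # P
    (-25.0, 8.0, -0.12),  # Q
    (0.0, 11.0, 1.0),  # R
    (28.0, 9.0, -0.22),  # S
    (240.0, 45.0, 0.30),  # T
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic exam.

    Defaults emulate the 20 kHz acquisition regime: ~7 s series at ~20.4
    B-scans/s, 125 Hz ECG, heart rate 70 bpm with 3 % R-R jitter, and a true
    heart-retina delay of 144 ms.  ``peak_velocity_au`` defaults to 80 % of
    the principal-lobe bound lambda/(4 n t) so the washout inversion is
    single-valued for the designed waveform.
    """

    seed: int = 0
    duration_s: float = 7.0
    heart_rate_bpm: float = 70.0
    rr_jitter_frac: float = 0.03
    true_hrt_ms: float = 144.0
    frame_rate_hz: float = 20.4
    ecg_rate_hz: float = 125.0
    ecg_noise_snr_db: float = 25.0
    ecg_ts_jitter_ms: float = 0.5
    oct_noise_sd: float = 0.002
    scan: ScanParams = field(default_factory=ScanParams)
    peak_velocity_au: float | None = None  # m/s; None -> 0.8 * lambda/(4 n t)
    clock_offset_ms: float = 0.0
    jitter_max_px: float = 3.0
    jitter_max_deg: float = 0.3
    n_settle_frames: int = 10
    lumen_level: float = 0.02
    quality_db: float = 42.0
    max_raw: float = 1.0e9
    vessel_radius_px: int | None = None
    n_vessels: int = 1

    def __post_init__(self) -> None:
        if min(self.duration_s, self.heart_rate_bpm, self.frame_rate_hz, self.ecg_rate_hz) <= 0:
            raise InvalidInputError("durations and rates must be positive")
        if self.true_hrt_ms < 0:
            raise InvalidInputError("true_hrt_ms must be >= 0")
        if not (0 <= self.rr_jitter_frac < 0.5):
            raise InvalidInputError("rr_jitter_frac must lie in [0, 0.5)")
        if self.ecg_ts_jitter_ms < 0 or self.ecg_ts_jitter_ms >= 500.0 / self.ecg_rate_hz:
            raise InvalidInputError("timestamp jitter must be below half the sample interval")
        if self.oct_noise_sd < 0 or self.lumen_level <= 0 or self.max_raw <= 0:
            raise InvalidInputError("noise, lumen level and max_raw must be valid")
        if self.jitter_max_px < 0 or self.jitter_max_deg < 0:
            raise InvalidInputError("motion amplitudes must be >= 0")
        if self.n_vessels < 1:
            raise InvalidInputError("n_vessels must be >= 1")

    @property
    def rr_mean_ms(self) -> float:
        return 60_000.0 / self.heart_rate_bpm

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def peak_velocity(self) -> float:
        if self.peak_velocity_au is not None:
            return self.peak_velocity_au
        s = self.scan
        return 0.8 * s.wavelength_m / (4.0 * s.refractive_index * s.integration_time_s)

    def to_dict(self) -> dict:
        return asdict(self)


def preset_20khz(**overrides) -> SimConfig:
    """20 kHz nominal A-scan rate: t = 44.8 us, ~20.4 frames/s, ~145 frames."""
    scan = overrides.pop("scan", ScanParams(integration_time_s=44.8e-6))
    return SimConfig(frame_rate_hz=20.4, scan=scan, **overrides)


def preset_85khz(**overrides) -> SimConfig:
    """85 kHz nominal A-scan rate: t = 11.2 us, ~74.4 frames/s, ~512 frames."""
    scan = overrides.pop("scan", ScanParams(integration_time_s=11.2e-6))
    return SimConfig(frame_rate_hz=74.4, scan=scan, **overrides)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    r_peak_times_ms: np.ndarray  # OCT clock
    arrival_times_ms: np.ndarray  # r_peak_times_ms + true_hrt_ms
    velocity_au: np.ndarray  # true axial velocity at the frame times, m/s
    designed_snr_drop: np.ndarray
    true_hrt_ms: float
    transforms: list[RigidTransform]  # per-frame alignment (inverse of motion)
    vessel_centers_px: list[tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "r_peak_times_ms": self.r_peak_times_ms.tolist(),
            "arrival_times_ms": self.arrival_times_ms.tolist(),
            "velocity_au": self.velocity_au.tolist(),
            "designed_snr_drop": self.designed_snr_drop.tolist(),
            "true_hrt_ms": self.true_hrt_ms,
            "transforms": [t.to_dict() for t in self.transforms],
            "vessel_centers_px": [list(c) for c in self.vessel_centers_px],
        }


@dataclass
class ExamBundle:
    """One complete synthetic exam: ECG + stack + annotations + truth."""

    subject_id: str
    exam_id: str
    cfg: SimConfig
    trace: ECGTrace
    stack: BScanStack
    tracks: list[VesselTrack]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

def _ecg_span_ms(cfg: SimConfig) -> float:
    return OCT_START_MS + cfg.duration_s * 1000.0 + 2000.0

def _beat_times(cfg: SimConfig) -> np.ndarray:
    """True R-peak times (ms, OCT clock); the beat process is seeded
    separately from waveform noise so the stack sees identical beats."""
    rng = np.random.default_rng([cfg.seed, 11])
    rr = cfg.rr_mean_ms
    j = cfg.rr_jitter_frac
    t = 500.0
    end = _ecg_span_ms(cfg) - 300.0
    times = []
    while t < end:
        times.append(t)
        t += rr * (1.0 + rng.uniform(-j, j))
    if len(times) < 2:
        raise InvalidInputError("configuration produces fewer than 2 heartbeats")
    return np.asarray(times)


def _ecg_template(t_ms: np.ndarray, r_times_ms: np.ndarray) -> np.ndarray:
    v = np.zeros_like(t_ms, dtype=float)
    for mu, sigma, amp in _ECG_WAVES:
        centers = r_times_ms + mu
        v += amp * np.exp(-0.5 * ((t_ms[:, None] - centers[None, :]) / sigma) ** 2).sum(axis=1)
    return v


def generate_ecg(cfg: SimConfig) -> tuple[ECGTrace, np.ndarray]:
    """Synthesise the monitor's ECG trace; returns (trace, true R times).

    Samples sit on the nominal acquisition grid with per-sample timestamp
    jitter (exercising the resampling stage) and carry additive Gaussian
    noise at ``ecg_noise_snr_db`` relative to the clean template power.
    The trace timestamps live on the ECG clock: the OCT-clock time minus
    ``clock_offset_ms``.
    """
    r_times = _beat_times(cfg)
    rng = np.random.default_rng([cfg.seed, 12])
    dt = 1000.0 / cfg.ecg_rate_hz
    n = int(_ecg_span_ms(cfg) / dt) + 1
    t_ms = np.arange(n) * dt
    if cfg.ecg_ts_jitter_ms > 0:
        jit = rng.uniform(-cfg.ecg_ts_jitter_ms, cfg.ecg_ts_jitter_ms, n)
        jit[0] = 0.0
        t_ms = t_ms + jit
    clean = _ecg_template(t_ms, r_times)
    values = clean
    if np.isfinite(cfg.ecg_noise_snr_db):
        power = float(np.mean(clean**2))
        sd = np.sqrt(power / 10.0 ** (cfg.ecg_noise_snr_db / 10.0))
        values = clean + rng.normal(0.0, sd, n)
    times_us = np.round((t_ms - cfg.clock_offset_ms) * 1000.0).astype(np.int64)
    trace = ECGTrace(times_us=times_us, values=values, clock_offset_ms=cfg.clock_offset_ms)
    return trace, r_times


# ---------------------------------------------------------------------------
# Flow waveform
# ---------------------------------------------------------------------------

def generate_flow_waveform(cfg: SimConfig, r_times_ms: np.ndarray, sample_times_ms: np.ndarray) -> np.ndarray:
    """True axial velocity (m/s) at the requested sample times.

    Each beat contributes a pulse starting at ``r + true_hrt_ms``: a logistic
    rise (10-90 % in under one frame interval, steepest at onset + half an
    interval) times an exponential decay; the sum relaxes to a diastolic
    baseline of 25 % of the systolic peak.
    """
    r = np.asarray(r_times_ms, dtype=float)
    if r.size == 0:
        raise InvalidInputError("r_times_ms must be non-empty")
    t = np.asarray(sample_times_ms, dtype=float)
    interval = cfg.frame_interval_ms
    tau_rise = interval / 5.0
    tau_decay = 0.35 * cfg.rr_mean_ms
    t_mid = r + cfg.true_hrt_ms + 0.5 * interval  # steepest-rise instant
    dt = t[:, None] - t_mid[None, :]
    pulses = expit(dt / tau_rise) * np.exp(-np.maximum(dt, 0.0) / tau_decay)
    env = pulses.max(axis=1)
    return cfg.peak_velocity * (0.25 + 0.75 * env)


# ---------------------------------------------------------------------------
# B-scan stack rendering
# ---------------------------------------------------------------------------

def _vessel_geometry(cfg: SimConfig) -> tuple[np.ndarray, int, int]:
    h, w = cfg.scan.height_px, cfg.scan.width_px
    radius = cfg.vessel_radius_px if cfg.vessel_radius_px is not None else max(9, min(h, w) // 30)
    cy = int(0.45 * h)
    cxs = np.linspace(0.2 * w, 0.8 * w, cfg.n_vessels).astype(int) if cfg.n_vessels > 1 else np.array([w // 2])
    margin = radius + 3
    if cy - margin < 0 or cy + margin >= h or cxs.min() - margin < 0 or cxs.max() + margin >= w:
        raise InvalidInputError("vessel placement violates the subarea margin")
    if cfg.n_vessels > 1 and np.min(np.diff(cxs)) < 2 * margin:
        raise InvalidInputError("vessels too close together for the chosen radius")
    return cxs, cy, radius


def generate_stack(cfg: SimConfig) -> tuple[BScanStack, list[VesselTrack], GroundTruth]:
    """Render the time-resolved B-scan stack with full ground truth.

    The per-frame quality score is set consistently with the rendered noise
    (``Q = 10 log10(1 / oct_noise_sd)``) so the subarea SNR computation sees
    the actual noise floor; in the noise-free case the configured
    ``quality_db`` is used and the designed SNR-drop sequence is recovered
    exactly.
    """
    r_times = _beat_times(cfg)
    rng = np.random.default_rng([cfg.seed, 13])
    rng_tex = np.random.default_rng([cfg.seed, 14])
    scan = cfg.scan
    h, w = scan.height_px, scan.width_px
    cxs, cy, radius = _vessel_geometry(cfg)

    n = int(round(cfg.duration_s * cfg.frame_rate_hz))
    if n < 2:
        raise InvalidInputError("configuration produces fewer than 2 frames")
    ts = OCT_START_MS + np.round(np.arange(n) * cfg.frame_interval_ms)

    v = generate_flow_waveform(cfg, r_times, ts)
    wp = WashoutParams.from_scan(scan)
    drops = forward_washout(v, wp)
    if np.any(drops <= 9.5 / 49.0):
        raise InvalidInputError(
            "peak velocity drives the SNR drop below the renderable range; "
            "reduce peak_velocity_au"
        )

    # Static background: layered bands modulated by band-limited speckle.
    # The speckle grain is smoothed to roughly the imaging PSF scale (~1 px
    # sigma); fully white per-pixel texture would alias under resampling.
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    bands = 0.002 + 0.004 * (1 + np.sin(2 * np.pi * yy / 37.0 + 0.7)) + 0.003 * (
        1 + np.sin(2 * np.pi * yy / 11.0)
    )
    lateral = 1.0 + 0.35 * np.sin(2 * np.pi * xx / 41.0 + 0.3) * np.sin(
        2 * np.pi * yy / 29.0 + 1.1
    )
    grain = gaussian_filter(rng_tex.standard_normal((h, w)), 1.0)
    grain = grain / max(grain.std(), 1e-12)
    base = bands * lateral * np.clip(1.0 + 0.6 * grain, 0.1, 2.2)

    ygrid, xgrid = np.mgrid[0:h, 0:w]
    lumen_mask = np.zeros((h, w), dtype=bool)
    patch_mask = np.zeros((h, w), dtype=bool)
    for cx in cxs:
        rho2 = (xgrid - cx) ** 2 + (ygrid - cy) ** 2
        wall = (rho2 >= radius**2) & (rho2 <= (radius + 2) ** 2)
        base[cy + radius + 3 :, cx - radius : cx + radius + 1] *= 0.3  # shadow
        base[wall] = 0.08 * rng_tex.uniform(0.8, 1.2, int(wall.sum()))
        lumen_mask |= rho2 < radius**2
        patch_mask[cy - 3 : cy, cx - 3 : cx] = True

    # Window composition: 9 static reference pixels at lumen_level L plus 40
    # lumen pixels compensated so the 7x7 mean is exactly L * drop_i.
    L = cfg.lumen_level
    lumen_val = L * (49.0 * drops - 9.0) / 40.0

    frames = np.empty((n, h, w), dtype=np.float32)
    frames[:] = base.astype(np.float32)
    frames[:, lumen_mask] = lumen_val[:, None].astype(np.float32)
    frames[:, patch_mask] = np.float32(L)

    if cfg.oct_noise_sd > 0:
        frames += cfg.oct_noise_sd * rng.standard_normal(frames.shape, dtype=np.float32)
    np.clip(frames, 0.0, 1.0, out=frames)

    transforms = [RigidTransform()] * n
    moving = cfg.jitter_max_px > 0 or cfg.jitter_max_deg > 0
    if moving:
        for i in range(cfg.n_settle_frames, n):
            dx, dy = rng.uniform(-cfg.jitter_max_px, cfg.jitter_max_px, 2)
            ang = rng.uniform(-cfg.jitter_max_deg, cfg.jitter_max_deg)
            motion = RigidTransform(float(dx), float(dy), float(ang))
            frames[i] = np.clip(apply_rigid(frames[i], motion), 0.0, 1.0)
            transforms[i] = motion.inverse()

    if cfg.oct_noise_sd > 0:
        q_eff = 10.0 * np.log10(1.0 / cfg.oct_noise_sd)
    else:
        q_eff = cfg.quality_db
    stack = BScanStack(
        frames=frames,
        timestamps_ms=ts,
        max_raw=np.full(n, cfg.max_raw),
        quality_db=np.full(n, q_eff),
        params=scan,
        registered=not moving,
    )
    centers = [(int(cx), cy) for cx in cxs]
    tracks = [
        VesselTrack(np.tile([cx, cy], (n, 1)), vessel_id=f"A{k + 1}")
        for k, (cx, cy_) in enumerate(centers)
    ]
    truth = GroundTruth(
        r_peak_times_ms=r_times,
        arrival_times_ms=r_times + cfg.true_hrt_ms,
        velocity_au=v,
        designed_snr_drop=np.asarray(drops),
        true_hrt_ms=cfg.true_hrt_ms,
        transforms=transforms,
        vessel_centers_px=centers,
    )
    return stack, tracks, truth


# ---------------------------------------------------------------------------
# Exam and cohort bundles
# ---------------------------------------------------------------------------

def generate_exam(cfg: SimConfig, subject_id: str = "S01", exam_id: str = "E01") -> ExamBundle:
    """Generate one complete coupled exam (ECG + stack + annotations)."""
    trace, _ = generate_ecg(cfg)
    stack, tracks, truth = generate_stack(cfg)
    return ExamBundle(subject_id, exam_id, cfg, trace, stack, tracks, truth)


def generate_cohort(
    n_subjects: int,
    exams_per_subject: int,
    vessels_per_exam: int,
    base_cfg: SimConfig,
    between_sd_frac: float,
    within_sd_frac: float,
) -> tuple[list[ExamBundle], pd.DataFrame]:
    """Generate a cohort with controlled between- and within-subject spread.

    Per-subject mean HRTs are drawn Normal(base, between_sd_frac * base) and
    per-exam HRTs Normal(subject mean, within_sd_frac * base); every vessel
    of an exam shares the exam's delay (synchronous arrival).  Returns the
    exam bundles and a truth table of the drawn delays.
    """
    if min(n_subjects, exams_per_subject, vessels_per_exam) < 1:
        raise InvalidInputError("all cohort counts must be >= 1")
    if between_sd_frac < 0 or within_sd_frac < 0:
        raise InvalidInputError("dispersion fractions must be >= 0")
    rng = np.random.default_rng([base_cfg.seed, 21])
    base = base_cfg.true_hrt_ms
    bundles = []
    rows = []
    for s in range(n_subjects):
        subj_mean = float(rng.normal(base, between_sd_frac * base))
        for e in range(exams_per_subject):
            hrt = max(float(rng.normal(subj_mean, within_sd_frac * base)), 10.0)
            seed = int((base_cfg.seed * 1_000_003 + s * 10_007 + e * 101 + 7) % 2_147_483_647)
            cfg = replace(
                base_cfg, seed=seed, true_hrt_ms=hrt, n_vessels=vessels_per_exam
            )
            bundles.append(generate_exam(cfg, f"S{s + 1:02d}", f"E{e + 1:02d}"))
            rows.append(
                {
                    "subject_id": f"S{s + 1:02d}",
                    "exam_id": f"E{e + 1:02d}",
                    "subject_mean_hrt_ms": subj_mean,
                    "true_hrt_ms": hrt,
                }
            )
    return bundles, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle IO
# ---------------------------------------------------------------------------

def write_bundle(bundle: ExamBundle, directory: str | Path) -> None:
    """Write an exam bundle: ecg.csv, stack/, annotations.csv, truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_ecg_csv(bundle.trace, d / "ecg.csv")
    save_stack(bundle.stack, d / "stack")
    write_annotations(bundle.tracks, d / "annotations.csv")
    (d / "truth.json").write_text(json.dumps(bundle.truth.to_dict()))
    (d / "bundle.json").write_text(
        json.dumps(
            {
                "subject_id": bundle.subject_id,
                "exam_id": bundle.exam_id,
                "clock_offset_ms": bundle.cfg.clock_offset_ms,
                "config": bundle.cfg.to_dict(),
            }
        )
    )
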