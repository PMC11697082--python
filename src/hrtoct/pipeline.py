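"""End-to-end orchestration: exam analysis, cohort aggregation, figures.

`analyze_exam` runs the full chain in memory (resample ECG -> detect R peaks
-> register -> extract subareas -> invert washout -> detect arrivals ->
estimate HRT) for every annotated vessel, isolating per-vessel failures.
`run_exam` / `run_cohort` wrap it with bundle IO, JSON results and the
standard report figures (per-vessel signal panel, cross-correlation curve,
cohort offset histogram with 50 ms bins).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from . import ecg as _ecg
from . import hrt as _hrt
from . import stack as _stack
from . import washout as _washout
from .errors import HrtOctError, InvalidInputError
from .hrt import CohortRecord, CoVReport, HRTConfig, HRTEstimate
from .stack import BScanStack, VesselTrack
from .synthetic import ExamBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File-level configuration of one exam run."""

    ecg_csv: Path
    stack_dir: Path
    annotations_csv: Path
    out_dir: Path
    clock_offset_ms: float = 0.0
    hrt: HRTConfig = field(default_factory=HRTConfig)
    register: bool = True
    n_branches: int = _washout.DEFAULT_N_BRANCHES
    smooth_window: int | None = None
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = {
            "ecg_csv": str(self.ecg_csv),
            "stack_dir": str(self.stack_dir),
            "annotations_csv": str(self.annotations_csv),
            "out_dir": str(self.out_dir),
            "clock_offset_ms": self.clock_offset_ms,
            "grid_rate_hz": self.hrt.grid_rate_hz,
            "sigma_samples": self.hrt.sigma_samples,
            "pad_before_s": self.hrt.pad_before_s,
            "pad_after_s": self.hrt.pad_after_s,
            "register": self.register,
            "n_branches": self.n_branches,
            "smooth_window": self.smooth_window,
        }
        return d


@dataclass
class VesselResult:
    """Per-vessel analysis products (or the error that stopped them)."""

    vessel_id: str
    series: _stack.SubareaSeries | None = None
    solutions: _washout.VelocitySolutionSet | None = None
    profile: _washout.FlowProfile | None = None
    arrivals: _ecg.PeakTrain | None = None
    estimate: HRTEstimate | None = None
    error: str | None = None


@dataclass
class ExamResult:
    ecg_signal: _ecg.UniformSignal
    r_peaks: _ecg.PeakTrain
    rr_mean_ms: float
    vessels: dict[str, VesselResult]
    transforms: list[_stack.RigidTransform] | None = None

    @property
    def n_failed(self) -> int:
        return sum(1 for v in self.vessels.values() if v.error is not None)


def analyze_exam(
    trace: _ecg.ECGTrace,
    stack: BScanStack,
    tracks: list[VesselTrack],
    hrt_cfg: HRTConfig = HRTConfig(),
    register: bool = True,
    n_branches: int = _washout.DEFAULT_N_BRANCHES,
    smooth_window: int | None = None,
) -> ExamResult:
    """Run the full analysis chain on in-memory objects.

    A failure in one vessel is captured in its `VesselResult.error`; the
    remaining vessels are still processed.
    """
    t0 = time.perf_counter()
    signal = _ecg.resample_ecg(trace, hrt_cfg.grid_rate_hz)
    r_peaks = _ecg.detect_r_peaks(signal)
    if len(r_peaks) < 2:
        raise InvalidInputError("fewer than 2 R peaks detected in the ECG")
    rr = _ecg.mean_rr_ms(r_peaks)
    logger.info("ECG: %d R peaks, mean RR %.1f ms", len(r_peaks), rr)

    transforms = None
    if register and not stack.registered:
        stack, transforms = _stack.register_stack(stack)
        logger.info("registration done in %.2f s", time.perf_counter() - t0)

    wp = _washout.WashoutParams.from_scan(stack.params, n_branches=n_branches)
    vessels: dict[str, VesselResult] = {}
    for track in tracks:
        res = VesselResult(vessel_id=track.vessel_id)
        vessels[track.vessel_id] = res
        try:
            res.series = _stack.extract_subarea_series(stack, track)
            res.solutions, res.profile = _washout.build_flow_profile(
                res.series, wp, smooth_window=smooth_window
            )
            res.arrivals = _washout.detect_pulse_arrivals(res.profile, rr)
            res.estimate = _hrt.estimate_hrt(res.arrivals, r_peaks, hrt_cfg)
            logger.info(
                "vessel %s: HRT %.1f ms (outlier=%s)",
                track.vessel_id,
                res.estimate.hrt_ms,
                res.estimate.is_outlier,
            )
        except HrtOctError as exc:
            res.error = f"{type(exc).__name__}: {exc}"
            logger.warning("vessel %s failed: %s", track.vessel_id, res.error)
    return ExamResult(signal, r_peaks, rr, vessels, transforms)


# ---------------------------------------------------------------------------
# File-level drivers
# ---------------------------------------------------------------------------

def load_bundle_dir(directory: str | Path) -> tuple[_ecg.ECGTrace, BScanStack, list[VesselTrack], dict]:
    """Load an exam bundle directory written by the synthetic generator."""
    d = Path(directory)
    info = {}
    if (d / "bundle.json").exists():
        info = json.loads((d / "bundle.json").read_text())
    trace = _ecg.read_ecg_csv(d / "ecg.csv", clock_offset_ms=info.get("clock_offset_ms", 0.0))
    stk = _stack.load_stack(d / "stack")
    tracks = _stack.read_annotations(d / "annotations.csv")
    return trace, stk, tracks, info


def run_exam(cfg: PipelineConfig) -> ExamResult:
    """Analyse one exam from files and write results + figures to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace = _ecg.read_ecg_csv(cfg.ecg_csv, clock_offset_ms=cfg.clock_offset_ms)
    stk = _stack.load_stack(cfg.stack_dir)
    tracks = _stack.read_annotations(cfg.annotations_csv)
    result = analyze_exam(
        trace,
        stk,
        tracks,
        cfg.hrt,
        register=cfg.register,
        n_branches=cfg.n_branches,
        smooth_window=cfg.smooth_window,
    )
    doc = {
        "config": cfg.to_dict(),
        "rr_mean_ms": result.rr_mean_ms,
        "r_peak_times_ms": result.r_peaks.times_ms.tolist(),
        "vessels": {},
    }
    for vid, res in result.vessels.items():
        if res.error is not None:
            doc["vessels"][vid] = {"error": res.error}
            continue
        doc["vessels"][vid] = {
            "hrt_ms": res.estimate.hrt_ms,
            "offset_ms": res.estimate.offset_ms,
            "argmax_offset_ms": res.estimate.argmax_offset_ms,
            "is_outlier": res.estimate.is_outlier,
            "n_arrivals": len(res.arrivals),
        }
        if cfg.make_figures:
            plot_exam_panel(result, vid, out / f"panel_{vid}")
            plot_cross_correlation(res.estimate, out / f"crosscorr_{vid}")
    (out / "results.json").write_text(json.dumps(doc, indent=2))
    return result


def run_cohort(
    root_dir: str | Path,
    out_dir: str | Path,
    hrt_cfg: HRTConfig = HRTConfig(),
    register: bool = True,
) -> tuple[CoVReport, list[CohortRecord], list[float]]:
    """Analyse every bundle under root_dir and aggregate CoV statistics.

    Returns the report, all vessel records (outliers flagged, retained in the
    output but excluded from the CoV computation) and the unrestricted argmax
    offsets feeding the 50 ms histogram.
    """
    root = Path(root_dir)
    bundle_dirs = sorted(p.parent for p in root.rglob("bundle.json"))
    if not bundle_dirs:
        raise InvalidInputError(f"no exam bundles found under {root}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[CohortRecord] = []
    offsets: list[float] = []
    n_failed = 0
    for d in bundle_dirs:
        trace, stk, tracks, info = load_bundle_dir(d)
        subject = info.get("subject_id", d.parent.name or "S?")
        exam = info.get("exam_id", d.name)
        try:
            result = analyze_exam(trace, stk, tracks, hrt_cfg, register=register)
        except HrtOctError as exc:
            logger.warning("exam %s/%s failed entirely: %s", subject, exam, exc)
            n_failed += 1
            continue
        for vid, res in result.vessels.items():
            if res.error is not None:
                n_failed += 1
                continue
            records.append(
                CohortRecord(subject, exam, vid, res.estimate.hrt_ms, res.estimate.is_outlier)
            )
            offsets.append(res.estimate.argmax_offset_ms)
    kept = [r for r in records if not r.is_outlier]
    report = _hrt.cov_report(kept)
    _hrt.write_records_jsonl(records, out / "records.jsonl")
    (out / "cov_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    plot_offset_histogram(offsets, out / "offset_histogram")
    return report, records, offsets


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _save(fig, stem: Path) -> None:
    stem.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(stem.with_suffix(".png"), dpi=110)
    fig.savefig(stem.with_suffix(".svg"))
    plt.close(fig)


def plot_exam_panel(result: ExamResult, vessel_id: str, stem: str | Path) -> None:
    """Five-row signal panel for one vessel: subarea SNR, velocity scatter
    with NSI colormap, gradient with detected rises, ECG with R peaks, and
    the two encoded trains overlaid."""
    res = result.vessels[vessel_id]
    if res.estimate is None:
        raise InvalidInputError(f"vessel {vessel_id!r} has no successful analysis")
    t_ref = res.series.timestamps_ms[0]
    fig, axes = plt.subplots(5, 1, figsize=(9, 11), sharex=True)

    t = (res.series.timestamps_ms - t_ref) / 1000.0
    axes[0].plot(t, res.series.snr, lw=0.8)
    axes[0].set_ylabel("subarea SNR")

    for ts, frame in zip(t, res.solutions.solutions):
        nsis = [nsi for nsi, _ in frame]
        vs = [v * 1000.0 for _, v in frame]
        axes[1].scatter([ts] * len(vs), vs, c=nsis, cmap="viridis", s=6, vmin=0, vmax=5)
    axes[1].plot(t, res.profile.envelope_v * 1000.0, "k-", lw=0.5, alpha=0.5)
    axes[1].set_ylabel("v [mm/s] (NSI colour)")

    axes[2].plot(t, res.profile.gradient * 1000.0, lw=0.8)
    for a in res.arrivals.times_ms:
        axes[2].axvline((a - t_ref) / 1000.0, color="r", lw=0.6, alpha=0.6)
    axes[2].set_ylabel("dv/dt")

    te = (result.ecg_signal.times_ms - t_ref) / 1000.0
    axes[3].plot(te, result.ecg_signal.values, lw=0.5)
    for rp in result.r_peaks.times_ms:
        axes[3].axvline((rp - t_ref) / 1000.0, color="g", lw=0.5, alpha=0.6)
    axes[3].set_ylabel("ECG [HP]")

    axes[4].eventplot(
        [
            (res.arrivals.times_ms - t_ref) / 1000.0,
            (result.r_peaks.times_ms - t_ref) / 1000.0,
        ],
        colors=["r", "g"],
        lineoffsets=[1, 0],
    )
    axes[4].set_yticks([0, 1], ["R peaks", "arrivals"])
    axes[4].set_xlabel("time since first B-scan [s]")
    axes[4].set_xlim(te.min(), te.max())
    fig.suptitle(f"vessel {vessel_id}: HRT {res.estimate.hrt_ms:.0f} ms")
    _save(fig, Path(stem))


def plot_cross_correlation(est: HRTEstimate, stem: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(est.lags_ms / 1000.0, est.cc, lw=0.8)
    ax.axvline(est.offset_ms / 1000.0, color="r", lw=0.8)
    ax.set_xlabel("ECG offset relative to OCT [s]")
    ax.set_ylabel("normalised cross-correlation")
    ax.set_title(f"offset {est.offset_ms:.0f} ms -> HRT {est.hrt_ms:.0f} ms")
    _save(fig, Path(stem))


def plot_offset_histogram(offsets_ms: list[float], stem: str | Path, bin_ms: float = 50.0) -> None:
    """Histogram of unrestricted cross-correlation argmax offsets (50 ms bins)."""
    offsets = np.asarray(offsets_ms, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    if offsets.size:
        lo = np.floor(offsets.min() / bin_ms) * bin_ms
        hi = np.ceil(offsets.max() / bin_ms) * bin_ms + bin_ms
        ax.hist(offsets, bins=np.arange(lo, hi + 1e-9, bin_ms), edgecolor="k")
    ax.set_xlabel("cross-correlation argmax offset [ms]")
    ax.set_ylabel("count")
    _save(fig, Path(stem))
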