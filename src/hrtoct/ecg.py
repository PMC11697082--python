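"""ECG trace handling: ingestion, resampling, R-peak detection and event-train encoding.

The electrocardiogram arrives as irregularly timestamped samples (microsecond
timestamps, voltage in the monitor's arbitrary "HP value" units).  The analysis
chain is: place the trace on the OCT clock via a single additive offset,
resample to a uniform grid by linear interpolation, detect R peaks with the
Engelse-Zeelenberg differentiator/adaptive-threshold detector, and encode the
resulting event train as a Gaussian-smoothed, [0, 1]-normalised signal for
cross-correlation against the pulse-arrival train.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Acquisition rate of the ECG monitor and default common analysis grid (Hz).
DEFAULT_ECG_RATE_HZ = 125.0
#: Standard deviation (in grid samples) of the Gaussian used to encode event
#: trains, modelling timing uncertainty of the detected events.
DEFAULT_SIGMA_SAMPLES = 1.25


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ECGTrace:
    """Irregularly sampled ECG voltage trace.

    Parameters
    ----------
    times_us
        Integer timestamps in microseconds since epoch, strictly increasing.
    values
        ECG voltage in arbitrary units ("HP value").
    clock_offset_ms
        Milliseconds to ADD to the ECG timestamps to place them on the OCT
        clock.  Houses the single-constant model of the network-time offset
        between the two devices.
    """

    times_us: np.ndarray
    values: np.ndarray
    clock_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_us, dtype=np.int64)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise InvalidInputError("times_us and values must be 1-D and equal length")
        if t.size < 2:
            raise InvalidInputError("ECG trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("ECG timestamps must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("ECG values must be finite")
        object.__setattr__(self, "times_us", t)
        object.__setattr__(self, "values", v)

    @property
    def times_oct_ms(self) -> np.ndarray:
        """Sample times in milliseconds on the OCT clock."""
        return self.times_us / 1000.0 + self.clock_offset_ms


@dataclass(frozen=True)
class UniformSignal:
    """Uniformly sampled signal on the OCT clock.

    Implied sample times are ``t0_ms + i * 1000 / rate_hz``.
    """

    t0_ms: float
    rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise InvalidInputError("rate_hz must be positive")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise InvalidInputError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("signal values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.values.size) * self.dt_ms

    @property
    def duration_s(self) -> float:
        return (self.values.size - 1) * self.dt_ms / 1000.0


@dataclass(frozen=True)
class PeakTrain:
    """Strictly increasing event times (ms, OCT clock) of one event kind."""

    times_ms: np.ndarray
    kind: str = "r_peak"  # one of {"r_peak", "pulse_arrival"}

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        if t.ndim != 1:
            raise InvalidInputError("times_ms must be 1-D")
        if t.size and not np.all(np.diff(t) > 0):
            raise InvalidInputError("event times must be strictly increasing")
        if self.kind not in ("r_peak", "pulse_arrival"):
            raise InvalidInputError(f"unknown event kind {self.kind!r}")
        object.__setattr__(self, "times_ms", t)

    def __len__(self) -> int:
        return self.times_ms.size

    def shifted(self, delta_ms: float) -> "PeakTrain":
        return PeakTrain(self.times_ms + delta_ms, self.kind)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "times_ms": self.times_ms.tolist()}


@dataclass(frozen=True)
class EncodedTrain:
    """Event train rasterised to a uniform grid and Gaussian smoothed.

    Values are in [0, 1]; the maximum equals 1 exactly whenever the source
    train is non-empty.
    """

    signal: UniformSignal
    sigma_samples: float
    source: PeakTrain

    def __post_init__(self) -> None:
        v = self.signal.values
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise InvalidInputError("encoded train values must lie in [0, 1]")
        if len(self.source) > 0 and abs(v.max() - 1.0) > 1e-12:
            raise InvalidInputError("non-empty encoded train must have max exactly 1")

    def to_dict(self) -> dict:
        return {
            "kind": self.source.kind,
            "t0_ms": self.signal.t0_ms,
            "rate_hz": self.signal.rate_hz,
            "values": self.signal.values.tolist(),
        }


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

def read_ecg_csv(path: str | Path, clock_offset_ms: float = 0.0) -> ECGTrace:
    """Read an ECG trace from the monitor's CSV logging format.

    The file must be comma-separated UTF-8 with a header row and the two
    mandatory columns ``timestamp_us`` (integer) and ``hp_value`` (float).
    Extra columns are ignored.
    """
    df = pd.read_csv(path)
    for col in ("timestamp_us", "hp_value"):
        if col not in df.columns:
            raise InvalidInputError(f"ECG CSV is missing mandatory column {col!r}")
    return ECGTrace(
        times_us=df["timestamp_us"].to_numpy(dtype=np.int64),
        values=df["hp_value"].to_numpy(dtype=float),
        clock_offset_ms=clock_offset_ms,
    )


def write_ecg_csv(trace: ECGTrace, path: str | Path) -> None:
    pd.DataFrame({"timestamp_us": trace.times_us, "hp_value": trace.values}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_ecg(trace: ECGTrace, rate_hz: float = DEFAULT_ECG_RATE_HZ) -> UniformSignal:
    """Resample an irregular ECG trace to a fixed-interval grid.

    The grid starts at the first (offset-corrected) sample time and spans the
    trace without extrapolation; each output sample is the linear
    interpolation of the two bracketing input samples.  Duplicate input
    timestamps are collapsed to their mean value before interpolation.
    """
    if rate_hz <= 0:
        raise InvalidInputError("rate_hz must be positive")
    t_ms = trace.times_oct_ms
    v = trace.values
    # Collapse duplicate timestamps (monotone non-strict would already have
    # been rejected by ECGTrace, but offset arithmetic keeps this cheap guard).
    if np.unique(t_ms).size != t_ms.size:  # pragma: no cover - defensive
        s = pd.Series(v).groupby(t_ms).mean()
        t_ms, v = s.index.to_numpy(), s.to_numpy()
    dt = 1000.0 / rate_hz
    n = int(np.floor((t_ms[-1] - t_ms[0]) / dt + 1e-9)) + 1
    grid = t_ms[0] + np.arange(n) * dt
    return UniformSignal(t0_ms=float(t_ms[0]), rate_hz=rate_hz, values=np.interp(grid, t_ms, v))


# ---------------------------------------------------------------------------
# R-peak detection (Engelse-Zeelenberg with adaptive threshold)
# ---------------------------------------------------------------------------

def detect_r_peaks(sig: UniformSignal) -> PeakTrain:
    """Detect ECG R peaks on a uniformly sampled signal.

    Implements the Engelse-Zeelenberg scheme: a 4-sample differentiator
    followed by a [1, 4, 6, 4, 1] low-pass, with the Lourenco-style adaptive
    threshold M tracked over the last five detected complexes and decayed
    between beats.  A candidate QRS is confirmed when the low-passed signal
    crosses below -M within 160 ms of the upward threshold crossing; the
    returned time is the raw-signal maximum inside the confirmation window,
    i.e. the R apex itself.

    Returns an empty train (with a logged warning) when no QRS is found.
    """
    fs = sig.rate_hz
    if fs < 100:
        raise InvalidInputError("R-peak detection requires a sampling rate >= 100 Hz")
    if sig.duration_s < 2.0:
        raise InvalidInputError("R-peak detection requires at least 2 s of signal")
    x = sig.values
    # Powerline band-stop (48-52 Hz) where the rate can represent it.
    if fs > 104:
        b, a = _signal.butter(4, [2 * 48.0 / fs, 2 * 52.0 / fs], btype="bandstop")
        filt = _signal.lfilter(b, a, x)
    else:  # pragma: no cover - rates below 104 Hz are unusual here
        filt = x.astype(float)

    diff = np.zeros_like(filt)
    diff[4:] = filt[4:] - filt[:-4]
    low = _signal.lfilter([1.0, 4.0, 6.0, 4.0, 1.0], [1.0], diff)

    ms200 = int(0.2 * fs)
    ms1200 = int(1.2 * fs)
    ms160 = int(0.16 * fs)
    neg_threshold = int(0.01 * fs)
    low[:ms200] = 0.0  # filter start-up transient

    m_slope = np.linspace(1.0, 0.6, ms1200 - ms200)
    train_end = min(int(5 * fs), low.size)
    # Threshold initialised from the whole training window, so baseline noise
    # before the first QRS cannot out-race an as-yet-untrained threshold.
    m_train = 0.6 * float(np.max(low[:train_end]))
    M = m_train
    MM: list[float] = [m_train] * 5
    new_m5 = 0.0
    qrs: list[int] = []
    peaks: list[int] = []
    thi_idx = -1
    thi = False
    thf = False
    counter = 0

    for i in range(low.size):
        # --- adaptive threshold update -----------------------------------
        if i < train_end and not qrs:
            M = m_train
        elif qrs and i < qrs[-1] + ms200:
            new_m5 = 0.6 * float(np.max(low[qrs[-1] : i + 1]))
            if MM and new_m5 > 1.5 * MM[-1]:
                new_m5 = 1.1 * MM[-1]
        elif qrs and i == qrs[-1] + ms200:
            if new_m5 == 0.0 and MM:
                new_m5 = MM[-1]
            MM.append(new_m5)
            if len(MM) > 5:
                MM.pop(0)
            M = float(np.mean(MM))
        elif qrs and qrs[-1] + ms200 < i < qrs[-1] + ms1200:
            M = float(np.mean(MM)) * m_slope[i - (qrs[-1] + ms200)]
        elif qrs and i >= qrs[-1] + ms1200:
            M = 0.6 * float(np.mean(MM))

        # --- QRS onset (refractory 200 ms) -------------------------------
        if (not qrs or i > qrs[-1] + ms200) and low[i] > M:
            qrs.append(i)
            thi_idx = i
            thi = True
            thf = False
            counter = 0

        # --- confirmation: negative excursion below -M within 160 ms -----
        if thi and i < thi_idx + ms160:
            if low[i] < -M and low[i - 1] > -M:
                thf = True
            if thf and low[i] < -M:
                counter += 1
            elif thf and low[i] > -M:
                counter = 0
                thi = False
                thf = False
        elif thi and i >= thi_idx + ms160:
            counter = 0
            thi = False
            thf = False

        if counter > neg_threshold:
            start = max(thi_idx - int(0.01 * fs), 0)
            peaks.append(start + int(np.argmax(x[start : i + 1])))
            counter = 0
            thi = False
            thf = False

    if not peaks:
        logger.warning("detect_r_peaks: no QRS complex found; returning empty train")
        return PeakTrain(np.empty(0), kind="r_peak")
    times = sig.t0_ms + np.asarray(sorted(set(peaks)), dtype=float) * sig.dt_ms
    return PeakTrain(times, kind="r_peak")


def mean_rr_ms(train: PeakTrain) -> float:
    """Arithmetic mean of successive R-R (or arrival-arrival) intervals, ms."""
    if len(train) < 2:
        raise InvalidInputError("mean RR interval needs at least 2 peaks")
    return float(np.mean(np.diff(train.times_ms)))


# ---------------------------------------------------------------------------
# Event-train encoding
# ---------------------------------------------------------------------------

def encode_train(
    train: PeakTrain,
    t0_ms: float,
    rate_hz: float,
    n_samples: int,
    sigma_samples: float = DEFAULT_SIGMA_SAMPLES,
) -> EncodedTrain:
    """Rasterise events to a uniform grid, Gaussian-smooth and normalise.

    Events are binarised as unit impulses at the nearest grid sample (ties
    round toward the earlier sample; events outside the grid are dropped),
    convolved with a discrete Gaussian of standard deviation ``sigma_samples``
    (kernel truncated at 4 sigma and renormalised to unit sum), and finally
    divided by the maximum so the peak value is exactly 1.  An empty train
    encodes to the all-zero signal.
    """
    if sigma_samples <= 0:
        raise InvalidInputError("sigma_samples must be positive")
    if rate_hz <= 0 or n_samples <= 0:
        raise InvalidInputError("grid must have positive rate and length")
    impulses = np.zeros(int(n_samples))
    if len(train):
        frac = (train.times_ms - t0_ms) * rate_hz / 1000.0
        idx = np.ceil(frac - 0.5).astype(int)  # nearest, exact halves -> earlier
        idx = idx[(idx >= 0) & (idx < n_samples)]
        impulses[idx] = 1.0
    radius = int(np.ceil(4.0 * sigma_samples))
    k = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (k / sigma_samples) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(impulses, kernel, mode="same")
    peak = smooth.max()
    if peak > 0:
        smooth = smooth / peak
    sig = UniformSignal(t0_ms=t0_ms, rate_hz=rate_hz, values=smooth)
    return EncodedTrain(signal=sig, sigma_samples=sigma_samples, source=train)


def train_to_json(obj: PeakTrain | EncodedTrain, path: str | Path) -> None:
    """Serialise a peak train or encoded train to a JSON document."""
    Path(path).write_text(json.dumps(obj.to_dict()))
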