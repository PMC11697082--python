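"""Fringe-washout velocimetry: the sinc^2 relation, its multi-branch inverse,
flow profiles and pulse-arrival detection.

Axial motion of blood during the detector integration time washes out the
interference fringes, dropping the vessel-subarea SNR according to

    SNR_drop = sin(k0 dz)^2 / (k0 dz)^2,      dz = n v t,

with k0 = 2 pi / lambda the central wavenumber, n the refractive index, v the
axial velocity component and t the integration time.  The relation is not
injective: every side lobe of sinc^2 below the observed drop contributes a
candidate velocity, indexed by the numerical solution index (NSI).  The flow
profile used downstream is the per-frame maximal-branch velocity (the
envelope), whose first derivative locates the sharpest rise of each pulse
wave - the pulse-arrival event cross-correlated against the ECG R peaks.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .ecg import PeakTrain
from .errors import InvalidInputError
from .stack import ScanParams, SubareaSeries

#: Default number of solution branches retained (principal + 4 side lobes).
DEFAULT_N_BRANCHES = 5


@dataclass(frozen=True)
class WashoutParams:
    """Physical constants of the washout relation.

    ``k0`` is the central wavenumber 2 pi / lambda (rad/m), ``n`` the
    refractive index, ``t`` the integration time in seconds.
    """

    k0: float
    n: float
    t: float
    n_branches: int = DEFAULT_N_BRANCHES

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.n <= 0 or self.t <= 0:
            raise InvalidInputError("k0, n and t must be positive")
        if self.n_branches < 1:
            raise InvalidInputError("n_branches must be >= 1")

    @classmethod
    def from_scan(cls, scan: ScanParams, n_branches: int = DEFAULT_N_BRANCHES) -> "WashoutParams":
        return cls(
            k0=2.0 * np.pi / scan.wavelength_m,
            n=scan.refractive_index,
            t=scan.integration_time_s,
            n_branches=n_branches,
        )

    @property
    def scale(self) -> float:
        """x = scale * v, i.e. k0 * n * t (rad per m/s)."""
        return self.k0 * self.n * self.t


@dataclass(frozen=True)
class VelocitySolutionSet:
    """All retained washout solutions per frame, ordered by NSI.

    ``solutions[i]`` is the frame-i list of ``(nsi, v)`` pairs with v in m/s,
    strictly increasing in nsi (and hence in v).
    """

    timestamps_ms: np.ndarray
    solutions: list[list[tuple[int, float]]]

    def to_dict(self) -> dict:
        return {
            "timestamps_ms": self.timestamps_ms.tolist(),
            "solutions": [[[nsi, v] for nsi, v in frame] for frame in self.solutions],
        }


@dataclass(frozen=True)
class FlowProfile:
    """Envelope (maximal-branch) velocity series and its time derivative."""

    timestamps_ms: np.ndarray
    envelope_v: np.ndarray  # m/s
    gradient: np.ndarray  # m/s per ms

    def to_dict(self) -> dict:
        return {
            "timestamps_ms": self.timestamps_ms.tolist(),
            "envelope_v": self.envelope_v.tolist(),
            "gradient": self.gradient.tolist(),
        }


# ---------------------------------------------------------------------------
# Forward relation and inversion
# ---------------------------------------------------------------------------

def _sinc2(x):
    return np.sinc(np.asarray(x, dtype=float) / np.pi) ** 2


def forward_washout(v, params: WashoutParams):
    """SNR drop for axial velocity v (m/s): sinc^2(k0 n v t), with value 1 at 0."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise InvalidInputError("velocity must be non-negative")
    out = _sinc2(params.scale * v)
    return float(out) if out.ndim == 0 else out


def _lobe_peak(m: int) -> tuple[float, float]:
    """Location and height of the m-th side lobe of sinc^2 (m >= 1)."""
    # Extremum solves x cos x = sin x inside (m pi, (m+1) pi).
    f = lambda x: x * np.cos(x) - np.sin(x)
    lo, hi = m * np.pi + 1e-9, (m + 1) * np.pi - 1e-9
    x = brentq(f, lo, hi, xtol=1e-13)
    return x, float(_sinc2(x))


def invert_washout(snr_drop: float, params: WashoutParams) -> list[tuple[int, float]]:
    """All candidate velocities for an observed SNR drop, ordered by NSI.

    Branch 0 is the unique root in the principal lobe x in [0, pi).  Branch
    m >= 1 is present only when the m-th side-lobe peak exceeds the observed
    drop; its representative root is taken on the lobe's falling flank so
    that velocity increases strictly with NSI.  Roots are bracketed and
    bisected to an absolute tolerance of 1e-12 in x, then scaled to
    v = x / (k0 n t).
    """
    if not (0.0 < snr_drop <= 1.0):
        raise InvalidInputError("snr_drop must lie in (0, 1]")
    s = params.scale
    if snr_drop == 1.0:
        return [(0, 0.0)]
    g = lambda x: _sinc2(x) - snr_drop
    x0 = brentq(g, 0.0, np.pi, xtol=1e-12)
    out = [(0, x0 / s)]
    for m in range(1, params.n_branches):
        xp, peak = _lobe_peak(m)
        if peak > snr_drop:
            x = brentq(g, xp, (m + 1) * np.pi, xtol=1e-12)
            out.append((m, x / s))
    return out


# ---------------------------------------------------------------------------
# Flow profile
# ---------------------------------------------------------------------------

def _finite_diff(values: np.ndarray, t_ms: np.ndarray) -> np.ndarray:
    """Central differences on actual timestamps; one-sided at the endpoints."""
    n = values.size
    grad = np.empty(n)
    if n == 1:  # pragma: no cover - stacks always have >= 2 frames
        grad[:] = 0.0
        return grad
    grad[0] = (values[1] - values[0]) / (t_ms[1] - t_ms[0])
    grad[-1] = (values[-1] - values[-2]) / (t_ms[-1] - t_ms[-2])
    if n > 2:
        grad[1:-1] = (values[2:] - values[:-2]) / (t_ms[2:] - t_ms[:-2])
    return grad


def build_flow_profile(
    series: SubareaSeries,
    params: WashoutParams,
    smooth_window: int | None = None,
) -> tuple[VelocitySolutionSet, FlowProfile]:
    """Invert every frame's SNR drop and build the envelope flow profile.

    ``envelope_v[i]`` is the maximal retained velocity solution of frame i;
    the gradient is a central difference on the (possibly uneven) frame
    timestamps.  An optional centred moving average (``smooth_window`` odd,
    default off) can be applied to the envelope before differentiation.
    """
    drops = np.asarray(series.snr_drop, dtype=float)
    if np.any(drops <= 0) or np.any(drops > 1):
        raise InvalidInputError("snr_drop values must lie in (0, 1]; clip upstream")
    sols = [invert_washout(float(d), params) for d in drops]
    envelope = np.array([max(v for _, v in frame) for frame in sols])
    if smooth_window:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise InvalidInputError("smooth_window must be a positive odd integer")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(envelope, pad, mode="edge")
        envelope = np.convolve(padded, kernel, mode="valid")
    grad = _finite_diff(envelope, series.timestamps_ms)
    return (
        VelocitySolutionSet(series.timestamps_ms.copy(), sols),
        FlowProfile(series.timestamps_ms.copy(), envelope, grad),
    )


def detect_pulse_arrivals(profile: FlowProfile, rr_ms: float) -> PeakTrain:
    """Sharpest-rise detection: one gradient maximum per heart-rate bin.

    The profile span is partitioned into consecutive bins of width ``rr_ms``
    anchored at the first frame timestamp.  Each bin holding at least three
    frames emits the timestamp of its maximal gradient value (ties toward the
    earlier frame); sparser bins emit nothing.
    """
    if rr_ms <= 0:
        raise InvalidInputError("rr_ms must be positive")
    t = profile.timestamps_ms
    if t.size == 0:
        raise InvalidInputError("empty flow profile")
    bins = np.floor((t - t[0]) / rr_ms).astype(int)
    times = []
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        if idx.size < 3:
            continue
        best = idx[int(np.argmax(profile.gradient[idx]))]
        times.append(t[best])
    return PeakTrain(np.asarray(times, dtype=float), kind="pulse_arrival")


def flow_to_json(solset: VelocitySolutionSet, profile: FlowProfile, path: str | Path) -> None:
    doc = profile.to_dict()
    doc["solutions"] = solset.to_dict()["solutions"]
    Path(path).write_text(json.dumps(doc))
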