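"""Time-resolved OCT B-scan stacks: preprocessing, registration and subarea SNR.

A B-scan stack is a sequence of normalised-intensity cross sections with
per-frame millisecond timestamps, the frame's maximum raw intensity, and the
scanner quality score Q (the B-scan SNR in dB).  The module provides the
fourth-root display transform, rigid registration of every frame against the
average of the first ten frames, extraction of the 7x7 vessel subarea series,
and the subarea SNR / SNR-drop computation that feeds the fringe-washout
velocity inversion.

The noise level of frame i is modelled as ``max_raw[i] / 10^(Q_i/10)``
(shot-noise-limited detection, quality score converted from dB to a linear
power ratio).  Because raw intensity is ``normalised intensity x max_raw``,
the subarea SNR reduces to ``mean(I) * 10^(Q/10)`` and is invariant to the
normalisation constant.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import transform as sktf
from skimage.registration import phase_cross_correlation

from .errors import InvalidInputError, RegistrationError

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanParams:
    """Scanner geometry and optics.

    Defaults mirror a clinical spectral-domain device: 880 nm source, average
    ocular refractive index 1.36, 1024 x 496 px over roughly 2.9 x 1.9 mm,
    and an integration time of 44.8 us (20 kHz nominal A-scan rate) or
    11.2 us (85 kHz).
    """

    wavelength_m: float = 880e-9
    refractive_index: float = 1.36
    integration_time_s: float = 44.8e-6
    width_px: int = 1024
    height_px: int = 496
    fov_lateral_mm: float = 2.9
    fov_axial_mm: float = 1.9

    def __post_init__(self) -> None:
        vals = (
            self.wavelength_m,
            self.refractive_index,
            self.integration_time_s,
            self.width_px,
            self.height_px,
            self.fov_lateral_mm,
            self.fov_axial_mm,
        )
        if any(v <= 0 for v in vals):
            raise InvalidInputError("all scan parameters must be positive")
        if not (400e-9 < self.wavelength_m < 1600e-9):
            raise InvalidInputError("wavelength must be in (400, 1600) nm")
        if self.refractive_index < 1:
            raise InvalidInputError("refractive index must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def subarea_size_um(params: ScanParams, half_width: int = 3) -> tuple[float, float]:
    """Physical (lateral, axial) size in micrometres of the (2h+1)^2 subarea."""
    side = 2 * half_width + 1
    lat = side * params.fov_lateral_mm * 1000.0 / params.width_px
    ax = side * params.fov_axial_mm * 1000.0 / params.height_px
    return lat, ax


@dataclass
class BScanStack:
    """Stack of normalised-intensity B-scans with per-frame metadata."""

    frames: np.ndarray  # (n, height, width), values in [0, 1]
    timestamps_ms: np.ndarray
    max_raw: np.ndarray
    quality_db: np.ndarray
    params: ScanParams
    registered: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        ts = np.asarray(self.timestamps_ms, dtype=float)
        mr = np.asarray(self.max_raw, dtype=float)
        q = np.asarray(self.quality_db, dtype=float)
        if f.ndim != 3:
            raise InvalidInputError("frames must be a (n, height, width) array")
        n = f.shape[0]
        if n < 2:
            raise InvalidInputError("stack needs at least 2 frames")
        if not (ts.shape == mr.shape == q.shape == (n,)):
            raise InvalidInputError("per-frame metadata must match the frame count")
        if not np.all(np.diff(ts) > 0):
            raise InvalidInputError("frame timestamps must be strictly increasing")
        if float(f.min()) < -1e-6 or float(f.max()) > 1 + 1e-6:
            raise InvalidInputError("normalised intensities must lie in [0, 1]")
        if np.any(q <= 0):
            raise InvalidInputError("quality_db must be positive")
        self.frames = f
        self.timestamps_ms = ts
        self.max_raw = mr
        self.quality_db = q

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class VesselTrack:
    """Per-frame vessel-centre annotation for one vessel."""

    centers_px: np.ndarray  # (n, 2) integer (x_lateral, y_axial)
    vessel_id: str = "A1"
    subarea_half_width: int = 3

    def __post_init__(self) -> None:
        c = np.asarray(self.centers_px, dtype=int)
        if c.ndim != 2 or c.shape[1] != 2:
            raise InvalidInputError("centers_px must be an (n, 2) array of (x, y)")
        if self.subarea_half_width < 1:
            raise InvalidInputError("subarea_half_width must be >= 1")
        object.__setattr__(self, "centers_px", c)


@dataclass(frozen=True)
class SubareaSeries:
    """Per-frame vessel-subarea statistics feeding the washout inversion."""

    timestamps_ms: np.ndarray
    mean_intensity: np.ndarray  # normalised units
    snr: np.ndarray  # linear power ratio
    reference_snr: float  # peak per-pixel SNR over the whole series
    snr_drop: np.ndarray  # in (0, 1]


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: rotate about the image centre, then translate.

    In pixel coordinates (x lateral, y axial) the map is
    ``p' = R(angle) (p - c) + c + (dx, dy)`` with c the image centre.
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    angle_deg: float = 0.0

    def inverse(self) -> "RigidTransform":
        th = np.deg2rad(-self.angle_deg)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d = -r @ np.array([self.dx_px, self.dy_px])
        return RigidTransform(float(d[0]), float(d[1]), -self.angle_deg)

    def to_dict(self) -> dict:
        return {"dx_px": self.dx_px, "dy_px": self.dy_px, "angle_deg": self.angle_deg}


def _rigid_matrix(tf: RigidTransform, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    th = np.deg2rad(tf.angle_deg)
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    m = np.eye(3)
    m[:2, :2] = r
    m[:2, 2] = c + np.array([tf.dx_px, tf.dy_px]) - r @ c
    return m


def apply_rigid(frame: np.ndarray, tf: RigidTransform) -> np.ndarray:
    """Warp a frame by a rigid transform; out-of-support regions are zero."""
    a = sktf.EuclideanTransform(matrix=_rigid_matrix(tf, frame.shape))
    return sktf.warp(
        frame.astype(float), a.inverse, order=1, mode="constant", cval=0.0,
        preserve_range=True,
    )


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def visualization_transform(frame: np.ndarray) -> np.ndarray:
    """Display transform ``V(x, y) = 255 * I(x, y)^(1/4)``.

    Strictly monotone in I, so pixel rank order is preserved.
    """
    f = np.asarray(frame, dtype=float)
    if f.min() < 0 or f.max() > 1:
        raise InvalidInputError("intensities must lie in [0, 1]")
    return 255.0 * f ** 0.25


def build_reference(stack: BScanStack, n_frames: int = 10) -> np.ndarray:
    """Pixelwise mean of the first ``n_frames`` frames (registration target)."""
    if n_frames < 1 or stack.n_frames < n_frames:
        raise InvalidInputError(f"stack has fewer than {n_frames} frames")
    return stack.frames[:n_frames].astype(float).mean(axis=0)


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def _angle_score(ref: np.ndarray, frame: np.ndarray, angle: float, upsample: int) -> tuple[float, np.ndarray]:
    moved = apply_rigid(frame, RigidTransform(0.0, 0.0, angle)) if angle else frame
    shift, error, _ = phase_cross_correlation(
        ref, moved, upsample_factor=upsample, normalization=None
    )
    return -float(error), shift


def _ncc_score(ref: np.ndarray, frame: np.ndarray, angle: float, upsample: int) -> tuple[float, np.ndarray]:
    """Similarity of the fully resolved candidate: rotate, estimate the shift,
    apply it, and correlate with the reference over the common support."""
    moved = apply_rigid(frame, RigidTransform(0.0, 0.0, angle)) if angle else frame
    shift, _, _ = phase_cross_correlation(
        ref, moved, upsample_factor=upsample, normalization=None
    )
    aligned = apply_rigid(frame, RigidTransform(float(shift[1]), float(shift[0]), angle))
    support = (aligned > 0) & (ref > 0)
    if support.sum() < 16:  # pragma: no cover - pathological overlap
        return -np.inf, shift
    ncc = np.corrcoef(aligned[support], ref[support])[0, 1]
    return float(ncc), shift


def register_stack(
    stack: BScanStack,
    n_reference: int = 10,
    max_angle_deg: float = 1.5,
    coarse_step_deg: float = 0.25,
    fine_step_deg: float = 0.05,
    upsample: int = 20,
) -> tuple[BScanStack, list[RigidTransform]]:
    """Rigidly align every frame to the first-ten-frame average reference.

    Coarse-to-fine rotation search: candidate angles are scanned at step
    ``coarse_step_deg`` and refined at step ``fine_step_deg`` around the
    winner, each candidate scored by the normalised cross-correlation of the
    fully resolved (rotated + phase-correlation-shifted) frame against the
    reference over their common support; the translation at the winning
    angle is then re-estimated by subpixel phase correlation.  Sub-degree
    rotations move pixels by well under a pixel at coarser pyramid levels,
    so the angle scoring works at native resolution.  Regions moved out of
    support are zero-filled, which produces the characteristic dark borders
    on strongly moving frames.

    Returns the registered stack and the per-frame alignment transforms
    (the transform that was applied to each frame).
    """
    ref = build_reference(stack, n_reference)
    if not np.any(ref):
        raise RegistrationError("reference image is identically zero")

    transforms: list[RigidTransform] = []
    aligned = np.empty_like(stack.frames, dtype=np.float32)
    for i in range(stack.n_frames):
        frame = stack.frames[i].astype(float)
        best_angle = 0.0
        if max_angle_deg > 0:
            coarse = np.arange(-max_angle_deg, max_angle_deg + 1e-9, coarse_step_deg)
            scores = [_ncc_score(ref, frame, a, 4)[0] for a in coarse]
            best_angle = float(coarse[int(np.argmax(scores))])
            half = coarse_step_deg + fine_step_deg
            fine = np.arange(best_angle - half, best_angle + half + 1e-9, fine_step_deg)
            fine = fine[np.abs(fine) <= max_angle_deg + 1e-9]
            scores = [_ncc_score(ref, frame, a, 10)[0] for a in fine]
            best_angle = float(fine[int(np.argmax(scores))])
        _, shift = _angle_score(ref, frame, best_angle, upsample)
        tf = RigidTransform(dx_px=float(shift[1]), dy_px=float(shift[0]), angle_deg=best_angle)
        transforms.append(tf)
        out = apply_rigid(frame, tf)
        aligned[i] = np.clip(out, 0.0, 1.0)

    reg = BScanStack(
        frames=aligned,
        timestamps_ms=stack.timestamps_ms.copy(),
        max_raw=stack.max_raw.copy(),
        quality_db=stack.quality_db.copy(),
        params=stack.params,
        registered=True,
    )
    return reg, transforms


# ---------------------------------------------------------------------------
# Subarea extraction and SNR
# ---------------------------------------------------------------------------

def extract_subarea_series(stack: BScanStack, track: VesselTrack) -> SubareaSeries:
    """Extract the vessel subarea series and compute SNR and SNR drop.

    For frame i with window W x H centred on the annotated vessel centre:

    * ``mean_intensity_i`` is the window mean of the normalised intensity;
    * ``noise_i = max_raw[i] / 10^(Q_i/10)`` converts the quality score to a
      linear power ratio;
    * ``snr_i = mean raw intensity / noise_i = mean_intensity_i * 10^(Q_i/10)``;
    * the reference SNR is the maximum per-pixel SNR over every window pixel
      of every frame of the series;
    * ``snr_drop_i = min(snr_i / reference_snr, 1)``.
    """
    if not stack.registered:
        raise InvalidInputError("stack must be registered before subarea extraction")
    if track.centers_px.shape[0] != stack.n_frames:
        raise InvalidInputError("annotation length must match the frame count")
    h = track.subarea_half_width
    height, width = stack.shape_px
    x = track.centers_px[:, 0]
    y = track.centers_px[:, 1]
    if np.any(x < h) or np.any(x >= width - h) or np.any(y < h) or np.any(y >= height - h):
        raise InvalidInputError(
            f"vessel {track.vessel_id!r}: subarea window touches the image border"
        )

    n = stack.n_frames
    gain = 10.0 ** (stack.quality_db / 10.0)
    mean_int = np.empty(n)
    peak_int = np.empty(n)
    for i in range(n):
        win = stack.frames[i, y[i] - h : y[i] + h + 1, x[i] - h : x[i] + h + 1]
        mean_int[i] = float(win.mean())
        peak_int[i] = float(win.max())
    snr = mean_int * gain
    reference_snr = float(np.max(peak_int * gain))
    if reference_snr <= 0:
        raise InvalidInputError("subarea series has zero reference SNR")
    drop = np.minimum(snr / reference_snr, 1.0)
    return SubareaSeries(
        timestamps_ms=stack.timestamps_ms.copy(),
        mean_intensity=mean_int,
        snr=snr,
        reference_snr=reference_snr,
        snr_drop=drop,
    )


# ---------------------------------------------------------------------------
# Container and annotation IO
# ---------------------------------------------------------------------------

_FRAMES_FILE = "frames.bin"
_META_FILE = "meta.json"


def save_stack(stack: BScanStack, directory: str | Path) -> None:
    """Write a stack container: meta.json + little-endian float32 frames."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": stack.params.to_dict(),
        "timestamps_ms": stack.timestamps_ms.tolist(),
        "max_raw": stack.max_raw.tolist(),
        "quality_db": stack.quality_db.tolist(),
        "registered": stack.registered,
        "n_frames": stack.n_frames,
        "height_px": stack.frames.shape[1],
        "width_px": stack.frames.shape[2],
        "dtype": "<f4",
    }
    (d / _META_FILE).write_text(json.dumps(meta))
    np.ascontiguousarray(stack.frames, dtype="<f4").tofile(d / _FRAMES_FILE)


def load_stack(directory: str | Path) -> BScanStack:
    """Read a stack container, validating the frame payload against metadata."""
    d = Path(directory)
    meta = json.loads((d / _META_FILE).read_text())
    shape = (meta["n_frames"], meta["height_px"], meta["width_px"])
    raw = np.fromfile(d / _FRAMES_FILE, dtype=meta.get("dtype", "<f4"))
    if raw.size != int(np.prod(shape)):
        raise InvalidInputError(
            f"frame payload has {raw.size} values, metadata implies {np.prod(shape)}"
        )
    return BScanStack(
        frames=raw.reshape(shape),
        timestamps_ms=np.asarray(meta["timestamps_ms"], dtype=float),
        max_raw=np.asarray(meta["max_raw"], dtype=float),
        quality_db=np.asarray(meta["quality_db"], dtype=float),
        params=ScanParams(**meta["params"]),
        registered=bool(meta["registered"]),
    )


def write_annotations(tracks: list[VesselTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for i, (x, y) in enumerate(tr.centers_px):
            rows.append({"frame_index": i, "x_px": int(x), "y_px": int(y), "vessel_id": tr.vessel_id})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations(path: str | Path, subarea_half_width: int = 3) -> list[VesselTrack]:
    """Read per-frame vessel-centre annotations (0-based pixel indices)."""
    df = pd.read_csv(path)
    for col in ("frame_index", "x_px", "y_px", "vessel_id"):
        if col not in df.columns:
            raise InvalidInputError(f"annotation CSV is missing column {col!r}")
    tracks = []
    for vid, grp in df.groupby("vessel_id", sort=True):
        grp = grp.sort_values("frame_index")
        if not np.array_equal(grp["frame_index"].to_numpy(), np.arange(len(grp))):
            raise InvalidInputError(f"vessel {vid!r}: frame indices must be 0..n-1")
        centers = grp[["x_px", "y_px"]].to_numpy(dtype=int)
        tracks.append(VesselTrack(centers, str(vid), subarea_half_width))
    return tracks
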