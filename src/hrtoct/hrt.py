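"""Heart-retina time estimation and reproducibility statistics.

The ECG R-peak train and the OCT pulse-arrival train are encoded on a common
uniform grid, Gaussian-smoothed, and compared by normalised cross-correlation
with the OCT series as the baseline.  The ECG window is padded 10 s before
the first and 1 s after the last OCT event.  A negative argmax lag means the
ECG pattern precedes the OCT pattern; the heart-retina time (HRT) is the
additive inverse of that offset.  Because both trains are near-periodic at
the heart rate, the correlation is a comb of peaks one R-R interval apart;
the physiologically meaningful offset is the one within one cardiac cycle,
and an unrestricted argmax outside [-RR, 0] flags the exam as an outlier.

Cohort reproducibility is summarised with the coefficient of variation (CoV,
sample SD over mean) at four levels: inter-subject, intra-subject,
intra-exam (across vessels of one exam) and intra-vessel (across exams of
one vessel).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import (
    DEFAULT_ECG_RATE_HZ,
    DEFAULT_SIGMA_SAMPLES,
    EncodedTrain,
    PeakTrain,
    encode_train,
    mean_rr_ms,
)
from .errors import DegenerateSignalError, InvalidInputError


@dataclass(frozen=True)
class HRTConfig:
    """Common-grid and padding settings for the cross-correlation."""

    grid_rate_hz: float = DEFAULT_ECG_RATE_HZ
    sigma_samples: float = DEFAULT_SIGMA_SAMPLES
    pad_before_s: float = 10.0
    pad_after_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.grid_rate_hz, self.sigma_samples, self.pad_before_s, self.pad_after_s) <= 0:
            raise InvalidInputError("all HRTConfig fields must be positive")


@dataclass(frozen=True)
class HRTEstimate:
    """Cross-correlation curve and the derived heart-retina time."""

    lags_ms: np.ndarray
    cc: np.ndarray
    offset_ms: float  # argmax restricted to [-RR_mean, 0]
    hrt_ms: float  # additive inverse of offset_ms
    rr_mean_ms: float
    is_outlier: bool  # unrestricted argmax outside [-RR_mean, 0]
    argmax_offset_ms: float = field(default=np.nan)  # unrestricted argmax lag

    def to_dict(self) -> dict:
        return {
            "offset_ms": self.offset_ms,
            "hrt_ms": self.hrt_ms,
            "rr_mean_ms": self.rr_mean_ms,
            "is_outlier": self.is_outlier,
            "argmax_offset_ms": self.argmax_offset_ms,
            "lags_ms": self.lags_ms.tolist(),
            "cc": self.cc.tolist(),
        }


@dataclass(frozen=True)
class CohortRecord:
    """One vessel-level HRT measurement inside a cohort."""

    subject_id: str
    exam_id: str
    vessel_id: str
    hrt_ms: float
    is_outlier: bool = False

    def __post_init__(self) -> None:
        if not (self.subject_id and self.exam_id and self.vessel_id):
            raise InvalidInputError("cohort record ids must be non-empty")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "exam_id": self.exam_id,
            "vessel_id": self.vessel_id,
            "hrt_ms": self.hrt_ms,
            "is_outlier": self.is_outlier,
        }


@dataclass(frozen=True)
class CoVReport:
    """Coefficient-of-variation summary; None marks a level with no group
    of at least two members."""

    inter_subject_cov: float | None
    intra_subject_cov_mean: float | None
    intra_subject_cov_sd: float | None
    intra_exam_cov_mean: float | None
    intra_exam_cov_sd: float | None
    intra_vessel_cov_mean: float | None
    intra_vessel_cov_sd: float | None
    overall_mean_ms: float | None
    overall_sd_ms: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Cross-correlation
# ---------------------------------------------------------------------------

def cross_correlate_trains(
    oct_train: EncodedTrain, ecg_train: EncodedTrain
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised cross-correlation of two encoded trains.

    Returns ``cc(l) = sum_t O(t) E(t + l) / sqrt(sum O^2 * sum E^2)`` for
    every integer-sample lag at which the (padded) ECG window fully covers
    the shifted OCT support.  The OCT train is the baseline: a negative
    argmax lag means the ECG pattern leads.
    """
    o_sig, e_sig = oct_train.signal, ecg_train.signal
    if not np.isclose(o_sig.rate_hz, e_sig.rate_hz):
        raise InvalidInputError("trains must share the same grid rate")
    o, e = o_sig.values, e_sig.values
    if e.size < o.size:
        raise InvalidInputError("ECG window must cover the OCT window")
    if not np.any(o) or not np.any(e):
        raise DegenerateSignalError("cannot correlate an all-zero train")
    denom = np.sqrt(np.sum(o**2) * np.sum(e**2))
    cc = np.correlate(e, o, mode="valid") / denom
    k = np.arange(cc.size)
    lags_ms = (e_sig.t0_ms - o_sig.t0_ms) + k * o_sig.dt_ms
    return lags_ms, cc


def _tie_break_argmax(lags: np.ndarray, cc: np.ndarray) -> int:
    """Index of the maximal cc value; exact ties go to the smallest |lag|."""
    top = np.flatnonzero(cc == cc.max())
    return int(top[np.argmin(np.abs(lags[top]))])


def estimate_hrt(arrivals: PeakTrain, r_peaks: PeakTrain, cfg: HRTConfig = HRTConfig()) -> HRTEstimate:
    """Estimate the heart-retina time from pulse arrivals and R peaks.

    Both trains are encoded on a common grid at ``cfg.grid_rate_hz``: the
    OCT arrival span defines the base window and the ECG window is padded
    ``pad_before_s`` before / ``pad_after_s`` after it.  The offset is the
    cross-correlation argmax restricted to one cardiac cycle, i.e. lags in
    [-RR_mean, 0]; the exam is flagged as an outlier when the unrestricted
    argmax falls outside that interval.  HRT is the additive inverse of the
    offset.
    """
    if len(arrivals) < 2 or len(r_peaks) < 2:
        raise InvalidInputError("need at least 2 events in each train")
    dt = 1000.0 / cfg.grid_rate_hz
    t0 = float(arrivals.times_ms[0])
    t_end = float(arrivals.times_ms[-1])
    n_oct = int(np.floor((t_end - t0) / dt + 1e-9)) + 1
    t0_e = t0 - cfg.pad_before_s * 1000.0
    end_e = t_end + cfg.pad_after_s * 1000.0
    n_ecg = int(np.floor((end_e - t0_e) / dt + 1e-9)) + 1

    r_in = r_peaks.times_ms
    r_in = r_in[(r_in >= t0_e) & (r_in <= t0_e + (n_ecg - 1) * dt)]
    if r_in.size == 0:
        raise InvalidInputError("ECG and OCT windows do not overlap")
    oct_enc = encode_train(arrivals, t0, cfg.grid_rate_hz, n_oct, cfg.sigma_samples)
    ecg_enc = encode_train(
        PeakTrain(r_in, kind="r_peak"), t0_e, cfg.grid_rate_hz, n_ecg, cfg.sigma_samples
    )
    lags, cc = cross_correlate_trains(oct_enc, ecg_enc)
    rr = mean_rr_ms(r_peaks)

    i_unres = _tie_break_argmax(lags, cc)
    unrestricted = float(lags[i_unres])
    in_cycle = (lags >= -rr - 1e-9) & (lags <= 1e-9)
    if not np.any(in_cycle):
        raise InvalidInputError("no correlation lag inside one cardiac cycle")
    sub = np.flatnonzero(in_cycle)
    i_res = sub[_tie_break_argmax(lags[sub], cc[sub])]
    offset = float(lags[i_res])
    return HRTEstimate(
        lags_ms=lags,
        cc=cc,
        offset_ms=offset,
        hrt_ms=-offset,
        rr_mean_ms=rr,
        is_outlier=not (-rr - 1e-9 <= unrestricted <= 1e-9),
        argmax_offset_ms=unrestricted,
    )


# ---------------------------------------------------------------------------
# Reproducibility statistics
# ---------------------------------------------------------------------------

def cov(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError("CoV needs at least 2 values")
    m = v.mean()
    if m == 0:
        raise InvalidInputError("CoV is undefined for zero mean")
    return float(np.std(v, ddof=1) / m)


def _group_cov_stats(df: pd.DataFrame, keys: list[str]) -> tuple[float | None, float | None]:
    covs = [
        cov(grp["hrt_ms"].to_numpy())
        for _, grp in df.groupby(keys, sort=True)
        if len(grp) >= 2
    ]
    if not covs:
        return None, None
    mean = float(np.mean(covs))
    sd = float(np.std(covs, ddof=1)) if len(covs) >= 2 else None
    return mean, sd


def cov_report(records: list[CohortRecord]) -> CoVReport:
    """Aggregate vessel-level HRT records into the four CoV levels.

    Outlier records are expected to be excluded upstream.  Levels without a
    single group of >= 2 members are reported as None rather than raising.
    """
    if not records:
        raise InvalidInputError("cov_report needs at least one record")
    df = pd.DataFrame([r.to_dict() for r in records])

    per_subject = df.groupby("subject_id", sort=True)["hrt_ms"].mean()
    inter = cov(per_subject.to_numpy()) if len(per_subject) >= 2 else None

    intra_subj_mean, intra_subj_sd = _group_cov_stats(df, ["subject_id"])
    intra_exam_mean, intra_exam_sd = _group_cov_stats(df, ["subject_id", "exam_id"])
    intra_vessel_mean, intra_vessel_sd = _group_cov_stats(df, ["subject_id", "vessel_id"])

    overall_mean = float(df["hrt_ms"].mean())
    overall_sd = float(df["hrt_ms"].std(ddof=1)) if len(df) >= 2 else None
    return CoVReport(
        inter_subject_cov=inter,
        intra_subject_cov_mean=intra_subj_mean,
        intra_subject_cov_sd=intra_subj_sd,
        intra_exam_cov_mean=intra_exam_mean,
        intra_exam_cov_sd=intra_exam_sd,
        intra_vessel_cov_mean=intra_vessel_mean,
        intra_vessel_cov_sd=intra_vessel_sd,
        overall_mean_ms=overall_mean,
        overall_sd_ms=overall_sd,
    )


def write_records_jsonl(records: list[CohortRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_records_jsonl(path: str | Path) -> list[CohortRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(CohortRecord(**json.loads(line)))
    return records
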