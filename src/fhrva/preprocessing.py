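"""Preprocessing of cardiotocographic fetal heart rate (FHR) traces.

The raw FHR channel of a cardiotocograph is an evenly resampled
beats-per-minute series contaminated by Doppler drop-outs (signal loss)
and implausible spikes.  This module detects and repairs those artifacts,
applies the study inclusion gate (signal loss, outlier fraction, minimum
duration, visual flag), estimates the *floatingline* -- a smooth curve
following slow alterations of the heart rate -- and extracts the FHRV
(fetal heart rate variability) signal as the residual after floatingline
subtraction.  An automated 15 bpm / 15 s acceleration counter is provided
as a reproducible stand-in for visual acceleration assessment.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FHRRecord",
    "QualityReport",
    "FHRVSignal",
    "detect_outliers",
    "repair_gaps",
    "quality_gate",
    "estimate_floatingline",
    "extract_fhrv",
    "count_accelerations",
    "longest_valid_span",
    "preprocess_record",
]

#: Physiological plausibility range for fetal heart rate samples (bpm).
FHR_MIN_BPM = 50.0
FHR_MAX_BPM = 220.0
#: Maximum plausible sample-to-sample jump (bpm) between valid samples.
MAX_JUMP_BPM = 25.0

#: Inclusion-gate thresholds.
MAX_SIGNAL_LOSS_FRACTION = 0.30
MAX_OUTLIER_FRACTION = 0.05
MIN_DURATION_MIN = 20.0

#: Acceleration definition (threshold over floatingline, minimum duration,
#: merge gap), following the standard 15 bpm / 15 s clinical convention.
ACCEL_THRESHOLD_BPM = 15.0
ACCEL_MIN_DURATION_S = 15.0
ACCEL_MERGE_GAP_S = 5.0


@dataclasses.dataclass
class FHRRecord:
    """One evenly sampled FHR trace with metadata.

    ``fhr`` is a bpm series where NaN marks signal loss.  ``week`` is the
    gestational week (28-42) when known; ``accel_count_target`` carries the
    reference acceleration count (e.g. generator ground truth or a visual
    count) when available.
    """

    record_id: str
    fhr: np.ndarray
    sampling_rate: float
    week: int | None = None
    accel_count_target: int | None = None
    visually_flagged: bool = False

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        if self.fhr.ndim != 1 or self.fhr.size < 1:
            raise ValueError("fhr must be a non-empty 1-D series")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.week is not None and not (28 <= self.week <= 42):
            raise ValueError(f"week must lie in [28, 42], got {self.week}")

    @property
    def duration_s(self) -> float:
        return self.fhr.size / self.sampling_rate


@dataclasses.dataclass
class QualityReport:
    """Outcome of the inclusion gate for one record."""

    record_id: str
    signal_loss_fraction: float
    outlier_fraction: float
    duration_min: float
    visually_flagged: bool
    included: bool
    reasons: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class FHRVSignal:
    """Variability residual after floatingline subtraction.

    Invariant: ``fhrv + floatingline == fhr_clean`` elementwise.
    """

    fhrv: np.ndarray
    floatingline: np.ndarray
    fhr_clean: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        n = len(self.fhrv)
        if not (len(self.floatingline) == n and len(self.fhr_clean) == n):
            raise ValueError("fhrv, floatingline and fhr_clean must share length")


def detect_outliers(fhr: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Flag physiologically implausible samples.

    A sample is an outlier when it lies outside [50, 220] bpm, or when the
    jump from the previous valid, in-range sample exceeds 25 bpm (the later
    sample of the step is flagged).  Missing (NaN) samples are never
    outliers.
    """
    x = np.asarray(fhr, dtype=float)
    if x.size == 0:
        raise ValueError("cannot detect outliers on an empty series")
    finite = np.isfinite(x)
    mask = finite & ((x < FHR_MIN_BPM) | (x > FHR_MAX_BPM))
    # Jump rule on adjacent samples that are both valid and in range, so a
    # single range-outlier does not drag its neighbours in.
    ok = finite & ~mask
    both = ok[1:] & ok[:-1]
    jump = np.zeros_like(mask)
    jump[1:] = both & (np.abs(np.diff(np.where(ok, x, np.nan))) > MAX_JUMP_BPM)
    return mask | jump


def repair_gaps(
    fhr: np.ndarray,
    mask: np.ndarray,
    sampling_rate: float,
    max_gap_s: float = 3.0,
) -> np.ndarray:
    """Interpolate short runs of flagged-or-missing samples.

    Runs of duration <= ``max_gap_s`` with valid samples on both sides are
    replaced by linear interpolation; longer runs, and runs touching an end
    of the record, are left missing (NaN).  Valid samples are never altered,
    which makes the operation idempotent.
    """
    x = np.asarray(fhr, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValueError("mask length must equal series length")
    bad = mask | ~np.isfinite(x)
    out = x.copy()
    if not bad.any():
        return out
    max_len = int(round(max_gap_s * sampling_rate))
    idx = np.flatnonzero(np.diff(np.concatenate(([False], bad, [False])).astype(int)))
    starts, ends = idx[::2], idx[1::2]  # bad runs are [start, end)
    for s, e in zip(starts, ends):
        if s == 0 or e == x.size or (e - s) > max_len:
            out[s:e] = np.nan
            continue
        left, right = out[s - 1], out[e]
        out[s:e] = left + (right - left) * np.arange(1, e - s + 1) / (e - s + 1)
    return out


def quality_gate(record: FHRRecord, mask: np.ndarray) -> QualityReport:
    """Apply the four inclusion criteria to a raw record.

    Included records have signal loss <= 30% of the record length, outliers
    < 5%, duration >= 20 min, and no visual artifact flag.
    """
    x = record.fhr
    mask = np.asarray(mask, dtype=bool)
    loss = float(np.mean(~np.isfinite(x)))
    outliers = float(np.mean(mask & np.isfinite(x)))
    duration_min = record.duration_s / 60.0
    reasons: list[str] = []
    if loss > MAX_SIGNAL_LOSS_FRACTION:
        reasons.append(
            f"signal loss {loss:.1%} exceeds {MAX_SIGNAL_LOSS_FRACTION:.0%} of signal length"
        )
    if not outliers < MAX_OUTLIER_FRACTION:
        reasons.append(f"outlier fraction {outliers:.1%} not below {MAX_OUTLIER_FRACTION:.0%}")
    if duration_min < MIN_DURATION_MIN:
        reasons.append(f"duration {duration_min:.1f} min below {MIN_DURATION_MIN:.0f} min")
    if record.visually_flagged:
        reasons.append("visually evident artifacts flagged")
    return QualityReport(
        record_id=record.record_id,
        signal_loss_fraction=loss,
        outlier_fraction=outliers,
        duration_min=duration_min,
        visually_flagged=record.visually_flagged,
        included=not reasons,
        reasons=reasons,
    )


def _interpolate_mask(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked samples by linear interpolation from unmasked ones."""
    if not mask.any():
        return x
    if mask.all():
        return x
    out = x.copy()
    idx = np.arange(x.size)
    out[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return out


def estimate_floatingline(
    fhr_clean: np.ndarray,
    sampling_rate: float,
    *,
    candidate_threshold_bpm: float = 10.0,
    cutoff_hz: float = 0.025,
    n_iterations: int = 2,
) -> np.ndarray:
    """Estimate the floatingline of a gap-repaired FHR series.

    The floatingline follows slow alterations of the heart rate (passband
    gain >= 0.9 at periods of 60 s and longer; components with periods of
    10 s and shorter attenuated below 0.1) while excluding transient
    excursions such as accelerations, so that they remain in the FHRV
    residual.  Smoothing is adaptive: samples more than
    ``candidate_threshold_bpm`` above a 60-s running median are treated as
    acceleration candidates and bridged by interpolation before smoothing;
    the detection is iterated so dense acceleration sequences that bias the
    first median are still caught.  The masked series then passes through a
    10-s running median (spike rejection) and a zero-phase 4th-order
    Butterworth low-pass at ``cutoff_hz``.
    """
    x = np.asarray(fhr_clean, dtype=float)
    fs = float(sampling_rate)
    min_len = int(round(60.0 * fs)) + 1
    if x.size < min_len:
        raise ValueError(f"series shorter than the smoothing support ({min_len} samples)")
    if not np.isfinite(x).all():
        raise ValueError("floatingline estimation requires a series without missing values")

    w_long = int(round(60.0 * fs)) | 1
    w_short = int(round(10.0 * fs)) | 1
    dilate = max(int(round(5.0 * fs)), 1)
    ref = ndimage.median_filter(x, size=w_long, mode="nearest")
    candidates = np.zeros(x.size, dtype=bool)
    base = x
    for _ in range(n_iterations):
        candidates |= (x - ref) > candidate_threshold_bpm
        # Widen the mask by 5 s each side to cover the bump tails.
        widened = ndimage.binary_dilation(candidates, iterations=dilate)
        base = _interpolate_mask(x, widened)
        ref = ndimage.median_filter(base, size=w_long, mode="nearest")
    base = ndimage.median_filter(base, size=w_short, mode="nearest")
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, base)


def extract_fhrv(
    fhr_clean: np.ndarray,
    floatingline: np.ndarray,
    sampling_rate: float,
) -> FHRVSignal:
    """Subtract the floatingline from the clean FHR to obtain the FHRV."""
    fhr_clean = np.asarray(fhr_clean, dtype=float)
    floatingline = np.asarray(floatingline, dtype=float)
    if fhr_clean.shape != floatingline.shape:
        raise ValueError("fhr_clean and floatingline must have equal length")
    return FHRVSignal(
        fhrv=fhr_clean - floatingline,
        floatingline=floatingline,
        fhr_clean=fhr_clean,
        sampling_rate=sampling_rate,
    )


def count_accelerations(
    fhr_clean: np.ndarray,
    floatingline: np.ndarray,
    sampling_rate: float,
    *,
    threshold_bpm: float = ACCEL_THRESHOLD_BPM,
    min_duration_s: float = ACCEL_MIN_DURATION_S,
    merge_gap_s: float = ACCEL_MERGE_GAP_S,
) -> int:
    """Count accelerations: residual >= 15 bpm sustained for >= 15 s.

    Maximal supra-threshold intervals separated by less than ``merge_gap_s``
    are merged before the duration test.
    """
    resid = np.asarray(fhr_clean, dtype=float) - np.asarray(floatingline, dtype=float)
    above = resid >= threshold_bpm
    if not above.any():
        return 0
    idx = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    starts, ends = list(idx[::2]), list(idx[1::2])
    merged = [[starts[0], ends[0]]]
    max_gap = merge_gap_s * sampling_rate
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = min_duration_s * sampling_rate
    return sum(1 for s, e in merged if (e - s) >= min_len)


def longest_valid_span(fhr: np.ndarray) -> slice:
    """Return the slice of the longest contiguous run without missing values."""
    x = np.asarray(fhr, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        return slice(0, 0)
    idx = np.flatnonzero(np.diff(np.concatenate(([False], ok, [False])).astype(int)))
    starts, ends = idx[::2], idx[1::2]
    best = int(np.argmax(ends - starts))
    return slice(int(starts[best]), int(ends[best]))


def preprocess_record(
    record: FHRRecord,
    *,
    max_gap_s: float = 3.0,
) -> tuple[FHRVSignal | None, QualityReport]:
    """Full preprocessing of one record: outliers, repair, gate, FHRV.

    Returns ``(None, report)`` for records that fail the inclusion gate.
    The FHRV is extracted on the longest contiguous valid span remaining
    after gap repair (longer gaps are excluded from the analysis span).
    """
    mask = detect_outliers(record.fhr, record.sampling_rate)
    report = quality_gate(record, mask)
    if not report.included:
        return None, report
    repaired = repair_gaps(record.fhr, mask, record.sampling_rate, max_gap_s=max_gap_s)
    span = longest_valid_span(repaired)
    clean = repaired[span]
    if clean.size / record.sampling_rate / 60.0 < MIN_DURATION_MIN:
        report.included = False
        report.reasons.append(
            f"longest uninterrupted span {clean.size / record.sampling_rate / 60.0:.1f} min "
            f"below {MIN_DURATION_MIN:.0f} min"
        )
        return None, report
    floatingline = estimate_floatingline(clean, record.sampling_rate)
    return extract_fhrv(clean, floatingline, record.sampling_rate), report
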