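"""Time- and frequency-domain FHRV features.

The linear description of the FHRV signal comprises three time-domain
indices -- short-term variability (STV, the mean of per-30-s-window
standard deviations), the standard deviation of the whole FHRV (SDev),
and the peak-to-peak amplitude of the clean FHR (PPA) -- and eight
frequency-domain indices: absolute and percentage power in the VLF
(0-0.003 Hz), LF (0.003-0.2 Hz) and HF (0.2-1 Hz) bands, the total power
(their sum), and the sympatho-vagal balance SVB = LF/HF.  Spectra are
estimated with an averaged short-time (Welch) periodogram using 300-s
Hann segments at 50% overlap, the finest usable resolution for the VLF
edge on 20-min records.

The two global features -- gestational week and mean FHR -- are carried
unchanged alongside the computed indices.
"""

from __future__ import annotations

import dataclasses
import typing
import warnings

import numpy as np
from scipy import signal as sps

from .preprocessing import FHRVSignal

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "Spectrum",
    "BandPowers",
    "FREQUENCY_BANDS",
    "compute_time_features",
    "compute_psd",
    "band_powers",
    "compute_linear_features",
]

#: Canonical order of the 19 features of one record.
FEATURE_NAMES = (
    "week", "mean_fhr",
    "STV", "SDev", "PPA",
    "VLF", "LF", "HF", "TotalPower", "pVLF", "pLF", "pHF", "SVB",
    "SampEn", "SD1", "SD2", "HFD", "VIRR", "VIFHR",
)

FREQUENCY_BANDS = {"VLF": (0.0, 0.003), "LF": (0.003, 0.2), "HF": (0.2, 1.0)}


class Spectrum(typing.NamedTuple):
    """One-sided power spectral density on a frequency grid (bpm^2/Hz)."""

    freqs: np.ndarray
    density: np.ndarray


class BandPowers(typing.NamedTuple):
    VLF: float
    LF: float
    HF: float
    TotalPower: float
    pVLF: float
    pLF: float
    pHF: float
    SVB: float


@dataclasses.dataclass
class FeatureVector:
    """The 19 named features of one record (NaN marks an undefined value)."""

    record_id: str
    week: float
    mean_fhr: float
    STV: float
    SDev: float
    PPA: float
    VLF: float
    LF: float
    HF: float
    TotalPower: float
    pVLF: float
    pLF: float
    pHF: float
    SVB: float
    SampEn: float
    SD1: float
    SD2: float
    HFD: float
    VIRR: float
    VIFHR: float

    def as_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        return {"record_id": d.pop("record_id"), **{k: d[k] for k in FEATURE_NAMES}}


def compute_time_features(
    fhrv: np.ndarray,
    fhr_clean: np.ndarray,
    sampling_rate: float,
    window_s: float = 30.0,
) -> tuple[float, float, float]:
    """Return (STV, SDev, PPA).

    STV averages the sample SD over consecutive non-overlapping windows of
    ``window_s`` (a trailing partial window is discarded); SDev is the
    sample SD of the whole FHRV; PPA is max - min of the clean FHR.
    All SDs use the n-1 denominator.
    """
    x = np.asarray(fhrv, dtype=float)
    w = int(round(window_s * sampling_rate))
    n_win = x.size // w
    if n_win < 1:
        raise ValueError("FHRV shorter than one STV window")
    windows = x[: n_win * w].reshape(n_win, w)
    stv = float(np.mean(np.std(windows, axis=1, ddof=1)))
    sdev = float(np.std(x, ddof=1))
    ppa = float(np.ptp(np.asarray(fhr_clean, dtype=float)))
    return stv, sdev, ppa


def compute_psd(
    fhrv: np.ndarray,
    sampling_rate: float,
    segment_s: float = 300.0,
) -> Spectrum:
    """Averaged short-time periodogram of the FHRV (Welch, Hann segments,
    50% overlap, per-segment mean removal).

    The returned density integrates to the series variance (Parseval,
    within ~2% for the default windowing).  Missing values are rejected.
    """
    x = np.asarray(fhrv, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("PSD estimation requires a series without missing values")
    nperseg = int(round(segment_s * sampling_rate))
    if x.size < nperseg:
        raise ValueError(
            f"series shorter than one {segment_s:.0f}-s segment ({nperseg} samples)"
        )
    freqs, density = sps.welch(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    return Spectrum(freqs=freqs, density=density)


def _band_integral(freqs: np.ndarray, density: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over [lo, hi], with the band
    edges added by linear interpolation so narrow bands are not lost
    between grid points."""
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, freqs, density)
    return float(np.trapezoid(vals, grid))


def band_powers(spectrum: Spectrum) -> BandPowers:
    """Integrate the PSD over the VLF/LF/HF bands.

    TotalPower is the exact sum of the three band powers; percentages are
    relative to it.  SVB = LF/HF is reported as NaN with a warning when
    HF is zero; percentages are NaN when the total power is zero.
    """
    freqs, density = spectrum
    if freqs[-1] < 1.0:
        raise ValueError("spectrum must cover 0-1 Hz (sampling rate >= 2 Hz required)")
    vlf = _band_integral(freqs, density, *FREQUENCY_BANDS["VLF"])
    lf = _band_integral(freqs, density, *FREQUENCY_BANDS["LF"])
    hf = _band_integral(freqs, density, *FREQUENCY_BANDS["HF"])
    total = vlf + lf + hf
    if total > 0:
        pvlf, plf, phf = (100.0 * b / total for b in (vlf, lf, hf))
    else:
        pvlf = plf = phf = np.nan
    if hf > 0:
        svb = lf / hf
    else:
        warnings.warn("HF power is zero; SVB undefined", stacklevel=2)
        svb = np.nan
    return BandPowers(vlf, lf, hf, total, pvlf, plf, phf, svb)


def compute_linear_features(
    sig: FHRVSignal,
    window_s: float = 30.0,
    segment_s: float = 300.0,
) -> dict[str, float]:
    """All time- and frequency-domain features of one FHRV signal, plus the
    mean FHR computed on the clean trace."""
    stv, sdev, ppa = compute_time_features(
        sig.fhrv, sig.fhr_clean, sig.sampling_rate, window_s=window_s
    )
    bp = band_powers(compute_psd(sig.fhrv, sig.sampling_rate, segment_s=segment_s))
    return {
        "mean_fhr": float(np.mean(sig.fhr_clean)),
        "STV": stv,
        "SDev": sdev,
        "PPA": ppa,
        **bp._asdict(),
    }
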