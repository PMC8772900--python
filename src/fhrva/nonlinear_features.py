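"""Nonlinear FHRV indices: sample entropy, Poincare descriptors, Higuchi
fractal dimension, and symbolic-dynamics variability indices.

Conventions follow common heart-rate-variability practice where the
source method leaves parameters open: SampEn uses embedding dimension
m=2 with tolerance r = 0.2 x SD of the series and the Chebyshev distance
with self-matches excluded; Higuchi uses k_max=8; symbolic dynamics
quantizes the series into 6 uniform levels spanning mean +/- 3 SD and
summarizes overlapping 3-symbol words by their normalized Shannon
entropy.  The variability index is computed both on the FHRV signal
(VIFHR) and on the increment series of beat-to-beat intervals derived
from the FHR (VIRR), with RR_i = 60000 / FHR_i in milliseconds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

from .preprocessing import FHRVSignal

__all__ = [
    "SymbolicConfig",
    "NonlinearParams",
    "sample_entropy",
    "poincare_sd",
    "higuchi_fd",
    "symbolize",
    "variability_index",
    "compute_nonlinear_features",
]


@dataclasses.dataclass
class SymbolicConfig:
    """Quantization settings for symbolic dynamic analysis."""

    n_levels: int = 6
    word_length: int = 3
    n_sigma: float = 3.0  # quantization span: mean +/- n_sigma * SD

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")


@dataclasses.dataclass
class NonlinearParams:
    m: int = 2            # SampEn embedding dimension
    r: float = 0.2        # SampEn tolerance, fraction of the series SD
    k_max: int = 8        # maximum Higuchi delay

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")


def _template_pairs(x: np.ndarray, m: int, n_templates: int, r_abs: float) -> int:
    """Count unordered template pairs of length ``m`` within Chebyshev
    distance r_abs, self-matches excluded."""
    emb = np.ascontiguousarray(sliding_window_view(x, m)[:n_templates])
    tree = cKDTree(emb)
    pairs = tree.count_neighbors(tree, r_abs, p=np.inf)
    return int(pairs - n_templates) // 2


def sample_entropy(series: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy: -ln(A/B), with B the number of length-m template
    pairs matching within ``r_abs`` (Chebyshev, self-matches excluded) and
    A the same at length m+1.  Both counts use the first n-m templates.

    Returns NaN with a warning when no pair matches at either length.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= m + 1:
        raise ValueError("series too short for the requested embedding dimension")
    if r_abs is None or not r_abs > 0:
        raise ValueError("r_abs must be a positive tolerance")
    n_templates = x.size - m
    b = _template_pairs(x, m, n_templates, r_abs)
    a = _template_pairs(x, m + 1, n_templates, r_abs)
    if a == 0 or b == 0:
        warnings.warn("no matching templates; SampEn undefined", stacklevel=2)
        return float("nan")
    return float(-np.log(a / b))


def poincare_sd(series: np.ndarray) -> tuple[float, float]:
    """Dispersion of the lag-1 Poincare scatter perpendicular (SD1) and
    parallel (SD2) to the identity line.

    SD1^2 = var(x_{i+1} - x_i)/2 and SD2^2 = 2 var(x) - SD1^2 (sample
    variances, n-1), so SD1^2 + SD2^2 = 2 var(x) by construction.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("Poincare descriptors require at least 3 samples")
    var_d = float(np.var(np.diff(x), ddof=1))
    var_x = float(np.var(x, ddof=1))
    sd1_sq = 0.5 * var_d
    sd2_sq = 2.0 * var_x - sd1_sq
    if sd2_sq < 0:
        warnings.warn("negative SD2 radicand clipped to 0", stacklevel=2)
        sd2_sq = 0.0
    return float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))


def higuchi_fd(series: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension from mean normalized curve lengths.

    L(k) is averaged over all offsets for k = 1..k_max and the dimension is
    the negative slope of ln L(k) against ln k.  The result is clipped to
    [1, 2] (with a warning) since a bounded series cannot leave that range;
    a constant series has dimension 1 by convention.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10 * k_max:
        raise ValueError(f"series of length {n} too short for k_max={k_max}")
    if np.ptp(x) == 0:
        return 1.0
    log_k, log_l = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m0 in range(k):
            sub = x[m0::k]
            n_i = sub.size - 1
            if n_i < 1:
                continue
            norm = (n - 1) / (n_i * k)
            lengths.append(np.abs(np.diff(sub)).sum() * norm / k)
        log_k.append(np.log(k))
        log_l.append(np.log(np.mean(lengths)))
    slope = np.polyfit(log_k, log_l, 1)[0]
    hfd = -float(slope)
    if not 1.0 <= hfd <= 2.0:
        # warn only on substantive excursions, not float round-off at the edges
        if hfd < 1.0 - 1e-6 or hfd > 2.0 + 1e-6:
            warnings.warn(f"HFD {hfd:.3f} outside [1, 2]; clipped", stacklevel=2)
        hfd = float(np.clip(hfd, 1.0, 2.0))
    return hfd


def symbolize(series: np.ndarray, config: SymbolicConfig | None = None) -> np.ndarray:
    """Uniformly quantize a series over mean +/- n_sigma*SD into n_levels
    bins; values outside the span are clipped to the edge bins.  A
    zero-variance series maps entirely to the middle bin."""
    cfg = config or SymbolicConfig()
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot symbolize an empty series")
    if not np.isfinite(x).all():
        raise ValueError("symbolize requires finite values")
    mu = x.mean()
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.full(x.size, (cfg.n_levels - 1) // 2, dtype=np.int64)
    edges = np.linspace(mu - cfg.n_sigma * sd, mu + cfg.n_sigma * sd, cfg.n_levels + 1)
    return np.digitize(x, edges[1:-1]).astype(np.int64)


def variability_index(
    symbols: np.ndarray,
    word_length: int = 3,
    n_levels: int | None = None,
) -> float:
    """Normalized Shannon entropy of the overlapping-word distribution.

    VI = H / ln(W), where H is the entropy of the empirical distribution of
    words of ``word_length`` consecutive symbols and W is the number of
    observable distinct words, min(n_levels^word_length, word count).  VI
    is 0 for a single repeated word and 1 when all observable words occur
    equally often; it is invariant under any relabeling of the alphabet.
    """
    s = np.asarray(symbols, dtype=np.int64)
    if s.size < word_length:
        raise ValueError("fewer symbols than word_length")
    if n_levels is None:
        n_levels = int(s.max()) + 1 if s.size else 2
    words = sliding_window_view(s, word_length)
    base = np.power(n_levels, np.arange(word_length), dtype=np.int64)
    codes = words @ base
    _, counts = np.unique(codes, return_counts=True)
    probs = counts / counts.sum()
    h = float(-(probs * np.log(probs)).sum())
    w_max = min(n_levels**word_length, codes.size)
    if w_max <= 1:
        return 0.0
    return h / float(np.log(w_max))


def compute_nonlinear_features(
    sig: FHRVSignal,
    params: NonlinearParams | None = None,
    sym_config: SymbolicConfig | None = None,
) -> dict[str, float]:
    """All six nonlinear indices of one record.

    SampEn, SD1/SD2, HFD and VIFHR are computed on the FHRV residual
    (SampEn tolerance r_abs = r x SD of the FHRV); VIRR is computed on the
    increment series of RR intervals derived from the clean FHR.
    """
    p = params or NonlinearParams()
    cfg = sym_config or SymbolicConfig()
    x = np.asarray(sig.fhrv, dtype=float)
    fhr = np.asarray(sig.fhr_clean, dtype=float)
    if np.any(fhr <= 0):
        raise ValueError("fhr_clean must be strictly positive to derive RR intervals")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        sampen, sd1, sd2, hfd = 0.0, 0.0, 0.0, 1.0
        vifhr = 0.0
    else:
        sampen = sample_entropy(x, m=p.m, r_abs=p.r * sd)
        sd1, sd2 = poincare_sd(x)
        hfd = higuchi_fd(x, k_max=p.k_max)
        vifhr = variability_index(symbolize(x, cfg), cfg.word_length, cfg.n_levels)
    rr = 60000.0 / fhr
    drr = np.diff(rr)
    virr = variability_index(symbolize(drr, cfg), cfg.word_length, cfg.n_levels)
    return {
        "SampEn": sampen,
        "SD1": sd1,
        "SD2": sd2,
        "HFD": hfd,
        "VIRR": virr,
        "VIFHR": vifhr,
    }
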