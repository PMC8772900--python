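"""Independent brute-force oracles used to cross-check the fast
implementations.  Each oracle follows the defining formula directly with
explicit loops and no shared code with the package."""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by O(n^2) template comparison (Chebyshev <= r,
    self-matches excluded, n - m templates at both lengths)."""
    x = list(map(float, x))
    n = len(x)
    n_templates = n - m

    def count(length: int) -> int:
        total = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if d <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def higuchi_bruteforce(x, k_max: int) -> float:
    """Higuchi fractal dimension from the defining curve-length sums, with
    the log-log slope computed by closed-form least squares."""
    x = list(map(float, x))
    n = len(x)
    pts = []
    for k in range(1, k_max + 1):
        lengths = []
        for m0 in range(k):
            n_i = (n - 1 - m0) // k
            if n_i < 1:
                continue
            s = 0.0
            for i in range(1, n_i + 1):
                s += abs(x[m0 + i * k] - x[m0 + (i - 1) * k])
            lengths.append(s * (n - 1) / (n_i * k) / k)
        pts.append((math.log(k), math.log(sum(lengths) / len(lengths))))
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    slope = sum((a - mx) * (b - my) for a, b in pts) / sum((a - mx) ** 2 for a in xs)
    return -slope


def poincare_rotated(x) -> tuple[float, float]:
    """SD1/SD2 via explicit 45-degree rotation of the lag-1 scatter."""
    x = np.asarray(x, dtype=float)
    u = (x[1:] - x[:-1]) / math.sqrt(2)   # perpendicular coordinate
    v = (x[1:] + x[:-1]) / math.sqrt(2)   # parallel coordinate
    return float(np.std(u, ddof=1)), float(np.std(v, ddof=1))


def vi_enumeration(symbols, word_length: int, n_levels: int) -> float:
    """Normalized word entropy by dictionary counting."""
    words = [tuple(symbols[i : i + word_length]) for i in range(len(symbols) - word_length + 1)]
    counts: dict[tuple, int] = {}
    for w in words:
        counts[w] = counts.get(w, 0) + 1
    total = len(words)
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    w_max = min(n_levels**word_length, total)
    if w_max <= 1:
        return 0.0
    return h / math.log(w_max)


def pca_svd_route(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/eigenvectors of the correlation matrix through the SVD
    of the z-scored data matrix (descending)."""
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / (x.shape[0] - 1)
    return eigvals, vt.T


def importance_double_loop(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Connection-weight contributions |sum_j a_ij b_j| by explicit loops."""
    n_in, n_hidden = a.shape
    out = np.zeros(n_in)
    for i in range(n_in):
        s = 0.0
        for j in range(n_hidden):
            s += a[i, j] * b[j]
        out[i] = abs(s)
    return out


def peak_count(clean: np.ndarray, baseline: np.ndarray, fs: float,
               threshold: float = 15.0, min_s: float = 15.0, merge_s: float = 5.0) -> int:
    """Acceleration counting by explicit scan over the residual."""
    resid = [c - b for c, b in zip(clean, baseline)]
    runs = []
    start = None
    for i, v in enumerate(resid):
        if v >= threshold and start is None:
            start = i
        elif v < threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(resid)))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_s * fs:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return sum(1 for s, e in merged if e - s >= min_s * fs)
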