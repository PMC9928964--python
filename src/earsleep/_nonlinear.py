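"""Non-linear signal measures: entropies, fractal dimensions, DFA, LZ.

The quadratic-time kernels (sample entropy, Lempel–Ziv) are numba-jitted;
the rest are vectorized numpy.  All functions return finite values for
degenerate (e.g. constant) inputs — entropies and exponents of flat
signals are 0 by convention so downstream z-scoring never sees NaN.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                dd = abs(x[i + k] - x[j + k])
                if dd > d:
                    d = dd
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """SampEn(m, r) with r = r_factor * std(x); 0 for constant input."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    sd = x.std()
    if sd == 0 or len(x) < m + 2:
        return 0.0
    a, b = _sampen_counts(x, m, r_factor * sd)
    if a == 0 or b == 0:
        return 0.0
    return float(-math.log(a / b))


@njit(cache=False)
def _lempel_ziv(bits: np.ndarray) -> int:
    """LZ76 complexity (number of phrases) of a binary sequence."""
    n = bits.shape[0]
    if n == 0:
        return 0
    complexity = 1
    prefix_len = 1
    len_substr = 1
    max_len = 0
    pointer = 0
    while prefix_len + len_substr <= n:
        if bits[pointer + len_substr - 1] == bits[prefix_len + len_substr - 1]:
            len_substr += 1
        else:
            if len_substr > max_len:
                max_len = len_substr
            pointer += 1
            if pointer == prefix_len:
                complexity += 1
                prefix_len += max_len if max_len > 0 else 1
                pointer = 0
                max_len = 0
                len_substr = 1
            else:
                len_substr = 1
    if len_substr > 1:
        complexity += 1
    return complexity


def lempel_ziv_complexity(x: np.ndarray, normalize: bool = True) -> float:
    """LZ76 complexity of the signal binarized around its median."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or x.std() == 0:
        return 0.0
    bits = np.ascontiguousarray((x > np.median(x)).astype(np.uint8))
    c = _lempel_ziv(bits)
    if not normalize:
        return float(c)
    return float(c * math.log2(n) / n)


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy in [0, 1]; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    n = len(x) - (order - 1) * delay
    if n <= 0 or x.std() == 0:
        return 0.0
    emb = np.lib.stride_tricks.sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]
    patterns = np.argsort(np.argsort(emb, axis=1, kind="stable"), axis=1)
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log2(p)).sum()
    return float(h / math.log2(math.factorial(order)))


def svd_entropy(x: np.ndarray, order: int = 10, delay: int = 1) -> float:
    """Entropy of normalized singular values of the delay embedding."""
    x = np.asarray(x, dtype=float)
    n = len(x) - (order - 1) * delay
    if n <= order or x.std() == 0:
        return 0.0
    emb = np.lib.stride_tricks.sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]
    s = np.linalg.svd(emb, compute_uv=False)
    s = s / s.sum()
    s = s[s > 0]
    return float(-(s * np.log2(s)).sum() / math.log2(order))


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < kmax + 2 or x.std() == 0:
        return 0.0
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            seg = x[m::k]
            if len(seg) < 2:
                continue
            ln = np.abs(np.diff(seg)).sum() * (n - 1) / (len(seg) - 1) / k
            lengths.append(ln)
        lk[k - 1] = np.mean(lengths) if lengths else 0.0
    valid = lk > 0
    if valid.sum() < 2:
        return 0.0
    ks = np.arange(1, kmax + 1)[valid]
    slope = np.polyfit(np.log(1.0 / ks), np.log(lk[valid]), 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2 or x.std() == 0:
        return 0.0
    dists = np.abs(np.diff(x))
    L = dists.sum()
    if L == 0:
        return 0.0
    a = L / len(dists)
    d = np.max(np.abs(x - x[0]))
    if d == 0:
        return 0.0
    return float(math.log10(L / a) / (math.log10(d / a) + math.log10(L / a)))


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the derivative."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3 or x.std() == 0:
        return 0.0
    diff = np.diff(x)
    nsc = int(np.sum(diff[1:] * diff[:-1] < 0))
    if nsc == 0:
        return 0.0
    return float(math.log10(n) / (math.log10(n) + math.log10(n / (n + 0.4 * nsc))))


def dfa_exponent(x: np.ndarray, min_box: int = 16, n_scales: int = 10) -> float:
    """Detrended fluctuation analysis scaling exponent (order-1 detrend)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 * min_box or x.std() == 0:
        return 0.0
    y = np.cumsum(x - x.mean())
    max_box = n // 4
    boxes = np.unique(
        np.floor(np.logspace(math.log10(min_box), math.log10(max_box), n_scales)).astype(int)
    )
    flucts = []
    for b in boxes:
        n_seg = n // b
        seg = y[: n_seg * b].reshape(n_seg, b)
        t = np.arange(b)
        tm = t - t.mean()
        denom = (tm**2).sum()
        slope = (seg * tm).sum(axis=1) / denom
        inter = seg.mean(axis=1)
        detrended = seg - (inter[:, None] + slope[:, None] * tm)
        flucts.append(np.sqrt((detrended**2).mean()))
    flucts = np.asarray(flucts)
    good = flucts > 0
    if good.sum() < 2:
        return 0.0
    return float(np.polyfit(np.log(boxes[good]), np.log(flucts[good]), 1)[0])
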