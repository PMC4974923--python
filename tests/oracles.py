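"""Independent brute-force oracles the implementation is checked against.

Each oracle evaluates its defining formula directly (naive loops, O(n^2)
DFT, explicit center-scale-project) and shares no code with the package.
"""
import math

import numpy as np


def naive_moving_average(series, w):
    """Direct re-summation: out[i] = mean(series[i:i+w])."""
    series = list(series)
    return np.array(
        [sum(series[i : i + w]) / w for i in range(len(series) - w + 1)]
    )


def moment(series, r):
    mean = sum(series) / len(series)
    return sum((v - mean) ** r for v in series) / len(series)


def naive_skewness(series):
    return moment(series, 3) / moment(series, 2) ** 1.5


def naive_kurtosis(series):
    return moment(series, 4) / moment(series, 2) ** 2


def naive_std(series):
    return math.sqrt(moment(series, 2))


def naive_correlation(a, b):
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / len(a)
    return cov / (naive_std(a) * naive_std(b))


def naive_dft(series):
    """O(n^2) direct-summation DFT: X_k = sum_j x_j exp(-i 2 pi k j / n)."""
    n = len(series)
    out = np.empty(n, dtype=complex)
    for k in range(n):
        out[k] = sum(
            series[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n)
        )
    return out


def naive_psd_summary(series, fs):
    """Periodogram mean/std over one-sided bins, built on the naive DFT."""
    n = len(series)
    spectrum = naive_dft(series)
    psd = np.abs(spectrum[: n // 2 + 1]) ** 2 / (n * fs)
    return psd.mean(), naive_std(psd)


def naive_projection(X, means, sigmas, components):
    """Explicit center, scale, dot — row by row."""
    out = np.zeros((len(X), len(components)))
    for i, row in enumerate(np.asarray(X, dtype=float)):
        z = np.array(
            [
                0.0 if s == 0 else (v - m) / s
                for v, m, s in zip(row, means, sigmas)
            ]
        )
        for k, comp in enumerate(components):
            out[i, k] = float(np.dot(z, comp))
    return out
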