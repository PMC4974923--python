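"""The 114-dimensional per-segment feature vector.

Each 128-sample segment is described by 38 features per axis:

* temporal — skewness, kurtosis (non-excess), standard deviation (all with
  population 1/n moments, no bias correction), and one pairwise axis
  correlation per axis slot (x-slot ← corr(x,y), y-slot ← corr(y,z),
  z-slot ← corr(x,z));
* frequency — mean and standard deviation of the power spectral density,
  estimated by the raw one-sided periodogram |X_k|² / (n·fs) over bins
  k = 0 .. n/2 (no Welch averaging, no detrend, no taper);
* temporal-frequency — the moduli of the first 32 unnormalised DFT
  coefficients |X_k|, k = 0 .. 31 (DC included, phase discarded).

Feature order is part of the serialisation contract: all x-axis features,
then y, then z; within an axis: skewness, kurtosis, std, correlation,
psd_mean, psd_std, fft_00 .. fft_31.

Zero-variance channels make skewness, kurtosis and correlation 0/0; the
low-level functions raise :class:`DegenerateFeatureError` and
:func:`extract_features` maps the value to 0 with a logged warning so
constant-axis edge cases still flow through the pipeline.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFeatureError, IntegrityError, LengthError
from .io_model import Segment

logger = logging.getLogger(__name__)

AXES = ("x", "y", "z")
N_FFT_COEFFICIENTS = 32
_PER_AXIS = ["skewness", "kurtosis", "std", "correlation", "psd_mean", "psd_std"] + [
    f"fft_{k:02d}" for k in range(N_FFT_COEFFICIENTS)
]

#: The canonical 114 feature names, in serialisation order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{axis}_{name}" for axis in AXES for name in _PER_AXIS
)
N_FEATURES = len(FEATURE_NAMES)  # 38 * 3 = 114
N_FEATURES_PER_AXIS = len(_PER_AXIS)  # 38

#: Which axis pair fills each axis's single correlation slot.
CORRELATION_PAIRS = {"x": ("x", "y"), "y": ("y", "z"), "z": ("x", "z")}


def _moments(a: np.ndarray) -> tuple[float, float, float, float]:
    a = np.asarray(a, dtype=float)
    mean = a.mean()
    d = a - mean
    m2 = float(np.mean(d**2))
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mean, m2, m3, m4


def skewness(axis_data: np.ndarray) -> float:
    """Population skewness m3 / m2^(3/2); raises on zero variance."""
    if len(axis_data) < 2:
        raise LengthError("skewness needs at least 2 values")
    _, m2, m3, _ = _moments(axis_data)
    if m2 == 0.0:
        raise DegenerateFeatureError("zero variance: skewness undefined")
    return m3 / m2**1.5


def kurtosis(axis_data: np.ndarray) -> float:
    """Population kurtosis m4 / m2² — non-excess (no −3 term)."""
    if len(axis_data) < 2:
        raise LengthError("kurtosis needs at least 2 values")
    _, m2, _, m4 = _moments(axis_data)
    if m2 == 0.0:
        raise DegenerateFeatureError("zero variance: kurtosis undefined")
    return m4 / m2**2


def standard_deviation(axis_data: np.ndarray) -> float:
    """Population standard deviation (divisor n)."""
    return float(np.std(np.asarray(axis_data, dtype=float)))


def axis_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with population covariance; in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise LengthError(f"axis length mismatch: {a.shape} vs {b.shape}")
    sa = np.std(a)
    sb = np.std(b)
    if sa == 0.0 or sb == 0.0:
        raise DegenerateFeatureError("zero variance: correlation undefined")
    cov = float(np.mean((a - a.mean()) * (b - b.mean())))
    return float(np.clip(cov / (sa * sb), -1.0, 1.0))


def fft_amplitudes(
    axis_data: np.ndarray,
    n_coefficients: int = N_FFT_COEFFICIENTS,
    expected_length: int = 128,
) -> np.ndarray:
    """Moduli of the first ``n_coefficients`` unnormalised DFT coefficients.

    X_k = sum_j x_j exp(-i 2π k j / n); the DC term is included and no
    1/n factor is applied.  ``expected_length`` pins the segment width
    (128 for the standard windows); pass the actual length for other
    window sizes.
    """
    axis_data = np.asarray(axis_data, dtype=float)
    if len(axis_data) != expected_length:
        raise LengthError(
            f"expected {expected_length} samples, got {len(axis_data)}"
        )
    if n_coefficients > len(axis_data) // 2 + 1:
        raise LengthError(
            f"{n_coefficients} coefficients exceed the one-sided spectrum "
            f"of a {len(axis_data)}-sample window"
        )
    return np.abs(np.fft.rfft(axis_data)[:n_coefficients])


def psd_summary(
    axis_data: np.ndarray, sampling_rate: float, expected_length: int = 128
) -> tuple[float, float]:
    """Mean and population std of the periodogram PSD over one-sided bins.

    P[k] = |X_k|² / (n·fs) for k = 0 .. n/2 (65 bins for n = 128).
    """
    axis_data = np.asarray(axis_data, dtype=float)
    if len(axis_data) != expected_length:
        raise LengthError(
            f"expected {expected_length} samples, got {len(axis_data)}"
        )
    n = len(axis_data)
    psd = np.abs(np.fft.rfft(axis_data)) ** 2 / (n * sampling_rate)
    return float(psd.mean()), float(np.std(psd))


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 114-entry descriptor of one segment."""

    values: np.ndarray
    names: tuple[str, ...]
    label: str
    subject_id: str
    site: str
    window_index: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names),):
            raise IntegrityError(
                f"values shape {values.shape} does not match {len(self.names)} names"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def _degenerate_to_zero(fn, *args, feature: str, provenance: tuple) -> float:
    try:
        return fn(*args)
    except DegenerateFeatureError:
        logger.warning("degenerate feature %s on segment %s mapped to 0", feature, provenance)
        return 0.0


def extract_features(seg: Segment, sampling_rate: float | None = None) -> FeatureVector:
    """Compute the full 114-entry feature vector of one segment."""
    if sampling_rate is None:
        sampling_rate = seg.source.sampling_rate
    n = len(seg)
    prov = (seg.source.subject_id, seg.source.site, seg.window_index)
    axes = {name: seg.axis(name) for name in AXES}
    values: list[float] = []
    for axis in AXES:
        data = axes[axis]
        p1, p2 = CORRELATION_PAIRS[axis]
        values.append(
            _degenerate_to_zero(skewness, data, feature=f"{axis}_skewness", provenance=prov)
        )
        values.append(
            _degenerate_to_zero(kurtosis, data, feature=f"{axis}_kurtosis", provenance=prov)
        )
        values.append(standard_deviation(data))
        values.append(
            _degenerate_to_zero(
                axis_correlation,
                axes[p1],
                axes[p2],
                feature=f"{axis}_correlation",
                provenance=prov,
            )
        )
        psd_mean, psd_std = psd_summary(data, sampling_rate, expected_length=n)
        values.extend([psd_mean, psd_std])
        values.extend(fft_amplitudes(data, expected_length=n))
    arr = np.asarray(values)
    if not np.all(np.isfinite(arr)):
        bad = FEATURE_NAMES[int(np.flatnonzero(~np.isfinite(arr))[0])]
        raise IntegrityError(f"non-finite feature {bad} on segment {prov}")
    return FeatureVector(
        values=arr,
        names=FEATURE_NAMES,
        label=seg.source.emotion,
        subject_id=seg.source.subject_id,
        site=seg.source.site,
        window_index=seg.window_index,
    )
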