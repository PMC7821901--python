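"""Calcium-trace processing: ΔF/F, Gaussian smoothing, first-order deconvolution.

A slow indicator such as GCaMP6s low-pass filters the underlying firing
rate with an ~0.5 s exponential decay.  The first-order deconvolution

    S_d(t) = tau * dS/dt + S(t),        tau = 0.5 s

cancels that decay and yields a firing-rate estimate still blurred by the
50–100 ms rise time.  Smoothing uses a unit-area Gaussian whose half-width
at half-maximum is 150 ms (sigma = 0.150 / sqrt(2 ln 2) ≈ 0.127 s),
truncated at ±4 sigma and renormalized over the valid support at the edges.

All three operations are linear; each is exposed both as a plain function
on 1-D arrays and as a scikit-learn transformer acting column-wise on a
(frames × cells) matrix so they compose in sklearn pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import InputError

#: sigma of a Gaussian with half-width at half-maximum of 1.
HWHM_TO_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))

VARIANTS = ("raw", "smoothed", "deconvolved")


@dataclass
class CalciumTrace:
    """A single cell's trace at fixed rate, tagged with its processing variant."""

    cell_id: str
    time: np.ndarray
    values: np.ndarray
    rate_hz: float = 20.0
    variant: str = "raw"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise InputError("time and values must have equal length")
        if self.variant not in VARIANTS:
            raise InputError(f"unknown variant '{self.variant}'")
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"trace '{self.cell_id}' contains non-finite values")

    def with_values(self, values: np.ndarray, variant: str) -> "CalciumTrace":
        return CalciumTrace(self.cell_id, self.time, values, self.rate_hz, variant)


def dff_normalize(values) -> np.ndarray:
    """ΔF/F: divide by the time-averaged mean and subtract 1.

    The output has zero mean by construction.  Raises on non-positive mean
    fluorescence (ΔF/F is undefined there).
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise InputError(f"ΔF/F undefined: trace mean {mean} is not positive")
    return values / mean - 1.0


def gaussian_kernel(rate_hz: float, half_width_s: float = 0.15, truncate_sigmas: float = 4.0):
    """Sampled unit-area Gaussian kernel; returns (kernel, radius_in_frames)."""
    sigma_f = half_width_s * HWHM_TO_SIGMA * rate_hz
    radius = max(1, int(math.ceil(truncate_sigmas * sigma_f)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma_f) ** 2)
    return k / k.sum(), radius


def gaussian_smooth(
    values,
    rate_hz: float,
    half_width_s: float = 0.15,
    truncate_sigmas: float = 4.0,
) -> np.ndarray:
    """Convolve with a truncated, unit-area Gaussian (150 ms half-width).

    Near the edges the kernel is renormalized over the in-bounds support, so
    a constant trace stays exactly constant everywhere.
    """
    values = np.asarray(values, dtype=float)
    kernel, radius = gaussian_kernel(rate_hz, half_width_s, truncate_sigmas)
    if values.size < 1:
        raise InputError("cannot smooth an empty trace")
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def deconvolve(values, rate_hz: float, tau_s: float = 0.5) -> np.ndarray:
    """First-order deconvolution S_d = tau * dS/dt + S.

    The derivative uses central differences on interior frames and one-sided
    differences at the edges (``numpy.gradient``), which keeps the estimate
    lag-symmetric.
    """
    if tau_s <= 0:
        raise InputError(f"tau must be positive, got {tau_s}")
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InputError("deconvolution requires at least 2 frames")
    dsdt = np.gradient(values, 1.0 / rate_hz)
    return tau_s * dsdt + values


class _ColumnwiseTransformer(TransformerMixin, BaseEstimator):
    """Stateless frame×cell transformer applying a 1-D op to each column."""

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, ensure_2d=True)
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} cells, got {X.shape[1]}"
            )
        return np.column_stack([self._apply(X[:, j]) for j in range(X.shape[1])])

    def _apply(self, col):  # pragma: no cover - overridden
        raise NotImplementedError


class DeltaFOverF(_ColumnwiseTransformer):
    """Per-cell ΔF/F normalization (divide by temporal mean, subtract 1)."""

    def _apply(self, col):
        return dff_normalize(col)


class GaussianSmoother(_ColumnwiseTransformer):
    """Per-cell Gaussian smoothing with a configurable half-width."""

    def __init__(self, rate_hz: float = 20.0, half_width_s: float = 0.15,
                 truncate_sigmas: float = 4.0):
        self.rate_hz = rate_hz
        self.half_width_s = half_width_s
        self.truncate_sigmas = truncate_sigmas

    def _apply(self, col):
        return gaussian_smooth(col, self.rate_hz, self.half_width_s, self.truncate_sigmas)


class FirstOrderDeconvolver(_ColumnwiseTransformer):
    """Per-cell first-order deconvolution with indicator decay ``tau_s``."""

    def __init__(self, rate_hz: float = 20.0, tau_s: float = 0.5):
        self.rate_hz = rate_hz
        self.tau_s = tau_s

    def _apply(self, col):
        return deconvolve(col, self.rate_hz, self.tau_s)
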