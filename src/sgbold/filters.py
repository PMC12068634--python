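"""Savitzky-Golay smoothing and SPM-style reference filters for BOLD time series.

A Savitzky-Golay (SG) filter replaces each sample of a series by the value, at
the window centre, of the least-squares polynomial

    y(l) = a0 + a1*l + ... + an*l**n

fitted to the ``m`` samples of a sliding window (``m`` odd, polynomial degree
``n < m``).  Because the fitted value at the centre is a fixed linear
combination of the window samples, the filter is a convolution; the weights
are computed once per (window, degree) pair.  Weights are obtained by solving
the least-squares problem in a Legendre basis on [-1, 1], which stays well
conditioned even for the aggressive detrending configurations used on BOLD
data (e.g. window 311, degree 40 over a 487-TR run).

Boundaries are handled by endpoint-inclusive mirror extension: the first
(m-1)/2 points are prepended in reverse order and the last (m-1)/2 points
appended in reverse order before filtering.

Three reference filters from the classical SPM tradition are provided for
comparison: a discrete-cosine high-pass (detrending) basis, a Gaussian
low-pass kernel, and a canonical double-gamma HRF low-pass kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy import stats

__all__ = [
    "TimeSeries",
    "FilterSpec",
    "BaselineFilterSpec",
    "DEFAULT_HRF_PARAMS",
    "extend_reflect",
    "sg_weights",
    "sg_smooth",
    "dct_detrend_basis",
    "gaussian_lowpass",
    "hrf_kernel",
    "hrf_lowpass",
    "apply_filter",
]

#: Canonical double-gamma HRF parameters (seconds):
#: response peak, undershoot peak, response/undershoot dispersions,
#: response:undershoot amplitude ratio, onset, kernel length.
DEFAULT_HRF_PARAMS: tuple[float, ...] = (6.0, 16.0, 1.0, 1.0, 6.0, 0.0, 32.0)


def _as_values(series) -> np.ndarray:
    """Accept a TimeSeries or any array-like; return a finite 1-D float array."""
    if isinstance(series, TimeSeries):
        return series.values
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


@dataclass(frozen=True)
class TimeSeries:
    """One node's BOLD samples over TRs.

    Parameters
    ----------
    values : sequence of float
        Samples in acquisition order (arbitrary BOLD units or z-units).
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    """

    values: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 3:
            raise ValueError("a time series needs at least 3 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FilterSpec:
    """Savitzky-Golay parameters: odd window length ``m`` and degree ``n``."""

    window: int
    degree: int

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 3, got {self.window}")
        if not 1 <= self.degree <= self.window - 1:
            raise ValueError(
                f"degree must satisfy 1 <= degree <= window-1, got "
                f"degree={self.degree}, window={self.window}"
            )

    @property
    def label(self) -> str:
        return f"SG({self.window}/{self.degree})"


@dataclass(frozen=True)
class BaselineFilterSpec:
    """One of the three SPM-style reference filters.

    kind
        ``dct_detrend``: discrete-cosine high-pass basis with period cutoff
        ``cutoff_seconds`` (SPM default 128 s).
        ``gaussian_lowpass``: Gaussian smoothing kernel of width
        ``width_seconds``; ``width_kind`` selects whether the width is the
        kernel standard deviation (``"sigma"``, default) or the FWHM.
        ``hrf_lowpass``: causal convolution with the canonical double-gamma
        hemodynamic response function.
    """

    kind: str
    cutoff_seconds: float | None = None
    width_seconds: float | None = None
    hrf_params: tuple[float, ...] | None = None
    width_kind: str = "sigma"

    def __post_init__(self):
        kinds = {"dct_detrend", "gaussian_lowpass", "hrf_lowpass"}
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {sorted(kinds)}, got {self.kind!r}")
        if self.kind == "dct_detrend":
            if self.cutoff_seconds is None or self.cutoff_seconds <= 0:
                raise ValueError("dct_detrend requires a positive cutoff_seconds")
            if self.width_seconds is not None or self.hrf_params is not None:
                raise ValueError("dct_detrend takes only cutoff_seconds")
        elif self.kind == "gaussian_lowpass":
            if self.width_seconds is None or self.width_seconds <= 0:
                raise ValueError("gaussian_lowpass requires a positive width_seconds")
            if self.cutoff_seconds is not None or self.hrf_params is not None:
                raise ValueError("gaussian_lowpass takes only width_seconds")
            if self.width_kind not in ("sigma", "fwhm"):
                raise ValueError("width_kind must be 'sigma' or 'fwhm'")
        else:  # hrf_lowpass
            if self.cutoff_seconds is not None or self.width_seconds is not None:
                raise ValueError("hrf_lowpass takes only hrf_params")
            if self.hrf_params is None:
                object.__setattr__(self, "hrf_params", DEFAULT_HRF_PARAMS)

    @property
    def label(self) -> str:
        if self.kind == "dct_detrend":
            return f"DCT({self.cutoff_seconds:g}s)"
        if self.kind == "gaussian_lowpass":
            return f"Gauss({self.width_seconds:g}s)"
        return "HRF"


def extend_reflect(series, window: int) -> np.ndarray:
    """Mirror-extend a series by (window-1)/2 points on each side.

    The first (m-1)/2 points are prepended in reverse order and the last
    (m-1)/2 points appended in reverse order (endpoint-inclusive mirror), so
    the output has length ``len(series) + window - 1``.
    """
    x = _as_values(series)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window < 1:
        raise ValueError(f"window must be positive, got {window}")
    half = (window - 1) // 2
    if window > 2 * x.size - 1:
        raise ValueError(
            f"window {window} too large for series of length {x.size} "
            f"(requires window <= 2*length-1)"
        )
    if half == 0:
        return x.copy()
    return np.concatenate([x[:half][::-1], x, x[-half:][::-1]])


def sg_weights(window: int, degree: int) -> np.ndarray:
    """Convolution weights of the SG smoother for one (window, degree) pair.

    The fitted value at the window centre equals ``weights @ window_samples``.
    Solved in a Legendre basis on [-1, 1] for numerical stability.
    """
    spec = FilterSpec(window, degree)  # validates
    x = np.linspace(-1.0, 1.0, spec.window)
    basis = legendre.legvander(x, spec.degree)  # (window, degree+1)
    centre_row = basis[(spec.window - 1) // 2]
    return centre_row @ np.linalg.pinv(basis)


def sg_smooth(series, spec: FilterSpec) -> np.ndarray:
    """Savitzky-Golay smooth a series; output length equals input length.

    Each output sample is the centre value of the degree-``spec.degree``
    least-squares polynomial fitted to the window centred there on the
    mirror-extended series.
    """
    x = _as_values(series)
    if x.size < spec.window:
        raise ValueError(
            f"series of length {x.size} is shorter than window {spec.window}"
        )
    padded = extend_reflect(x, spec.window)
    w = sg_weights(spec.window, spec.degree)
    # correlate keeps weight orientation: y[i] = sum_j w[j] * padded[i + j]
    return np.correlate(padded, w, mode="valid")


def dct_detrend_basis(n_trs: int, tr_seconds: float, cutoff_seconds: float) -> np.ndarray:
    """Discrete cosine detrending basis (constant excluded), periods >= cutoff.

    Returns an ``n_trs x k`` matrix with orthonormal columns,
    ``k = floor(2 * n_trs * tr_seconds / cutoff_seconds)``.
    """
    if cutoff_seconds <= 2 * tr_seconds:
        raise ValueError(
            f"cutoff_seconds must exceed 2*tr_seconds "
            f"({cutoff_seconds} <= {2 * tr_seconds})"
        )
    k = int(np.floor(2.0 * n_trs * tr_seconds / cutoff_seconds))
    if k == 0:
        warnings.warn(
            "DCT cutoff longer than twice the run duration; empty basis",
            stacklevel=2,
        )
        return np.empty((n_trs, 0))
    t = np.arange(n_trs)
    j = np.arange(1, k + 1)
    basis = np.sqrt(2.0 / n_trs) * np.cos(
        np.pi * np.outer(2 * t + 1, j) / (2.0 * n_trs)
    )
    return basis


def _symmetric_kernel_filter(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-phase filtering with a symmetric kernel and mirror boundaries."""
    window = kernel.size
    padded = extend_reflect(x, window)
    return np.correlate(padded, kernel, mode="valid")


def gaussian_lowpass(
    series,
    width_seconds: float,
    tr_seconds: float,
    width_kind: str = "sigma",
) -> np.ndarray:
    """Convolve with a unit-sum discrete Gaussian kernel (mirror boundaries).

    ``width_seconds`` is the kernel standard deviation by default
    (``width_kind="sigma"``); pass ``width_kind="fwhm"`` to interpret it as
    the full width at half maximum instead.
    """
    if width_seconds <= 0:
        raise ValueError("width_seconds must be positive")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    x = _as_values(series)
    if width_kind == "sigma":
        sigma_s = width_seconds
    elif width_kind == "fwhm":
        sigma_s = width_seconds / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    else:
        raise ValueError("width_kind must be 'sigma' or 'fwhm'")
    sigma_tr = sigma_s / tr_seconds
    radius = max(1, int(np.ceil(4.0 * sigma_tr)))
    # keep the mirror extension feasible for short series
    radius = min(radius, x.size - 1)
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma_tr) ** 2)
    kernel /= kernel.sum()
    return _symmetric_kernel_filter(x, kernel)


def hrf_kernel(tr_seconds: float, params: Sequence[float] = DEFAULT_HRF_PARAMS) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, normalized to unit sum.

    ``params = (p1..p7)``: response peak delay, undershoot delay, response and
    undershoot dispersions, response:undershoot ratio, onset, length (s).
    """
    p = tuple(float(v) for v in params)
    if len(p) != 7:
        raise ValueError("hrf params must have 7 entries")
    t = np.arange(0.0, p[6] + tr_seconds / 2.0, tr_seconds) - p[5]
    h = stats.gamma.pdf(t, p[0] / p[2], scale=p[2]) - stats.gamma.pdf(
        t, p[1] / p[3], scale=p[3]
    ) / p[4]
    total = h.sum()
    if total <= 0:
        raise ValueError("degenerate HRF parameters: kernel does not sum > 0")
    return h / total


def hrf_lowpass(series, tr_seconds: float, params: Sequence[float] = DEFAULT_HRF_PARAMS) -> np.ndarray:
    """Causal convolution with the unit-sum double-gamma HRF kernel.

    The run start is mirror-extended so early samples are filtered against a
    reflected warm-up rather than zeros; constants pass unchanged.
    """
    x = _as_values(series)
    kernel = hrf_kernel(tr_seconds, params)
    klen = kernel.size
    if klen > x.size:
        raise ValueError(
            f"HRF kernel ({klen} taps) longer than series ({x.size} samples)"
        )
    if klen == 1:
        return x * kernel[0]
    padded = np.concatenate([x[: klen - 1][::-1], x])
    return np.convolve(padded, kernel, mode="valid")


def apply_filter(series, spec, tr_seconds: float) -> np.ndarray:
    """Dispatch a low-pass filter spec (SG, Gaussian, or HRF) onto a series."""
    if isinstance(spec, FilterSpec):
        return sg_smooth(series, spec)
    if isinstance(spec, BaselineFilterSpec):
        if spec.kind == "gaussian_lowpass":
            return gaussian_lowpass(
                series, spec.width_seconds, tr_seconds, width_kind=spec.width_kind
            )
        if spec.kind == "hrf_lowpass":
            return hrf_lowpass(series, tr_seconds, spec.hrf_params)
        raise ValueError(
            "dct_detrend is a detrending basis, not a point-wise filter; "
            "use it through the GLM"
        )
    raise TypeError(f"unsupported filter spec: {spec!r}")
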