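"""FFT power spectra of time courses and residual-noise audits.

The residual noise time course is what a cleaning filter removed: the
denoised/detrended series minus its cleaned version.  If cleaning is doing its
job, the residual spectrum should be near zero in task-related frequency
bands (here 0.04-0.25 Hz) — any task power in the residual means the filter
discarded cognitive signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .filters import _as_values

__all__ = [
    "PowerSpectrum",
    "power_spectrum",
    "mean_spectrum",
    "residual_noise",
    "band_power",
]


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum: frequencies 0..Nyquist and per-bin power.

    Power is scaled so that ``sum(power) == n * variance`` of the mean-removed
    series (discrete Parseval identity).
    """

    frequencies_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("frequencies and power must align")
        if np.any(p < -1e-12):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "power", np.maximum(p, 0.0))

    @property
    def nyquist_hz(self) -> float:
        return float(self.frequencies_hz[-1])


def power_spectrum(series, tr_seconds: float) -> PowerSpectrum:
    """One-sided FFT power spectrum of the mean-removed series.

    No taper is applied (rectangular window).  Non-DC, non-Nyquist bins are
    doubled so the one-sided sum preserves total power.
    """
    x = _as_values(series)
    if x.size < 8:
        raise ValueError("need at least 8 samples for a spectrum")
    n = x.size
    x = x - x.mean()
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    return PowerSpectrum(freqs, power)


def mean_spectrum(spectra: Iterable[PowerSpectrum]) -> PowerSpectrum:
    """Grand mean of spectra sharing one frequency grid (power, not amplitude)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    f0 = spectra[0].frequencies_hz
    for s in spectra[1:]:
        if s.frequencies_hz.shape != f0.shape or not np.allclose(
            s.frequencies_hz, f0
        ):
            raise ValueError("spectra are on different frequency grids")
    return PowerSpectrum(f0, np.mean([s.power for s in spectra], axis=0))


def residual_noise(denoised_detrended, cleaned) -> np.ndarray:
    """What the cleaning filter removed: element-wise difference of the two."""
    a = _as_values(denoised_detrended)
    b = _as_values(cleaned)
    if a.shape != b.shape:
        raise ValueError(
            f"length mismatch: {a.size} (denoised/detrended) vs {b.size} (cleaned)"
        )
    return a - b


def band_power(spectrum: PowerSpectrum, f_lo: float, f_hi: float) -> float:
    """Sum of power over bins with f_lo <= f <= f_hi."""
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi > spectrum.nyquist_hz * (1 + 1e-9):
        raise ValueError(
            f"f_hi {f_hi} exceeds Nyquist {spectrum.nyquist_hz:.4f} Hz"
        )
    mask = (spectrum.frequencies_hz >= f_lo) & (spectrum.frequencies_hz <= f_hi)
    if not mask.any():
        warnings.warn("no spectral bins inside the requested band", stacklevel=2)
        return 0.0
    return float(spectrum.power[mask].sum())
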