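"""Per-subject preprocessing: discard initial volumes, linear detrend,
Gaussian spatial smoothing, and ideal band restriction.

The pipeline order is fixed: discard -> detrend -> smooth; the band
restriction to the low-frequency band is applied spectrally inside the
amplitude computation (see :mod:`alffkit.alff_map`), keeping filter and
spectrum exactly consistent. The band-edge rule is a closed interval:
a frequency bin at f is in-band iff low <= f <= high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_core import TimeSeriesVolume

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "discard_initial",
    "detrend_linear",
    "gaussian_smooth",
    "bandpass",
    "preprocess_volume",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    n_discard/n_keep follow the acquisition convention of dropping the first
    volumes before equilibrium (default 20 dropped, 240 kept). smooth_fwhm_mm
    is the Gaussian kernel full width at half maximum in millimetres (default
    6 mm, the common single-subject choice). The low-frequency band is
    0.02-0.07 Hz; it must sit below the Nyquist frequency 1/(2*TR).
    """

    n_discard: int = 20
    n_keep: int = 240
    smooth_fwhm_mm: float = 6.0
    band_low_hz: float = 0.02
    band_high_hz: float = 0.07

    def validate(self, tr_seconds: float, n_timepoints: int | None = None) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 <= self.band_low_hz < self.band_high_hz <= nyquist + 1e-12):
            raise ValueError(
                f"band [{self.band_low_hz}, {self.band_high_hz}] must satisfy "
                f"0 <= low < high <= Nyquist ({nyquist:g} Hz)"
            )
        if n_timepoints is not None and self.n_discard + self.n_keep > n_timepoints:
            raise ValueError(
                f"series of length {n_timepoints} too short for "
                f"discard {self.n_discard} + keep {self.n_keep}"
            )


def discard_initial(vol: TimeSeriesVolume, n_discard: int = 20, n_keep: int = 240) -> TimeSeriesVolume:
    """Drop the first ``n_discard`` frames and retain the next ``n_keep``."""
    if n_discard < 0 or n_keep < 1:
        raise ValueError("n_discard must be >= 0 and n_keep >= 1")
    n = vol.n_timepoints
    if n_discard + n_keep > n:
        raise ValueError(f"series of length {n} too short for discard {n_discard} + keep {n_keep}")
    return replace(vol, data=vol.data[..., n_discard : n_discard + n_keep])


def detrend_linear(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the least-squares line (slope and mean) along ``axis``.

    The mean is removed together with the slope so no DC component can leak
    into total-power normalization downstream. Idempotent.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    if n < 3:
        raise ValueError(f"need at least 3 time points to detrend, got {n}")
    x = np.moveaxis(x, axis, -1)
    t = np.arange(n, dtype=float)
    t = t - t.mean()
    # project out [1, t]: centred time axis makes the two regressors orthogonal
    mean = x.mean(axis=-1, keepdims=True)
    slope = (x @ t)[..., None] / (t @ t)
    out = x - mean - slope * t
    return np.moveaxis(out, -1, axis)


def gaussian_smooth(
    vol3d: np.ndarray, fwhm_mm: float, voxel_size_mm: np.ndarray | tuple[float, ...]
) -> np.ndarray:
    """Separable Gaussian smoothing of a 3D (or 4D: smoothed frame-wise)
    array, with sigma = FWHM/(2*sqrt(2 ln 2)) per axis in voxel units.

    Boundary handling is symmetric reflection, which leaves constant volumes
    exactly unchanged and conserves total intensity for inputs supported
    away from the edges. ``fwhm_mm = 0`` is the identity.
    """
    arr = np.asarray(vol3d, dtype=float)
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return arr.copy()
    voxel = np.asarray(voxel_size_mm, dtype=float)
    if voxel.shape != (3,) or (voxel <= 0).any():
        raise ValueError("voxel_size_mm must be 3 positive lengths")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel
    if arr.ndim == 3:
        return ndimage.gaussian_filter(arr, sigma=sigma_vox, mode="reflect")
    if arr.ndim == 4:
        return ndimage.gaussian_filter(arr, sigma=(*sigma_vox, 0.0), mode="reflect")
    raise ValueError(f"expected 3D or 4D input, got {arr.ndim}D")


def bandpass(series: np.ndarray, tr: float, low_hz: float, high_hz: float, axis: int = -1) -> np.ndarray:
    """Ideal spectral band restriction: DFT, zero every bin with frequency
    outside the closed interval [low, high], inverse DFT.

    DC is always removed (low must be > 0), making the constant component of
    the input vanish in the output.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 < low_hz < high_hz <= nyquist + 1e-12):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] must satisfy 0 < low < high <= Nyquist ({nyquist:g} Hz)"
        )
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low_hz - 1e-15) & (freqs <= high_hz + 1e-15)
    spec = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = len(freqs)
    spec = spec * keep.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)


def preprocess_volume(vol: TimeSeriesVolume, config: PreprocessConfig = PreprocessConfig()) -> TimeSeriesVolume:
    """Full per-subject chain: discard -> detrend (voxel-wise) -> smooth.

    The band restriction is intentionally not applied here; amplitude maps
    take it spectrally, and the fractional amplitude needs the full spectrum
    in its denominator.
    """
    config.validate(vol.tr_seconds, vol.n_timepoints)
    logger.info(
        "preprocess: discard %d keep %d, detrend, smooth fwhm=%.1f mm",
        config.n_discard, config.n_keep, config.smooth_fwhm_mm,
    )
    out = discard_initial(vol, config.n_discard, config.n_keep)
    data = detrend_linear(out.data, axis=-1)
    data = gaussian_smooth(data, config.smooth_fwhm_mm, out.voxel_size_mm)
    return replace(out, data=data)
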