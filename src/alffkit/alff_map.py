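"""Voxel-wise amplitude of low-frequency fluctuation (ALFF) and its
fractional variant (f-ALFF), plus map standardization.

ALFF is the mean one-sided spectral amplitude (square root of periodogram
power) over the low-frequency band, the field's standard convention even
where "energy" and "power" are used loosely; f-ALFF divides the in-band
amplitude sum by the amplitude sum over the full available band
(0-0.25 Hz at TR = 2 s), DC excluded, Nyquist included. Both are computed
from the unfiltered (detrended, smoothed) series: filtering before f-ALFF
would make its denominator equal its numerator. The frequency grid is the
unpadded DFT grid, so band bin counts are exact: for n = 240 points at
TR = 2 s the 0.02-0.07 Hz band is bins k = 10..33 under the closed-interval
rule, and the total band (0, 0.25] Hz is bins 1..120.

A ``use_power`` switch computes both quantities on squared amplitudes
instead, for comparison with power-convention pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import BrainMask, StatMap, TimeSeriesVolume

__all__ = [
    "Spectrum",
    "AlffConfig",
    "periodogram",
    "compute_alff",
    "compute_falff",
    "map_subject",
    "standardize_map",
]


@dataclass(frozen=True)
class AlffConfig:
    """Band definitions and conventions for the amplitude maps."""

    band: tuple[float, float] = (0.02, 0.07)
    total_band: tuple[float, float] = (0.0, 0.25)
    use_power: bool = False
    standardize: str | None = "divide_by_global_mean"


@dataclass
class Spectrum:
    """One-sided amplitude spectrum on the grid 0..Nyquist.

    ``amplitude[k]`` is (2/n)|X_k| for interior bins, so a pure sinusoid of
    amplitude a at an exact bin frequency shows amplitude a there; the DC and
    Nyquist bins are not doubled. ``power`` uses a^2/2 interior (a^2 at the
    unpaired DC/Nyquist bins) so the total over k >= 1 satisfies Parseval
    against the series variance.
    """

    frequencies_hz: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.frequencies_hz.shape != self.amplitude.shape:
            raise ValueError("frequency and amplitude grids differ in length")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def power(self) -> np.ndarray:
        p = 0.5 * self.amplitude**2
        p[0] = self.amplitude[0] ** 2
        # Nyquist bin is unpaired only for even series length; the grid always
        # ends at Nyquist when built by `periodogram` on even n
        p[-1] = self.amplitude[-1] ** 2
        return p


def periodogram(series: np.ndarray, tr: float) -> Spectrum:
    """One-sided amplitude spectrum of a (detrended) series.

    Requires an even length n >= 8 (the acquisition grids used here are
    even-length); rejects NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("periodogram expects a 1D series")
    n = x.size
    if n < 8:
        raise ValueError(f"series too short for a spectrum: {n} < 8")
    if n % 2 != 0:
        raise ValueError("even series length required (one-sided grid ends at Nyquist)")
    if np.any(np.isnan(x)):
        raise ValueError("NaN in series")
    spec = np.abs(np.fft.rfft(x))
    amp = (2.0 / n) * spec
    amp[0] = spec[0] / n
    amp[-1] = spec[-1] / n
    freqs = np.fft.rfftfreq(n, d=tr)
    return Spectrum(frequencies_hz=freqs, amplitude=amp)


def _band_bins(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    """Closed-interval band rule: low <= f <= high (float-tolerant)."""
    return (freqs >= low - 1e-12) & (freqs <= high + 1e-12)


def compute_alff(spec: Spectrum, band: tuple[float, float] = (0.02, 0.07), use_power: bool = False) -> float:
    """Mean amplitude (or power) over the in-band bins."""
    low, high = band
    sel = _band_bins(spec.frequencies_hz, low, high)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band [{low}, {high}]")
    values = spec.power if use_power else spec.amplitude
    return float(values[sel].mean())


def compute_falff(
    spec: Spectrum,
    band: tuple[float, float] = (0.02, 0.07),
    total_band: tuple[float, float] = (0.0, 0.25),
    use_power: bool = False,
) -> float:
    """In-band amplitude sum over total amplitude sum, in [0, 1].

    DC is excluded from the denominator even when total_band starts at 0
    (detrending zeroes it anyway); returns 0 for an all-zero spectrum.
    """
    low, high = band
    tlow, thigh = total_band
    if low < tlow - 1e-12 or high > thigh + 1e-12:
        raise ValueError(f"band [{low}, {high}] not contained in total band [{tlow}, {thigh}]")
    values = spec.power if use_power else spec.amplitude
    num_sel = _band_bins(spec.frequencies_hz, low, high)
    den_sel = _band_bins(spec.frequencies_hz, max(tlow, 1e-300), thigh)
    den_sel[0] = False  # DC never counts
    num = float(values[num_sel & den_sel].sum())
    den = float(values[den_sel].sum())
    if den == 0.0:
        return 0.0
    return num / den


def map_subject(
    vol: TimeSeriesVolume, mask: BrainMask, config: AlffConfig = AlffConfig()
) -> tuple[StatMap, StatMap]:
    """Per-voxel ALFF and f-ALFF maps inside the mask (NaN outside).

    The per-voxel computation is vectorized through a single real FFT over
    the masked voxel-by-time matrix.
    """
    mask.check_shape(vol.shape)
    n = vol.n_timepoints
    if n < 8 or n % 2 != 0:
        raise ValueError("need an even series length >= 8")
    series = vol.data[mask.data]  # (n_voxels, n_timepoints)
    spec = np.abs(np.fft.rfft(series, axis=-1))
    amp = (2.0 / n) * spec
    amp[:, 0] = spec[:, 0] / n
    amp[:, -1] = spec[:, -1] / n
    freqs = np.fft.rfftfreq(n, d=vol.tr_seconds)
    values = 0.5 * amp**2 if config.use_power else amp
    if config.use_power:
        values[:, 0] = amp[:, 0] ** 2
        values[:, -1] = amp[:, -1] ** 2

    low, high = config.band
    tlow, thigh = config.total_band
    if low < tlow - 1e-12 or high > thigh + 1e-12:
        raise ValueError("band not contained in total band")
    band_sel = _band_bins(freqs, low, high)
    if not band_sel.any():
        raise ValueError("no frequency bins inside band")
    total_sel = _band_bins(freqs, max(tlow, 1e-300), thigh)
    total_sel[0] = False

    alff_vals = values[:, band_sel].mean(axis=1)
    num = values[:, band_sel & total_sel].sum(axis=1)
    den = values[:, total_sel].sum(axis=1)
    falff_vals = np.divide(num, den, out=np.zeros_like(num), where=den > 0)

    alff = np.full(vol.shape[:3], np.nan)
    falff = np.full(vol.shape[:3], np.nan)
    alff[mask.data] = alff_vals
    falff[mask.data] = falff_vals
    return (
        StatMap(data=alff, kind="alff", affine=vol.affine, mask=mask),
        StatMap(data=falff, kind="falff", affine=vol.affine, mask=mask),
    )


def standardize_map(stat_map: StatMap, mask: BrainMask, mode: str = "divide_by_global_mean") -> StatMap:
    """Standardize a subject map for group comparison.

    ``divide_by_global_mean`` divides by the within-mask mean (the mALFF
    convention; output mean is exactly 1); ``zscore`` centres and scales to
    in-mask mean 0, SD 1.
    """
    mask.check_shape(stat_map.data.shape)
    inside = stat_map.data[mask.data]
    out = np.full_like(stat_map.data, np.nan)
    if mode == "divide_by_global_mean":
        g = inside.mean()
        if g == 0:
            raise ValueError("global mean is zero; cannot divide")
        out[mask.data] = inside / g
        kind = {"alff": "malff", "falff": "mfalff"}.get(stat_map.kind, stat_map.kind)
    elif mode == "zscore":
        sd = inside.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance; cannot z-score")
        out[mask.data] = (inside - inside.mean()) / sd
        kind = stat_map.kind if stat_map.kind in ("t", "p") else "malff" if stat_map.kind in ("alff", "malff") else "mfalff"
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    return StatMap(data=out, kind=kind, affine=stat_map.affine, mask=mask)
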