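"""Temporal preprocessing of aligned 4D BOLD volumes.

Implements the per-voxel temporal chain applied before activity-measure
extraction: least-squares linear detrending, an ideal (rectangular)
frequency-domain bandpass, and mask-renormalized Gaussian spatial smoothing.
Volumes are assumed to be already aligned to a common grid; spatial
registration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BoldVolume

__all__ = [
    "BrainMask",
    "BandSpec",
    "linear_detrend",
    "bandpass_filter",
    "gaussian_smooth",
    "fwhm_to_sigma_voxels",
]

#: Tolerance used when deciding whether a DFT bin lies inside the passband,
#: so that bin-edge ties are stable across platforms.
BIN_EDGE_EPS = 1e-12


@dataclass(frozen=True)
class BrainMask:
    """3D boolean mask selecting the voxels that enter the analysis."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not data.any():
            raise ValueError("mask must contain at least one voxel")
        object.__setattr__(self, "data", data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_grid(self, grid: tuple[int, int, int]) -> None:
        if self.data.shape != tuple(grid):
            raise ValueError(
                f"mask grid {self.data.shape} does not match volume grid {tuple(grid)}"
            )


@dataclass(frozen=True)
class BandSpec:
    """Passband in Hz; the default 0.01-0.1 Hz is the standard low-frequency
    fluctuation band of resting-state fMRI."""

    low_hz: float = 0.01
    high_hz: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")

    def validate_for(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if self.high_hz > nyquist + BIN_EDGE_EPS:
            raise ValueError(
                f"high_hz={self.high_hz} exceeds Nyquist {nyquist} for TR={tr_seconds}s"
            )


def band_bin_mask(freqs: np.ndarray, low_hz: float, high_hz: float) -> np.ndarray:
    """Boolean mask of DFT bins with low <= f <= high (edge-tolerant)."""
    return (freqs >= low_hz - BIN_EDGE_EPS) & (freqs <= high_hz + BIN_EDGE_EPS)


def linear_detrend(volume: BoldVolume, mask: BrainMask) -> BoldVolume:
    """Remove the per-voxel least-squares line (intercept + slope * t).

    Out-of-mask voxels are zeroed in the output.
    """
    mask.check_grid(volume.grid)
    T = volume.n_timepoints
    if T < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    t = np.arange(T, dtype=float)
    # Orthonormal design: demeaned time regressor + intercept.
    tc = t - t.mean()
    data = volume.data
    mean = data.mean(axis=3, keepdims=True)
    slope = (data * tc).sum(axis=3, keepdims=True) / (tc * tc).sum()
    out = data - mean - slope * tc
    out[~mask.data] = 0.0
    return volume.with_data(out)


def bandpass_filter(volume: BoldVolume, band: BandSpec, mask: BrainMask) -> BoldVolume:
    """Ideal rectangular frequency-domain bandpass, applied per in-mask voxel.

    DFT bins with frequency inside [low_hz, high_hz] are retained; all other
    bins, including DC, are zeroed before the inverse transform. Because the
    default low edge is positive, slow scanner drifts and the mean are
    removed along with out-of-band noise.
    """
    mask.check_grid(volume.grid)
    band.validate_for(volume.tr_seconds)
    T = volume.n_timepoints
    freqs = np.fft.rfftfreq(T, d=volume.tr_seconds)
    keep = band_bin_mask(freqs, band.low_hz, band.high_hz)
    spectrum = np.fft.rfft(volume.data, axis=3)
    spectrum[..., ~keep] = 0.0
    out = np.fft.irfft(spectrum, n=T, axis=3)
    out[~mask.data] = 0.0
    return volume.with_data(out)


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: tuple[float, float, float]) -> tuple[float, ...]:
    """Per-axis Gaussian standard deviation in voxel units.

    sigma = FWHM / (2 sqrt(2 ln 2)) / voxel_size.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    return tuple(fwhm_mm / factor / v for v in voxel_size_mm)


def gaussian_smooth(
    map3d: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
    mask: BrainMask,
) -> np.ndarray:
    """Separable Gaussian smoothing restricted to the mask.

    Uses mask-renormalized convolution: the map is smoothed with out-of-mask
    voxels treated as zero and then divided by the identically smoothed mask,
    so a constant map stays exactly constant and values near the mask border
    are not dimmed. Out-of-mask output voxels are zero.
    """
    map3d = np.asarray(map3d, dtype=float)
    if map3d.shape != mask.data.shape:
        raise ValueError("map and mask shapes differ")
    sigma = fwhm_to_sigma_voxels(fwhm_mm, voxel_size_mm)
    m = mask.data.astype(float)
    num = ndimage.gaussian_filter(map3d * m, sigma=sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="constant", cval=0.0)
    out = np.zeros_like(map3d)
    inside = mask.data
    out[inside] = num[inside] / den[inside]
    return out
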