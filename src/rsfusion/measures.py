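"""Voxel-wise resting-state activity measures: ALFF, fALFF, ReHo, VMHC.

ALFF is the mean one-sided spectral amplitude (2|X(f)|/T) over the
low-frequency band; fALFF is the fraction of total spectral amplitude
(0 < f <= Nyquist) that falls inside that band. ReHo is Kendall's
coefficient of concordance W among the time series of a voxel's 3x3x3
neighbourhood; VMHC is the Fisher z-transformed Pearson correlation between
each voxel and its left-right mirror. Maps can be z-scored over the mask
("standardized") for cross-subject comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

from .preprocess import BandSpec, BrainMask, band_bin_mask, gaussian_smooth
from .volume import BoldVolume

__all__ = [
    "ActivityMap",
    "compute_alff",
    "compute_falff",
    "compute_reho",
    "compute_vmhc",
    "standardize_map",
    "extract_subject_maps",
    "MEASURES",
    "REHO_NEIGHBORHOOD_SIZE",
]

MEASURES = ("alff", "falff", "reho", "vmhc")

#: Voxels in the cubic ReHo cluster (the voxel itself plus 26 neighbours).
REHO_NEIGHBORHOOD_SIZE = 27

#: Correlations are clipped to +/- (1 - VMHC_CLIP) before atanh so perfectly
#: (anti)correlated pairs stay finite.
VMHC_CLIP = 1e-7


@dataclass(frozen=True)
class ActivityMap:
    """One 3D voxel-wise measure map over a mask.

    ``flags`` marks voxels whose value was defined by convention rather than
    computed (isolated ReHo voxels, unpaired or zero-variance VMHC voxels).
    """

    data: np.ndarray
    measure: str
    mask: BrainMask
    standardized: bool = False
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.mask.data.shape:
            raise ValueError("map and mask shapes differ")
        if not np.all(np.isfinite(data[self.mask.data])):
            raise ValueError("non-finite values inside mask")
        object.__setattr__(self, "data", data)

    def in_mask_values(self) -> np.ndarray:
        return self.data[self.mask.data]


def _amplitude_spectrum(volume: BoldVolume) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum 2|X(f)|/T per voxel, with bin frequencies."""
    T = volume.n_timepoints
    freqs = np.fft.rfftfreq(T, d=volume.tr_seconds)
    amp = 2.0 * np.abs(np.fft.rfft(volume.data, axis=3)) / T
    return amp, freqs


def _check_band(volume: BoldVolume, band: BandSpec, freqs: np.ndarray) -> np.ndarray:
    band.validate_for(volume.tr_seconds)
    in_band = band_bin_mask(freqs, band.low_hz, band.high_hz)
    if not in_band.any():
        raise ValueError(
            "no DFT bins fall inside the band; the series is too short for "
            f"band {band.low_hz}-{band.high_hz} Hz at TR={volume.tr_seconds}s"
        )
    return in_band


def compute_alff(volume: BoldVolume, mask: BrainMask,
                 band: BandSpec | None = None) -> ActivityMap:
    """Amplitude of low-frequency fluctuations.

    Mean one-sided spectral amplitude over bins with low <= f <= high.
    Expects a detrended (not bandpassed) volume: filtering to the analysis
    band beforehand would make the measure trivial.
    """
    band = band or BandSpec()
    mask.check_grid(volume.grid)
    if volume.n_timepoints < 16:
        raise ValueError("ALFF needs at least 16 timepoints")
    amp, freqs = _amplitude_spectrum(volume)
    in_band = _check_band(volume, band, freqs)
    out = amp[..., in_band].mean(axis=3)
    out[~mask.data] = 0.0
    return ActivityMap(out, "alff", mask)


def compute_falff(volume: BoldVolume, mask: BrainMask,
                  band: BandSpec | None = None) -> ActivityMap:
    """Fractional ALFF: in-band amplitude mass over total (0, Nyquist] mass.

    A voxel with zero total spectral mass (identically constant series) gets
    fALFF = 0 by convention.
    """
    band = band or BandSpec()
    mask.check_grid(volume.grid)
    if volume.n_timepoints < 16:
        raise ValueError("fALFF needs at least 16 timepoints")
    amp, freqs = _amplitude_spectrum(volume)
    in_band = _check_band(volume, band, freqs)
    positive = freqs > 0.0
    num = amp[..., in_band].sum(axis=3)
    den = amp[..., positive].sum(axis=3)
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out[~mask.data] = 0.0
    return ActivityMap(out, "falff", mask)


def compute_reho(volume: BoldVolume, mask: BrainMask) -> ActivityMap:
    """Regional homogeneity: Kendall's W over the 3x3x3 voxel cluster.

    Each in-mask voxel's time series is ranked over time; for the K <= 27
    in-mask voxels of the cube centred on a voxel,

        W = 12 * sum_t (R_t - K(T+1)/2)^2 / (K^2 (T^3 - T))

    where R_t is the rank sum at timepoint t. Ties get average ranks with no
    tie correction. Voxels with K < 2 (isolated in the mask) are set to 0 and
    flagged.
    """
    mask.check_grid(volume.grid)
    T = volume.n_timepoints
    if T < 4:
        raise ValueError("ReHo needs at least 4 timepoints")
    ranks = stats.rankdata(volume.data, axis=3)
    ranks[~mask.data] = 0.0
    # Rank sums over the cubic neighbourhood via a box filter per timepoint.
    rank_sums = (
        ndimage.uniform_filter(ranks, size=(3, 3, 3, 1), mode="constant", cval=0.0)
        * REHO_NEIGHBORHOOD_SIZE
    )
    k_map = (
        ndimage.uniform_filter(
            mask.data.astype(float), size=3, mode="constant", cval=0.0
        )
        * REHO_NEIGHBORHOOD_SIZE
    )
    K = np.rint(k_map)
    mean_rank_sum = K[..., None] * (T + 1) / 2.0
    ss = ((rank_sums - mean_rank_sum) ** 2).sum(axis=3)
    out = np.zeros(volume.grid)
    flags = np.zeros(volume.grid, dtype=bool)
    valid = mask.data & (K >= 2)
    out[valid] = 12.0 * ss[valid] / (K[valid] ** 2 * (T**3 - T))
    flags[mask.data & (K < 2)] = True
    return ActivityMap(out, "reho", mask, flags=flags)


def compute_vmhc(volume: BoldVolume, mask: BrainMask) -> ActivityMap:
    """Voxel-mirrored homotopic connectivity.

    The first grid axis is treated as left-right; the mirror of voxel
    (x, y, z) is (X-1-x, y, z). For each in-mask voxel with a distinct
    in-mask mirror, the value is atanh of the (clipped) Pearson correlation
    between the two series. Self-mirrored voxels, voxels whose mirror is
    outside the mask, and zero-variance series are set to 0 and flagged.
    """
    mask.check_grid(volume.grid)
    X = volume.grid[0]
    data = volume.data
    centred = data - data.mean(axis=3, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=3))
    mirrored = centred[::-1, :, :, :]
    mirror_norms = norms[::-1, :, :]
    mirror_mask = mask.data[::-1, :, :]

    self_mirrored = np.zeros(volume.grid, dtype=bool)
    if X % 2 == 1:
        self_mirrored[X // 2, :, :] = True

    paired = mask.data & mirror_mask & ~self_mirrored
    nonzero = (norms > 0) & (mirror_norms > 0)
    valid = paired & nonzero

    out = np.zeros(volume.grid)
    flags = np.zeros(volume.grid, dtype=bool)
    num = (centred * mirrored).sum(axis=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (norms * mirror_norms)
    r = np.clip(r, -1.0 + VMHC_CLIP, 1.0 - VMHC_CLIP)
    out[valid] = np.arctanh(r[valid])
    flags[mask.data & ~valid] = True
    return ActivityMap(out, "vmhc", mask, flags=flags)


def standardize_map(amap: ActivityMap) -> ActivityMap:
    """Z-score the map over in-mask voxels (population-sd convention)."""
    values = amap.in_mask_values()
    if values.size < 2:
        raise ValueError("standardization needs at least 2 in-mask voxels")
    mean = values.mean()
    sd = values.std()  # ddof=0
    if sd == 0:
        raise ValueError("zero variance across mask; cannot standardize")
    out = np.zeros_like(amap.data)
    out[amap.mask.data] = (values - mean) / sd
    return replace(amap, data=out, standardized=True)


def extract_subject_maps(
    volume: BoldVolume,
    mask: BrainMask,
    band: BandSpec | None = None,
    fwhm_mm: float = 4.0,
) -> dict[str, ActivityMap]:
    """Full per-subject measure extraction with the standard ordering.

    The volume is linearly detrended; ALFF and fALFF are computed on the
    detrended series (bandpassing first would make fALFF degenerate), while
    ReHo and VMHC are computed on the detrended + bandpassed series. Each map
    is standardized over the mask; ALFF, fALFF and ReHo maps are then
    smoothed (FWHM ``fwhm_mm``), VMHC is not re-smoothed.
    """
    from .preprocess import bandpass_filter, linear_detrend

    band = band or BandSpec()
    detrended = linear_detrend(volume, mask)
    filtered = bandpass_filter(detrended, band, mask)
    maps = {
        "alff": compute_alff(detrended, mask, band),
        "falff": compute_falff(detrended, mask, band),
        "reho": compute_reho(filtered, mask),
        "vmhc": compute_vmhc(filtered, mask),
    }
    out: dict[str, ActivityMap] = {}
    for name, amap in maps.items():
        smap = standardize_map(amap)
        if name in ("alff", "falff", "reho"):
            smoothed = gaussian_smooth(smap.data, fwhm_mm, volume.voxel_size_mm, mask)
            smap = replace(smap, data=smoothed)
        out[name] = smap
    return out
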