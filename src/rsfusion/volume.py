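"""Core 4D BOLD container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BoldVolume"]


@dataclass(frozen=True)
class BoldVolume:
    """A single subject's 4D BOLD grid (X, Y, Z, T) with voxel geometry.

    Parameters
    ----------
    data
        Real-valued array of shape ``(X, Y, Z, T)``; all values finite.
    voxel_size_mm
        Physical voxel edge lengths along x, y, z in millimetres.
    tr_seconds
        Repetition time (sampling interval of the time series) in seconds.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (X,Y,Z,T), got ndim={data.ndim}")
        if data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if not np.all(np.isfinite(data)):
            raise ValueError("BOLD data contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_mm must be three positive reals")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", vs)
        object.__setattr__(self, "tr_seconds", float(self.tr_seconds))

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        """Highest detectable frequency, 1 / (2 TR)."""
        return 1.0 / (2.0 * self.tr_seconds)

    def with_data(self, data: np.ndarray) -> "BoldVolume":
        return BoldVolume(data, self.voxel_size_mm, self.tr_seconds)
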