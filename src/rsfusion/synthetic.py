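"""Synthetic two-group 4D BOLD cohorts with planted activity effects.

Generates patient/control cohorts in which group differences are planted in
the quantities the downstream measures detect: band-limited oscillation
amplitude (ALFF / fALFF), local temporal coherence across a voxel
neighbourhood (ReHo), and mirrored inter-hemispheric correlation (VMHC).
Every subject is reproducible from the cohort seed alone, so the full
pipeline is testable without any acquisition data.

The generator is deliberately minimal: background voxels carry white
Gaussian noise on a constant baseline plus a shared linear drift. It does
not attempt haemodynamics, motion or physiological noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BrainMask
from .volume import BoldVolume

__all__ = [
    "EffectRegion",
    "CohortSpec",
    "generate_subject",
    "generate_cohort",
    "add_rician_noise",
    "full_mask",
    "PATIENT",
    "CONTROL",
]

PATIENT = "patient"
CONTROL = "control"

EFFECT_KINDS = ("alff", "reho", "vmhc")


@dataclass(frozen=True)
class EffectRegion:
    """A set of voxels carrying a planted group effect.

    ``effect_size`` is a multiplicative amplitude factor (in units of the
    baseline noise standard deviation) for ``alff`` regions, and a
    shared-signal mixing weight in [0, 1] for ``reho`` / ``vmhc`` regions.
    ``vmhc`` voxel sets must be closed under the left-right mirror map
    ``x -> X-1-x``.
    """

    kind: str
    voxels: tuple[tuple[int, int, int], ...]
    effect_size: float
    applies_to: str = PATIENT

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.applies_to not in (PATIENT, CONTROL):
            raise ValueError(f"applies_to must be {PATIENT!r} or {CONTROL!r}")
        voxels = tuple(tuple(int(c) for c in v) for v in self.voxels)
        if not voxels:
            raise ValueError("effect region must contain at least one voxel")
        if self.kind in ("reho", "vmhc") and not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("mixing weight must lie in [0, 1]")
        object.__setattr__(self, "voxels", voxels)

    def validate_for_grid(self, grid: tuple[int, int, int]) -> None:
        for v in self.voxels:
            if any(c < 0 or c >= g for c, g in zip(v, grid)):
                raise ValueError(f"effect voxel {v} outside grid {grid}")
        if self.kind == "vmhc":
            X = grid[0]
            vox = set(self.voxels)
            for (x, y, z) in self.voxels:
                if (X - 1 - x, y, z) not in vox:
                    raise ValueError(
                        "vmhc effect region must be closed under the x-mirror map"
                    )


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults are the desk-scale conditions used throughout the test suite:
    a 12x14x12 grid of 3 mm isotropic voxels, 120 timepoints at TR = 2 s,
    and 10 subjects per group, sized so a full pipeline run stays in the
    minutes range on one CPU.
    """

    n_patients: int = 10
    n_controls: int = 10
    grid: tuple[int, int, int] = (12, 14, 12)
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    effect_regions: tuple[EffectRegion, ...] = ()
    baseline_noise_sd: float = 1.0
    baseline_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        if self.n_timepoints < 16:
            raise ValueError("need at least 16 timepoints")
        grid = tuple(int(g) for g in self.grid)
        if len(grid) != 3 or any(g < 4 for g in grid):
            raise ValueError("grid dims must be >= 4")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be non-negative")
        for val in (self.tr_seconds, *self.voxel_size_mm, self.baseline_noise_sd,
                    self.baseline_mean):
            if not np.isfinite(val):
                raise ValueError("spec reals must be finite")
        regions = tuple(self.effect_regions)
        for region in regions:
            region.validate_for_grid(grid)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "effect_regions", regions)

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def subject_seed(self, subject_index: int) -> int:
        """Deterministic per-subject seed: cohort seed * 1e6 + subject index."""
        return self.seed * 10**6 + subject_index

    def subject_label(self, subject_index: int) -> str:
        return PATIENT if subject_index < self.n_patients else CONTROL


def default_effect_regions(
    grid: tuple[int, int, int] = (12, 14, 12),
    alff_amplitude: float = 4.0,
    reho_mixing: float = 0.9,
    vmhc_mixing: float = 1.0,
) -> tuple[EffectRegion, ...]:
    """Three disjoint 3x3x3 planted regions, one per measure family.

    These are the package's standard strong-effect study conditions: an
    oscillation of four noise standard deviations for the ALFF family, and
    near-total shared-signal mixing for ReHo and VMHC, so each family's
    planted voxels separate the groups by an order of magnitude more than
    the between-subject noise. The VMHC region is a mirrored block pair.
    """
    X, Y, Z = grid

    def block(x0, y0, z0):
        return tuple(
            (x, y, z)
            for x in range(x0, x0 + 3)
            for y in range(y0, y0 + 3)
            for z in range(z0, z0 + 3)
        )

    vmhc_left = block(1, Y - 4, 2)
    vmhc_right = tuple((X - 1 - x, y, z) for (x, y, z) in vmhc_left)
    return (
        EffectRegion("alff", block(1, 2, 2), alff_amplitude, PATIENT),
        EffectRegion("reho", block(X - 5, Y - 6, Z - 6), reho_mixing, PATIENT),
        EffectRegion("vmhc", vmhc_left + vmhc_right, vmhc_mixing, PATIENT),
    )


def full_mask(grid: tuple[int, int, int]) -> BrainMask:
    """All-voxel mask for a synthetic grid (no anatomy is simulated)."""
    return BrainMask(np.ones(tuple(grid), dtype=bool))


def _band_limited_series(rng: np.random.Generator, n_timepoints: int,
                         tr_seconds: float, n_components: int = 5) -> np.ndarray:
    """Unit-variance sum of sinusoids with frequencies in 0.01-0.1 Hz.

    Random frequencies and phases guarantee in-band spectral energy, so
    planted amplitude effects are visible to ALFF/fALFF by construction.
    """
    t = np.arange(n_timepoints) * tr_seconds
    freqs = rng.uniform(0.01, 0.1, size=n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
    series = np.sqrt(2.0 / n_components) * np.sum(
        np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0
    )
    return series


def generate_subject(spec: CohortSpec, group: str, subject_seed: int) -> BoldVolume:
    """Generate one subject's 4D volume.

    Background voxels carry independent Gaussian noise (sd =
    ``baseline_noise_sd``) on a constant baseline plus a subject-wide linear
    drift. Voxels of each effect region whose ``applies_to`` matches
    ``group`` additionally carry the region's planted signal. Noise and
    signal use separate random streams derived from ``subject_seed`` so a
    subject is reproducible in isolation.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"unknown group label {group!r}")
    rng_noise = np.random.default_rng([subject_seed, 0])
    rng_signal = np.random.default_rng([subject_seed, 1])
    X, Y, Z = spec.grid
    T = spec.n_timepoints
    data = rng_noise.normal(0.0, spec.baseline_noise_sd, size=(X, Y, Z, T))
    data += spec.baseline_mean
    # Shared linear drift, removed downstream by detrending.
    slope = rng_signal.normal(0.0, 0.5)
    t_norm = np.linspace(-0.5, 0.5, T)
    data += slope * t_norm

    for region in spec.effect_regions:
        if region.applies_to != group:
            # Burn the same number of draws so the background realisation of
            # non-affected subjects does not depend on group membership.
            _burn_region_draws(rng_signal, region, spec)
            continue
        if region.kind == "alff":
            for (x, y, z) in region.voxels:
                data[x, y, z, :] += region.effect_size * _band_limited_series(
                    rng_signal, T, spec.tr_seconds
                )
        elif region.kind == "reho":
            shared = _band_limited_series(rng_signal, T, spec.tr_seconds)
            for (x, y, z) in region.voxels:
                data[x, y, z, :] += region.effect_size * shared
        elif region.kind == "vmhc":
            for (x, y, z) in _mirror_pairs(region, X):
                shared = _band_limited_series(rng_signal, T, spec.tr_seconds)
                mx = X - 1 - x
                data[x, y, z, :] += region.effect_size * shared
                if mx != x:
                    data[mx, y, z, :] += region.effect_size * shared
    return BoldVolume(data, spec.voxel_size_mm, spec.tr_seconds)


def _mirror_pairs(region: EffectRegion, X: int):
    """Canonical representative (x <= mirror x) of each mirrored voxel pair."""
    seen = set()
    for (x, y, z) in region.voxels:
        key = (min(x, X - 1 - x), y, z)
        if key not in seen:
            seen.add(key)
            yield key


def _burn_region_draws(rng: np.random.Generator, region: EffectRegion,
                       spec: CohortSpec) -> None:
    if region.kind == "alff":
        n_series = len(region.voxels)
    elif region.kind == "reho":
        n_series = 1
    else:
        n_series = sum(1 for _ in _mirror_pairs(region, spec.grid[0]))
    for _ in range(n_series):
        _band_limited_series(rng, spec.n_timepoints, spec.tr_seconds)


def generate_cohort(spec: CohortSpec) -> list[tuple[BoldVolume, str]]:
    """Generate all subjects: patients first, then controls.

    Subject ``i`` uses seed ``spec.seed * 1e6 + i``, so individual subjects
    can be regenerated without building the whole cohort.
    """
    cohort = []
    for i in range(spec.n_subjects):
        label = spec.subject_label(i)
        cohort.append((generate_subject(spec, label, spec.subject_seed(i)), label))
    return cohort


def add_rician_noise(volume: BoldVolume, sigma: float, noise_seed: int) -> BoldVolume:
    """Corrupt a volume with Rician noise of scale ``sigma``.

    Each value v becomes sqrt((v + n1)^2 + n2^2) with n1, n2 independent
    N(0, sigma^2) — the magnitude-image noise model of MRI. sigma = 0 is an
    exact identity. Output is everywhere non-negative for sigma > 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return volume.with_data(volume.data.copy())
    rng = np.random.default_rng(noise_seed)
    shape = volume.data.shape
    n1 = rng.normal(0.0, sigma, size=shape)
    n2 = rng.normal(0.0, sigma, size=shape)
    out = np.sqrt((volume.data + n1) ** 2 + n2**2)
    return volume.with_data(out)
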