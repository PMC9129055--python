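"""End-to-end convenience layer: volumes -> maps -> features -> CV report."""

from __future__ import annotations

import numpy as np

from .evaluate import CvConfig, CvReport, Scheme, nested_cv
from .measures import MEASURES, extract_subject_maps
from .preprocess import BandSpec, BrainMask
from .selection import FeatureMatrix, maps_to_feature_matrix

__all__ = ["extract_feature_matrices", "run_scheme"]


def extract_feature_matrices(
    cohort,
    mask: BrainMask,
    band: BandSpec | None = None,
    fwhm_mm: float = 4.0,
    measures: tuple[str, ...] = MEASURES,
) -> dict[str, FeatureMatrix]:
    """Compute per-subject activity maps and vectorize them per measure."""
    labels = np.asarray([lab for _, lab in cohort])
    all_maps = [extract_subject_maps(vol, mask, band, fwhm_mm) for vol, _ in cohort]
    return {
        m: maps_to_feature_matrix(all_maps, labels, mask, (m,)) for m in measures
    }


def run_scheme(
    cohort,
    mask: BrainMask,
    scheme: Scheme,
    config: CvConfig | None = None,
    band: BandSpec | None = None,
    fwhm_mm: float = 4.0,
) -> CvReport:
    """Full pipeline on a cohort of (volume, label) pairs."""
    features = extract_feature_matrices(
        cohort, mask, band, fwhm_mm, measures=tuple(scheme.measures)
    )
    return nested_cv(features, scheme, config)
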