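"""Convenience composition of the pipeline stages.

Thin glue: simulate/clean/measure/extract in one call, used by the CLI-less
programmatic path (tests, notebooks, the acceptance script).
"""

from __future__ import annotations

import pandas as pd

from .cohort_stats import PairedCohort
from .keypoints_io import SkeletonSequence, clean_sequence
from .skeleton_geometry import compute_parameter_series
from .synthetic_motion import CohortConfig, generate_paired_cohort
from .timeseries_features import AnalysisConfig, FeatureVector, extract_features, features_to_frame


def features_for_sequence(
    seq: SkeletonSequence,
    cfg: AnalysisConfig | None = None,
    *,
    clean: bool = True,
) -> FeatureVector:
    """Clean a keypoint sequence, compute the 11 series, extract 33 features."""
    if clean:
        seq = clean_sequence(seq)
    return extract_features(compute_parameter_series(seq), cfg)


def simulate_cohort_features(
    cohort_cfg: CohortConfig,
    analysis_cfg: AnalysisConfig | None = None,
) -> PairedCohort:
    """Generate a synthetic paired cohort and run it through to features."""
    before_rows: list[FeatureVector] = []
    after_rows: list[FeatureVector] = []
    for _, before_seq, after_seq in generate_paired_cohort(cohort_cfg):
        before_rows.append(features_for_sequence(before_seq, analysis_cfg))
        after_rows.append(features_for_sequence(after_seq, analysis_cfg))
    return PairedCohort.from_feature_frames(
        features_to_frame(before_rows), features_to_frame(after_rows)
    )
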