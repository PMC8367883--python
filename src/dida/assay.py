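"""End-to-end assay analysis: recordings in, profiles and verdicts out.

This is the programmatic equivalent of the full laboratory workflow: measure
the reference anchors from the background and intact-tablet recordings,
convert each disintegration replicate to a % remaining profile, summarize
the replicates at the pharmacopoeial timepoints and classify the behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .frames import FrameSequence
from .mgv import (
    AssayConditions,
    AssayReferences,
    MGVSeries,
    RegionOfInterest,
    measure_references,
    mgv_series,
)
from .profile import (
    CANONICAL_TIMEPOINTS_S,
    ClassificationResult,
    DisintegrationProfile,
    TimepointSummary,
    build_profile,
    classify_profile,
    estimate_noise_floor,
    summarize_timepoints,
)
from .simulate import AssayBundle, suggested_roi

__all__ = ["AssayAnalysis", "analyze_recordings", "analyze_bundle"]


@dataclass(frozen=True)
class AssayAnalysis:
    """Everything the pipeline derives from one assay's recordings."""

    references: AssayReferences
    mgv_replicates: tuple[MGVSeries, ...]
    profiles: tuple[DisintegrationProfile, ...]
    summaries: tuple[TimepointSummary, ...]
    classifications: tuple[ClassificationResult, ...]
    noise_floor_pct: float

    @property
    def consensus_category(self) -> str:
        """Majority category across replicates (ties broken by first seen)."""
        counts: dict[str, int] = {}
        for c in self.classifications:
            counts[c.category] = counts.get(c.category, 0) + 1
        return max(counts, key=counts.get)


def analyze_recordings(
    background: FrameSequence,
    tablet_only: FrameSequence,
    replicates: Sequence[FrameSequence],
    roi: RegionOfInterest,
    conditions: AssayConditions | None = None,
    timepoints_s: Sequence[float] = CANONICAL_TIMEPOINTS_S,
    smoothing_window_s: float | None = None,
    classification_kwargs: Mapping | None = None,
) -> AssayAnalysis:
    """Run the complete analysis on already-loaded recordings.

    The same fixed ROI is applied to every recording. Classification
    thresholds may be overridden via ``classification_kwargs`` (passed to
    :func:`dida.profile.classify_profile`).
    """
    refs = measure_references(background, tablet_only, roi)
    mgvs = tuple(mgv_series(seq, roi) for seq in replicates)
    profiles = tuple(
        build_profile(
            m,
            refs,
            conditions=conditions,
            smoothing_window_s=smoothing_window_s,
            replicate_id=f"replicate_{i}",
        )
        for i, m in enumerate(mgvs)
    )
    summaries = tuple(summarize_timepoints(profiles, timepoints_s))
    kwargs = dict(classification_kwargs or {})
    classifications = tuple(classify_profile(p, **kwargs) for p in profiles)
    # background recording pushed through the same normalization gives the
    # assay's noise floor in percentage units
    background_pct = build_profile(mgv_series(background, roi), refs)
    noise_floor = estimate_noise_floor(background_pct.percent_remaining, refs)
    return AssayAnalysis(
        references=refs,
        mgv_replicates=mgvs,
        profiles=profiles,
        summaries=summaries,
        classifications=classifications,
        noise_floor_pct=noise_floor,
    )


def analyze_bundle(
    bundle: AssayBundle,
    roi: RegionOfInterest | None = None,
    timepoints_s: Sequence[float] = CANONICAL_TIMEPOINTS_S,
    smoothing_window_s: float | None = None,
    classification_kwargs: Mapping | None = None,
) -> AssayAnalysis:
    """Analyze a simulated assay bundle; the ROI defaults to the simulator's
    suggested fixed rectangle around the tablet."""
    if roi is None:
        roi = suggested_roi(bundle.config)
    return analyze_recordings(
        bundle.background,
        bundle.tablet_only,
        bundle.replicates,
        roi,
        timepoints_s=timepoints_s,
        smoothing_window_s=smoothing_window_s,
        classification_kwargs=classification_kwargs,
    )
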