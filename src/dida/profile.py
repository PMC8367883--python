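"""Disintegration profiles: construction, summaries, classification, comparison.

A disintegration profile is the % tablet remaining plotted against time for
one replicate. Profiles are summarized at pharmacopoeial timepoints
(canonically 10 s, 30 s and 180 s — the FDA 30 s and Ph. Eur. 3 min limits
for fast-disintegrating tablets, plus an early 10 s read), classified into
behavioural categories (instant / fast / prolonged disintegration, swelling,
partial disintegration), and compared across conditions with a Welch
two-sample t-test on replicate summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateVarianceError,
    InputError,
    OutOfRangeError,
)
from .mgv import AssayConditions, AssayReferences, MGVSeries, percent_remaining

__all__ = [
    "DisintegrationProfile",
    "TimepointSummary",
    "ClassificationResult",
    "ComparisonResult",
    "build_profile",
    "value_at",
    "summarize_timepoints",
    "classify_profile",
    "estimate_noise_floor",
    "welch_t_from_summary",
    "stars_for_p",
    "CANONICAL_TIMEPOINTS_S",
]

#: 10 s early read, FDA 30 s limit, European Pharmacopoeia 3 min limit.
CANONICAL_TIMEPOINTS_S = (10.0, 30.0, 180.0)

#: Defaults for behavioural classification (all configurable per call).
DEFAULT_COMPLETION_THRESHOLD_PCT = 10.0
DEFAULT_INSTANT_LIMIT_S = 10.0
DEFAULT_FAST_LIMIT_S = 30.0
DEFAULT_PROLONGED_LIMIT_S = 180.0
DEFAULT_SWELLING_THRESHOLD_PCT = 105.0
DEFAULT_SWELLING_SUSTAIN_S = 5.0
DEFAULT_BURN_IN_S = 5.0

CATEGORIES = ("instant", "fast", "prolonged", "swelling", "partial")


@dataclass(frozen=True)
class DisintegrationProfile:
    """% tablet remaining vs time for one replicate."""

    times_s: np.ndarray
    percent_remaining: np.ndarray
    replicate_id: str = ""
    conditions: AssayConditions | None = None
    smoothed: bool = False
    smoothing_window_s: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=np.float64)
        values = np.asarray(self.percent_remaining, dtype=np.float64)
        if times.shape != values.shape or times.ndim != 1 or times.size == 0:
            raise ConfigurationError(
                "times_s and percent_remaining must be non-empty, 1-D, equal length"
            )
        if times[0] != 0.0:
            raise ConfigurationError("profile times must start at 0 s")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ConfigurationError("profile times must be strictly increasing")
        if self.smoothed and not (
            self.smoothing_window_s is not None and self.smoothing_window_s > 0
        ):
            raise ConfigurationError(
                "smoothed profiles must record a positive smoothing_window_s"
            )
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "percent_remaining", values)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1])

    @property
    def flags(self) -> list[str]:
        """Per-sample flags: 'swelling' for values > 100 %, 'negative' below 0 %."""
        out = []
        for v in self.percent_remaining:
            if v > 100.0:
                out.append("swelling")
            elif v < 0.0:
                out.append("negative")
            else:
                out.append("")
        return out

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class TimepointSummary:
    """Replicate mean ± sd of % remaining at one timepoint."""

    timepoint_s: float
    mean_percent: float
    sd_percent: float
    n: int


@dataclass(frozen=True)
class ClassificationResult:
    """Behavioural category of one profile plus the evidence for it."""

    category: str
    endpoint_time_s: float | None
    max_percent: float
    final_percent: float
    thresholds_used: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ComparisonResult:
    """Welch two-sample t-test between two replicate groups."""

    t_statistic: float
    degrees_freedom: float
    p_value: float
    significance_stars: str


def _moving_average(values: np.ndarray, times: np.ndarray, window_s: float) -> np.ndarray:
    """Centered moving average over a time window, shrinking at the edges."""
    out = np.empty_like(values)
    half = window_s / 2.0
    for i, t in enumerate(times):
        sel = (times >= t - half) & (times <= t + half)
        out[i] = values[sel].mean()
    return out


def build_profile(
    mgv: MGVSeries,
    refs: AssayReferences,
    conditions: AssayConditions | None = None,
    smoothing_window_s: float | None = None,
    replicate_id: str = "",
) -> DisintegrationProfile:
    """Convert an MGV series into a disintegration profile.

    Applies the % remaining normalization per sample; optionally smooths
    with a centered moving average of the given window (in seconds),
    recording the window in the profile metadata. Smoothing defaults off.
    """
    values = percent_remaining(mgv.values, refs)
    values = np.atleast_1d(values)
    smoothed = False
    if smoothing_window_s is not None:
        if smoothing_window_s <= 0:
            raise ConfigurationError("smoothing_window_s must be positive")
        values = _moving_average(values, mgv.times_s, smoothing_window_s)
        smoothed = True
    return DisintegrationProfile(
        times_s=mgv.times_s,
        percent_remaining=values,
        replicate_id=replicate_id,
        conditions=conditions,
        smoothed=smoothed,
        smoothing_window_s=smoothing_window_s if smoothed else None,
    )


def value_at(profile: DisintegrationProfile, t_s: float) -> float:
    """% remaining at time ``t_s``, linearly interpolated between samples."""
    if t_s < 0 or t_s > profile.duration_s:
        raise OutOfRangeError(
            f"t={t_s} s outside recording span [0, {profile.duration_s}] s"
            + (f" of replicate '{profile.replicate_id}'" if profile.replicate_id else "")
        )
    return float(np.interp(t_s, profile.times_s, profile.percent_remaining))


def summarize_timepoints(
    profiles: Sequence[DisintegrationProfile],
    timepoints_s: Sequence[float] = CANONICAL_TIMEPOINTS_S,
) -> list[TimepointSummary]:
    """Replicate mean and sample sd (n−1 denominator) at each timepoint.

    Every replicate must cover every requested timepoint; with a single
    replicate the sd is reported as 0.
    """
    if not profiles:
        raise InputError("at least one replicate profile is required")
    out = []
    for t in timepoints_s:
        vals = np.array([value_at(p, t) for p in profiles])
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out.append(
            TimepointSummary(
                timepoint_s=float(t),
                mean_percent=float(vals.mean()),
                sd_percent=sd,
                n=vals.size,
            )
        )
    return out


def _sustained_maximum(
    times: np.ndarray, values: np.ndarray, burn_in_s: float, sustain_s: float
) -> float:
    """Largest level the profile holds for at least ``sustain_s`` seconds.

    Only samples after the burn-in are considered, excluding transients from
    medium addition. For each contiguous run of samples at or above a
    candidate level, the run must span ``sustain_s``; the returned value is
    the largest minimum over any sufficiently long window.
    """
    sel = times >= burn_in_s
    t, v = times[sel], values[sel]
    if t.size == 0:
        return float(values.max())
    if t[-1] - t[0] < sustain_s:
        return float(v.min())
    # sliding minimum over the shortest windows spanning at least sustain_s
    best = -np.inf
    j = 0
    for i in range(t.size):
        while j + 1 < i and t[i] - t[j + 1] >= sustain_s:
            j += 1
        if t[i] - t[j] >= sustain_s:
            best = max(best, v[j : i + 1].min())
    return float(best) if np.isfinite(best) else float(v.min())


def classify_profile(
    profile: DisintegrationProfile,
    completion_threshold_pct: float = DEFAULT_COMPLETION_THRESHOLD_PCT,
    instant_limit_s: float = DEFAULT_INSTANT_LIMIT_S,
    fast_limit_s: float = DEFAULT_FAST_LIMIT_S,
    prolonged_limit_s: float = DEFAULT_PROLONGED_LIMIT_S,
    swelling_threshold_pct: float = DEFAULT_SWELLING_THRESHOLD_PCT,
    swelling_sustain_s: float = DEFAULT_SWELLING_SUSTAIN_S,
    burn_in_s: float = DEFAULT_BURN_IN_S,
) -> ClassificationResult:
    """Classify a profile's disintegration behaviour.

    Decision order:

    1. *swelling* — the profile sustains a level at or above
       ``swelling_threshold_pct`` for at least ``swelling_sustain_s`` seconds
       (after a burn-in excluding the medium-addition transient);
    2. otherwise find the endpoint: the first time the profile drops to or
       below ``completion_threshold_pct`` and never rises above it again.
       *instant* if the endpoint is within ``instant_limit_s``, *fast*
       within ``fast_limit_s``, *prolonged* otherwise;
    3. *partial* — no endpoint within the recording (material remains).
    """
    if not (instant_limit_s < fast_limit_s < prolonged_limit_s):
        raise ConfigurationError(
            "category limits must satisfy instant < fast < prolonged, got "
            f"{instant_limit_s}, {fast_limit_s}, {prolonged_limit_s}"
        )
    if swelling_threshold_pct <= 100.0:
        raise ConfigurationError("swelling_threshold_pct must exceed 100 %")
    thresholds = {
        "completion_threshold_pct": completion_threshold_pct,
        "instant_limit_s": instant_limit_s,
        "fast_limit_s": fast_limit_s,
        "prolonged_limit_s": prolonged_limit_s,
        "swelling_threshold_pct": swelling_threshold_pct,
        "swelling_sustain_s": swelling_sustain_s,
        "burn_in_s": burn_in_s,
    }
    times = profile.times_s
    values = profile.percent_remaining
    max_percent = float(values.max())
    final_percent = float(values[-1])

    sustained_max = _sustained_maximum(times, values, burn_in_s, swelling_sustain_s)
    if sustained_max >= swelling_threshold_pct:
        return ClassificationResult(
            category="swelling",
            endpoint_time_s=None,
            max_percent=max_percent,
            final_percent=final_percent,
            thresholds_used=thresholds,
        )

    # endpoint: first index from which the profile stays <= threshold
    below = values <= completion_threshold_pct
    endpoint_time = None
    if below[-1]:
        # last index where the profile is above the threshold
        above_idx = np.nonzero(~below)[0]
        first_stay = 0 if above_idx.size == 0 else int(above_idx[-1]) + 1
        endpoint_time = float(times[first_stay])
    if endpoint_time is not None:
        if endpoint_time <= instant_limit_s:
            category = "instant"
        elif endpoint_time <= fast_limit_s:
            category = "fast"
        else:
            # slower than the fast limit counts as prolonged, even past the
            # pharmacopoeial 3 min bound — it still disintegrated completely
            category = "prolonged"
    else:
        category = "partial"
    return ClassificationResult(
        category=category,
        endpoint_time_s=endpoint_time,
        max_percent=max_percent,
        final_percent=final_percent,
        thresholds_used=thresholds,
    )


def estimate_noise_floor(
    background_percent_values: Sequence[float],
    refs: AssayReferences | None = None,
) -> float:
    """Noise floor in percentage units: sd of a background-only % profile.

    A background-only recording pushed through the full pipeline should read
    0 %; the standard deviation of what it actually reads is the assay's
    noise floor. Profile changes smaller than about 3× this floor should not
    be interpreted. ``refs`` is accepted for interface symmetry with the
    rest of the pipeline; the estimate needs only the percentage values.
    """
    values = np.asarray(background_percent_values, dtype=np.float64)
    if values.size == 0:
        raise InputError("background profile is empty")
    return float(values.std(ddof=0))


def stars_for_p(p: float) -> str:
    """Significance stars: '***' for P ≤ 0.001, '**' ≤ 0.01, '*' ≤ 0.05."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def welch_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
) -> ComparisonResult:
    """Welch (unequal-variance) two-sided t-test from summary statistics.

    Uses the Welch–Satterthwaite degrees of freedom. With both sds zero and
    equal means the groups are identical and p = 1 by convention; with both
    sds zero and unequal means the statistic is undefined.
    """
    if n1 < 2 or n2 < 2:
        raise InputError(f"each group needs n ≥ 2 replicates, got {n1} and {n2}")
    if sd1 < 0 or sd2 < 0:
        raise InputError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return ComparisonResult(
                t_statistic=0.0, degrees_freedom=float(n1 + n2 - 2),
                p_value=1.0, significance_stars="",
            )
        raise DegenerateVarianceError(
            "both groups have zero variance but different means"
        )
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ComparisonResult(
        t_statistic=float(t),
        degrees_freedom=float(df),
        p_value=p,
        significance_stars=stars_for_p(p),
    )
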