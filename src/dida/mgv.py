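"""Mean grey values and the % tablet remaining normalization.

The assay's measurement is the mean grey value (MGV): the arithmetic mean
pixel intensity inside a fixed region of interest covering the formulation.
Two companion recordings anchor the scale — medium-only frames give the
background MGV (the 0 % anchor and the sensor noise floor), and an
intact-tablet recording gives the full-tablet MGV (the 100 % anchor, itself
background-corrected so both anchors live on the same scale). The % tablet
remaining at time t is then

    percent(t) = 100 * (MGV(t) - MGV_bg) / MGV_0

deliberately unclipped: values above 100 % indicate swelling, small
negative values are noise around an empty vessel and carry information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, NoContrastError
from .frames import FrameSequence

__all__ = [
    "RegionOfInterest",
    "MGVSeries",
    "AssayReferences",
    "AssayConditions",
    "compute_mgv",
    "mgv_series",
    "measure_references",
    "percent_remaining",
]

#: Minimum background-corrected full-tablet MGV (grey levels) for a usable assay.
DEFAULT_CONTRAST_TOLERANCE = 5.0


@dataclass(frozen=True)
class RegionOfInterest:
    """Fixed pixel region over which the MGV is computed.

    The same ROI is applied to every frame of an assay (background,
    intact-tablet and disintegration recordings alike).
    """

    mask: np.ndarray
    name: str = "roi"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ConfigurationError(f"ROI mask must be 2-D, got {mask.ndim}-D")
        if not mask.any():
            raise ConfigurationError("ROI selects zero pixels")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_rectangle(
        cls,
        x0: int,
        y0: int,
        x1: int,
        y1: int,
        frame_shape: tuple[int, int],
        name: str | None = None,
    ) -> "RegionOfInterest":
        """Build a rectangular ROI from 0-based, half-open pixel coordinates."""
        height, width = frame_shape
        if not (0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height):
            raise ConfigurationError(
                f"rectangle ({x0},{y0})–({x1},{y1}) does not fit a "
                f"{height}×{width} frame"
            )
        mask = np.zeros((height, width), dtype=bool)
        mask[y0:y1, x0:x1] = True
        return cls(mask=mask, name=name or f"rect[{x0}:{x1},{y0}:{y1}]")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class MGVSeries:
    """Per-frame mean grey values (grey levels, 0–255) with their timestamps."""

    times_s: np.ndarray
    values: np.ndarray
    roi_ref: str = "roi"

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        if times.shape != values.shape or times.ndim != 1:
            raise ConfigurationError("times_s and values must be 1-D and equal length")
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AssayReferences:
    """The 0 %/100 % anchors of an assay.

    ``mgv_background`` is the mean MGV of the medium-only recording and
    ``mgv_background_sd`` the standard deviation of its per-frame MGVs (the
    sensor noise floor in grey levels). ``mgv_tablet_full`` is the mean MGV
    of the intact-tablet recording minus the background — the contrast the
    whole percentage scale is built on.
    """

    mgv_background: float
    mgv_background_sd: float
    mgv_tablet_full: float
    n_frames_background: int = 0
    n_frames_reference: int = 0
    mgv_tablet_raw: float | None = None

    def __post_init__(self) -> None:
        if self.mgv_tablet_raw is None:
            object.__setattr__(
                self, "mgv_tablet_raw", self.mgv_background + self.mgv_tablet_full
            )
        if self.mgv_tablet_full <= 0:
            raise NoContrastError(
                f"background-corrected full-tablet MGV must be positive, "
                f"got {self.mgv_tablet_full}"
            )
        if self.mgv_background_sd < 0:
            raise ConfigurationError("mgv_background_sd must be non-negative")


@dataclass(frozen=True)
class AssayConditions:
    """Metadata labels for one assay condition; no physics is computed from them."""

    formulation_name: str = ""
    medium_name: str = ""
    medium_volume_ml: float | None = None
    temperature_label_c: float | None = None

    def __post_init__(self) -> None:
        if self.medium_volume_ml is not None and self.medium_volume_ml <= 0:
            raise ConfigurationError("medium_volume_ml must be positive")
        if self.temperature_label_c is not None and not (
            20.0 <= self.temperature_label_c <= 45.0
        ):
            raise ConfigurationError(
                f"temperature_label_c {self.temperature_label_c} outside the sane "
                "20–45 °C range"
            )


def _check_roi(frame_shape: tuple[int, int], roi: RegionOfInterest) -> None:
    if roi.shape != tuple(frame_shape):
        raise ConfigurationError(
            f"ROI shape {roi.shape} does not match frame shape {tuple(frame_shape)}"
        )


def compute_mgv(frame: np.ndarray, roi: RegionOfInterest) -> float:
    """Arithmetic mean intensity of the pixels inside the ROI, in grey levels."""
    frame = np.asarray(frame)
    _check_roi(frame.shape, roi)
    return float(frame[roi.mask].astype(np.float64).mean())


def mgv_series(seq: FrameSequence, roi: RegionOfInterest) -> MGVSeries:
    """One MGV per frame of the sequence, preserving order and timestamps."""
    _check_roi(seq.frame_shape, roi)
    # flat indexing once, mean over axis: identical to per-frame masked means
    flat = seq.frames.reshape(seq.n_frames, -1)[:, roi.mask.ravel()]
    values = flat.astype(np.float64).mean(axis=1)
    return MGVSeries(times_s=seq.timestamps_s, values=values, roi_ref=roi.name)


def measure_references(
    background_seq: FrameSequence,
    tablet_seq: FrameSequence,
    roi: RegionOfInterest,
    contrast_tolerance: float = DEFAULT_CONTRAST_TOLERANCE,
) -> AssayReferences:
    """Measure the assay anchors from the two companion recordings.

    Both MGV anchors are means over their whole recordings, which averages
    away per-frame sensor noise; the noise floor is the standard deviation
    of the background recording's per-frame MGVs.

    Raises
    ------
    NoContrastError
        When the background-corrected full-tablet MGV does not exceed
        ``contrast_tolerance`` grey levels — a tablet indistinguishable from
        its background produces unstable percentage ratios and is rejected.
    """
    if background_seq.frame_shape != tablet_seq.frame_shape:
        raise ConfigurationError(
            "background and tablet recordings have different frame geometry"
        )
    bg = mgv_series(background_seq, roi)
    tab = mgv_series(tablet_seq, roi)
    mgv_background = float(bg.values.mean())
    mgv_background_sd = float(bg.values.std(ddof=0))
    mgv_tablet_raw = float(tab.values.mean())
    mgv_tablet_full = mgv_tablet_raw - mgv_background
    if mgv_tablet_full <= contrast_tolerance:
        raise NoContrastError(
            f"tablet is indistinguishable from background: corrected full-tablet "
            f"MGV {mgv_tablet_full:.3f} ≤ tolerance {contrast_tolerance} grey levels"
        )
    return AssayReferences(
        mgv_background=mgv_background,
        mgv_background_sd=mgv_background_sd,
        mgv_tablet_full=mgv_tablet_full,
        n_frames_background=background_seq.n_frames,
        n_frames_reference=tablet_seq.n_frames,
        mgv_tablet_raw=mgv_tablet_raw,
    )


def percent_remaining(mgv_t, refs: AssayReferences):
    """Convert MGV(s) to % tablet remaining on the assay's 0 %/100 % scale.

    Accepts a scalar or an array; the result is *not* clipped — values above
    100 % indicate swelling and slightly negative values arise from noise
    around an empty vessel.

    The two anchors are float-exact: the background MGV maps to exactly 0.0
    and the intact-tablet reading (``refs.mgv_tablet_raw``) to exactly 100.0,
    because the ratio is formed before scaling by 100.
    """
    mgv_t = np.asarray(mgv_t, dtype=np.float64)
    result = 100.0 * ((mgv_t - refs.mgv_background) / refs.mgv_tablet_full)
    if result.ndim == 0:
        return float(result)
    return result
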