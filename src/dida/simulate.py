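"""Synthetic assay recordings with known ground truth.

The simulator reproduces the optical structure of the camera assay: a
bright, roughly disc-shaped tablet on a near-black vessel floor, recorded
at 10 frames per second for a few minutes, with additive per-pixel Gaussian
sensor noise and 8-bit quantization. Three phases mirror the laboratory
protocol — a medium-only *background* recording, an intact *tablet_only*
recording, and the *disintegration* recording itself.

Disintegration is rendered as area shrinkage: the disc radius scales as
sqrt(R(t)/100) so that the disc's area — and hence the ideal ROI mean grey
value above background — is proportional to the ground-truth % remaining
R(t). Swelling is disc-area growth at constant intensity, matching the
observed increase in tablet footprint. An optional intensity-fade mode
scales the disc's brightness instead; both modes produce the same ideal
ROI-MGV by construction. The link between remaining solid and MGV is a
linear optical proxy, an assumption documented in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .frames import FrameSequence
from .mgv import RegionOfInterest

__all__ = [
    "KineticsModel",
    "SimulationConfig",
    "AssayBundle",
    "ground_truth_percent",
    "render_sequence",
    "generate_assay",
    "suggested_roi",
]

PHASES = ("background", "tablet_only", "disintegration")
_PHASE_CODES = {name: i for i, name in enumerate(PHASES)}

KINETICS_MODELS = ("decay_to_plateau", "swelling", "biphasic")


@dataclass(frozen=True)
class KineticsModel:
    """Closed-form ground-truth kinetics R(t), in % of the intact tablet.

    ``decay_to_plateau``
        R(t) = plateau + (100 − plateau)·exp(−k·(t − lag)); first-order loss
        toward a residual plateau (0 for complete disintegration).
    ``swelling``
        R(t) = 100 + A·(1 − exp(−k·(t − lag))); saturating growth past the
        intact signal, A being the asymptotic excess over 100 %.
    ``biphasic``
        R(t) = max(0, plateau + (100 − plateau)·exp(−k·(t − lag))
        − s·(t − lag)); a fast first-order phase superposed with a slow
        linear tail of slope ``s`` (``tail_slope_pct_per_s``), floored at 0.

    Before the lag (medium contact) R(t) = 100 in every model.
    """

    model: str = "decay_to_plateau"
    rate_k_per_s: float = 0.1
    plateau_pct: float = 0.0
    swell_amplitude_pct: float = 0.0
    lag_s: float = 0.0
    tail_slope_pct_per_s: float = 0.02

    def __post_init__(self) -> None:
        if self.model not in KINETICS_MODELS:
            raise ConfigurationError(
                f"unknown kinetics model '{self.model}'; expected one of {KINETICS_MODELS}"
            )
        if self.rate_k_per_s <= 0:
            raise ConfigurationError("rate_k_per_s must be positive")
        if not (0 <= self.plateau_pct < 100):
            raise ConfigurationError("plateau_pct must lie in [0, 100)")
        if self.swell_amplitude_pct < 0:
            raise ConfigurationError("swell_amplitude_pct must be non-negative")
        if self.lag_s < 0:
            raise ConfigurationError("lag_s must be non-negative")

    @property
    def max_percent(self) -> float:
        """Largest R(t) the model can reach (sizing swollen geometry)."""
        if self.model == "swelling":
            return 100.0 + self.swell_amplitude_pct
        return 100.0


def ground_truth_percent(kinetics: KineticsModel, t_s) -> float | np.ndarray:
    """Evaluate the analytic % remaining R(t); scalar in, scalar out."""
    t = np.asarray(t_s, dtype=np.float64)
    if np.any(t < 0):
        raise ConfigurationError("t_s must be non-negative")
    dt = np.maximum(t - kinetics.lag_s, 0.0)
    decay = np.exp(-kinetics.rate_k_per_s * dt)
    if kinetics.model == "decay_to_plateau":
        r = kinetics.plateau_pct + (100.0 - kinetics.plateau_pct) * decay
    elif kinetics.model == "swelling":
        r = 100.0 + kinetics.swell_amplitude_pct * (1.0 - decay)
    else:  # biphasic
        r = (
            kinetics.plateau_pct
            + (100.0 - kinetics.plateau_pct) * decay
            - kinetics.tail_slope_pct_per_s * dt
        )
        r = np.maximum(r, 0.0)
    r = np.where(dt > 0, r, 100.0)
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class SimulationConfig:
    """Full parametric description of one synthetic assay recording.

    Defaults reflect the study conditions: 10 frames/s over 250 s, a bright
    disc (grey level 220) on a near-black vessel (grey level 15), mild
    consumer-sensor noise (sd 2 grey levels), three replicates.
    """

    frame_size_px: tuple[int, int] = (120, 120)
    tablet_center_px: tuple[float, float] = (60.0, 60.0)
    tablet_radius_px: float = 30.0
    tablet_intensity: float = 220.0
    background_intensity: float = 15.0
    noise_sd: float = 2.0
    frame_rate_hz: float = 10.0
    duration_s: float = 250.0
    kinetics: KineticsModel = field(default_factory=KineticsModel)
    seed: int = 0
    n_replicates: int = 3
    render_mode: str = "area"  # or "intensity"

    def __post_init__(self) -> None:
        if self.tablet_intensity <= self.background_intensity:
            raise ConfigurationError(
                "tablet_intensity must exceed background_intensity "
                "(white-on-black contrast)"
            )
        if not (0 <= self.background_intensity and self.tablet_intensity <= 255):
            raise ConfigurationError("intensities must lie within [0, 255]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigurationError("frame_rate_hz and duration_s must be positive")
        if self.tablet_radius_px <= 0:
            raise ConfigurationError("tablet_radius_px must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")
        if self.render_mode not in ("area", "intensity"):
            raise ConfigurationError("render_mode must be 'area' or 'intensity'")
        h, w = self.frame_size_px
        cy, cx = self.tablet_center_px
        rmax = self.max_radius_px
        if not (
            rmax <= cy <= h - rmax and rmax <= cx <= w - rmax
        ):
            raise ConfigurationError(
                f"tablet disc (max radius {rmax:.1f} px, including swelling) "
                f"does not fit inside a {h}×{w} frame at center ({cy}, {cx})"
            )

    @property
    def max_radius_px(self) -> float:
        """Largest radius the disc reaches, including swelling growth."""
        if self.render_mode == "intensity":
            return self.tablet_radius_px
        return self.tablet_radius_px * np.sqrt(self.kinetics.max_percent / 100.0)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=np.float64) / self.frame_rate_hz


def suggested_roi(config: SimulationConfig, margin_px: int = 4) -> RegionOfInterest:
    """Rectangular ROI covering the disc at its largest extent, plus a margin.

    Mirrors the laboratory practice of drawing a fixed area covering only
    the formulation.
    """
    h, w = config.frame_size_px
    cy, cx = config.tablet_center_px
    r = config.max_radius_px + margin_px
    y0, y1 = max(0, int(np.floor(cy - r))), min(h, int(np.ceil(cy + r)))
    x0, x1 = max(0, int(np.floor(cx - r))), min(w, int(np.ceil(cx + r)))
    return RegionOfInterest.from_rectangle(x0, y0, x1, y1, (h, w), name="sim-roi")


def _disc_coverage(config: SimulationConfig, radii: np.ndarray) -> np.ndarray:
    """Per-pixel disc coverage, anti-aliased, for each radius in ``radii``.

    Coverage ramps linearly across a one-pixel-wide rim, then each frame is
    rescaled so its total coverage equals the exact disc area πr². This
    keeps the rendered area — and hence the ideal ROI mean grey value —
    proportional to the ground-truth % remaining at every radius, and lets
    the disc vanish completely as r → 0 (a raw ramp would leave a
    half-covered center pixel).
    """
    h, w = config.frame_size_px
    cy, cx = config.tablet_center_px
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2).astype(np.float32)
    r = radii.astype(np.float32)[:, None, None]
    cov = np.clip(r - dist[None, :, :] + 0.5, 0.0, 1.0)
    target_area = np.pi * radii.astype(np.float64) ** 2
    raw_area = cov.sum(axis=(1, 2), dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(raw_area > 0, target_area / raw_area, 0.0)
    # the linear ramp always over-covers (by ~pi/12 px^2), so scale <= 1 and
    # no pixel exceeds full coverage after rescaling
    return cov * scale.astype(np.float32)[:, None, None]


def _rng_for(config: SimulationConfig, phase: str, replicate: int) -> np.random.Generator:
    # replicate r draws from seed+r; the phase index decorrelates the three
    # recordings of one replicate
    return np.random.default_rng([config.seed + replicate, _PHASE_CODES[phase]])


def render_sequence(
    config: SimulationConfig, phase: str, replicate: int = 0
) -> FrameSequence:
    """Render one phase of the assay as a canonical 8-bit frame sequence.

    With a fixed seed the output is bit-identical across runs. Gaussian
    noise (sd ``noise_sd``) is added per pixel, then values are clipped to
    [0, 255] and quantized to 8-bit levels.
    """
    if phase not in PHASES:
        raise ConfigurationError(f"unknown phase '{phase}'; expected one of {PHASES}")
    times = config.times_s
    n = times.size
    contrast = config.tablet_intensity - config.background_intensity

    if phase == "background":
        signal = np.full(
            (n, *config.frame_size_px), config.background_intensity, dtype=np.float32
        )
    else:
        if phase == "tablet_only":
            fractions = np.ones(n)
        else:
            fractions = np.asarray(ground_truth_percent(config.kinetics, times)) / 100.0
        if config.render_mode == "area":
            radii = config.tablet_radius_px * np.sqrt(fractions)
            cov = _disc_coverage(config, radii)
            signal = config.background_intensity + contrast * cov
        else:
            cov = _disc_coverage(
                config, np.full(n, config.tablet_radius_px)
            )
            signal = (
                config.background_intensity
                + contrast * fractions.astype(np.float32)[:, None, None] * cov
            )

    if config.noise_sd > 0:
        rng = _rng_for(config, phase, replicate)
        noise = rng.standard_normal(size=signal.shape, dtype=np.float32)
        signal = signal + np.float32(config.noise_sd) * noise
    frames = np.rint(np.clip(signal, 0.0, 255.0)).astype(np.float32)
    return FrameSequence(
        frames=frames,
        timestamps_s=times,
        frame_rate_hz=config.frame_rate_hz,
        bit_depth=8,
        source_id=f"sim:{phase}:rep{replicate}:seed{config.seed}",
    )


@dataclass(frozen=True)
class AssayBundle:
    """A complete synthetic assay: recordings plus per-frame ground truth."""

    config: SimulationConfig
    background: FrameSequence
    tablet_only: FrameSequence
    replicates: tuple[FrameSequence, ...]
    ground_truth_times_s: np.ndarray
    ground_truth_percent: np.ndarray

    @property
    def manifest(self) -> dict:
        """All parameters of the bundle, JSON-serializable."""
        cfg = dataclasses.asdict(self.config)
        cfg["frame_size_px"] = list(cfg["frame_size_px"])
        cfg["tablet_center_px"] = list(cfg["tablet_center_px"])
        return {
            "config": cfg,
            "phases": list(PHASES),
            "n_replicates": self.config.n_replicates,
            "ground_truth": {
                "time_s": self.ground_truth_times_s.tolist(),
                "percent_remaining": self.ground_truth_percent.tolist(),
            },
        }


def generate_assay(config: SimulationConfig) -> AssayBundle:
    """Generate background, intact-tablet and replicate disintegration recordings.

    Replicate ``r`` uses seed ``seed + r``, so replicates are distinct noise
    realizations of the identical ground-truth kinetics; rerunning with the
    same config reproduces the bundle bit-for-bit.
    """
    background = render_sequence(config, "background", replicate=0)
    tablet_only = render_sequence(config, "tablet_only", replicate=0)
    reps = tuple(
        render_sequence(config, "disintegration", replicate=r)
        for r in range(config.n_replicates)
    )
    times = config.times_s
    truth = np.asarray(ground_truth_percent(config.kinetics, times))
    return AssayBundle(
        config=config,
        background=background,
        tablet_only=tablet_only,
        replicates=reps,
        ground_truth_times_s=times,
        ground_truth_percent=truth,
    )
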