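"""Frame sequences: loading recordings and canonicalizing them to 8-bit grayscale.

A recording — a video of the disintegration vessel or an ordered stack of
still frames — is represented as a :class:`FrameSequence`: a 3-D array of
grayscale frames on the canonical 0–255 floating-point scale, with a
timestamp per frame derived from the nominal frame rate. Container-embedded
timestamps are ignored so that repeated loads of the same source are
bit-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import EmptyRecordingError, FormatError, InputError

__all__ = ["FrameSequence", "to_grayscale", "load_frames"]

# BT.601 luma weights: the de-facto default of common image software.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}
_VIDEO_EXTENSIONS = {".mp4", ".avi", ".mov", ".mkv", ".webm"}


@dataclass(frozen=True)
class FrameSequence:
    """Ordered grayscale frames with timestamps; the raw observable of the assay.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Grayscale intensities on the canonical 0–255 scale.
    timestamps_s : ndarray, shape (n_frames,)
        Seconds from recording start, strictly increasing, first frame at 0.
    frame_rate_hz : float
        Nominal capture rate of the *source* recording.
    bit_depth : int
        Bit depth of the source material (8 or 16).
    source_id : str
        Free-text provenance label.
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    frame_rate_hz: float
    bit_depth: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        times = np.asarray(self.timestamps_s, dtype=np.float64)
        if frames.ndim != 3:
            raise FormatError(
                f"frames must be a (n, height, width) array, got shape {frames.shape}"
            )
        if frames.shape[0] == 0:
            raise EmptyRecordingError(f"empty recording: {self.source_id or '<frames>'}")
        if times.shape != (frames.shape[0],):
            raise FormatError("timestamps_s length must equal the number of frames")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise FormatError("timestamps must be strictly increasing")
        if self.frame_rate_hz <= 0:
            raise FormatError("frame_rate_hz must be positive")
        fmin, fmax = float(frames.min()), float(frames.max())
        if fmin < 0.0 or fmax > 255.0:
            raise FormatError(
                f"canonical frames must lie in [0, 255]; got range [{fmin}, {fmax}]"
            )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps_s", times)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return float(self.timestamps_s[-1])

    def __len__(self) -> int:
        return self.n_frames


def to_grayscale(frame: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Canonicalize one frame to 2-D grayscale on the 0–255 scale.

    3-channel input is combined with BT.601 luma weights (0.299, 0.587,
    0.114); 16-bit input is linearly rescaled by 255/65535. The operation is
    idempotent: applying it to an already-canonical frame returns the frame
    unchanged.
    """
    if bit_depth not in (8, 16):
        raise FormatError(f"unsupported bit depth {bit_depth}; expected 8 or 16")
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif arr.shape[2] in (3, 4):
            arr = arr[:, :, :3] @ _LUMA_WEIGHTS
        else:
            raise FormatError(
                f"unsupported channel count {arr.shape[2]}; expected 1, 3 or 4"
            )
    elif arr.ndim != 2:
        raise FormatError(f"frame must be 2-D or 3-D, got {arr.ndim} dimensions")
    if bit_depth == 16:
        arr = arr * (255.0 / 65535.0)
    return arr


def _infer_bit_depth(arr: np.ndarray, declared: int | None) -> int:
    if declared is not None:
        return declared
    if arr.dtype == np.uint16:
        return 16
    return 8


def _read_image_file(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        return iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - backend-specific failures
        raise InputError(f"cannot read image file {path}: {exc}") from exc


def _read_stack(path: Path) -> list[np.ndarray]:
    """Read a single file that may contain one frame or a multi-page stack."""
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        try:
            data = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise InputError(f"cannot read TIFF file {path}: {exc}") from exc
        if data.ndim >= 3 and data.shape[-1] not in (1, 3, 4):
            return list(data)  # page-major stack
        if data.ndim == 4:
            return list(data)
        return [data]
    return [_read_image_file(path)]


def _read_video(path: Path) -> list[np.ndarray]:
    import imageio.v3 as iio

    try:
        return [frame for frame in iio.imiter(path)]
    except Exception as exc:  # noqa: BLE001
        raise InputError(
            f"cannot decode video {path}: {exc}. "
            "If no video backend is installed, convert the recording to an "
            "ordered PNG/TIFF frame stack first."
        ) from exc


def load_frames(
    source: str | os.PathLike | Sequence | np.ndarray,
    frame_rate_hz: float,
    decimation: int = 1,
    bit_depth: int | None = None,
    source_id: str | None = None,
) -> FrameSequence:
    """Load a recording into a canonical :class:`FrameSequence`.

    Parameters
    ----------
    source
        One of: a directory of image frames (read in lexicographic order), a
        multi-page TIFF or single image file, a video file, an ordered list
        of image-file paths, a list of arrays, or an (n, h, w[, c]) array.
    frame_rate_hz
        Nominal capture rate of the source; timestamps are
        ``frame_index / frame_rate_hz`` with the pre-decimation index, so a
        decimated sequence keeps its original time base.
    decimation
        Keep every ``decimation``-th frame, starting with the first.
    bit_depth
        Source bit depth; inferred from dtype (uint16 → 16, else 8) when None.
    """
    if frame_rate_hz <= 0:
        raise InputError("frame_rate_hz must be positive")
    if decimation < 1 or int(decimation) != decimation:
        raise InputError(f"decimation must be a positive integer, got {decimation}")
    decimation = int(decimation)

    raw: list[np.ndarray]
    label = source_id
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        label = label or str(path)
        if path.is_dir():
            files = sorted(
                p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS
            )
            if not files:
                raise EmptyRecordingError(f"no image frames found in directory {path}")
            raw = [_read_image_file(p) for p in files]
        elif path.is_file():
            if path.suffix.lower() in _VIDEO_EXTENSIONS:
                raw = _read_video(path)
            else:
                raw = _read_stack(path)
        else:
            raise InputError(f"source does not exist: {path}")
    elif isinstance(source, np.ndarray):
        if source.ndim not in (3, 4):
            raise FormatError(
                f"array source must have shape (n, h, w) or (n, h, w, c), got {source.shape}"
            )
        raw = list(source)
        label = label or "<array>"
    else:
        items = list(source)
        if items and isinstance(items[0], (str, os.PathLike)):
            raw = [_read_image_file(Path(p)) for p in items]
            label = label or f"<{len(items)} files>"
        else:
            raw = [np.asarray(item) for item in items]
            label = label or "<arrays>"

    if not raw:
        raise EmptyRecordingError(f"empty recording: {label}")

    kept_indices = range(0, len(raw), decimation)
    frames = []
    for i in kept_indices:
        arr = np.asarray(raw[i])
        frames.append(to_grayscale(arr, _infer_bit_depth(arr, bit_depth)))
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"frames have inconsistent shapes: {sorted(shapes)}")
    stack = np.stack(frames)
    timestamps = np.array([i / frame_rate_hz for i in kept_indices], dtype=np.float64)
    return FrameSequence(
        frames=stack,
        timestamps_s=timestamps,
        frame_rate_hz=frame_rate_hz,
        bit_depth=bit_depth or _infer_bit_depth(np.asarray(raw[0]), None),
        source_id=label or "",
    )
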