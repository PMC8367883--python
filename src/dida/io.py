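"""Tabular and on-disk interchange: CSV profiles, JSON records, frame stacks.

All writers are deterministic: the same in-memory objects always produce
byte-identical files, so a rerun of the pipeline on identical inputs can be
verified by comparing artifacts directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .mgv import MGVSeries, RegionOfInterest
from .profile import (
    ClassificationResult,
    ComparisonResult,
    DisintegrationProfile,
    TimepointSummary,
)
from .simulate import AssayBundle

__all__ = [
    "roi_from_spec",
    "profile_frame",
    "write_profile_csv",
    "write_summary_csv",
    "read_summary_csv",
    "classification_record",
    "comparison_record",
    "write_bundle",
    "config_hash",
]


def roi_from_spec(spec, frame_shape: tuple[int, int]) -> RegionOfInterest:
    """Build an ROI from a JSON file path, a dict, or a mask image file.

    Rectangles are given as ``{"x0":…, "y0":…, "x1":…, "y1":…}`` in 0-based,
    half-open pixel coordinates; any image file with nonzero pixels marking
    the region is accepted as a mask.
    """
    if isinstance(spec, RegionOfInterest):
        return spec
    if isinstance(spec, dict):
        rect = spec
    else:
        path = Path(spec)
        if not path.exists():
            raise InputError(f"ROI file does not exist: {path}")
        if path.suffix.lower() == ".json":
            rect = json.loads(path.read_text())
        else:
            import imageio.v3 as iio

            mask = np.asarray(iio.imread(path))
            if mask.ndim == 3:
                mask = mask[..., :3].max(axis=2)
            return RegionOfInterest(mask=mask > 0, name=path.name)
    try:
        x0, y0, x1, y1 = (int(rect[k]) for k in ("x0", "y0", "x1", "y1"))
    except KeyError as exc:
        raise InputError(f"ROI rectangle must define x0, y0, x1, y1; missing {exc}")
    return RegionOfInterest.from_rectangle(x0, y0, x1, y1, frame_shape)


def profile_frame(
    profile: DisintegrationProfile, mgv: MGVSeries | None = None
) -> pd.DataFrame:
    """Profile as a DataFrame with columns time_s, mgv, percent_remaining, flags."""
    data = {
        "time_s": profile.times_s,
        "mgv": mgv.values if mgv is not None else np.full(len(profile), np.nan),
        "percent_remaining": profile.percent_remaining,
        "flags": profile.flags,
    }
    return pd.DataFrame(data)


def write_profile_csv(
    path, profile: DisintegrationProfile, mgv: MGVSeries | None = None
) -> None:
    profile_frame(profile, mgv).to_csv(path, index=False, float_format="%.6f")


def write_summary_csv(path, summaries: Sequence[TimepointSummary]) -> None:
    df = pd.DataFrame(
        {
            "timepoint_s": [s.timepoint_s for s in summaries],
            "mean_percent": [s.mean_percent for s in summaries],
            "sd_percent": [s.sd_percent for s in summaries],
            "n": [s.n for s in summaries],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_summary_csv(path) -> list[TimepointSummary]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary file does not exist: {path}")
    df = pd.read_csv(path)
    required = {"timepoint_s", "mean_percent", "sd_percent", "n"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"summary file {path} lacks columns: {sorted(missing)}")
    return [
        TimepointSummary(
            timepoint_s=float(r.timepoint_s),
            mean_percent=float(r.mean_percent),
            sd_percent=float(r.sd_percent),
            n=int(r.n),
        )
        for r in df.itertuples()
    ]


def classification_record(result: ClassificationResult) -> dict:
    return {
        "category": result.category,
        "endpoint_time_s": result.endpoint_time_s,
        "max_percent": result.max_percent,
        "final_percent": result.final_percent,
        "thresholds": dict(result.thresholds_used),
    }


def comparison_record(result: ComparisonResult, timepoint_s: float | None = None) -> dict:
    record = {
        "t": result.t_statistic,
        "df": result.degrees_freedom,
        "p": result.p_value,
        "stars": result.significance_stars,
    }
    if timepoint_s is not None:
        record["timepoint_s"] = timepoint_s
    return record


def _dump_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def config_hash(config) -> str:
    """Stable short hash of any JSON-serializable (or dataclass) configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_stack(directory: Path, frames: np.ndarray) -> None:
    import imageio.v3 as iio

    directory.mkdir(parents=True, exist_ok=True)
    n_digits = max(5, len(str(frames.shape[0])))
    for i, frame in enumerate(frames):
        iio.imwrite(
            directory / f"frame_{i:0{n_digits}d}.png",
            np.rint(frame).astype(np.uint8),
        )


def write_bundle(bundle: AssayBundle, outdir) -> Path:
    """Write a simulated assay to disk as PNG frame stacks plus metadata.

    Layout: ``background/``, ``tablet_only/`` and ``replicate_<r>/`` frame
    directories, a ``manifest.json`` with every parameter and the per-frame
    ground truth, and ``ground_truth.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_stack(outdir / "background", bundle.background.frames)
    _write_stack(outdir / "tablet_only", bundle.tablet_only.frames)
    for r, seq in enumerate(bundle.replicates):
        _write_stack(outdir / f"replicate_{r}", seq.frames)
    _dump_json(outdir / "manifest.json", bundle.manifest)
    pd.DataFrame(
        {
            "time_s": bundle.ground_truth_times_s,
            "percent_remaining": bundle.ground_truth_percent,
        }
    ).to_csv(outdir / "ground_truth.csv", index=False, float_format="%.6f")
    return outdir


def write_json(path, obj) -> None:
    """Public deterministic JSON writer (sorted keys, trailing newline)."""
    _dump_json(path, obj)
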