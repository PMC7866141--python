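"""Format plumbing: image sequences, TIFF stacks, CSV tables, YAML configs.

Recordings are exchanged either as a directory of numbered PNG/TIFF frames
or as a single multi-page TIFF stack; tables travel as tidy CSV.  Every
command's provenance (resolved config, seed, package version) is written
next to its outputs as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .track import FrameSequence, TrackerConfig

_FRAME_EXTS = (".png", ".tif", ".tiff")


def write_frame_sequence(seq: FrameSequence, out_dir, fmt: str = "png") -> Path:
    """Write frames as a numbered image sequence ``frame_000000.png`` ..."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out_dir / f"frame_{i:06d}.{fmt}", frame)
    return out_dir


def read_frame_sequence(path, frame_rate: float) -> FrameSequence:
    """Read a recording from a frame directory or a multi-page TIFF stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS
        )
        if not files:
            raise ValueError(f"no image frames (*.png, *.tif) found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    elif path.suffix.lower() in (".tif", ".tiff"):
        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise ValueError(
            f"unsupported recording format {path.suffix!r}: use a frame "
            "directory or a multi-page TIFF stack"
        )
    return FrameSequence(frames=frames, frame_rate=frame_rate)


def write_tiff_stack(seq: FrameSequence, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(seq.frames), extension=".tif")
    return path


def load_tracker_config(path) -> TrackerConfig:
    """Tracker config from YAML/JSON; absent keys fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(TrackerConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown tracker config keys: {sorted(unknown)}")
    return TrackerConfig(**raw)


def read_cohort_csv(path) -> pd.DataFrame:
    from .stats import validate_cohort

    df = pd.read_csv(path)
    return validate_cohort(df)


def write_provenance(out_dir, seed, config: dict) -> Path:
    """Machine-readable record that makes a run reproducible."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = {"version": __version__, "seed": seed, "config": config}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(rec, indent=2, default=str))
    return path
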