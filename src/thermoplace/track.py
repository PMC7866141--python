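"""Frame-differencing tracker: which half of the two-plate arena holds the mouse.

The pipeline, per pair of consecutive frames:

1. preprocess each frame — resize, grayscale, median filter;
2. absolute pixel-wise difference, binarized at a fixed threshold, median
   filtered again to suppress isolated noise pixels;
3. count white (changed) pixels left and right of the arena midline; the
   richer side is where the animal moved.

Frame differencing is blind to a perfectly still animal, so iterations with
too little motion are classified "unknown" and later resolved by carrying
forward the last determined side — the animal cannot teleport between
plates.  Time accounting credits 1/frame_rate seconds per iteration to the
resolved side, so per-session percentages conserve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage.transform import resize as _sk_resize

from .protocol import PlatePair, colder_side

__all__ = [
    "TrackerConfig",
    "FrameSequence",
    "MotionMask",
    "OccupancySeries",
    "SessionResult",
    "TrackError",
    "preprocess",
    "difference_mask",
    "classify_iteration",
    "track_session",
]

#: Rec. 601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class TrackError(RuntimeError):
    """Raised when a recording cannot be tracked."""


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable knobs of the differencing pipeline.

    ``midline_x`` is expressed in **post-resize** pixel coordinates
    (native midline times ``resize_factor``, rounded); the half-open rule
    assigns the midline column itself to the right side.  ``tie_policy``
    governs exact left/right pixel-count ties: both available policies mark
    the iteration "unknown" at classification time; "hold" documents that
    the carry-forward pass will then keep the previous side.
    """

    resize_factor: float = 0.5
    median_kernel: int = 3
    binarize_threshold: float = 15.0
    min_motion_pixels: int = 5
    midline_x: int = 32
    tie_policy: str = "hold"
    stride: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.resize_factor <= 1.0):
            raise ValueError("resize_factor must lie in (0, 1]")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.binarize_threshold <= 0:
            raise ValueError("binarize_threshold must be positive")
        if self.min_motion_pixels < 0:
            raise ValueError("min_motion_pixels must be >= 0")
        if self.tie_policy not in ("hold", "unknown"):
            raise ValueError("tie_policy must be 'hold' or 'unknown'")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class FrameSequence:
    """Ordered grayscale (or RGB) frames plus timing.

    ``true_sides`` optionally carries simulator ground truth for
    validation; it never influences tracking.
    """

    frames: np.ndarray
    frame_rate: float
    true_sides: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (n, h, w) or (n, h, w, 3)")
        if len(self.frames) < 2:
            raise TrackError("a recording needs >= 2 frames to difference")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self.frames)) / self.frame_rate


@dataclass
class MotionMask:
    """Binary motion image with white-pixel counts per arena side."""

    mask: np.ndarray
    n_left: int
    n_right: int

    def __post_init__(self) -> None:
        uniq = np.unique(self.mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask must be strictly binary")


def preprocess(frame: np.ndarray, cfg: TrackerConfig) -> np.ndarray:
    """Resize, convert to grayscale luminance, median filter.

    Returns a float array on the 0-255 intensity scale.  Deterministic;
    with ``resize_factor == 1`` and ``median_kernel == 1`` the output equals
    the grayscale input exactly.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim == 3:
        frame = frame @ _LUMA
    elif frame.ndim != 2:
        raise ValueError(f"expected 2D or 3-channel frame, got shape {frame.shape}")
    out = frame.astype(float)
    if cfg.resize_factor != 1.0:
        h = max(int(round(out.shape[0] * cfg.resize_factor)), 1)
        w = max(int(round(out.shape[1] * cfg.resize_factor)), 1)
        out = _sk_resize(out, (h, w), anti_aliasing=True, preserve_range=True)
    if cfg.median_kernel > 1:
        out = median_filter(out, size=cfg.median_kernel, mode="nearest")
    return out


def difference_mask(
    frame_t: np.ndarray, frame_t1: np.ndarray, cfg: TrackerConfig
) -> MotionMask:
    """Binarized absolute difference of two preprocessed frames.

    Pixels whose absolute intensity change reaches ``binarize_threshold``
    become white (1); the mask is then median filtered (kernel > 1) to
    remove isolated noise, and white pixels are counted on each side of
    ``midline_x`` under the half-open rule.
    """
    if frame_t.shape != frame_t1.shape:
        raise ValueError(
            f"frame shape mismatch: {frame_t.shape} vs {frame_t1.shape}"
        )
    diff = np.abs(frame_t1.astype(float) - frame_t.astype(float))
    mask = (diff >= cfg.binarize_threshold).astype(np.uint8)
    if cfg.median_kernel > 1:
        mask = median_filter(mask, size=cfg.median_kernel, mode="nearest")
    n_left = int(mask[:, : cfg.midline_x].sum())
    n_right = int(mask[:, cfg.midline_x :].sum())
    return MotionMask(mask=mask, n_left=n_left, n_right=n_right)


def classify_iteration(mask: MotionMask, cfg: TrackerConfig) -> str:
    """Side call for one frame pair: "left", "right" or "unknown".

    The richer side wins, provided total motion reaches
    ``min_motion_pixels``; a motionless pair (stationary animal) and exact
    ties are "unknown" and left to the carry-forward pass.
    """
    total = mask.n_left + mask.n_right
    if total == 0 or total < cfg.min_motion_pixels:
        return "unknown"
    if mask.n_left > mask.n_right:
        return "left"
    if mask.n_right > mask.n_left:
        return "right"
    return "unknown"  # exact tie; resolved per tie_policy by carry-forward


@dataclass
class OccupancySeries:
    """Per-iteration tracker output, raw and after unknown-resolution."""

    t: np.ndarray
    n_left: np.ndarray
    n_right: np.ndarray
    raw_side: np.ndarray
    resolved_side: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.t)),
                "t": self.t,
                "n_left": self.n_left,
                "n_right": self.n_right,
                "raw_side": self.raw_side,
                "resolved_side": self.resolved_side,
            }
        )

    @property
    def n_unresolved(self) -> int:
        return int((self.raw_side == "unknown").sum())


@dataclass
class SessionResult:
    """Zone-occupancy summary of one tracked session."""

    seconds_left: float
    seconds_right: float
    pct_left: float
    pct_right: float
    pct_colder: float
    pct_warmer: float
    n_iterations: int
    n_unresolved_iterations: int

    def to_dict(self) -> dict:
        return {
            "seconds_left": self.seconds_left,
            "seconds_right": self.seconds_right,
            "pct_left": self.pct_left,
            "pct_right": self.pct_right,
            "pct_colder": self.pct_colder,
            "pct_warmer": self.pct_warmer,
            "n_iterations": self.n_iterations,
            "n_unresolved_iterations": self.n_unresolved_iterations,
        }


def _resolve_unknowns(raw: np.ndarray) -> np.ndarray:
    """Carry the last determined side forward; backfill leading unknowns
    from the first determined side.  Raises if nothing was ever determined."""
    known = raw != "unknown"
    if not known.any():
        raise TrackError("no motion detected in recording")
    idx = np.where(known, np.arange(len(raw)), -1)
    np.maximum.accumulate(idx, out=idx)
    first = int(np.argmax(known))
    resolved = np.where(idx >= 0, raw[np.maximum(idx, 0)], raw[first])
    return resolved


def track_session(
    frames: FrameSequence,
    cfg: TrackerConfig | None = None,
    pair: PlatePair | None = None,
) -> tuple[OccupancySeries, SessionResult]:
    """Track a full recording: one iteration per consecutive frame pair.

    Each iteration contributes ``stride / frame_rate`` seconds to its
    resolved side (the final frame opens no extra iteration), so
    ``pct_left + pct_right == 100`` exactly.  The warmer/colder orientation
    of the result comes from ``pair``; without one, those fields are NaN.
    """
    cfg = cfg or TrackerConfig()
    n = len(frames)
    pre = [preprocess(frames.frames[i], cfg) for i in range(0, n, cfg.stride)]
    if len(pre) < 2:
        raise TrackError("a recording needs >= 2 frames to difference")

    n_iter = len(pre) - 1
    n_left = np.empty(n_iter, dtype=int)
    n_right = np.empty(n_iter, dtype=int)
    raw = np.empty(n_iter, dtype=object)
    for i in range(n_iter):
        m = difference_mask(pre[i], pre[i + 1], cfg)
        n_left[i], n_right[i] = m.n_left, m.n_right
        raw[i] = classify_iteration(m, cfg)
    raw = raw.astype(str)
    resolved = _resolve_unknowns(raw)

    dt = cfg.stride / frames.frame_rate
    t = (np.arange(n_iter) + 1) * dt
    series = OccupancySeries(
        t=t, n_left=n_left, n_right=n_right, raw_side=raw, resolved_side=resolved
    )

    n_l = int((resolved == "left").sum())
    pct_left = 100.0 * n_l / n_iter
    pct_right = 100.0 - pct_left
    if pair is not None:
        cold = colder_side(pair)
        pct_colder = pct_left if cold == "left" else pct_right
    else:
        pct_colder = float("nan")
    result = SessionResult(
        seconds_left=n_l * dt,
        seconds_right=(n_iter - n_l) * dt,
        pct_left=pct_left,
        pct_right=pct_right,
        pct_colder=pct_colder,
        pct_warmer=100.0 - pct_colder if pair is not None else float("nan"),
        n_iterations=n_iter,
        n_unresolved_iterations=series.n_unresolved,
    )
    return series, result
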