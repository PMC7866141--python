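"""Experimental-design vocabulary for the two-plate thermal preference assay.

A session confronts a freely moving mouse with two adjacent plates held at
different temperatures; the standard screen walks the 0-45 degC range in nine
contiguous 5 degC pairs.  Each animal is measured at three timepoints:
before the neuropathy-inducing chemotherapeutic (``before_oxa``), after it
but before the candidate analgesic (``pre_drug``), and after the analgesic
(``post_drug``).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
import yaml

TEMP_MIN = 0.0
TEMP_MAX = 45.0

#: Session length of the standard protocol, seconds.
STANDARD_DURATION_S = 300.0

#: The nine contiguous plate-temperature pairs of the standard screen.
STANDARD_PAIRS: tuple[tuple[float, float], ...] = tuple(
    (float(t), float(t + 5)) for t in range(0, 45, 5)
)


class Timepoint(str, enum.Enum):
    """The three measurement timepoints, in temporal order."""

    BEFORE_OXA = "before_oxa"
    PRE_DRUG = "pre_drug"
    POST_DRUG = "post_drug"

    @classmethod
    def ordered(cls) -> tuple["Timepoint", ...]:
        return (cls.BEFORE_OXA, cls.PRE_DRUG, cls.POST_DRUG)


@dataclass(frozen=True)
class PlatePair:
    """Temperature configuration of one session: a left and a right plate.

    Temperatures are in degC and must lie in [0, 45]; the two plates must
    differ, otherwise the session is ill-posed (there is no colder starting
    plate and no preference to measure).
    """

    t_left: float
    t_right: float
    session_id: int = 0

    def __post_init__(self) -> None:
        for name, t in (("t_left", self.t_left), ("t_right", self.t_right)):
            if not np.isfinite(t):
                raise ValueError(f"{name} must be finite, got {t!r}")
            if not (TEMP_MIN <= t <= TEMP_MAX):
                raise ValueError(
                    f"{name}={t} outside the device range [{TEMP_MIN}, {TEMP_MAX}] degC"
                )
        if self.t_left == self.t_right:
            raise ValueError(
                f"equal plate temperatures ({self.t_left} degC) make the session "
                "ill-posed: no colder starting plate exists"
            )

    @property
    def t_cold(self) -> float:
        return min(self.t_left, self.t_right)

    @property
    def t_warm(self) -> float:
        return max(self.t_left, self.t_right)

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "t_left": self.t_left,
            "t_right": self.t_right,
        }


def colder_side(pair: PlatePair) -> str:
    """Side ("left"/"right") holding the lower temperature.

    The animal starts each session on this plate, and preference calls are
    oriented warmer/colder through it.
    """
    if pair.t_left == pair.t_right:  # defensive; PlatePair forbids this
        raise ValueError("equal plate temperatures: colder side undefined")
    return "left" if pair.t_left < pair.t_right else "right"


def warmer_side(pair: PlatePair) -> str:
    return "right" if colder_side(pair) == "left" else "left"


@dataclass(frozen=True)
class ArenaGeometry:
    """Pixel geometry of the two-plate arena as seen by the camera.

    ``midline_x`` is the column separating the plates.  Half-open
    convention: column ``c`` is "left" iff ``c < midline_x``; the midline
    column itself belongs to the right plate.
    """

    width_px: int = 128
    height_px: int = 64
    midline_x: int = 64

    def __post_init__(self) -> None:
        if not (0 < self.midline_x < self.width_px):
            raise ValueError(
                f"midline_x={self.midline_x} must lie strictly inside (0, {self.width_px})"
            )

    def side_of(self, x) -> np.ndarray:
        """Vectorized side label for pixel column(s) ``x`` (half-open rule)."""
        return np.where(np.asarray(x) < self.midline_x, "left", "right")


@dataclass
class SessionProtocol:
    """An ordered list of sessions plus shared timing parameters."""

    sessions: list[PlatePair]
    duration_s: float = STANDARD_DURATION_S
    frame_rate: float = 10.0
    habituation: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def to_dict(self) -> dict:
        return {
            "sessions": [p.to_dict() for p in self.sessions],
            "duration_s": self.duration_s,
            "frame_rate": self.frame_rate,
            "habituation": self.habituation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionProtocol":
        sessions = [
            PlatePair(
                t_left=float(s["t_left"]),
                t_right=float(s["t_right"]),
                session_id=int(s["session_id"]),
            )
            for s in d["sessions"]
        ]
        return cls(
            sessions=sessions,
            duration_s=float(d.get("duration_s", STANDARD_DURATION_S)),
            frame_rate=float(d.get("frame_rate", 10.0)),
            habituation=bool(d.get("habituation", False)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SessionProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def standard_protocol(
    randomize_sides: bool = False, seed: int | None = None
) -> SessionProtocol:
    """The standard nine-session 0-45 degC schedule.

    Without randomization the colder plate is always on the left.  With
    ``randomize_sides`` the cold plate of each session is assigned to the
    left or right by a generator seeded with ``seed``, emulating the random
    cooling/heating of either plate that prevents the animal from learning
    a fixed spatial cue.
    """
    rng = np.random.default_rng(seed)
    sessions = []
    for i, (t_lo, t_hi) in enumerate(STANDARD_PAIRS, start=1):
        if randomize_sides and rng.random() < 0.5:
            t_lo, t_hi = t_hi, t_lo
        sessions.append(PlatePair(t_left=t_lo, t_right=t_hi, session_id=i))
    return SessionProtocol(sessions=sessions, duration_s=STANDARD_DURATION_S)
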