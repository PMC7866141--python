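"""Synthetic thermotaxis data: a stochastic agent, a video renderer, a cohort generator.

No behavioral recordings ship with the package, so every downstream stage
(tracking, statistics, drug-effect calls) is validated against data from a
minimal agent model chosen to generate the three observable regimes of the
assay — preference, preference loss, preference reversal — with a single
gain parameter:

* a **comfort curve** over temperature, maximal near the murine thermal
  preferendum (~26 degC) and falling off toward 0 degC and beyond the
  heat-stress onset (~34 degC);
* **Poisson crossing attempts**: at rate ``crossing_rate`` the agent
  reconsiders its side and settles on the left plate with probability
  ``sigmoid(beta * (comfort_left - comfort_right))`` — ``beta = 0`` gives an
  unbiased coin regardless of temperatures;
* **Gaussian within-plate jitter** (an Ornstein-Uhlenbeck pull toward the
  occupied plate's center) and **Bernoulli immobility episodes** that freeze
  the animal — the failure mode frame differencing must survive;
* treatment is modelled as an :class:`EffectProfile` that rescales (or
  inverts) the gain and shifts the comfort curve per timepoint.

Everything is reproducible from a single seed via ``numpy`` seed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .protocol import (
    ArenaGeometry,
    PlatePair,
    SessionProtocol,
    Timepoint,
    colder_side,
)

__all__ = [
    "AgentParams",
    "EffectProfile",
    "Trajectory",
    "RenderConfig",
    "comfort",
    "simulate_trajectory",
    "render_frames",
    "simulate_cohort",
    "identity_effects",
    "oxaliplatin_profile",
    "duloxetine_effects",
    "pregabalin_effects",
]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the thermotaxis agent.

    comfort_optimum / comfort_width
        Center and scale (degC) of the quadratic comfort curve; defaults put
        the optimum at 26 degC, inside the 22-30 degC murine preferendum.
    heat_stress_onset / heat_stress_gain
        Above the onset (34 degC) an extra quadratic penalty steepens the
        decline, modelling heat-stress avoidance.
    beta
        Dimensionless preference gain (>= 0): 0 means no thermal bias, larger
        values sharpen the side choice.
    crossing_rate
        Poisson rate (events/s) of side reconsiderations.
    immobility_prob / immobility_block_s
        Per-block probability of a complete-immobility episode and the block
        length in seconds.
    step_sd / home_pull
        Within-plate jitter: Gaussian step (px/frame) and pull strength
        toward the occupied plate's center per frame.
    """

    comfort_optimum: float = 26.0
    comfort_width: float = 8.0
    heat_stress_onset: float = 34.0
    heat_stress_gain: float = 1.0
    beta: float = 3.0
    crossing_rate: float = 0.1
    immobility_prob: float = 0.1
    immobility_block_s: float = 10.0
    step_sd: float = 1.5
    home_pull: float = 0.15

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (0.0 <= self.immobility_prob <= 1.0):
            raise ValueError("immobility_prob must lie in [0, 1]")
        if self.crossing_rate <= 0:
            raise ValueError("crossing_rate must be positive")
        if self.comfort_width <= 0:
            raise ValueError("comfort_width must be positive")


def comfort(temp, params: AgentParams):
    """Comfort score (real, unitless) of ambient temperature ``temp``.

    A concave bump: negative quadratic around ``comfort_optimum`` plus an
    extra quadratic penalty beyond ``heat_stress_onset``.  Maximal at the
    optimum, strictly decreasing toward 0 degC and beyond the onset; the
    *differences* of this score drive the side choice.
    """
    t = np.asarray(temp, dtype=float)
    z = (t - params.comfort_optimum) / params.comfort_width
    base = -0.5 * z**2
    over = np.maximum(t - params.heat_stress_onset, 0.0) / params.comfort_width
    out = base - params.heat_stress_gain * over**2
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EffectProfile:
    """Treatment modifiers applied to the agent at one timepoint.

    ``beta_scale`` multiplies the gain globally; ``band_scales`` is a tuple
    of ``(t_lo, t_hi, scale)`` entries whose scale composes with it
    (multiplicatively) whenever the session's pair of temperatures lies
    inside ``[t_lo, t_hi]`` — a band scale of 0 abolishes the thermal bias
    there (preference loss), a negative one inverts the current state's
    bias (preference reversal).  ``optimum_shift``
    (degC) and ``width_scale`` deform the comfort curve, e.g. cold
    hypersensitivity as a warm-shifted optimum.  The default instance is the
    identity.
    """

    beta_scale: float = 1.0
    band_scales: tuple[tuple[float, float, float], ...] = ()
    optimum_shift: float = 0.0
    width_scale: float = 1.0

    def is_identity(self) -> bool:
        return (
            self.beta_scale == 1.0
            and not self.band_scales
            and self.optimum_shift == 0.0
            and self.width_scale == 1.0
        )

    def apply(self, agent: AgentParams, pair: PlatePair) -> tuple[AgentParams, float]:
        """(shaped agent, signed effective gain) in effect for ``pair``.

        The comfort-curve deformation lands in the returned agent; the gain
        is returned separately because a negative scale (reversal) makes it
        signed, whereas the agent's base ``beta`` is a magnitude.
        """
        scale = self.beta_scale
        for t_lo, t_hi, s in self.band_scales:
            if t_lo <= pair.t_cold and pair.t_warm <= t_hi:
                scale *= s
                break
        shaped = replace(
            agent,
            comfort_optimum=agent.comfort_optimum + self.optimum_shift,
            comfort_width=agent.comfort_width * self.width_scale,
        )
        return shaped, agent.beta * scale


def identity_effects() -> dict[Timepoint, EffectProfile]:
    """No treatment effect at any timepoint."""
    return {tp: EffectProfile() for tp in Timepoint.ordered()}


def oxaliplatin_profile() -> EffectProfile:
    """Cold-hypersensitive state after the chemotherapeutic.

    Modelled as a warm-shifted comfort optimum (preferred temperature moves
    to ~30 degC) plus a sharpened gain: cold plates become more aversive,
    giving the neuropathic animal a clear warm preference throughout the
    0-30 degC pairs and a cold preference above the heat-stress onset.
    """
    return EffectProfile(beta_scale=1.5, optimum_shift=4.0)


def _with_oxa(band_scales: tuple[tuple[float, float, float], ...]) -> EffectProfile:
    oxa = oxaliplatin_profile()
    return replace(oxa, band_scales=band_scales)


def duloxetine_effects() -> dict[Timepoint, EffectProfile]:
    """Temperature-selective analgesic: bias abolished at 0-5 degC, inverted
    at 5-10 degC, untouched at 10-20 degC (the neuropathic state persists)."""
    return {
        Timepoint.BEFORE_OXA: EffectProfile(),
        Timepoint.PRE_DRUG: oxaliplatin_profile(),
        Timepoint.POST_DRUG: _with_oxa(((0.0, 5.0, 0.0), (5.0, 10.0, -1.0))),
    }


def pregabalin_effects() -> dict[Timepoint, EffectProfile]:
    """Broad-band analgesic: bias abolished at 0-5 degC and inverted across
    5-30 degC."""
    return {
        Timepoint.BEFORE_OXA: EffectProfile(),
        Timepoint.PRE_DRUG: oxaliplatin_profile(),
        Timepoint.POST_DRUG: _with_oxa(((0.0, 5.0, 0.0), (5.0, 30.0, -1.0))),
    }


# ---------------------------------------------------------------------------
# Occupancy process
# ---------------------------------------------------------------------------


def _side_choice_prob_left(pair: PlatePair, agent: AgentParams, gain: float) -> float:
    """P(settle on the left plate) at a crossing attempt."""
    dc = comfort(pair.t_left, agent) - comfort(pair.t_right, agent)
    return float(1.0 / (1.0 + np.exp(-gain * dc)))


def _immobile_frames(
    n_frames: int, frame_rate: float, agent: AgentParams, rng: np.random.Generator
) -> np.ndarray:
    """Boolean per-frame immobility mask from Bernoulli 10-s blocks."""
    block = max(int(round(agent.immobility_block_s * frame_rate)), 1)
    n_blocks = -(-n_frames // block)
    frozen = rng.random(n_blocks) < agent.immobility_prob
    return np.repeat(frozen, block)[:n_frames]


def _occupancy_frames(
    pair: PlatePair,
    agent: AgentParams,
    gain: float,
    rng: np.random.Generator,
    duration_s: float,
    frame_rate: float,
    start_side: str = "colder",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame target side (0=left, 1=right) and immobility mask.

    The side only changes at Poisson crossing attempts; attempts falling in
    an immobility block are suppressed.  ``start_side`` is "colder" (the
    protocol's rule: the animal is placed on the colder plate) or "random"
    (a fair coin — the start-neutral variant used for null calibration,
    since the colder start alone biases occupancy toward the cold plate).
    """
    n_frames = int(round(duration_s * frame_rate))
    immobile = _immobile_frames(n_frames, frame_rate, agent, rng)
    p_left = _side_choice_prob_left(pair, agent, gain)

    n_attempts = rng.poisson(agent.crossing_rate * duration_s)
    attempt_t = np.sort(rng.uniform(0.0, duration_s, size=n_attempts))
    choices = (rng.random(n_attempts) >= p_left).astype(np.int8)  # 1 = right

    frame_t = np.arange(n_frames) / frame_rate
    # drop attempts during immobility
    if n_attempts:
        att_frame = np.minimum((attempt_t * frame_rate).astype(int), n_frames - 1)
        keep = ~immobile[att_frame]
        attempt_t, choices = attempt_t[keep], choices[keep]

    if start_side == "colder":
        start = np.int8(0 if colder_side(pair) == "left" else 1)
    elif start_side == "random":
        start = np.int8(rng.integers(0, 2))
    else:
        raise ValueError("start_side must be 'colder' or 'random'")
    side_after = np.concatenate(([start], choices))
    idx = np.searchsorted(attempt_t, frame_t, side="right")
    return side_after[idx], immobile


# ---------------------------------------------------------------------------
# Trajectory + rendering
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Ground-truth path of the agent: per-frame blob center and side."""

    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    arena: ArenaGeometry
    pair: PlatePair

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self.x)) / self.frame_rate

    @property
    def sides(self) -> np.ndarray:
        """True side labels under the half-open midline rule."""
        return self.arena.side_of(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.x)),
                "t": self.timestamps,
                "x": self.x,
                "y": self.y,
                "true_side": self.sides,
            }
        )


def simulate_trajectory(
    pair: PlatePair,
    agent: AgentParams,
    effect: EffectProfile | None = None,
    timepoint: Timepoint = Timepoint.BEFORE_OXA,
    duration_s: float = 300.0,
    frame_rate: float = 10.0,
    arena: ArenaGeometry | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> Trajectory:
    """Simulate one session's continuous path, starting on the colder plate.

    The occupancy (which plate the agent heads for) follows the Poisson
    crossing process; within a plate the position is an OU-style jitter
    around the plate center, and immobility blocks freeze it.  Fully
    reproducible from ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if arena is None:
        arena = ArenaGeometry()
    eff_agent, gain = (effect or EffectProfile()).apply(agent, pair)
    rng = np.random.default_rng(seed)

    target, immobile = _occupancy_frames(
        pair, eff_agent, gain, rng, duration_s, frame_rate
    )
    n = len(target)
    half_l = 0.5 * arena.midline_x
    half_r = 0.5 * (arena.midline_x + arena.width_px)
    home_x = np.where(target == 0, half_l, half_r)
    home_y = 0.5 * arena.height_px

    steps = rng.normal(0.0, eff_agent.step_sd, size=(n, 2))
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = home_x[0], home_y
    k = eff_agent.home_pull
    for i in range(1, n):
        if immobile[i]:
            x[i], y[i] = x[i - 1], y[i - 1]
            continue
        x[i] = x[i - 1] + k * (home_x[i] - x[i - 1]) + steps[i, 0]
        y[i] = y[i - 1] + k * (home_y - y[i - 1]) + steps[i, 1]
    margin = 6.0  # keep a default-size blob inside the frame
    np.clip(x, margin, arena.width_px - 1 - margin, out=x)
    np.clip(y, margin, arena.height_px - 1 - margin, out=y)
    return Trajectory(x=x, y=y, frame_rate=frame_rate, arena=arena, pair=pair)


@dataclass(frozen=True)
class RenderConfig:
    """How a trajectory is drawn into noisy grayscale frames.

    The blob must be darker than both plate backgrounds so that frame
    differencing can see it.  Illumination drift is a slow global sinusoid;
    its frame-to-frame increment stays far below the binarization threshold.
    """

    width_px: int = 128
    height_px: int = 64
    blob_radius: float = 5.0
    blob_intensity: float = 40.0
    bg_left: float = 175.0
    bg_right: float = 185.0
    noise_sd: float = 3.0
    drift_amplitude: float = 4.0
    drift_period_s: float = 60.0
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.blob_intensity >= min(self.bg_left, self.bg_right):
            raise ValueError("blob must be darker than both plate backgrounds")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


def render_frames(
    traj: Trajectory,
    cfg: RenderConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
):
    """Render a trajectory into a :class:`~thermoplace.track.FrameSequence`.

    One frame per trajectory point: plate backgrounds, a dark disk at the
    blob center, seeded Gaussian sensor noise, and optional slow
    illumination drift.  Ground-truth side labels ride along on the
    returned sequence.  Raises if the blob would leave the image.
    """
    from .track import FrameSequence  # local import to avoid a cycle

    cfg = cfg or RenderConfig()
    rng = np.random.default_rng(seed)
    h, w, r = cfg.height_px, cfg.width_px, cfg.blob_radius
    if (
        traj.x.min() < r
        or traj.x.max() > w - 1 - r
        or traj.y.min() < r
        or traj.y.max() > h - 1 - r
    ):
        raise ValueError("trajectory places the blob (partly) out of image bounds")

    mid = traj.arena.midline_x
    background = np.empty((h, w), dtype=float)
    background[:, :mid] = cfg.bg_left
    background[:, mid:] = cfg.bg_right

    yy, xx = np.mgrid[0:h, 0:w]
    n = len(traj)
    t = traj.timestamps
    drift = (
        cfg.drift_amplitude * np.sin(2 * np.pi * t / cfg.drift_period_s)
        if cfg.drift_amplitude
        else np.zeros(n)
    )
    frames = np.empty((n, h, w), dtype=np.uint8)
    for i in range(n):
        img = background.copy()
        disk = (xx - traj.x[i]) ** 2 + (yy - traj.y[i]) ** 2 <= r**2
        img[disk] = cfg.blob_intensity
        img += drift[i]
        if cfg.noise_sd:
            img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameSequence(
        frames=frames, frame_rate=cfg.frame_rate, true_sides=traj.sides
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _jitter_agent(
    agent: AgentParams, rng: np.random.Generator, beta_jitter_sd: float, optimum_jitter_sd: float
) -> AgentParams:
    """Per-subject biological variation: lognormal gain, Gaussian optimum."""
    return replace(
        agent,
        beta=agent.beta * float(np.exp(rng.normal(0.0, beta_jitter_sd))),
        comfort_optimum=agent.comfort_optimum + float(rng.normal(0.0, optimum_jitter_sd)),
    )


def simulate_cohort(
    n_subjects: int,
    protocol: SessionProtocol,
    agent: AgentParams | None = None,
    effects: dict[Timepoint, EffectProfile] | None = None,
    seed: int | np.random.SeedSequence | None = None,
    frame_rate: float = 10.0,
    beta_jitter_sd: float = 0.2,
    optimum_jitter_sd: float = 1.0,
    spatial: bool = False,
    start_side: str = "colder",
) -> pd.DataFrame:
    """Simulate a cohort: % time per plate per subject x session x timepoint.

    Occupancy is drawn from the same crossing process that drives
    :func:`simulate_trajectory`, discretized to frames so that per-session
    times conserve exactly (``pct_colder + pct_warmer == 100``).  With
    ``spatial=True`` the full spatial path is simulated instead and sides
    are read off blob positions — slower, used for cross-validation.
    Per-subject parameter jitter models biological variation; each
    subject's random stream is spawned deterministically from ``seed``.

    Returns a tidy frame with columns ``subject``, ``session_id``,
    ``timepoint``, ``t_left``, ``t_right``, ``t_cold``, ``t_warm``,
    ``pct_left``, ``pct_colder``, ``pct_warmer``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a cohort")
    agent = agent or AgentParams()
    effects = effects or identity_effects()
    root = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence
    ) else seed
    subject_seeds = root.spawn(n_subjects)

    rows = []
    for s_idx, sseq in enumerate(subject_seeds, start=1):
        streams = sseq.spawn(len(protocol.sessions) * len(Timepoint) + 1)
        jit_rng = np.random.default_rng(streams[0])
        subj_agent = _jitter_agent(agent, jit_rng, beta_jitter_sd, optimum_jitter_sd)
        k = 1
        for pair in protocol.sessions:
            for tp in Timepoint.ordered():
                eff = effects.get(tp, EffectProfile())
                if spatial:
                    traj = simulate_trajectory(
                        pair,
                        subj_agent,
                        eff,
                        tp,
                        duration_s=protocol.duration_s,
                        frame_rate=frame_rate,
                        seed=streams[k],
                    )
                    sides = (traj.sides == "right").astype(np.int8)
                else:
                    rng = np.random.default_rng(streams[k])
                    shaped, gain = eff.apply(subj_agent, pair)
                    sides, _ = _occupancy_frames(
                        pair,
                        shaped,
                        gain,
                        rng,
                        protocol.duration_s,
                        frame_rate,
                        start_side=start_side,
                    )
                k += 1
                n_frames = len(sides)
                n_right = int(sides.sum())
                pct_left = 100.0 * (n_frames - n_right) / n_frames
                pct_cold = pct_left if colder_side(pair) == "left" else 100.0 - pct_left
                rows.append(
                    {
                        "subject": s_idx,
                        "session_id": pair.session_id,
                        "timepoint": tp.value,
                        "t_left": pair.t_left,
                        "t_right": pair.t_right,
                        "t_cold": pair.t_cold,
                        "t_warm": pair.t_warm,
                        "pct_left": pct_left,
                        "pct_colder": pct_cold,
                        "pct_warmer": 100.0 - pct_cold,
                    }
                )
    return pd.DataFrame(rows)
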