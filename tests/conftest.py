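import numpy as np
import pytest

import thermoplace as tp


@pytest.fixture
def pair05() -> tp.PlatePair:
    return tp.PlatePair(t_left=0.0, t_right=5.0, session_id=1)


@pytest.fixture
def default_agent() -> tp.AgentParams:
    return tp.AgentParams()


@pytest.fixture
def small_render() -> tp.RenderConfig:
    """Noise-free, drift-free renderer for exact-arithmetic tests."""
    return tp.RenderConfig(noise_sd=0.0, drift_amplitude=0.0)


@pytest.fixture
def short_video(pair05, default_agent):
    """A 30 s default-render recording with ground truth attached."""
    traj = tp.simulate_trajectory(pair05, default_agent, duration_s=30.0, seed=11)
    return traj, tp.render_frames(traj, seed=12)


@pytest.fixture
def make_frames():
    """Factory: frames for a hand-built list of (x, y) blob centers."""

    def _make(positions, *, arena=None, render=None, seed=None):
        arena = arena or tp.ArenaGeometry()
        render = render or tp.RenderConfig(noise_sd=0.0, drift_amplitude=0.0)
        xs = np.array([p[0] for p in positions], dtype=float)
        ys = np.array([p[1] for p in positions], dtype=float)
        traj = tp.Trajectory(
            x=xs,
            y=ys,
            frame_rate=render.frame_rate,
            arena=arena,
            pair=tp.PlatePair(0.0, 5.0, 1),
        )
        return traj, tp.render_frames(traj, render, seed=seed)

    return _make
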