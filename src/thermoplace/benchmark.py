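"""Validation benchmarks: tracker-vs-truth and statistical calibration.

These routines run the full pipeline on synthetic data with known ground
truth and summarize how well each stage performs: per-iteration tracking
agreement, occupancy-percentage error, Type-I error of the plate test on
null cohorts, and recovery of the lost/reversed/maintained call pattern
under the built-in drug profiles.  They are what the test suite asserts
against and what the reproduction script reports.
"""

from __future__ import annotations

import numpy as np

from .protocol import ArenaGeometry, PlatePair, Timepoint, standard_protocol
from .simulate import (
    AgentParams,
    RenderConfig,
    Trajectory,
    duloxetine_effects,
    pregabalin_effects,
    render_frames,
    simulate_cohort,
    simulate_trajectory,
)
from .stats import call_drug_effect, call_preference, tukey_pairwise
from .track import TrackerConfig, track_session

__all__ = [
    "tracker_benchmark",
    "noise_free_benchmark",
    "stationary_fallback_benchmark",
    "null_calibration",
    "drug_pattern_recovery",
]


def tracker_benchmark(
    n_videos: int = 10,
    duration_s: float = 300.0,
    seed: int = 0,
) -> dict:
    """Track ``n_videos`` default-render synthetic sessions against truth.

    Videos cycle through the standard protocol's temperature pairs; each is
    rendered at 64x128 px, 10 fps with default noise and drift, tracked
    with the default configuration, and compared per iteration with the
    simulator's ground-truth side labels.

    Returns min/mean agreement and the worst absolute error of the
    colder-plate percentage (percentage points).
    """
    protocol = standard_protocol()
    root = np.random.SeedSequence(seed)
    agreements, pct_errors = [], []
    for i, sub_seed in enumerate(root.spawn(n_videos)):
        pair = protocol.sessions[i % len(protocol.sessions)]
        s_traj, s_render = sub_seed.spawn(2)
        traj = simulate_trajectory(
            pair, AgentParams(), duration_s=duration_s, seed=s_traj
        )
        seq = render_frames(traj, RenderConfig(), seed=s_render)
        series, res = track_session(seq, TrackerConfig(), pair)
        truth = traj.sides[1:]  # iteration i spans frames (i, i+1)
        agreements.append(float((series.resolved_side == truth).mean()))
        truth_pct_cold = 100.0 * (truth == ("left" if pair.t_left < pair.t_right else "right")).mean()
        pct_errors.append(abs(res.pct_colder - truth_pct_cold))
    return {
        "n_videos": n_videos,
        "agreement_min": min(agreements),
        "agreement_mean": float(np.mean(agreements)),
        "pct_colder_abs_error_max": max(pct_errors),
        "pct_colder_abs_error_mean": float(np.mean(pct_errors)),
    }


def noise_free_benchmark(duration_s: float = 30.0) -> dict:
    """Exact-arithmetic check: zero noise, no filtering, always-moving blob.

    A triangle-wave path sweeps the blob back and forth across the arena at
    2 px/frame.  With zero render noise and kernel 1 the tracked side must
    equal the true side on every iteration where the blob stays fully on
    one side of the midline in both frames.
    """
    render = RenderConfig(noise_sd=0.0, drift_amplitude=0.0)
    n = int(round(duration_s * render.frame_rate))
    lo, hi, step = 24.0, 104.0, 2.0
    span = hi - lo
    saw = (np.arange(n) * step) % (2 * span)
    x = lo + np.where(saw < span, saw, 2 * span - saw)
    traj = Trajectory(
        x=x,
        y=np.full(n, 32.0),
        frame_rate=render.frame_rate,
        arena=ArenaGeometry(),
        pair=PlatePair(0.0, 5.0, 1),
    )
    seq = render_frames(traj, render)
    cfg = TrackerConfig(
        resize_factor=1.0, median_kernel=1, min_motion_pixels=1, midline_x=64
    )
    series, _ = track_session(seq, cfg, traj.pair)
    clear = np.abs(traj.x - 64.0) > render.blob_radius + 1
    same = traj.sides[:-1] == traj.sides[1:]
    check = clear[:-1] & clear[1:] & same
    agree = series.resolved_side[check] == traj.sides[1:][check]
    return {
        "n_checked_iterations": int(check.sum()),
        "agreement": float(agree.mean()),
    }


def stationary_fallback_benchmark(duration_s: float = 300.0) -> dict:
    """Blob jitters on the left for 10 s, then freezes for the remainder.

    The carry-forward rule must credit nearly the whole session to the
    left plate despite the differencing signal vanishing.
    """
    render = RenderConfig()
    fr = render.frame_rate
    n_move = int(10 * fr)
    n_total = int(duration_s * fr)
    x = np.full(n_total, 30.0)
    x[:n_move] += 3.0 * (np.arange(n_move) % 2)  # guaranteed motion
    traj = Trajectory(
        x=x,
        y=np.full(n_total, 32.0),
        frame_rate=fr,
        arena=ArenaGeometry(),
        pair=PlatePair(0.0, 5.0, 1),
    )
    seq = render_frames(traj, render, seed=99)
    _, res = track_session(seq, TrackerConfig(), traj.pair)
    return {"pct_left": res.pct_left, "n_unresolved": res.n_unresolved_iterations}


def null_calibration(
    n_cohorts: int = 500,
    n_subjects: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the plate-vs-plate test on gain-zero cohorts.

    The agent has no thermal bias and its start side is randomized (the
    protocol's start-on-colder rule alone biases occupancy, so the
    calibration null must neutralize it).  Counts rejections of the plate
    contrast over every session x timepoint cell.
    """
    protocol = standard_protocol()
    agent = AgentParams(beta=0.0)
    root = np.random.SeedSequence(seed)
    rej = 0
    n_tests = 0
    for sub_seed in root.spawn(n_cohorts):
        coh = simulate_cohort(
            n_subjects, protocol, agent=agent, seed=sub_seed, start_side="random"
        )
        for pair in protocol.sessions:
            fam = tukey_pairwise(coh, pair.session_id, family="plate")
            rej += int((fam["p_adj"] < alpha).sum())
            n_tests += len(fam)
    return {
        "n_cohorts": n_cohorts,
        "n_tests": n_tests,
        "rejection_rate": rej / n_tests,
    }


def drug_pattern_recovery(
    n_cohorts: int = 200,
    n_subjects: int = 10,
    seed: int = 0,
) -> dict:
    """How often the pipeline recovers each drug profile's call pattern.

    Simulates cohorts under the temperature-selective (duloxetine-like) and
    broad-band (pregabalin-like) profiles and records, per session of
    interest, the fraction of cohorts in which the expected category is
    called: loss at 0-5 degC and reversal at 5-10 degC with preference
    maintained at 10-20 degC for the selective drug; reversal across the
    5-30 degC band for the broad one.
    """
    protocol = standard_protocol()
    expectations = {
        "duloxetine": (duloxetine_effects(), {1: "lost", 2: "reversed", 3: "maintained", 4: "maintained"}),
        "pregabalin": (pregabalin_effects(), {2: "reversed", 3: "reversed", 4: "reversed", 5: "reversed", 6: "reversed"}),
    }
    root = np.random.SeedSequence(seed)
    out: dict = {}
    for (name, (effects, expected)), drug_seed in zip(
        expectations.items(), root.spawn(len(expectations))
    ):
        hits = {s: 0 for s in expected}
        for sub_seed in drug_seed.spawn(n_cohorts):
            coh = simulate_cohort(n_subjects, protocol, effects=effects, seed=sub_seed)
            for session_id, want in expected.items():
                pre = call_preference(coh, session_id, Timepoint.PRE_DRUG)
                post = call_preference(coh, session_id, Timepoint.POST_DRUG)
                if call_drug_effect(pre, post).category == want:
                    hits[session_id] += 1
        out[name] = {
            "n_cohorts": n_cohorts,
            "expected": expected,
            "rates": {s: hits[s] / n_cohorts for s in expected},
        }
    return out
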