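import numpy as np
import pytest

from codecide import SimConfig, default_profiles, simulate_session
from codecide.data_model import ArenaGeometry


@pytest.fixture(scope="session")
def geometry():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def small_session():
    """16-trial, 3-participant simulated session at 50 Hz (fast to build)."""
    config = SimConfig(group_size=3, n_trials=16, sample_rate=50.0, seed=11)
    return simulate_session(config, session_id="fix-small")


@pytest.fixture(scope="session")
def pair_session():
    """2-participant session (relative series are exact negations)."""
    config = SimConfig(group_size=2, n_trials=16, sample_rate=50.0, seed=13)
    return simulate_session(config, session_id="fix-pair")


@pytest.fixture(scope="session")
def small_corpus():
    """Six short sessions, two per group size, at 50 Hz."""
    sessions = []
    for i, size in enumerate([2, 2, 3, 3, 4, 4]):
        config = SimConfig(group_size=size, n_trials=16, sample_rate=50.0,
                           training=i % 2, seed=50 + i)
        sessions.append(simulate_session(config, session_id=f"fix-{i:02d}"))
    return sessions


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_straight_session(speeds, answers, geometry=None, sample_rate=100.0,
                          session_id="straight"):
    """Deterministic straight-line session for closed-form oracles.

    Every agent moves noise-free toward its private answer; useful when a
    test needs exact kinematics.  ``speeds`` maps to confidence via
    speed = speed_gain * confidence with speed_gain = 1, i.e. confidence is
    clipped to 1..4 but speeds beyond that should be supplied via repeated
    agents instead.
    """
    import dataclasses

    from codecide.synthetic import AgentProfile, SimConfig, simulate_trial
    from codecide.data_model import Session, TrialRecord

    n = len(speeds)
    config = SimConfig(group_size=n, sample_rate=sample_rate,
                       social_weight=0.0, majority_bonus=0.0)
    profiles = [AgentProfile(speed_gain=s, motor_noise_sd=0.0)
                for s in speeds]
    rng = np.random.default_rng(0)
    pairs = [(a, 1) for a in answers]  # confidence 1 -> speed = speed_gain
    trajs, cons, cons_t = simulate_trial(config, profiles, pairs, rng)
    pids = [f"p{i+1}" for i in range(n)]
    trial = TrialRecord(session_id=session_id, trial_index=1, difficulty=1,
                        correct_target=answers[0], training=0,
                        private_answer=dict(zip(pids, answers)),
                        confidence={p: 1 for p in pids},
                        consensus_target=cons, consensus_time=cons_t)
    return Session(session_id, n, config.geometry, [trial],
                   {(1, p): tr for p, tr in zip(pids, trajs)},
                   participants=pids)
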