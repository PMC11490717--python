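"""Agent-based generator of group-decision sessions.

The generator emulates the statistical structure the downstream analysis
assumes: groups of 2-4 agents each privately pick one of four targets with a
difficulty-dependent probability of being correct, attach a 1-4 confidence
rating with above-chance metacognitive sensitivity, and then drag avatars
across a shared square arena until everyone rests at one target.

Behavioral couplings built in (each one a signature the analysis should
detect):

* accuracy decreases with stimulus difficulty;
* confidence ratings separate correct from incorrect answers (second-order
  area under the ROC around 0.6 at the default meta noise);
* movement speed increases with confidence;
* an agent facing opposition revises its goal with a hazard that grows with
  the number of agents at a common other target and shrinks with its own
  confidence and persistence, so minorities that do prevail take longer.

It is a behavioral mimic, not a cognitive-process model: there is no
evidence accumulation and no haptic coupling between agents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtri

from .data_model import ArenaGeometry, Session, TrialRecord, Trajectory

__all__ = [
    "AgentProfile",
    "SimConfig",
    "default_profiles",
    "draw_private_answers",
    "simulate_trial",
    "simulate_session",
    "simulate_corpus",
    "STUDY_GROUP_COUNTS",
]

#: Retained sessions per group size (2, 3, 4) in the study the generator
#: emulates.
STUDY_GROUP_COUNTS = {2: 17, 3: 14, 4: 13}

#: Latent evidence separation between correct and incorrect answers; the
#: confidence model only depends on the ratio separation / meta_noise.
_EVIDENCE_SEPARATION = 1.0

#: Competence shift for sessions run after the other (discarded) task
#: condition, i.e. with prior practice.
TRAINING_COMPETENCE_BOOST = 0.04


@dataclass(frozen=True)
class AgentProfile:
    """Behavioral parameters of one simulated participant.

    competence
        Probability of a correct private answer at each difficulty 1-4.
    meta_noise
        SD of the latent evidence signal that confidence ratings discretize;
        larger values blur the correct/incorrect separation (Aroc -> 0.5 as
        meta_noise -> inf, -> 1 as meta_noise -> 0).  The default population
        value 2.6 puts the explicit Aroc near 0.6.
    speed_gain
        cm/s of movement speed per confidence unit.
    persistence
        Scales down the goal-revision hazard; confident, persistent agents
        hold their opinion longer.
    motor_noise_sd
        SD (cm/s) of speed jitter added per sample.
    """

    competence: tuple[float, float, float, float] = (0.72, 0.66, 0.60, 0.54)
    meta_noise: float = 2.6
    speed_gain: float = 2.0
    persistence: float = 1.0
    motor_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        comp = np.asarray(self.competence, float)
        if comp.shape != (4,):
            raise ValueError("competence needs one probability per difficulty 1-4")
        if np.any(comp < 0.25) or np.any(comp > 1.0):
            raise ValueError("competence probabilities must lie in [0.25, 1]")
        if self.speed_gain < 0:
            raise ValueError("speed_gain must be >= 0")
        if not self.persistence > 0:
            raise ValueError("persistence must be > 0")
        if self.meta_noise < 0 or self.motor_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study-level design parameters of one simulated session."""

    group_size: int = 3
    n_trials: int = 64
    n_difficulties: int = 4
    difficulty_schedule: str = "balanced"  # or "uniform"
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)
    sample_rate: float = 100.0  # Hz
    max_trial_duration: float = 15.0  # s
    social_weight: float = 0.7  # hazard (1/s) per opposing agent per confidence-deficit unit
    majority_bonus: float = 3.0  # hazard multiplier when opposers hold a strict majority
    arrival_weight: float = 0.1  # pull of an opposer still traveling, relative to one at its target
    training: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.group_size <= 4:
            raise ValueError("group_size must be 2..4")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if self.difficulty_schedule == "balanced" and \
                self.n_trials % self.n_difficulties != 0:
            raise ValueError("balanced schedule needs n_trials divisible by "
                             "the number of difficulty levels")
        for name in ("max_trial_duration", "social_weight", "majority_bonus",
                     "arrival_weight"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = ArenaGeometry.from_dict(d["geometry"])
        return cls(**d)


def default_profiles(group_size: int, rng: np.random.Generator,
                     competence_spread: float = 0.08) -> list[AgentProfile]:
    """Draw a heterogeneous group from the default population.

    Per-agent competence is the population curve shifted by a clipped
    Gaussian offset so that groups contain better and worse members (the
    spread drives the best-individual and average-accuracy analyses).
    """
    base = np.asarray(AgentProfile().competence)
    profiles = []
    for _ in range(group_size):
        offset = rng.normal(0.0, competence_spread)
        comp = np.clip(base + offset, 0.25, 1.0)
        profiles.append(AgentProfile(
            competence=tuple(comp),
            persistence=float(np.exp(rng.normal(0.0, 0.2))),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Private answers and confidence
# ---------------------------------------------------------------------------

def draw_private_answers(profiles: Sequence[AgentProfile], difficulty: int,
                         correct_target: int, rng: np.random.Generator,
                         ) -> list[tuple[int, int]]:
    """Draw one (answer, confidence) pair per agent.

    The answer equals ``correct_target`` with probability
    ``competence[difficulty-1]`` and is uniform over the other three targets
    otherwise.  Confidence discretizes a latent evidence signal centered at
    +s/2 for correct and -s/2 for incorrect answers with SD ``meta_noise``;
    the three cutpoints are the marginal-distribution quartiles, so ratings
    are roughly uniform and the correct/incorrect overlap (hence the Aroc)
    is controlled by meta_noise alone.
    """
    if not 1 <= difficulty <= 4:
        raise ValueError("difficulty must be 1..4")
    out = []
    half = _EVIDENCE_SEPARATION / 2
    for prof in profiles:
        p = prof.competence[difficulty - 1]
        correct = rng.random() < p
        if correct:
            answer = correct_target
        else:
            others = [k for k in range(1, 5) if k != correct_target]
            answer = int(rng.choice(others))
        evidence = (half if correct else -half) + rng.normal(0.0, prof.meta_noise)
        scale = np.sqrt(prof.meta_noise ** 2 + half ** 2)
        cuts = scale * ndtri([0.25, 0.5, 0.75])
        confidence = 1 + int(np.sum(evidence > cuts))
        out.append((answer, confidence))
    return out


# ---------------------------------------------------------------------------
# Movement dynamics
# ---------------------------------------------------------------------------

def simulate_trial(config: SimConfig, profiles: Sequence[AgentProfile],
                   answers: Sequence[tuple[int, int]],
                   rng: np.random.Generator,
                   ) -> tuple[list[Trajectory], int | None, float | None]:
    """Simulate the group-movement phase of one trial.

    Each agent heads toward its current goal target at speed
    ``speed_gain * confidence`` plus Gaussian jitter and halts once its
    avatar center lies inside the goal circle.  At every sample an agent
    whose goal is opposed revises it with hazard

        social_weight * n_at_plurality_other * (5 - confidence)
        / persistence   [* majority_bonus if that target holds a majority]

    adopting the most common other goal.  The trial ends when all avatar
    centers rest inside the same target circle (consensus) or at
    ``max_trial_duration`` (consensus missing).
    """
    n = config.group_size
    if len(profiles) != n or len(answers) != n:
        raise ValueError("need one profile and one answer per agent")
    geom = config.geometry
    dt = 1.0 / config.sample_rate
    n_steps = int(round(config.max_trial_duration * config.sample_rate))
    targets = geom.target_positions()

    pos = geom.start_positions(n).copy()
    goals = np.array([a for a, _ in answers], dtype=int)
    conf = np.array([c for _, c in answers], dtype=int)
    speed = np.array([prof.speed_gain for prof in profiles]) * conf
    persistence = np.array([prof.persistence for prof in profiles])
    motor_sd = np.array([prof.motor_noise_sd for prof in profiles])

    half = geom.arena_side / 2
    path = np.empty((n_steps + 1, n, 2))
    path[0] = pos
    consensus_target: int | None = None
    consensus_time: float | None = None

    for step in range(1, n_steps + 1):
        # goal revision under social pressure.  An opposing agent exerts
        # full pull only once it rests at its target (displayed commitment);
        # while still traveling it counts arrival_weight.  Pull is further
        # diluted by the agent's own support, so a backed agent resists a
        # lone dissenter and minorities must out-wait a standoff.
        at_goal = (np.hypot(*(targets[goals - 1] - pos).T)
                   <= geom.target_radius + 1e-9)
        for i in range(n):
            raw = np.zeros(5, dtype=int)
            weight = np.zeros(5)
            for j in range(n):
                if j == i:
                    continue
                raw[goals[j]] += 1
                weight[goals[j]] += 1.0 if at_goal[j] else config.arrival_weight
            n_same = 1 + weight[goals[i]]
            raw[goals[i]] = 0
            weight[goals[i]] = 0.0
            m = weight.max()
            if m <= 0:
                continue
            hazard = (config.social_weight * m / n_same
                      * (5 - conf[i]) / persistence[i])
            if raw[np.argmax(weight)] > n / 2:
                hazard *= config.majority_bonus
            if rng.random() < -np.expm1(-hazard * dt):
                top = np.flatnonzero(weight == m)
                goals[i] = int(top[0] if top.size == 1 else rng.choice(top))

        # kinematics
        vec = targets[goals - 1] - pos
        dist = np.hypot(vec[:, 0], vec[:, 1])
        inside = dist <= geom.target_radius
        v = np.maximum(speed + rng.normal(0.0, 1.0, n) * motor_sd, 0.0)
        step_len = np.where(inside, 0.0, v * dt)
        # halt exactly at the capture boundary instead of overshooting it
        step_len = np.minimum(step_len, np.maximum(dist - geom.target_radius, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(dist[:, None] > 0, vec / np.maximum(dist, 1e-12)[:, None], 0.0)
        pos = np.clip(pos + unit * step_len[:, None], -half, half)
        path[step] = pos

        dist_after = np.hypot(*(targets[goals - 1] - pos).T)
        if consensus_target is None and len(set(goals)) == 1 and \
                np.all(dist_after <= geom.target_radius + 1e-9):
            consensus_target = int(goals[0])
            consensus_time = step * dt
            break

    last = step if consensus_target is not None else n_steps
    t = np.arange(last + 1) * dt
    trajs = [Trajectory(f"p{i + 1}", t, path[:last + 1, i, 0], path[:last + 1, i, 1])
             for i in range(n)]
    return trajs, consensus_target, consensus_time


def _difficulty_schedule(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    levels = np.arange(1, config.n_difficulties + 1)
    if config.difficulty_schedule == "balanced":
        per = config.n_trials // config.n_difficulties
        # balanced blocks, shuffled within each block of n_difficulties
        # trials: evenly interspersed without clusters of one level
        blocks = [rng.permutation(levels) for _ in range(per)]
        return np.concatenate(blocks)
    if config.difficulty_schedule == "uniform":
        return rng.integers(1, config.n_difficulties + 1, config.n_trials)
    raise ValueError(f"unknown difficulty_schedule {config.difficulty_schedule!r}")


def simulate_session(config: SimConfig,
                     profiles: Sequence[AgentProfile] | None = None,
                     session_id: str = "sim-000",
                     rng: np.random.Generator | None = None) -> Session:
    """Simulate a full session of ``config.n_trials`` trials."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if profiles is None:
        profiles = default_profiles(config.group_size, rng)
        if config.training:
            # groups that saw the other condition first start the analyzed
            # block practiced: a small uniform competence boost
            profiles = [dataclasses.replace(
                p, competence=tuple(np.clip(np.asarray(p.competence)
                                            + TRAINING_COMPETENCE_BOOST,
                                            0.25, 1.0)))
                for p in profiles]
    if len(profiles) != config.group_size:
        raise ValueError("need one profile per group member")

    difficulties = _difficulty_schedule(config, rng)
    pids = [f"p{i + 1}" for i in range(config.group_size)]
    trials: list[TrialRecord] = []
    trajectories: dict[tuple[int, str], Trajectory] = {}
    for k, diff in enumerate(difficulties, start=1):
        correct_target = int(rng.integers(1, 5))
        answers = draw_private_answers(profiles, int(diff), correct_target, rng)
        trajs, cons_target, cons_time = simulate_trial(config, profiles, answers, rng)
        trials.append(TrialRecord(
            session_id=session_id, trial_index=k, difficulty=int(diff),
            correct_target=correct_target, training=config.training,
            private_answer={p: a for p, (a, _) in zip(pids, answers)},
            confidence={p: c for p, (_, c) in zip(pids, answers)},
            consensus_target=cons_target, consensus_time=cons_time,
        ))
        for pid, traj in zip(pids, trajs):
            trajectories[(k, pid)] = traj

    return Session(
        session_id=session_id, group_size=config.group_size,
        geometry=config.geometry, trials=trials, trajectories=trajectories,
        participants=pids,
        meta={"seed": config.seed, "simulated": True,
              "config": config.to_dict()},
    )


def simulate_corpus(seed: int,
                    group_counts: dict[int, int] | None = None,
                    n_trials: int = 64,
                    sample_rate: float = 100.0,
                    training_counterbalanced: bool = True) -> list[Session]:
    """Simulate a study-scale corpus (default 17/14/13 groups of size 2/3/4).

    Every session gets an independent child seed spawned from ``seed``; the
    training flag alternates across sessions when counterbalanced.
    """
    if group_counts is None:
        group_counts = dict(STUDY_GROUP_COUNTS)
    ss = np.random.SeedSequence(seed)
    sessions: list[Session] = []
    k = 0
    for size in sorted(group_counts):
        for _ in range(group_counts[size]):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            training = (k % 2) if training_counterbalanced else 0
            config = SimConfig(group_size=size, n_trials=n_trials,
                               sample_rate=sample_rate, training=training,
                               seed=int(child.generate_state(1)[0] % (2 ** 31)))
            sessions.append(simulate_session(
                config, session_id=f"sim-{k:03d}", rng=rng))
            k += 1
    return sessions
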