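"""The deterministic two-step ("spaceship") task environment.

Each trial starts in one of two first-stage states, each offering a pair of
spaceships (stimuli).  Every spaceship flies deterministically to one of two
planets, and the planet pays an integer number of points that drifts across
trials as a discretized Gaussian random walk bounded in [-4, 5].  Because
both first-stage states reach both planets, knowledge of the spaceship ->
planet map can be transferred between states: that transfer is what
distinguishes model-based from model-free play.

This module owns the environment only: transition structure, reward walks,
session simulation against an arbitrary policy, payout conversion, and the
model-agnostic "stay" coding of behaviour (did the current choice target the
same planet as the previous one?).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .exceptions import ConfigError, InputError

PLANETS = ("red", "green")
FIRST_STATES = (1, 2)
ACTIONS = (1, 2)

#: default spaceship -> planet map, indexed [first_state - 1][action - 1];
#: 0 = red, 1 = green.  Action slots are deliberately anti-aligned across the
#: two states so that "same response slot" and "same planet" differ.
DEFAULT_TRANSITIONS = ((0, 1), (1, 0))


def stimulus_id(first_state: int, action: int) -> int:
    """Spaceship identity (1..4) determined by first-stage state x action."""
    return 2 * (first_state - 1) + action


@dataclass(frozen=True)
class TaskConfig:
    """Static description of one session of the task.

    ``drift_schedule`` assigns one drift level (the SD of the latent Gaussian
    increments) to every trial, in contiguous blocks.  ``first_state_sequence``
    lists the first-stage state (1 or 2) presented on each trial.
    """

    n_trials: int = 200
    reward_bounds: tuple[int, int] = (-4, 5)
    drift_levels: tuple[float, ...] = (0.5, 1.0, 2.0)
    drift_schedule: tuple[float, ...] = ()
    transition_map: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_TRANSITIONS
    first_state_sequence: tuple[int, ...] = ()
    points_to_cents: float = 4.0

    def __post_init__(self):
        lo, hi = self.reward_bounds
        if lo >= hi:
            raise ConfigError(f"inverted reward bounds {self.reward_bounds}")
        if self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")
        if self.points_to_cents <= 0:
            raise ConfigError("points_to_cents must be positive")
        if self.drift_schedule and len(self.drift_schedule) != self.n_trials:
            raise ConfigError(
                f"drift_schedule length {len(self.drift_schedule)} != n_trials {self.n_trials}"
            )
        if any(d not in self.drift_levels for d in self.drift_schedule):
            raise ConfigError("drift_schedule contains a level not in drift_levels")
        if self.first_state_sequence and len(self.first_state_sequence) != self.n_trials:
            raise ConfigError("first_state_sequence length != n_trials")
        tm = np.asarray(self.transition_map)
        if tm.shape != (2, 2) or not np.all(np.isin(tm, (0, 1))):
            raise ConfigError("transition_map must be 2x2 over planets {0,1}")
        if tm[0, 0] == tm[0, 1] or tm[1, 0] == tm[1, 1]:
            raise ConfigError("each first-stage state must reach both planets")


def default_config(n_trials: int = 200, seed: int = 0, n_blocks: int = 6,
                   p_same_state: float = 0.5) -> TaskConfig:
    """Build a config with a concrete drift schedule and first-state sequence.

    The three drift levels are laid out in ``n_blocks`` contiguous blocks,
    cycling through a seeded shuffle of the levels.  The first-state sequence
    alternates pseudo-randomly with probability ``p_same_state`` of repeating
    the previous state, which keeps the two states near-equally frequent.
    """
    rng = np.random.default_rng(seed)
    levels = list(TaskConfig.drift_levels)
    order: list[float] = []
    while len(order) < n_blocks:
        chunk = list(rng.permutation(levels))
        order.extend(chunk)
    order = order[:n_blocks]
    edges = np.linspace(0, n_trials, n_blocks + 1).astype(int)
    schedule = np.empty(n_trials)
    for b in range(n_blocks):
        schedule[edges[b]:edges[b + 1]] = order[b]

    states = np.empty(n_trials, dtype=int)
    states[0] = rng.integers(1, 3)
    repeats = rng.random(n_trials - 1) < p_same_state
    for t in range(1, n_trials):
        states[t] = states[t - 1] if repeats[t - 1] else 3 - states[t - 1]

    return TaskConfig(
        n_trials=n_trials,
        drift_schedule=tuple(schedule),
        first_state_sequence=tuple(int(s) for s in states),
    )


@dataclass(frozen=True)
class RewardWalk:
    """Integer reward sequence for one planet plus its latent trajectory."""

    planet: str
    rewards: np.ndarray  # int, length n_trials, all within bounds
    latent: np.ndarray = field(repr=False, default=None)
    seed: int | None = None


def _reflect(x: float, lo: float, hi: float) -> float:
    # iterated reflection keeps mass near the bounds instead of piling on them
    while x < lo or x > hi:
        if x > hi:
            x = 2.0 * hi - x
        if x < lo:
            x = 2.0 * lo - x
    return x


def generate_reward_walk(config: TaskConfig, planet: str, seed: int) -> RewardWalk:
    """Discretized Gaussian random walk with reflecting ("bouncing") bounds.

    The latent value takes Gaussian steps with SD equal to the scheduled
    drift level, reflects off the bounds, and is rounded to the nearest
    integer for delivery.  The latent trajectory stays continuous.
    """
    if planet not in PLANETS:
        raise InputError(f"unknown planet {planet!r}")
    if not config.drift_schedule:
        raise ConfigError("config has no drift_schedule; use default_config()")
    lo, hi = config.reward_bounds
    rng = np.random.default_rng(seed)
    latent = np.empty(config.n_trials)
    x = rng.uniform(lo, hi)
    for t, sd in enumerate(config.drift_schedule):
        x = _reflect(x + rng.normal(0.0, sd), lo, hi)
        latent[t] = x
    rewards = np.rint(latent).astype(int)
    return RewardWalk(planet=planet, rewards=rewards, latent=latent, seed=seed)


def generate_session_walks(config: TaskConfig, seed: int) -> dict[str, RewardWalk]:
    """Independent walks for both planets, seeded off a single integer."""
    child = np.random.SeedSequence(seed).spawn(2)
    return {
        planet: generate_reward_walk(config, planet, child[i].generate_state(1)[0] % (2**31))
        for i, planet in enumerate(PLANETS)
    }


def resolve_transition(config: TaskConfig, first_state: int, action: int) -> str:
    """Deterministic spaceship -> planet transition."""
    if first_state not in FIRST_STATES:
        raise InputError(f"unknown first_state {first_state!r}")
    if action not in ACTIONS:
        raise InputError(f"unknown action {action!r}")
    return PLANETS[config.transition_map[first_state - 1][action - 1]]


class TrialRecord(NamedTuple):
    """One completed trial; the atomic unit every likelihood consumes."""

    subject_id: str
    session: int
    trial_index: int  # 1-based
    first_state: int  # 1 or 2
    action: int       # 1 or 2
    stimulus_id: int  # 1..4
    planet: str
    reward: int


class StayEvent(NamedTuple):
    """Stay/switch coding of one trial with respect to its predecessor.

    ``stayed`` compares the planets targeted by consecutive choices — not the
    stimuli — so it is well defined even when the first-stage state changes.
    """

    trial_index: int
    same_first_state: bool
    prev_points: int
    stayed: bool


Policy = Callable[[int, int, list[TrialRecord]], int]


def simulate_session(
    policy: Policy,
    config: TaskConfig,
    walks: dict[str, RewardWalk],
    seed: int = 0,
    subject_id: str = "sim",
    session: int = 1,
) -> list[TrialRecord]:
    """Run one session of the task against ``policy``.

    ``policy(trial_index, first_state, history) -> action`` may be stochastic;
    it receives the (1-based) trial index, the presented first-stage state and
    the list of completed TrialRecords.  Rewards are read off the walks.
    """
    if not config.first_state_sequence:
        raise ConfigError("config has no first_state_sequence; use default_config()")
    for planet in PLANETS:
        if len(walks[planet].rewards) != config.n_trials:
            raise ConfigError("walk length does not match n_trials")
    records: list[TrialRecord] = []
    for t, s in enumerate(config.first_state_sequence, start=1):
        a = policy(t, s, records)
        if a not in ACTIONS:
            raise InputError(f"policy returned invalid action {a!r}")
        planet = resolve_transition(config, s, a)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                session=session,
                trial_index=t,
                first_state=s,
                action=a,
                stimulus_id=stimulus_id(s, a),
                planet=planet,
                reward=int(walks[planet].rewards[t - 1]),
            )
        )
    return records


def code_stay_events(session: Sequence[TrialRecord]) -> list[StayEvent]:
    """Stay coding for trials 2..n of a session.

    An event is attached to the later trial of each consecutive pair:
    ``stayed`` is true iff the current choice targets the same planet as the
    previous choice, regardless of which spaceship implements it.
    """
    events: list[StayEvent] = []
    for prev, cur in zip(session, session[1:]):
        events.append(
            StayEvent(
                trial_index=cur.trial_index,
                same_first_state=cur.first_state == prev.first_state,
                prev_points=prev.reward,
                stayed=cur.planet == prev.planet,
            )
        )
    return events


def points_to_payout(total_points: int, config: TaskConfig | None = None) -> float:
    """Convert accumulated points to euros (4 Eurocents per point by default)."""
    cents = (config.points_to_cents if config is not None else 4.0)
    return total_points * cents / 100.0


def session_to_arrays(session: Sequence[TrialRecord]) -> dict[str, np.ndarray]:
    """0-based integer arrays (first_state, action, planet, reward) for kernels."""
    return {
        "first_state": np.array([r.first_state - 1 for r in session], dtype=np.int64),
        "action": np.array([r.action - 1 for r in session], dtype=np.int64),
        "planet": np.array([PLANETS.index(r.planet) for r in session], dtype=np.int64),
        "reward": np.array([r.reward for r in session], dtype=np.float64),
    }
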