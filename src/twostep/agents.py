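"""Generative choice models for the deterministic two-step task.

Four model variants share one choice rule — a softmax over the weighted
average of model-based and model-free action values,

    Q(a, s) = omega * QMB(a, s) + (1 - omega) * QMF(a, s)
    P(a)    = exp(eta * Q(a)) / sum_a' exp(eta * Q(a'))

— and differ in how the values are learned:

* ``M1``        last-outcome learner: QMF of the chosen spaceship is set to
                the delivered reward; all other model-free entries shrink
                toward 0 by a factor (1 - gamma); the model-based side sets
                the reached planet's value to the reward, which transfers to
                the matching spaceship in the *other* first-stage state.
* ``M1_sticky`` M1 plus additive response (rho) and stimulus (pi) stickiness
                toward the previous trial's action slot / spaceship.
* ``M2``        dual-system TD(lambda) learner with separate stage-1 and
                stage-2 learning rates alpha1, alpha2.
* ``M3``        M2 with the two learning rates tied.

The step-by-step functions here (``mixed_value``, ``choice_prob``,
``m1_update``, ``td_update``) are the readable reference; ``session_loglik``
and ``simulate_choices`` default to the numba kernels in ``_kernels`` and a
pure-Python engine is available for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .exceptions import InputError, NumericalError
from .task import (
    DEFAULT_TRANSITIONS,
    PLANETS,
    TaskConfig,
    TrialRecord,
    RewardWalk,
    session_to_arrays,
    stimulus_id,
)
from .transforms import MODEL_IDS, model_family

__all__ = [
    "M1Params", "RLParams", "ValueState", "mixed_value", "choice_prob",
    "m1_update", "td_update", "session_loglik", "simulate_choices",
    "MODEL_IDS",
]


def _check_unit(name, value):
    if not 0.0 <= value <= 1.0:
        raise InputError(f"{name}={value} outside [0, 1]")


@dataclass(frozen=True)
class M1Params:
    """Native parameters of the last-outcome learner (M1 / M1_sticky)."""

    omega: float
    gamma: float
    eta: float
    rho: float = 0.0
    pi: float = 0.0

    def __post_init__(self):
        _check_unit("omega", self.omega)
        _check_unit("gamma", self.gamma)
        if self.eta < 0:
            raise InputError(f"eta={self.eta} must be non-negative")

    def to_kernel(self) -> np.ndarray:
        return np.array([self.omega, self.gamma, self.eta, self.rho, self.pi])


@dataclass(frozen=True)
class RLParams:
    """Native parameters of the dual-system TD learner (M2 / M3)."""

    omega: float
    eta: float
    alpha1: float
    alpha2: float
    lam: float

    def __post_init__(self):
        _check_unit("omega", self.omega)
        _check_unit("alpha1", self.alpha1)
        _check_unit("alpha2", self.alpha2)
        _check_unit("lambda", self.lam)
        if self.eta < 0:
            raise InputError(f"eta={self.eta} must be non-negative")

    def to_kernel(self) -> np.ndarray:
        return np.array([self.omega, self.eta, self.alpha1, self.alpha2, self.lam])


def _params_to_kernel(params, model_id: str) -> tuple[np.ndarray, int]:
    family = model_family(model_id)
    if isinstance(params, (M1Params, RLParams)):
        if family == _kernels.FAMILY_DET and not isinstance(params, M1Params):
            raise InputError(f"model {model_id} needs M1Params")
        if family == _kernels.FAMILY_TD and not isinstance(params, RLParams):
            raise InputError(f"model {model_id} needs RLParams")
        if model_id == "M3" and params.alpha1 != params.alpha2:
            raise InputError("M3 requires alpha1 == alpha2")
        if model_id == "M1" and (params.rho != 0.0 or params.pi != 0.0):
            raise InputError("plain M1 has no stickiness; use M1_sticky")
        vec = params.to_kernel()
    else:
        vec = np.asarray(params, dtype=float)
        if vec.shape != (5,):
            raise InputError("raw parameter vector must have length 5")
    return vec, family


class ValueState:
    """Mutable learner state: model-free values, planet values, history.

    ``QMB[s, a]`` is always derived as ``Q2[transition_map[s, a]]`` — the
    model-based component is the planet value reached by that spaceship.
    """

    def __init__(self, transition_map=DEFAULT_TRANSITIONS):
        self.tmap = np.asarray(transition_map, dtype=np.int64)
        self.QMF = np.zeros((2, 2))
        self.Q2 = np.zeros(2)
        self.prev_action: int | None = None
        self.prev_stimulus: int | None = None

    @property
    def QMB(self) -> np.ndarray:
        return self.Q2[self.tmap]

    def observe(self, trial: TrialRecord):
        self.prev_action = trial.action
        self.prev_stimulus = trial.stimulus_id


def mixed_value(params, state: ValueState, first_state: int) -> np.ndarray:
    """Choice values Q(a) for both actions of ``first_state`` (1-based)."""
    s = first_state - 1
    omega = params.omega
    q = omega * state.QMB[s] + (1.0 - omega) * state.QMF[s]
    if isinstance(params, M1Params) and state.prev_action is not None:
        q = q.copy()
        q[state.prev_action - 1] += params.rho
        for a in (1, 2):
            if stimulus_id(first_state, a) == state.prev_stimulus:
                q[a - 1] += params.pi
    return q


def choice_prob(q, eta: float) -> np.ndarray:
    """Softmax probabilities over the two actions, numerically stabilized."""
    if eta < 0:
        raise InputError(f"eta={eta} must be non-negative")
    x = eta * np.asarray(q, dtype=float)
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def m1_update(state: ValueState, trial: TrialRecord, gamma: float) -> ValueState:
    """Last-outcome update of M1 (in place; returns the state).

    The chosen spaceship's model-free value becomes the reward; the other
    three model-free entries shrink by (1 - gamma).  The reached planet's
    value becomes the reward, which propagates to the model-based value of
    both spaceships flying there; the other planet's value is untouched.
    """
    s, a = trial.first_state - 1, trial.action - 1
    r = float(trial.reward)
    keep = 1.0 - gamma
    state.QMF *= keep
    state.QMF[s, a] = r
    state.Q2[PLANETS.index(trial.planet)] = r
    state.observe(trial)
    return state


def td_update(state: ValueState, trial: TrialRecord, alpha1: float,
              alpha2: float, lam: float) -> ValueState:
    """SARSA-style TD update of M2/M3 (in place; returns the state).

    Order matters: the stage-1 prediction error uses the planet value from
    *before* the stage-2 update, then the stage-2 error is formed and a
    fraction lambda of it is passed back to the stage-1 action.
    """
    s, a = trial.first_state - 1, trial.action - 1
    p = PLANETS.index(trial.planet)
    r = float(trial.reward)
    d1 = state.Q2[p] - state.QMF[s, a]
    state.QMF[s, a] += alpha1 * d1
    d2 = r - state.Q2[p]
    state.Q2[p] += alpha2 * d2
    state.QMF[s, a] += lam * alpha1 * d2
    state.observe(trial)
    return state


def _session_loglik_python(params, model_id, session, transition_map) -> float:
    state = ValueState(transition_map)
    total = 0.0
    for trial in session:
        q = mixed_value(params, state, trial.first_state)
        p = choice_prob(q, params.eta)
        total += np.log(p[trial.action - 1])
        if isinstance(params, M1Params):
            m1_update(state, trial, params.gamma)
        else:
            td_update(state, trial, params.alpha1, params.alpha2, params.lam)
    return float(total)


def session_loglik(params, model_id: str, session: Sequence[TrialRecord],
                   transition_map=DEFAULT_TRANSITIONS, engine: str = "numba") -> float:
    """Sum over trials of log P(observed action | values before the trial).

    Values start at zero (so trial 1 always contributes log 0.5 for
    non-sticky models) and are updated after each choice is scored.
    """
    if engine == "python":
        out = _session_loglik_python(params, model_id, session, transition_map)
    else:
        vec, family = _params_to_kernel(params, model_id)
        arr = session_to_arrays(session)
        out = _kernels.session_loglik(
            vec, family, arr["first_state"], arr["action"], arr["planet"],
            arr["reward"], np.asarray(transition_map, dtype=np.int64),
        )
    if not np.isfinite(out):
        raise NumericalError(f"non-finite session log-likelihood ({out})")
    return float(out)


def simulate_choices(params, model_id: str, config: TaskConfig,
                     walks: dict[str, RewardWalk], seed: int,
                     subject_id: str = "sim", session: int = 1) -> list[TrialRecord]:
    """Forward-simulate one session; generative mirror of ``session_loglik``.

    Choices are sampled from the softmax probabilities; at eta -> inf exact
    value ties resolve uniformly at random (P = 0.5 each), via the sampled
    uniforms.
    """
    vec, family = _params_to_kernel(params, model_id)
    fs_seq = np.asarray(config.first_state_sequence, dtype=np.int64) - 1
    if fs_seq.size != config.n_trials:
        raise InputError("config has no first_state_sequence of length n_trials")
    walk_rewards = np.stack([np.asarray(walks[p].rewards, dtype=float) for p in PLANETS])
    if walk_rewards.shape[1] != config.n_trials:
        raise InputError("walk length does not match n_trials")
    rng = np.random.default_rng(seed)
    uniforms = rng.random(config.n_trials)
    tmap = np.asarray(config.transition_map, dtype=np.int64)
    actions, planets, rewards = _kernels.simulate_session(
        vec, family, fs_seq, walk_rewards, tmap, uniforms
    )
    records = []
    for t in range(config.n_trials):
        s = int(fs_seq[t]) + 1
        a = int(actions[t]) + 1
        records.append(
            TrialRecord(
                subject_id=subject_id, session=session, trial_index=t + 1,
                first_state=s, action=a, stimulus_id=stimulus_id(s, a),
                planet=PLANETS[int(planets[t])], reward=int(rewards[t]),
            )
        )
    return records
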