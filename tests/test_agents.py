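"""Choice models: value updates, softmax, sequential likelihood, simulation.

The likelihood checks use an independent dictionary-based oracle implemented
here from the model equations, exhaustively enumerated over all possible
choice sequences of a short session.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twostep import (
    M1Params,
    RLParams,
    ValueState,
    choice_prob,
    code_stay_events,
    default_config,
    generate_session_walks,
    m1_update,
    mixed_value,
    session_loglik,
    simulate_choices,
    td_update,
)
from twostep.exceptions import InputError
from twostep.task import DEFAULT_TRANSITIONS, PLANETS, TrialRecord, stimulus_id


# ---------------------------------------------------------------------------
# independent step-by-step oracle (dict-based, written from the equations)

TMAP = {(s, a): PLANETS[DEFAULT_TRANSITIONS[s - 1][a - 1]]
        for s in (1, 2) for a in (1, 2)}


def oracle_loglik(model, pars, trials):
    """trials: list of (first_state, action, reward); planet from TMAP."""
    qmf = {(s, a): 0.0 for s in (1, 2) for a in (1, 2)}
    q2 = {"red": 0.0, "green": 0.0}
    prev_action = None
    prev_stim = None
    total = 0.0
    for s, a, r in trials:
        values = {}
        for act in (1, 2):
            q = (pars["omega"] * q2[TMAP[s, act]]
                 + (1 - pars["omega"]) * qmf[(s, act)])
            if model == "M1_sticky" and prev_action is not None:
                if act == prev_action:
                    q += pars["rho"]
                if (s, act) == prev_stim:
                    q += pars["pi"]
            values[act] = q
        denom = sum(math.exp(pars["eta"] * values[x]) for x in (1, 2))
        total += math.log(math.exp(pars["eta"] * values[a]) / denom)
        if model in ("M1", "M1_sticky"):
            for key in qmf:
                if key == (s, a):
                    qmf[key] = r
                else:
                    qmf[key] = (1 - pars["gamma"]) * qmf[key]
            q2[TMAP[s, a]] = r
        else:
            planet = TMAP[s, a]
            d1 = q2[planet] - qmf[(s, a)]
            qmf[(s, a)] += pars["alpha1"] * d1
            d2 = r - q2[planet]
            q2[planet] += pars["alpha2"] * d2
            qmf[(s, a)] += pars["lambda"] * pars["alpha1"] * d2
        prev_action = a
        prev_stim = (s, a)
    return total


def make_session(choices, states, rewards):
    records = []
    for t, (s, a) in enumerate(zip(states, choices), start=1):
        planet = TMAP[(s, a)]
        records.append(TrialRecord("x", 1, t, s, a, stimulus_id(s, a),
                                   planet, rewards[t - 1][planet]))
    return records


FIVE_TRIAL_STATES = (1, 2, 1, 1, 2)
FIVE_TRIAL_REWARDS = [
    {"red": 3, "green": -2}, {"red": 1, "green": 4}, {"red": -4, "green": 0},
    {"red": 5, "green": 2}, {"red": 0, "green": -1},
]

MODEL_CASES = [
    ("M1", M1Params(0.65, 0.3, 1.4),
     dict(omega=0.65, gamma=0.3, eta=1.4)),
    ("M1_sticky", M1Params(0.4, 0.2, 0.9, rho=0.6, pi=-0.3),
     dict(omega=0.4, gamma=0.2, eta=0.9, rho=0.6, pi=-0.3)),
    ("M2", RLParams(0.5, 1.2, 0.35, 0.8, 0.4),
     dict(omega=0.5, eta=1.2, alpha1=0.35, alpha2=0.8, **{"lambda": 0.4})),
    ("M3", RLParams(0.7, 0.8, 0.55, 0.55, 0.25),
     dict(omega=0.7, eta=0.8, alpha1=0.55, alpha2=0.55, **{"lambda": 0.25})),
]


class TestSessionLoglik:
    @pytest.mark.parametrize("model,params,pars", MODEL_CASES,
                             ids=[c[0] for c in MODEL_CASES])
    def test_matches_oracle_on_all_32_choice_sequences(self, model, params, pars):
        for choices in itertools.product((1, 2), repeat=5):
            session = make_session(choices, FIVE_TRIAL_STATES, FIVE_TRIAL_REWARDS)
            trials = [(r.first_state, r.action, r.reward) for r in session]
            expected = oracle_loglik(model, pars, trials)
            assert session_loglik(params, model, session) == pytest.approx(
                expected, abs=1e-10)
            assert session_loglik(params, model, session, engine="python") \
                == pytest.approx(expected, abs=1e-10)

    def test_first_trial_contributes_log_half(self):
        session = make_session((1,), (1,), FIVE_TRIAL_REWARDS[:1])
        ll = session_loglik(M1Params(0.8, 0.5, 3.0), "M1", session)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_zero_inverse_temperature_gives_uniform_choice(self, m1_session):
        n = len(m1_session)
        ll = session_loglik(M1Params(0.5, 0.5, 0.0), "M1", m1_session)
        assert ll == pytest.approx(n * np.log(0.5), abs=1e-10)

    def test_m3_equals_m2_with_tied_learning_rates(self, small_config):
        rng = np.random.default_rng(17)
        for i in range(100):
            omega, alpha, lam = rng.random(3)
            eta = rng.uniform(0.1, 4)
            walks = generate_session_walks(small_config, seed=1000 + i)
            session = simulate_choices(
                RLParams(omega, eta, alpha, alpha, lam), "M2",
                small_config, walks, seed=i)
            p = RLParams(omega, eta, alpha, alpha, lam)
            assert session_loglik(p, "M3", session) == pytest.approx(
                session_loglik(p, "M2", session), abs=1e-10)

    def test_m1_is_td_limit_at_unit_rates(self, small_config, small_walks):
        """With alpha1 = alpha2 = lambda = 1 the TD learner's planet values
        follow the same last-outcome trajectory as M1's, so a fully
        model-based (omega = 1) likelihood coincides with M1 at gamma
        arbitrary (gamma touches only model-free values)."""
        session = simulate_choices(M1Params(1.0, 0.0, 1.5), "M1",
                                   small_config, small_walks, seed=3)
        ll_m1 = session_loglik(M1Params(1.0, 0.7, 1.5), "M1", session)
        ll_td = session_loglik(RLParams(1.0, 1.5, 1.0, 1.0, 1.0), "M2", session)
        assert ll_m1 == pytest.approx(ll_td, abs=1e-10)

    def test_omega_one_ignores_spaceship_level_history(self):
        """A fully model-based likelihood depends on rewards only through
        the planet-level sequence: swapping which spaceship pair delivered
        the experience leaves it unchanged."""
        rewards = FIVE_TRIAL_REWARDS
        base = make_session((1, 2, 1, 2, 1), (1, 1, 2, 2, 1), rewards)
        # move the same planet-visits onto the other first-stage state
        swapped_states = tuple(3 - s for s in (1, 1, 2, 2, 1))
        swapped_actions = []
        for rec, s_new in zip(base, swapped_states):
            a_new = next(a for a in (1, 2) if TMAP[(s_new, a)] == rec.planet)
            swapped_actions.append(a_new)
        swapped = make_session(tuple(swapped_actions), swapped_states, rewards)
        p = M1Params(1.0, 0.4, 2.0)
        assert session_loglik(p, "M1", base) == pytest.approx(
            session_loglik(p, "M1", swapped), abs=1e-10)


class TestChoiceRule:
    def test_mixture_endpoints(self):
        state = ValueState()
        state.QMF[0] = [2.0, -1.0]
        state.Q2[:] = [0.5, 3.0]
        q_mb = mixed_value(M1Params(1.0, 0.0, 1.0), state, 1)
        assert np.allclose(q_mb, state.QMB[0])
        q_mf = mixed_value(M1Params(0.0, 0.0, 1.0), state, 1)
        assert np.allclose(q_mf, state.QMF[0])

    def test_mixture_midpoint(self):
        state = ValueState()
        state.QMF[0] = [0.0, 0.0]
        state.Q2[:] = [2.0, 2.0]
        q = mixed_value(M1Params(0.5, 0.0, 1.0), state, 1)
        assert np.allclose(q, [1.0, 1.0])

    def test_softmax_values(self):
        assert choice_prob([1.0, 0.0], 1.0)[0] == pytest.approx(0.7311, abs=1e-4)
        assert np.allclose(choice_prob([5.0, -3.0], 0.0), [0.5, 0.5])
        assert np.allclose(choice_prob([2.0, 2.0], 7.5), [0.5, 0.5])

    def test_negative_eta_rejected(self):
        with pytest.raises(InputError):
            choice_prob([1.0, 0.0], -0.5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(q1=st.floats(-10, 10), q2=st.floats(-10, 10), eta=st.floats(0, 50))
    def test_softmax_normalizes(self, q1, q2, eta):
        p = choice_prob([q1, q2], eta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)
        assert p.max() <= 1.0


class TestValueUpdates:
    def _trial(self, s, a, reward):
        planet = TMAP[(s, a)]
        return TrialRecord("x", 1, 1, s, a, stimulus_id(s, a), planet, reward)

    def test_m1_update_transfers_to_other_state(self):
        """Reaching the red planet with reward 3 must set the model-based
        value of the *other* state's red-planet spaceship to 3 as well."""
        state = ValueState()
        m1_update(state, self._trial(1, 1, 3), gamma=0.0)  # state1/action1 -> red
        assert state.QMF[0, 0] == 3.0
        assert state.Q2[PLANETS.index("red")] == 3.0
        # state 2's red-flying action is action 2 under the default map
        assert state.QMB[1, 1] == 3.0
        assert state.QMB[1, 0] == 0.0

    def test_m1_full_forgetting_zeroes_unchosen(self):
        state = ValueState()
        state.QMF[:] = [[1.0, 2.0], [3.0, 4.0]]
        m1_update(state, self._trial(1, 1, -2), gamma=1.0)
        assert state.QMF[0, 0] == -2.0
        assert state.QMF[0, 1] == 0.0 and np.all(state.QMF[1] == 0.0)

    def test_m1_zero_forgetting_preserves_unchosen(self):
        state = ValueState()
        state.QMF[:] = [[1.0, 2.0], [3.0, 4.0]]
        m1_update(state, self._trial(1, 1, -2), gamma=0.0)
        assert state.QMF[0, 1] == 2.0 and state.QMF[1, 0] == 3.0

    def test_td_update_stage1_error_uses_pre_update_planet_value(self):
        state = ValueState()
        td_update(state, self._trial(1, 1, 4), alpha1=1.0, alpha2=1.0, lam=0.0)
        assert state.Q2[PLANETS.index("red")] == 4.0
        # delta1 was computed against Q2 = 0, so stage-1 value stays 0
        assert state.QMF[0, 0] == 0.0

    def test_td_full_second_stage_rate_overwrites(self):
        state = ValueState()
        state.Q2[:] = [2.5, -1.0]
        td_update(state, self._trial(1, 1, 4), alpha1=0.3, alpha2=1.0, lam=0.5)
        assert state.Q2[PLANETS.index("red")] == 4.0

    def test_td_zero_rates_is_noop(self):
        state = ValueState()
        state.QMF[:] = [[1.0, 2.0], [3.0, 4.0]]
        state.Q2[:] = [0.5, -0.5]
        before_qmf, before_q2 = state.QMF.copy(), state.Q2.copy()
        td_update(state, self._trial(2, 1, 5), alpha1=0.0, alpha2=0.0, lam=0.0)
        assert np.array_equal(state.QMF, before_qmf)
        assert np.array_equal(state.Q2, before_q2)


class TestSimulateChoices:
    def test_seeded_reproducibility(self, small_config, small_walks):
        p = RLParams(0.5, 1.5, 0.4, 0.7, 0.3)
        a = simulate_choices(p, "M2", small_config, small_walks, seed=44)
        b = simulate_choices(p, "M2", small_config, small_walks, seed=44)
        assert a == b

    def test_greedy_model_based_agent_chases_best_planet(self, small_config,
                                                         small_walks):
        """At near-infinite precision and omega = 1, once both planets have
        been visited every choice targets the planet with the higher
        last-seen reward."""
        session = simulate_choices(M1Params(1.0, 0.0, 1e6), "M1",
                                   small_config, small_walks, seed=5)
        last = {}
        seen_both = False
        for rec in session:
            if seen_both and last["red"] != last["green"]:
                best = max(last, key=last.get)
                assert rec.planet == best
            last[rec.planet] = rec.reward
            seen_both = len(last) == 2

    def test_stay_probability_increases_with_previous_reward(self):
        """Same-state stay rates after the best outcomes exceed those after
        the worst outcomes for a mixed agent (the behavioural signature the
        stay regression measures)."""
        cfg = default_config(n_trials=150, seed=1)
        p = M1Params(0.5, 0.3, 2.0)
        good, bad = [], []
        for seed in range(200):
            walks = generate_session_walks(cfg, seed=seed)
            session = simulate_choices(p, "M1", cfg, walks, seed=seed)
            for ev in code_stay_events(session):
                if not ev.same_first_state:
                    continue
                if ev.prev_points >= 4:
                    good.append(ev.stayed)
                elif ev.prev_points <= -3:
                    bad.append(ev.stayed)
        assert np.mean(good) > np.mean(bad)

    def test_model_param_mismatch_rejected(self, small_config, small_walks):
        with pytest.raises(InputError):
            simulate_choices(M1Params(0.5, 0.5, 1.0), "M2",
                             small_config, small_walks, seed=0)
        with pytest.raises(InputError):
            session_loglik(RLParams(0.5, 1.0, 0.3, 0.6, 0.2), "M3", [])
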