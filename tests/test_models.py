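"""The model ladder: choice rule, updates, likelihoods, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import volabandit as vb
from volabandit.errors import ConfigurationError, ValidationError
from volabandit.task import TrialRecord


def _trial(condition="stable", y="red", choice="red", idx=0, pid="P1"):
    rewarded = int(choice == y)
    return TrialRecord(participant_id=pid, trial_index=idx, condition=condition,
                       block_index=None, rewarded_stimulus=y, points_red=50,
                       points_blue=50, choice=choice, chosen_rewarded=rewarded,
                       points_won=50 * rewarded)


class TestModelSpace:
    def test_ladder_shape(self, model_space):
        assert len(model_space) == 12
        assert model_space[0].model_id == "M0" and model_space[0].n_params == 0
        assert model_space[2].family == "wsls"
        last = model_space[-1]
        assert last.model_id == "M11"
        assert last.n_params == 5
        assert last.lr_split == "by_valence_and_condition"
        assert last.temperature_split == "shared"

    def test_all_split_combinations_present(self, model_space):
        combos = {(s.lr_split, s.temperature_split) for s in model_space
                  if s.family == "delta_rule" and s.lr_split != "fixed_one"}
        assert combos == {(a, b)
                          for a in ("single", "by_valence", "by_condition",
                                    "by_valence_and_condition")
                          for b in ("shared", "by_condition")}

    def test_unique_parameter_names_and_ids(self, model_space):
        ids = [s.model_id for s in model_space]
        assert len(set(ids)) == 12
        for s in model_space:
            assert len(set(s.parameter_names)) == s.n_params

    def test_agent_params_validation(self, m11):
        with pytest.raises(ConfigurationError):
            vb.AgentParams.for_spec(m11, temperature=0.5)  # missing alphas
        with pytest.raises(ConfigurationError):
            vb.AgentParams.for_spec(m11, temperature=-1.0, alpha_pos_stable=0.2,
                                    alpha_neg_stable=0.4, alpha_pos_volatile=0.6,
                                    alpha_neg_volatile=0.8)


class TestChoiceRule:
    def test_symmetric_values_give_half(self, m11, m11_params):
        for tau in (0.1, 1.0, 10.0):
            p = vb.AgentParams(m11.model_id, {**m11_params.values, "temperature": tau})
            assert vb.choice_probability(vb.ValueState(0.5), p, m11) == 0.5

    def test_closed_form_value(self, m11, m11_params):
        # (2*0.75 - 1)/0.5 = 1 -> logistic(1)
        p = vb.choice_probability(vb.ValueState(0.75), m11_params, m11)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)

    def test_greedy_limit(self, m11):
        p = vb.AgentParams.for_spec(
            vb.get_spec("M11"), temperature=1e-6, alpha_pos_stable=0.2,
            alpha_neg_stable=0.4, alpha_pos_volatile=0.6, alpha_neg_volatile=0.8)
        assert vb.choice_probability(vb.ValueState(0.9), p, m11) > 1.0 - 1e-9

    def test_exploration_limit(self, m11, m11_params):
        p = vb.AgentParams(m11.model_id, {**m11_params.values, "temperature": 1e6})
        assert vb.choice_probability(vb.ValueState(0.9), p, m11) == pytest.approx(0.5, abs=1e-5)

    @given(v=st.floats(0.0, 1.0), tau=st.floats(0.05, 20.0))
    def test_monotone_and_complementary(self, v, tau):
        m11 = vb.get_spec("M11")
        p = vb.AgentParams.for_spec(m11, temperature=tau, alpha_pos_stable=0.2,
                                    alpha_neg_stable=0.4, alpha_pos_volatile=0.6,
                                    alpha_neg_volatile=0.8)
        pr = vb.choice_probability(vb.ValueState(v), p, m11)
        mirrored = vb.choice_probability(vb.ValueState(1.0 - v), p, m11)
        assert pr + mirrored == pytest.approx(1.0, abs=1e-12)
        if v > 0.5:
            assert pr > 0.5


class TestLearningRateSelection:
    def test_four_way_split(self, m11, m11_params):
        assert vb.select_learning_rate(m11, m11_params, "volatile", "negative") == 0.8
        assert vb.select_learning_rate(m11, m11_params, "stable", "positive") == 0.2

    def test_zero_pe_routes_positive(self, m11, m11_params):
        assert vb.select_learning_rate(m11, m11_params, "stable", 0.0) == 0.2

    def test_single_split_ignores_everything(self):
        spec = vb.get_spec("M4")
        p = vb.AgentParams.for_spec(spec, temperature=0.5, alpha=0.3)
        for cond in ("stable", "volatile"):
            for sign in ("positive", "negative"):
                assert vb.select_learning_rate(spec, p, cond, sign) == 0.3

    def test_by_valence_ignores_condition(self):
        spec = vb.get_spec("M6")
        p = vb.AgentParams.for_spec(spec, temperature=0.5, alpha_pos=0.3, alpha_neg=0.7)
        assert (vb.select_learning_rate(spec, p, "stable", "positive")
                == vb.select_learning_rate(spec, p, "volatile", "positive") == 0.3)


class TestValueUpdate:
    def test_midpoint_half_step(self, m11):
        p = vb.AgentParams.for_spec(m11, temperature=0.5, alpha_pos_stable=0.5,
                                    alpha_neg_stable=0.5, alpha_pos_volatile=0.5,
                                    alpha_neg_volatile=0.5)
        out = vb.update_values(vb.ValueState(0.5), _trial(), p, m11)
        assert out.v_red == pytest.approx(0.75, abs=1e-12)

    def test_negative_delta_arithmetic(self, m11):
        # V_c = 0.8, alpha = 0.25, r = 0 -> 0.8 + 0.25 * (0 - 0.8) = 0.6
        p = vb.AgentParams.for_spec(m11, temperature=0.5, alpha_pos_stable=0.9,
                                    alpha_neg_stable=0.25, alpha_pos_volatile=0.9,
                                    alpha_neg_volatile=0.9)
        out = vb.update_values(vb.ValueState(0.8), _trial(y="blue", choice="red"), p, m11)
        assert out.v_red == pytest.approx(0.6, abs=1e-12)

    def test_zero_learning_rate_is_identity(self, m11):
        p = vb.AgentParams.for_spec(m11, temperature=0.5, alpha_pos_stable=1e-12,
                                    alpha_neg_stable=1e-12, alpha_pos_volatile=1e-12,
                                    alpha_neg_volatile=1e-12)
        for choice, y in [("red", "red"), ("red", "blue"), ("blue", "red")]:
            out = vb.update_values(vb.ValueState(0.3), _trial(y=y, choice=choice), p, m11)
            assert out.v_red == pytest.approx(0.3, abs=1e-9)

    @given(v=st.floats(0.01, 0.99), alpha=st.floats(0.01, 0.99),
           chose_red=st.booleans(), red_rewarded=st.booleans())
    def test_update_stays_in_unit_interval(self, v, alpha, chose_red, red_rewarded):
        m11 = vb.get_spec("M11")
        p = vb.AgentParams.for_spec(m11, temperature=0.5, alpha_pos_stable=alpha,
                                    alpha_neg_stable=alpha, alpha_pos_volatile=alpha,
                                    alpha_neg_volatile=alpha)
        t = _trial(y="red" if red_rewarded else "blue",
                   choice="red" if chose_red else "blue")
        out = vb.update_values(vb.ValueState(v), t, p, m11)
        assert 0.0 <= out.v_red <= 1.0


def hand_trace_m11():
    """Independent arithmetic trace of five trials under M11.

    tau = 0.5; alphas (pos/neg x stable/volatile) = 0.2/0.4, 0.6/0.8.
    """
    sig = lambda x: 1.0 / (1.0 + math.exp(-x))
    ll = []
    v = 0.5
    # t0: stable, red rewarded, chose red (win, delta>0 -> 0.2)
    ll.append(math.log(sig((2 * v - 1) / 0.5)))
    v = v + 0.2 * (1 - v)  # 0.6
    # t1: stable, blue rewarded, chose red (loss, delta<0 -> 0.4)
    ll.append(math.log(sig((2 * v - 1) / 0.5)))
    v = v + 0.4 * (0 - v)  # 0.36
    # t2: volatile, blue rewarded, chose blue (win, delta>0 -> 0.6)
    ll.append(math.log(1.0 - sig((2 * v - 1) / 0.5)))
    v = v + 0.6 * (0 - v)  # 0.144
    # t3: volatile, red rewarded, chose blue (loss, delta<0 -> 0.8)
    ll.append(math.log(1.0 - sig((2 * v - 1) / 0.5)))
    v = v + 0.8 * (1 - v)  # 0.8288
    # t4: volatile, red rewarded, chose red (win, delta>0 -> 0.6)
    ll.append(math.log(sig((2 * v - 1) / 0.5)))
    return np.array(ll)


def hand_trace_trials():
    spec = [("stable", "red", "red"), ("stable", "blue", "red"),
            ("volatile", "blue", "blue"), ("volatile", "red", "blue"),
            ("volatile", "red", "red")]
    return [_trial(condition=c, y=y, choice=ch, idx=i)
            for i, (c, y, ch) in enumerate(spec)]


class TestSessionLoglik:
    def test_null_closed_form(self, default_config):
        m0 = vb.get_spec("M0")
        p0 = vb.AgentParams(m0.model_id, {})
        sched = vb.generate_schedule(default_config, seed=0)
        records = vb.simulate_agent(m0, p0, sched, seed=0)
        total, per = vb.session_loglik(m0, p0, records)
        assert total == pytest.approx(160 * math.log(0.5), abs=1e-9)

    def test_empty_session(self, m11, m11_params):
        total, per = vb.session_loglik(m11, m11_params, [])
        assert total == 0.0 and per.size == 0

    def test_hand_trace(self, m11, m11_params):
        total, per = vb.session_loglik(m11, m11_params, hand_trace_trials())
        expected = hand_trace_m11()
        np.testing.assert_allclose(per, expected, atol=1e-12)
        assert total == pytest.approx(expected.sum(), abs=1e-12)

    def test_per_trial_sums_to_total(self, m11, m11_params, default_config):
        sched = vb.generate_schedule(default_config, seed=1)
        records = vb.simulate_agent(m11, m11_params, sched, seed=1)
        total, per = vb.session_loglik(m11, m11_params, records)
        assert total == pytest.approx(per.sum())

    def test_mixed_participants_rejected(self, m11, m11_params):
        trials = [_trial(pid="P1"), _trial(pid="P2", idx=1)]
        with pytest.raises(ValidationError):
            vb.session_loglik(m11, m11_params, trials)

    def test_nested_model_equality(self, default_config):
        """M11 with equal alphas matches the single-alpha rung exactly."""
        m11, m4 = vb.get_spec("M11"), vb.get_spec("M4")
        p11 = vb.AgentParams.for_spec(m11, temperature=0.37, alpha_pos_stable=0.55,
                                      alpha_neg_stable=0.55, alpha_pos_volatile=0.55,
                                      alpha_neg_volatile=0.55)
        p4 = vb.AgentParams.for_spec(m4, temperature=0.37, alpha=0.55)
        sched = vb.generate_schedule(default_config, seed=9)
        records = vb.simulate_agent(m11, p11, sched, seed=3)
        _, per11 = vb.session_loglik(m11, p11, records)
        _, per4 = vb.session_loglik(m4, p4, records)
        np.testing.assert_allclose(per11, per4, atol=1e-12)

    def test_python_and_kernel_paths_agree(self, m11, small_cohort):
        """The numba likelihood must match the reference loop exactly."""
        from volabandit import _likelihoods as lk

        cohort, trials = small_cohort
        sd = lk.pack_sessions(trials)
        ll, _ = lk.loglik_grad(m11, sd, cohort.theta())
        for i, pid in enumerate(sd.ids):
            one = trials[trials.participant_id == pid]
            k = list(cohort.ids).index(pid)
            total, _ = vb.session_loglik(m11, cohort.params[k], one)
            assert total == pytest.approx(ll[i], abs=1e-9)


class TestSimulation:
    def test_determinism(self, m11, m11_params, default_config):
        sched = vb.generate_schedule(default_config, seed=0)
        a = vb.simulate_agent(m11, m11_params, sched, seed=5)
        b = vb.simulate_agent(m11, m11_params, sched, seed=5)
        assert a == b

    def test_zero_alpha_agents_choose_at_chance(self, default_config):
        m4 = vb.get_spec("M4")
        p = vb.AgentParams.for_spec(m4, temperature=0.5, alpha=1e-9)
        sched = vb.generate_schedule(default_config, seed=0)
        reds = [sum(r.choice == "red" for r in vb.simulate_agent(m4, p, sched, seed=s))
                for s in range(60)]
        assert abs(np.mean(reds) / 160 - 0.5) < 0.02

    def test_greedy_slow_learner_locks_onto_stable_majority(self, default_config):
        """tau -> 0 with a slow-moving value estimate: after the estimate
        settles above 0.5 the agent picks the majority side on every trial,
        hitting the 75% schedule ceiling."""
        m4 = vb.get_spec("M4")
        p = vb.AgentParams.for_spec(m4, temperature=1e-4, alpha=0.1)
        sched = vb.generate_schedule(default_config, seed=0)
        recs = vb.simulate_agent(m4, p, sched, seed=1)
        late_stable = recs[20:80]
        assert np.mean([r.choice == "red" for r in late_stable]) > 0.9
        assert np.mean([r.chosen_rewarded for r in late_stable]) > 0.65

    def test_wsls_stays_after_win(self):
        m2 = vb.get_spec("M2")
        p = vb.AgentParams.for_spec(m2, stay_after_win=1.0 - 1e-12,
                                    shift_after_loss=1.0 - 1e-12)
        sched = vb.generate_schedule(vb.TaskConfig(), seed=0)
        recs = vb.simulate_agent(m2, p, sched, seed=2)
        for prev, cur in zip(recs, recs[1:]):
            if prev.chosen_rewarded:
                assert cur.choice == prev.choice
            else:
                assert cur.choice != prev.choice

    def test_grid_likelihood_recovers_generating_alpha(self, default_config):
        """Brute-force grid MLE over alpha centers on the generating value."""
        from volabandit import _likelihoods as lk

        m4 = vb.get_spec("M4")
        alpha_true, tau = 0.6, 0.3
        n_agents = 200
        sched = vb.generate_schedule(default_config, seed=0)
        y = np.tile([s.rewarded_stimulus == "red" for s in sched], (n_agents, 1)).astype(np.int8)
        cond = np.tile([s.condition == "volatile" for s in sched], (n_agents, 1)).astype(np.int8)
        lens = np.full(n_agents, 160, dtype=np.int64)
        theta_true = np.column_stack([np.full(n_agents, tau), np.full(n_agents, alpha_true)])
        rng = np.random.default_rng(42)
        c = lk.simulate_choices(m4, theta_true, y, cond, lens, rng)
        sd = lk.SessionData(ids=tuple(f"A{i}" for i in range(n_agents)),
                            y=y, c=c, cond=cond, lens=lens)
        grid = np.linspace(0.05, 0.95, 91)
        lls = np.empty((len(grid), n_agents))
        for j, a in enumerate(grid):
            th = np.column_stack([np.full(n_agents, tau), np.full(n_agents, a)])
            lls[j], _ = lk.loglik_grad(m4, sd, th)
        alpha_hat = grid[np.argmax(lls, axis=0)]
        assert abs(alpha_hat.mean() - alpha_true) < 0.05

    def test_high_negative_alpha_switches_faster_after_reversal(self, default_config):
        """Asymmetric-LR agents: big negative LR speeds post-reversal switching."""
        from volabandit import _likelihoods as lk

        m11 = vb.get_spec("M11")
        n = 200
        sched = vb.generate_schedule(default_config, seed=0)
        y = np.tile([s.rewarded_stimulus == "red" for s in sched], (n, 1)).astype(np.int8)
        cond = np.tile([s.condition == "volatile" for s in sched], (n, 1)).astype(np.int8)
        lens = np.full(n, 160, dtype=np.int64)

        def mean_post_reversal_accuracy(a_pos, a_neg, seed):
            theta = np.tile([0.2, a_pos, a_neg, a_pos, a_neg], (n, 1))
            c = lk.simulate_choices(m11, theta, y, cond, lens,
                                    np.random.default_rng(seed))
            correct = (c == y)
            # first 10 trials after each within-volatile reversal
            windows = [slice(100, 110), slice(120, 130), slice(140, 150)]
            return np.mean([correct[:, w].mean() for w in windows])

        fast_neg = mean_post_reversal_accuracy(0.2, 0.9, seed=7)
        slow_neg = mean_post_reversal_accuracy(0.9, 0.2, seed=7)
        assert fast_neg > slow_neg
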