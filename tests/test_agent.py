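"""Coupled AN-TN agent: trial loop, simulation, teacher forcing."""

import numpy as np
import pytest

import chunknet as ck
from chunknet.agent import LAPSE


class TestModelParams:
    def test_derived_constants(self):
        p = ck.ModelParams(alpha=0.4, beta=7, epsilon=0.0, QP=0.2)
        assert p.QM == pytest.approx(0.02)
        assert p.g_I == 0.5

    @pytest.mark.parametrize("kw", [
        {"alpha": 1.5}, {"alpha": -0.1}, {"beta": -1}, {"epsilon": 2},
        {"QP": -0.2}, {"J_INC": 1.2},
    ])
    def test_out_of_range_params_raise(self, kw):
        base = {"alpha": 0.4, "beta": 7.0, "epsilon": 0.0}
        with pytest.raises(ValueError):
            ck.ModelParams(**{**base, **kw})


class TestStepSemantics:
    def test_inference_disabled_equals_an_only_step(self, rng):
        p0 = ck.ModelParams(alpha=0.4, beta=7, epsilon=0.0, QP=0.17,
                            J_INC=0.0)
        a1 = ck.Agent(p0, 3, 4, with_inference=True)
        a2 = ck.Agent(p0, 3, 4, with_inference=False)
        for _ in range(50):
            s, act, r = (int(rng.integers(3)), int(rng.integers(4)),
                         int(rng.integers(2)))
            a1.learn(s, act, r)
            a2.learn(s, act, r)
        assert np.array_equal(a1.an, a2.an)
        assert np.array_equal(a1.tn, a2.tn)

    def test_idealized_first_rewarded_correct_saturates_taskset(self, rng):
        """With the fully chunked encoding and J_INC=1, one rewarded
        correct response drives every AN weight of the task-set to 1."""
        tasksets = ck.make_recurrent_tasksets(3, 4, rng)
        tn = ck.idealized_chunked_tn(tasksets, 3, 4)
        p = ck.ModelParams(alpha=0.4, beta=7, epsilon=0.0, QP=0.17,
                           J_INC=1.0)
        agent = ck.Agent(p, 3, 4, tn_weights=tn, freeze_tn=True)
        ts = tasksets[0]
        agent.learn(0, ts[0], reward=1)
        assert all(agent.an[s, a] == 1.0 for s, a in ts.items())

    def test_unrewarded_trial_has_zero_inference_magnitude(self, rng):
        p = ck.ModelParams(alpha=0.4, beta=7, epsilon=0.0, QP=0.17,
                           J_INC=0.7)
        agent = ck.Agent(p, 3, 4)
        _, im = agent.learn(0, 1, reward=0)
        assert im == 0.0

    def test_lapse_step_skips_all_updates(self):
        p = ck.ModelParams(alpha=0.4, beta=7, epsilon=0.0, QP=0.17,
                           J_INC=0.7)
        agent = ck.Agent(p, 3, 4)
        agent.learn(0, 1, 1)
        an, tn, prev = agent.an.copy(), agent.tn.copy(), agent.prev_pop
        rec, row = agent.step(2, forced_action=LAPSE)
        assert rec.action == LAPSE and np.isnan(row["p_chosen"])
        assert np.array_equal(agent.an, an)
        assert np.array_equal(agent.tn, tn)
        assert agent.prev_pop == prev


class TestSimulateSession:
    def test_fixed_seed_reproducible(self, sim_params, small_plan):
        d1, t1 = ck.simulate_session(sim_params, small_plan, True,
                                     np.random.default_rng(3))
        d2, t2 = ck.simulate_session(sim_params, small_plan, True,
                                     np.random.default_rng(3))
        assert np.array_equal(d1.action, d2.action)
        assert np.array_equal(t1.p_actions, t2.p_actions)

    def test_beta_zero_pins_performance_at_chance(self, small_plan, rng):
        p = ck.ModelParams(alpha=0.4, beta=0.0, epsilon=0.0)
        _, trace = ck.simulate_session(p, small_plan, False, rng)
        assert np.allclose(trace.p_correct, 0.25)

    def test_records_satisfy_reward_invariant(self, small_dataset):
        resp = small_dataset.action != LAPSE
        assert np.array_equal(
            small_dataset.reward[resp],
            (small_dataset.correct ^ small_dataset.noisy)[resp])

    def test_trace_invariants(self, sim_params, small_plan, rng):
        _, trace = ck.simulate_session(sim_params, small_plan, True, rng)
        assert np.allclose(trace.p_actions.sum(axis=1), 1.0)
        # inference magnitude is zero exactly on unrewarded trials
        data, trace = ck.simulate_session(sim_params, small_plan, True,
                                          np.random.default_rng(0))
        assert (trace.inference_magnitude[data.reward == 0] == 0).all()
        assert (trace.inference_magnitude[data.reward == 1] > 0).all()

    def test_inference_improves_late_performance_when_tn_slow(self, rng):
        """Paired sessions, QP < alpha: task-set retrieval raises the
        probability assigned to correct actions late in the session."""
        gains = []
        for seed in range(12):
            plan = ck.generate_session(ck.SessionConfig(n_episodes=15),
                                       np.random.default_rng(seed))
            p = ck.ModelParams(alpha=0.4, beta=7, epsilon=0.0, QP=0.17,
                               J_INC=0.7)
            late = slice(2 * plan.n_trials // 3, None)
            _, tw = ck.simulate_session(p, plan, True,
                                        np.random.default_rng(100 + seed))
            _, to = ck.simulate_session(p, plan, False,
                                        np.random.default_rng(100 + seed))
            gains.append(tw.p_correct[late].mean()
                         - to.p_correct[late].mean())
        assert np.mean(gains) > 0


class TestTeacherForcing:
    def test_replays_own_simulation_probabilities(self, sim_params,
                                                  small_plan):
        data, sim_trace = ck.simulate_session(sim_params, small_plan, True,
                                              np.random.default_rng(5))
        forced = ck.teacher_forced_run(sim_params, data, True)
        assert np.allclose(forced.p_actions, sim_trace.p_actions)
        assert np.allclose(forced.p_chosen, sim_trace.p_chosen)
        assert forced.active_sets == sim_trace.active_sets

    def test_variant_equivalence_without_inference(self, sim_params,
                                                   small_dataset):
        p0 = ck.ModelParams(alpha=sim_params.alpha, beta=sim_params.beta,
                            epsilon=sim_params.epsilon, QP=sim_params.QP,
                            J_INC=0.0)
        t1 = ck.teacher_forced_run(p0, small_dataset, with_inference=True)
        t2 = ck.teacher_forced_run(p0, small_dataset, with_inference=False)
        assert np.array_equal(t1.p_chosen, t2.p_chosen, equal_nan=True)
        assert t1.active_sets == t2.active_sets
        assert t1.log_likelihood == t2.log_likelihood

    def test_single_trial_fresh_state_is_uniform(self, sim_params):
        data = ck.BehaviorDataset(
            subject_id="s", session_type="recurrent",
            episode=np.array([0]), trial=np.array([0]),
            stimulus=np.array([1]), action=np.array([2]),
            reward=np.array([0]), correct=np.array([False]),
            noisy=np.array([False]), rt=np.array([np.nan]))
        trace = ck.teacher_forced_run(sim_params, data, True)
        assert trace.p_chosen[0] == pytest.approx(0.25)

    def test_unknown_action_id_raises(self, sim_params, small_dataset):
        bad = small_dataset
        bad.action[0] = 7
        with pytest.raises(ValueError):
            ck.teacher_forced_run(sim_params, bad, True)

    def test_lapses_skip_likelihood_and_updates(self, sim_params,
                                                small_dataset):
        full = ck.teacher_forced_run(sim_params, small_dataset, True)
        lapsed = small_dataset
        lapsed.action[10] = LAPSE
        lapsed.reward[10] = 0
        lapsed.correct[10] = False
        part = ck.teacher_forced_run(sim_params, lapsed, True)
        assert np.isnan(part.p_chosen[10])
        # downstream state differs (trial 10's updates are gone) but the
        # lapse contributes nothing to the likelihood
        assert np.isfinite(part.log_likelihood)


def test_overlapping_tasksets_depress_following_trials(rng):
    """Two task-sets sharing one association: the shared pair retrieves
    an ambiguous chunk, so performance on the trial after producing it
    is lower than after a non-shared correct pair."""
    ts1 = ck.TaskSet((0, 1, 2))
    ts2 = ck.TaskSet((3, 2, 1))
    ts3 = ck.TaskSet((0, 3, 1))   # shares (0, 0) with ts1
    sets = [ts1, ts2, ts3]
    shared_after, other_after = [], []
    for seed in range(15):
        rng = np.random.default_rng(seed)
        # balanced schedule without immediate repeats; the overlapping
        # pair ts1/ts3 may be adjacent (schedule override)
        schedule = [sets[rng.integers(3)]]
        while len(schedule) < 12:
            cand = sets[rng.integers(3)]
            if cand != schedule[-1]:
                schedule.append(cand)
        plan = ck.generate_session(ck.SessionConfig(n_episodes=12), rng,
                                   episode_tasksets=schedule)
        p = ck.ModelParams(alpha=0.4, beta=7, epsilon=0.0, QP=0.17,
                           J_INC=0.7)
        data, trace = ck.simulate_session(
            p, plan, True, np.random.default_rng(300 + seed))
        ep_of = plan.episode_of_trial
        for t in range(plan.n_trials - 1):
            ep = ep_of[t]
            # second half of the session, early in the episode, and
            # only trials where retrieval actually fired (closure > 1):
            # the shared pair retrieves an ambiguous chunk, non-shared
            # pairs retrieve their own task-set
            if ep < 6 or ep != ep_of[t + 1]:
                continue
            if data.trial[t] >= 12 or not data.correct[t]:
                continue
            act = trace.active_sets[t]
            if act is None or len(act) < 2:
                continue
            if (data.stimulus[t], data.action[t]) == (0, 0) \
                    and plan.tasksets[ep] in (ts1, ts3):
                shared_after.append(trace.p_correct[t + 1])
            else:
                other_after.append(trace.p_correct[t + 1])
    assert np.mean(shared_after) < np.mean(other_after)


def test_trace_exports_to_frame(sim_params, small_plan, rng):
    _, trace = ck.simulate_session(sim_params, small_plan, True, rng)
    frame = trace.to_frame()
    assert len(frame) == small_plan.n_trials
    assert {"p_action_0", "p_action_3", "w_chosen", "inference_magnitude",
            "active_cluster"} <= set(frame.columns)
    probs = frame[[f"p_action_{j}" for j in range(4)]].to_numpy()
    assert np.allclose(probs.sum(axis=1), 1.0)
    # cluster serialization round-trips to (stimulus, action) pairs
    row = frame["active_cluster"].iloc[-1]
    pairs = {tuple(map(int, tok.split(":"))) for tok in row.split("|")}
    assert pairs == set(trace.active_sets[-1])
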