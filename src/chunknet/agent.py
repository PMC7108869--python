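"""Coupled AN-TN agent: trial loop, simulation and teacher forcing.

Within a trial the agent (1) selects an action from the associative
network's softmax policy (or takes a recorded action in teacher-forced
mode), (2) receives the reward, (3) applies the AN reward-modulated
update, (4) computes the TN activation closure seeded by the trial's
stimulus-action conjunction, using the TN weights from the start of the
trial, (5) applies TN temporal-Hebbian plasticity, and (6) on rewarded
trials sends the inference signal: every AN weight whose conjunction is
in the active TN cluster is pushed toward 1 at rate ``J_INC``. The
inference thus biases the response to the *next* trial's stimulus.

The "without inference" model variant is the associative network alone;
it is behaviorally identical to the full model with ``J_INC = 0`` (a
tested equivalence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .environment import SessionPlan, TaskSet
from .taskset_network import DEFAULT_G_I, QM_OVER_QP

__all__ = [
    "ModelParams",
    "TrialRecord",
    "BehaviorDataset",
    "ModelTrace",
    "Agent",
    "simulate_session",
    "teacher_forced_run",
    "idealized_chunked_tn",
    "LAPSE",
]

#: Sentinel action id for a lapse (no recorded response).
LAPSE = -1


@dataclass(frozen=True)
class ModelParams:
    """The model's free parameters.

    alpha
        AN learning rate, in [0, 1].
    beta
        Inverse decision noise of the softmax (1/beta is the noise), >= 0.
    epsilon
        Undirected exploration: probability mass spread uniformly over
        actions, in [0, 1].
    QP
        TN potentiation rate, in [0, 1]. The depression rate is fixed at
        ``QM = QP / 10``.
    J_INC
        Strength of the TN -> AN inference signal, in [0, 1]. 0 disables
        task-set retrieval.

    The TN inhibition threshold ``g_I`` is fixed at 0.5 so that QP is
    the TN's only free parameter.
    """

    alpha: float
    beta: float
    epsilon: float
    QP: float = 0.0
    J_INC: float = 0.0
    g_I: float = DEFAULT_G_I

    def __post_init__(self) -> None:
        for name in ("alpha", "epsilon", "QP", "J_INC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def QM(self) -> float:
        return self.QP * QM_OVER_QP

    def without_inference(self) -> "ModelParams":
        return replace(self, QP=0.0, J_INC=0.0)


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial. ``action == LAPSE`` marks a missing response."""

    episode: int
    trial: int
    stimulus: int
    action: int
    reward: int
    correct: bool
    noisy: bool
    rt: float = float("nan")


@dataclass
class BehaviorDataset:
    """Per-trial behavioral log of one subject's session.

    Columns are parallel numpy arrays; ``trial`` counts within episode.
    The invariant ``reward == correct XOR noisy`` holds on every trial
    with a recorded action.
    """

    subject_id: str
    session_type: str
    episode: np.ndarray
    trial: np.ndarray
    stimulus: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    correct: np.ndarray
    noisy: np.ndarray
    rt: np.ndarray
    n_stimuli: int = 3
    n_actions: int = 4
    schedule: list[TaskSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.stimulus)
        for name in ("episode", "trial", "action", "reward", "correct",
                     "noisy", "rt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        resp = self.action != LAPSE
        bad = np.flatnonzero(
            resp & (self.reward != (self.correct ^ self.noisy)))
        if bad.size:
            raise ValueError(
                f"reward != correct XOR noisy at row {int(bad[0])}")

    @property
    def n_trials(self) -> int:
        return len(self.stimulus)

    @property
    def n_responses(self) -> int:
        """Number of non-lapse trials."""
        return int((self.action != LAPSE).sum())

    def records(self):
        for i in range(self.n_trials):
            yield TrialRecord(int(self.episode[i]), int(self.trial[i]),
                              int(self.stimulus[i]), int(self.action[i]),
                              int(self.reward[i]), bool(self.correct[i]),
                              bool(self.noisy[i]), float(self.rt[i]))


@dataclass
class ModelTrace:
    """Per-trial internal quantities of a model run.

    p_actions
        Full action-probability vector at decision time.
    p_correct
        Probability assigned to the correct action (the model's
        trial performance in simulation).
    p_chosen
        Probability of the executed (or recorded) action; NaN on lapses.
    w_chosen
        AN weight of the chosen association at decision time.
    inference_magnitude
        Mean of ``J_INC * (1 - J_AN)`` over the AN synapses updated by
        the inference signal; 0 on unrewarded trials and when J_INC=0.
    active_sets
        Per trial, the TN activation closure as a tuple of
        (stimulus, action) pairs (None on lapses).
    """

    p_actions: np.ndarray
    p_correct: np.ndarray
    p_chosen: np.ndarray
    w_chosen: np.ndarray
    inference_magnitude: np.ndarray
    active_sets: list
    an_weights: np.ndarray
    tn_weights: np.ndarray

    @property
    def log_likelihood(self) -> float:
        """Sum of log probabilities of the executed actions (lapses skipped)."""
        p = self.p_chosen[~np.isnan(self.p_chosen)]
        return float(np.log(p).sum())

    def to_frame(self):
        """Per-trial table: action probabilities, chosen-association
        weight, inference magnitude, and the active TN cluster
        serialized as ``stimulus:action`` pairs."""
        import pandas as pd

        cols = {f"p_action_{j}": self.p_actions[:, j]
                for j in range(self.p_actions.shape[1])}
        cols.update(p_correct=self.p_correct, p_chosen=self.p_chosen,
                    w_chosen=self.w_chosen,
                    inference_magnitude=self.inference_magnitude,
                    active_cluster=[
                        "" if act is None else
                        "|".join(f"{s}:{a}" for s, a in act)
                        for act in self.active_sets])
        return pd.DataFrame(cols)


class Agent:
    """Stateful AN-TN agent.

    Parameters
    ----------
    params : ModelParams
    n_stimuli, n_actions : int
        Session dimensions.
    with_inference : bool
        If False the TN -> AN inference signal is disabled (the TN still
        runs, so traces of the two variants are directly comparable).
    tn_weights : ndarray, optional
        Initial TN weight matrix, e.g. from :func:`idealized_chunked_tn`.
    freeze_tn : bool
        Disable TN plasticity (used with idealized TN encodings).
    track_tn : bool
        If False the TN is skipped entirely; valid only when its output
        cannot influence behavior (inference disabled). Fast path for
        likelihood evaluation of the AN-only variant.
    depress_active_set : bool
        If True (default), pre-activated depression applies to the
        outgoing synapses of *every* population with activity 1 — the
        driven conjunction and all populations co-activated through the
        closure. If False, only the driven conjunction's synapses decay
        (the single-pair primitive of
        :func:`chunknet.taskset_network.tn_update` applied verbatim).
        The active-set form is the stable one: co-activation then
        accelerates the decay of a cluster's stray outgoing synapses,
        and spurious weights (notably between conjunctions sharing a
        stimulus) are held well below the activation threshold instead
        of creeping across it during exploration and merging clusters.
    cluster_potentiation : bool
        If True, temporal potentiation links *all* populations active on
        consecutive trials rather than only the two directly driven
        conjunctions. Off by default: once two clusters co-activate,
        cluster-wide potentiation locks them into a single blob that
        depression can no longer separate. Exposed for sensitivity
        analysis.
    """

    def __init__(self, params: ModelParams, n_stimuli: int, n_actions: int,
                 with_inference: bool = True,
                 tn_weights: np.ndarray | None = None,
                 freeze_tn: bool = False,
                 track_tn: bool = True,
                 depress_active_set: bool = True,
                 cluster_potentiation: bool = False):
        self.params = params
        self.n_stimuli = n_stimuli
        self.n_actions = n_actions
        self.with_inference = with_inference
        self.freeze_tn = freeze_tn
        self.inference_on = with_inference and params.J_INC > 0
        if not track_tn and self.inference_on:
            raise ValueError("cannot skip the TN while inference is active")
        self.track_tn = track_tn
        self.depress_active_set = depress_active_set
        self.cluster_potentiation = cluster_potentiation
        self.an = np.zeros((n_stimuli, n_actions))
        n_pop = n_stimuli * n_actions
        if tn_weights is not None:
            if tn_weights.shape != (n_pop, n_pop):
                raise ValueError("tn_weights has wrong shape")
            self.tn = np.array(tn_weights, dtype=float)
        else:
            self.tn = np.zeros((n_pop, n_pop))
        self.prev_pop: int | None = None  # persists across episode switches
        self.prev_active: np.ndarray | None = None  # closure on trial t-1

    # -- decision ----------------------------------------------------------

    def action_probabilities(self, stimulus: int) -> np.ndarray:
        z = self.params.beta * self.an[stimulus]
        z = z - z.max()
        e = np.exp(z)
        return self.params.epsilon / self.n_actions \
            + (1.0 - self.params.epsilon) * e / e.sum()

    # -- learning ----------------------------------------------------------

    def _closure_mask(self, seed: int) -> np.ndarray:
        above = self.tn >= self.params.g_I
        active = np.zeros(self.tn.shape[0], dtype=bool)
        active[seed] = True
        frontier = [seed]
        while len(frontier):
            reached = above[frontier].any(axis=0) & ~active
            active |= reached
            frontier = np.flatnonzero(reached)
        return active

    def learn(self, stimulus: int, action: int, reward: int
              ) -> tuple[np.ndarray | None, float]:
        """Apply all plasticity for one executed trial.

        Returns the TN active mask (None if the TN is skipped) and the
        inference magnitude.
        """
        p = self.params
        # (3) AN reward-modulated update, presented stimulus' row only
        row = self.an[stimulus]
        old = row[action]
        if reward:
            row *= 1.0 - p.alpha
            row[action] = old + p.alpha * (1.0 - old)
        else:
            row += p.alpha * (1.0 - row)
            row[action] = (1.0 - p.alpha) * old

        if not self.track_tn:
            return None, 0.0

        curr = stimulus * self.n_actions + action
        # (4) activation closure with start-of-trial TN weights
        mask = self._closure_mask(curr)
        # (5) TN plasticity: depression of the active populations'
        # outgoing synapses first, then temporal potentiation
        if not self.freeze_tn:
            if self.depress_active_set:
                self.tn[mask] *= 1.0 - p.QM
            else:
                self.tn[curr] *= 1.0 - p.QM
            if self.cluster_potentiation:
                if self.prev_active is not None:
                    blk = self.tn[np.ix_(self.prev_active, mask)]
                    self.tn[np.ix_(self.prev_active, mask)] = \
                        blk + p.QP * (1.0 - blk)
                    np.fill_diagonal(self.tn, 0.0)
            else:
                prev = self.prev_pop
                if prev is not None and prev != curr:
                    w = self.tn[prev, curr]
                    self.tn[prev, curr] = w + p.QP * (1.0 - w)
        self.prev_pop = curr
        self.prev_active = mask
        # (6) inference: push AN weights of the active cluster toward 1
        inf_mag = 0.0
        if reward and self.inference_on:
            idx = np.flatnonzero(mask)
            s_idx, a_idx = np.divmod(idx, self.n_actions)
            w = self.an[s_idx, a_idx]
            deltas = p.J_INC * (1.0 - w)
            inf_mag = float(deltas.mean())
            self.an[s_idx, a_idx] = w + deltas
        return mask, inf_mag

    # -- public stepping ---------------------------------------------------

    def step(self, stimulus: int,
             forced_action: int | None = None,
             reward: int | None = None,
             task_set: TaskSet | None = None,
             noisy: bool = False,
             rng: np.random.Generator | None = None,
             episode: int = 0, trial: int = 0,
             ) -> tuple[TrialRecord, dict]:
        """Execute one trial and return its record and trace row.

        The action is ``forced_action`` if given (teacher forcing; pass
        ``LAPSE`` for a missing response, which skips all updates), else
        sampled from the current policy. The reward is ``reward`` if
        given, else computed from ``task_set`` and ``noisy``.
        """
        probs = self.action_probabilities(stimulus)
        if forced_action is None:
            if rng is None:
                raise ValueError("rng required to sample an action")
            action = int(np.searchsorted(np.cumsum(probs), rng.random(),
                                         side="right").clip(0, probs.size - 1))
        else:
            action = forced_action

        if action == LAPSE:
            rec = TrialRecord(episode, trial, stimulus, LAPSE, 0, False, noisy)
            return rec, {"p_actions": probs, "p_chosen": float("nan"),
                         "w_chosen": float("nan"), "active": None,
                         "inference_magnitude": 0.0}

        correct = task_set is not None and action == task_set[stimulus]
        if reward is None:
            if task_set is None:
                raise ValueError("need a reward or a task_set")
            reward = int(correct != noisy)
        w_chosen = float(self.an[stimulus, action])
        mask, inf_mag = self.learn(stimulus, action, int(reward))
        rec = TrialRecord(episode, trial, stimulus, action, int(reward),
                          bool(correct), bool(noisy))
        return rec, {"p_actions": probs, "p_chosen": float(probs[action]),
                     "w_chosen": w_chosen, "active": mask,
                     "inference_magnitude": inf_mag}


def idealized_chunked_tn(tasksets: list[TaskSet], n_stimuli: int,
                         n_actions: int, weight: float = 0.7) -> np.ndarray:
    """TN weight matrix with perfect, fully chunked task-set encoding.

    All populations belonging to one task-set are mutually connected at
    ``weight`` (above the 0.5 threshold); all other synapses are 0. With
    this encoding a single correct association retrieves its entire
    task-set.
    """
    n = n_stimuli * n_actions
    tn = np.zeros((n, n))
    for ts in tasksets:
        idx = [s * n_actions + a for s, a in ts.items()]
        for i in idx:
            for j in idx:
                if i != j:
                    tn[i, j] = weight
    return tn


def _mask_to_pairs(mask: np.ndarray | None, n_actions: int):
    if mask is None:
        return None
    return tuple((int(i) // n_actions, int(i) % n_actions)
                 for i in np.flatnonzero(mask))


def simulate_session(params: ModelParams, plan: SessionPlan,
                     with_inference: bool,
                     rng: np.random.Generator,
                     tn_weights: np.ndarray | None = None,
                     freeze_tn: bool = False,
                     subject_id: str = "sim",
                     collect_trace: bool = True,
                     ) -> tuple[BehaviorDataset, ModelTrace | None]:
    """Free-running simulation of one session.

    The agent's actions are sampled trial by trial from its own policy;
    feedback follows the plan's task-set schedule and noise mask. The
    trace records the probability the model assigns to the correct
    action on every trial (the model's performance measure).
    """
    cfg = plan.config
    agent = Agent(params, cfg.n_stimuli, cfg.n_actions, with_inference,
                  tn_weights=tn_weights, freeze_tn=freeze_tn)
    n = plan.n_trials
    stimuli = plan.stimuli
    noisy = plan.noisy
    episode_of = plan.episode_of_trial
    correct_act = plan.correct_actions

    actions = np.empty(n, dtype=int)
    rewards = np.empty(n, dtype=int)
    correct = np.empty(n, dtype=bool)
    trial_in_ep = np.empty(n, dtype=int)
    if collect_trace:
        p_actions = np.empty((n, cfg.n_actions))
        p_corr = np.empty(n)
        p_chosen = np.empty(n)
        w_chosen = np.empty(n)
        inf_mag = np.empty(n)
        active_sets: list = []

    tcount = 0
    last_ep = -1
    cum = np.empty(cfg.n_actions)
    for t in range(n):
        ep = episode_of[t]
        if ep != last_ep:
            tcount, last_ep = 0, ep
        s = int(stimuli[t])
        probs = agent.action_probabilities(s)
        np.cumsum(probs, out=cum)
        a = int(np.searchsorted(cum, rng.random(), side="right"))
        if a >= cfg.n_actions:
            a = cfg.n_actions - 1
        c = a == correct_act[t]
        r = int(c != noisy[t])
        wch = agent.an[s, a]
        mask, im = agent.learn(s, a, r)
        actions[t], rewards[t], correct[t] = a, r, c
        trial_in_ep[t] = tcount
        tcount += 1
        if collect_trace:
            p_actions[t] = probs
            p_corr[t] = probs[correct_act[t]]
            p_chosen[t] = probs[a]
            w_chosen[t] = wch
            inf_mag[t] = im
            active_sets.append(_mask_to_pairs(mask, cfg.n_actions))

    data = BehaviorDataset(
        subject_id=subject_id, session_type=cfg.session_type,
        episode=episode_of.copy(), trial=trial_in_ep,
        stimulus=stimuli.copy(), action=actions, reward=rewards,
        correct=correct, noisy=noisy.copy(), rt=np.full(n, np.nan),
        n_stimuli=cfg.n_stimuli, n_actions=cfg.n_actions,
        schedule=list(plan.tasksets))
    if not collect_trace:
        return data, None
    trace = ModelTrace(p_actions, p_corr, p_chosen, w_chosen, inf_mag,
                       active_sets, agent.an.copy(), agent.tn.copy())
    return data, trace


def teacher_forced_run(params: ModelParams, dataset: BehaviorDataset,
                       with_inference: bool,
                       tn_weights: np.ndarray | None = None,
                       freeze_tn: bool = False,
                       collect_trace: bool = True,
                       ) -> ModelTrace | float:
    """Evolve the model under a subject's recorded actions and rewards.

    Returns the full trace, including the per-trial probability the
    model assigns to the recorded action — the model's performance on a
    trial, and the basis of the fitting likelihood. Lapse trials
    (missing action) are skipped entirely: no probability, no updates.

    With ``collect_trace=False`` only the summed log-likelihood of the
    recorded actions is returned (fast path used by the fitter).
    """
    nS, nA = dataset.n_stimuli, dataset.n_actions
    if dataset.stimulus.size and (dataset.stimulus.min() < 0
                                  or dataset.stimulus.max() >= nS):
        raise ValueError("stimulus id out of range for this configuration")
    resp = dataset.action != LAPSE
    if resp.any() and dataset.action[resp].max() >= nA:
        raise ValueError("action id out of range for this configuration")

    track_tn = collect_trace or (with_inference and params.J_INC > 0)
    agent = Agent(params, nS, nA, with_inference, tn_weights=tn_weights,
                  freeze_tn=freeze_tn, track_tn=track_tn)
    n = dataset.n_trials
    stimuli = dataset.stimulus
    actions = dataset.action
    rewards = dataset.reward

    if collect_trace:
        p_actions = np.empty((n, nA))
        p_chosen = np.full(n, np.nan)
        p_corr = np.full(n, np.nan)
        w_chosen = np.full(n, np.nan)
        inf_mag = np.zeros(n)
        active_sets: list = []
        correct_act = None
        if dataset.schedule:
            per_ep = np.array([ts.actions for ts in dataset.schedule])
            correct_act = per_ep[dataset.episode, stimuli]
    logp = 0.0

    for t in range(n):
        a = actions[t]
        if a == LAPSE:
            if collect_trace:
                p_actions[t] = agent.action_probabilities(int(stimuli[t]))
                if correct_act is not None:
                    p_corr[t] = p_actions[t][correct_act[t]]
                active_sets.append(None)
            continue
        s = int(stimuli[t])
        probs = agent.action_probabilities(s)
        logp += np.log(probs[a])
        wch = agent.an[s, a]
        mask, im = agent.learn(s, int(a), int(rewards[t]))
        if collect_trace:
            p_actions[t] = probs
            p_chosen[t] = probs[a]
            if correct_act is not None:
                p_corr[t] = probs[correct_act[t]]
            w_chosen[t] = wch
            inf_mag[t] = im
            active_sets.append(_mask_to_pairs(mask, nA))

    if not collect_trace:
        return float(logp)
    return ModelTrace(p_actions, p_corr, p_chosen, w_chosen, inf_mag,
                      active_sets, agent.an.copy(), agent.tn.copy())
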