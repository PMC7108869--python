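"""Task environment: task-sets, episode schedules, stimuli and feedback.

The task is a trial-and-error association experiment. On each trial a
stimulus is shown, the agent presses one of several response keys, and a
binary feedback follows. The set of correct stimulus->response
associations (the *task-set*) stays fixed for an uncued block of trials
(an *episode*) and then switches to a non-overlapping set. A fixed
fraction of trials carries misleading (inverted) feedback.

Stimuli and actions are 0-based integer ids throughout;
:data:`STIMULUS_LABELS` and :data:`ACTION_LABELS` give the display labels
used in the original experiment.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "TaskSet",
    "SessionConfig",
    "SessionPlan",
    "make_recurrent_tasksets",
    "next_episode_taskset",
    "generate_session",
    "feedback",
    "STIMULUS_LABELS",
    "ACTION_LABELS",
]

#: Display labels for the default 3-stimulus / 4-action design.
STIMULUS_LABELS = ("1", "3", "5")
ACTION_LABELS = ("d", "f", "j", "k")


@dataclass(frozen=True)
class TaskSet:
    """An injective stimulus -> action mapping.

    ``actions[i]`` is the correct action id for stimulus ``i``. Two
    stimuli are never mapped to the same action.
    """

    actions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.actions)) != len(self.actions):
            raise ValueError(f"task-set must be injective, got {self.actions}")

    def __getitem__(self, stimulus: int) -> int:
        return self.actions[stimulus]

    def __len__(self) -> int:
        return len(self.actions)

    def items(self):
        """Iterate over (stimulus, action) pairs."""
        return enumerate(self.actions)

    def overlap(self, other: "TaskSet") -> int:
        """Number of stimulus-action pairs shared with ``other``."""
        return sum(a == b for a, b in zip(self.actions, other.actions))


def _random_injective_map(n_stimuli: int, n_actions: int,
                          rng: np.random.Generator) -> TaskSet:
    return TaskSet(tuple(int(a) for a in
                         rng.choice(n_actions, size=n_stimuli, replace=False)))


def make_recurrent_tasksets(n_stimuli: int, n_actions: int,
                            rng: np.random.Generator,
                            n_sets: int = 3) -> list[TaskSet]:
    """Draw ``n_sets`` pairwise non-overlapping injective task-sets.

    Pairwise non-overlapping means no two sets share any stimulus-action
    pair, so an episode switch within the pool changes the correct
    response to every stimulus. Feasible iff ``n_sets <= n_actions``
    (each stimulus needs ``n_sets`` distinct images).

    Raises
    ------
    ValueError
        If no such family of maps exists.
    """
    if n_actions < n_stimuli:
        raise ValueError("need n_actions >= n_stimuli for injective task-sets")
    if n_sets > n_actions:
        raise ValueError(
            f"cannot build {n_sets} pairwise-disjoint injective maps "
            f"with only {n_actions} actions")
    # Rejection sampling explores the full space; the cyclic construction
    # below is a guaranteed fallback for tightly constrained designs.
    for _ in range(2000):
        sets = [_random_injective_map(n_stimuli, n_actions, rng)]
        ok = True
        for _ in range(n_sets - 1):
            for _ in range(200):
                cand = _random_injective_map(n_stimuli, n_actions, rng)
                if all(cand.overlap(s) == 0 for s in sets):
                    sets.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return sets
    # Cyclic shifts of a random injective base map along a random action
    # permutation are pairwise disjoint by construction.
    perm = [int(a) for a in rng.permutation(n_actions)]
    base = [int(i) for i in rng.choice(n_actions, n_stimuli, replace=False)]
    inv = {a: i for i, a in enumerate(perm)}
    return [
        TaskSet(tuple(perm[(inv[base[s]] + k) % n_actions]
                      for s in range(n_stimuli)))
        for k in range(n_sets)
    ]


def all_injective_tasksets(n_stimuli: int, n_actions: int) -> list[TaskSet]:
    """Enumerate every injective stimulus -> action map."""
    return [TaskSet(p) for p in
            itertools.permutations(range(n_actions), n_stimuli)]


def next_episode_taskset(session_type: str,
                         previous: TaskSet | None,
                         pool: list[TaskSet],
                         rng: np.random.Generator,
                         forbidden: set[TaskSet] | None = None) -> TaskSet:
    """Pick the next episode's task-set with zero overlap with ``previous``.

    For a recurrent session ``pool`` is the fixed family of reoccurring
    sets and the draw is uniform over the members other than ``previous``.
    For an open-ended session ``pool`` is the full space of injective
    maps; ``forbidden`` excludes full mappings already used in the
    session so no task-set repeats. When every unused map overlaps the
    previous episode's set (a small design can exhaust the 24 injective
    maps of the 3x4 default before 25 episodes), the no-repeat
    constraint is relaxed and only non-overlap is enforced.
    """
    forbidden = forbidden or set()
    if session_type == "recurrent":
        candidates = [ts for ts in pool if ts != previous]
    else:
        fresh = [ts for ts in pool
                 if previous is None or ts.overlap(previous) == 0]
        candidates = [ts for ts in fresh if ts not in forbidden] or fresh
    if not candidates:
        raise ValueError("no admissible task-set for the next episode")
    return candidates[int(rng.integers(len(candidates)))]


@dataclass
class SessionConfig:
    """Design constants of one experimental session."""

    n_stimuli: int = 3
    n_actions: int = 4
    n_episodes: int = 25
    episode_length_range: tuple[int, int] = (36, 54)
    noise_fraction: float = 0.10
    session_type: str = "recurrent"
    n_recurrent_tasksets: int = 3

    def __post_init__(self) -> None:
        if self.n_actions < self.n_stimuli:
            raise ValueError("n_actions must be >= n_stimuli")
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must be in [0, 1)")
        lo, hi = self.episode_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid episode_length_range")
        if self.session_type not in ("recurrent", "open_ended"):
            raise ValueError(f"unknown session_type {self.session_type!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "episode_length_range" in d:
            d["episode_length_range"] = tuple(d["episode_length_range"])
        return cls(**d)


@dataclass
class SessionPlan:
    """A fully materialized session: episodes, stimuli and noise mask."""

    config: SessionConfig
    tasksets: list[TaskSet]        # one per episode
    lengths: np.ndarray            # trials per episode
    stimuli: np.ndarray            # per-trial stimulus id
    noisy: np.ndarray              # per-trial bool, feedback inverted
    pool: list[TaskSet] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return int(self.lengths.sum())

    @property
    def episode_of_trial(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.lengths)), self.lengths)

    @property
    def correct_actions(self) -> np.ndarray:
        """Per-trial correct action under the episode's task-set."""
        per_episode = np.array([ts.actions for ts in self.tasksets])
        return per_episode[self.episode_of_trial, self.stimuli]

    def to_json(self) -> str:
        return json.dumps({
            "config": asdict(self.config),
            "tasksets": [list(ts.actions) for ts in self.tasksets],
            "lengths": self.lengths.tolist(),
            "stimuli": self.stimuli.tolist(),
            "noisy": self.noisy.astype(int).tolist(),
            "pool": [list(ts.actions) for ts in self.pool],
        })

    @classmethod
    def from_json(cls, s: str) -> "SessionPlan":
        d = json.loads(s)
        return cls(
            config=SessionConfig.from_dict(d["config"]),
            tasksets=[TaskSet(tuple(a)) for a in d["tasksets"]],
            lengths=np.asarray(d["lengths"], dtype=int),
            stimuli=np.asarray(d["stimuli"], dtype=int),
            noisy=np.asarray(d["noisy"], dtype=bool),
            pool=[TaskSet(tuple(a)) for a in d.get("pool", [])],
        )


def generate_session(config: SessionConfig,
                     rng: np.random.Generator,
                     episode_tasksets: list[TaskSet] | None = None,
                     ) -> SessionPlan:
    """Generate one session plan.

    Episode lengths are discrete uniform on the configured range. The
    stimulus sequence is pseudo-randomized: uniform over the stimulus
    set with no immediate repetitions (each trial's stimulus is drawn
    uniformly from the other stimuli). The number of
    misleading-feedback trials is exactly
    ``round(noise_fraction * n_trials)`` with shuffled positions.

    ``episode_tasksets`` overrides the task-set schedule (e.g. to study
    deliberately overlapping task-sets); the non-overlap constraint is
    then not enforced.
    """
    lo, hi = config.episode_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_episodes)

    if episode_tasksets is not None:
        if len(episode_tasksets) != config.n_episodes:
            raise ValueError("episode_tasksets length must equal n_episodes")
        tasksets = list(episode_tasksets)
        pool: list[TaskSet] = []
    elif config.session_type == "recurrent":
        pool = make_recurrent_tasksets(config.n_stimuli, config.n_actions,
                                       rng, config.n_recurrent_tasksets)
        tasksets = []
        prev: TaskSet | None = None
        for _ in range(config.n_episodes):
            prev = next_episode_taskset("recurrent", prev, pool, rng)
            tasksets.append(prev)
    else:
        pool = all_injective_tasksets(config.n_stimuli, config.n_actions)
        tasksets = []
        used: set[TaskSet] = set()
        prev = None
        for _ in range(config.n_episodes):
            prev = next_episode_taskset("open_ended", prev, pool, rng, used)
            used.add(prev)
            tasksets.append(prev)

    n = int(lengths.sum())
    if config.n_stimuli == 1:
        stimuli = np.zeros(n, dtype=int)
    else:
        # uniform with no immediate repetition: draw a uniform shift in
        # {1, .., n_stimuli - 1} relative to the previous stimulus
        shifts = rng.integers(1, config.n_stimuli, size=n)
        stimuli = np.empty(n, dtype=int)
        stimuli[0] = rng.integers(config.n_stimuli)
        prev = int(stimuli[0])
        for t in range(1, n):
            prev = (prev + int(shifts[t])) % config.n_stimuli
            stimuli[t] = prev
    n_noisy = round(config.noise_fraction * n)
    noisy = np.zeros(n, dtype=bool)
    noisy[rng.choice(n, size=n_noisy, replace=False)] = True
    return SessionPlan(config=config, tasksets=tasksets,
                       lengths=np.asarray(lengths, dtype=int),
                       stimuli=stimuli, noisy=noisy, pool=pool)


def feedback(task_set: TaskSet, stimulus: int, action: int,
             noisy: bool) -> int:
    """Binary reward: correctness XOR'd with the misleading-trial flag.

    A correct association is rewarded unless the trial is a noisy one;
    an incorrect association is rewarded exactly when it is.
    """
    if not 0 <= stimulus < len(task_set):
        raise ValueError(f"stimulus {stimulus} out of range")
    if action < 0:
        raise ValueError(f"invalid action {action}")
    correct = action == task_set[stimulus]
    return int(correct != bool(noisy))
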