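"""Synthetic behavioral cohorts and behavioral-data CSV I/O.

The original subjects' data are not redistributable, so analyses and
fitting pipelines run on synthetic cohorts: agents simulated on the
same task, with per-subject parameters drawn around the means estimated
from the human cohort (learning rate alpha ~ 0.35, TN rate QP ~ 0.17,
inference strength J_INC ~ 0.70 in the recurrent session and ~ 0.16 in
the open-ended one). Lapses are emulated by deleting responses on a
configurable fraction of trials.

Behavioral data interchange is a single CSV (one row per trial) with a
commented JSON header carrying the session dimensions and, when known,
the per-episode task-set schedules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import LAPSE, BehaviorDataset, ModelParams, simulate_session
from .environment import SessionConfig, TaskSet, generate_session

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "write_behavior_csv",
    "read_behavior_csv",
    "COLUMNS",
]

COLUMNS = ["subject", "session", "episode", "trial", "stimulus", "action",
           "reward", "correct", "noisy", "rt"]

_HEADER_TAG = "# chunknet-behavior-v1 "

#: Cohort parameter distributions: (mean, sd), or a point value.
#: Means follow the human-cohort estimates; J_INC depends on session type.
DEFAULT_PARAMS = {
    "alpha": (0.35, 0.0073),
    "beta": 7.0,
    "epsilon": 0.05,
    "QP": (0.17, 0.0070),
    "J_INC": {"recurrent": (0.70, 0.037), "open_ended": (0.16, 0.0062)},
}


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    ``params`` entries may be a point value, a ``(mean, sd)`` pair
    (sampled from a truncated normal within the parameter's range), or a
    dict keyed by session type.
    """

    n_subjects: int = 22
    session_types: tuple[str, ...] = ("recurrent",)
    params: dict = field(default_factory=dict)
    lapse_rate: float = 0.0
    seed: int = 0
    config: dict = field(default_factory=dict)

    def resolved_params(self) -> dict:
        return {**DEFAULT_PARAMS, **self.params}


def _draw(value, session_type: str, rng: np.random.Generator,
          lo: float = 0.0, hi: float = 1.0) -> float:
    if isinstance(value, dict):
        value = value[session_type]
    if isinstance(value, (tuple, list)):
        mean, sd = value
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                return float(v)
        return float(np.clip(mean, lo, hi))
    return float(value)


def _draw_params(spec: CohortSpec, session_type: str,
                 rng: np.random.Generator) -> ModelParams:
    p = spec.resolved_params()
    return ModelParams(
        alpha=_draw(p["alpha"], session_type, rng),
        beta=_draw(p["beta"], session_type, rng, hi=50.0),
        epsilon=_draw(p["epsilon"], session_type, rng),
        QP=_draw(p["QP"], session_type, rng),
        J_INC=_draw(p["J_INC"], session_type, rng),
    )


def _inject_lapses(data: BehaviorDataset, rate: float,
                   rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    n = data.n_trials
    k = round(rate * n)
    idx = rng.choice(n, size=k, replace=False)
    data.action[idx] = LAPSE
    data.reward[idx] = 0
    data.correct[idx] = False


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[BehaviorDataset], pd.DataFrame]:
    """Simulate a cohort; returns datasets and the ground-truth table.

    One session per subject and session type. Each subject's parameters
    are drawn once per session type from the spec's distributions, the
    agent is simulated on a freshly generated session plan, and lapses
    are injected by deleting responses. The same master seed reproduces
    the cohort exactly.
    """
    root = np.random.SeedSequence(spec.seed)
    datasets: list[BehaviorDataset] = []
    truth_rows = []
    for i, child in enumerate(root.spawn(spec.n_subjects)):
        rng = np.random.default_rng(child)
        subject = f"S{i:03d}"
        for session_type in spec.session_types:
            params = _draw_params(spec, session_type, rng)
            cfg = SessionConfig(session_type=session_type, **spec.config)
            plan = generate_session(cfg, rng)
            data, _ = simulate_session(params, plan, with_inference=True,
                                       rng=rng, subject_id=subject,
                                       collect_trace=False)
            _inject_lapses(data, spec.lapse_rate, rng)
            datasets.append(data)
            truth_rows.append({"subject": subject, "session": session_type,
                               "alpha": params.alpha, "beta": params.beta,
                               "epsilon": params.epsilon, "QP": params.QP,
                               "J_INC": params.J_INC})
    return datasets, pd.DataFrame(truth_rows)


def _dataset_frame(data: BehaviorDataset) -> pd.DataFrame:
    action = pd.array(data.action, dtype="Int64")
    action[data.action == LAPSE] = pd.NA
    return pd.DataFrame({
        "subject": data.subject_id, "session": data.session_type,
        "episode": data.episode, "trial": data.trial,
        "stimulus": data.stimulus, "action": action,
        "reward": data.reward, "correct": data.correct.astype(int),
        "noisy": data.noisy.astype(int), "rt": data.rt,
    })


def write_behavior_csv(datasets: list[BehaviorDataset] | BehaviorDataset,
                       path) -> None:
    """Write one or more behavioral datasets to a single CSV file.

    Missing actions (lapses) are written as empty fields. A commented
    JSON header records the session dimensions and the task-set
    schedules, making the round trip lossless.
    """
    if isinstance(datasets, BehaviorDataset):
        datasets = [datasets]
    for d in datasets:
        resp = d.action != LAPSE
        bad = np.flatnonzero(resp & (d.reward != (d.correct ^ d.noisy)))
        if bad.size:
            raise ValueError(
                f"{d.subject_id}: reward != correct XOR noisy at "
                f"row {int(bad[0])}")
    meta = {"n_stimuli": datasets[0].n_stimuli,
            "n_actions": datasets[0].n_actions,
            "schedules": {f"{d.subject_id}|{d.session_type}":
                          [list(ts.actions) for ts in d.schedule]
                          for d in datasets if d.schedule}}
    frame = pd.concat([_dataset_frame(d) for d in datasets],
                      ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_HEADER_TAG + json.dumps(meta) + "\n")
        frame.to_csv(fh, index=False)


def read_behavior_csv(path) -> list[BehaviorDataset]:
    """Read behavioral datasets from CSV, one per (subject, session).

    Validates the schema and the per-row invariant
    ``reward == correct XOR noisy`` for trials with a response.
    """
    with open(path) as fh:
        first = fh.readline()
        meta = (json.loads(first[len(_HEADER_TAG):])
                if first.startswith(_HEADER_TAG) else {})
        frame = pd.read_csv(fh if first.startswith(_HEADER_TAG) else path)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    resp = frame["action"].notna()
    bad = frame.index[resp & (frame["reward"].astype(int)
                              != (frame["correct"].astype(int)
                                  ^ frame["noisy"].astype(int)))]
    if len(bad):
        raise ValueError(
            f"reward != correct XOR noisy at row {int(bad[0])}")

    datasets = []
    for (subject, session), g in frame.groupby(["subject", "session"],
                                               sort=False):
        action = g["action"].to_numpy(dtype=object)
        action = np.array([LAPSE if pd.isna(a) else int(a) for a in action])
        key = f"{subject}|{session}"
        schedule = [TaskSet(tuple(a)) for a in
                    meta.get("schedules", {}).get(key, [])]
        datasets.append(BehaviorDataset(
            subject_id=str(subject), session_type=str(session),
            episode=g["episode"].to_numpy(int),
            trial=g["trial"].to_numpy(int),
            stimulus=g["stimulus"].to_numpy(int),
            action=action,
            reward=g["reward"].to_numpy(int),
            correct=g["correct"].to_numpy(bool),
            noisy=g["noisy"].to_numpy(bool),
            rt=g["rt"].to_numpy(float),
            n_stimuli=meta.get("n_stimuli", 3),
            n_actions=meta.get("n_actions", 4),
            schedule=schedule))
    return datasets
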