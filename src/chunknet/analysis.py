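"""Behavioral analyses: model-based trial labels and aligned curves.

The central analysis classifies prediction trials as *chunked* or
*independent*. A trial is chunked when, according to a teacher-forced
run of the model through the preceding events, the TN activation
closure on the previous trial contained a conjunction matching the
upcoming stimulus — i.e. the inference signal biased the response. Two
kinds of prediction trials are labeled:

retrieval
    The trial after the episode's first correct response, for a
    different stimulus. Chunking predicts retrieval of the correct
    task-set and hence *higher* accuracy on chunked trials.
misleading
    The trial after an incorrect-but-rewarded (noisy) trial. Chunking
    then retrieves the *wrong* task-set and predicts *lower* accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agent import (LAPSE, BehaviorDataset, ModelParams, ModelTrace,
                    teacher_forced_run)

__all__ = [
    "TrialLabel",
    "AlignedCurve",
    "label_retrieval_trials",
    "label_misleading_trials",
    "labels_to_frame",
    "label_summary",
    "label_position_ks",
    "model_p_correct",
    "aligned_performance",
    "newly_seen_events",
    "newly_seen_performance",
]


@dataclass(frozen=True)
class TrialLabel:
    """A labeled prediction trial.

    ``index`` is the prediction trial's position in the session;
    ``position`` its position within the episode (used for the
    distribution-confound control). ``outcome_correct`` is the response
    accuracy on the prediction trial.
    """

    subject_id: str
    episode: int
    index: int
    position: int
    kind: str               # "retrieval" | "misleading"
    label: str              # "chunked" | "independent"
    outcome_correct: bool


def _closure_contains_stimulus(active, stimulus: int) -> bool:
    return active is not None and any(s == stimulus for s, _ in active)


def _trace_for_labels(dataset: BehaviorDataset, params: ModelParams
                      ) -> ModelTrace:
    return teacher_forced_run(params, dataset, with_inference=True)


def label_retrieval_trials(dataset: BehaviorDataset, params: ModelParams,
                           trace: ModelTrace | None = None
                           ) -> list[TrialLabel]:
    """Label the trial following each episode's first correct response.

    The first correct response is the first trial whose action matches
    the episode's task-set, whatever the (possibly misleading) feedback.
    The following trial is a prediction trial only if it presents a
    different stimulus and carries a response. It is labeled *chunked*
    when the first correct trial was rewarded (the inference signal is
    reward-gated) and the TN closure seeded by its stimulus-action pair
    reached a conjunction of the upcoming stimulus; otherwise
    *independent*. Episodes without a correct response yield no label.
    """
    if trace is None:
        trace = _trace_for_labels(dataset, params)
    labels = []
    for ep in np.unique(dataset.episode):
        idx = np.flatnonzero(dataset.episode == ep)
        hits = idx[dataset.correct[idx]]
        if hits.size == 0:
            continue
        t = int(hits[0])
        nxt = t + 1
        if nxt >= dataset.n_trials or dataset.episode[nxt] != ep:
            continue
        if dataset.stimulus[nxt] == dataset.stimulus[t]:
            continue
        if dataset.action[nxt] == LAPSE or dataset.action[t] == LAPSE:
            continue
        chunked = bool(dataset.reward[t]) and _closure_contains_stimulus(
            trace.active_sets[t], int(dataset.stimulus[nxt]))
        labels.append(TrialLabel(
            dataset.subject_id, int(ep), nxt, int(dataset.trial[nxt]),
            "retrieval", "chunked" if chunked else "independent",
            bool(dataset.correct[nxt])))
    return labels


def label_misleading_trials(dataset: BehaviorDataset, params: ModelParams,
                            trace: ModelTrace | None = None
                            ) -> list[TrialLabel]:
    """Label trials following an incorrect-but-rewarded (noisy) trial.

    The misleading reward can cause the model to retrieve the task-set
    the erroneous response belongs to. The following trial (different
    stimulus, response present, same episode) is labeled *chunked* when
    the TN closure from the erroneously produced pair reached a
    conjunction of the upcoming stimulus — predicting an incorrect
    association and reduced accuracy there.
    """
    if trace is None:
        trace = _trace_for_labels(dataset, params)
    labels = []
    mis = np.flatnonzero(dataset.noisy & ~dataset.correct
                         & (dataset.reward == 1)
                         & (dataset.action != LAPSE))
    for t in mis:
        nxt = int(t) + 1
        if nxt >= dataset.n_trials or dataset.episode[nxt] != dataset.episode[t]:
            continue
        if dataset.stimulus[nxt] == dataset.stimulus[t]:
            continue
        if dataset.action[nxt] == LAPSE:
            continue
        chunked = _closure_contains_stimulus(
            trace.active_sets[t], int(dataset.stimulus[nxt]))
        labels.append(TrialLabel(
            dataset.subject_id, int(dataset.episode[t]), nxt,
            int(dataset.trial[nxt]), "misleading",
            "chunked" if chunked else "independent",
            bool(dataset.correct[nxt])))
    return labels


def labels_to_frame(labels: list[TrialLabel]) -> pd.DataFrame:
    return pd.DataFrame([l.__dict__ for l in labels])


def model_p_correct(dataset: BehaviorDataset, params: ModelParams,
                    with_inference: bool) -> np.ndarray:
    """Per-trial model probability of the *correct* action.

    Requires the dataset's task-set schedule. Used to score labeled
    trials with a model observer (e.g. the AN-only variant) instead of
    the subject's realized accuracy.
    """
    if not dataset.schedule:
        raise ValueError("dataset has no task-set schedule")
    trace = teacher_forced_run(params, dataset, with_inference=with_inference)
    return trace.p_correct


def label_summary(labels: list[TrialLabel],
                  values: np.ndarray | None = None) -> pd.DataFrame:
    """Mean outcome per (kind, label) group.

    By default the outcome is the recorded response accuracy; ``values``
    substitutes any per-trial score (e.g. :func:`model_p_correct`),
    indexed by the prediction trial.
    """
    frame = labels_to_frame(labels)
    if frame.empty:
        return pd.DataFrame(columns=["kind", "label", "mean", "sem", "n"])
    score = (frame["outcome_correct"].astype(float) if values is None
             else np.asarray(values, dtype=float)[frame["index"]])
    frame = frame.assign(score=score)
    g = frame.groupby(["kind", "label"])["score"]
    return (pd.DataFrame({"mean": g.mean(), "sem": g.sem(), "n": g.size()})
            .reset_index())


def label_position_ks(labels: list[TrialLabel]) -> tuple[float, float]:
    """KS test of within-episode positions, chunked vs. independent.

    Guards against the confound that chunked prediction trials might
    simply occur later in episodes than independent ones.
    """
    frame = labels_to_frame(labels)
    a = frame.loc[frame["label"] == "chunked", "position"]
    b = frame.loc[frame["label"] == "independent", "position"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("need both label classes for the KS test")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AlignedCurve:
    """Mean performance around an alignment event."""

    alignment: str
    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alignment": self.alignment,
                             "offset": self.offsets, "mean": self.mean,
                             "sem": self.sem, "n": self.n})


def _alignment_events(dataset: BehaviorDataset, alignment: str,
                      late_fraction: float, max_offset: int) -> list[int]:
    events: list[int] = []
    for ep in np.unique(dataset.episode):
        idx = np.flatnonzero(dataset.episode == ep)
        if alignment == "episode_switch":
            events.append(int(idx[0]))
        elif alignment == "first_correct":
            hits = idx[dataset.correct[idx]]
            if hits.size:
                events.append(int(hits[0]))
        elif alignment == "misleading_late":
            # isolated correct-but-unrewarded trials late in the
            # episode: the forward window must not cross the episode
            # switch (a switch collapses performance for reasons
            # unrelated to the feedback), and no other noisy trial may
            # fall in the window (the probe is the response to a
            # single inconsistent feedback)
            start = idx[0] + int(np.ceil(len(idx) * (1 - late_fraction)))
            late = idx[(idx >= start) & (idx + max_offset <= idx[-1])]
            hits = late[dataset.correct[late] & dataset.noisy[late]
                        & (dataset.action[late] != LAPSE)]
            for h in hits:
                lo = max(0, h - max_offset)
                hi = min(dataset.n_trials, h + max_offset + 1)
                if dataset.noisy[lo:hi].sum() == 1:
                    events.append(int(h))
        else:
            raise ValueError(f"unknown alignment {alignment!r}")
    return events


def aligned_performance(datasets: list[BehaviorDataset], alignment: str,
                        offsets: range = range(-5, 6),
                        values: list[np.ndarray] | None = None,
                        late_fraction: float = 1 / 3) -> AlignedCurve:
    """Event-aligned average performance curve.

    ``alignment`` is one of ``episode_switch`` (offset 0 = first trial
    of the new episode), ``first_correct`` (offset 0 = the episode's
    first correct response) or ``misleading_late`` (offset 0 = a
    correct-but-unrewarded trial in the last ``late_fraction`` of an
    episode). Performance defaults to recorded response accuracy;
    ``values`` substitutes per-trial scores such as the model's
    probability of the correct action. Offsets are clipped at session
    boundaries.
    """
    offsets = np.asarray(list(offsets), dtype=int)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=int)
    sq = np.zeros(offsets.size)
    any_events = False
    for di, ds in enumerate(datasets):
        perf = (ds.correct.astype(float) if values is None
                else np.asarray(values[di], dtype=float))
        events = _alignment_events(ds, alignment, late_fraction,
                                   int(offsets.max()))
        any_events = any_events or bool(events)
        for e in events:
            pos = e + offsets
            ok = (pos >= 0) & (pos < ds.n_trials)
            v = perf[pos[ok]]
            keep = ~np.isnan(v)
            sums[ok] += np.where(keep, np.nan_to_num(v), 0.0)
            sq[ok] += np.where(keep, np.nan_to_num(v) ** 2, 0.0)
            counts[ok] += keep
    if not any_events:
        raise ValueError(f"no {alignment!r} events in the supplied data")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = sq / counts - mean ** 2
        sem = np.sqrt(np.clip(var, 0, None) / np.maximum(counts - 1, 1))
    return AlignedCurve(alignment, offsets, mean, sem, counts)


def newly_seen_events(dataset: BehaviorDataset,
                      last_fraction: float = 1 / 3
                      ) -> list[tuple[str, int]]:
    """(rank, trial index) of first presentations of newly seen stimuli.

    A stimulus is newly seen when its first presentation in an episode
    falls after the episode's first correct response; ranks follow the
    episode's distinct-stimulus appearance order. Restricted to the
    last ``last_fraction`` of the session's episodes; lapse trials are
    skipped.
    """
    n_ep = int(dataset.episode.max()) + 1
    first_late = int(np.ceil(n_ep * (1 - last_fraction)))
    rank_names = {2: "second", 3: "third"}
    events: list[tuple[str, int]] = []
    for ep in range(first_late, n_ep):
        idx = np.flatnonzero(dataset.episode == ep)
        if idx.size == 0:
            continue
        hits = idx[dataset.correct[idx]]
        if hits.size == 0:
            continue
        t0 = int(hits[0])
        seen: set[int] = set()
        appearance_rank: dict[int, int] = {}
        for t in idx:
            s = int(dataset.stimulus[t])
            if s not in appearance_rank:
                appearance_rank[s] = len(appearance_rank) + 1
            if t <= t0:
                seen.add(s)
            elif s not in seen:
                seen.add(s)
                name = rank_names.get(appearance_rank[s])
                if name is not None and dataset.action[t] != LAPSE:
                    events.append((name, int(t)))
    return events


def newly_seen_performance(dataset: BehaviorDataset,
                           last_fraction: float = 1 / 3) -> pd.DataFrame:
    """Accuracy on stimuli first seen after an episode's first correct trial.

    Restricted to the last ``last_fraction`` of the session's episodes.
    In each episode, stimuli whose first presentation falls after the
    first correct response are scored on that first presentation, and
    ranked *second* or *third* by the episode's distinct-stimulus
    appearance order (the first-correct stimulus having appeared
    earlier). A task-set learner retrieves the whole mapping from the
    single correct response, lifting these proportions well above the
    trial-and-error baseline.
    """
    scores: dict[str, list[float]] = {"second": [], "third": []}
    for name, t in newly_seen_events(dataset, last_fraction):
        scores[name].append(float(dataset.correct[t]))
    return pd.DataFrame(
        {"proportion_correct": [np.mean(v) if v else np.nan
                                for v in scores.values()],
         "n": [len(v) for v in scores.values()]},
        index=pd.Index(scores.keys(), name="stimulus_rank"))
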