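"""Task-set network (TN): conjunction populations and temporal chunking.

The TN contains one binary population per stimulus-action conjunction.
Directed synapses between populations are potentiated when their
conjunctions occur on consecutive trials and homeostatically depressed
whenever the source population is active (pre-activated depression).
When a synapse exceeds the inhibition threshold ``g_I`` the target
population is co-activated with the source, and this co-activation is
iterated to a closure: a chunk. Chunks are the network's encoding of
task-sets.

Populations are indexed both as flat ids (``stimulus * n_actions +
action``) and as (stimulus, action) pairs; :func:`pop_index` /
:func:`pop_pair` convert between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TNState",
    "pop_index",
    "pop_pair",
    "tn_activate",
    "tn_update",
    "tn_equilibrium",
    "DEFAULT_G_I",
    "QM_OVER_QP",
]

#: Inhibition threshold for co-activation. Fixed by design so that the
#: potentiation rate is the TN's only free parameter.
DEFAULT_G_I = 0.5

#: Fixed ratio of depression to potentiation rate (QM = QP / 10).
QM_OVER_QP = 0.1


def pop_index(stimulus: int, action: int, n_actions: int) -> int:
    """Flat id of the conjunction population for (stimulus, action)."""
    return stimulus * n_actions + action


def pop_pair(index: int, n_actions: int) -> tuple[int, int]:
    """(stimulus, action) of a flat population id."""
    return divmod(index, n_actions)


@dataclass
class TNState:
    """Directed TN weight matrix with zero diagonal, entries in [0, 1]."""

    weights: np.ndarray
    n_actions: int
    g_I: float = DEFAULT_G_I

    @classmethod
    def zeros(cls, n_stimuli: int, n_actions: int,
              g_I: float = DEFAULT_G_I) -> "TNState":
        n = n_stimuli * n_actions
        return cls(np.zeros((n, n)), n_actions, g_I)

    @property
    def n_populations(self) -> int:
        return self.weights.shape[0]


def _closure(weights: np.ndarray, g_I: float, seed: int) -> np.ndarray:
    """Boolean mask of populations reachable from ``seed`` along
    edges with weight >= g_I (seed included)."""
    above = weights >= g_I
    active = np.zeros(weights.shape[0], dtype=bool)
    active[seed] = True
    frontier = [seed]
    while len(frontier):
        reached = above[frontier].any(axis=0) & ~active
        active |= reached
        frontier = np.flatnonzero(reached)
    return active


def tn_activate(state: TNState, stimulus: int, action: int
                ) -> frozenset[tuple[int, int]]:
    """Activation closure seeded by one conjunction.

    The seed population activates every population it projects to with
    weight >= ``g_I``; the step is iterated until no new population
    activates (directed-graph reachability over the thresholded weight
    matrix). Returns the active set as (stimulus, action) pairs,
    including the seed.
    """
    seed = pop_index(stimulus, action, state.n_actions)
    mask = _closure(state.weights, state.g_I, seed)
    return frozenset(pop_pair(int(i), state.n_actions)
                     for i in np.flatnonzero(mask))


def tn_update(state: TNState,
              prev: tuple[int, int] | None,
              curr: tuple[int, int],
              QP: float, QM: float) -> TNState:
    """One trial of TN plasticity (in place).

    Every synapse leaving the currently driven population decays by the
    factor ``1 - QM`` (pre-activated depression), and the synapse from
    the previous trial's population to the current one is potentiated
    toward 1 at rate ``QP``. The diagonal stays zero: repeating the same
    conjunction depresses but never self-potentiates. The two updates
    touch disjoint entries, so their order is immaterial.
    """
    na = state.n_actions
    c = pop_index(curr[0], curr[1], na)
    state.weights[c] *= 1.0 - QM
    if prev is not None:
        p = pop_index(prev[0], prev[1], na)
        if p != c:
            w = state.weights[p, c]
            state.weights[p, c] = w + QP * (1.0 - w)
    return state


def tn_equilibrium(p_transition: float, QP: float, QM: float) -> float:
    """Fixed point of the expected one-trial update of a TN synapse.

    For a synapse whose source conjunction recurs with stationary
    statistics and is followed by the target conjunction with
    probability ``p_transition``, the expected potentiation balances the
    expected depression at ``J* = p*QP / (p*QP + QM)`` (treating
    successive conjunctions as i.i.d.). The equilibrium grows with the
    transition probability; chunking requires ``J* > g_I``.
    """
    if not 0 <= p_transition <= 1:
        raise ValueError("p_transition must be in [0, 1]")
    if p_transition == 0:
        return 0.0
    if QM == 0:
        return 1.0
    x = p_transition * QP
    return x / (x + QM)
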