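"""Associative network (AN): decision making and reward-modulated plasticity.

The AN holds one plastic synaptic weight per stimulus-action pair,
bounded in [0, 1]. Actions are drawn by a soft, noisy winner-take-all
rule (a softmax over the presented stimulus' weights mixed with a
uniform lapse component), and the weights are updated after each trial
by a reward-modulated Hebbian rule with soft bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ANState", "action_probabilities", "sample_action", "an_update"]


@dataclass
class ANState:
    """Plastic stimulus -> action weights, every entry in [0, 1].

    Weights start at 0: all actions are then equiprobable under the
    softmax, and the first potentiation has maximal headroom.
    """

    weights: np.ndarray

    @classmethod
    def zeros(cls, n_stimuli: int, n_actions: int) -> "ANState":
        return cls(np.zeros((n_stimuli, n_actions)))

    @property
    def n_actions(self) -> int:
        return self.weights.shape[1]


def action_probabilities(state: ANState, stimulus: int,
                         beta: float, epsilon: float) -> np.ndarray:
    """Choice probabilities for one stimulus.

    ``P(a) = epsilon / n_actions + (1 - epsilon) * softmax(beta * w)[a]``
    where ``w`` is the stimulus' weight row, ``1/beta`` is the decision
    noise and ``epsilon`` the undirected-exploration (lapse) rate.
    Computed via a max-shifted exponential, so large ``beta`` cannot
    overflow.
    """
    w = state.weights[stimulus]
    z = beta * w
    z = z - z.max()
    e = np.exp(z)
    return epsilon / w.size + (1.0 - epsilon) * e / e.sum()


def sample_action(probabilities: np.ndarray, rng: np.random.Generator) -> int:
    """Categorical draw from a probability vector over actions."""
    p = np.asarray(probabilities, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    # inverse-CDF draw: cheap and reproducible under a fixed generator
    return int(np.searchsorted(np.cumsum(p), rng.random(), side="right")
               .clip(0, p.size - 1))


def an_update(state: ANState, stimulus: int, action: int, reward: int,
              alpha: float) -> ANState:
    """One reward-modulated plasticity step (in place).

    Only the presented stimulus' row is touched. On reward, the chosen
    synapse is potentiated toward 1 and its row competitors are
    depressed toward 0; on null reward the roles swap. All rates equal
    ``alpha``; the soft-bound form keeps weights in [0, 1].
    """
    row = state.weights[stimulus]
    if reward:
        old = row[action]
        row *= 1.0 - alpha          # depress non-chosen (chosen fixed below)
        row[action] = old + alpha * (1.0 - old)
    else:
        old = row[action]
        row += alpha * (1.0 - row)  # potentiate non-chosen
        row[action] = (1.0 - alpha) * old
    return state
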