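"""Compiled fast path for the teacher-forced choice likelihood.

The kernel replays a subject's trial sequence through the coupled
AN-TN model exactly as :func:`chunknet.agent.teacher_forced_run` does,
but accumulates only the summed log-probability of the recorded
actions. It exists because maximum-likelihood fitting evaluates the
likelihood thousands of times per subject; agreement with the traced
implementation is enforced by tests.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _forced_loglik(stimuli, actions, rewards, n_stimuli, n_actions,
                   alpha, beta, epsilon, QP, QM, g_I, J_INC, use_tn):
    n = stimuli.shape[0]
    n_pop = n_stimuli * n_actions
    W = np.zeros((n_stimuli, n_actions))
    T = np.zeros((n_pop, n_pop))
    active = np.zeros(n_pop, np.bool_)
    stack = np.empty(n_pop, np.int64)
    prev = -1
    logp = 0.0
    for t in range(n):
        a = actions[t]
        if a < 0:  # lapse: no likelihood, no updates
            continue
        s = stimuli[t]
        r = rewards[t]
        # choice probability of the recorded action (max-shifted softmax)
        m = beta * W[s, 0]
        for j in range(1, n_actions):
            z = beta * W[s, j]
            if z > m:
                m = z
        denom = 0.0
        for j in range(n_actions):
            denom += math.exp(beta * W[s, j] - m)
        pa = epsilon / n_actions \
            + (1.0 - epsilon) * math.exp(beta * W[s, a] - m) / denom
        logp += math.log(pa)
        # AN reward-modulated update
        old = W[s, a]
        if r == 1:
            for j in range(n_actions):
                W[s, j] *= 1.0 - alpha
            W[s, a] = old + alpha * (1.0 - old)
        else:
            for j in range(n_actions):
                W[s, j] += alpha * (1.0 - W[s, j])
            W[s, a] = (1.0 - alpha) * old
        if not use_tn:
            continue
        curr = s * n_actions + a
        # activation closure over the thresholded start-of-trial weights
        for i in range(n_pop):
            active[i] = False
        active[curr] = True
        stack[0] = curr
        top = 1
        while top > 0:
            top -= 1
            u = stack[top]
            for v in range(n_pop):
                if not active[v] and T[u, v] >= g_I:
                    active[v] = True
                    stack[top] = v
                    top += 1
        # pre-activated depression of the active populations' rows
        for i in range(n_pop):
            if active[i]:
                for v in range(n_pop):
                    T[i, v] *= 1.0 - QM
        # temporal potentiation of the driven transition
        if prev >= 0 and prev != curr:
            T[prev, curr] += QP * (1.0 - T[prev, curr])
        prev = curr
        # reward-gated inference onto the AN
        if r == 1 and J_INC > 0.0:
            for i in range(n_pop):
                if active[i]:
                    si = i // n_actions
                    ai = i % n_actions
                    W[si, ai] += J_INC * (1.0 - W[si, ai])
    return logp


def forced_loglik(params, dataset, with_inference: bool) -> float:
    """Summed log-likelihood of the recorded actions (fast path)."""
    use_tn = bool(with_inference and params.J_INC > 0)
    return float(_forced_loglik(
        np.ascontiguousarray(dataset.stimulus, dtype=np.int64),
        np.ascontiguousarray(dataset.action, dtype=np.int64),
        np.ascontiguousarray(dataset.reward, dtype=np.int64),
        dataset.n_stimuli, dataset.n_actions,
        params.alpha, params.beta, params.epsilon,
        params.QP, params.QM, params.g_I,
        params.J_INC if with_inference else 0.0, use_tn))
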