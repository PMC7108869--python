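# Methods

## The task

An agent (human subject or model) learns, by trial and error, which of
`n_A = 4` response keys goes with each of `n_S = 3` visual stimuli. The
complete injective stimulus→action mapping — the *task-set* — stays
fixed for an uncued *episode* of 36–54 trials and then switches to a
mapping that shares no stimulus-action pair with its predecessor. A
fixed 10% of trials carry *misleading* feedback: the reward is the
inversion of the response's correctness. In a *recurrent* session three
task-sets reoccur across the 25 episodes, so a single correct response
identifies the entire valid mapping; in an *open-ended* session each
episode brings a fresh mapping and nothing generalizes across episodes.

The simulator reproduces this design exactly: episode lengths are
discrete-uniform on [36, 54]; the misleading-trial count is exactly
`round(0.1 · n_trials)` with shuffled positions; consecutive episodes'
task-sets never overlap. The stimulus sequence is pseudo-randomized as
uniform *without immediate repetition* (each trial's stimulus drawn
uniformly from the other two). This constraint matters mechanistically:
it guarantees that the trial after a misleading feedback presents a
different stimulus, giving the reward-gated inference signal (below)
one rewarded trial in which to restore the perturbed weights before the
misled stimulus returns. With fully independent draws that guarantee
disappears and the model no longer ignores isolated misleading
feedback, contrary to the behavior the architecture is built to
produce.

## The model

Two interacting subnetworks with binary population activity:

**Associative network (AN).** One plastic weight `J^AN[s, a] ∈ [0, 1]`
per stimulus–action pair, all starting at 0. Given stimulus `s`, action
`a` is chosen with probability

    P(a | s) = ε / n_A + (1 − ε) · exp(β J^AN[s, a]) / Σ_k exp(β J^AN[s, k])

where `1/β` is decision noise and `ε` a uniform lapse mixture. After
the outcome `r ∈ {0, 1}`, only row `s` is updated, with soft bounds and
a single rate `α`:

- `r = 1`: chosen entry `J ← J + α (1 − J)`; other entries `J ← (1 − α) J`
- `r = 0`: chosen entry `J ← (1 − α) J`; other entries `J ← J + α (1 − J)`

The `r = 0` branch deliberately *potentiates* the non-chosen actions —
a built-in "try something else" drive. It makes exploration fast but
caps the stationary plateau of the AN alone at ≈ 0.86 correct under 10%
misleading feedback (a misleading null reward simultaneously depresses
the correct synapse and lifts its three competitors).

**Task-set network (TN).** One population per stimulus–action
conjunction (12 here), fully connected with directed weights
`J^TN ∈ [0, 1]`, zero diagonal. Each trial the produced conjunction is
activated; any population receiving a synapse `≥ g_I = 0.5` from an
active population activates too, iterated to closure. The closed set is
a *chunk*. Plasticity is temporal-Hebbian:

- *Potentiation*: the synapse from the previous trial's driven
  conjunction to the current one moves toward 1 at rate `Q_P`.
- *Pre-activated depression*: the outgoing synapses of every population
  active this trial (driven and co-activated) decay by the factor
  `1 − Q_M`, with `Q_M = Q_P / 10` fixed.

For an isolated synapse whose source recurs with stationary statistics
and is followed by its target with probability `p`, the expected update
balances at `J* = p Q_P / (p Q_P + Q_M)` (`tn_equilibrium`); chunking
requires `J* > g_I`. At a behavioral plateau within a task-set,
`p ≈ 0.9 / 2` under the no-repeat schedule, comfortably above
threshold, while synapses between task-sets equilibrate well below it.

The scope of the two activity gates was the one genuinely open design
point. We evaluated all four combinations by simulation at the
reference point (α = 0.4, β = 7, ε = 0, J_INC = 0.7, 25-episode
recurrent sessions):

- pairwise potentiation + *driven-only* depression: synapses between
  conjunctions sharing a stimulus are depressed only when their source
  is itself produced, equilibrate near `g_I`, and under the inference
  feedback loop bridge the clusters until every chunk merges into one
  blob; the inference then *hurts* even at slow TN rates.
- *cluster-wide* potentiation (either depression scope): once two
  chunks co-activate, all their cross synapses are potentiated every
  trial and the merged blob is irreversible.
- pairwise potentiation + active-set depression (the default): chunks
  form from the pre-chunking pairwise statistics, and co-activation
  then accelerates the decay of a chunk's stray outgoing synapses;
  spurious weights stay near 0.1–0.15 and clusters remain clean.

Both non-default scopes remain available on `Agent` for sensitivity
analysis (`depress_active_set=False`, `cluster_potentiation=True`).

**Inference signal.** If trial `t` was rewarded, every AN weight whose
conjunction is in the TN's active closure is increased:
`J^AN ← J^AN + J_INC (1 − J^AN)`. This includes the trial's own pair
(its activity is 1 by construction). Applied after TN plasticity, it
biases the response from trial `t + 1` onward: one rewarded correct
response can re-instate a whole previously learned task-set — or, after
a misleadingly rewarded error, the wrong one.

**Trial order** (fixed, tested): choice → reward → AN update → TN
closure (start-of-trial weights) → TN plasticity → inference.
`prev`-pair memory persists across episode switches (they are uncued)
and resets between sessions.

## Free parameters

| name   | meaning                         | range    | reference value |
|--------|---------------------------------|----------|-----------------|
| α      | AN learning rate                | [0, 1]   | 0.35 (fitted mean), 0.4 in sweeps |
| 1/β    | decision noise                  | β ∈ [0, 50] | β = 7 |
| ε      | lapse / undirected exploration  | [0, 1]   | 0.05 |
| Q_P    | TN potentiation rate            | [0, 1]   | 0.17 recurrent / 0.44 open-ended (fitted means) |
| J_INC  | inference strength              | [0, 1]   | 0.70 recurrent / 0.16 open-ended (fitted means) |

`g_I = 0.5` and `Q_M = Q_P/10` are fixed to keep Q_P the TN's only free
parameter. The *without-inference* variant is the AN alone (3 free
parameters); it is bitwise equivalent to the full model with
`J_INC = 0`, a tested property.

## Fitting and model comparison

Subject-by-subject maximum likelihood via teacher forcing: the model's
state evolves under the subject's recorded actions and rewards, and the
likelihood multiplies the per-trial probabilities of those actions.
Lapse trials (no response) contribute neither likelihood nor state
updates. A numba-compiled kernel evaluates the same recursion as the
traced implementation (agreement enforced to 1e-10 in tests) so that a
full fit takes seconds.

Optimization is a factorial grid (3 values per free parameter) followed
by Nelder-Mead from the three best grid points — chosen because the
activation threshold makes the likelihood piecewise in Q_P and J_INC —
with an L-BFGS-B polish; ties break by lower negative log-likelihood,
then lexicographically, making fits deterministic.

Information criteria use the halved convention

    BIC = −logL + (k/2) ln n,    AIC = −logL + k

(the negative Laplace-approximation evidence), with `n` the number of
non-lapse trials and `k` = 5 or 3. Only differences matter for
selection, where this convention and the common `−2 logL + k ln n`
agree up to the factor 2.

## Synthetic cohorts

The original subjects' data are not redistributable, so all pipelines
run on simulated cohorts. Per-subject parameters are drawn from
truncated normals centred on the human-cohort estimates (α: 0.35, Q_P:
0.17, J_INC: 0.70 recurrent / 0.16 open-ended) with the reported
s.e.m.-scale dispersions; β = 7 and ε = 0.05 are held at the values
used throughout the simulation figures. Lapses are emulated by deleting
responses at a configurable rate (default 0). What the generator does
*not* emulate: reaction times (carried as a passthrough column),
within-session fatigue or learning-to-learn, subject-specific stimulus
confusability, and the debriefing-based exploiter/explorer split.
Passing tests therefore demonstrate internal consistency of the method
on data satisfying the model's own assumptions, not its adequacy for
any particular human dataset.

## Numerical and procedural choices

- Softmax computed max-shifted; exact agreement with the direct formula
  is verified to 1e-12 over random states.
- Closure threshold comparison is `≥ g_I` (inclusive).
- Within a trial, depression precedes potentiation; the two touch
  disjoint entries in the pairwise primitive, so order only matters for
  the active-set variant, where it is fixed and documented.
- The idealized fully chunked TN (within-task-set weights 0.7, all
  others 0) runs with TN plasticity frozen: it represents the end state
  of learning, not a learning condition.
- Aligned analysis of misleading feedback uses *isolated* events late
  in an episode whose analysis window neither crosses the episode
  switch nor contains another noisy trial; unrestricted windows mix in
  the switch-induced collapse, which is unrelated to the feedback.
- The retrieval label requires the first correct trial to be rewarded
  (the inference is reward-gated) and the following trial to present a
  different stimulus; misleading labels use the same different-stimulus
  restriction.
- Problem sizes in tests and in `scripts/acceptance.py` (200 paired
  runs per sweep condition, ~5,000 misleading events, 20 recovery
  subjects, 10 null subjects) were chosen so every directional effect
  is several Monte-Carlo standard errors from zero.

## Known limitations

- The AN-only plateau (~0.86) sits below the ~0.94 pre-switch accuracy
  of well-trained human subjects; the printed `r = 0` branch trades
  plateau height for switch speed.
- A newly seen stimulus after task-set retrieval is a two-way softmax
  tie between the retrieved association (weight 1) and the previous
  episode's stale association (also ~1, never unlearned while the
  stimulus is absent); the model therefore predicts ~0.5 accuracy
  there, above its trial-and-error baseline but below a perfect
  rule-follower.
- Open-ended sessions need 25 distinct mappings but only 24 injective
  3→4 maps exist; uniqueness is enforced until the non-overlapping
  unused pool empties, then relaxed (non-overlap always holds).
- Parameter recovery is demonstrated at the reference cohort point;
  identifiability degrades as β → 0 or ε → 1 (any dataset looks
  uniform) and when Q_P is large enough that no stable chunks form.
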