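# Methods

## Model

The network maps a one-hot stimulus to action values through two parallel
branches and is trained online with on-policy temporal-difference learning
(SARSA). All learning signals are local to a synapse plus one globally
broadcast scalar (the TD error), which is what makes the family interesting
as a biologically plausible alternative to backpropagation.

**Feedforward pass.** The regular branch applies a sigmoid layer to the
sustained stimulus, `y_R = σ(V_R s)`. The memory branch sees only stimulus
*transitions*: 2S transient units carry rectified onsets `[s(t)−s(t−1)]+`
and offsets `[s(t−1)−s(t)]+`. Memory potentials integrate this drive with a
fixed per-unit leak coefficient,

    h_M[j](t) = φ_j · h_M[j](t−1) + (V_M s_trans)(j),     φ_j ∈ [0, 1],

and `y_M = σ(h_M)`. Action values are the linear read-out
`q = W_R y_R + W_M y_M`. φ is a constant of the architecture, not a trained
or input-dependent gate: φ = 1 is a perfect integrator, φ = 0.7 forgets
with a ~3-step timescale. Three presets are used throughout: *standard*
(φ ≡ 1), *leaky* (φ ≡ 0.7) and *hybrid* (first half of the memory units
conservative, second half leaky).

**Action selection.** With probability 1 − ε the max-Q action is taken
(ties broken uniformly); with probability ε an action is sampled from a
softmax over `g(t)·q`, with `g(t) = 1 + (m/π)·arctan(t/t*)` and `t`
counting completed trials. The growing g concentrates exploratory draws on
the best action late in training, which is what allows long
consecutive-correct streaks to survive while exploration stays on.

**Learning.** After the action at time t is chosen, the TD error for the
*previous* action is `δ = r + γ q_a(t) − Q_{a'}(t−1)`; at trial end a
terminal update `δ = r − Q_{a'}` is applied (no successor value — an
episodic-reset convention the sources of this model family leave implicit).
Every weight then moves by `β · e · δ`, where the eligibility traces are:

- read-out synapses: `e_W ← y · z + (1 − α) e_W` with z the one-hot of the
  chosen action (α = 1 − γλ);
- input synapses, via the attentional feedback pass: a momentary tag
  `T_R = s · σ'(h_R)` (regular) or `T_M = X_M · σ'(h_M)` (memory) is
  multiplied by the feedback weight of the chosen action,
  `e_V ← T · (W' z) + (1 − α) e_V`. The memory branch's presynaptic trace
  `X_M ← φ ⊙ X_M + s_trans` decays at the memory unit's own φ, which makes
  the tag equal to the true `∂Q/∂V_M` once feedback aligns with the
  read-out.

Feedback weights `W'` are initialised independently but receive the same
increments as their feedforward partners (transposed), so the relative
discrepancy `‖W' − Wᵀ‖/‖W‖` shrinks as training accumulates shared updates.
The test suite verifies the gradient claim directly: with α = 1 and tied
feedback weights, `e_VM` matches central finite differences of the chosen
action's Q-value to 1e−4 relative tolerance, and `X_M` matches its closed
form Σ_τ φ^(t−τ) s_trans(τ) at machine precision.

**Trial boundaries.** Memory potentials, synaptic traces, tags and all
eligibility traces are zeroed at the end of every trial (for 12AX: every
outer loop), and the previous-stimulus register is blanked so the next
trial's first symbol registers as a pure onset. Only stating a memory reset
and leaving trace lifetimes open would let credit leak between unrelated
episodes; we reset everything.

## Parameters

| parameter | default | meaning |
|---|---|---|
| β | 0.15 | learning rate |
| λ | 0.15 | eligibility persistence (enters via α) |
| γ | 0.9 | discount factor |
| α | 1 − γλ = 0.865 | per-step trace decay |
| ε | 0.025 | exploration probability per step |
| t\* | 2000 trials | softmax sharpening timescale |
| m | 10 | softmax sharpening asymptote (g → 6) |
| φ_leak | 0.7 | leak coefficient of leaky memory units |
| init scale | 0.25 | uniform weight-init half-range |

Architectures: 12AX uses S = 8, R = 10, M = 20, A = 2; sequence prediction
uses R = 3, M = 8, A = 2 with one sensory unit per distinct symbol
(S = D + 2 for D distractors; a published table's S = L − 1 does not match
any one-unit-per-symbol count and we keep the symbol-count coding).
Weight initialisation is i.i.d. uniform on [−0.25, 0.25] for all six
matrices; the sources are silent here and any small symmetric range works —
the scale is exposed in the configuration.

## Task generators

The generators *are* the study conditions; their defaults are not tuning
knobs.

**Sequence prediction.** A cue drawn uniformly from {A, X} is followed by a
fixed chain of D distractors (default D = 3); the action taken at the last
letter is the prediction, rewarded +1/−1; earlier steps are unscored
(reward 0 regardless of action — SARSA still selects an action there).
Generalization tests use sequences one letter longer: D distractors
resampled uniformly with replacement from the trained set, the final go
signal kept fixed, evaluated greedily with frozen weights on 1,000
sequences.

**12AX.** Each outer loop: a uniform digit, then N ~ Uniform{1,2,3,4}
pairs drawn i.i.d. with P(A-X) = P(B-Y) = 0.25 and the other seven pairs at
0.5/7 each — hence target pairs at exactly 25%. Correct targets earn +1,
correct non-targets +0.1, errors −1. Under this generator the expected
non-target:target ratio is ≈8.6:1; a published figure of 8.96:1 is
consistent instead with N ∈ {1,2,3} (a plausible off-by-one in the original
generator) and we treat it as descriptive only.

**Convergence.** Sequence prediction: 100 consecutive correct final
predictions. 12AX: 1,000 consecutive correct symbol-level responses
(≈167 average-length loops), budget 10⁶ loops. The counter judges emitted
actions, exploration included, and any error resets it; learning time is
the number of completed trials when the criterion is first met.

**Test phases.** 12AX evaluation freezes the weights and reports the
fraction of outer loops answered entirely correctly. `greedy` always takes
argmax Q; `eps_greedy` is the classic rule (uniform random action with
probability ε — the g = 0 limit of the exploratory softmax), which is the
harsher exploration the reported test phase uses; a `softmax` option keeps
the training-time policy with g frozen at its end-of-training value.

## Numerics and determinism

- The per-trial inner loop is compiled with numba; a granular numpy
  reference path implements the same operations one call per step, and a
  test pins the two to identical actions and numerically identical weight
  trajectories (rtol 1e−9; BLAS vs explicit-loop summation order prevents
  bit equality across paths).
- Softmax sampling subtracts the max logit before exponentiation and uses
  inverse-CDF sampling; exactly two uniforms are consumed per step
  (exploration draw, then selection draw) in a fixed order, so a run is a
  pure function of its configuration and seed on both code paths.
- Batches derive per-simulation generators from a master seed via numpy
  SeedSequence spawning. Per-run draw order: weight init, then per trial
  the task draws followed by the per-step policy draws.
- Non-finite weights or TD errors abort a step with a diagnostic rather
  than propagating.

## Problem sizes used in the shipped checks

The full published batches use 100 simulations per condition; the test
suite and `scripts/acceptance.py` rerun the same protocols at desk scale:
20 seeds for the 12AX hybrid/leaky batches, 10 seeds for the
standard-variant failure check with the trial cap at 2×10⁵ (failure is
visible long before; the converging variants need ~10⁴), 20 seeds per
distractor count for sequence prediction, 10 trained networks per
generalization cell, and 2,000 evaluation loops per 12AX test-phase policy
after one 150,000-loop training. Stochastic checks use three standard
errors of the scaled-down batch, with small pre-registered floors where a
published table prints no dispersion.

## Known limitations

- Trials are synthetic symbol streams; nothing here models stimulus noise,
  response timing or biological spiking, so passing tests speak to the
  learning rule and memory dynamics, not to fits of behavioural data.
- Learning times are substantially seed-dependent (the 12AX hybrid times
  range over roughly 7k–340k loops in a 20-seed batch); comparisons between
  variants are robust, absolute means are not.
- Our implementation converges roughly twice as fast on 12AX as the
  originally reported means and its leaky control generalizes better on
  perturbed sequences; the discrepancies are consistent with the
  inner-pair-count ambiguity noted above and with unstated exploration
  bookkeeping in the original experiments, and we keep the documented
  generator rather than chase reported numbers.
- The leak coefficients are fixed by construction; learnable or
  input-dependent gating is deliberately out of scope.
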