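"""Task environments: sequence prediction and 12AX.

Both tasks are delivered as seeded generators of discrete trials behind a
common protocol. A :class:`Trial` carries the one-hot stimulus indices, the
scored (correct) action per step and the reward schedule, which is all the
training loop needs; :class:`TrialEnv` wraps the same trials in an explicit
``reset``/``step`` interface with SARSA reward timing (the reward returned at
step t pays for the action taken at t-1).

Sequence prediction: a cue (A or X) is followed by a fixed chain of D
distractors; at the last letter (the *go* signal) the agent must predict the
sequence's final letter — Z after cue A, Y after cue X. Only the final
prediction is rewarded (+1 correct / -1 wrong). Generalization tests use
sequences one letter longer with uniformly shuffled distractors, keeping the
go signal fixed.

12AX: a hierarchical target-detection task. Each outer loop starts with a
digit (1 or 2) fixing the context, followed by 1-4 letter pairs. The target
response R is correct exactly on an X preceded by A in context 1, or a Y
preceded by B in context 2; every other symbol requires L. Correct targets
earn +1, correct non-targets +0.1, errors -1 — positive reward is thereby
balanced between the rare targets and the frequent non-targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "Trial",
    "EnvStep",
    "SequencePredictionTask",
    "TwelveAXTask",
    "TrialEnv",
    "twelveax_correct_response",
]


@dataclass
class Trial:
    """One trial: stimulus stream, scored actions and reward schedule.

    ``correct[t]`` is -1 on unscored steps (then both reward entries are 0);
    otherwise the reward for the step-t action is ``reward_correct[t]`` on a
    match and ``reward_wrong[t]`` on a mismatch.
    """

    stimuli: np.ndarray          # int64[T], one-hot indices
    correct: np.ndarray          # int64[T], -1 where unscored
    reward_correct: np.ndarray   # float64[T]
    reward_wrong: np.ndarray     # float64[T]

    def __len__(self):
        return self.stimuli.shape[0]


@dataclass
class EnvStep:
    """One record of the reset/step protocol.

    ``done`` turns True on the record carrying the trial's last symbol and
    stays True on the closing reward-only record (stimulus None), which
    delivers the reward of the final action.
    """

    stimulus: Optional[int]
    reward_for_prev: float
    correct_action: Optional[int]
    done: bool


# ---------------------------------------------------------------------------
# sequence prediction
# ---------------------------------------------------------------------------

class SequencePredictionTask:
    """Cue + fixed distractor chain; predict the final letter at the go cue.

    Sensory coding is one one-hot unit per distinct symbol: unit 0 = cue A,
    unit 1 = cue X, units 2..D+1 = the distractors in their trained order.
    Actions: 0 = predict Z (required after cue A), 1 = predict Y (after X).
    """

    CUE_A, CUE_X = 0, 1
    PREDICT_Z, PREDICT_Y = 0, 1

    def __init__(self, n_distractors: int = 3, reward_correct: float = 1.0,
                 reward_wrong: float = -1.0):
        if n_distractors < 0:
            raise ValueError("n_distractors must be >= 0")
        self.n_distractors = n_distractors
        self.n_symbols = n_distractors + 2
        self.n_actions = 2
        self.symbol_level = False  # convergence counts whole predictions
        self._r_ok = float(reward_correct)
        self._r_bad = float(reward_wrong)
        # distractor chain: fixed alphabetical order, symbols 2..D+1
        self._chain = np.arange(2, 2 + n_distractors, dtype=np.int64)

    @property
    def symbol_names(self):
        # cue letters plus distractors labelled alphabetically from B
        return ["A", "X"] + [chr(ord("B") + k)
                             for k in range(self.n_distractors)]

    @property
    def action_names(self):
        return ["Z", "Y"]

    def _final_action(self, cue: int) -> int:
        return self.PREDICT_Z if cue == self.CUE_A else self.PREDICT_Y

    def _build(self, stimuli: np.ndarray, cue: int) -> Trial:
        T = stimuli.shape[0]
        correct = np.full(T, -1, dtype=np.int64)
        correct[-1] = self._final_action(cue)
        r_ok = np.zeros(T)
        r_bad = np.zeros(T)
        r_ok[-1] = self._r_ok
        r_bad[-1] = self._r_bad
        return Trial(stimuli, correct, r_ok, r_bad)

    def sample_trial(self, rng: np.random.Generator) -> Trial:
        """Training trial: uniform cue, then the fixed distractor chain."""
        cue = int(rng.integers(2))
        stimuli = np.concatenate(([cue], self._chain)).astype(np.int64)
        return self._build(stimuli, cue)

    def sample_test_trial(self, rng: np.random.Generator) -> Trial:
        """Perturbed test sequence, one letter longer than training.

        D+1 distractors: the first D sampled uniformly with replacement from
        the trained distractor set, the last fixed to the trained final
        letter (the go signal).
        """
        if self.n_distractors < 1:
            raise ValueError("test sequences require at least one distractor")
        cue = int(rng.integers(2))
        mid = rng.integers(2, 2 + self.n_distractors,
                           size=self.n_distractors)
        stimuli = np.concatenate(
            ([cue], mid, [self._chain[-1]])).astype(np.int64)
        return self._build(stimuli, cue)


# ---------------------------------------------------------------------------
# 12AX
# ---------------------------------------------------------------------------

_SYMBOLS = ("1", "2", "A", "B", "C", "X", "Y", "Z")
_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}


def twelveax_correct_response(symbol, digit_context, prev_symbol) -> int:
    """Correct action for a 12AX symbol: 1 (R) on a valid target, else 0 (L).

    R is required exactly when the current symbol is X immediately preceded
    by A in digit context 1, or Y immediately preceded by B in context 2.
    Accepts symbol strings ('1','2','A',...,'Z') or one-hot indices.
    """
    sym = _INDEX[symbol] if isinstance(symbol, str) else int(symbol)
    dig = _INDEX[digit_context] if isinstance(digit_context, str) \
        else int(digit_context)
    prev = (_INDEX[prev_symbol] if isinstance(prev_symbol, str)
            else (-1 if prev_symbol is None else int(prev_symbol)))
    if dig == _INDEX["1"] and prev == _INDEX["A"] and sym == _INDEX["X"]:
        return 1
    if dig == _INDEX["2"] and prev == _INDEX["B"] and sym == _INDEX["Y"]:
        return 1
    return 0


class TwelveAXTask:
    """Hierarchical 1-2/A-X target detection with distractor pairs.

    Each outer loop: a uniform digit (1 or 2), then N ~ Uniform{1..4} pairs
    drawn i.i.d. with P(A-X) = P(B-Y) = 0.25 and the remaining seven pairs at
    0.5/7 each. Combined with the digit, the overall target-pair probability
    is 25%. Symbols map to one-hot indices in the order 1,2,A,B,C,X,Y,Z.
    """

    SYMBOLS = _SYMBOLS
    PAIRS = ("AX", "AY", "BX", "BY", "CX", "CY", "AZ", "BZ", "CZ")
    ACTION_L, ACTION_R = 0, 1

    def __init__(self, p_ax: float = 0.25, p_by: float = 0.25,
                 n_pairs_range=(1, 4), reward_target: float = 1.0,
                 reward_nontarget: float = 0.1, reward_wrong: float = -1.0,
                 max_trials: int = 1_000_000):
        self.n_symbols = 8
        self.n_actions = 2
        self.symbol_level = True   # convergence counts single responses
        self.max_trials = max_trials
        self._r_target = float(reward_target)
        self._r_nontarget = float(reward_nontarget)
        self._r_bad = float(reward_wrong)
        self._n_lo, self._n_hi = n_pairs_range
        rest = (1.0 - p_ax - p_by) / 7.0
        probs = np.full(9, rest)
        probs[self.PAIRS.index("AX")] = p_ax
        probs[self.PAIRS.index("BY")] = p_by
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("invalid pair probabilities")
        self.pair_probs = probs
        self._cum = np.cumsum(probs)
        self._pair_idx = np.array(
            [[_INDEX[p[0]], _INDEX[p[1]]] for p in self.PAIRS],
            dtype=np.int64)

    @property
    def symbol_names(self):
        return list(self.SYMBOLS)

    @property
    def action_names(self):
        return ["L", "R"]

    def sample_pairs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n pair indices from the configured pair distribution."""
        return np.searchsorted(self._cum, rng.random(n), side="right")

    def sample_trial(self, rng: np.random.Generator) -> Trial:
        """One outer loop: digit then N pairs. Draw order: digit, N, pairs."""
        digit = int(rng.integers(2))              # 0 -> '1', 1 -> '2'
        n_pairs = int(rng.integers(self._n_lo, self._n_hi + 1))
        pairs = self.sample_pairs(n_pairs, rng)
        T = 1 + 2 * n_pairs
        stimuli = np.empty(T, dtype=np.int64)
        stimuli[0] = digit
        stimuli[1::2] = self._pair_idx[pairs, 0]
        stimuli[2::2] = self._pair_idx[pairs, 1]
        correct = np.zeros(T, dtype=np.int64)
        target_pair = self.PAIRS.index("AX") if digit == 0 \
            else self.PAIRS.index("BY")
        target_pos = 2 + 2 * np.nonzero(pairs == target_pair)[0]
        correct[target_pos] = self.ACTION_R
        r_ok = np.full(T, self._r_nontarget)
        r_ok[target_pos] = self._r_target
        r_bad = np.full(T, self._r_bad)
        return Trial(stimuli, correct, r_ok, r_bad)

    # test trials come from the same generator
    sample_test_trial = sample_trial


# ---------------------------------------------------------------------------
# reset/step protocol
# ---------------------------------------------------------------------------

class TrialEnv:
    """Uniform reset/step wrapper around a task's trial generator.

    ``reset`` draws a fresh trial and returns its first record; ``step(a)``
    returns the next stimulus together with the reward for action ``a``
    (one-step reward lag). Stepping past the closing record is an error.
    """

    def __init__(self, task, rng: np.random.Generator, test: bool = False):
        self.task = task
        self.rng = rng
        self._sample = task.sample_test_trial if test else task.sample_trial
        self._trial: Optional[Trial] = None
        self._pos = 0
        self._closed = True

    @property
    def trial(self) -> Optional[Trial]:
        return self._trial

    def reset(self) -> EnvStep:
        tr = self._sample(self.rng)
        self._trial = tr
        self._pos = 0
        self._closed = False
        c = int(tr.correct[0]) if tr.correct[0] >= 0 else None
        return EnvStep(int(tr.stimuli[0]), 0.0, c, done=(len(tr) == 1))

    def step(self, action: int) -> EnvStep:
        if self._closed or self._trial is None:
            raise RuntimeError("step() after the trial ended; call reset()")
        tr = self._trial
        t = self._pos
        if action == tr.correct[t]:
            r = float(tr.reward_correct[t])
        else:
            r = float(tr.reward_wrong[t])
        self._pos += 1
        if self._pos < len(tr):
            t = self._pos
            c = int(tr.correct[t]) if tr.correct[t] >= 0 else None
            return EnvStep(int(tr.stimuli[t]), r, c,
                           done=(self._pos == len(tr) - 1))
        self._closed = True
        return EnvStep(None, r, None, done=True)
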