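"""Training protocols, convergence batches, loss curves and test phases.

Convergence is defined by a run of consecutive correct responses: whole
final predictions for sequence prediction (100 in a row), single symbol-level
responses for 12AX (1,000 in a row, roughly 167 average-length outer loops).
The counter judges the action actually emitted — exploratory actions
included — and resets to zero on any error.

Learning times are reported in trials (outer loops). Batches derive one
child seed per simulation from a master seed via ``numpy``'s SeedSequence
spawning, so a batch is a pure function of (variant, task, n_sims, seed).
Per-run draw order: weight initialisation, then per trial the task draws
followed by two policy draws per step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .network import Architecture, HyperParams, Network, g_weight

__all__ = [
    "ConvergenceCriterion",
    "ConsecutiveCounter",
    "RunStats",
    "BatchResult",
    "architecture_for",
    "make_network",
    "train_until_convergence",
    "run_batch",
    "td_loss_curves",
    "seqpred_generalization_test",
    "twelveax_test",
    "export_memory_weights",
    "SEQPRED_CRITERION",
    "TWELVEAX_CRITERION",
]

# task-specific layer sizes (sensory size comes from the task itself)
_LAYER_DEFAULTS = {
    "seqpred": dict(n_regular=3, n_memory=8, n_actions=2),
    "12ax": dict(n_regular=10, n_memory=20, n_actions=2),
}


@dataclass
class ConvergenceCriterion:
    """Required run of consecutive correct responses within a trial budget."""

    n_consecutive: int
    max_trials: int


SEQPRED_CRITERION = ConvergenceCriterion(100, 10_000)
TWELVEAX_CRITERION = ConvergenceCriterion(1000, 1_000_000)


class ConsecutiveCounter:
    """Consecutive-correct counter; any error resets it.

    Symbol-level mode counts every response of a trial; trial-level mode
    counts one prediction per trial, judged on the final step only.
    """

    def __init__(self, symbol_level: bool):
        self.symbol_level = symbol_level
        self.count = 0

    def update(self, actions: np.ndarray, correct: np.ndarray) -> int:
        if self.symbol_level:
            wrong = np.nonzero(actions != correct)[0]
            if wrong.size == 0:
                self.count += actions.shape[0]
            else:
                self.count = actions.shape[0] - 1 - int(wrong[-1])
        else:
            if actions[-1] == correct[-1]:
                self.count += 1
            else:
                self.count = 0
        return self.count


@dataclass
class RunStats:
    """Outcome of one training run."""

    converged: bool
    trials_to_criterion: Optional[int]
    n_trials: int
    network: Network
    deltas: Optional[np.ndarray] = None     # one TD error per prediction
    stimuli: Optional[np.ndarray] = None    # stimulus index per prediction


@dataclass
class BatchResult:
    """Aggregate over independent seeded runs.

    Learning-time statistics are computed over converged runs only;
    ``time_sd`` is None when fewer than two runs converged.
    """

    n_sims: int
    success_fraction: float
    time_mean: Optional[float]
    time_sd: Optional[float]
    trials_to_criterion: List[Optional[int]]
    master_seed: int

    @property
    def time_se(self) -> Optional[float]:
        if self.time_sd is None:
            return None
        n = sum(t is not None for t in self.trials_to_criterion)
        return self.time_sd / np.sqrt(n)


def architecture_for(task, variant: str, phi=None,
                     phi_leak: float = 0.7, **overrides) -> Architecture:
    """Build the task's default architecture for a named variant.

    Variants: 'standard' (phi = 1 everywhere), 'leaky' (phi = 0.7
    everywhere), 'hybrid' (first half conservative, second half leaky),
    'custom' (explicit phi vector).
    """
    from .tasks import TwelveAXTask
    kind = "12ax" if isinstance(task, TwelveAXTask) else "seqpred"
    sizes = dict(_LAYER_DEFAULTS[kind], n_sensory=task.n_symbols)
    sizes["n_actions"] = task.n_actions
    sizes.update(overrides)
    if variant == "custom":
        if phi is None:
            raise ValueError("custom variant requires an explicit phi vector")
        return Architecture(phi=np.asarray(phi, dtype=float), **sizes)
    if variant not in ("standard", "leaky", "hybrid"):
        raise ValueError(f"unknown variant {variant!r}")
    factory = getattr(Architecture, variant)
    if variant == "standard":
        return factory(**sizes)
    return factory(phi_leak=phi_leak, **sizes)


def make_network(task, variant: str, rng: np.random.Generator,
                 hp: Optional[HyperParams] = None, **arch_kwargs) -> Network:
    arch = architecture_for(task, variant, **arch_kwargs)
    return Network(arch, hp=hp, rng=rng)


def train_until_convergence(network: Network, task,
                            criterion: ConvergenceCriterion,
                            rng: np.random.Generator,
                            record: bool = False,
                            stop_at_criterion: bool = True) -> RunStats:
    """Train until the consecutive-correct criterion or the trial budget.

    With ``stop_at_criterion=False`` training always runs the full
    ``criterion.max_trials`` (used e.g. for fixed-length training regimes),
    while still recording when the criterion was first met.
    """
    counter = ConsecutiveCounter(task.symbol_level)
    deltas = [] if record else None
    stimuli = [] if record else None
    trials_to_criterion = None
    trial = 0
    while trial < criterion.max_trials:
        tr = task.sample_trial(rng)
        actions, d = network.run_trial(tr, rng, learn=True)
        trial += 1
        if record:
            deltas.append(d)
            stimuli.append(tr.stimuli)
        if trials_to_criterion is None:
            if counter.update(actions, tr.correct) >= criterion.n_consecutive:
                trials_to_criterion = trial
                if stop_at_criterion:
                    break
    converged = trials_to_criterion is not None
    return RunStats(
        converged=converged,
        trials_to_criterion=trials_to_criterion,
        n_trials=trial,
        network=network,
        deltas=np.concatenate(deltas) if record else None,
        stimuli=np.concatenate(stimuli) if record else None,
    )


def spawn_rngs(master_seed: int, n: int):
    """One independent Generator per simulation, derived from a master seed."""
    return [np.random.default_rng(ss)
            for ss in np.random.SeedSequence(master_seed).spawn(n)]


def run_batch(variant: str, task, n_sims: int,
              criterion: ConvergenceCriterion, master_seed: int,
              hp: Optional[HyperParams] = None,
              return_stats: bool = False, **arch_kwargs):
    """Independent seeded trainings; success fraction and learning times."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    times: List[Optional[int]] = []
    stats: List[RunStats] = []
    for rng in spawn_rngs(master_seed, n_sims):
        net = make_network(task, variant, rng, hp=hp, **arch_kwargs)
        st = train_until_convergence(net, task, criterion, rng)
        times.append(st.trials_to_criterion)
        if return_stats:
            stats.append(st)
    conv = [t for t in times if t is not None]
    result = BatchResult(
        n_sims=n_sims,
        success_fraction=len(conv) / n_sims,
        time_mean=float(np.mean(conv)) if conv else None,
        time_sd=float(np.std(conv, ddof=1)) if len(conv) > 1 else None,
        trials_to_criterion=times,
        master_seed=master_seed,
    )
    return (result, stats) if return_stats else result


def td_loss_curves(deltas: np.ndarray, stimuli: Optional[np.ndarray] = None,
                   target_stimuli=(5, 6), window: int = 2000):
    """Smoothed TD loss E = delta^2 / 2 per prediction.

    Returns a dict of DataFrames (columns ``prediction``, ``loss``): the
    overall curve, and — when per-prediction stimuli are given — curves
    restricted to potential target cues (X/Y for 12AX) and to all other
    cues. Smoothing is a moving average over ``window`` consecutive
    predictions of the respective subset.
    """
    loss = 0.5 * np.asarray(deltas, dtype=float) ** 2

    def smooth(values, index):
        s = (pd.Series(values)
             .rolling(window, min_periods=1).mean().to_numpy())
        return pd.DataFrame({"prediction": index, "loss": s})

    idx = np.arange(loss.shape[0])
    curves = {"all": smooth(loss, idx)}
    if stimuli is not None:
        mask = np.isin(stimuli, list(target_stimuli))
        curves["target_cues"] = smooth(loss[mask], idx[mask])
        curves["non_target_cues"] = smooth(loss[~mask], idx[~mask])
    return curves


def seqpred_generalization_test(network: Network, task, n_test: int = 1000,
                                rng: Optional[np.random.Generator] = None,
                                seed: int = 0) -> float:
    """Mean final-prediction accuracy on perturbed, longer test sequences.

    Weights frozen, greedy policy (the intermediate actions are unscored).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    g = g_weight(network.state.trial_index, network.hp)
    n_correct = 0
    for _ in range(n_test):
        tr = task.sample_test_trial(rng)
        actions, _ = network.run_trial(tr, rng, learn=False, g=g, eps=0.0)
        n_correct += int(actions[-1] == tr.correct[-1])
    return n_correct / n_test


def twelveax_test(network: Network, task, n_trials: int = 2000,
                  policy: str = "greedy",
                  rng: Optional[np.random.Generator] = None,
                  seed: int = 0) -> float:
    """Fraction of outer loops answered entirely correctly, weights frozen.

    ``policy='eps_greedy'`` is the classic rule — with probability eps the
    action is drawn uniformly at random (the g = 0 limit of the exploratory
    softmax), which is the harsher exploration used in the separate test
    phase; ``policy='softmax'`` keeps the training-time sharpened softmax
    with g frozen at its end-of-training value; ``policy='greedy'`` always
    takes the max-Q action.
    """
    if policy not in ("greedy", "eps_greedy", "softmax"):
        raise ValueError(f"unknown policy {policy!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if policy == "softmax":
        g = g_weight(network.state.trial_index, network.hp)
        eps = network.hp.eps
    elif policy == "eps_greedy":
        g = 0.0
        eps = network.hp.eps
    else:
        g = 0.0
        eps = 0.0
    n_ok = 0
    for _ in range(n_trials):
        tr = task.sample_trial(rng)
        actions, _ = network.run_trial(tr, rng, learn=False, g=g, eps=eps)
        n_ok += int(np.array_equal(actions, tr.correct))
    return n_ok / n_trials


def export_memory_weights(network: Network, task):
    """Labelled memory-branch weight tables for heatmap rendering.

    Returns (V_M, W_M) DataFrames: V_M rows are memory units tagged with
    their leak class (C conservative / L leaky), columns the ON(+)/OFF(-)
    transient unit of each symbol; W_M rows are the actions.
    """
    names = task.symbol_names
    cols = [f"{s}+" for s in names] + [f"{s}-" for s in names]
    phi = network.arch.phi
    rows = [f"M{j + 1}-{'C' if phi[j] == 1.0 else 'L'}"
            for j in range(network.arch.n_memory)]
    vm = pd.DataFrame(network.weights.V_M, index=rows, columns=cols)
    wm = pd.DataFrame(network.weights.W_M, index=task.action_names,
                      columns=rows)
    return vm, wm
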