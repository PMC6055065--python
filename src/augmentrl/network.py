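"""Three-layer attention-gated memory network trained with SARSA and synaptic tags.

The network (AuGMEnT family) maps a one-hot stimulus to action values through
two parallel branches. The *regular* branch sees the sustained stimulus; the
*memory* branch sees only stimulus transitions (ON/OFF transient units) and
integrates them in memory units with fixed per-unit leak coefficients
``phi`` — ``phi = 1`` is a conservative (non-leaky) integrator, ``phi < 1``
forgets with a finite timescale. Action values are linear read-outs of both
branches; an epsilon-greedy/softmax policy picks the action.

Learning is on-policy temporal-difference learning (SARSA) with a three-factor
rule: a global TD error, per-synapse eligibility traces, and an attentional
feedback pass through dedicated feedback weights that restricts credit to the
synapses that drove the chosen action. Momentary synaptic tags (presynaptic
trace x postsynaptic gain derivative) bridge the feedforward and feedback
passes; the memory branch's presynaptic trace is itself a leaky running sum of
transient inputs so that tags can link events across time steps.

This module is the granular reference implementation: one function per
conceptual operation, operating on small dataclasses. The numerically
identical fast per-trial loop used for training runs lives in
:mod:`augmentrl._kernel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernel

__all__ = [
    "HyperParams",
    "Architecture",
    "NetworkWeights",
    "NetworkState",
    "StepOutput",
    "Network",
    "encode_transient",
    "g_weight",
    "select_action",
    "td_error",
    "apply_weight_update",
    "update_tags_and_temporal_traces",
    "feedback_pass",
    "feedforward",
    "init_weights",
    "sigmoid",
]


def sigmoid(x):
    """Logistic gain function sigma(x) = 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class HyperParams:
    """Learning and exploration constants.

    Parameters
    ----------
    beta : float
        Learning rate of the three-factor weight update.
    lam : float
        Eligibility persistence (the lambda of SARSA(lambda)); enters only
        through the default ``alpha``.
    gamma : float
        Discount factor of the TD error.
    alpha : float, optional
        Per-step eligibility-trace decay. Defaults to ``1 - gamma * lam``.
    eps : float
        Exploration rate: probability of replacing the greedy action by a
        softmax draw.
    t_star : float
        Time scale, in completed trials, of the softmax sharpening schedule.
    m : float
        Asymptotic scaling factor of the softmax sharpening schedule.
    """

    beta: float = 0.15
    lam: float = 0.15
    gamma: float = 0.9
    alpha: Optional[float] = None
    eps: float = 0.025
    t_star: float = 2000.0
    m: float = 10.0

    def __post_init__(self):
        if self.alpha is None:
            self.alpha = 1.0 - self.gamma * self.lam
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError(f"eps must be in [0, 1], got {self.eps}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass
class Architecture:
    """Layer sizes and per-memory-unit leak coefficients.

    ``phi[j]`` multiplies memory potential j every time step: 1 keeps it
    (conservative unit), values below 1 make it leak.
    """

    n_sensory: int
    n_regular: int
    n_memory: int
    n_actions: int
    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (self.n_memory,):
            raise ValueError(
                f"phi must have length n_memory={self.n_memory}, "
                f"got shape {self.phi.shape}"
            )
        if np.any(self.phi < 0.0) or np.any(self.phi > 1.0):
            raise ValueError("all leak coefficients phi must be in [0, 1]")

    # --- presets -----------------------------------------------------------
    @classmethod
    def standard(cls, n_sensory, n_regular, n_memory, n_actions):
        """All memory units conservative (phi = 1)."""
        return cls(n_sensory, n_regular, n_memory, n_actions,
                   np.ones(n_memory))

    @classmethod
    def leaky(cls, n_sensory, n_regular, n_memory, n_actions, phi_leak=0.7):
        """All memory units leaky with a common coefficient."""
        return cls(n_sensory, n_regular, n_memory, n_actions,
                   np.full(n_memory, phi_leak))

    @classmethod
    def hybrid(cls, n_sensory, n_regular, n_memory, n_actions, phi_leak=0.7):
        """First half of the memory conservative, second half leaky."""
        phi = np.full(n_memory, phi_leak)
        phi[: n_memory // 2] = 1.0
        return cls(n_sensory, n_regular, n_memory, n_actions, phi)


@dataclass
class NetworkWeights:
    """The six synaptic matrices.

    ``V_R`` (R x S) and ``V_M`` (M x 2S) feed the hidden layer; ``W_R``
    (A x R) and ``W_M`` (A x M) read it out into action values; ``Wp_R``
    (R x A) and ``Wp_M`` (M x A) are the feedback weights used by the
    attentional feedback pass. Feedback weights receive the same increments as
    their feedforward partners, so they converge toward the transpose of the
    read-out weights during learning even though they are initialised
    independently.
    """

    V_R: np.ndarray
    V_M: np.ndarray
    W_R: np.ndarray
    W_M: np.ndarray
    Wp_R: np.ndarray
    Wp_M: np.ndarray

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(*(m.copy() for m in self.as_tuple()))

    def as_tuple(self):
        return (self.V_R, self.V_M, self.W_R, self.W_M, self.Wp_R, self.Wp_M)

    def check_shapes(self, arch: Architecture):
        S, R, M, A = (arch.n_sensory, arch.n_regular,
                      arch.n_memory, arch.n_actions)
        expected = {"V_R": (R, S), "V_M": (M, 2 * S), "W_R": (A, R),
                    "W_M": (A, M), "Wp_R": (R, A), "Wp_M": (M, A)}
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValueError(f"{name} has shape {got}, expected {shape}")


def init_weights(arch: Architecture, rng: np.random.Generator,
                 scale: float = 0.25) -> NetworkWeights:
    """Draw all six matrices i.i.d. uniform on [-scale, scale].

    Feedforward and feedback matrices are drawn independently; the learning
    rule, not the initialisation, is what aligns them over training.
    """
    S, R, M, A = (arch.n_sensory, arch.n_regular,
                  arch.n_memory, arch.n_actions)

    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)

    return NetworkWeights(
        V_R=u(R, S), V_M=u(M, 2 * S), W_R=u(A, R),
        W_M=u(A, M), Wp_R=u(R, A), Wp_M=u(M, A),
    )


@dataclass
class NetworkState:
    """Trial-local state: memory potentials, traces, tags, SARSA bookkeeping.

    Everything except ``trial_index`` is zeroed at each trial boundary;
    carrying traces across trials would leak credit between unrelated
    episodes.
    """

    s_prev: np.ndarray
    h_M: np.ndarray
    X_M: np.ndarray
    Tag_R: np.ndarray
    Tag_M: np.ndarray
    e_VR: np.ndarray
    e_VM: np.ndarray
    e_WR: np.ndarray
    e_WM: np.ndarray
    a_prev: Optional[int] = None
    Q_prev: float = 0.0
    trial_index: int = 0

    @classmethod
    def zeros(cls, arch: Architecture) -> "NetworkState":
        S, R, M, A = (arch.n_sensory, arch.n_regular,
                      arch.n_memory, arch.n_actions)
        return cls(
            s_prev=np.zeros(S), h_M=np.zeros(M), X_M=np.zeros((M, 2 * S)),
            Tag_R=np.zeros((R, S)), Tag_M=np.zeros((M, 2 * S)),
            e_VR=np.zeros((R, S)), e_VM=np.zeros((M, 2 * S)),
            e_WR=np.zeros((A, R)), e_WM=np.zeros((A, M)),
        )


@dataclass
class StepOutput:
    """Activities produced by one feedforward pass (action filled in later)."""

    y_R: np.ndarray
    y_M: np.ndarray
    q: np.ndarray
    h_R: np.ndarray
    s_trans: np.ndarray
    action: Optional[int] = None
    z: Optional[np.ndarray] = None
    delta: Optional[float] = None


# ---------------------------------------------------------------------------
# granular operations
# ---------------------------------------------------------------------------

def encode_transient(s_prev: np.ndarray, s_curr: np.ndarray) -> np.ndarray:
    """Rectified ON/OFF encoding of the stimulus transition.

    Returns a length-2S vector: the first S entries are stimulus onsets
    ``[s(t) - s(t-1)]_+``, the last S entries offsets ``[s(t-1) - s(t)]_+``.
    """
    s_prev = np.asarray(s_prev, dtype=float)
    s_curr = np.asarray(s_curr, dtype=float)
    if s_prev.shape != s_curr.shape:
        raise ValueError(
            f"stimulus length mismatch: {s_prev.shape} vs {s_curr.shape}")
    on = np.maximum(s_curr - s_prev, 0.0)
    off = np.maximum(s_prev - s_curr, 0.0)
    return np.concatenate([on, off])


def g_weight(trial_index: int, hp: HyperParams) -> float:
    """Softmax sharpening factor g(t) = 1 + (m/pi) * arctan(t / t_star).

    ``t`` counts completed trials; g grows from 1 toward 1 + m/2, gradually
    concentrating the exploratory softmax on the best action.
    """
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    return 1.0 + hp.m / np.pi * np.arctan(trial_index / hp.t_star)


def feedforward(s_curr: np.ndarray, state: NetworkState, w: NetworkWeights,
                arch: Architecture) -> StepOutput:
    """One feedforward pass; updates ``state.h_M`` and ``state.s_prev``.

    Regular branch: y_R = sigma(V_R s). Memory branch: potentials leak by phi
    and integrate the transient drive, y_M = sigma(h_M). Action values are the
    linear combination of both branches.
    """
    for name, mat in zip(("V_R", "V_M", "W_R", "W_M", "Wp_R", "Wp_M"),
                         w.as_tuple()):
        if not np.all(np.isfinite(mat)):
            raise FloatingPointError(f"non-finite values in weights {name}")
    s_curr = np.asarray(s_curr, dtype=float)
    h_R = w.V_R @ s_curr
    y_R = sigmoid(h_R)
    s_trans = encode_transient(state.s_prev, s_curr)
    state.h_M = arch.phi * state.h_M + w.V_M @ s_trans
    y_M = sigmoid(state.h_M)
    q = w.W_R @ y_R + w.W_M @ y_M
    state.s_prev = s_curr.copy()
    return StepOutput(y_R=y_R, y_M=y_M, q=q, h_R=h_R, s_trans=s_trans)


def select_action(q: np.ndarray, trial_index: int, hp: HyperParams,
                  rng: np.random.Generator, g: Optional[float] = None):
    """Epsilon-greedy action selection with a sharpening softmax.

    With probability 1 - eps the max-Q action is taken (ties broken uniformly
    at random); with probability eps the action is sampled from a softmax with
    logits ``g(t) * Q``. Exactly two uniforms are consumed per call, in a
    fixed order, so runs are reproducible draw-for-draw across the reference
    and compiled code paths.
    """
    q = np.asarray(q, dtype=float)
    if g is None:
        g = g_weight(trial_index, hp)
    u_explore = rng.random()
    u_select = rng.random()
    a = _kernel.select(q, float(g), float(hp.eps), u_explore, u_select)
    z = np.zeros(q.shape[0])
    z[a] = 1.0
    return int(a), z


def td_error(r: float, q_next: Optional[float], state: NetworkState,
             hp: HyperParams) -> float:
    """SARSA TD error for the previously taken action.

    delta = r + gamma * Q(a, t) - Q(a', t-1); at a terminal step
    (``q_next is None``) there is no successor value and delta = r - Q(a').
    """
    if state.a_prev is None:
        raise RuntimeError("td_error requires a previous action in the trial")
    if q_next is None:
        return r - state.Q_prev
    return r + hp.gamma * q_next - state.Q_prev


def apply_weight_update(delta: float, state: NetworkState, w: NetworkWeights,
                        hp: HyperParams) -> None:
    """Three-factor update: every weight moves by beta * eligibility * delta.

    Feedback weights receive the same increment as their feedforward partner
    (transposed), which is what aligns the attentional feedback pathway with
    the read-out over training.
    """
    if not np.isfinite(delta):
        raise FloatingPointError(f"non-finite TD error: {delta}")
    b = hp.beta * delta
    w.V_R += b * state.e_VR
    w.V_M += b * state.e_VM
    w.W_R += b * state.e_WR
    w.W_M += b * state.e_WM
    w.Wp_R += b * state.e_WR.T
    w.Wp_M += b * state.e_WM.T


def update_tags_and_temporal_traces(out: StepOutput, s_curr: np.ndarray,
                                    state: NetworkState, hp: HyperParams,
                                    phi: np.ndarray) -> None:
    """Refresh output-synapse eligibility traces, synaptic traces and tags.

    The temporal traces at the read-out synapses accumulate pre x post
    activity of the chosen action and decay by (1 - alpha). The memory
    branch's presynaptic trace X_M is a leaky running sum of transient inputs
    (``X <- phi * X + s``, per-unit phi). Tags are momentary — overwritten
    every step — and equal presynaptic activity times the sigmoid gain
    derivative at the current potential.
    """
    decay = 1.0 - hp.alpha
    state.e_WR = out.y_R * out.z[:, None] + decay * state.e_WR
    state.e_WM = out.y_M * out.z[:, None] + decay * state.e_WM
    state.X_M = phi[:, None] * state.X_M + np.asarray(out.s_trans, dtype=float)
    sp_R = out.y_R * (1.0 - out.y_R)        # sigma'(h_R)
    sp_M = out.y_M * (1.0 - out.y_M)        # sigma'(h_M)
    state.Tag_R = np.outer(sp_R, np.asarray(s_curr, dtype=float))
    state.Tag_M = state.X_M * sp_M[:, None]


def feedback_pass(out: StepOutput, state: NetworkState, w: NetworkWeights,
                  hp: HyperParams) -> None:
    """Attention-gated update of the input-synapse eligibility traces.

    The chosen action's unit sends its feedback weight down to each hidden
    unit; the tag converts that attentional signal into per-synapse credit:
    e_V <- Tag * (W' z) + (1 - alpha) * e_V.
    """
    decay = 1.0 - hp.alpha
    fb_R = w.Wp_R @ out.z
    fb_M = w.Wp_M @ out.z
    state.e_VR = state.Tag_R * fb_R[:, None] + decay * state.e_VR
    state.e_VM = state.Tag_M * fb_M[:, None] + decay * state.e_VM


# ---------------------------------------------------------------------------
# the network object
# ---------------------------------------------------------------------------

class Network:
    """A configured network: weights + trial state + the full SARSA step.

    Two execution paths share these weights. ``step``/``end_trial`` run the
    granular reference operations one call per time step; ``run_trial``
    executes a whole trial in the compiled kernel (used by
    :mod:`augmentrl.experiments`). Do not interleave the two within a trial.
    """

    def __init__(self, arch: Architecture, hp: Optional[HyperParams] = None,
                 weights: Optional[NetworkWeights] = None,
                 rng: Optional[np.random.Generator] = None,
                 init_scale: float = 0.25):
        self.arch = arch
        self.hp = hp if hp is not None else HyperParams()
        if weights is None:
            if rng is None:
                raise ValueError("provide either weights or an rng to "
                                 "initialise them")
            weights = init_weights(arch, rng, scale=init_scale)
        weights.check_shapes(arch)
        self.weights = weights
        self.state = NetworkState.zeros(arch)

    # -- granular path ------------------------------------------------------
    def _as_onehot(self, stimulus) -> np.ndarray:
        if np.isscalar(stimulus):
            s = np.zeros(self.arch.n_sensory)
            s[int(stimulus)] = 1.0
            return s
        return np.asarray(stimulus, dtype=float)

    def step(self, stimulus, reward: float, rng: np.random.Generator,
             g: Optional[float] = None) -> StepOutput:
        """One full time step: feedforward, action choice, SARSA update,
        trace/tag refresh, feedback pass.

        ``reward`` is the reward delivered for the *previous* action (SARSA
        timing); it is ignored on the first step of a trial, where no
        previous action exists and no weight update occurs.
        """
        s = self._as_onehot(stimulus)
        out = feedforward(s, self.state, self.weights, self.arch)
        out.action, out.z = select_action(out.q, self.state.trial_index,
                                          self.hp, rng, g=g)
        if self.state.a_prev is not None:
            out.delta = td_error(reward, float(out.q[out.action]),
                                 self.state, self.hp)
            apply_weight_update(out.delta, self.state, self.weights, self.hp)
        update_tags_and_temporal_traces(out, s, self.state, self.hp,
                                        self.arch.phi)
        feedback_pass(out, self.state, self.weights, self.hp)
        self.state.a_prev = out.action
        self.state.Q_prev = float(out.q[out.action])
        return out

    def end_trial(self, reward: float) -> float:
        """Terminal SARSA update (no successor value), then trial reset."""
        delta = td_error(reward, None, self.state, self.hp)
        apply_weight_update(delta, self.state, self.weights, self.hp)
        self.reset_trial()
        return delta

    def reset_trial(self) -> None:
        """Zero memory potentials, traces and tags; count the trial."""
        trial_index = self.state.trial_index + 1
        self.state = NetworkState.zeros(self.arch)
        self.state.trial_index = trial_index

    # -- compiled path ------------------------------------------------------
    def run_trial(self, trial, rng: np.random.Generator, learn: bool = True,
                  g: Optional[float] = None, eps: Optional[float] = None):
        """Run one whole trial through the compiled kernel.

        Parameters
        ----------
        trial : tasks.Trial
            Stimulus stream, correct actions and reward schedule.
        learn : bool
            If False the weights are frozen (evaluation mode).
        g, eps : float, optional
            Override the policy parameters (e.g. freeze g at its
            end-of-training value, or set eps=0 for a greedy test phase).

        Returns
        -------
        actions, deltas : int64[T], float64[T]
            The action emitted at each step and the TD error attributed to
            each prediction (the terminal one included).
        """
        T = trial.stimuli.shape[0]
        u = rng.random((T, 2))
        actions = np.empty(T, dtype=np.int64)
        deltas = np.empty(T, dtype=np.float64)
        if g is None:
            g = g_weight(self.state.trial_index, self.hp)
        if eps is None:
            eps = self.hp.eps
        _kernel.run_trial(
            trial.stimuli, trial.correct, trial.reward_correct,
            trial.reward_wrong, u, float(g), float(eps),
            self.hp.beta if learn else 0.0, self.hp.gamma, self.hp.alpha,
            self.arch.phi, *self.weights.as_tuple(), actions, deltas,
        )
        if learn:
            if not np.all(np.isfinite(deltas)):
                raise FloatingPointError("non-finite TD error during trial")
            self.state.trial_index += 1
        return actions, deltas

    def clone_frozen(self) -> "Network":
        """Copy of this network with its own weight arrays (for test phases)."""
        net = Network(self.arch, hp=replace(self.hp),
                      weights=self.weights.copy())
        net.state.trial_index = self.state.trial_index
        return net
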