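"""Compiled inner loop: one whole task trial per call.

The SARSA/tagging step is inherently sequential, and the experiment
protocols need millions of steps, so the per-step math is compiled with
numba. Weight matrices are updated in place; memory potentials, synaptic
traces and eligibility traces are zeroed at every trial boundary and
therefore live entirely inside the kernel.

The math here mirrors :mod:`augmentrl.network` operation for operation (a
test asserts trajectory equivalence). Randomness is injected as a
pre-drawn ``(T, 2)`` array of uniforms — two per step, exploration draw then
selection draw — so the reference and compiled paths consume the host
Generator identically.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def select(q, g, eps, u_explore, u_select):
    """Epsilon-greedy with softmax exploration; consumes two uniforms.

    Greedy: argmax of q, ties broken uniformly via u_select. Exploratory
    (u_explore < eps): inverse-CDF sample from softmax(g * q), max-subtracted
    for overflow safety.
    """
    A = q.shape[0]
    mx = q[0]
    for k in range(1, A):
        if q[k] > mx:
            mx = q[k]
    if u_explore < eps:
        total = 0.0
        for k in range(A):
            total += np.exp(g * (q[k] - mx))
        thresh = u_select * total
        acc = 0.0
        for k in range(A):
            acc += np.exp(g * (q[k] - mx))
            if acc > thresh:
                return k
        return A - 1
    n_ties = 0
    for k in range(A):
        if q[k] == mx:
            n_ties += 1
    pick = int(u_select * n_ties)
    if pick >= n_ties:
        pick = n_ties - 1
    seen = 0
    for k in range(A):
        if q[k] == mx:
            if seen == pick:
                return k
            seen += 1
    return A - 1


@njit(cache=True)
def _apply_update(stepsize, e_VR, e_VM, e_WR, e_WM,
                  V_R, V_M, W_R, W_M, Wp_R, Wp_M):
    # feedback weights get the transposed increment of their partner
    R, S = V_R.shape
    M, S2 = V_M.shape
    A = W_R.shape[0]
    for j in range(R):
        for i in range(S):
            V_R[j, i] += stepsize * e_VR[j, i]
    for j in range(M):
        for i in range(S2):
            V_M[j, i] += stepsize * e_VM[j, i]
    for k in range(A):
        for j in range(R):
            inc = stepsize * e_WR[k, j]
            W_R[k, j] += inc
            Wp_R[j, k] += inc
        for j in range(M):
            inc = stepsize * e_WM[k, j]
            W_M[k, j] += inc
            Wp_M[j, k] += inc


@njit(cache=True)
def run_trial(stim, correct, r_correct, r_wrong, u, g, eps,
              beta, gamma, alpha, phi,
              V_R, V_M, W_R, W_M, Wp_R, Wp_M,
              actions, deltas):
    """Run one trial; fill ``actions`` and ``deltas`` (one per prediction).

    ``stim`` holds one-hot stimulus indices; ``correct[t]`` is the scored
    action at step t (-1 if the step is unscored, in which case both reward
    entries are 0). ``deltas[t]`` is the TD error attributed to the
    prediction made at step t (computed one step later; the last entry is the
    terminal update). ``beta = 0`` freezes the weights (evaluation mode).
    """
    T = stim.shape[0]
    R, S = V_R.shape
    M = V_M.shape[0]
    A = W_R.shape[0]
    S2 = 2 * S
    h_M = np.zeros(M)
    X_M = np.zeros((M, S2))
    e_VR = np.zeros((R, S))
    e_VM = np.zeros((M, S2))
    e_WR = np.zeros((A, R))
    e_WM = np.zeros((A, M))
    y_R = np.empty(R)
    y_M = np.empty(M)
    q = np.empty(A)
    decay = 1.0 - alpha
    prev = -1
    a_prev = -1
    Q_prev = 0.0

    for t in range(T):
        i_t = stim[t]
        # --- feedforward: regular branch sees the sustained one-hot input
        for j in range(R):
            y_R[j] = 1.0 / (1.0 + np.exp(-V_R[j, i_t]))
        # transient ON/OFF drive into the memory branch
        on = -1
        off = -1
        if i_t != prev:
            on = i_t
            if prev >= 0:
                off = prev
        for j in range(M):
            h = phi[j] * h_M[j]
            if on >= 0:
                h += V_M[j, on]
            if off >= 0:
                h += V_M[j, S + off]
            h_M[j] = h
            y_M[j] = 1.0 / (1.0 + np.exp(-h))
        for k in range(A):
            acc = 0.0
            for j in range(R):
                acc += W_R[k, j] * y_R[j]
            for j in range(M):
                acc += W_M[k, j] * y_M[j]
            q[k] = acc
        # --- action selection
        a = select(q, g, eps, u[t, 0], u[t, 1])
        actions[t] = a
        # --- SARSA update for the previous action
        if a_prev >= 0:
            if a_prev == correct[t - 1]:
                r = r_correct[t - 1]
            else:
                r = r_wrong[t - 1]
            delta = r + gamma * q[a] - Q_prev
            deltas[t - 1] = delta
            if beta != 0.0:
                _apply_update(beta * delta, e_VR, e_VM, e_WR, e_WM,
                              V_R, V_M, W_R, W_M, Wp_R, Wp_M)
        # --- temporal eligibility traces at the read-out synapses
        for k in range(A):
            for j in range(R):
                e_WR[k, j] *= decay
            for j in range(M):
                e_WM[k, j] *= decay
        for j in range(R):
            e_WR[a, j] += y_R[j]
        for j in range(M):
            e_WM[a, j] += y_M[j]
        # --- synaptic traces: X <- phi * X + s_transient
        for j in range(M):
            pj = phi[j]
            for i in range(S2):
                X_M[j, i] *= pj
        if on >= 0:
            for j in range(M):
                X_M[j, on] += 1.0
        if off >= 0:
            for j in range(M):
                X_M[j, S + off] += 1.0
        # --- feedback pass: tags x attentional feedback of the chosen action
        for j in range(R):
            for i in range(S):
                e_VR[j, i] *= decay
            e_VR[j, i_t] += y_R[j] * (1.0 - y_R[j]) * Wp_R[j, a]
        for j in range(M):
            sp = y_M[j] * (1.0 - y_M[j])
            fb = Wp_M[j, a]
            for i in range(S2):
                e_VM[j, i] = decay * e_VM[j, i] + X_M[j, i] * sp * fb
        Q_prev = q[a]
        a_prev = a
        prev = i_t

    # --- terminal update: reward for the final action, no successor value
    if a_prev == correct[T - 1]:
        r = r_correct[T - 1]
    else:
        r = r_wrong[T - 1]
    delta = r - Q_prev
    deltas[T - 1] = delta
    if beta != 0.0:
        _apply_update(beta * delta, e_VR, e_VM, e_WR, e_WM,
                      V_R, V_M, W_R, W_M, Wp_R, Wp_M)
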