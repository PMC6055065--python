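"""Unit tests for the granular network operations."""

import numpy as np
import pytest

from augmentrl.network import (Architecture, HyperParams, Network,
                               NetworkState, apply_weight_update,
                               encode_transient, feedback_pass, feedforward,
                               g_weight, init_weights, select_action,
                               sigmoid, td_error,
                               update_tags_and_temporal_traces)


def onehot(i, n):
    v = np.zeros(n)
    v[i] = 1.0
    return v


class TestEncodeTransient:
    @pytest.mark.parametrize("prev,curr,expected_on,expected_off", [
        (3, 3, None, None),          # no transition -> all zero
        (None, 1, 1, None),          # onset from blank screen
        (1, 2, 2, 1),                # switch: onset of new, offset of old
    ])
    def test_rectified_onsets_and_offsets(self, prev, curr, expected_on,
                                          expected_off):
        S = 5
        s_prev = np.zeros(S) if prev is None else onehot(prev, S)
        s_curr = onehot(curr, S)
        out = encode_transient(s_prev, s_curr)
        expected = np.zeros(2 * S)
        if expected_on is not None:
            expected[expected_on] = 1.0
        if expected_off is not None:
            expected[S + expected_off] = 1.0
        np.testing.assert_array_equal(out, expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            encode_transient(np.zeros(3), np.zeros(4))


class TestGWeight:
    def test_schedule(self):
        hp = HyperParams(t_star=2000, m=10)
        assert g_weight(0, hp) == 1.0
        assert g_weight(2000, hp) == pytest.approx(3.5)   # 1 + m/4
        assert g_weight(10 ** 9, hp) == pytest.approx(6.0, abs=1e-5)

    def test_monotone(self):
        hp = HyperParams()
        gs = [g_weight(t, hp) for t in range(0, 10000, 500)]
        assert all(b >= a for a, b in zip(gs, gs[1:]))


class TestFeedforward:
    def test_zero_weights_give_half_activities_and_zero_q(self, small_arch):
        net = Network(small_arch, weights=_zero_weights(small_arch))
        out = feedforward(onehot(0, 4), net.state, net.weights, net.arch)
        np.testing.assert_array_equal(out.y_R, 0.5 * np.ones(3))
        np.testing.assert_array_equal(out.y_M, 0.5 * np.ones(4))
        np.testing.assert_array_equal(out.q, np.zeros(2))

    def test_repeated_stimulus_leaves_conservative_memory_unchanged(self,
                                                                    rng):
        arch = Architecture.standard(4, 3, 4, 2)
        net = Network(arch, rng=rng)
        s = onehot(2, 4)
        feedforward(s, net.state, net.weights, net.arch)
        h1 = net.state.h_M.copy()
        feedforward(s, net.state, net.weights, net.arch)
        np.testing.assert_array_equal(net.state.h_M, h1)

    def test_leaky_memory_accumulates_geometric_series(self):
        # three successive onsets of a fixed drive d: h = d (1 + phi + phi^2)
        arch = Architecture.leaky(2, 1, 1, 1, phi_leak=0.7)
        net = Network(arch, weights=_zero_weights(arch))
        d = 0.8
        net.weights.V_M[0, :] = 0.0
        net.weights.V_M[0, 0] = d    # ON unit of symbol 0
        net.weights.V_M[0, 1] = d    # ON unit of symbol 1
        net.weights.V_M[0, 2] = 0.0  # OFF weights zero
        net.weights.V_M[0, 3] = 0.0
        stims = [0, 1, 0]            # alternating -> onset every step
        for s in stims:
            feedforward(onehot(s, 2), net.state, net.weights, net.arch)
        assert net.state.h_M[0] == pytest.approx(d * (1 + 0.7 + 0.49))

    def test_nonfinite_weights_rejected(self, small_arch, rng):
        net = Network(small_arch, rng=rng)
        net.weights.W_M[0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="W_M"):
            feedforward(onehot(0, 4), net.state, net.weights, net.arch)


class TestSelectAction:
    def test_greedy_when_eps_zero(self, rng):
        hp = HyperParams(eps=0.0)
        for _ in range(50):
            a, z = select_action(np.array([0.2, 0.9]), 0, hp, rng)
            assert a == 1
            np.testing.assert_array_equal(z, [0.0, 1.0])

    def test_z_is_onehot_of_action(self, rng):
        hp = HyperParams(eps=1.0)
        for _ in range(100):
            q = rng.normal(size=3)
            a, z = select_action(q, 100, hp, rng)
            assert z.sum() == 1.0 and z[a] == 1.0

    def test_symmetric_softmax_is_uniform(self, rng):
        hp = HyperParams(eps=1.0)
        q = np.array([0.3, 0.3])
        counts = np.zeros(2)
        for _ in range(4000):
            a, _ = select_action(q, 0, hp, rng)
            counts[a] += 1
        # each action ~ Binomial(4000, 0.5); 5 sigma ~ 158
        assert abs(counts[0] - 2000) < 160

    def test_softmax_closed_form_frequencies(self, rng):
        # logits (0, ln 3) -> probabilities (0.25, 0.75)
        hp = HyperParams(eps=1.0, m=0.0)   # g = 1 exactly
        q = np.array([0.0, np.log(3.0)])
        n = 100_000
        hits = sum(select_action(q, 0, hp, rng)[0] for _ in range(n))
        se = np.sqrt(0.75 * 0.25 / n)
        assert hits / n == pytest.approx(0.75, abs=4 * se)


class TestTDError:
    @pytest.mark.parametrize("r,q_next,q_prev,expected", [
        (1.0, 0.0, 1.0, 0.0),
        (0.1, 0.5, 0.4, 0.15),
        (-1.0, None, 0.0, -1.0),     # terminal: no successor value
    ])
    def test_values(self, r, q_next, q_prev, expected):
        hp = HyperParams(gamma=0.9)
        state = NetworkState.zeros(Architecture.standard(2, 1, 1, 2))
        state.a_prev = 0
        state.Q_prev = q_prev
        assert td_error(r, q_next, state, hp) == pytest.approx(expected)

    def test_requires_previous_action(self):
        state = NetworkState.zeros(Architecture.standard(2, 1, 1, 2))
        with pytest.raises(RuntimeError, match="previous action"):
            td_error(1.0, 0.0, state, HyperParams())


class TestWeightUpdate:
    def test_zero_delta_changes_nothing(self, small_arch, rng):
        net = Network(small_arch, rng=rng)
        before = net.weights.copy()
        net.state.e_WM[:] = rng.normal(size=net.state.e_WM.shape)
        apply_weight_update(0.0, net.state, net.weights, net.hp)
        for a, b in zip(before.as_tuple(), net.weights.as_tuple()):
            np.testing.assert_array_equal(a, b)

    def test_feedforward_and_feedback_partners_move_together(self,
                                                             small_arch):
        net = Network(small_arch, weights=_zero_weights(small_arch),
                      hp=HyperParams(beta=0.15))
        net.state.e_WM[1, 2] = 2.0
        apply_weight_update(0.1, net.state, net.weights, net.hp)
        assert net.weights.W_M[1, 2] == pytest.approx(0.03)
        assert net.weights.Wp_M[2, 1] == pytest.approx(0.03)
        # synapses with zero trace never change
        assert net.weights.W_M[0, 0] == 0.0
        assert np.count_nonzero(net.weights.W_M) == 1

    def test_nonfinite_delta_rejected(self, small_net):
        with pytest.raises(FloatingPointError, match="TD error"):
            apply_weight_update(np.nan, small_net.state, small_net.weights,
                                small_net.hp)


class TestTracesAndTags:
    def _step_out(self, net, stim, action):
        out = feedforward(onehot(stim, net.arch.n_sensory), net.state,
                          net.weights, net.arch)
        out.action = action
        out.z = onehot(action, net.arch.n_actions)
        return out

    def test_alpha_one_gives_memoryless_output_traces(self, small_arch, rng):
        net = Network(small_arch, rng=rng, hp=HyperParams(alpha=1.0))
        out = self._step_out(net, 0, 1)
        update_tags_and_temporal_traces(out, onehot(0, 4), net.state,
                                        net.hp, net.arch.phi)
        np.testing.assert_array_equal(net.state.e_WR[1], out.y_R)
        np.testing.assert_array_equal(net.state.e_WR[0], np.zeros(3))

    def test_tag_at_zero_potential_is_quarter_of_trace(self, small_arch):
        # sigma'(0) = 0.25
        net = Network(small_arch, weights=_zero_weights(small_arch))
        out = self._step_out(net, 2, 0)
        update_tags_and_temporal_traces(out, onehot(2, 4), net.state,
                                        net.hp, net.arch.phi)
        np.testing.assert_allclose(net.state.Tag_M,
                                   0.25 * net.state.X_M)

    def test_synaptic_trace_accumulates_with_leak(self):
        # same ON unit active at t-1 and t with phi = 0.7 -> X = 1.7
        arch = Architecture.leaky(3, 1, 2, 2, phi_leak=0.7)
        net = Network(arch, weights=_zero_weights(arch))
        for stim in (0, 1, 0):       # ON_0 fires at steps 0 and 2
            out = self._step_out(net, stim, 0)
            update_tags_and_temporal_traces(out, onehot(stim, 3), net.state,
                                            net.hp, arch.phi)
        # ON_0 drive at t=0 decayed twice (0.49), again at t=2 (+1)
        assert net.state.X_M[0, 0] == pytest.approx(0.49 + 1.0)
        # ON_1 fired once, one decay step ago
        assert net.state.X_M[0, 1] == pytest.approx(0.7)


class TestFeedbackPass:
    def test_zero_tags_leave_only_decay(self, small_arch, rng):
        net = Network(small_arch, rng=rng)
        net.state.e_VM[:] = 1.0
        out = feedforward(onehot(0, 4), net.state, net.weights, net.arch)
        out.action, out.z = 0, onehot(0, 2)
        net.state.Tag_R[:] = 0.0
        net.state.Tag_M[:] = 0.0
        feedback_pass(out, net.state, net.weights, net.hp)
        np.testing.assert_allclose(net.state.e_VM,
                                   (1 - net.hp.alpha) * np.ones((4, 8)))

    def test_attentional_gating_uses_only_chosen_action(self, small_arch):
        net = Network(small_arch, weights=_zero_weights(small_arch),
                      hp=HyperParams(alpha=1.0))
        net.weights.Wp_M[1, 0] = 2.0     # feedback from action 0
        net.weights.Wp_M[1, 1] = 99.0    # unchosen action: must not matter
        net.state.Tag_M[1, 3] = 0.5
        out = feedforward(onehot(0, 4), net.state, net.weights, net.arch)
        out.action, out.z = 0, onehot(0, 2)
        # keep the tag configured above
        net.state.Tag_M[:] = 0.0
        net.state.Tag_M[1, 3] = 0.5
        feedback_pass(out, net.state, net.weights, net.hp)
        assert net.state.e_VM[1, 3] == pytest.approx(1.0)
        assert np.count_nonzero(net.state.e_VM) == 1


class TestInitWeights:
    def test_reproducible_and_bounded(self, small_arch):
        w1 = init_weights(small_arch, np.random.default_rng(7))
        w2 = init_weights(small_arch, np.random.default_rng(7))
        for a, b in zip(w1.as_tuple(), w2.as_tuple()):
            np.testing.assert_array_equal(a, b)
            assert np.all(np.abs(a) <= 0.25)

    def test_feedback_weights_independent_of_feedforward(self, small_arch):
        w = init_weights(small_arch, np.random.default_rng(7))
        assert not np.allclose(w.Wp_M, w.W_M.T)


class TestStepAndReset:
    def test_identical_seeds_identical_trajectories(self, small_arch):
        def run(seed):
            rng = np.random.default_rng(seed)
            net = Network(small_arch, rng=rng)
            for stim in [0, 1, 2, 3, 1]:
                net.step(stim, 0.1, rng)
            net.end_trial(1.0)
            return net.weights
        w1, w2 = run(3), run(3)
        for a, b in zip(w1.as_tuple(), w2.as_tuple()):
            np.testing.assert_array_equal(a, b)

    def test_hybrid_with_unit_phi_matches_standard_exactly(self):
        S, R, M, A = 4, 3, 4, 2
        archs = [Architecture.standard(S, R, M, A),
                 Architecture.hybrid(S, R, M, A, phi_leak=1.0)]
        results = []
        for arch in archs:
            rng = np.random.default_rng(11)
            net = Network(arch, rng=rng)
            for stim in [0, 2, 1, 3]:
                net.step(stim, -0.2, rng)
            net.end_trial(1.0)
            results.append(net.weights)
        for a, b in zip(results[0].as_tuple(), results[1].as_tuple()):
            np.testing.assert_array_equal(a, b)

    def test_zero_learning_rate_leaves_weights_unchanged(self, small_arch):
        rng = np.random.default_rng(5)
        net = Network(small_arch, hp=HyperParams(beta=0.0), rng=rng)
        before = net.weights.copy()
        net.step(0, 0.0, rng)
        net.end_trial(-1.0)
        for a, b in zip(before.as_tuple(), net.weights.as_tuple()):
            np.testing.assert_array_equal(a, b)

    def test_reset_clears_state_and_counts_trial(self, small_net, rng):
        small_net.step(0, 0.0, rng)
        small_net.step(1, 0.1, rng)
        t0 = small_net.state.trial_index
        small_net.reset_trial()
        st = small_net.state
        assert st.trial_index == t0 + 1
        for arr in (st.h_M, st.X_M, st.e_VR, st.e_VM, st.e_WR, st.e_WM,
                    st.Tag_R, st.Tag_M, st.s_prev):
            assert np.all(arr == 0.0)
        assert st.a_prev is None
        # next stimulus registers as a fresh onset
        out = feedforward(onehot(1, 4), st, small_net.weights,
                          small_net.arch)
        np.testing.assert_array_equal(out.s_trans[:4], onehot(1, 4))
        np.testing.assert_array_equal(out.s_trans[4:], np.zeros(4))
        # memory activity back at sigma(0) = 0.5 under zero drive
        assert np.all((out.y_M > 0) & (out.y_M < 1))

    def test_step_outputs_in_open_unit_interval(self, small_net, rng):
        for stim in [0, 3, 2, 0, 1]:
            out = small_net.step(stim, 0.0, rng)
            assert np.all((out.y_R > 0) & (out.y_R < 1))
            assert np.all((out.y_M > 0) & (out.y_M < 1))


class TestFeedbackAlignment:
    def test_relative_discrepancy_decreases_over_training(self):
        """Feedback weights converge toward the transpose of their
        feedforward partners as training accumulates shared increments."""
        from augmentrl.tasks import TwelveAXTask
        from augmentrl.experiments import make_network
        task = TwelveAXTask()
        rng = np.random.default_rng(2)
        net = make_network(task, "hybrid", rng)

        def rel_disc(w):
            return (np.linalg.norm(w.Wp_M - w.W_M.T)
                    / np.linalg.norm(w.W_M))

        d0 = rel_disc(net.weights)
        for _ in range(2000):
            tr = task.sample_trial(rng)
            net.run_trial(tr, rng)
        assert rel_disc(net.weights) < d0


class TestHyperParams:
    def test_default_alpha_is_one_minus_gamma_lambda(self):
        hp = HyperParams(gamma=0.9, lam=0.15)
        assert hp.alpha == pytest.approx(1 - 0.9 * 0.15)

    @pytest.mark.parametrize("kwargs", [
        dict(gamma=1.5), dict(eps=-0.1), dict(alpha=2.0), dict(beta=-1.0),
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HyperParams(**kwargs)

    def test_phi_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            Architecture(4, 3, 4, 2, phi=np.array([1.3, 1, 1, 1]))


def _zero_weights(arch):
    from augmentrl.network import NetworkWeights
    S, R, M, A = (arch.n_sensory, arch.n_regular, arch.n_memory,
                  arch.n_actions)
    return NetworkWeights(np.zeros((R, S)), np.zeros((M, 2 * S)),
                          np.zeros((A, R)), np.zeros((A, M)),
                          np.zeros((R, A)), np.zeros((M, A)))
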