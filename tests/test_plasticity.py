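"""The learning rule: gradients, strength updates, metaplasticity, theory."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stochsyn as ss
from stochsyn.network import softmax
from stochsyn.plasticity import effective_learning_rate, explicit_strength_update


def loss_with_masks(net, X, y, masks):
    """Independent cross-entropy evaluation through fixed release masks."""
    a = X
    for li, lyr in enumerate(net.layers):
        z = np.einsum("bji,ji,bi->bj", masks[li], lyr.m, a, optimize=True)
        a = np.maximum(z, 0.0) if li < len(net.layers) - 1 else softmax(z)
    return -np.log(a[np.arange(len(y)), y]).mean()


class TestUpdateDirection:
    def test_matches_finite_differences(self, small_net):
        """Backprop through the sampled network equals central finite
        differences of the loss in the strengths, converted by 1/p."""
        net = small_net.copy()
        rng = np.random.default_rng(3)
        X = rng.random((2, 6))
        y = np.array([0, 2])
        _, cache = ss.forward_stochastic(net, X, rng=5)
        g = ss.compute_update_direction(net, y, cache, ss.MetaplasticityConfig())
        eps = 1e-6
        for li in range(len(net.layers)):
            fd = np.zeros_like(net.layers[li].m)
            for idx in np.ndindex(*fd.shape):
                orig = net.layers[li].m[idx]
                net.layers[li].m[idx] = orig + eps
                lp = loss_with_masks(net, X, y, cache.masks)
                net.layers[li].m[idx] = orig - eps
                lm = loss_with_masks(net, X, y, cache.masks)
                net.layers[li].m[idx] = orig
                fd[idx] = (lp - lm) / (2 * eps)
            np.testing.assert_allclose(
                g.g[li], fd / net.layers[li].p, rtol=5e-4, atol=1e-6
            )

    def test_failed_release_contributes_no_gradient(self, small_net):
        # a synapse that did not transmit for the only example gets zero
        # strength gradient from it
        net = small_net.copy()
        X = np.random.default_rng(0).random((1, 6))
        _, cache = ss.forward_stochastic(net, X, rng=9)
        g = ss.compute_update_direction(
            net, np.array([1]), cache, ss.MetaplasticityConfig()
        )
        failed = ~cache.masks[0][0]
        assert np.all(g.g[0][failed] == 0.0)

    def test_l2_term_is_additive(self, small_net):
        net = small_net.copy()
        X = np.random.default_rng(1).random((3, 6))
        y = np.array([0, 1, 2])
        _, cache = ss.forward_stochastic(net, X, rng=2)
        g0 = ss.compute_update_direction(
            net, y, cache, ss.MetaplasticityConfig(lambda_l2=0.0)
        )
        g1 = ss.compute_update_direction(
            net, y, cache, ss.MetaplasticityConfig(lambda_l2=0.5)
        )
        for a, b, lyr in zip(g0.g, g1.g, net.layers):
            np.testing.assert_allclose(b - a, 0.5 * lyr.w_bar, atol=1e-12)

    def test_missing_cache_and_bad_labels_raise(self, small_net):
        with pytest.raises(ValueError):
            ss.compute_update_direction(
                small_net, np.array([0]), None, ss.MetaplasticityConfig()
            )
        net = small_net.copy()
        X = np.random.default_rng(0).random((1, 6))
        _, cache = ss.forward_stochastic(net, X, rng=0)
        with pytest.raises(ValueError):
            ss.compute_update_direction(
                net, np.array([7]), cache, ss.MetaplasticityConfig()
            )


class TestStrengthUpdate:
    def test_learning_rate_modulation(self):
        cfg = ss.MetaplasticityConfig(eta0=0.01, consolidation_on=True)
        lyr = ss.SynapseLayer(
            p=np.array([[0.9]]), m=np.array([[1.0]]),
            frozen=np.zeros((1, 1), bool),
        )
        assert effective_learning_rate(lyr, cfg) == pytest.approx(0.001)
        lyr.p[:] = 1.0
        assert effective_learning_rate(lyr, cfg) == pytest.approx(0.0)

    def test_hand_worked_strength_update(self):
        # p 0.5 -> 0.55, m = 2, g = 0.1, eta = 0.05:
        # m' = (0.5*2 - 0.05*0.1) / 0.55
        m_new = explicit_strength_update(
            np.array(0.5), np.array(0.55), np.array(2.0), 0.05, np.array(0.1)
        )
        assert m_new == pytest.approx(1.8090909090909089, abs=1e-12)

    def test_update_consistency_with_explicit_form(self):
        """Updating w_bar then dividing by the new p equals the explicit
        strength update to 1e-12 relative error."""
        rng = np.random.default_rng(8)
        net = ss.init_network([10, 7, 4], p_init=0.5, rng=1)
        cfg = ss.MetaplasticityConfig(p_up=0.07, p_down=0.07, eta0=0.05)
        for lyr in net.layers:
            lyr.p[:] = rng.uniform(0.25, 1.0, lyr.p.shape)
        g = ss.UpdateDirection(
            g=[rng.standard_normal(lyr.m.shape) * 0.01 for lyr in net.layers]
        )
        before = [(lyr.p.copy(), lyr.m.copy()) for lyr in net.layers]
        ss.apply_update(net, g, cfg)
        for lyr, (p_old, m_old), gl in zip(net.layers, before, g.g):
            expected = explicit_strength_update(p_old, lyr.p, m_old, cfg.eta0, gl)
            np.testing.assert_allclose(lyr.m, expected, rtol=1e-12)

    def test_nonfinite_gradient_rejected(self, small_net):
        net = small_net.copy()
        g = ss.UpdateDirection(g=[np.full(lyr.m.shape, np.nan) for lyr in net.layers])
        with pytest.raises(ValueError):
            ss.apply_update(net, g, ss.MetaplasticityConfig())


class TestReleaseProbabilityUpdate:
    def make_layer(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return ss.NetworkState(
            layers=[
                ss.SynapseLayer(p=p.copy(), m=np.ones_like(p),
                                frozen=np.zeros_like(p, dtype=bool))
            ]
        )

    def test_increase_branch_with_published_constants(self):
        net = self.make_layer([0.25])
        cfg = ss.MetaplasticityConfig(p_up=0.0516, p_down=0.0520, g_lim=0.001)
        ss.update_release_probabilities(
            net, ss.UpdateDirection(g=[np.array([[0.002]])]), cfg
        )
        assert net.layers[0].p[0, 0] == pytest.approx(0.3016)

    def test_boundary_gradient_takes_decrease_branch(self):
        # |g| exactly equal to g_lim decreases p (the rule uses <=)
        net = self.make_layer([0.5])
        cfg = ss.MetaplasticityConfig(p_up=0.1, p_down=0.1, g_lim=0.001)
        ss.update_release_probabilities(
            net, ss.UpdateDirection(g=[np.array([[0.001]])]), cfg
        )
        assert net.layers[0].p[0, 0] == pytest.approx(0.4)

    def test_clamping_at_both_ends(self):
        net = self.make_layer([0.25, 0.98])
        cfg = ss.MetaplasticityConfig(p_up=0.07, p_down=0.07, g_lim=0.001)
        g = ss.UpdateDirection(g=[np.array([[0.0, 0.5]])])
        ss.update_release_probabilities(net, g, cfg)
        np.testing.assert_allclose(net.layers[0].p, [[0.25, 1.0]])

    def test_freeze_caps_at_threshold_and_is_permanent(self):
        net = self.make_layer([0.85])
        cfg = ss.MetaplasticityConfig(
            p_up=0.2, p_down=0.2, g_lim=0.001, p_freeze=0.9, consolidation_on=True
        )
        up = ss.UpdateDirection(g=[np.array([[1.0]])])
        down = ss.UpdateDirection(g=[np.array([[0.0]])])
        ss.update_release_probabilities(net, up, cfg)
        # crossing the threshold freezes AT it, keeping 1 - p > 0
        assert net.layers[0].p[0, 0] == pytest.approx(0.9)
        assert net.layers[0].frozen[0, 0]
        for g in (up, down, up):
            ss.update_release_probabilities(net, g, cfg)
            assert net.layers[0].p[0, 0] == pytest.approx(0.9)

    def test_ghost_mode_keeps_transmission_fixed(self):
        net = self.make_layer([0.5])
        net.layers[0].ghost_p = np.array([[0.25]])
        cfg = ss.MetaplasticityConfig(
            p_up=0.1, p_down=0.1, g_lim=0.001, consolidation_on=True
        )
        ss.update_release_probabilities(
            net, ss.UpdateDirection(g=[np.array([[0.5]])]), cfg
        )
        assert net.layers[0].p[0, 0] == 0.5  # transmission untouched
        assert net.layers[0].ghost_p[0, 0] == pytest.approx(0.35)

    @given(
        seed=st.integers(0, 2**31 - 1),
        n_steps=st.integers(1, 60),
        consolidation=st.booleans(),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_clamp_and_freeze_invariants(self, seed, n_steps, consolidation):
        """Random update sequences keep p in [p_min, 1]; frozen entries
        never move again."""
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(0.25, 1.0, (3, 4))
        net = ss.NetworkState(
            layers=[ss.SynapseLayer(p=p0.copy(), m=np.ones_like(p0),
                                    frozen=np.zeros_like(p0, dtype=bool))]
        )
        cfg = ss.MetaplasticityConfig(
            p_up=0.0516, p_down=0.0520, g_lim=0.001,
            consolidation_on=consolidation,
        )
        frozen_values = {}
        for _ in range(n_steps):
            g = ss.UpdateDirection(g=[rng.standard_normal((3, 4)) * 0.002])
            ss.update_release_probabilities(net, g, cfg)
            lyr = net.layers[0]
            assert lyr.p.min() >= 0.25 and lyr.p.max() <= 1.0
            for idx in zip(*np.nonzero(lyr.frozen)):
                if idx in frozen_values:
                    assert lyr.p[idx] == frozen_values[idx]
                else:
                    frozen_values[idx] = lyr.p[idx]

    @pytest.mark.parametrize("direction", ["up", "down"])
    def test_absorbing_dynamics_step_count(self, direction):
        """Constant |g| regimes reach the absorbing value in exactly
        ceil((1 - p0)/p_up) (or the mirrored count) steps and stay there."""
        p0 = 0.25 if direction == "up" else 0.97
        net = self.make_layer([p0])
        cfg = ss.MetaplasticityConfig(p_up=0.07, p_down=0.07, g_lim=0.001)
        gval = 0.5 if direction == "up" else 0.0
        g = ss.UpdateDirection(g=[np.array([[gval]])])
        target = 1.0 if direction == "up" else 0.25
        gap = (1.0 - p0) if direction == "up" else (p0 - 0.25)
        n_expected = int(np.ceil(gap / 0.07))
        for step in range(1, n_expected + 5):
            ss.update_release_probabilities(net, g, cfg)
            if step < n_expected:
                assert net.layers[0].p[0, 0] != pytest.approx(target)
            else:
                assert net.layers[0].p[0, 0] == pytest.approx(target)


class TestAnalyticIncreaseProbability:
    def test_known_value_and_limits(self):
        assert ss.analytic_increase_probability(1.0, 1.0) == pytest.approx(
            0.31731050786291415, abs=1e-12
        )
        assert ss.analytic_increase_probability(1.0, 1e-12) == pytest.approx(1.0)

    def test_monotone_in_sigma(self):
        sigmas = np.linspace(0.1, 5.0, 25)
        vals = [ss.analytic_increase_probability(s, 0.5) for s in sigmas]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            ss.analytic_increase_probability(0.0, 0.5)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ss.MetaplasticityConfig(p_up=0.0)
        with pytest.raises(ValueError):
            ss.MetaplasticityConfig(g_lim=-1.0)
        with pytest.raises(ValueError):
            ss.MetaplasticityConfig(p_freeze=0.1)

    def test_file_round_trip(self, tmp_path):
        cfg = ss.MetaplasticityConfig.lifelong(eta0=0.001)
        path = tmp_path / "meta.yaml"
        cfg.to_file(path)
        assert ss.MetaplasticityConfig.from_file(path) == cfg
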