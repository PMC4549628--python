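"""Dual-system coordination: deciding probability, the three agents, lesions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dualsys as ds
from dualsys.agents import (
    EntropyCoordinationAgent,
    VPISelectionAgent,
    WeightMixtureAgent,
    lesion_entropies,
    p_deciding,
)
from tests.conftest import positive_store

H_MAX = math.log2(5)


class TestPDeciding:
    def test_first_trial_certain_decision(self):
        for lam1, lam2 in [(0.1, 0.1), (1.0, 1.0), (500.0, 2.0)]:
            assert p_deciding(0, 0, H_MAX, H_MAX, lam1, lam2, H_MAX) == 1.0

    def test_exhausted_memory_certain_decision(self):
        assert p_deciding(5, 5, H_MAX, H_MAX, 100.0, 0.01, H_MAX) == 1.0

    def test_direct_substitution(self):
        assert p_deciding(5, 0, H_MAX, H_MAX, 1.0, 1.0, H_MAX) == pytest.approx(1 / 6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 9),
        lam1=st.floats(1e-5, 1e3),
        lam2=st.floats(1e-5, 10),
        h_bwm=st.floats(0, H_MAX),
        h_ql=st.floats(0, H_MAX),
    )
    def test_monotonicities(self, n, lam1, lam2, h_bwm, h_ql):
        base = p_deciding(n, 0, h_bwm, h_ql, lam1, lam2, H_MAX)
        assert 0 < base <= 1
        # non-decreasing in items processed
        for i in range(n + 1):
            assert p_deciding(n, i, h_bwm, h_ql, lam1, lam2, H_MAX) >= base - 1e-15
        # non-increasing as the store grows
        assert p_deciding(n + 1 if n < 9 else n, 0, h_bwm, h_ql, lam1, lam2, H_MAX) <= base + 1e-15
        # non-decreasing in each entropy deficit
        assert p_deciding(n, 0, h_bwm * 0.5, h_ql, lam1, lam2, H_MAX) >= base - 1e-15
        assert p_deciding(n, 0, h_bwm, h_ql * 0.5, lam1, lam2, H_MAX) >= base - 1e-15


class TestEntropyCoordination:
    def make(self, **kw):
        defaults = dict(alpha=0.3, beta=5.0, N=5, epsilon=0.01,
                        lambda1=5.0, lambda2=3.0, seed=0)
        defaults.update(kw)
        return EntropyCoordinationAgent(**defaults)

    def test_first_trial_uniform_no_retrieval(self):
        p, diag = self.make().policy(0)
        assert diag["i"] == 0
        assert np.allclose(p, 0.2)

    def test_translation_invariance_of_final_policy(self):
        """Adding a constant to all habitual values leaves the policy fixed."""
        a1, a2 = self.make(seed=7), self.make(seed=7)
        for agent in (a1, a2):
            for (s, a, r) in [(0, 1, 0), (0, 2, 1), (1, 0, 0)]:
                agent.learn(s, a, r)
        a2.ql.Q += 3.7
        p1, d1 = a1.policy(0)
        p2, d2 = a2.policy(0)
        assert d1["i"] == d2["i"]  # identical decide/retrieve draws
        assert np.allclose(p1, p2, atol=1e-12)

    def test_zero_final_temperature_uniform(self):
        agent = self.make(beta_final=0.0)
        agent.learn(0, 2, 1)
        p, _ = agent.policy(0)
        assert np.allclose(p, 0.2)

    def test_acquisition_regime_favors_retrieval(self):
        """With a loaded store and maximal habitual entropy, items are
        usually processed before deciding."""
        agent = self.make(lambda1=50.0, lambda2=1.0, alpha=0.01, seed=3)
        for (s, a) in [(0, 0), (0, 1), (1, 2), (2, 3)]:
            agent.learn(s, a, 0)
        iis = [agent.policy(0)[1]["i"] for _ in range(200)]
        assert np.mean(iis) > 1.0

    def test_reproducible_with_seed(self, small_config):
        logs = [
            ds.run_session(self.make(seed=5), small_config, seed=11)
            for _ in range(2)
        ]
        assert [(r.action, r.i_processed) for r in logs[0]] == [
            (r.action, r.i_processed) for r in logs[1]
        ]


class TestWeightMixture:
    def make(self, **kw):
        defaults = dict(alpha=0.3, beta=5.0, N=5, theta=1.0, epsilon=0.01,
                        w0=0.5, seed=0)
        defaults.update(kw)
        return WeightMixtureAgent(**defaults)

    def test_pure_bwm_and_pure_ql_limits(self):
        agent = self.make()
        agent.learn(0, 2, 1)
        p_ql = agent.ql.policy(0)
        trace = ds.bwm_decide(agent.store, 0)
        agent.w[:] = 1.0
        assert np.allclose(agent.policy(0)[0], trace.p_bwm)
        agent.w[:] = 0.0
        assert np.allclose(agent.policy(0)[0], p_ql)

    def test_mixture_arithmetic(self):
        agent = self.make()
        agent.w[:] = 0.5
        p_ql = np.full(5, 0.2)
        p_bwm = np.array([1.0, 0, 0, 0, 0])
        agent._last[0] = (p_ql, p_bwm)
        p = 0.5 * p_ql + 0.5 * p_bwm
        assert np.allclose(p, [0.6, 0.1, 0.1, 0.1, 0.1])

    def test_weight_update_posterior(self):
        agent = self.make(w0=0.5)
        agent._last[0] = (np.full(5, 0.2), np.array([0.8, 0.05, 0.05, 0.05, 0.05]))
        agent.learn(0, 0, 1)  # rewarded: BWM predicted 0.8, QL 0.2
        assert agent.w[0] == pytest.approx(0.8)

    def test_equal_likelihoods_leave_weight_fixed(self):
        agent = self.make(w0=0.37)
        agent._last[0] = (np.full(5, 0.2), np.full(5, 0.2))
        agent.learn(0, 1, 1)
        assert agent.w[0] == pytest.approx(0.37)

    def test_zero_weight_absorbing(self):
        agent = self.make(w0=0.5)
        agent.w[:] = 0.0
        for r in (1, 0, 1):
            agent._last[0] = (np.full(5, 0.2), np.array([0.9, 0.025, 0.025, 0.025, 0.025]))
            agent.learn(0, 0, r)
            assert agent.w[0] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000), w0=st.floats(0.01, 0.99))
    def test_weight_stays_in_unit_interval(self, seed, w0):
        rng = np.random.default_rng(seed)
        agent = self.make(w0=w0, seed=seed)
        for _ in range(60):
            s = int(rng.integers(3))
            agent.policy(s)
            agent.learn(s, int(rng.integers(5)), int(rng.integers(2)))
            assert np.all((agent.w >= 0) & (agent.w <= 1))


class TestVPISelection:
    def make(self, **kw):
        defaults = dict(beta=5.0, N=5, theta=1.0, epsilon=0.01,
                        eta=1e-4, sigma_r=0.3, seed=0)
        defaults.update(kw)
        return VPISelectionAgent(**defaults)

    def test_session_start_consults_memory(self):
        agent = self.make()
        agent.learn(0, 1, 0)  # an early error: reward rate still zero
        _, diag = agent.policy(0)
        assert diag["system"] != "ql"
        assert diag["i"] >= 1

    def test_high_reward_rate_pure_habitual(self):
        agent = self.make()
        agent.learn(0, 1, 1)
        agent.rate.rate[:] = 1.0  # far above any VPI from tiny eta
        p, diag = agent.policy(0)
        assert diag["system"] == "ql"
        assert diag["i"] == 0
        assert np.allclose(p, ds.softmax_policy(agent.kalman.mean[0], 5.0))

    def test_tie_goes_to_habitual_branch(self):
        agent = self.make()
        v = ds.vpi(agent.kalman, 0)
        assert np.allclose(v, v[0])  # equal means: identical VPIs
        agent.rate.rate[0] = v[0]  # exactly equal, strict > required
        _, diag = agent.policy(0)
        assert diag["system"] == "ql"

    def test_learns_task_closed_loop(self, small_config):
        agent = self.make(beta=10.0, sigma_r=0.2, N=8, theta=0.7)
        log = ds.run_session(agent, small_config, seed=2)
        late = [r.outcome for r in log if r.trial >= 30]
        assert np.mean(late) > 0.8


class TestLesions:
    def test_mixture_zero_weight_matches_ql_only(self, nonrep_log):
        # w = 0 is absorbing under the posterior update, so the habitual
        # system carries the whole policy
        agent = WeightMixtureAgent(alpha=0.3, beta=5.0, w0=0.0, seed=0)
        sub = nonrep_log.subset_blocks([0])
        ent = lesion_entropies(agent, sub)
        assert np.allclose(ent[:, 0], ent[:, 2], atol=1e-12)

    def test_vpi_pure_ql_regime_matches_ql_only(self, nonrep_log):
        agent = VPISelectionAgent(beta=5.0, eta=1e-5, sigma_r=0.9, seed=0)
        sub = nonrep_log.subset_blocks([0])
        ent = lesion_entropies(agent, sub)
        # once the reward rate exceeds the (tiny) VPI, full == QL-only
        late = ent[20:]
        assert np.allclose(late[:, 0], late[:, 2], atol=1e-9)

    def test_entropy_coordination_synergy_on_consolidated_trials(self, ec_subject):
        """Combining systems carries more information than either alone."""
        gt, log = ec_subject
        agent = ds.make_agent(gt.model_id, gt.params, seed=41)
        ent = lesion_entropies(agent, log)
        late = np.array(
            [k for k, r in enumerate(log.trials) if r.trial >= 28]
        )
        h_full = ent[late, 0].mean()
        assert h_full <= ent[late, 1].mean() + 1e-9
        assert h_full <= ent[late, 2].mean() + 1e-9


def test_all_policies_are_pmfs_and_reproducible(small_config):
    for mid in ds.MODEL_IDS:
        a1 = ds.make_agent(mid, seed=9)
        a2 = ds.make_agent(mid, seed=9)
        l1 = ds.run_session(a1, small_config, seed=4)
        l2 = ds.run_session(a2, small_config, seed=4)
        assert [(r.action, r.outcome) for r in l1] == [
            (r.action, r.outcome) for r in l2
        ]
        agent = ds.make_agent(mid, seed=1)
        p, diag = agent.policy(1)
        assert p.min() >= 0 and p.sum() == pytest.approx(1.0)
        assert diag["i"] >= 0
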