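"""Fitness functions, Pareto machinery, aggregation, BIC, NSGA-II."""

import math

import numpy as np
import pytest

import dualsys as ds
from dualsys.fitting import (
    MODEL_SPECS,
    AggregationConfig,
    FitContext,
    ParetoSolution,
    _replay,
    aggregate,
    bic,
    best_by_likelihood,
    choice_likelihood,
    decode_params,
    diversity,
    leave_one_out,
    nsga2_fit,
    pareto_front,
    pareto_mask,
    rt_fitness,
)


# ---------------------------------------------------------------------------
# choice likelihood


class TestChoiceLikelihood:
    def test_uniform_policy_closed_form(self, small_config):
        log = ds.run_session(ds.UniformRandomAgent(seed=0), small_config, seed=0)
        log.trials = log.trials[:10]
        log.config = ds.TaskConfig(n_blocks=1, trials_per_block=42)
        # beta = 0 makes the habitual policy uniform on every trial
        res = choice_likelihood("qlearning", dict(alpha=0.5, beta=0.0), log)
        assert res["log_likelihood"] == pytest.approx(10 * math.log(0.2))
        assert np.allclose(res["per_trial"], 0.2)

    def test_hand_iterated_ql_chain(self):
        """Four-trial oracle: softmax/update chain computed independently."""
        cfg = ds.TaskConfig(n_blocks=1, trials_per_block=42)
        trials = [
            ds.TrialRecord(0, 0, 0, 1, 0),
            ds.TrialRecord(0, 1, 0, 2, 1),
            ds.TrialRecord(0, 2, 0, 2, 1),
            ds.TrialRecord(0, 3, 1, 0, 0),
        ]
        log = ds.BehaviorLog("oracle", cfg, trials)
        alpha, beta = 0.5, 10.0
        Q = np.zeros((3, 5))
        expected = 0.0
        for rec in trials:
            z = np.exp(beta * (Q[rec.stimulus] - Q[rec.stimulus].max()))
            p = z / z.sum()
            expected += math.log(p[rec.action])
            Q[rec.stimulus, rec.action] += alpha * (
                rec.outcome - Q[rec.stimulus, rec.action]
            )
        res = choice_likelihood("qlearning", dict(alpha=alpha, beta=beta), log)
        assert res["log_likelihood"] == pytest.approx(expected, abs=1e-10)

    def test_floor_warns_on_impossible_action(self):
        cfg = ds.TaskConfig(n_blocks=1, trials_per_block=42)
        trials = [ds.TrialRecord(0, t, 0, 0 if t else 1, 1) for t in range(4)]
        log = ds.BehaviorLog("x", cfg, trials)
        with pytest.warns(RuntimeWarning):
            res = choice_likelihood("qlearning", dict(alpha=0.9, beta=99.0), log)
        assert np.isfinite(res["log_likelihood"])


class TestKernelAgentConsistency:
    """The compiled replay kernels must match the reference agents."""

    CASES = {
        "qlearning": dict(alpha=0.4, beta=8.0),
        "bwm": dict(N=6, theta=1.2, epsilon=0.03),
        "weight_mixture": dict(alpha=0.35, beta=6.0, N=5, theta=1.0,
                               epsilon=0.02, w0=0.6),
        "vpi_selection": dict(beta=7.0, N=5, theta=1.0, epsilon=0.02,
                              eta=3e-4, sigma_r=0.3),
    }

    @staticmethod
    def _agent_replay(model_id, params, log):
        agent = ds.make_agent(model_id, params, seed=0)
        probs, iis, hs = [], [], []
        prev = None
        for rec in log:
            if rec.block != prev:
                agent.reset()
                prev = rec.block
            p, diag = agent.policy(rec.stimulus)
            probs.append(p[rec.action])
            iis.append(diag["i"])
            hs.append(diag["entropy"])
            agent.learn(rec.stimulus, rec.action, rec.outcome)
        return np.array(probs), np.array(iis), np.array(hs)

    @pytest.mark.parametrize("model_id", sorted(CASES))
    def test_deterministic_families_exact(self, model_id, ec_subject):
        _, log = ec_subject
        s, a, r, b = log.arrays()
        pk, ik, hk = _replay(model_id, self.CASES[model_id], s, a, r, b, 3, 5, 0)
        pa, ia, ha = self._agent_replay(model_id, self.CASES[model_id], log)
        assert np.allclose(pk, pa, atol=1e-12)
        assert np.array_equal(ik, ia)
        assert np.allclose(hk, ha, atol=1e-12)

    def test_entropy_coordination_exact_in_deciding_regime(self, ec_subject):
        # lambda1 -> 0 makes p(deciding) ~ 1: no retrieval, both paths agree
        _, log = ec_subject
        params = dict(alpha=0.3, beta=5.0, N=5, epsilon=0.02,
                      lambda1=1e-5, lambda2=1.0)
        s, a, r, b = log.arrays()
        pk, ik, _ = _replay("entropy_coordination", params, s, a, r, b, 3, 5, 1)
        pa, ia, _ = self._agent_replay("entropy_coordination", params, log)
        assert np.array_equal(ik, ia)
        assert np.allclose(pk, pa, atol=1e-10)

    def test_entropy_coordination_statistical_agreement(self, ec_subject):
        _, log = ec_subject
        sub = log.subset_blocks([0])
        params = dict(alpha=0.3, beta=5.0, N=5, epsilon=0.02,
                      lambda1=10.0, lambda2=3.0)
        s, a, r, b = sub.arrays()
        n_rep = 80
        pk = np.mean(
            [_replay("entropy_coordination", params, s, a, r, b, 3, 5, k)[0]
             for k in range(n_rep)],
            axis=0,
        )
        runs = []
        for k in range(n_rep):
            agent = ds.make_agent("entropy_coordination", params, seed=1000 + k)
            probs = []
            for rec in sub:
                p, _ = agent.policy(rec.stimulus)
                probs.append(p[rec.action])
                agent.learn(rec.stimulus, rec.action, rec.outcome)
            runs.append(probs)
        pa = np.mean(runs, axis=0)
        se = np.std(runs, axis=0, ddof=1) / math.sqrt(n_rep)
        assert np.all(np.abs(pk - pa) <= 5 * se + 0.02)


# ---------------------------------------------------------------------------
# RT fitness, diversity, Pareto, aggregation, BIC


class TestRTFitness:
    def test_identical_series_is_maximum(self):
        x = np.linspace(-1, 1, 15)
        assert rt_fitness(x, x) == 0.0

    def test_unit_offset_per_step(self):
        x = np.zeros(15)
        assert rt_fitness(x, x + 1.0) == pytest.approx(-15.0)

    def test_two_step_toy(self):
        assert rt_fitness(np.array([0.1, 0.8]), np.array([0.5, 1.0])) == pytest.approx(-0.2)

    def test_missing_steps_excluded_pairwise(self):
        m = np.array([0.0, np.nan, 1.0])
        s = np.array([1.0, 2.0, np.nan])
        assert rt_fitness(m, s) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            rt_fitness(np.full(3, np.nan), s)


class TestDiversity:
    def test_duplicate_scores_zero(self):
        pop = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(diversity(pop, k=1), 0.0)

    def test_opposite_corners(self):
        pop = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert np.allclose(diversity(pop, k=5), math.sqrt(2))

    def test_equally_spaced_line_k1(self):
        pop = np.array([[0.0], [0.3], [0.6]])
        assert diversity(pop, k=1)[1] == pytest.approx(0.3)

    def test_singleton_population(self):
        assert diversity(np.array([[0.2, 0.8]]))[0] == 0.0


def brute_force_front(F):
    keep = []
    for i, fi in enumerate(F):
        dominated = False
        for j, fj in enumerate(F):
            if i == j:
                continue
            if all(x >= y for x, y in zip(fj, fi)) and any(
                x > y for x, y in zip(fj, fi)
            ):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


class TestParetoFront:
    def test_mutually_nondominated_all_kept(self):
        F = np.array([[1, 0], [0, 1], [0.5, 0.5]])
        assert pareto_mask(F).all()

    def test_dominated_point_removed(self):
        F = np.array([[1, 1], [0.5, 0.5]])
        assert pareto_mask(F).tolist() == [True, False]

    def test_duplicates_kept(self):
        F = np.array([[1, 1], [1, 1], [0, 2]])
        assert pareto_mask(F).tolist() == [True, True, True]

    @pytest.mark.parametrize("m", [2, 3])
    def test_matches_brute_force(self, m, rng):
        F = rng.normal(0, 1, (120, m))
        assert sorted(np.flatnonzero(pareto_mask(F))) == brute_force_front(F)

    def test_solution_wrapper(self):
        sols = [
            ParetoSolution("qlearning", {}, fit_choice=-10.0, fit_rt=-1.0),
            ParetoSolution("bwm", {}, fit_choice=-12.0, fit_rt=-0.5),
            ParetoSolution("bwm", {}, fit_choice=-12.0, fit_rt=-2.0),
        ]
        front = pareto_front(sols)
        assert len(front) == 2


class TestAggregate:
    def _front(self, points, model="qlearning"):
        return [
            ParetoSolution(model, {}, fit_choice=float(x), fit_rt=float(y))
            for x, y in points
        ]

    def test_chebyshev_picks_balanced_solution(self):
        front = self._front([(1, 0), (0, 1), (0.7, 0.7)])
        win = aggregate(front, AggregationConfig(method="chebyshev", eps=0.001))
        assert win.fitness == (0.7, 0.7)

    def test_owa_min_operator(self):
        front = self._front([(0, 1), (1, 0), (0.2, 0.8)])
        cfg = AggregationConfig(method="owa", owa_weights=(1.0, 0.0))
        win = aggregate(front, cfg)
        # w = (1, 0) scores each solution by its worst coordinate
        assert win.fitness == (0.2, 0.8)

    def test_distance_to_reference(self):
        front = self._front([(1, 0), (0, 1), (0.9, 0.9)])
        win = aggregate(front, AggregationConfig(method="distance"))
        assert win.fitness == (0.9, 0.9)

    def test_chebyshev_winner_is_pareto_optimal(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 1, (30, 2))
            front = self._front(pts)
            win = aggregate(front, AggregationConfig(method="chebyshev"))
            F = np.array([s.fitness for s in front])
            mask = pareto_mask(F)
            k = next(
                i for i, s in enumerate(front) if s.fitness == win.fitness
            )
            assert mask[k]

    def test_degenerate_front_warns_and_returns_first(self):
        front = self._front([(0.5, 0.5), (0.5, 0.5)])
        with pytest.warns(RuntimeWarning):
            win = aggregate(front)
        assert win is front[0]


class TestBIC:
    def test_parameter_penalty_direction(self):
        n = 168
        assert bic(-100.0, 3, n) + 4 * math.log(n) == pytest.approx(bic(-100.0, 7, n))

    def test_zero_parameters(self):
        assert bic(-50.0, 0, 100) == pytest.approx(100.0)

    def test_unit_case(self):
        # with logL = 0, one parameter and n = e, the criterion is exactly 1
        assert bic(0.0, 1, math.e) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# NSGA-II


class TestNSGA2:
    @pytest.fixture(scope="class")
    def ql_log(self):
        # beta* = 5 keeps choices stochastic enough that the learning rate
        # is identifiable (a near-greedy generator leaves an alpha-beta ridge)
        gt = ds.GroundTruth("qlearning", dict(alpha=0.5, beta=5.0), seed=5)
        return ds.generate_subject(gt)

    def test_deterministic_given_seed(self, ql_log):
        f1 = nsga2_fit("qlearning", ql_log, pop=12, generations=6, seed=3)
        f2 = nsga2_fit("qlearning", ql_log, pop=12, generations=6, seed=3)
        assert [(s.fit_choice, s.fit_rt) for s in f1] == [
            (s.fit_choice, s.fit_rt) for s in f2
        ]

    def test_integer_gene_yields_integral_capacity(self, ql_log):
        front = nsga2_fit("bwm", ql_log, pop=12, generations=6, seed=1)
        assert all(float(s.params["N"]).is_integer() for s in front)
        assert all(2 <= s.params["N"] <= 9 for s in front)

    def test_parameters_within_bounds(self, ql_log):
        front = nsga2_fit("weight_mixture", ql_log, pop=10, generations=4, seed=2)
        for sol in front:
            for spec in MODEL_SPECS["weight_mixture"]:
                assert spec.low <= sol.params[spec.name] <= spec.high

    def test_ql_parameter_recovery(self, ql_log):
        """The front's best-likelihood solution recovers the generating
        learning rate and is not worse than the generating parameters."""
        front = nsga2_fit("qlearning", ql_log, pop=40, generations=100, seed=7)
        best = best_by_likelihood(front)
        truth = choice_likelihood("qlearning", dict(alpha=0.5, beta=5.0), ql_log)
        assert abs(best.params["alpha"] - 0.5) <= 0.15
        assert best.fit_choice >= truth["log_likelihood"] - 1.0


class TestLeaveOneOut:
    def test_four_folds_and_agreement(self, ec_subject):
        _, log = ec_subject
        res = leave_one_out(
            ("qlearning", "bwm"), log, pop=10, generations=5, seed=0
        )
        assert len(res["folds"]) == 4
        assert len(res["table"]) == 5
        assert 0.0 <= res["agreement"] <= 1.0

    def test_rejects_single_block(self, small_config):
        log = ds.run_session(ds.NonRepeatingAgent(seed=0), small_config, seed=0)
        with pytest.raises(ValueError):
            leave_one_out(("qlearning",), log)
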