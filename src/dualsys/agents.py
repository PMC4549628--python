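"""The five agent families: two single-system baselines and three
dual-system coordination mechanisms.

* ``QLearningAgent`` -- habitual system alone (softmax over cached Q-values).
* ``BWMAgent`` -- Bayesian Working Memory alone (threshold-stopped retrieval).
* ``EntropyCoordinationAgent`` -- the fixed retrieval threshold is replaced by
  a probabilistic decide/retrieve choice whose probability grows with the
  information already extracted by *both* systems; at decision the normalized
  BWM policy and the raw QL values are summed and passed through a softmax.
* ``WeightMixtureAgent`` -- the two systems' policies are blended with a
  per-stimulus weight updated as a Bayesian posterior over which system
  better predicted the outcome.
* ``VPISelectionAgent`` -- speed/accuracy arbitration: working memory is
  consulted only for actions whose value of perfect information exceeds the
  running reward rate, otherwise the cached Kalman means answer directly.

Every agent exposes ``policy(s) -> (p, diag)`` (action distribution without
sampling, used for teacher-forced likelihoods), ``act(s)`` (sample an action),
``learn(s, a, r)``, and ``reset`` / ``reset_memory`` for block boundaries.
``diag`` carries the processed-item count ``i`` and final-policy entropy used
by the simulated reaction time model.
"""

from __future__ import annotations

import math

import numpy as np

from .habitual import (
    KalmanQState,
    QLState,
    RewardRateState,
    kalman_update,
    ql_update,
    reward_rate_update,
    softmax_policy,
    vpi,
)
from .working_memory import (
    BWMParams,
    MemoryStore,
    RetrievalTrace,
    _start_trace,
    bwm_decide,
    encode_item,
    entropy,
    push_and_decay,
    retrieve_step,
)

__all__ = [
    "p_deciding",
    "QLearningAgent",
    "BWMAgent",
    "EntropyCoordinationAgent",
    "WeightMixtureAgent",
    "VPISelectionAgent",
    "make_agent",
    "lesion_entropies",
    "MODEL_IDS",
]

MODEL_IDS = (
    "qlearning",
    "bwm",
    "entropy_coordination",
    "weight_mixture",
    "vpi_selection",
)

#: Families combining the habitual and working-memory systems.
DUAL_SYSTEM_IDS = ("entropy_coordination", "weight_mixture", "vpi_selection")


def p_deciding(
    n: int,
    i: int,
    h_bwm: float,
    h_ql: float,
    lambda1: float,
    lambda2: float,
    h_max: float,
) -> float:
    """Probability of engaging the decision (vs retrieving one more item).

        p = 1 / (1 + lambda1 * (n - i) * exp(-lambda2 * (2 H_max - H_bwm - H_ql)))

    It is 1 when nothing is left to retrieve (i = n, in particular on the
    very first trial where n = 0), decreases with the number of unprocessed
    items, and increases with the information already gained by either system
    (the entropy deficits H_max - H).
    """
    if not 0 <= i <= n:
        raise ValueError("need 0 <= i <= n")
    deficit = 2.0 * h_max - h_bwm - h_ql
    return 1.0 / (1.0 + lambda1 * (n - i) * math.exp(-lambda2 * deficit))


class _AgentBase:
    n_stimuli = 3
    n_actions = 5

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def act(self, s: int):
        p, diag = self.policy(s)
        a = int(self.rng.choice(self.n_actions, p=p))
        return a, diag

    def policy(self, s: int):  # pragma: no cover - abstract
        raise NotImplementedError

    def learn(self, s: int, a: int, r: int) -> None:  # pragma: no cover
        raise NotImplementedError

    def reset(self) -> None:
        raise NotImplementedError

    def reset_memory(self) -> None:
        self.reset()


class QLearningAgent(_AgentBase):
    """Habitual strategy alone: no memory search, i is always 0."""

    model_id = "qlearning"

    def __init__(self, alpha=0.1, beta=3.0, gamma=0.0, sigma=1.0,
                 n_stimuli=3, n_actions=5, seed=0):
        super().__init__(seed)
        self.n_stimuli, self.n_actions = n_stimuli, n_actions
        self.sigma = sigma
        self.ql = QLState(n_stimuli, n_actions, alpha=alpha, beta=beta, gamma=gamma)

    def policy(self, s: int):
        p = self.ql.policy(s)
        return p, {"i": 0, "entropy": entropy(p), "system": "ql"}

    def learn(self, s, a, r) -> None:
        ql_update(self.ql, s, a, r)

    def reset(self) -> None:
        self.ql.reset()

    def reset_memory(self) -> None:
        pass  # no memory; cached values persist unless reset() is called


class BWMAgent(_AgentBase):
    """Working memory alone with the fixed entropy threshold theta."""

    model_id = "bwm"

    def __init__(self, N=5, theta=1.0, epsilon=0.01, sigma=1.0,
                 n_stimuli=3, n_actions=5, seed=0):
        super().__init__(seed)
        self.n_stimuli, self.n_actions = n_stimuli, n_actions
        self.sigma = sigma
        self.params = BWMParams(N=N, epsilon=epsilon, theta=theta,
                                n_stimuli=n_stimuli, n_actions=n_actions)
        self.store = MemoryStore(self.params)

    def policy(self, s: int):
        trace = bwm_decide(self.store, s)
        return trace.p_bwm, {"i": trace.i, "entropy": trace.H, "system": "bwm"}

    def learn(self, s, a, r) -> None:
        push_and_decay(self.store, encode_item(s, a, r, self.n_stimuli, self.n_actions))

    def reset(self) -> None:
        self.store.reset()


class EntropyCoordinationAgent(_AgentBase):
    """Probabilistic decide/retrieve arbitration driven by both entropies.

    The policy itself is stochastic (the number of items retrieved is
    sampled), so two calls with the same state can return different
    distributions; likelihood evaluation averages over replays.
    """

    model_id = "entropy_coordination"

    def __init__(self, alpha=0.1, beta=3.0, N=5, epsilon=0.01,
                 lambda1=1.0, lambda2=1.0, beta_final=None, sigma=1.0,
                 gamma=0.0, n_stimuli=3, n_actions=5, seed=0):
        super().__init__(seed)
        self.n_stimuli, self.n_actions = n_stimuli, n_actions
        self.sigma = sigma
        self.lambda1, self.lambda2 = lambda1, lambda2
        # default fitting configuration ties beta_final to beta
        self.beta_final = beta if beta_final is None else beta_final
        self.ql = QLState(n_stimuli, n_actions, alpha=alpha, beta=beta, gamma=gamma)
        self.params = BWMParams(N=N, epsilon=epsilon, theta=1.0,
                                n_stimuli=n_stimuli, n_actions=n_actions)
        self.store = MemoryStore(self.params)

    def _retrieve(self, s: int) -> tuple[RetrievalTrace, float]:
        h_max = self.params.h_max
        h_ql = entropy(self.ql.policy(s))
        n = len(self.store)
        trace = _start_trace(self.n_stimuli, self.n_actions)
        while True:
            p_dec = p_deciding(n, trace.i, trace.H, h_ql,
                               self.lambda1, self.lambda2, h_max)
            if trace.i >= n or self.rng.random() < p_dec:
                break
            retrieve_step(trace, self.store, s)
        return trace, h_ql

    def policy(self, s: int):
        trace, h_ql = self._retrieve(s)
        q_final = trace.p_bwm + self.ql.Q[s]
        p = softmax_policy(q_final, self.beta_final)
        return p, {
            "i": trace.i,
            "entropy": entropy(p),
            "h_ql": h_ql,
            "h_bwm": trace.H,
            "system": "both",
        }

    def lesioned_policies(self, s: int):
        trace, _ = self._retrieve(s)
        full = softmax_policy(trace.p_bwm + self.ql.Q[s], self.beta_final)
        bwm_only = softmax_policy(trace.p_bwm, self.beta_final)
        ql_only = softmax_policy(self.ql.Q[s], self.beta_final)
        return full, bwm_only, ql_only

    def learn(self, s, a, r) -> None:
        ql_update(self.ql, s, a, r)
        push_and_decay(self.store, encode_item(s, a, r, self.n_stimuli, self.n_actions))

    def reset(self) -> None:
        self.ql.reset()
        self.store.reset()

    def reset_memory(self) -> None:
        self.store.reset()


class WeightMixtureAgent(_AgentBase):
    """Per-stimulus posterior weighting of the two systems' policies."""

    model_id = "weight_mixture"

    def __init__(self, alpha=0.1, beta=3.0, N=5, theta=1.0, epsilon=0.01,
                 w0=0.5, sigma=1.0, gamma=0.0, n_stimuli=3, n_actions=5, seed=0):
        super().__init__(seed)
        self.n_stimuli, self.n_actions = n_stimuli, n_actions
        self.sigma = sigma
        self.w0 = w0
        self.ql = QLState(n_stimuli, n_actions, alpha=alpha, beta=beta, gamma=gamma)
        self.params = BWMParams(N=N, epsilon=epsilon, theta=theta,
                                n_stimuli=n_stimuli, n_actions=n_actions)
        self.store = MemoryStore(self.params)
        self.w = np.full(n_stimuli, w0)
        self._last = {}  # stimulus -> (p_ql, p_bwm) from the acting step

    def policy(self, s: int):
        p_ql = self.ql.policy(s)
        trace = bwm_decide(self.store, s)
        p = (1.0 - self.w[s]) * p_ql + self.w[s] * trace.p_bwm
        self._last[s] = (p_ql, trace.p_bwm)
        return p, {"i": trace.i, "entropy": entropy(p), "system": "both"}

    def lesioned_policies(self, s: int):
        p, _ = self.policy(s)
        p_ql, p_bwm = self._last[s]
        return p, p_bwm, p_ql

    def learn(self, s, a, r) -> None:
        if s not in self._last:  # teacher forcing may skip the acting step
            self.policy(s)
        p_ql, p_bwm = self._last.pop(s)
        # posterior weight update from the outcome likelihood of each system
        lik_bwm = p_bwm[a] if r else 1.0 - p_bwm[a]
        lik_ql = p_ql[a] if r else 1.0 - p_ql[a]
        denom = lik_bwm * self.w[s] + lik_ql * (1.0 - self.w[s])
        if denom > 0:
            self.w[s] = lik_bwm * self.w[s] / denom
        ql_update(self.ql, s, a, r)
        push_and_decay(self.store, encode_item(s, a, r, self.n_stimuli, self.n_actions))

    def reset(self) -> None:
        self.ql.reset()
        self.store.reset()
        self.w[:] = self.w0
        self._last.clear()

    def reset_memory(self) -> None:
        self.store.reset()
        self._last.clear()


class VPISelectionAgent(_AgentBase):
    """Speed/accuracy arbitration between Kalman Q-values and the BWM.

    Per action: if VPI(s,a) exceeds the reward rate R(s), that action's value
    is taken from the working-memory policy, otherwise from the Kalman mean
    (ties go to the habitual branch).  Retrieval is skipped entirely (i = 0)
    when no action's VPI exceeds R(s).
    """

    model_id = "vpi_selection"

    def __init__(self, beta=3.0, N=5, theta=1.0, epsilon=0.01,
                 eta=1e-4, sigma_r=0.2, sigma=1.0, gamma=0.0,
                 n_stimuli=3, n_actions=5, seed=0, per_action=True):
        super().__init__(seed)
        self.n_stimuli, self.n_actions = n_stimuli, n_actions
        self.sigma = sigma
        self.beta = beta
        self.per_action = per_action
        self.kalman = KalmanQState(n_stimuli, n_actions, eta=eta, gamma=gamma)
        self.rate = RewardRateState(n_stimuli, sigma_r=sigma_r)
        self.params = BWMParams(N=N, epsilon=epsilon, theta=theta,
                                n_stimuli=n_stimuli, n_actions=n_actions)
        self.store = MemoryStore(self.params)

    def _values(self, s: int):
        v = vpi(self.kalman, s)
        rbar = self.rate.rate[s]
        mask = v > rbar
        if mask.any():
            trace = bwm_decide(self.store, s)
            if self.per_action:
                q = np.where(mask, trace.p_bwm, self.kalman.mean[s])
            else:
                q = trace.p_bwm
            return q, trace.i, ("both" if self.per_action and not mask.all() else "bwm")
        return self.kalman.mean[s].copy(), 0, "ql"

    def policy(self, s: int):
        q, i, system = self._values(s)
        p = softmax_policy(q, self.beta)
        return p, {"i": i, "entropy": entropy(p), "system": system}

    def lesioned_policies(self, s: int):
        q, _, _ = self._values(s)
        full = softmax_policy(q, self.beta)
        trace = bwm_decide(self.store, s)
        bwm_only = softmax_policy(trace.p_bwm, self.beta)
        ql_only = softmax_policy(self.kalman.mean[s], self.beta)
        return full, bwm_only, ql_only

    def learn(self, s, a, r) -> None:
        kalman_update(self.kalman, s, a, r)
        reward_rate_update(self.rate, s, r)
        push_and_decay(self.store, encode_item(s, a, r, self.n_stimuli, self.n_actions))

    def reset(self) -> None:
        self.kalman.reset()
        self.rate.reset()
        self.store.reset()

    def reset_memory(self) -> None:
        self.store.reset()


_AGENT_CLASSES = {
    "qlearning": QLearningAgent,
    "bwm": BWMAgent,
    "entropy_coordination": EntropyCoordinationAgent,
    "weight_mixture": WeightMixtureAgent,
    "vpi_selection": VPISelectionAgent,
}


def make_agent(model_id: str, params: dict | None = None, seed: int = 0, **kwargs):
    """Instantiate an agent family by id with a flat parameter mapping."""
    if model_id not in _AGENT_CLASSES:
        raise ValueError(f"unknown model id {model_id!r}; choose from {MODEL_IDS}")
    params = dict(params or {})
    params.update(kwargs)
    return _AGENT_CLASSES[model_id](seed=seed, **params)


def lesion_entropies(agent, log) -> np.ndarray:
    """Teacher-forced replay returning per-trial entropies of the final
    policy computed three ways: full model, with the QL contribution removed
    (BWM only), and with the BWM contribution removed (QL only).

    Returns an array of shape (n_trials, 3): (H_full, H_bwm_only, H_ql_only).
    """
    out = np.empty((len(log), 3))
    prev_block = None
    for t, rec in enumerate(log):
        if rec.block != prev_block:
            agent.reset()
            prev_block = rec.block
        full, bwm_only, ql_only = agent.lesioned_policies(rec.stimulus)
        out[t] = (entropy(full), entropy(bwm_only), entropy(ql_only))
        agent.learn(rec.stimulus, rec.action, rec.outcome)
    return out
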