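"""Habitual (model-free) value learning.

Two learners live here.  The standard tabular Q-Learning rule

    Q(s,a) <- Q(s,a) + alpha * (r + gamma * max_a' Q(s',a') - Q(s,a))

with a softmax policy p(a) proportional to exp(beta * Q(s,a)), and a
per-(state, action) scalar Kalman filter over Q-values which additionally
tracks a posterior variance sigma^2(s,a).  The Kalman variant feeds the
value-of-perfect-information (VPI) computation used by the selection model:
VPI(s,a) is the expected gain from learning action a's true value exactly,
evaluated under the Gaussian posterior N(mean(s,a), sigma^2(s,a)) against the
current best (or second best) action.  A stimulus-wise exponential moving
average reward rate provides the opportunity cost VPI is compared with.

In this task stimuli are independent and reward is immediate, so the
discount factor defaults to gamma = 0 (it remains configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "QLState",
    "KalmanQState",
    "RewardRateState",
    "softmax_policy",
    "ql_update",
    "kalman_update",
    "vpi",
    "reward_rate_update",
]


def softmax_policy(values: np.ndarray, beta: float) -> np.ndarray:
    """Softmax action probabilities p(a) = exp(beta*v_a) / sum exp(beta*v).

    Computed with max-subtraction so large beta*v never overflows.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax requires finite values")
    if beta < 0:
        raise ValueError("inverse temperature must be >= 0")
    z = beta * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class QLState:
    """Tabular Q-values with learning rate, discount and inverse temperature."""

    n_stimuli: int = 3
    n_actions: int = 5
    alpha: float = 0.1
    beta: float = 3.0
    gamma: float = 0.0
    Q: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 <= self.beta < 100:
            raise ValueError(f"beta must be in [0,100), got {self.beta}")
        if not 0 <= self.gamma <= 1:
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if self.Q is None:
            self.Q = np.zeros((self.n_stimuli, self.n_actions))

    def policy(self, s: int) -> np.ndarray:
        return softmax_policy(self.Q[s], self.beta)

    def reset(self) -> None:
        self.Q[:] = 0.0


def ql_update(state: QLState, s: int, a: int, r: float, s_next: int | None = None) -> float:
    """One temporal-difference update in place; returns the TD error delta.

    With ``s_next`` None (terminal / independent-trial setting) the bootstrap
    term is dropped, which coincides with gamma = 0.
    """
    boot = 0.0
    if s_next is not None and state.gamma > 0:
        boot = state.gamma * state.Q[s_next].max()
    delta = r + boot - state.Q[s, a]
    state.Q[s, a] += state.alpha * delta
    return float(delta)


@dataclass
class KalmanQState:
    """Gaussian Q-value beliefs: per-(s,a) mean and variance.

    ``eta`` initializes the variances (the prior uncertainty); observation
    noise enters the Kalman gain, process noise re-inflates variance each
    step (0 for a stationary task).  Observation noise defaults to ``eta``
    itself: with prior variance equal to observation noise the gains follow
    the 1/2, 1/3, 1/4, ... schedule of a running sample mean, so after
    convergence the means sit where a plain Q-Learner's values would.
    """

    n_stimuli: int = 3
    n_actions: int = 5
    eta: float = 1e-4
    observation_noise: float | None = None
    process_noise: float = 0.0
    gamma: float = 0.0
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    var: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.observation_noise is None:
            self.observation_noise = self.eta
        if self.observation_noise < 0 or self.process_noise < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.mean is None:
            self.mean = np.zeros((self.n_stimuli, self.n_actions))
        if self.var is None:
            self.var = np.full((self.n_stimuli, self.n_actions), self.eta)

    def reset(self) -> None:
        self.mean[:] = 0.0
        self.var[:] = self.eta


def kalman_update(
    state: KalmanQState, s: int, a: int, r: float, s_next: int | None = None
) -> float:
    """Scalar Kalman step on the (s,a) belief; returns the gain used."""
    target = r
    if s_next is not None and state.gamma > 0:
        target = r + state.gamma * state.mean[s_next].max()
    gain = state.var[s, a] / (state.var[s, a] + state.observation_noise)
    state.mean[s, a] += gain * (target - state.mean[s, a])
    state.var[s, a] = (1.0 - gain) * state.var[s, a] + state.process_noise
    return float(gain)


def vpi(state: KalmanQState, s: int) -> np.ndarray:
    """Value of perfect information for every action at stimulus ``s``.

    With a1 the best and a2 the second-best action by posterior mean (ties
    broken by lowest index), the gain from perfectly knowing action a's value
    is the expected shortfall across the decision boundary:

        a == a1:  (m2 - m1) * Phi((m2 - m1)/sd1) + sd1 * phi((m2 - m1)/sd1)
        a != a1:  (ma - m1) * Phi((ma - m1)/sda) ... mirrored against a1

    where Phi/phi are the standard normal CDF/pdf.  Always >= 0; the sd -> 0
    limit is 0 for distinct means.
    """
    means = state.mean[s]
    sds = np.sqrt(state.var[s])
    if means.size < 2:
        raise ValueError("VPI needs at least 2 actions")
    order = np.argsort(-means, kind="stable")  # ties -> lowest index first
    a1, a2 = int(order[0]), int(order[1])
    out = np.empty_like(means)
    for a in range(means.size):
        if a == a1:
            gap = means[a2] - means[a1]  # <= 0
            sd = sds[a1]
        else:
            gap = means[a] - means[a1]  # <= 0
            sd = sds[a]
        if sd == 0.0:
            out[a] = 0.0  # perfect-information limit
            continue
        z = gap / sd
        out[a] = gap * norm.cdf(z) + sd * norm.pdf(z)
    return np.maximum(out, 0.0)


@dataclass
class RewardRateState:
    """Stimulus-wise exponential moving average of the binary outcome."""

    n_stimuli: int = 3
    sigma_r: float = 0.2
    rate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 < self.sigma_r < 1:
            raise ValueError(f"sigma_r must be in (0,1), got {self.sigma_r}")
        if self.rate is None:
            self.rate = np.zeros(self.n_stimuli)

    def reset(self) -> None:
        self.rate[:] = 0.0


def reward_rate_update(state: RewardRateState, s: int, r: float) -> float:
    """R(s) <- (1 - sigma_r) R(s) + sigma_r * r; returns the new rate."""
    state.rate[s] = (1.0 - state.sigma_r) * state.rate[s] + state.sigma_r * r
    return float(state.rate[s])
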