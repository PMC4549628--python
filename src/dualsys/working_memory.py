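"""Bayesian Working Memory (BWM): the deliberative, goal-directed system.

The BWM stores a bounded FIFO list of explicit trial descriptions.  Each item
holds three probability mass functions -- p(s|t_i) over stimuli, p(a|s,t_i)
over actions per stimulus, and p(r=1|a,s,t_i) per (stimulus, action).  A fresh
item is (near-)deterministic on the trial it encodes; every stored item is
blended toward the uniform distribution once per subsequent trial (decay rate
epsilon), so older items carry less information.

At decision time the items are processed most-recent-first.  Their
contributions are accumulated into a joint mass over (s, a, r), sliced at the
presented stimulus, normalized per outcome, and converted to action values by
the ratio Q(a) = p(a|r=1) / p(a|r=0): actions recalled as rewarded are
promoted, actions recalled as unrewarded are suppressed.  The normalized
ratios are the action probabilities; retrieval stops as soon as their Shannon
entropy H drops to a threshold theta (or the store is exhausted).  A positive
recall of the current stimulus collapses H almost to zero, while a negative
recall removes only one candidate action and lowers H just a little -- this
asymmetry is what makes entropy a useful stopping signal here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MemoryItem",
    "MemoryStore",
    "RetrievalTrace",
    "BWMParams",
    "encode_item",
    "push_and_decay",
    "retrieve_step",
    "entropy",
    "bwm_decide",
]

_EPS_DIV = 1e-8  # floor for the r=0 denominator in the Q ratio


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log(0) := 0."""
    p = np.asarray(p, dtype=float)
    if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("entropy expects a probability mass function")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass
class MemoryItem:
    """One stored trial: pmfs over stimuli, actions|stimulus, reward|(s,a)."""

    p_s: np.ndarray  # (n_stimuli,)
    p_a: np.ndarray  # (n_stimuli, n_actions)
    p_r: np.ndarray  # (n_stimuli, n_actions) -- probability that r = 1

    def validate(self) -> None:
        if abs(self.p_s.sum() - 1.0) > 1e-9:
            raise ValueError("p(s) does not sum to 1")
        if np.any(np.abs(self.p_a.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("p(a|s) rows do not sum to 1")
        for arr in (self.p_s, self.p_a, self.p_r):
            if arr.min() < -1e-12 or arr.max() > 1.0 + 1e-12:
                raise ValueError("pmf entries outside [0,1]")

    def copy(self) -> "MemoryItem":
        return MemoryItem(self.p_s.copy(), self.p_a.copy(), self.p_r.copy())


def encode_item(
    s: int, a: int, r: int, n_stimuli: int = 3, n_actions: int = 5
) -> MemoryItem:
    """Encode a trial as a fresh, deterministic memory item.

    The observed stimulus gets mass 1, the performed action mass 1 in that
    stimulus's row, and the outcome probability is the observed r.  Rows for
    contexts not observed this trial are uninformative (uniform over actions,
    0.5 for the outcome) -- these entries only matter once decay leaks mass
    onto unobserved stimuli.
    """
    p_s = np.zeros(n_stimuli)
    p_s[s] = 1.0
    p_a = np.full((n_stimuli, n_actions), 1.0 / n_actions)
    p_a[s] = 0.0
    p_a[s, a] = 1.0
    p_r = np.full((n_stimuli, n_actions), 0.5)
    p_r[s, a] = 1.0 if r > 0 else 0.0
    return MemoryItem(p_s, p_a, p_r)


@dataclass
class BWMParams:
    """Capacity N, decay epsilon, and entropy threshold theta."""

    N: int = 5
    epsilon: float = 0.01
    theta: float = 1.0
    n_stimuli: int = 3
    n_actions: int = 5

    def __post_init__(self) -> None:
        if not 1 < self.N < 10:
            raise ValueError(f"N must satisfy 1 < N < 10, got {self.N}")
        if not 0 <= self.epsilon < 0.1:
            raise ValueError(f"epsilon must be in [0, 0.1), got {self.epsilon}")
        h_max = np.log2(self.n_actions)
        if not 0 < self.theta <= h_max + 1e-12:
            raise ValueError(f"theta must be in (0, log2|A|], got {self.theta}")

    @property
    def h_max(self) -> float:
        return float(np.log2(self.n_actions))


@dataclass
class MemoryStore:
    """Bounded FIFO of memory items, most recent first."""

    params: BWMParams
    items: list[MemoryItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def reset(self) -> None:
        self.items.clear()

    def to_json(self) -> str:
        """Debug/teaching serialization; not a stable interchange format."""
        payload = [
            {
                "p_s": it.p_s.tolist(),
                "p_a": it.p_a.tolist(),
                "p_r": it.p_r.tolist(),
            }
            for it in self.items
        ]
        return json.dumps(payload)


def push_and_decay(store: MemoryStore, item: MemoryItem) -> None:
    """Prepend ``item``, evict beyond capacity, then decay the older items.

    Decay blends every pmf toward uniform (outcome entries toward 0.5) with
    rate epsilon; the freshly pushed item is not decayed on its own trial.
    """
    eps = store.params.epsilon
    n_a = store.params.n_actions
    n_s = store.params.n_stimuli
    for old in store.items:
        old.p_s = (1 - eps) * old.p_s + eps / n_s
        old.p_a = (1 - eps) * old.p_a + eps / n_a
        old.p_r = (1 - eps) * old.p_r + eps * 0.5
    store.items.insert(0, item)
    del store.items[store.params.N :]


@dataclass
class RetrievalTrace:
    """State of the within-trial iterative retrieval."""

    joint: np.ndarray  # (n_actions, 2) accumulated mass at the presented s
    p_bwm: np.ndarray  # normalized action probabilities
    q_bwm: np.ndarray  # ratio values p(a|r=1)/p(a|r=0)
    i: int
    H: float
    h_max: float


def _start_trace(n_stimuli: int, n_actions: int) -> RetrievalTrace:
    # Uniform joint initialization: mass 1/(|S||A||R|) per cell, so i=0
    # yields the uniform policy and H = log2|A|.
    joint = np.full((n_actions, 2), 1.0 / (n_stimuli * n_actions * 2))
    p = np.full(n_actions, 1.0 / n_actions)
    return RetrievalTrace(
        joint=joint,
        p_bwm=p,
        q_bwm=np.ones(n_actions),
        i=0,
        H=float(np.log2(n_actions)),
        h_max=float(np.log2(n_actions)),
    )


def _finish_trace(trace: RetrievalTrace) -> None:
    j = trace.joint
    p_a_r1 = j[:, 1] / j[:, 1].sum()
    p_a_r0 = j[:, 0] / j[:, 0].sum()
    q = p_a_r1 / np.maximum(p_a_r0, _EPS_DIV)
    trace.q_bwm = q
    trace.p_bwm = q / q.sum()
    trace.H = entropy(trace.p_bwm)


def retrieve_step(trace: RetrievalTrace, store: MemoryStore, s_t: int) -> RetrievalTrace:
    """Fold the next most-recent unprocessed item into the trace (in place).

    The item's contribution to the joint at the presented stimulus is
    p(s_t|t_i) * p(a|s_t,t_i) * p(r|a,s_t,t_i); successive items are summed
    (independence hypothesis), then the slice is renormalized per outcome and
    converted to the ratio values and their entropy.
    """
    if trace.i >= len(store):
        raise RuntimeError("retrieval past the end of the memory store")
    item = store.items[trace.i]
    w_s = item.p_s[s_t]
    p_a = item.p_a[s_t]
    p_r1 = item.p_r[s_t]
    trace.joint[:, 1] += w_s * p_a * p_r1
    trace.joint[:, 0] += w_s * p_a * (1.0 - p_r1)
    trace.i += 1
    _finish_trace(trace)
    return trace


def bwm_decide(
    store: MemoryStore, s_t: int, theta: float | None = None
) -> RetrievalTrace:
    """Retrieve items most-recent-first until H <= theta or none remain.

    With an empty store no items are processed and the policy is uniform.
    Equality counts as reaching the threshold, so a theta at the maximal
    entropy stops retrieval immediately.
    """
    params = store.params
    if theta is None:
        theta = params.theta
    trace = _start_trace(params.n_stimuli, params.n_actions)
    while trace.H > theta and trace.i < len(store):
        retrieve_step(trace, store, s_t)
    return trace
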