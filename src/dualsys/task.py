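"""Arbitrary visuomotor learning task.

Subjects (or agents) learn by trial and error which of five finger movements
is the correct response to each of three colored circles.  The correct
stimulus-response associations are not set a priori: the first presentation of
a stimulus is always followed by an incorrect outcome, and the correct
response is assigned dynamically once the learner has produced the required
number of *distinct* incorrect movements (1 for S1, 3 for S3, 4 for S4 -- the
stimulus label encodes the requirement).  This guarantees a fixed minimum
number of errors per stimulus and highly reproducible acquisition curves.

Each block is an independent learning episode: tried-response sets and the
assigned correct responses are cleared at block boundaries (working memory and
agent value states are reset there too, see :func:`run_session`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TaskState",
    "TrialRecord",
    "BehaviorLog",
    "new_session",
    "evaluate_response",
    "run_session",
    "STIMULUS_LABELS",
]

#: Human-readable labels for the default three stimuli (the digit is the
#: number of required errors).
STIMULUS_LABELS = ("S1", "S3", "S4")


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the task."""

    n_stimuli: int = 3
    n_actions: int = 5
    trials_per_block: int = 42
    n_blocks: int = 4
    #: stimulus index -> number of distinct incorrect responses required
    #: before the correct response may be assigned.
    error_requirements: tuple[int, ...] = (1, 3, 4)

    def __post_init__(self) -> None:
        if self.n_stimuli <= 0 or self.n_actions <= 0:
            raise ValueError("stimulus and action counts must be positive")
        if self.trials_per_block <= 0 or self.n_blocks <= 0:
            raise ValueError("trial and block counts must be positive")
        if self.trials_per_block % self.n_stimuli != 0:
            raise ValueError(
                "trials_per_block must be divisible by n_stimuli "
                f"({self.trials_per_block} % {self.n_stimuli} != 0)"
            )
        if len(self.error_requirements) != self.n_stimuli:
            raise ValueError("one error requirement per stimulus is required")
        for req in self.error_requirements:
            if not 0 <= req <= self.n_actions - 1:
                raise ValueError(
                    f"error requirement {req} outside [0, {self.n_actions - 1}]"
                )

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def stimulus_label(self, s: int) -> str:
        if self.n_stimuli == len(STIMULUS_LABELS):
            return STIMULUS_LABELS[s]
        return f"S{s}"


@dataclass
class TaskState:
    """Mutable per-block task state plus the full-session stimulus sequence."""

    config: TaskConfig
    sequence: np.ndarray  # shape (n_blocks * trials_per_block,)
    tried: list[set[int]] = field(default_factory=list)
    correct: list[int | None] = field(default_factory=list)
    presentations: list[int] = field(default_factory=list)
    cursor: int = 0

    def __post_init__(self) -> None:
        if not self.tried:
            self.reset_block()

    def reset_block(self) -> None:
        """Start a fresh learning episode (called at each block boundary)."""
        n = self.config.n_stimuli
        self.tried = [set() for _ in range(n)]
        self.correct = [None] * n
        self.presentations = [0] * n

    def next_stimulus(self) -> int:
        s = int(self.sequence[self.cursor])
        self.cursor += 1
        return s


def new_session(config: TaskConfig, seed: int) -> TaskState:
    """Create a session state with a balanced, shuffled stimulus sequence.

    Within every block each stimulus appears exactly
    ``trials_per_block / n_stimuli`` times; the order inside a block is
    shuffled by a generator seeded with ``seed`` (same seed, same sequence).
    """
    rng = np.random.default_rng(seed)
    per_stim = config.trials_per_block // config.n_stimuli
    blocks = []
    for _ in range(config.n_blocks):
        block = np.repeat(np.arange(config.n_stimuli), per_stim)
        rng.shuffle(block)
        blocks.append(block)
    return TaskState(config=config, sequence=np.concatenate(blocks))


def evaluate_response(state: TaskState, stimulus: int, action: int) -> int:
    """Deliver the outcome for ``action`` to the currently presented stimulus.

    Rules: the first presentation is always incorrect; afterwards, any action
    is incorrect until the required number of *distinct* incorrect responses
    has been produced, at which point the next untried action is assigned as
    the (permanent, within-block) correct response.  Repeating a previously
    tried incorrect action never advances the requirement.
    """
    cfg = state.config
    if not 0 <= action < cfg.n_actions:
        raise ValueError(f"action {action} out of range [0, {cfg.n_actions})")
    if not 0 <= stimulus < cfg.n_stimuli:
        raise ValueError(f"stimulus {stimulus} out of range")

    state.presentations[stimulus] += 1
    assigned = state.correct[stimulus]
    if assigned is not None:
        return int(action == assigned)

    tried = state.tried[stimulus]
    if state.presentations[stimulus] == 1:
        tried.add(action)
        return 0
    if len(tried) >= cfg.error_requirements[stimulus] and action not in tried:
        state.correct[stimulus] = action
        return 1
    tried.add(action)  # no-op if already tried
    return 0


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one session, with model diagnostics when available."""

    block: int
    trial: int  # index within block
    stimulus: int
    action: int
    outcome: int
    rt: float | None = None  # seconds (subjects) or arbitrary units (models)
    i_processed: int | None = None  # memory items processed
    entropy: float | None = None  # final policy entropy, bits
    system: str | None = None  # deciding-system tag

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome}")
        if self.i_processed is not None and self.i_processed < 0:
            raise ValueError("i_processed must be >= 0")


@dataclass
class BehaviorLog:
    """Ordered trial records for one session of one subject or agent."""

    subject: str
    config: TaskConfig
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def validate(self) -> None:
        expected = [
            (b, t)
            for b in range(self.config.n_blocks)
            for t in range(self.config.trials_per_block)
        ]
        got = [(rec.block, rec.trial) for rec in self.trials]
        if got != expected:
            raise ValueError("trials are not strictly ordered by (block, trial)")
        per_stim = self.config.trials_per_block // self.config.n_stimuli
        for b in range(self.config.n_blocks):
            counts = np.bincount(
                [r.stimulus for r in self.trials if r.block == b],
                minlength=self.config.n_stimuli,
            )
            if not np.all(counts == per_stim):
                raise ValueError(f"unbalanced stimulus counts in block {b}")

    def block(self, b: int) -> list[TrialRecord]:
        return [r for r in self.trials if r.block == b]

    def subset_blocks(self, blocks) -> "BehaviorLog":
        """A new log restricted to ``blocks`` (re-indexed consecutively)."""
        keep = sorted(set(blocks))
        cfg = replace(self.config, n_blocks=len(keep))
        trials = []
        for new_b, b in enumerate(keep):
            for r in self.block(b):
                trials.append(replace(r, block=new_b))
        return BehaviorLog(subject=self.subject, config=cfg, trials=trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [self.subject] * len(self.trials),
                "block": [r.block for r in self.trials],
                "trial": [r.trial for r in self.trials],
                "stimulus": [r.stimulus for r in self.trials],
                "action": [r.action for r in self.trials],
                "outcome": [r.outcome for r in self.trials],
                "rt": [r.rt for r in self.trials],
                "i_processed": [r.i_processed for r in self.trials],
                "entropy": [r.entropy for r in self.trials],
                "system": [r.system for r in self.trials],
            }
        )

    def arrays(self):
        """(stimulus, action, outcome, block) as int arrays, trial-ordered."""
        s = np.array([r.stimulus for r in self.trials], dtype=np.int64)
        a = np.array([r.action for r in self.trials], dtype=np.int64)
        r_ = np.array([r.outcome for r in self.trials], dtype=np.int64)
        b = np.array([r.block for r in self.trials], dtype=np.int64)
        return s, a, r_, b

    def rts(self) -> np.ndarray:
        return np.array(
            [np.nan if r.rt is None else r.rt for r in self.trials], dtype=float
        )


def run_session(
    agent,
    config: TaskConfig,
    seed: int,
    subject: str = "agent",
    reset_values: bool = True,
) -> BehaviorLog:
    """Drive ``agent`` closed-loop through a full session.

    ``agent`` must expose ``act(stimulus) -> (action, diagnostics)`` and
    ``learn(stimulus, action, outcome)``; ``diagnostics`` is a mapping that may
    carry ``rt``, ``i``, ``entropy`` and ``system`` entries.  Working memory is
    cleared at every block start; with ``reset_values`` (default) cached value
    states are cleared too, otherwise they persist across blocks.
    """
    state = new_session(config, seed)
    log = BehaviorLog(subject=subject, config=config)
    for b in range(config.n_blocks):
        state.reset_block()
        if reset_values:
            agent.reset()
        else:
            agent.reset_memory()
        for t in range(config.trials_per_block):
            s = state.next_stimulus()
            action, diag = agent.act(s)
            if not 0 <= int(action) < config.n_actions:
                raise RuntimeError(f"agent returned invalid action {action}")
            r = evaluate_response(state, s, int(action))
            agent.learn(s, int(action), r)
            log.trials.append(
                TrialRecord(
                    block=b,
                    trial=t,
                    stimulus=s,
                    action=int(action),
                    outcome=r,
                    rt=diag.get("rt"),
                    i_processed=diag.get("i"),
                    entropy=diag.get("entropy"),
                    system=diag.get("system"),
                )
            )
    return log


class NonRepeatingAgent:
    """Scripted probe agent with perfect memory of its own errors.

    Tries a new untried finger for each stimulus until rewarded, then always
    repeats the rewarded finger.  Against the task rules it realizes the
    minimum error counts (1/3/4) exactly.
    """

    def __init__(self, n_stimuli: int = 3, n_actions: int = 5, seed: int = 0):
        self.n_stimuli = n_stimuli
        self.n_actions = n_actions
        self.rng = np.random.default_rng(seed)
        self.reset()

    def reset(self) -> None:
        self.tried = [set() for _ in range(self.n_stimuli)]
        self.known = [None] * self.n_stimuli

    reset_memory = reset

    def act(self, s):
        if self.known[s] is not None:
            return self.known[s], {}
        untried = [a for a in range(self.n_actions) if a not in self.tried[s]]
        return int(self.rng.choice(untried)), {}

    def learn(self, s, a, r) -> None:
        if r:
            self.known[s] = a
        else:
            self.tried[s].add(a)


class UniformRandomAgent:
    """Baseline agent sampling actions uniformly at random."""

    def __init__(self, n_actions: int = 5, seed: int = 0):
        self.n_actions = n_actions
        self.rng = np.random.default_rng(seed)

    def reset(self) -> None:
        pass

    reset_memory = reset

    def act(self, s):
        return int(self.rng.integers(self.n_actions)), {}

    def learn(self, s, a, r) -> None:
        pass
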