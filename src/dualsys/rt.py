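"""Simulated reaction times, RT standardization, representative-step
reordering and probability-of-correct-response (PCR) curves.

The simulated reaction time of a model trial combines the cost of memory
search with the residual uncertainty of the final policy:

    sRT = (log2(i + 1))^sigma + H

where ``i`` is the number of memory items processed and ``H`` the Shannon
entropy (bits) of the final action distribution.  A pure habitual decision
has i = 0, so its sRT reduces to the entropy term and can only shrink as
values converge; memory-driven decisions grow with search depth, which is
what produces the rise-then-fall group RT curve across learning.

Because model sRTs are in arbitrary units and subject RTs in seconds, both
are standardized per individual by median and interquartile range before any
comparison.  Trials are then reordered onto 15 *representative steps*: for
each stimulus, the first presentations (up to its required-error count plus
one) form acquisition steps 1-5, and post-first-correct presentations form
consolidation steps 6-15, so stimuli with different acquisition lengths can
be averaged together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import BehaviorLog

__all__ = [
    "simulated_rt",
    "standardize",
    "representative_steps",
    "step_assignments",
    "RepresentativeStepSeries",
    "pcr_curves",
    "N_STEPS",
    "N_ACQUISITION",
]

N_STEPS = 15
N_ACQUISITION = 5  # steps 1-5 are the acquisition phase


def simulated_rt(i, H, sigma: float):
    """sRT = (log2(i+1))^sigma + H; vectorized over i and H."""
    i = np.asarray(i, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(i < 0) or np.any(H < -1e-12):
        raise ValueError("need i >= 0 and H >= 0")
    out = np.power(np.log2(i + 1.0), sigma, where=i > 0, out=np.zeros_like(i)) + H
    return out if out.ndim else float(out)


def standardize(values) -> np.ndarray:
    """(x - median) / IQR elementwise; NaNs are ignored and passed through."""
    x = np.asarray(values, dtype=float)
    med = np.nanmedian(x)
    q75, q25 = np.nanpercentile(x, [75, 25])
    iqr = q75 - q25
    if not np.isfinite(iqr) or iqr == 0:
        raise ValueError("degenerate RT distribution (zero interquartile range)")
    return (x - med) / iqr


@dataclass
class RepresentativeStepSeries:
    """Mean standardized RT per representative step, with counts and spread."""

    mean: np.ndarray  # (15,), NaN where no trial contributed
    count: np.ndarray  # (15,) int
    sd: np.ndarray  # (15,), NaN where count < 2

    def to_frame(self) -> pd.DataFrame:
        se = self.sd / np.sqrt(np.maximum(self.count, 1))
        return pd.DataFrame(
            {
                "step": np.arange(1, N_STEPS + 1),
                "mean": self.mean,
                "se": se,
                "n": self.count,
            }
        )


def step_assignments(log: BehaviorLog, offset: int = 1) -> np.ndarray:
    """Representative step (1..15) of every trial, or 0 when unmapped.

    Per stimulus and block, presentation p maps to acquisition step p while
    p <= required_errors + 1.  Consolidation steps start after the first
    correct outcome (presentation c): presentation c + offset + j maps to
    step 5 + j (default offset 1, i.e., step 6 is the *second* post-correct
    presentation).  Everything else -- extra errors beyond the requirement,
    skipped early post-correct presentations, steps past 15 -- is unmapped.
    """
    if not 0 <= offset <= 2:
        raise ValueError("offset must be in 0..2")
    cfg = log.config
    steps = np.zeros(len(log), dtype=int)
    for b in range(cfg.n_blocks):
        pres = np.zeros(cfg.n_stimuli, dtype=int)
        first_correct = np.zeros(cfg.n_stimuli, dtype=int)  # 0 = not yet
        for t, rec in enumerate(log.trials):
            if rec.block != b:
                continue
            s = rec.stimulus
            pres[s] += 1
            p = pres[s]
            req = cfg.error_requirements[s]
            if p <= req + 1:
                steps[t] = p
            elif first_correct[s] and p >= first_correct[s] + offset + 1:
                step = N_ACQUISITION + (p - first_correct[s] - offset)
                if step <= N_STEPS:
                    steps[t] = step
            if rec.outcome == 1 and not first_correct[s]:
                first_correct[s] = p
    return steps


def representative_steps(
    log: BehaviorLog,
    rts: np.ndarray | None = None,
    offset: int = 1,
    standardized: bool = True,
) -> RepresentativeStepSeries:
    """Average (standardized) RTs over representative steps.

    ``rts`` defaults to the log's recorded RTs.  Standardization uses this
    individual's whole RT distribution; missing steps are reported as NaN
    with count 0, never imputed.
    """
    x = log.rts() if rts is None else np.asarray(rts, dtype=float)
    if standardized:
        x = standardize(x)
    steps = step_assignments(log, offset=offset)
    mean = np.full(N_STEPS, np.nan)
    count = np.zeros(N_STEPS, dtype=int)
    sd = np.full(N_STEPS, np.nan)
    for k in range(1, N_STEPS + 1):
        vals = x[(steps == k) & np.isfinite(x)]
        count[k - 1] = vals.size
        if vals.size:
            mean[k - 1] = vals.mean()
        if vals.size >= 2:
            sd[k - 1] = vals.std(ddof=1)
    return RepresentativeStepSeries(mean=mean, count=count, sd=sd)


def pcr_curves(logs) -> pd.DataFrame:
    """Probability of correct response by stimulus and presentation index.

    The k-th presentation of a stimulus within a block is one observation;
    the PCR is the fraction of observations (pooled over blocks and logs)
    that were correct.  Returns columns stimulus, presentation, pcr, se, n.
    """
    logs = list(logs)
    if not logs:
        raise ValueError("at least one log is required")
    cfg = logs[0].config
    per_stim = cfg.trials_per_block // cfg.n_stimuli
    hits = np.zeros((cfg.n_stimuli, per_stim))
    n = np.zeros((cfg.n_stimuli, per_stim))
    for log in logs:
        for b in range(cfg.n_blocks):
            pres = np.zeros(cfg.n_stimuli, dtype=int)
            for rec in log.block(b):
                k = pres[rec.stimulus]
                hits[rec.stimulus, k] += rec.outcome
                n[rec.stimulus, k] += 1
                pres[rec.stimulus] += 1
    pcr = np.divide(hits, n, where=n > 0, out=np.full_like(hits, np.nan))
    se = np.sqrt(np.clip(pcr * (1 - pcr), 0, None) / np.maximum(n, 1))
    rows = []
    for s in range(cfg.n_stimuli):
        for k in range(per_stim):
            rows.append(
                {
                    "stimulus": s,
                    "presentation": k + 1,
                    "pcr": pcr[s, k],
                    "se": se[s, k],
                    "n": int(n[s, k]),
                }
            )
    return pd.DataFrame(rows)
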