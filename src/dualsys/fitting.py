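"""Multi-objective model fitting and model selection.

A candidate parameterization of a model family is scored under *teacher
forcing*: the model's policy is evaluated at every trial of the recorded
session, the probability it assigns to the recorded action enters the choice
likelihood, and the model is then updated with the recorded (stimulus,
action, outcome).  Two behavioral objectives are maximized jointly --

* fit to choices: the log of  L = prod_t p(a_t^subject | s_t)
* fit to RT:      E_RT = - sum_steps (RT_step - sRT_step)^2  over
  representative-step means of standardized reaction times

-- plus a diversity objective (mean distance to the k nearest neighbours in
normalized parameter space) that keeps the evolutionary search spread out.
Optimization uses NSGA-II (non-dominated sorting, crowding distance, binary
tournament, SBX crossover, polynomial mutation) implemented here.

After fitting, each model contributes its non-dominated set projected onto
the two behavioral objectives; fronts are merged across models per subject
and a single preferred solution is picked by a scalarizing aggregation
function (augmented Chebyshev distance to the ideal point by default; ordered
weighted average and plain distance-to-reference are also provided).  BIC
re-ranking and leave-one-out block validation round out the selection tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels
from .agents import DUAL_SYSTEM_IDS, MODEL_IDS
from .rt import N_STEPS, representative_steps, simulated_rt, standardize, step_assignments
from .task import BehaviorLog

__all__ = [
    "ParamSpec",
    "MODEL_SPECS",
    "free_parameter_count",
    "FitContext",
    "choice_likelihood",
    "rt_fitness",
    "diversity",
    "pareto_front",
    "ParetoSolution",
    "AggregationConfig",
    "aggregate",
    "bic",
    "nsga2_fit",
    "merge_fronts",
    "leave_one_out",
]

_LIK_FLOOR = 1e-12
_H_MAX5 = math.log2(5)


# ---------------------------------------------------------------------------
# parameter spaces


@dataclass(frozen=True)
class ParamSpec:
    """One free parameter: bounds, optional log-scale gene, integrality."""

    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def decode(self, gene: float) -> float:
        g = min(max(gene, 0.0), 1.0)
        if self.log:
            value = 10 ** (math.log10(self.low) + g * (math.log10(self.high) - math.log10(self.low)))
        else:
            value = self.low + g * (self.high - self.low)
        if self.integer:
            value = int(round(value))
        return value

    def encode(self, value: float) -> float:
        if self.log:
            g = (math.log10(value) - math.log10(self.low)) / (
                math.log10(self.high) - math.log10(self.low)
            )
        else:
            g = (value - self.low) / (self.high - self.low)
        return min(max(g, 0.0), 1.0)


_ALPHA = ParamSpec("alpha", 1e-3, 1 - 1e-3)
_BETA = ParamSpec("beta", 0.01, 99.9)
_N = ParamSpec("N", 2, 9, integer=True)
_THETA = ParamSpec("theta", 0.01, _H_MAX5 - 0.01)
_EPSILON = ParamSpec("epsilon", 1e-4, 0.0999)
_SIGMA = ParamSpec("sigma", 0.01, 19.99)

#: Free-parameter sets per model family (Table-1 ranges; the dual systems
#: inherit their subsystems' parameters, entropy coordination ties the final
#: softmax temperature to the habitual one so it counts seven parameters).
MODEL_SPECS: dict[str, tuple[ParamSpec, ...]] = {
    "qlearning": (_ALPHA, _BETA),
    "bwm": (_N, _THETA, _EPSILON, _SIGMA),
    "entropy_coordination": (
        _ALPHA,
        _BETA,
        _N,
        _EPSILON,
        ParamSpec("lambda1", 1e-5, 1e3, log=True),
        ParamSpec("lambda2", 1e-5, 1e3, log=True),
        _SIGMA,
    ),
    "weight_mixture": (
        _ALPHA,
        _BETA,
        _N,
        _THETA,
        _EPSILON,
        ParamSpec("w0", 1e-3, 1 - 1e-3),
        _SIGMA,
    ),
    "vpi_selection": (
        _BETA,
        _N,
        _THETA,
        _EPSILON,
        ParamSpec("eta", 1e-5, 1e-3, log=True),
        ParamSpec("sigma_r", 1e-3, 1 - 1e-3),
        _SIGMA,
    ),
}

#: Families whose policy is itself stochastic (likelihood averaged over replays).
STOCHASTIC_MODELS = frozenset({"entropy_coordination"})


def free_parameter_count(model_id: str) -> int:
    return len(MODEL_SPECS[model_id])


def decode_params(model_id: str, genes: np.ndarray) -> dict[str, float]:
    return {
        spec.name: spec.decode(g) for spec, g in zip(MODEL_SPECS[model_id], genes)
    }


def encode_params(model_id: str, params: dict[str, float]) -> np.ndarray:
    return np.array(
        [spec.encode(params[spec.name]) for spec in MODEL_SPECS[model_id]]
    )


def validate_params(model_id: str, params: dict[str, float]) -> None:
    for spec in MODEL_SPECS[model_id]:
        if spec.name not in params:
            raise ValueError(f"{model_id}: missing parameter {spec.name!r}")
        v = params[spec.name]
        if not spec.low <= v <= spec.high:
            raise ValueError(
                f"{model_id}: {spec.name}={v} outside [{spec.low}, {spec.high}]"
            )


# ---------------------------------------------------------------------------
# teacher-forced evaluation


def _replay(model_id, params, s, a, r, b, n_s, n_a, seed):
    p = params
    if model_id == "qlearning":
        return kernels.replay_qlearning(p["alpha"], p["beta"], s, a, r, b, n_s, n_a)
    if model_id == "bwm":
        return kernels.replay_bwm(int(p["N"]), p["theta"], p["epsilon"], s, a, r, b, n_s, n_a)
    if model_id == "entropy_coordination":
        beta_final = p.get("beta_final", p["beta"])
        return kernels.replay_entropy_coordination(
            p["alpha"], p["beta"], beta_final, int(p["N"]), p["epsilon"],
            p["lambda1"], p["lambda2"], s, a, r, b, n_s, n_a, seed,
        )
    if model_id == "weight_mixture":
        return kernels.replay_weight_mixture(
            p["alpha"], p["beta"], int(p["N"]), p["theta"], p["epsilon"], p["w0"],
            s, a, r, b, n_s, n_a,
        )
    if model_id == "vpi_selection":
        return kernels.replay_vpi_selection(
            p["beta"], int(p["N"]), p["theta"], p["epsilon"], p["eta"], p["sigma_r"],
            s, a, r, b, n_s, n_a,
        )
    raise ValueError(f"unknown model id {model_id!r}")


@dataclass
class FitContext:
    """Precomputed per-log quantities shared by all candidate evaluations."""

    s: np.ndarray
    a: np.ndarray
    r: np.ndarray
    b: np.ndarray
    n_stimuli: int
    n_actions: int
    steps: np.ndarray  # representative step of each trial (0 = unmapped)
    subject_steps: np.ndarray | None  # (15,) standardized subject RT step means

    @classmethod
    def from_log(cls, log: BehaviorLog, offset: int = 1) -> "FitContext":
        s, a, r, b = log.arrays()
        steps = step_assignments(log, offset=offset)
        subject_steps = None
        rts = log.rts()
        if np.isfinite(rts).sum() >= 2:
            subject_steps = representative_steps(log, offset=offset).mean
        return cls(
            s=s, a=a, r=r, b=b,
            n_stimuli=log.config.n_stimuli,
            n_actions=log.config.n_actions,
            steps=steps,
            subject_steps=subject_steps,
        )

    def step_means(self, values: np.ndarray) -> np.ndarray:
        out = np.full(N_STEPS, np.nan)
        for k in range(1, N_STEPS + 1):
            mask = self.steps == k
            if mask.any():
                out[k - 1] = values[mask].mean()
        return out


def _standardize_or_zero(x: np.ndarray) -> np.ndarray:
    # degenerate candidates (constant sRT) get a flat standardized series
    # instead of an error so the optimizer can simply score them poorly
    q75, q25 = np.percentile(x, [75, 25])
    if q75 - q25 == 0:
        return np.zeros_like(x)
    return (x - np.median(x)) / (q75 - q25)


def evaluate_candidate(
    ctx: FitContext,
    model_id: str,
    params: dict[str, float],
    n_rep: int = 3,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """(log-likelihood, E_RT, per-trial choice probabilities) for a candidate.

    Stochastic-policy models average per-trial probabilities and sRTs over
    ``n_rep`` seeded replays; deterministic models use a single replay.
    """
    reps = n_rep if model_id in STOCHASTIC_MODELS else 1
    sigma = params.get("sigma", 1.0)
    probs = np.zeros(len(ctx.s))
    srt = np.zeros(len(ctx.s))
    for rep in range(reps):
        p, i, h = _replay(
            model_id, params, ctx.s, ctx.a, ctx.r, ctx.b,
            ctx.n_stimuli, ctx.n_actions, seed + rep,
        )
        probs += p
        srt += simulated_rt(i, np.maximum(h, 0.0), sigma)
    probs /= reps
    srt /= reps
    loglik = float(np.log(np.maximum(probs, _LIK_FLOOR)).sum())
    e_rt = np.nan
    if ctx.subject_steps is not None:
        model_steps = ctx.step_means(_standardize_or_zero(srt))
        e_rt = rt_fitness(model_steps, ctx.subject_steps)
    return loglik, e_rt, probs


def choice_likelihood(
    model_id: str,
    params: dict[str, float],
    log: BehaviorLog,
    n_rep: int = 3,
    seed: int = 0,
) -> dict:
    """Teacher-forced choice likelihood L = prod_t p(a_t | s_t).

    Returns the likelihood, its log, and the per-trial probabilities.
    Zero-probability trials are floored at 1e-12 (with a warning) so the log
    stays finite.
    """
    ctx = FitContext.from_log(log)
    loglik, _, probs = evaluate_candidate(ctx, model_id, params, n_rep, seed)
    if np.any(probs < _LIK_FLOOR):
        warnings.warn("per-trial probability floored at 1e-12", RuntimeWarning)
    with np.errstate(under="ignore"):
        lik = float(np.exp(loglik))
    return {"likelihood": lik, "log_likelihood": loglik, "per_trial": probs}


def rt_fitness(model_steps: np.ndarray, subject_steps: np.ndarray) -> float:
    """E_RT = -sum over shared steps of squared step-mean differences."""
    m = np.asarray(model_steps, dtype=float)
    s = np.asarray(subject_steps, dtype=float)
    mask = np.isfinite(m) & np.isfinite(s)
    if not mask.any():
        raise ValueError("no overlapping representative steps")
    return float(-np.sum((s[mask] - m[mask]) ** 2))


# ---------------------------------------------------------------------------
# diversity and Pareto machinery


def diversity(population: np.ndarray, k: int = 5) -> np.ndarray:
    """Mean Euclidean distance to the k nearest neighbours, per individual.

    ``population`` is (n, d) in normalized [0,1] parameter space.  A
    population of one scores 0.
    """
    pop = np.asarray(population, dtype=float)
    n = len(pop)
    if n < 2:
        return np.zeros(n)
    d2 = ((pop[:, None, :] - pop[None, :, :]) ** 2).sum(-1)
    dist = np.sqrt(d2)
    np.fill_diagonal(dist, np.inf)
    kk = min(k, n - 1)
    part = np.partition(dist, kk - 1, axis=1)[:, :kk]
    return part.mean(axis=1)


def _dominance_matrix(F: np.ndarray) -> np.ndarray:
    """dom[i, j] True iff solution i dominates j (all objectives maximized)."""
    ge = (F[:, None, :] >= F[None, :, :]).all(-1)
    gt = (F[:, None, :] > F[None, :, :]).any(-1)
    return ge & gt


def pareto_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of the maximal non-dominated subset of fitness rows."""
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or len(F) == 0:
        raise ValueError("need a non-empty (n, m) fitness array")
    return ~_dominance_matrix(F).any(axis=0)


@dataclass
class ParetoSolution:
    """One non-dominated (model, parameters, fitness) triple."""

    model_id: str
    params: dict[str, float]
    fit_choice: float  # log-likelihood
    fit_rt: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def fitness(self) -> tuple[float, ...]:
        if self.fit_rt is None or not np.isfinite(self.fit_rt):
            return (self.fit_choice,)
        return (self.fit_choice, self.fit_rt)

    @property
    def likelihood(self) -> float:
        with np.errstate(under="ignore"):
            return float(np.exp(self.fit_choice))


def pareto_front(solutions: list[ParetoSolution]) -> list[ParetoSolution]:
    """Maximal non-dominated subset under (fit_choice, fit_rt) maximization."""
    if not solutions:
        raise ValueError("need at least one solution")
    m = len(solutions[0].fitness)
    F = np.array([sol.fitness[:m] for sol in solutions])
    mask = pareto_mask(F)
    return [sol for sol, keep in zip(solutions, mask) if keep]


def merge_fronts(fronts: dict[str, list[ParetoSolution]]) -> list[ParetoSolution]:
    """Mix the per-model fronts and re-filter dominance across models."""
    pooled = [sol for sols in fronts.values() for sol in sols]
    return pareto_front(pooled)


# ---------------------------------------------------------------------------
# aggregation (scalarization) and BIC


@dataclass
class AggregationConfig:
    method: str = "chebyshev"  # chebyshev | owa | distance
    weights: tuple[float, ...] = (0.5, 0.5)
    eps: float = 0.001  # augmentation term of the Chebyshev function
    owa_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("chebyshev", "owa", "distance"):
            raise ValueError(f"unknown aggregation method {self.method!r}")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be a simplex vector")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def _normalize_front(F: np.ndarray) -> np.ndarray:
    ideal = F.max(axis=0)
    nadir = F.min(axis=0)
    span = ideal - nadir
    x = np.ones_like(F)
    ok = span > 0
    x[:, ok] = (F[:, ok] - nadir[ok]) / span[ok]
    return x


def aggregate(
    front: list[ParetoSolution], cfg: AggregationConfig | None = None
) -> ParetoSolution:
    """Pick the preferred solution from a (merged) front.

    Objectives are first normalized to [0,1] using the front's own best
    (ideal) and worst (nadir) values.  Ties are broken by better fit to
    choice, then by model id order.
    """
    if not front:
        raise ValueError("front is empty")
    cfg = cfg or AggregationConfig()
    m = min(len(sol.fitness) for sol in front)
    F = np.array([sol.fitness[:m] for sol in front])
    ideal, nadir = F.max(axis=0), F.min(axis=0)
    if np.all(ideal == nadir):
        warnings.warn("degenerate front: all fitness vectors equal", RuntimeWarning)
        return front[0]
    x = _normalize_front(F)
    lam = np.asarray(cfg.weights[:m], dtype=float)
    lam = lam / lam.sum()
    if cfg.method == "chebyshev":
        regret = lam * (1.0 - x)  # lambda_i * (alpha_i - x_i)/(alpha_i - beta_i)
        score = regret.max(axis=1) + cfg.eps * regret.sum(axis=1)
        best = score.min()
        tied = np.flatnonzero(score <= best + 1e-12)
    elif cfg.method == "owa":
        w = np.asarray(
            cfg.owa_weights if cfg.owa_weights is not None else lam, dtype=float
        )
        score = (np.sort(x, axis=1) * w[:m]).sum(axis=1)
        best = score.max()
        tied = np.flatnonzero(score >= best - 1e-12)
    else:  # distance to the reference point 1
        score = np.sqrt(((1.0 - x) ** 2).sum(axis=1))
        best = score.min()
        tied = np.flatnonzero(score <= best + 1e-12)
    if len(tied) > 1:
        order = sorted(
            tied,
            key=lambda j: (-front[j].fit_choice, MODEL_IDS.index(front[j].model_id)),
        )
        return front[order[0]]
    return front[int(tied[0])]


def bic(log_likelihood: float, k_params: int, n_trials: int) -> float:
    """Bayesian Information Criterion: -2 logL + k ln(n); lower is better."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return -2.0 * log_likelihood + k_params * math.log(n_trials)


# ---------------------------------------------------------------------------
# NSGA-II


def _nondominated_rank(F: np.ndarray) -> np.ndarray:
    dom = _dominance_matrix(F)
    n_dominators = dom.sum(axis=0).astype(int)
    rank = np.full(len(F), -1)
    current = 0
    remaining = n_dominators.copy()
    assigned = np.zeros(len(F), dtype=bool)
    while not assigned.all():
        front = (remaining == 0) & ~assigned
        if not front.any():  # numerical safety; cannot happen
            front = ~assigned
        rank[front] = current
        assigned |= front
        remaining = remaining - dom[front].sum(axis=0)
        current += 1
    return rank


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    crowd = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        crowd[order[0]] = crowd[order[-1]] = np.inf
        if span > 0:
            gaps = (F[order[2:], j] - F[order[:-2], j]) / span
            crowd[order[1:-1]] += gaps
    return crowd


def _sbx_crossover(p1, p2, rng, eta=15.0, prob=0.9):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    u = rng.random(p1.size)
    beta = np.where(
        u <= 0.5,
        (2 * u) ** (1.0 / (eta + 1)),
        (1.0 / (2 * (1 - u))) ** (1.0 / (eta + 1)),
    )
    mean = 0.5 * (p1 + p2)
    diff = 0.5 * np.abs(p2 - p1)
    c1 = mean - beta * diff
    c2 = mean + beta * diff
    return np.clip(c1, 0, 1), np.clip(c2, 0, 1)


def _poly_mutation(x, rng, eta=20.0, prob=None):
    d = x.size
    prob = 1.0 / d if prob is None else prob
    y = x.copy()
    do = rng.random(d) < prob
    u = rng.random(d)
    delta = np.where(
        u < 0.5,
        (2 * u) ** (1.0 / (eta + 1)) - 1.0,
        1.0 - (2 * (1 - u)) ** (1.0 / (eta + 1)),
    )
    y[do] += delta[do]
    return np.clip(y, 0, 1)


def _tournament(rank, crowd, rng):
    i, j = rng.integers(len(rank)), rng.integers(len(rank))
    if rank[i] < rank[j]:
        return i
    if rank[j] < rank[i]:
        return j
    return i if crowd[i] >= crowd[j] else j


def nsga2_fit(
    model_id: str,
    log: BehaviorLog,
    pop: int = 40,
    generations: int = 100,
    seed: int = 0,
    n_rep: int = 3,
    objectives: str = "choice+rt",
    diversity_k: int = 5,
) -> list[ParetoSolution]:
    """Fit one model family to one session with NSGA-II.

    Maximizes (log-likelihood[, E_RT], diversity); the returned front is the
    final population's non-dominated set projected onto the behavioral
    objectives (diversity dropped at extraction).  Deterministic given
    ``seed``.
    """
    if objectives not in ("choice", "choice+rt"):
        raise ValueError("objectives must be 'choice' or 'choice+rt'")
    ctx = FitContext.from_log(log)
    if objectives == "choice+rt" and ctx.subject_steps is None:
        raise ValueError("log has no usable RTs; fit with objectives='choice'")
    specs = MODEL_SPECS[model_id]
    d = len(specs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, MODEL_IDS.index(model_id)]))
    eval_counter = [0]

    def evaluate(genes_matrix):
        rows = []
        for genes in genes_matrix:
            params = decode_params(model_id, genes)
            rep_seed = int((seed * 1_000_003 + eval_counter[0]) % (2**31 - 1))
            eval_counter[0] += 1
            loglik, e_rt, _ = evaluate_candidate(ctx, model_id, params, n_rep, rep_seed)
            rows.append((loglik, e_rt) if objectives == "choice+rt" else (loglik,))
        return np.array(rows)

    P = rng.random((pop, d))
    F = evaluate(P)
    for _ in range(generations):
        div = diversity(P, k=diversity_k)
        F_full = np.column_stack([F, div])
        rank = _nondominated_rank(F_full)
        crowd = np.zeros(pop)
        for rk in np.unique(rank):
            sel = rank == rk
            crowd[sel] = _crowding_distance(F_full[sel])
        children = []
        while len(children) < pop:
            a = P[_tournament(rank, crowd, rng)]
            b = P[_tournament(rank, crowd, rng)]
            c1, c2 = _sbx_crossover(a, b, rng)
            children.append(_poly_mutation(c1, rng))
            if len(children) < pop:
                children.append(_poly_mutation(c2, rng))
        Q = np.array(children)
        FQ = evaluate(Q)
        R = np.vstack([P, Q])
        FR = np.vstack([F, FQ])
        div = diversity(R, k=diversity_k)
        FR_full = np.column_stack([FR, div])
        rank = _nondominated_rank(FR_full)
        keep: list[int] = []
        for rk in range(rank.max() + 1):
            idx = np.flatnonzero(rank == rk)
            if len(keep) + len(idx) <= pop:
                keep.extend(idx.tolist())
            else:
                crowd = _crowding_distance(FR_full[idx])
                order = np.argsort(-crowd, kind="stable")
                keep.extend(idx[order[: pop - len(keep)]].tolist())
                break
        P, F = R[keep], FR[keep]

    mask = pareto_mask(F)
    solutions = []
    for genes, fit in zip(P[mask], F[mask]):
        solutions.append(
            ParetoSolution(
                model_id=model_id,
                params=decode_params(model_id, genes),
                fit_choice=float(fit[0]),
                fit_rt=float(fit[1]) if objectives == "choice+rt" else None,
                provenance={"seed": seed, "pop": pop, "generations": generations},
            )
        )
    return solutions


def fit_all_models(
    log: BehaviorLog,
    model_ids=MODEL_IDS,
    pop: int = 40,
    generations: int = 100,
    seed: int = 0,
    n_rep: int = 3,
    objectives: str = "choice+rt",
) -> dict[str, list[ParetoSolution]]:
    return {
        mid: nsga2_fit(
            mid, log, pop=pop, generations=generations, seed=seed,
            n_rep=n_rep, objectives=objectives,
        )
        for mid in model_ids
    }


def best_by_likelihood(front: list[ParetoSolution]) -> ParetoSolution:
    return max(front, key=lambda sol: sol.fit_choice)


def select_model(
    fronts: dict[str, list[ParetoSolution]],
    agg_cfg: AggregationConfig | None = None,
    use_bic: bool = False,
    n_trials: int | None = None,
) -> ParetoSolution:
    """Pick the winning (model, parameters) from per-model fronts.

    Default: merge the fronts and aggregate.  With ``use_bic`` the best
    likelihood per model is penalized by parameter count (choice-only path).
    """
    if use_bic:
        if n_trials is None:
            raise ValueError("BIC selection requires n_trials")
        candidates = {m: best_by_likelihood(f) for m, f in fronts.items() if f}
        return min(
            candidates.values(),
            key=lambda sol: (
                bic(sol.fit_choice, free_parameter_count(sol.model_id), n_trials),
                MODEL_IDS.index(sol.model_id),
            ),
        )
    return aggregate(merge_fronts(fronts), agg_cfg)


def leave_one_out(
    model_ids,
    log: BehaviorLog,
    pop: int = 40,
    generations: int = 100,
    seed: int = 0,
    n_rep: int = 3,
    agg_cfg: AggregationConfig | None = None,
) -> dict:
    """Block-wise leave-one-out validation of the model selection.

    For each held-out block, all families are refit on the remaining blocks
    and the merged-front aggregation winner is recorded; the all-blocks
    winner and the fold agreement rate complete the table.
    """
    if log.config.n_blocks < 2:
        raise ValueError("leave-one-out needs at least 2 blocks")
    folds = {}
    for b in range(log.config.n_blocks):
        train = log.subset_blocks(
            [x for x in range(log.config.n_blocks) if x != b]
        )
        fronts = fit_all_models(
            train, model_ids, pop=pop, generations=generations,
            seed=seed + b + 1, n_rep=n_rep,
        )
        folds[b] = select_model(fronts, agg_cfg)
    fronts_all = fit_all_models(
        log, model_ids, pop=pop, generations=generations, seed=seed, n_rep=n_rep
    )
    winner_all = select_model(fronts_all, agg_cfg)
    agreement = float(
        np.mean([folds[b].model_id == winner_all.model_id for b in folds])
    )
    table = pd.DataFrame(
        {
            "fold": [f"-block{b + 1}" for b in folds] + ["all_blocks"],
            "winner": [folds[b].model_id for b in folds] + [winner_all.model_id],
        }
    )
    return {
        "folds": folds,
        "all_blocks": winner_all,
        "agreement": agreement,
        "table": table,
    }
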