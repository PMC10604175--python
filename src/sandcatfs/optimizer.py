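"""The binary sand cat swarm loop, with and without enhancement.

Both run modes share one engine:

1. Initialize N bit-vectors to all-ones (every gene selected).
2. Each iteration: score every individual with the cross-validated SVM
   fitness, refresh the elitist archive (the global best never
   regresses), then update every position — exploitation toward the
   best along a random angle when the phase draw ``R`` is small,
   exploration relative to a random peer otherwise — and binarize each
   coordinate through the tansig transfer function immediately.
3. (Enhanced mode only.)  Per individual, a fair coin picks one of two
   archive-improvement operators: single-point crossover of the best
   with the individual's row (the better offspring replaces the best
   only on strict improvement; the row is untouched), or a
   pinhole-imaging opposition candidate ``(NOT row) AND best`` (on
   strict improvement it replaces both the best and the row).

The plain mode (step 3 skipped) is the baseline the enhanced variant is
compared against on convergence traces.

Replacement is always guarded by strict improvement, with exact-kappa
ties broken toward fewer genes, so the best-fitness trace is
non-decreasing by construction.  All randomness flows from one seeded
generator; two runs with the same inputs and seed are identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .binarization import binarize_positions
from .fitness import CVConfig, FitnessEvaluator, FitnessResult
from .io import LabeledExpression
from .scso_core import ScheduleState, compute_R, compute_r
from .variation_ops import PinholeParams, piobl_candidate, single_point_crossover

__all__ = [
    "OptimizerConfig",
    "RunRecord",
    "init_population",
    "bscso_step",
    "enhancement_step",
    "run_pilc_bscso",
    "run_bscso",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """All knobs of the swarm loop and its fitness evaluation.

    ``phase_test`` selects the exploitation condition: ``"abs_unit"``
    uses |R| <= 1; ``"unit_interval"`` the stricter 0 < R < 1 variant.
    """

    n_population: int = 100
    n_iterations: int = 50
    sm: float = 2.0
    phase_test: str = "abs_unit"
    abs_distance: bool = True
    pinhole_K: float = 0.05
    piobl_threshold: float = 0.5
    enhance_prob: float = 0.5
    crossover_writes_row: bool = False
    n_folds: int = 10
    n_repeats: int = 3
    svm_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.n_population < 1 or self.n_iterations < 0:
            raise ValueError("n_population must be >= 1 and n_iterations >= 0")
        if self.phase_test not in ("abs_unit", "unit_interval"):
            raise ValueError(f"unknown phase_test {self.phase_test!r}")


@dataclass
class RunRecord:
    """Everything needed to report and reproduce one optimization run."""

    algorithm: str
    trace: list[FitnessResult]
    best_bits: np.ndarray
    best_fitness: FitnessResult
    config: dict
    seed: int
    evaluations: int  # actual classifier-training batches (cache misses)
    fitness_queries: int
    gene_ids: list[str] | None = field(default=None, repr=False)

    @property
    def kappa_trace(self) -> list[float]:
        return [fr.kappa for fr in self.trace]

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.best_bits)


def init_population(n_population: int, n_genes: int) -> np.ndarray:
    """All-ones start: every individual begins with every gene selected."""
    if n_population < 1 or n_genes < 1:
        raise ValueError("population size and dimension must be positive")
    return np.ones((n_population, n_genes), dtype=np.int8)


def bscso_step(
    pop: np.ndarray,
    best: np.ndarray,
    sched: ScheduleState,
    rng: np.random.Generator,
    phase_test: str = "abs_unit",
    abs_distance: bool = True,
) -> np.ndarray:
    """One position-update sweep over the whole population, in place.

    Per individual: one phase draw R and one sensitivity draw r.  Per
    dimension: a fresh angle, fresh uniforms, and for exploration a
    fresh candidate row (read from the current, partially updated
    matrix, matching the in-place pseudocode semantics).  Each updated
    coordinate is immediately passed through tansig + stochastic
    threshold, so the stored state stays binary.
    """
    n, d = pop.shape
    rg = sched.rg
    for i in range(n):
        R = compute_R(rg, rng.uniform())
        r = compute_r(rg, rng.uniform())
        exploit = abs(R) <= 1.0 if phase_test == "abs_unit" else 0.0 < R < 1.0
        theta = rng.uniform(0.0, 360.0, size=d)
        row = pop[i].astype(float)
        if exploit:
            u1 = rng.uniform(size=d)
            u2 = rng.uniform(size=d)
            xrand = u1 * best - row
            if abs_distance:
                xrand = np.abs(xrand)
            new = best - u2 * xrand * np.cos(np.radians(theta))
        else:
            cp = (n * rng.uniform(size=d)).astype(int)  # floor(N*u), per dimension
            cand_vals = pop[cp, np.arange(d)].astype(float)
            u = rng.uniform(size=d)
            new = r * (cand_vals - u * row)
        pop[i] = binarize_positions(new, rng)
    return pop


def enhancement_step(
    i: int,
    pop: np.ndarray,
    best: np.ndarray,
    best_fit: FitnessResult,
    rng: np.random.Generator,
    evaluator: FitnessEvaluator,
    cfg: OptimizerConfig,
) -> tuple[np.ndarray, FitnessResult]:
    """Crossover-or-opposition improvement attempt for individual ``i``.

    Returns the (possibly replaced) archive best and its fitness; may
    write the opposition candidate into row ``i`` on success.
    """
    d = pop.shape[1]
    if rng.uniform() < cfg.enhance_prob:
        # crossover branch: offspring may replace the archive, row untouched
        cut = int(rng.integers(1, d)) if d >= 2 else None
        if cut is None:
            return best, best_fit
        q1, q2 = single_point_crossover(best, pop[i], cut)
        f1 = evaluator.evaluate(q1)
        f2 = evaluator.evaluate(q2)
        if f1.better_than(f2) and f1.better_than(best_fit):
            best, best_fit = q1.astype(np.int8), f1
            if cfg.crossover_writes_row:
                pop[i] = best
        elif f2.better_than(best_fit):
            best, best_fit = q2.astype(np.int8), f2
            if cfg.crossover_writes_row:
                pop[i] = best
    else:
        # opposition branch: (NOT row) AND best, replaces both on success
        params = PinholeParams(K=cfg.pinhole_K, binarize_threshold=cfg.piobl_threshold)
        cand = piobl_candidate(pop[i], best, params)
        fc = evaluator.evaluate(cand)
        if fc.better_than(best_fit):
            best, best_fit = cand, fc
            pop[i] = cand
    return best, best_fit


def _optimize(
    X: np.ndarray,
    y: np.ndarray,
    cfg: OptimizerConfig,
    seed: int,
    enhance: bool,
    gene_ids: list[str] | None = None,
    extra_config: dict | None = None,
) -> RunRecord:
    """Shared engine for the plain and enhanced runs."""
    rng = np.random.default_rng(seed)
    cv = CVConfig(
        n_folds=cfg.n_folds, n_repeats=cfg.n_repeats,
        svm_cost=cfg.svm_cost, seed=int(seed) % (2**31),
    )
    evaluator = FitnessEvaluator(X, y, cv)
    n, t_max = cfg.n_population, cfg.n_iterations
    pop = init_population(n, X.shape[1])

    def refresh_best(best, best_fit):
        for i in range(n):
            fit = evaluator.evaluate(pop[i])
            if best_fit is None or fit.better_than(best_fit):
                best, best_fit = pop[i].copy(), fit
        return best, best_fit

    best, best_fit = refresh_best(None, None)
    trace = [best_fit]
    for t in range(1, t_max + 1):
        sched = ScheduleState(t=t, T=t_max, sM=cfg.sm)
        bscso_step(pop, best, sched, rng,
                   phase_test=cfg.phase_test, abs_distance=cfg.abs_distance)
        best, best_fit = refresh_best(best, best_fit)
        if enhance:
            for i in range(n):
                best, best_fit = enhancement_step(
                    i, pop, best, best_fit, rng, evaluator, cfg
                )
        trace.append(best_fit)

    config = asdict(cfg)
    config.update(extra_config or {})
    return RunRecord(
        algorithm="pilc-bscso" if enhance else "bscso",
        trace=trace,
        best_bits=best.astype(np.int8),
        best_fitness=best_fit,
        config=config,
        seed=int(seed),
        evaluations=evaluator.n_trainings,
        fitness_queries=evaluator.n_queries,
        gene_ids=gene_ids,
    )


def _check_run_inputs(data: LabeledExpression, cfg: OptimizerConfig) -> None:
    counts = np.bincount(data.y)
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"the {cfg.n_folds} CV folds"
        )


def run_pilc_bscso(
    data: LabeledExpression, cfg: OptimizerConfig = OptimizerConfig(), seed: int = 0
) -> RunRecord:
    """Enhanced run (crossover + pinhole opposition) on a labeled matrix.

    ``data`` is expected to be already standardized/prefiltered; the
    loop optimizes over whatever gene columns it is given.
    """
    _check_run_inputs(data, cfg)
    classes = data.classes
    return _optimize(
        data.values, data.y, cfg, seed, enhance=True, gene_ids=list(data.gene_ids),
        extra_config={"label_encoding": {classes[0]: 0, classes[1]: 1}},
    )


def run_bscso(
    data: LabeledExpression, cfg: OptimizerConfig = OptimizerConfig(), seed: int = 0
) -> RunRecord:
    """Plain baseline run (no enhancement operators); same contract."""
    _check_run_inputs(data, cfg)
    classes = data.classes
    return _optimize(
        data.values, data.y, cfg, seed, enhance=False, gene_ids=list(data.gene_ids),
        extra_config={"label_encoding": {classes[0]: 0, classes[1]: 1}},
    )
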