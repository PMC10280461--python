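"""Master-slave execution of independent islands and the Pareto archive.

Each island evolves its own population with no migration; the master gathers
the final populations, drops duplicate masks, and keeps the 30 "top"
solutions under the two objectives (maximise cross-validated accuracy,
minimise selected-feature count). Parallelism here is a contract, not a
technology: islands are seeded `base_seed + island_id`, never communicate,
and the gathered result is a pure function of (dataset, config, base_seed,
n_islands) — sequential emulation and a process pool produce bit-identical
archives.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import TabularDataset, make_folds
from .hho_core import Population, SearchConfig, run_island
from .knn_eval import CrossValidatedKNN

__all__ = [
    "ParallelConfig",
    "Solution",
    "ParetoArchive",
    "ParallelResult",
    "run_parallel",
    "dedupe",
    "pareto_front",
    "select_top",
    "dominates",
]


@dataclass
class ParallelConfig:
    """Island count, base seed, and execution mode.

    mode is "sequential" (default, same results, no processes) or "process"
    (a process pool; useful when the fitness dominates run time).
    """

    n_islands: int = 4
    base_seed: int = 0
    mode: str = "sequential"

    def __post_init__(self) -> None:
        if self.n_islands < 1:
            raise ValueError("need at least one island")
        if self.mode not in ("sequential", "process"):
            raise ValueError("mode must be 'sequential' or 'process'")


@dataclass(frozen=True)
class Solution:
    """One gathered candidate: mask (as an immutable bit tuple) + objectives."""

    mask: tuple[int, ...]
    accuracy: float
    n_selected: int
    island: int = -1


@dataclass
class ParetoArchive:
    """Deduplicated gathered solutions, their non-dominated front, and the
    up-to-30 selected for reporting."""

    solutions: list[Solution]
    front: list[Solution]
    selected: list[Solution]


@dataclass
class ParallelResult:
    """Everything the master gathers from the islands."""

    populations: list[Population]
    solutions: list[Solution]
    total_evals: int
    island_seeds: list[int] = field(default_factory=list)


def _population_solutions(pop: Population, island: int) -> list[Solution]:
    return [
        Solution(
            mask=tuple(int(b) for b in h.mask),
            accuracy=h.fitness,
            n_selected=h.n_selected,
            island=island,
        )
        for h in pop.hawks
    ]


def _island_task(args):
    ds, cfg, seed, evaluator, n_features = args
    return run_island(ds, cfg, seed=seed, evaluator=evaluator, n_features=n_features)


def run_parallel(
    ds: TabularDataset | None,
    cfg: SearchConfig,
    pcfg: ParallelConfig,
    evaluator_factory=None,
    n_features: int | None = None,
) -> ParallelResult:
    """Run n_islands independent searches and gather their populations.

    Island i is seeded ``base_seed + i``. All islands score masks against the
    same cross-validation fold assignment (drawn from ``cfg.fold_seed`` or
    ``base_seed``) so their accuracies are directly comparable at the master.
    ``evaluator_factory(ds, cfg, fold_seed)`` may replace the KNN fitness.
    """
    seeds = [pcfg.base_seed + i for i in range(pcfg.n_islands)]
    fold_seed = cfg.fold_seed if cfg.fold_seed is not None else pcfg.base_seed

    if evaluator_factory is None:
        if ds is None:
            raise ValueError("a dataset is required for the default KNN fitness")
        evaluator = CrossValidatedKNN(ds, cfg.knn, fold_seed=fold_seed)
    else:
        evaluator = evaluator_factory(ds, cfg, fold_seed)
    if ds is None and n_features is None:
        raise ValueError("n_features required when running without a dataset")

    tasks = [(ds, cfg, seed, evaluator, n_features) for seed in seeds]
    if pcfg.mode == "process":
        with ProcessPoolExecutor(max_workers=min(pcfg.n_islands, 8)) as pool:
            try:
                populations = list(pool.map(_island_task, tasks))
            except Exception as exc:  # pragma: no cover - surfaced for operators
                raise RuntimeError(f"island worker failed: {exc}") from exc
    else:
        populations = []
        for i, task in enumerate(tasks):
            try:
                populations.append(_island_task(task))
            except Exception as exc:
                raise RuntimeError(f"island {i} failed: {exc}") from exc

    solutions = []
    for i, pop in enumerate(populations):
        solutions.extend(_population_solutions(pop, i))
    total = sum(p.eval_counter for p in populations)
    return ParallelResult(
        populations=populations,
        solutions=solutions,
        total_evals=total,
        island_seeds=seeds,
    )


def dedupe(solutions: list[Solution]) -> list[Solution]:
    """Keep the first occurrence of every distinct mask."""
    seen: set[tuple[int, ...]] = set()
    out = []
    for s in solutions:
        if s.mask not in seen:
            seen.add(s.mask)
            out.append(s)
    return out


def dominates(a: Solution, b: Solution) -> bool:
    """True when `a` is at least as good on both objectives and better on one."""
    return (
        a.accuracy >= b.accuracy
        and a.n_selected <= b.n_selected
        and (a.accuracy > b.accuracy or a.n_selected < b.n_selected)
    )


def pareto_front(solutions: list[Solution]) -> list[Solution]:
    """All solutions not dominated under (accuracy up, feature count down)."""
    if not solutions:
        return []
    acc = np.array([s.accuracy for s in solutions])
    nsel = np.array([s.n_selected for s in solutions])
    # a dominates b: acc_a >= acc_b, nsel_a <= nsel_b, with one strict
    ge = acc[:, None] >= acc[None, :]
    le = nsel[:, None] <= nsel[None, :]
    strict = (acc[:, None] > acc[None, :]) | (nsel[:, None] < nsel[None, :])
    dominated = (ge & le & strict).any(axis=0)
    return [s for s, d in zip(solutions, dominated) if not d]


def _rank(s: Solution) -> tuple:
    return (-s.accuracy, s.n_selected, s.mask)


def select_top(solutions: list[Solution], limit: int = 30) -> ParetoArchive:
    """Build the archive: full front first, then fill to `limit`.

    If the front exceeds the limit, its highest-accuracy members are kept;
    if it is smaller, the remainder is filled with the best non-front
    solutions ranked by accuracy (descending) then feature count (ascending).
    Input must already be deduplicated.
    """
    solutions = list(solutions)
    front = pareto_front(solutions)
    front_sorted = sorted(front, key=_rank)
    if len(front_sorted) >= limit:
        selected = front_sorted[:limit]
    else:
        front_set = {s.mask for s in front_sorted}
        rest = sorted((s for s in solutions if s.mask not in front_set), key=_rank)
        selected = front_sorted + rest[: limit - len(front_sorted)]
    return ParetoArchive(solutions=solutions, front=front_sorted, selected=selected)
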