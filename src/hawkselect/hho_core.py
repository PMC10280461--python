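"""Binary Harris Hawks search over feature masks on a single island.

Harris Hawks Optimization models a population of hawks converging on escaping
prey (the "rabbit", here the best mask found so far). A per-hawk escaping
energy E = 2*E0*(1 - t/T), with E0 redrawn uniformly in (-1, 1) each
generation, decays linearly over the run and gates the move:

* |E| >= 1  — exploration: copy a block of bits from a random partner
  (q below the configured split) or seed the current mask with a random
  subset of the best mask's selected features (q above);
* |E| in [0.5, 1) — soft besiege: copy several of the rabbit's differing bits,
  the count scaled by |E| and a jump strength J; with r < 0.5 the "dive"
  variant adds one extra random bit-flip as a perturbation;
* |E| < 0.5 — hard besiege: copy exactly one differing bit of the rabbit
  (the dive variant at low energy is deliberately identical — minimal
  perturbation near convergence).

Every candidate is scored (cross-validated KNN accuracy by default), counted
against the evaluation budget, discarded if its mask already exists in the
population, and otherwise replaces the worst hawk only when strictly better
under the ranking (higher accuracy, ties to fewer selected features). Masks
always keep at least one selected feature; the population never holds two
identical masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import TabularDataset
from .knn_eval import CrossValidatedKNN, KNNConfig

__all__ = [
    "SearchError",
    "Hawk",
    "Population",
    "SearchConfig",
    "LinearMaskFitness",
    "escape_energy",
    "init_population",
    "exploration_one",
    "exploration_two",
    "soft_besiege",
    "hard_besiege",
    "soft_besiege_dive",
    "hard_besiege_dive",
    "generation_step",
    "run_island",
    "default_evaluator_factory",
]

BRANCHES = (
    "explore_random",
    "explore_best",
    "soft_besiege",
    "hard_besiege",
    "soft_besiege_dive",
    "hard_besiege_dive",
)


class SearchError(RuntimeError):
    """Raised when the search cannot satisfy its own invariants."""


@dataclass
class Hawk:
    """A candidate solution: a binary feature mask with its cached fitness."""

    mask: np.ndarray  # uint8 vector, 1 = feature selected
    fitness: float

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def rank_key(self) -> tuple[float, int]:
        """Sort key under the ranking rule: higher is better."""
        return (self.fitness, -self.n_selected)


@dataclass
class SearchConfig:
    """All knobs of one island's search.

    Defaults follow the published configuration: population of 30 hawks
    evolved for 500 generations with a 5-NN, 5-fold fitness.
    """

    population_size: int = 30
    iterations: int = 500
    knn: KNNConfig = field(default_factory=KNNConfig)
    seed: int = 0
    min_features: int = 1
    fold_seed: int | None = None  # None: derive from the island seed
    explore_random_if_q_below: float = 0.5

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class Population:
    """One island's hawks plus search bookkeeping."""

    hawks: list[Hawk]
    rabbit: Hawk
    eval_counter: int = 0
    branch_counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BRANCHES})
    best_history: list[float] = field(default_factory=list)
    _mask_keys: set[bytes] = field(default_factory=set, repr=False)

    def contains_mask(self, mask: np.ndarray) -> bool:
        return mask.tobytes() in self._mask_keys


class LinearMaskFitness:
    """Deterministic synthetic fitness: weighted fraction of selected bits.

    A separable stand-in objective (each feature contributes a fixed positive
    weight) used for accounting and scaling exercises where the cost of the
    cross-validated classifier is beside the point. Picklable, so it works
    across process-based islands.
    """

    def __init__(self, n_features: int, seed: int = 0):
        self.weights = np.random.default_rng(seed).random(n_features)
        self._total = float(self.weights.sum())

    def __call__(self, mask) -> float:
        return float(self.weights[np.asarray(mask, dtype=bool)].sum() / self._total)


def escape_energy(e0: float, t: int, total: int) -> float:
    """Escaping energy E = 2*E0*(1 - t/T): linear decay to 0 at t = T."""
    if total <= 0:
        raise ValueError("total iterations must be positive")
    if not 0 <= t <= total:
        raise ValueError("iteration t must lie in [0, T]")
    return 2.0 * e0 * (1.0 - t / total)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Guarantee at least one selected feature (flip one random bit to 1)."""
    if not mask.any():
        mask[rng.integers(mask.size)] = 1
    return mask


def init_population(
    ds_or_n_features, cfg: SearchConfig, rng: np.random.Generator, evaluator=None
) -> Population:
    """Draw N distinct fair-coin masks, repair, and evaluate them all.

    The N initial evaluations establish the starting population and are not
    charged to the operator-candidate counter. Raises if the feature space
    cannot hold N distinct non-empty masks.
    """
    d = ds_or_n_features.n_features if isinstance(ds_or_n_features, TabularDataset) else int(ds_or_n_features)
    n = cfg.population_size
    if d < 63 and 2**d - 1 < n:
        raise SearchError(
            f"cannot build {n} distinct non-empty masks over {d} features"
        )
    if evaluator is None:
        raise ValueError("an evaluator (mask -> fitness) is required")

    seen: set[bytes] = set()
    hawks: list[Hawk] = []
    attempts = 0
    while len(hawks) < n:
        if attempts > 1000 * n:
            raise SearchError("failed to draw distinct initial masks")
        attempts += 1
        mask = (rng.random(d) < 0.5).astype(np.uint8)
        _repair(mask, rng)
        key = mask.tobytes()
        if key in seen:
            continue
        seen.add(key)
        hawks.append(Hawk(mask=mask, fitness=float(evaluator(mask))))

    rabbit = max(hawks, key=Hawk.rank_key)
    pop = Population(hawks=hawks, rabbit=rabbit, _mask_keys=seen)
    pop.best_history.append(rabbit.fitness)
    return pop


def exploration_one(
    source: np.ndarray, target: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Copy a random block of a partner's bits into the current mask.

    The block is a uniform subset of positions of size 1..ceil(d/2).
    """
    d = target.size
    size = int(rng.integers(1, -(-d // 2) + 1))
    pos = rng.choice(d, size=size, replace=False)
    out = target.copy()
    out[pos] = source[pos]
    return _repair(out, rng)


def exploration_two(
    best: np.ndarray, current: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Switch on a random subset of the best mask's selected features."""
    ones = np.flatnonzero(best)
    out = current.copy()
    if ones.size:
        size = int(rng.integers(1, ones.size + 1))
        pos = rng.choice(ones, size=size, replace=False)
        out[pos] = 1
    return _repair(out, rng)


def _copy_from_rabbit(
    current: np.ndarray, rabbit: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Copy `m` of the rabbit's differing bit values into the current mask.

    Identical masks instead flip one random bit — duplicates of the rabbit
    are useless to a population that forbids redundant solutions.
    """
    diff = np.flatnonzero(current != rabbit)
    out = current.copy()
    if diff.size == 0:
        out[rng.integers(out.size)] ^= 1
    else:
        m = min(m, diff.size)
        pos = rng.choice(diff, size=m, replace=False) if m < diff.size else diff
        out[pos] = rabbit[pos]
    if not out.any():
        # repair toward the prey: besiege moves must not back away from it
        ones = np.flatnonzero(rabbit)
        if ones.size:
            out[rng.choice(ones)] = 1
        else:
            out[rng.integers(out.size)] = 1
    return out


def soft_besiege(
    current: np.ndarray,
    rabbit: np.ndarray,
    e: float,
    j: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """High-energy besiege: copy ~|E|*J*d/4 of the rabbit's differing bits."""
    m = max(1, round(abs(e) * j * current.size / 4))
    return _copy_from_rabbit(current, rabbit, m, rng)


def hard_besiege(
    current: np.ndarray, rabbit: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Low-energy besiege: copy exactly one differing bit of the rabbit."""
    return _copy_from_rabbit(current, rabbit, 1, rng)


def soft_besiege_dive(
    current: np.ndarray, rabbit: np.ndarray, e: float, rng: np.random.Generator
) -> np.ndarray:
    """Soft besiege with progressive dive: rabbit copy plus one perturbing flip.

    Copies ~|E|*d/4 differing bits, then flips one uniformly random bit —
    the perturbation that lets the prey "survive" a high-energy attack.
    """
    m = max(1, round(abs(e) * current.size / 4))
    out = _copy_from_rabbit(current, rabbit, m, rng)
    out[rng.integers(out.size)] ^= 1
    return _repair(out, rng)


def hard_besiege_dive(
    current: np.ndarray, rabbit: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Low-energy dive: same single-bit approach as the hard besiege.

    Near convergence only the distance to the prey is reduced; no extra
    perturbation is added.
    """
    return _copy_from_rabbit(current, rabbit, 1, rng)


def _worst_index(hawks: list[Hawk]) -> int:
    worst = 0
    worst_key = hawks[0].rank_key()
    for i in range(1, len(hawks)):
        k = hawks[i].rank_key()
        if k < worst_key:
            worst, worst_key = i, k
    return worst


def generation_step(
    pop: Population,
    cfg: SearchConfig,
    evaluator,
    rng: np.random.Generator,
    t: int,
    total: int,
) -> None:
    """One generation: propose, score, and maybe insert one candidate per hawk.

    Branch choice per hawk: draw E0 in (-1,1), E by the energy schedule, and
    uniform q, r, with jump strength J = 2*(1-u). |E| >= 1 explores, otherwise
    the (r, |E|) quadrant picks one of the four besiege regimes. Every
    candidate costs one fitness evaluation whether or not it enters the
    population; duplicates of existing masks are discarded; insertion replaces
    the worst hawk only on strict improvement.
    """
    n = len(pop.hawks)
    d = pop.hawks[0].mask.size
    for i in range(n):
        current = pop.hawks[i].mask
        draws = rng.random(4)
        e0 = 2.0 * draws[0] - 1.0
        e = escape_energy(e0, t, total)
        q, r = draws[1], draws[2]
        j = 2.0 * (1.0 - draws[3])
        abs_e = abs(e)

        if abs_e >= 1.0:
            if q < cfg.explore_random_if_q_below:
                partner = int(rng.integers(n - 1))
                if partner >= i:
                    partner += 1
                cand = exploration_one(pop.hawks[partner].mask, current, rng)
                branch = "explore_random"
            else:
                cand = exploration_two(pop.rabbit.mask, current, rng)
                branch = "explore_best"
        elif r >= 0.5 and abs_e >= 0.5:
            cand = soft_besiege(current, pop.rabbit.mask, e, j, rng)
            branch = "soft_besiege"
        elif r >= 0.5:
            cand = hard_besiege(current, pop.rabbit.mask, rng)
            branch = "hard_besiege"
        elif abs_e >= 0.5:
            cand = soft_besiege_dive(current, pop.rabbit.mask, e, rng)
            branch = "soft_besiege_dive"
        else:
            cand = hard_besiege_dive(current, pop.rabbit.mask, rng)
            branch = "hard_besiege_dive"
        pop.branch_counts[branch] += 1

        fitness = float(evaluator(cand))
        pop.eval_counter += 1

        key = cand.tobytes()
        if key in pop._mask_keys:
            continue
        new_hawk = Hawk(mask=cand, fitness=fitness)
        w = _worst_index(pop.hawks)
        if new_hawk.rank_key() > pop.hawks[w].rank_key():
            pop._mask_keys.discard(pop.hawks[w].mask.tobytes())
            pop._mask_keys.add(key)
            pop.hawks[w] = new_hawk
            if new_hawk.rank_key() > pop.rabbit.rank_key():
                pop.rabbit = new_hawk


def default_evaluator_factory(ds: TabularDataset, cfg: SearchConfig, fold_seed: int):
    """The standard fitness: cross-validated KNN accuracy on the masked data."""
    return CrossValidatedKNN(ds, cfg.knn, fold_seed=fold_seed)


def run_island(
    ds: TabularDataset | None,
    cfg: SearchConfig,
    seed: int | None = None,
    evaluator=None,
    n_features: int | None = None,
) -> Population:
    """Run one island: init, T generations, one candidate per hawk per step.

    Deterministic for a fixed seed. The returned population carries the
    operator-candidate count (`eval_counter`, exactly N*T), the per-generation
    best-fitness history, and branch usage counts. `evaluator` defaults to the
    cross-validated KNN on `ds`; a custom callable (mask -> fitness) may be
    supplied, in which case `ds` may be None if `n_features` is given.
    """
    if seed is None:
        seed = cfg.seed
    if evaluator is None:
        if ds is None:
            raise ValueError("either a dataset or an evaluator is required")
        fold_seed = cfg.fold_seed if cfg.fold_seed is not None else seed
        evaluator = default_evaluator_factory(ds, cfg, fold_seed)
    d = ds.n_features if ds is not None else n_features
    if d is None:
        raise ValueError("n_features required when running without a dataset")

    rng = np.random.default_rng(seed)
    pop = init_population(d, cfg, rng, evaluator)
    for t in range(cfg.iterations):
        generation_step(pop, cfg, evaluator, rng, t, cfg.iterations)
        pop.best_history.append(pop.rabbit.fitness)
    return pop
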