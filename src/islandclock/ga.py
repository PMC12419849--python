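"""Penalised genetic-algorithm islands model for CpG feature selection.

Each candidate solution ("chromosome") is a binary inclusion vector over
the post-prefilter CpG universe.  Its fitness is the 10-fold
cross-validated mean absolute error (years) of a ridge regression of
chronological age on the included CpGs' M-values — averaged with equal
weight over tissues so that small tissues count as much as large ones —
plus a sparsity charge of ``cpg_penalty`` years per included CpG.  Lower
fitness is better.

The population is split across islands that evolve independently
(elitism, single-point crossover among the elite, single-bit mutation)
and exchange their best chromosome around a ring every
``migration_interval`` generations.

The penalty makes the objective honest about model size: a CpG survives
only if its removal would raise the cross-validated error by more than
the per-CpG charge.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .types import IslandClockError, MethylationMatrix, align_sheet

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "FitnessResult",
    "IslandState",
    "ridge_fitness",
    "init_population",
    "evolve_generation",
    "migrate",
    "run_ga",
]


@dataclass
class GAConfig:
    """Tunables of the island GA; defaults follow the published recipe."""

    population_size: int = 200
    n_islands: int = 4
    elite_fraction: float = 0.05
    crossover_rate: float = 0.70
    mutation_rate: float = 0.10
    mutation_mode: str = "per_child"  # or "per_bit" (p = mutation_rate / n_features)
    migration_interval: int = 10
    n_generations: int = 400
    cpg_penalty: float = 0.01  # years charged per included CpG
    cv_folds: int = 10
    init_density: float = 0.10
    ridge_lambda_grid: np.ndarray = field(default_factory=lambda: np.logspace(-3, 3, 50))
    error_metric: str = "mae"  # or "rmse"
    seed: int = 0

    def validate(self) -> None:
        if self.population_size % self.n_islands != 0:
            raise IslandClockError("population_size must be divisible by n_islands")
        for name in ("elite_fraction", "crossover_rate", "mutation_rate", "init_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise IslandClockError(f"{name} must lie in [0, 1], got {v}")
        if self.population_size // self.n_islands < 2:
            raise IslandClockError("each island needs at least 2 chromosomes")
        if self.error_metric not in ("mae", "rmse"):
            raise IslandClockError("error_metric must be 'mae' or 'rmse'")
        if self.mutation_mode not in ("per_child", "per_bit"):
            raise IslandClockError("mutation_mode must be 'per_child' or 'per_bit'")

    @property
    def island_size(self) -> int:
        return self.population_size // self.n_islands


@dataclass
class FitnessResult:
    """Decomposed fitness of one chromosome (all units: years)."""

    per_tissue_mae: dict[str, float]
    mean_mae: float
    n_selected: int
    penalty: float
    fitness: float

    @classmethod
    def from_parts(cls, per_tissue: dict[str, float], n_selected: int, cpg_penalty: float):
        mean_mae = float(np.mean(list(per_tissue.values())))
        penalty = cpg_penalty * n_selected
        return cls(
            per_tissue_mae={k: float(v) for k, v in per_tissue.items()},
            mean_mae=mean_mae,
            n_selected=int(n_selected),
            penalty=penalty,
            fitness=mean_mae + penalty,
        )


@dataclass
class IslandState:
    population: list[np.ndarray]  # boolean bit vectors
    fitnesses: list[FitnessResult] | None
    generation: int
    rng: np.random.Generator


def _make_folds(tissues: np.ndarray, cv_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Tissue-stratified CV folds, reduced (with a log line) if a tissue is tiny."""
    _, counts = np.unique(tissues, return_counts=True)
    k = min(cv_folds, int(counts.min()))
    if k < cv_folds:
        logger.warning("smallest tissue has %d samples; folds reduced to %d", counts.min(), k)
    if k < 2:
        raise IslandClockError("need at least 2 samples per tissue for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(tissues)), tissues))


def _oof_ridge_predictions(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    alphas: np.ndarray,
) -> np.ndarray:
    """Out-of-fold ridge predictions for every penalty in ``alphas``.

    Features are standardised within each training fold; the ridge solution
    for the whole penalty grid is obtained from a single SVD per fold.
    Returns an (n_samples, n_alphas) array.
    """
    n = len(y)
    oof = np.empty((n, len(alphas)))
    for tr, te in folds:
        Xtr = X[tr]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0.0] = 1.0
        Z = (Xtr - mu) / sd
        ybar = y[tr].mean()
        yc = y[tr] - ybar
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        Uty = U.T @ yc
        shrink = s[:, None] / (s[:, None] ** 2 + alphas[None, :])  # (rank, n_alphas)
        W = Vt.T @ (shrink * Uty[:, None])  # (p, n_alphas)
        Zte = (X[te] - mu) / sd
        oof[te] = Zte @ W + ybar
    return oof


def _intercept_only_oof(y: np.ndarray, folds) -> np.ndarray:
    oof = np.empty(len(y))
    for tr, te in folds:
        oof[te] = y[tr].mean()
    return oof


def ridge_fitness(
    chromosome: np.ndarray,
    M_train: MethylationMatrix,
    sheet_train: pd.DataFrame,
    config: GAConfig,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> FitnessResult:
    """Evaluate one chromosome: CV ridge error, equal-weighted over tissues.

    The ridge penalty is chosen on a fixed log-spaced grid by minimising
    the overall out-of-fold error; per-tissue errors are then read off the
    out-of-fold predictions at that penalty.  The total fitness is the
    unweighted mean of per-tissue errors plus ``cpg_penalty`` years per
    selected CpG — exactly, so the decomposition can be audited.
    """
    meta = align_sheet(sheet_train, M_train)
    y = meta["age"].to_numpy()
    tissues = meta["tissue"].to_numpy()
    bits = np.asarray(chromosome, dtype=bool)
    if bits.shape != (M_train.n_cpgs,):
        raise IslandClockError("chromosome length must equal the candidate CpG count")
    if folds is None:
        folds = _make_folds(tissues, config.cv_folds, config.seed)
    n_selected = int(bits.sum())
    if n_selected == 0:
        pred = _intercept_only_oof(y, folds)
    else:
        X = M_train.values[:, bits]
        if np.isnan(X).any():
            raise IslandClockError("selected CpGs contain missing values; impute first")
        oof = _oof_ridge_predictions(X, y, folds, np.asarray(config.ridge_lambda_grid, dtype=float))
        if config.error_metric == "mae":
            overall = np.abs(oof - y[:, None]).mean(axis=0)
        else:
            overall = np.sqrt(((oof - y[:, None]) ** 2).mean(axis=0))
        pred = oof[:, int(np.argmin(overall))]
    if not np.all(np.isfinite(pred)):
        raise IslandClockError("non-finite fitness predictions")
    per_tissue = {}
    for t in np.unique(tissues):
        rows = tissues == t
        err = pred[rows] - y[rows]
        if config.error_metric == "mae":
            per_tissue[str(t)] = float(np.abs(err).mean())
        else:
            per_tissue[str(t)] = float(np.sqrt((err**2).mean()))
    return FitnessResult.from_parts(per_tissue, n_selected, config.cpg_penalty)


# ------------------------------------------------------------------ evolution

def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(len(bits))] = True
    return bits


def init_population(config: GAConfig, n_features: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random chromosomes with each bit set at ``init_density``."""
    if n_features < 1:
        raise IslandClockError("need at least one candidate feature")
    pop = []
    for _ in range(config.population_size):
        bits = rng.random(n_features) < config.init_density
        pop.append(_repair(bits, rng))
    return pop


def _rank(fitnesses: list[FitnessResult], population: list[np.ndarray]) -> list[int]:
    """Indices sorted best-first; ties broken by fewer set bits, then index."""
    return sorted(
        range(len(population)),
        key=lambda i: (fitnesses[i].fitness, int(population[i].sum()), i),
    )


def _crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover at a uniform cut position."""
    cut = int(rng.integers(1, len(a)))
    c1 = np.concatenate([a[:cut], b[cut:]])
    c2 = np.concatenate([b[:cut], a[cut:]])
    return c1, c2


def _mutate(bits: np.ndarray, config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    if config.mutation_mode == "per_child":
        if rng.random() < config.mutation_rate:
            bits = bits.copy()
            j = int(rng.integers(len(bits)))
            bits[j] = ~bits[j]
    else:
        flips = rng.random(len(bits)) < (config.mutation_rate / len(bits))
        if flips.any():
            bits = np.logical_xor(bits, flips)
    return _repair(bits, rng)


def evolve_generation(island: IslandState, fitness_fn, config: GAConfig) -> IslandState:
    """One generation: elitism, crossover among the elite, mutation.

    The lowest-fitness ``ceil(elite_fraction * island size)`` chromosomes
    survive unchanged; offspring are bred from uniformly drawn elite parent
    pairs (single-point crossover at ``crossover_rate``, otherwise copies)
    and each child is mutated with probability ``mutation_rate``.
    """
    size = len(island.population)
    if size < 2:
        raise IslandClockError("island size must be at least 2")
    if island.fitnesses is None:
        island.fitnesses = [fitness_fn(c) for c in island.population]
    rng = island.rng
    order = _rank(island.fitnesses, island.population)
    n_elite = math.ceil(config.elite_fraction * size)
    elite = [island.population[i].copy() for i in order[:n_elite]]
    offspring: list[np.ndarray] = []
    while len(offspring) < size - n_elite:
        pa = elite[int(rng.integers(n_elite))]
        pb = elite[int(rng.integers(n_elite))]
        if rng.random() < config.crossover_rate:
            c1, c2 = _crossover(pa, pb, rng)
        else:
            c1, c2 = pa.copy(), pb.copy()
        offspring.append(_mutate(c1, config, rng))
        if len(offspring) < size - n_elite:
            offspring.append(_mutate(c2, config, rng))
    return IslandState(
        population=elite + offspring,
        fitnesses=None,
        generation=island.generation + 1,
        rng=rng,
    )


def migrate(islands: list[IslandState], config: GAConfig) -> list[IslandState]:
    """Ring migration: each island's best replaces the next island's worst."""
    if len(islands) < 2:
        return islands
    bests = []
    for isl in islands:
        if isl.fitnesses is None:
            raise IslandClockError("islands must be evaluated before migration")
        order = _rank(isl.fitnesses, isl.population)
        bests.append((isl.population[order[0]].copy(), isl.fitnesses[order[0]]))
    for i, isl in enumerate(islands):
        migrant_bits, migrant_fit = bests[(i - 1) % len(islands)]
        order = _rank(isl.fitnesses, isl.population)
        worst = order[-1]
        isl.population[worst] = migrant_bits
        isl.fitnesses[worst] = migrant_fit
    return islands


def run_ga(
    M_train: MethylationMatrix,
    sheet_train: pd.DataFrame,
    candidate_cpgs: list[str],
    config: GAConfig,
) -> tuple[np.ndarray, FitnessResult, pd.DataFrame]:
    """Run the island GA over the candidate CpGs.

    Returns the best chromosome ever evaluated (a boolean vector over
    ``candidate_cpgs``), its fitness decomposition, and a per-generation
    history frame (generation, island, best_fitness, mean_fitness,
    best_n_selected).  The run is fully determined by ``config.seed``;
    fitness evaluations are memoised, so cloned chromosomes cost nothing.
    """
    config.validate()
    sub = M_train.subset_cpgs(candidate_cpgs)
    meta = align_sheet(sheet_train, sub)
    folds = _make_folds(meta["tissue"].to_numpy(), config.cv_folds, config.seed)

    cache: dict[bytes, FitnessResult] = {}

    def fitness_fn(bits: np.ndarray) -> FitnessResult:
        key = np.packbits(bits).tobytes()
        hit = cache.get(key)
        if hit is None:
            hit = ridge_fitness(bits, sub, sheet_train, config, folds=folds)
            cache[key] = hit
        return hit

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_islands + 1)
    init_rng = np.random.default_rng(child_seeds[0])
    pop = init_population(config, len(candidate_cpgs), init_rng)
    size = config.island_size
    islands = [
        IslandState(
            population=pop[i * size : (i + 1) * size],
            fitnesses=None,
            generation=0,
            rng=np.random.default_rng(child_seeds[i + 1]),
        )
        for i in range(config.n_islands)
    ]

    best_bits: np.ndarray | None = None
    best_fit: FitnessResult | None = None
    history_rows = []

    def consider(bits: np.ndarray, fit: FitnessResult) -> None:
        nonlocal best_bits, best_fit
        if (
            best_fit is None
            or fit.fitness < best_fit.fitness
            or (fit.fitness == best_fit.fitness and fit.n_selected < best_fit.n_selected)
        ):
            best_bits, best_fit = bits.copy(), fit

    for gen in range(1, config.n_generations + 1):
        for idx, isl in enumerate(islands):
            if isl.fitnesses is None:
                isl.fitnesses = [fitness_fn(c) for c in isl.population]
            order = _rank(isl.fitnesses, isl.population)
            consider(isl.population[order[0]], isl.fitnesses[order[0]])
            history_rows.append(
                {
                    "generation": gen,
                    "island": idx,
                    "best_fitness": isl.fitnesses[order[0]].fitness,
                    "mean_fitness": float(np.mean([f.fitness for f in isl.fitnesses])),
                    "best_n_selected": isl.fitnesses[order[0]].n_selected,
                }
            )
        if config.n_islands > 1 and gen % config.migration_interval == 0:
            islands = migrate(islands, config)
        islands = [evolve_generation(isl, fitness_fn, config) for isl in islands]

    assert best_bits is not None and best_fit is not None
    history = pd.DataFrame(history_rows)
    return best_bits, best_fit, history
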