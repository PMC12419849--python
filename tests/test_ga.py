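"""Fitness function and island-evolution mechanics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from islandclock import IslandClockError, simulate_dataset
from islandclock.ga import (
    FitnessResult,
    GAConfig,
    IslandState,
    _crossover,
    evolve_generation,
    init_population,
    migrate,
    ridge_fitness,
    run_ga,
)
from .conftest import two_tissue_truth


def _planted_bits(matrix, truth, candidates=None):
    cpgs = candidates if candidates is not None else matrix.cpg_ids
    planted = set(truth.planted_age_cpgs)
    return np.array([c in planted for c in cpgs])


# ------------------------------------------------------------------- fitness

def test_fitness_decomposition_arithmetic():
    """Two tissues with MAEs 2 and 6 and 100 selected CpGs: mean 4, fitness 5."""
    fr = FitnessResult.from_parts({"a": 2.0, "b": 6.0}, n_selected=100, cpg_penalty=0.01)
    assert fr.mean_mae == 4.0
    assert fr.penalty == pytest.approx(1.0)
    assert fr.fitness == pytest.approx(5.0)
    assert fr.fitness - fr.penalty == fr.mean_mae  # exact decomposition


def test_fitness_on_planted_chromosome_is_mostly_penalty(noiseless_dataset):
    """With no noise, the planted chromosome predicts age almost perfectly,
    so fitness ~ 0.01 x (number planted)."""
    matrix, sheet, truth = noiseless_dataset
    cfg = GAConfig(seed=0)
    bits = _planted_bits(matrix, truth)
    fr = ridge_fitness(bits, matrix, sheet, cfg)
    assert all(v < 0.1 for v in fr.per_tissue_mae.values())
    assert fr.penalty == pytest.approx(0.01 * bits.sum())
    assert fr.fitness == pytest.approx(fr.penalty, abs=0.1)


def test_adding_noise_cpg_raises_fitness(noiseless_dataset):
    """On noiseless data the planted chromosome already predicts age, so
    appending one pure-noise CpG costs close to the full 0.01-year penalty:
    fitness rises by >= 0.005 in at least 95 of 100 trials."""
    matrix, sheet, truth = noiseless_dataset
    cfg = GAConfig(seed=0)
    base_bits = _planted_bits(matrix, truth)
    base = ridge_fitness(base_bits, matrix, sheet, cfg)
    noise_cols = np.flatnonzero(~base_bits & ~np.isin(matrix.cpg_ids, truth.identity_cpg_ids))
    rng = np.random.default_rng(42)
    wins = 0
    trials = 100
    for _ in range(trials):
        bits = base_bits.copy()
        bits[rng.choice(noise_cols)] = True
        fr = ridge_fitness(bits, matrix, sheet, cfg)
        wins += (fr.fitness - base.fitness) >= 0.005
    assert wins >= 95


def test_all_zero_chromosome_is_intercept_only(small_dataset):
    matrix, sheet, _ = small_dataset
    cfg = GAConfig(seed=0)
    fr = ridge_fitness(np.zeros(matrix.n_cpgs, dtype=bool), matrix, sheet, cfg)
    assert fr.n_selected == 0 and fr.penalty == 0.0
    ages = sheet["age"].to_numpy()
    # intercept-only CV error is of the order of the age spread
    assert fr.mean_mae > 0.5 * np.abs(ages - ages.mean()).mean()


def test_equal_tissue_weighting(noiseless_dataset):
    """Duplicating every sample of one tissue must leave the mean per-tissue
    error essentially unchanged on noiseless data."""
    matrix, sheet, truth = noiseless_dataset
    cfg = GAConfig(seed=0)
    bits = _planted_bits(matrix, truth)
    base = ridge_fitness(bits, matrix, sheet, cfg)
    rows = sheet["tissue"].to_numpy() == "b"
    dup_vals = np.vstack([matrix.values, matrix.values[rows]])
    dup_ids = matrix.sample_ids + [f"{s}_dup" for s, r in zip(matrix.sample_ids, rows) if r]
    from islandclock import MethylationMatrix

    dup_matrix = MethylationMatrix(dup_vals, dup_ids, matrix.cpg_ids, "m")
    dup_sheet = pd.concat(
        [sheet, sheet[rows].assign(sample_id=lambda d: d["sample_id"] + "_dup")], ignore_index=True
    )
    dup = ridge_fitness(bits, dup_matrix, dup_sheet, cfg)
    assert abs(dup.mean_mae - base.mean_mae) < 0.1


# ------------------------------------------------------------------ mechanics

def test_init_population_density_and_determinism():
    cfg = GAConfig(population_size=200, init_density=0.10, seed=0)
    rng = np.random.default_rng(0)
    pop = init_population(cfg, n_features=400, rng=rng)
    assert len(pop) == 200
    assert all(b.any() for b in pop)  # all-zero repaired
    mean_bits = np.mean([b.sum() for b in pop])
    expect = 400 * 0.10
    sigma = np.sqrt(400 * 0.1 * 0.9)
    assert abs(mean_bits - expect) < 3 * sigma / np.sqrt(200)
    pop2 = init_population(cfg, n_features=400, rng=np.random.default_rng(0))
    assert all(np.array_equal(a, b) for a, b in zip(pop, pop2))
    dense = init_population(GAConfig(init_density=1.0), 10, np.random.default_rng(0))
    assert all(b.all() for b in dense)


def test_single_point_crossover_mechanics():
    a = np.array([0, 0, 0, 0, 1, 1], dtype=bool)
    b = np.array([1, 1, 0, 0, 0, 0], dtype=bool)

    class FixedCut:
        def integers(self, *args, **kwargs):
            return 2

    c1, c2 = _crossover(a, b, FixedCut())
    np.testing.assert_array_equal(c1, [0, 0, 0, 0, 0, 0])  # repaired downstream
    np.testing.assert_array_equal(c2, [1, 1, 0, 0, 1, 1])


def test_noop_evolution_preserves_elite(small_dataset):
    matrix, sheet, _ = small_dataset
    cfg = GAConfig(population_size=8, n_islands=1, crossover_rate=0.0, mutation_rate=0.0, seed=0)
    rng = np.random.default_rng(0)
    pop = init_population(cfg, matrix.n_cpgs, rng)
    fit = lambda b: ridge_fitness(b, matrix, sheet, cfg)  # noqa: E731
    island = IslandState(pop, [fit(b) for b in pop], 0, rng)
    best = min(island.fitnesses, key=lambda f: f.fitness)
    nxt = evolve_generation(island, fit, cfg)
    assert len(nxt.population) == 8
    # with no crossover and no mutation every chromosome is an elite copy
    assert all(np.array_equal(c, nxt.population[0]) for c in nxt.population)
    assert fit(nxt.population[0]).fitness == best.fitness


def test_migration_conserves_sizes_and_best(small_dataset):
    matrix, sheet, _ = small_dataset
    cfg = GAConfig(population_size=12, n_islands=3, seed=0)
    rng = np.random.default_rng(1)
    fit = lambda b: ridge_fitness(b, matrix, sheet, cfg)  # noqa: E731
    islands = []
    for i in range(3):
        pop = init_population(GAConfig(population_size=4, seed=i), matrix.n_cpgs, np.random.default_rng(i))
        islands.append(IslandState(pop, [fit(b) for b in pop], 0, rng))
    global_best = min(f.fitness for isl in islands for f in isl.fitnesses)
    out = migrate(islands, cfg)
    assert all(len(isl.population) == 4 for isl in out)
    assert min(f.fitness for isl in out for f in isl.fitnesses) <= global_best
    # identical islands stay identical to each other: each receives the same
    # migrant (the shared best) over its worst member
    pop = init_population(GAConfig(population_size=4, seed=9), matrix.n_cpgs, np.random.default_rng(9))
    fits = [fit(b) for b in pop]
    twins = [IslandState([b.copy() for b in pop], list(fits), 0, rng) for _ in range(2)]
    out = migrate(twins, cfg)
    keys0 = sorted(tuple(b.tolist()) for b in out[0].population)
    keys1 = sorted(tuple(b.tolist()) for b in out[1].population)
    assert keys0 == keys1
    assert min(f.fitness for f in out[0].fitnesses) == min(f.fitness for f in fits)
    # uniform populations are a strict fixed point of migration
    uniform = [IslandState([pop[0].copy() for _ in range(4)], [fits[0]] * 4, 0, rng) for _ in range(2)]
    out = migrate(uniform, cfg)
    for isl in out:
        assert all(np.array_equal(b, pop[0]) for b in isl.population)


def test_run_ga_bookkeeping_elitism_and_determinism():
    """History covers every generation and island; the best-fitness trace
    never worsens (elitism); identical seeds give identical selections."""
    truth = two_tissue_truth(seed=2, n_cpgs=120, n_shared_age_cpgs=6,
                             n_specific_age_cpgs_per_tissue=2, n_identity_cpgs=10)
    matrix, sheet, truth = simulate_dataset(truth)
    cfg = GAConfig(population_size=16, n_islands=2, n_generations=12, seed=5)
    bits, fit, hist = run_ga(matrix, sheet, matrix.cpg_ids, cfg)
    assert len(hist) == 12 * 2
    assert fit.fitness == pytest.approx(fit.mean_mae + fit.penalty, abs=1e-12)
    global_best = hist.groupby("generation")["best_fitness"].min()
    assert (global_best.diff().dropna() <= 1e-12).all()
    bits2, fit2, hist2 = run_ga(matrix, sheet, matrix.cpg_ids, cfg)
    np.testing.assert_array_equal(bits, bits2)
    pd.testing.assert_frame_equal(hist, hist2)


def test_elitism_trace_non_increasing_across_seeds(small_dataset):
    matrix, sheet, _ = small_dataset
    for seed in range(5):
        cfg = GAConfig(population_size=8, n_islands=2, n_generations=6, seed=seed)
        _, _, hist = run_ga(matrix, sheet, matrix.cpg_ids[:60], cfg)
        trace = hist.groupby("generation")["best_fitness"].min()
        assert (trace.diff().dropna() <= 1e-12).all()


def test_config_validation():
    with pytest.raises(IslandClockError):
        GAConfig(population_size=10, n_islands=3).validate()
    with pytest.raises(IslandClockError):
        GAConfig(mutation_rate=1.5).validate()
    GAConfig().validate()
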