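"""Genetic-algorithm descriptor subset selection for MLR.

Binary chromosomes (bit = column in/out), fitness = leave-one-out Q2, with a
hard cap on subset size.  Tournament selection, uniform crossover, per-bit
mutation and elitism; fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import MlrModel, fit_ols

__all__ = ["GaConfig", "ga_search", "exhaustive_search"]


@dataclass(frozen=True)
class GaConfig:
    population: int = 100
    generations: int = 500
    crossover_prob: float = 0.7
    mutation_prob: float | None = None  # default: 2 / n_descriptors
    max_subset: int = 6
    elitism: int = 2
    tournament: int = 2
    seed: int = 0
    top_m: int = 10

    def __post_init__(self):
        if not (0 <= self.crossover_prob <= 1):
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.mutation_prob is not None and not (0 <= self.mutation_prob <= 1):
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.max_subset < 1:
            raise ValueError("max_subset must be >= 1")
        if self.population < 2:
            raise ValueError("population must be >= 2")


def _evaluate(mask: np.ndarray, X: pd.DataFrame, y: pd.Series,
              cache: dict) -> float:
    key = mask.tobytes()
    if key in cache:
        return cache[key]
    k = int(mask.sum())
    if k == 0 or len(X) <= k + 1:
        fit = -np.inf
    else:
        try:
            fit = fit_ols(X.loc[:, mask.astype(bool)], y).q2
        except ValueError:
            fit = -np.inf
    cache[key] = fit
    return fit


def _repair(mask: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    on = np.flatnonzero(mask)
    if len(on) > cap:
        drop = rng.choice(on, size=len(on) - cap, replace=False)
        mask = mask.copy()
        mask[drop] = 0
    return mask


def ga_search(X: pd.DataFrame, y: pd.Series,
              cfg: GaConfig | None = None) -> list[MlrModel]:
    """Evolve descriptor subsets; returns the distinct top models by Q2."""
    cfg = cfg or GaConfig()
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 candidate descriptors")
    if cfg.max_subset >= len(X) - 1:
        raise ValueError("max_subset too large for the sample size")
    rng = np.random.default_rng(cfg.seed)
    mut = cfg.mutation_prob if cfg.mutation_prob is not None else 2.0 / p
    cache: dict = {}

    # initial population: random subsets of size 1..max_subset
    pop = np.zeros((cfg.population, p), dtype=np.int8)
    for i in range(cfg.population):
        size = rng.integers(1, cfg.max_subset + 1)
        pop[i, rng.choice(p, size=size, replace=False)] = 1

    fitness = np.array([_evaluate(m, X, y, cache) for m in pop])

    for _ in range(cfg.generations):
        order = np.argsort(-fitness)
        next_pop = [pop[i].copy() for i in order[:cfg.elitism]]
        while len(next_pop) < cfg.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, cfg.population, size=cfg.tournament)
                parents.append(pop[idx[np.argmax(fitness[idx])]].copy())
            a, b = parents
            if rng.random() < cfg.crossover_prob:
                swap = rng.random(p) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                flip = rng.random(p) < mut
                child[flip] ^= 1
                child = _repair(child, cfg.max_subset, rng)
                if len(next_pop) < cfg.population:
                    next_pop.append(child)
        pop = np.array(next_pop, dtype=np.int8)
        fitness = np.array([_evaluate(m, X, y, cache) for m in pop])

    # distinct top-m subsets over everything ever evaluated
    scored = sorted(
        ((fit, key) for key, fit in cache.items() if np.isfinite(fit)),
        key=lambda t: -t[0])
    models = []
    seen = set()
    for fit, key in scored:
        if key in seen:
            continue
        seen.add(key)
        mask = np.frombuffer(key, dtype=np.int8).astype(bool)
        models.append(fit_ols(X.loc[:, mask], y))
        if len(models) >= cfg.top_m:
            break
    return models


def exhaustive_search(X: pd.DataFrame, y: pd.Series,
                      max_subset: int) -> MlrModel:
    """Brute-force best-Q2 subset up to ``max_subset`` columns (oracle)."""
    from itertools import combinations

    best = None
    for k in range(1, max_subset + 1):
        for sub in combinations(X.columns, k):
            try:
                model = fit_ols(X.loc[:, list(sub)], y)
            except ValueError:
                continue
            if best is None or model.q2 > best.q2:
                best = model
    if best is None:
        raise ValueError("no valid subset found")
    return best
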