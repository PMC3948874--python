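"""Synthetic fixtures: inputs with the statistical structure the analysis
assumes, generated without running evolution.

Three generators:

* :func:`generate_logistic_outcomes` — run-level binary outcomes following a
  known logistic relation between poison level and avoidance, with final
  abundances synthesized consistently with the predation-pressure classifier
  (avoid: 900–1,000; not avoid: 300–700 — the disjoint ranges keep classifier
  and model tests from interacting);
* :func:`generate_timeseries_fixture` — canned replicate time series with
  known per-update means and display proportions, for the trajectory and
  mimicry summaries;
* :func:`worked_example_scenario` — a deterministic miniature world encoding
  the poisoned-predator bookkeeping example (a 9-unit predator, a 10-unit
  poisonous prey at poison level 0.1, then either eight 1-unit prey or one
  8-unit prey to climb back to the 10-unit reproduction threshold at 25%
  conversion efficiency).

All fixtures are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .analysis import OUTCOME_COLUMNS, PRESSURE_CUTOFF
from .config import ExperimentConfig, POISON_LEVEL_SWEEP
from .ecology import AttackOutcome, resolve_attack
from .sim import RunRecord
from .world import PreyClass, World
from . import instructions as ins


def generate_logistic_outcomes(intercept: float, slope: float,
                               poison_levels=POISON_LEVEL_SWEEP,
                               n_per_level: int = 30,
                               seed: int | None = None,
                               predator_range: tuple[int, int] = (120, 400)) -> pd.DataFrame:
    """Draw run outcomes with P(avoid) = logistic(intercept + slope * level).

    Returns the outcome table consumed by the avoidance model; abundances are
    consistent with the classifier by construction (below the cutoff iff not
    avoided).
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for p in poison_levels:
        prob = expit(intercept + slope * p)
        for _ in range(n_per_level):
            avoid = rng.random() < prob
            if avoid:
                abundance = int(rng.integers(900, 1001))
            else:
                abundance = int(rng.integers(300, 701))
            rows.append((float(p), abundance, abundance < PRESSURE_CUTOFF,
                         int(rng.integers(*predator_range))))
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def _largest_remainder_counts(total: int, proportions: np.ndarray) -> np.ndarray:
    """Integer counts summing to ``total`` with the given proportions
    (largest-remainder rounding, deterministic)."""
    raw = proportions * total
    counts = np.floor(raw).astype(np.int64)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def generate_timeseries_fixture(mean_functions, noise_sd: float = 0.0,
                                n_replicates: int = 5, n_updates: int = 100,
                                record_every: int = 1,
                                display_proportions=(1.0, 0.0, 0.0),
                                cap: int = 1000, seed: int | None = None,
                                treatment: str = "fixture",
                                poison_level: float = 0.1) -> list[RunRecord]:
    """Replicate run records whose series are known mean functions plus iid
    Gaussian noise, clamped to [0, cap] and rounded.

    ``mean_functions`` maps the series names ``non-poisonous``, ``mimic``,
    ``poisonous``, ``predator`` to either a constant or a callable of the
    update array; missing series default to 0.  Display counts split the
    mimic abundance by ``display_proportions`` (largest-remainder rounding,
    exact at noise 0 when the proportions and abundance are compatible).
    """
    updates = np.arange(0, n_updates + 1, record_every, dtype=np.int64)
    names = ("non-poisonous", "mimic", "poisonous", "predator")
    means = np.zeros((len(updates), 4))
    for s, name in enumerate(names):
        f = mean_functions.get(name, 0.0)
        means[:, s] = f(updates) if callable(f) else float(f)
    props = np.asarray(display_proportions, dtype=float)
    if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("display_proportions must be 3 values summing to 1")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_replicates):
        noisy = means + rng.normal(0.0, noise_sd, size=means.shape) if noise_sd > 0 else means.copy()
        series = np.clip(np.rint(noisy), 0, cap).astype(np.int64)
        displays = np.stack([_largest_remainder_counts(m, props) for m in series[:, 1]])
        cfg = {"poison_level": poison_level, "class_cap": cap, "treatment": treatment}
        records.append(RunRecord(
            treatment=treatment, seed=(0 if seed is None else int(seed)) + rep,
            updates=updates.copy(), abundance=series[:, :3],
            predators=series[:, 3], displays=displays, config=cfg,
        ))
    return records


@dataclass
class WorkedExample:
    """Deterministic attack-arithmetic scenario.

    One predator holding 9 resource units faces a queue of prey stacked in
    the cell in front of it: first a poisonous prey holding 10 units, then
    the configured refeeding plan.  Ecology: conversion efficiency 0.25,
    poison level 0.1, reproduction threshold 10, prey floor disabled.
    ``kill_next()`` resolves one generalist attack at a time.
    """

    world: World
    predator: int
    poisonous_prey: int
    safe_prey: list[int] = field(default_factory=list)

    def kill_next(self) -> AttackOutcome:
        return resolve_attack(self.world, self.predator, {0, 1, 2})

    @property
    def predator_stored(self) -> float:
        return float(self.world.organism(self.predator).stored)

    @property
    def can_reproduce(self) -> bool:
        return self.predator_stored >= self.world.config.reproduction_threshold


def worked_example_scenario(prey_plan: str = "eight_ones") -> WorkedExample:
    """Build the miniature poisoned-predator world.

    ``prey_plan``: ``"eight_ones"`` queues eight prey with 1 unit each;
    ``"one_eight"`` queues a single prey with 8 units.
    """
    cfg = ExperimentConfig(
        width=8, height=8, conversion_efficiency=0.25, poison_level=0.1,
        reproduction_threshold=10.0, prey_floor=0, class_cap=1000,
        n_updates=0, n_replicates=1,
    )
    world = World(cfg, seed=0)
    idle = np.array([ins.NOP_A], dtype=np.int8)
    predator = world.add_organism(idle, None, 3, 3, facing=2, stored=9.0,
                                  is_predator=True)
    if prey_plan == "eight_ones":
        stores = [1.0] * 8
    elif prey_plan == "one_eight":
        stores = [8.0]
    else:
        raise ValueError(f"unknown prey_plan {prey_plan!r}")
    # stack the queue in the faced cell; the occupancy list is LIFO, so add
    # the refeeding prey first and the poisonous prey last (attacked first)
    safe = [world.add_organism(idle, PreyClass.NON_POISONOUS, 4, 3, stored=s)
            for s in stores]
    poisonous = world.add_organism(idle, PreyClass.POISONOUS, 4, 3, stored=10.0)
    return WorkedExample(world=world, predator=predator,
                         poisonous_prey=poisonous, safe_prey=safe)
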