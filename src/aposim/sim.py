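"""Scheduler: drives updates, replicates and treatments, and records the
per-update time series behind the population-trajectory and mimicry analyses.

An *update* is the simulation time unit: every alive organism executes a
fixed instruction budget (default 30) in a freshly shuffled order, then the
resource layers regrow and ages advance.  A *replicate* starts from three
ancestors (one prey of each class, each with a fresh random forager genome)
and runs a configured number of updates, recording the class abundances,
predator count and mimic display counts on a fixed interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .config import ExperimentConfig
from .instructions import ancestral_genome
from .world import CLASS_NAMES, PreyClass, World


@dataclass
class RunRecord:
    """Per-update time series and final snapshot of one replicate.

    ``abundance`` has shape (n_records, 3) (classes in :class:`PreyClass`
    order), ``predators`` (n_records,), ``displays`` (n_records, 3) — among
    alive mimic-class prey, how many display each class.  ``config`` is the
    treatment echo that makes any serialization self-describing.
    """

    treatment: str
    seed: int
    updates: np.ndarray
    abundance: np.ndarray
    predators: np.ndarray
    displays: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.updates)
        if not (len(self.abundance) == len(self.predators) == len(self.displays) == n):
            raise ValueError("series lengths disagree")

    @property
    def n_records(self) -> int:
        return len(self.updates)

    @property
    def final_abundance(self) -> np.ndarray:
        return self.abundance[-1]

    @property
    def final_predators(self) -> int:
        return int(self.predators[-1])

    def final_display_proportions(self) -> np.ndarray:
        """Final-update proportions of mimic-class prey displaying each class
        (NaN when no mimics are alive)."""
        total = self.displays[-1].sum()
        if total == 0:
            return np.full(3, np.nan)
        return self.displays[-1] / total

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: abundance rows for the three prey classes and the
        predator count, plus display-count rows for the mimic class."""
        rows = []
        for t, ab, np_, dc in zip(self.updates, self.abundance, self.predators, self.displays):
            for c in range(3):
                rows.append((int(t), CLASS_NAMES[c], int(ab[c]), "", np.nan))
            rows.append((int(t), "predator", int(np_), "", np.nan))
            for c in range(3):
                rows.append((int(t), "mimic", np.nan, CLASS_NAMES[c], int(dc[c])))
        df = pd.DataFrame(rows, columns=["update", "class", "abundance", "displayed_as", "count"])
        df["replicate"] = 0
        df["treatment"] = self.treatment
        df["seed"] = self.seed
        return df


def step_organism(world: World, i: int) -> str:
    """Execute one instruction of organism ``i``; returns the mnemonic of the
    executed opcode (the single-step entry point of the VM)."""
    from .instructions import MNEMONICS

    if not world._alive[i]:
        raise ValueError(f"organism {i} is not alive")
    op = K.execute_instruction_entry(*world.kargs, i)
    return MNEMONICS[int(op)]


def run_update(world: World) -> World:
    """Advance the world exactly one update (shuffled turns, 30 instructions
    each, regrowth, ageing)."""
    K.step_update(*world.kargs)
    return world


def _record_state(world: World):
    return (world.update, world.prey_counts, world.n_predators, world.display_counts())


def run_replicate(cfg: ExperimentConfig, seed: int | None = None) -> RunRecord:
    """Run one replicate: three ancestors, ``cfg.n_updates`` updates, series
    recorded at ``cfg.record_every`` (always including update 0 and the final
    update)."""
    seed = cfg.seed if seed is None else int(seed)
    world = World(cfg, seed=seed)
    init_rng = np.random.default_rng(seed)
    for cls in PreyClass:
        g = ancestral_genome(cfg.genome_length, init_rng)
        x = int(init_rng.integers(cfg.width))
        y = int(init_rng.integers(cfg.height))
        facing = int(init_rng.integers(8))
        world.add_organism(g, cls, x, y, facing=facing)

    records = [_record_state(world)]
    done = 0
    while done < cfg.n_updates:
        chunk = min(cfg.record_every, cfg.n_updates - done)
        K.run_updates(*world.kargs, chunk)
        done += chunk
        records.append(_record_state(world))

    updates = np.array([r[0] for r in records], dtype=np.int64)
    abundance = np.stack([r[1] for r in records]).astype(np.int64)
    predators = np.array([r[2] for r in records], dtype=np.int64)
    displays = np.stack([r[3] for r in records]).astype(np.int64)
    rec = RunRecord(
        treatment=cfg.label, seed=seed, updates=updates, abundance=abundance,
        predators=predators, displays=displays, config=cfg.to_dict(),
    )
    rec.world = world  # final state kept for snapshot consumers
    return rec


def run_treatment(cfg: ExperimentConfig, n_replicates: int | None = None,
                  base_seed: int | None = None, progress: bool = False) -> list[RunRecord]:
    """Run independent replicates with seeds ``base_seed + i``; order-stable."""
    n = cfg.n_replicates if n_replicates is None else int(n_replicates)
    if n < 1:
        raise ValueError("n_replicates must be >= 1")
    base = cfg.seed if base_seed is None else int(base_seed)
    out = []
    for i in range(n):
        rec = run_replicate(cfg, seed=(base + i) & 0x7FFFFFFF)
        out.append(rec)
        if progress:
            print(f"[{cfg.label}] replicate {i + 1}/{n}: "
                  f"prey={rec.final_abundance.tolist()} predators={rec.final_predators}")
    return out
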