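"""World state: the resource layers, the organism tables and their indexes.

``World`` owns the column-table state the JIT kernels operate on and offers a
Python-side API for building and inspecting worlds: adding organisms directly
(used by fixtures and tests), reading per-class counts, and viewing a single
organism as an object.  All heavy lifting during simulation happens in
:mod:`aposim._kernels`; the per-field attributes here (``_alive``, ``_x``,
...) are zero-copy column views into the same memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from . import _kernels as K
from .config import ExperimentConfig
from .grid import ResourceGrid
from .instructions import InstructionSet


class PreyClass(IntEnum):
    """The three prey morph classes (closed enumeration)."""

    NON_POISONOUS = 0
    MIMIC = 1
    POISONOUS = 2


CLASS_NAMES = ("non-poisonous", "mimic", "poisonous")


@dataclass
class OrganismView:
    """Read-only snapshot of one organism's state."""

    id: int
    alive: bool
    is_predator: bool
    true_class: PreyClass | None
    displayed_class: PreyClass | None
    stored: float
    position: tuple[int, int]
    facing: int
    age: int


class World:
    """Spatial world: resource layers plus all organisms.

    Parameters
    ----------
    config : ExperimentConfig
        The treatment configuration; geometry, ecology and genetics are all
        read from it.
    seed : int, optional
        Seeds the simulation RNG (shared by every stochastic rule).  When
        omitted, ``config.seed`` is used.
    """

    def __init__(self, config: ExperimentConfig | None = None, seed: int | None = None):
        cfg = config or ExperimentConfig()
        cfg.validate()
        self.config = cfg
        C = cfg.capacity
        W, H = cfg.width, cfg.height
        L = 3 if cfg.per_class_resources else 1
        self.n_layers = L
        gmax = cfg.max_genome_length

        self._oi8 = np.zeros((C, 4), dtype=np.int8)
        self._oi8[:, K.TCLASS] = -1
        self._oi8[:, K.DISP] = -1
        self._oi32 = np.zeros((C, 9), dtype=np.int32)
        self._oi32[:, K.GLEN] = 1
        self._oi32[:, K.NXT] = -1
        self._oi32[:, K.PRV] = -1
        self._of8 = np.zeros((C, 4), dtype=np.float64)
        self._genome = np.zeros((C, gmax), dtype=np.int8)
        self._cell_head = np.full(W * H, -1, dtype=np.int32)
        self._members = np.zeros((3, cfg.class_cap + 1), dtype=np.int32)
        self._free = np.arange(C - 1, -1, -1, dtype=np.int32)
        self._meta = np.zeros(8, dtype=np.int64)
        self._meta[K.M_NFREE] = C
        self._stock = np.full((L, H, W), float(cfg.initial_stock), dtype=np.float64)
        self._rs = np.zeros(1, dtype=np.uint64)

        # named column views (shared memory, zero copy)
        self._alive = self._oi8[:, K.ALIVE]
        self._is_pred = self._oi8[:, K.ISPRED]
        self._tclass = self._oi8[:, K.TCLASS]
        self._disp = self._oi8[:, K.DISP]
        self._x = self._oi32[:, K.X]
        self._y = self._oi32[:, K.Y]
        self._facing = self._oi32[:, K.FACING]
        self._age = self._oi32[:, K.AGE]
        self._ip = self._oi32[:, K.IP]
        self._glen = self._oi32[:, K.GLEN]
        self._nxt = self._oi32[:, K.NXT]
        self._prv = self._oi32[:, K.PRV]
        self._cpos = self._oi32[:, K.CPOS]
        self._stored = self._of8[:, K.STORED]
        self._regs = self._of8[:, 1:]
        self._class_n = self._meta[K.M_CLASS0:K.M_CLASS0 + 3]

        self.pf = np.array([
            cfg.conversion_efficiency, cfg.poison_level, cfg.fidelity,
            cfg.reproduction_threshold, cfg.max_per_cell, cfg.inflow_rate,
            cfg.p_substitution, cfg.p_insertion, cfg.p_deletion,
            cfg.birth_fractions[0], cfg.birth_fractions[1], cfg.birth_fractions[2],
        ], dtype=np.float64)
        self.pi = np.array([
            W, H, cfg.class_cap, cfg.prey_floor, cfg.max_age, cfg.exec_budget,
            int(cfg.mimicry_enabled), int(cfg.poisonous_kills_yield_gain),
            gmax, int(not cfg.per_class_resources), 0, 0,
        ], dtype=np.int64)
        self.mut_pool = InstructionSet(attack_enabled=cfg.attack_enabled).opcodes
        self.kargs = (self._oi8, self._oi32, self._of8, self._genome,
                      self._cell_head, self._members, self._free, self._meta,
                      self._stock, self._rs, self.pf, self.pi, self.mut_pool)
        self.reseed(cfg.seed if seed is None else seed)

        # per-class grid views sharing the stock memory
        self.grids = []
        for layer in range(L):
            g = ResourceGrid.__new__(ResourceGrid)
            g._width, g._height = W, H
            g.max_per_cell = cfg.max_per_cell
            g.inflow_rate = cfg.inflow_rate
            g.stock = self._stock[layer]
            self.grids.append(g)

    # -- RNG ---------------------------------------------------------------

    def reseed(self, seed: int) -> None:
        """Seed the simulation RNG (all stochastic rules flow from it)."""
        self._rs[0] = np.uint64(K.splitmix64(int(seed)))

    # -- construction ------------------------------------------------------

    def layer_of(self, prey_class: int) -> int:
        return 0 if self.n_layers == 1 else int(prey_class)

    def add_organism(self, genome, true_class: PreyClass | int | None,
                     x: int, y: int, facing: int = 2, stored: float = 0.0,
                     is_predator: bool = False, displayed: PreyClass | int | None = None,
                     enforce_cap: bool = False) -> int:
        """Place an organism directly into the world and return its id.

        Used by replicate initialization, fixtures and tests; births during
        simulation go through the reproduction kernel instead.  ``true_class``
        of ``None`` requires ``is_predator=True``.
        """
        cfg = self.config
        genome = np.asarray(genome, dtype=np.int8)
        if genome.ndim != 1 or len(genome) < 1 or len(genome) > cfg.max_genome_length:
            raise ValueError("genome must be 1-D with 1..max_genome_length instructions")
        if self._meta[K.M_NFREE] == 0:
            raise RuntimeError("organism capacity exhausted")
        if true_class is None and not is_predator:
            raise ValueError("only predators may lack a prey class")
        x, y = x % cfg.width, y % cfg.height
        self._meta[K.M_NFREE] -= 1
        i = int(self._free[self._meta[K.M_NFREE]])
        self._alive[i] = 1
        self._is_pred[i] = int(bool(is_predator))
        tc = -1 if true_class is None else int(true_class)
        self._tclass[i] = tc
        if displayed is None:
            self._disp[i] = tc
        else:
            if tc != int(PreyClass.MIMIC) and int(displayed) != tc:
                raise ValueError("only mimics can display a class other than their own")
            self._disp[i] = int(displayed)
        self._stored[i] = float(stored)
        self._x[i], self._y[i] = x, y
        self._facing[i] = int(facing) % 8
        self._age[i] = 0
        self._ip[i] = 0
        self._regs[i, :] = 0.0
        self._glen[i] = len(genome)
        self._genome[i, : len(genome)] = genome
        self._link_cell(i, y * cfg.width + x)
        if is_predator:
            self._meta[K.M_NPRED] += 1
        else:
            self._members[tc, self._class_n[tc]] = i
            self._cpos[i] = self._class_n[tc]
            self._class_n[tc] += 1
            if enforce_cap:
                K.enforce_class_cap_entry(*self.kargs, tc)
        return i

    def _link_cell(self, i: int, cell: int) -> None:
        head = int(self._cell_head[cell])
        self._nxt[i] = head
        self._prv[i] = -1
        if head >= 0:
            self._prv[head] = i
        self._cell_head[cell] = i

    def remove_organism(self, i: int) -> None:
        if not self._alive[i]:
            raise ValueError(f"organism {i} is not alive")
        K.remove_organism_entry(*self.kargs, i)

    # -- inspection --------------------------------------------------------

    @property
    def update(self) -> int:
        return int(self._meta[K.M_UPDATE])

    @property
    def n_predators(self) -> int:
        return int(self._meta[K.M_NPRED])

    @property
    def prey_counts(self) -> np.ndarray:
        """Per-class prey abundances, indexed by :class:`PreyClass`."""
        return self._class_n.copy()

    @property
    def total_prey(self) -> int:
        return int(self._class_n.sum())

    @property
    def n_alive(self) -> int:
        return int((self._alive != 0).sum())

    @property
    def instructions_executed(self) -> int:
        return int(self._meta[K.M_INSTR])

    @property
    def births_refused(self) -> int:
        return int(self._meta[K.M_REFUSED])

    def organism(self, i: int) -> OrganismView:
        tc = int(self._tclass[i])
        dc = int(self._disp[i])
        return OrganismView(
            id=i,
            alive=bool(self._alive[i]),
            is_predator=bool(self._is_pred[i]),
            true_class=None if tc < 0 else PreyClass(tc),
            displayed_class=None if dc < 0 else PreyClass(dc),
            stored=float(self._stored[i]),
            position=(int(self._x[i]), int(self._y[i])),
            facing=int(self._facing[i]),
            age=int(self._age[i]),
        )

    def genome_of(self, i: int) -> np.ndarray:
        return self._genome[i, : self._glen[i]].copy()

    def alive_ids(self) -> np.ndarray:
        return np.flatnonzero(self._alive)

    def class_members(self, prey_class: PreyClass | int) -> np.ndarray:
        c = int(prey_class)
        return self._members[c, : self._class_n[c]].copy()

    def display_counts(self) -> np.ndarray:
        """Among alive mimic-class prey, how many currently display
        (non-poisonous, mimic, poisonous)."""
        ids = self.class_members(PreyClass.MIMIC)
        if len(ids) == 0:
            return np.zeros(3, dtype=np.int64)
        return np.bincount(self._disp[ids], minlength=3).astype(np.int64)

    def occupants(self, x: int, y: int) -> list[int]:
        """Organism ids in cell (x, y), head of list first."""
        cell = (y % self.config.height) * self.config.width + (x % self.config.width)
        out = []
        j = int(self._cell_head[cell])
        while j >= 0:
            out.append(j)
            j = int(self._nxt[j])
        return out

    def faced_cell(self, i: int) -> tuple[int, int]:
        cfg = self.config
        fx = (int(self._x[i]) + int(K.DX[self._facing[i]])) % cfg.width
        fy = (int(self._y[i]) + int(K.DY[self._facing[i]])) % cfg.height
        return fx, fy

    def grid_snapshot(self):
        """Resource stocks as a tidy table (x, y, layer, stock)."""
        import pandas as pd

        L, H, W = self._stock.shape
        layer, yy, xx = np.meshgrid(np.arange(L), np.arange(H), np.arange(W), indexing="ij")
        return pd.DataFrame({
            "x": xx.ravel(), "y": yy.ravel(), "layer": layer.ravel(),
            "stock": self._stock.ravel(),
        })
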