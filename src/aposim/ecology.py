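"""Interaction and demographic rules: perception, attack resolution, display
changes, reproduction, birth-class assignment and cap enforcement.

These are the operation-level entry points; during full simulation the same
kernels run inside the scheduler loop.  Stochastic operations draw from the
world's simulation RNG (seed with ``world.reseed``); the two pure helpers
(:func:`perceive_class`, :func:`assign_birth_class`) accept an explicit numpy
``Generator`` so they are usable without a world.

Rule summary.  A predator perceives a mimic's displayed class with
probability ``fidelity`` and its true class otherwise (non-mimics always look
like what they are).  An attack is blocked outright while total prey numbers
sit below the prey floor; otherwise it needs a prey in the faced cell whose
perceived class is in the attack's target set.  A kill removes the victim;
a poisonous victim costs the attacker ``poison_level x victim.stored``
(floored at zero stores, no gain), any other victim yields
``conversion_efficiency x victim.stored``.  The first kill irreversibly turns
the attacker into a predator, removing it from the prey classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import _kernels as K
from .config import ConfigError, EcologyConfig
from .world import OrganismView, PreyClass, World

__all__ = [
    "PreyClass", "EcologyConfig", "AttackResult", "AttackOutcome",
    "perceive_class", "resolve_attack", "apply_display_change", "reproduce",
    "assign_birth_class", "enforce_class_cap",
]


class AttackResult(Enum):
    NO_TARGET = "no-target"
    BLOCKED_BY_FLOOR = "blocked-by-floor"
    CLASS_MISMATCH = "class-mismatch"
    KILL = "kill"


_RESULT_BY_CODE = {
    K.NO_TARGET: AttackResult.NO_TARGET,
    K.BLOCKED_BY_FLOOR: AttackResult.BLOCKED_BY_FLOOR,
    K.CLASS_MISMATCH: AttackResult.CLASS_MISMATCH,
    K.KILL: AttackResult.KILL,
}


@dataclass(frozen=True)
class AttackOutcome:
    result: AttackResult
    resource_delta_attacker: float
    victim: int | None


def perceive_class(prey: OrganismView, fidelity: float,
                   rng: np.random.Generator | None = None) -> PreyClass:
    """Class a predator perceives for ``prey``: the displayed class with
    probability ``fidelity``, the true class otherwise."""
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must be in [0, 1]")
    if prey.displayed_class == prey.true_class:
        return prey.true_class
    if rng is None:
        rng = np.random.default_rng()
    return prey.displayed_class if rng.random() < fidelity else prey.true_class


def _mask_of(target_set) -> int:
    mask = 0
    for c in target_set:
        mask |= 1 << int(c)
    if mask == 0:
        raise ValueError("target set must be nonempty")
    return mask


def resolve_attack(world: World, attacker: int, target_set) -> AttackOutcome:
    """Resolve one attack by organism ``attacker`` against whatever prey
    occupies its faced cell, honouring the prey floor and the target set."""
    if not world._alive[attacker]:
        raise ValueError("attacker is not alive")
    code, delta, victim = K.resolve_attack_entry(*world.kargs, attacker,
                                                 _mask_of(target_set))
    return AttackOutcome(_RESULT_BY_CODE[int(code)], float(delta),
                         None if victim < 0 else int(victim))


def apply_display_change(world: World, organism: int,
                         requested: PreyClass | int) -> None:
    """Set a mimic's displayed class (persists until changed again); a no-op
    for non-mimics or when mimicry is disabled."""
    req = int(requested)
    if req not in (0, 1, 2):
        raise ValueError(f"invalid prey class {requested}")
    if world._tclass[organism] == int(PreyClass.MIMIC) and world.config.mimicry_enabled:
        world._disp[organism] = req


def reproduce(world: World, parent: int) -> int | None:
    """Attempt reproduction by ``parent``; returns the offspring id, or
    ``None`` when refused (stores below threshold or no capacity)."""
    if not world._alive[parent]:
        raise ValueError("parent is not alive")
    child = K.reproduce_entry(*world.kargs, parent)
    return None if child < 0 else int(child)


def assign_birth_class(cfg: EcologyConfig,
                       rng: np.random.Generator | None = None) -> PreyClass:
    """Independent categorical draw over the configured birth fractions."""
    bf = cfg.birth_fractions
    if abs(sum(bf) - 1.0) > 1e-9:
        raise ConfigError(f"birth_fractions must sum to 1, got {sum(bf)}")
    if rng is None:
        rng = np.random.default_rng()
    u = rng.random()
    if u < bf[0]:
        return PreyClass.NON_POISONOUS
    if u < bf[0] + bf[1]:
        return PreyClass.MIMIC
    return PreyClass.POISONOUS


def enforce_class_cap(world: World, prey_class: PreyClass | int) -> int | None:
    """Called right after a prey birth: if the class exceeds its cap, one
    uniformly random pre-existing member (never the newborn, which occupies
    the last member slot) is removed.  Returns the removed id or ``None``."""
    victim = K.enforce_class_cap_entry(*world.kargs, int(prey_class))
    return None if victim < 0 else int(victim)
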