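"""Instruction set and genome operations for the digital-organism virtual machine.

Organisms carry a linear genome of opcodes drawn from a small, closed
instruction set.  Execution is cyclic (the instruction pointer wraps) and a
scheduler grants each organism a fixed instruction budget per update, so
"infinite loops" are harmless.  Several instructions take their argument from
the *following* instruction in the genome: an ``attack`` is modified by the
next opcode, which selects the prey classes the attack may hit, and
``set-display`` is modified the same way to select which class a mimic
advertises.  Eight modifier no-ops (``nop-A`` .. ``nop-H``) exist solely to
serve as such arguments; standalone they do nothing.

The heritable unit is the genome.  At each birth the offspring genome is the
parent's, passed through three independent point-mutation events
(substitution / insertion / deletion), each occurring at most once per
offspring with its configured probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Opcodes.  Values are stable: genomes are stored as int8 arrays of these.
# ---------------------------------------------------------------------------

NOP_A, NOP_B, NOP_C, NOP_D, NOP_E, NOP_F, NOP_G, NOP_H = range(8)
TURN_LEFT = 8
TURN_RIGHT = 9
MOVE = 10
SENSE_FOOD = 11      # stock of own resource layer in the faced cell -> reg 0
SENSE_CLASS = 12     # perceived class of prey in faced cell (+1; 0 = none) -> reg 1
EAT = 13             # harvest up to 1 unit of own-class resource from current cell
ATTACK = 14          # attack prey in faced cell; target set from following opcode
SET_DISPLAY = 15     # mimics only: displayed class from following opcode
IF_LESS = 16         # execute next instruction only if reg0 < reg1
IF_GREATER = 17      # execute next instruction only if reg0 > reg1
ADD = 18             # reg0 += reg1
SUB = 19             # reg0 -= reg1
SWAP = 20            # reg0 <-> reg1
REPRODUCE = 21       # spend the reproduction threshold to spawn an offspring

N_OPS = 22
N_REGISTERS = 3

MNEMONICS = (
    "nop-A", "nop-B", "nop-C", "nop-D", "nop-E", "nop-F", "nop-G", "nop-H",
    "turn-left", "turn-right", "move", "sense-food", "sense-class", "eat",
    "attack", "set-display", "if-less", "if-greater", "add", "sub", "swap",
    "reproduce",
)
OPCODE_OF = {m: i for i, m in enumerate(MNEMONICS)}

NOPS = tuple(range(8))

# ---------------------------------------------------------------------------
# Attack targeting.  The opcode following an attack selects the set of prey
# classes the attack may hit, encoded as a 3-bit mask over class codes
# (bit 0 = non-poisonous, bit 1 = mimic, bit 2 = poisonous).  A follower that
# is not a modifier no-op leaves the attack a generalist (all three classes),
# as do nop-C and nop-G.
# ---------------------------------------------------------------------------

ALL_CLASSES_MASK = 0b111

ATTACK_MASK = np.full(N_OPS, ALL_CLASSES_MASK, dtype=np.int8)
ATTACK_MASK[NOP_A] = ATTACK_MASK[NOP_E] = 0b001  # non-poisonous only
ATTACK_MASK[NOP_B] = ATTACK_MASK[NOP_F] = 0b010  # mimic only
ATTACK_MASK[NOP_C] = ATTACK_MASK[NOP_G] = ALL_CLASSES_MASK
ATTACK_MASK[NOP_D] = ATTACK_MASK[NOP_H] = 0b100  # poisonous only

# Display targeting mirrors the attack scheme: nop-A/E request the
# non-poisonous look, nop-B/F the mimic (honest) look, nop-D/H the poisonous
# look; anything else reverts the mimic to its honest appearance (-1).
DISPLAY_REQUEST = np.full(N_OPS, -1, dtype=np.int8)
DISPLAY_REQUEST[NOP_A] = DISPLAY_REQUEST[NOP_E] = 0
DISPLAY_REQUEST[NOP_B] = DISPLAY_REQUEST[NOP_F] = 1
DISPLAY_REQUEST[NOP_D] = DISPLAY_REQUEST[NOP_H] = 2


def target_set_from_mask(mask: int) -> frozenset:
    """Decode a 3-bit target mask into a frozenset of class codes."""
    return frozenset(c for c in range(3) if mask & (1 << c))


def parse_attack_sequence(genome: np.ndarray, attack_position: int) -> frozenset:
    """Return the set of prey class codes targeted by the attack at
    ``attack_position``, determined by the following instruction (wrapping at
    the genome end).

    Raises ``IndexError`` for an out-of-range position and ``ValueError`` if
    the instruction there is not ``attack``.
    """
    genome = np.asarray(genome, dtype=np.int8)
    n = len(genome)
    if not 0 <= attack_position < n:
        raise IndexError(f"attack_position {attack_position} out of range for genome of length {n}")
    if genome[attack_position] != ATTACK:
        raise ValueError(f"instruction at position {attack_position} is not 'attack'")
    follower = genome[(attack_position + 1) % n]
    return target_set_from_mask(int(ATTACK_MASK[follower]))


# ---------------------------------------------------------------------------
# Instruction set (the mutable pool) and genome construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InstructionSet:
    """The pool of opcodes available to mutation.

    ``attack_enabled=False`` removes the attack opcode from the pool, which
    (ancestors carrying none) makes predators impossible — the predation-free
    control configuration.
    """

    attack_enabled: bool = True

    @property
    def opcodes(self) -> np.ndarray:
        ops = [op for op in range(N_OPS) if self.attack_enabled or op != ATTACK]
        return np.array(ops, dtype=np.int8)


# Opcodes the hand-written ancestors are built from: random walking, foraging
# and reproduction only — no attack, no display manipulation, no conditionals.
ANCESTOR_POOL = np.array(
    [EAT, MOVE, TURN_LEFT, TURN_RIGHT, REPRODUCE, SENSE_FOOD] + list(NOPS),
    dtype=np.int8,
)
ANCESTOR_WEIGHTS = np.array(
    [0.30, 0.25, 0.07, 0.07, 0.15, 0.06] + [0.10 / 8] * 8
)


def ancestral_genome(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random founder genome: moves, eats and reproduces, nothing else.

    Guaranteed to contain at least one ``eat``, one ``move`` and one
    ``reproduce`` (patched in at random distinct positions if the draw missed
    one), and no attack or display-change instruction.
    """
    if length < 1:
        raise ValueError("genome length must be >= 1")
    g = rng.choice(ANCESTOR_POOL, size=length, p=ANCESTOR_WEIGHTS / ANCESTOR_WEIGHTS.sum())
    required = [EAT, MOVE, REPRODUCE][: min(3, length)]
    missing = [op for op in required if op not in g]
    if missing:
        pos = rng.choice(length, size=len(missing), replace=False)
        g[pos] = missing
    return g.astype(np.int8)


@dataclass(frozen=True)
class MutationRates:
    """Per-offspring probabilities of one substitution / insertion / deletion."""

    p_substitution: float = 0.25
    p_insertion: float = 0.05
    p_deletion: float = 0.05

    def __post_init__(self):
        for name in ("p_substitution", "p_insertion", "p_deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class MutationEvents:
    """Which mutation events were applied to one offspring genome."""

    substitution: bool = False
    insertion: bool = False
    deletion: bool = False


def mutate_offspring_genome(
    parent: np.ndarray,
    rates: MutationRates,
    instruction_set: InstructionSet | np.ndarray = InstructionSet(),
    rng: np.random.Generator | None = None,
    return_events: bool = False,
):
    """Copy ``parent`` through the divide-time mutation operator.

    Three independent events, each at most once per offspring: with
    ``p_substitution`` one uniformly chosen position is replaced by a uniform
    draw from the instruction pool (the draw may silently equal the original);
    with ``p_insertion`` one uniform pool instruction is inserted at a uniform
    position; with ``p_deletion`` one uniform position is deleted.  Deletion is
    skipped on a length-1 genome so the genome never empties.
    """
    if rng is None:
        rng = np.random.default_rng()
    pool = instruction_set.opcodes if isinstance(instruction_set, InstructionSet) else np.asarray(instruction_set, dtype=np.int8)
    g = np.array(parent, dtype=np.int8, copy=True)
    ev = MutationEvents()
    if rng.random() < rates.p_substitution:
        ev.substitution = True
        g[rng.integers(len(g))] = pool[rng.integers(len(pool))]
    if rng.random() < rates.p_insertion:
        ev.insertion = True
        pos = int(rng.integers(len(g) + 1))
        g = np.insert(g, pos, pool[rng.integers(len(pool))])
    if rng.random() < rates.p_deletion:
        if len(g) > 1:
            ev.deletion = True
            g = np.delete(g, int(rng.integers(len(g))))
    if return_events:
        return g, ev
    return g


# ---------------------------------------------------------------------------
# Plain-text genome serialization (one mnemonic per line)
# ---------------------------------------------------------------------------

def genome_to_text(genome: np.ndarray) -> str:
    return "\n".join(MNEMONICS[int(op)] for op in genome) + "\n"


def genome_from_text(text: str) -> np.ndarray:
    ops = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            ops.append(OPCODE_OF[line])
        except KeyError:
            raise ValueError(f"unknown mnemonic {line!r} on line {lineno}") from None
    if not ops:
        raise ValueError("empty genome")
    return np.array(ops, dtype=np.int8)
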