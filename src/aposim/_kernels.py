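"""JIT-compiled simulation core.

All mutable world state lives in a small set of numpy arrays owned by
:class:`aposim.world.World`; every kernel entry point takes the full array
set positionally (the order below, frozen), followed by the float/int
parameter vectors ``pf``/``pi`` and the mutable instruction pool, then any
operation-specific arguments.  The world object bundles the full argument
set as ``World.kargs``, so calls read ``kernel(*world.kargs, ...)``.  The
same kernels back both the one-call-per-operation API used by the unit tests
and the whole-update scheduler loop, so there is a single implementation of
the interaction rules.

Deliberate low-level choices that keep the instruction-dispatch loop fast on
one CPU (each measured to matter by an order of magnitude or close):

* per-organism fields are packed into three column tables (``oi8``, ``oi32``,
  ``of8``) instead of ~20 separate vectors, keeping the argument count — and
  with it LLVM's live array-descriptor set and register spills — small;
* arrays are passed individually, never inside a tuple, so numba marks them
  non-aliasing;
* all randomness comes from an inline xorshift64* generator whose state is
  the ``rs`` array, so the hot loop contains no external calls acting as
  optimization barriers (and replays do not depend on numba's RNG
  internals).  Seeding is the world's job.

Array set::

    oi8      i1[C, 4]   columns: 0 alive, 1 is_pred, 2 true class, 3 displayed
                        class (class codes 0/1/2; -1 = none)
    oi32     i4[C, 9]   columns: 0 x, 1 y, 2 facing, 3 age, 4 instruction
                        pointer, 5 genome length, 6/7 next/prev organism in
                        cell (occupancy list), 8 index in class member list
    of8      f8[C, 4]   columns: 0 stored resources, 1..3 VM registers
    genome   i1[C, GMAX]
    cell_head i4[H*W]   head of each cell's occupancy list (-1 = empty)
    members  i4[3, cap+1]  per-class prey member lists (swap-remove)
    free     i4[C]      stack of free organism slots
    meta     i8[8]      0 predator count, 1 instructions executed, 2 births
                        refused for lack of capacity, 3 update counter,
                        4 free-slot count, 5/6/7 per-class prey counts
    stock    f8[L,H,W]  resource layers
    rs       u8[1]      RNG state

``pf``: 0 conversion efficiency e, 1 poison level p, 2 fidelity f,
3 reproduction threshold, 4 max stock per cell, 5 inflow rate,
6/7/8 substitution/insertion/deletion probabilities, 9/10/11 birth fractions
(non-poisonous, mimic, poisonous).

``pi``: 0 width, 1 height, 2 class cap, 3 prey floor, 4 max age,
5 per-update instruction budget, 6 mimicry enabled, 7 poisonous kills also
yield the conversion gain (off by default), 8 max genome length,
9 shared resource layer flag.
"""

import numpy as np
from numba import njit

from .instructions import (
    ATTACK, ATTACK_MASK, DISPLAY_REQUEST, EAT, IF_GREATER, IF_LESS, MOVE,
    REPRODUCE, SENSE_CLASS, SENSE_FOOD, SET_DISPLAY, SUB, SWAP, TURN_LEFT,
    TURN_RIGHT, ADD,
)

# column indices
ALIVE, ISPRED, TCLASS, DISP = 0, 1, 2, 3                      # oi8
X, Y, FACING, AGE, IP, GLEN, NXT, PRV, CPOS = range(9)        # oi32
STORED = 0                                                    # of8 (regs at 1..3)

# meta indices
M_NPRED, M_INSTR, M_REFUSED, M_UPDATE, M_NFREE, M_CLASS0 = 0, 1, 2, 3, 4, 5

# compass directions 0..7 = N, NE, E, SE, S, SW, W, NW
DX = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)
DY = np.array([-1, -1, 0, 1, 1, 1, 0, -1], dtype=np.int64)

# attack outcome codes
NO_TARGET, BLOCKED_BY_FLOOR, CLASS_MISMATCH, KILL = 0, 1, 2, 3

_ATTACK_MASK = ATTACK_MASK.copy()
_DISPLAY_REQUEST = DISPLAY_REQUEST.copy()

_U12 = np.uint64(12)
_U25 = np.uint64(25)
_U27 = np.uint64(27)
_U11 = np.uint64(11)
_MULT = np.uint64(0x2545F4914F6CDD1D)
_INV53 = 1.1102230246251565e-16  # 2**-53


def splitmix64(seed: int) -> int:
    """Expand a small seed into a well-mixed nonzero 64-bit RNG state."""
    mask = (1 << 64) - 1
    z = (int(seed) + 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z ^= z >> 31
    return z or 0x9E3779B97F4A7C15


@njit(cache=True)
def _rand01(rs):
    """Uniform double in [0, 1) from xorshift64* (53 mantissa bits)."""
    s = rs[0]
    s ^= s >> _U12
    s ^= s << _U25
    s ^= s >> _U27
    rs[0] = s
    return float((s * _MULT) >> _U11) * _INV53


@njit(cache=True)
def _randbelow(rs, n):
    """Uniform integer in [0, n) for n >= 1."""
    r = int(_rand01(rs) * n)
    return r if r < n else n - 1


@njit(cache=True)
def _link(oi32, cell_head, i, cell):
    head = cell_head[cell]
    oi32[i, NXT] = head
    oi32[i, PRV] = -1
    if head >= 0:
        oi32[head, PRV] = i
    cell_head[cell] = i


@njit(cache=True)
def _unlink(oi32, cell_head, i, cell):
    p = oi32[i, PRV]
    nx = oi32[i, NXT]
    if p >= 0:
        oi32[p, NXT] = nx
    else:
        cell_head[cell] = nx
    if nx >= 0:
        oi32[nx, PRV] = p


@njit(cache=True)
def _members_remove(oi32, members, meta, i, cls):
    p = oi32[i, CPOS]
    last = meta[M_CLASS0 + cls] - 1
    j = members[cls, last]
    members[cls, p] = j
    oi32[j, CPOS] = p
    meta[M_CLASS0 + cls] = last


@njit(cache=True)
def remove_organism(oi8, oi32, members, cell_head, free, meta, width, i):
    """Remove organism ``i`` from the world (death of any cause)."""
    _unlink(oi32, cell_head, i, oi32[i, Y] * width + oi32[i, X])
    oi8[i, ALIVE] = 0
    if oi8[i, ISPRED] != 0:
        meta[M_NPRED] -= 1
    elif oi8[i, TCLASS] >= 0:
        _members_remove(oi32, members, meta, i, oi8[i, TCLASS])
    free[meta[M_NFREE]] = i
    meta[M_NFREE] += 1


@njit(cache=True)
def perceive(oi8, rs, j, fidelity):
    """Class a predator perceives for organism ``j``: the displayed class with
    probability ``fidelity``, the true class otherwise.  Non-mimics always
    display truthfully, so no draw is spent on them."""
    t = oi8[j, TCLASS]
    d = oi8[j, DISP]
    if t != 1 or d == t:
        return t
    if _rand01(rs) < fidelity:
        return d
    return t


@njit(cache=True)
def _find_prey_in_cell(oi8, oi32, cell_head, cell):
    """First non-predator occupant of ``cell`` (insertion order), or -1."""
    j = cell_head[cell]
    while j >= 0:
        if oi8[j, ISPRED] == 0:
            return j
        j = oi32[j, NXT]
    return -1


@njit(cache=True)
def _resolve_attack(oi8, oi32, of8, cell_head, members, free, meta, rs,
                    pf, pi, i, mask):
    """Resolve one attack by organism ``i`` with target mask ``mask``.

    Returns ``(outcome, resource_delta, victim)``; victim is -1 except on a
    kill.  Order of checks: prey floor, target presence, perceived-class
    match, then the kill with its resource bookkeeping and the attacker's
    (irreversible) promotion to predator.
    """
    total_prey = meta[M_CLASS0] + meta[M_CLASS0 + 1] + meta[M_CLASS0 + 2]
    if total_prey < pi[3]:
        return BLOCKED_BY_FLOOR, 0.0, -1
    width, height = pi[0], pi[1]
    f = oi32[i, FACING]
    fx = oi32[i, X] + DX[f]
    fy = oi32[i, Y] + DY[f]
    if fx < 0:
        fx += width
    elif fx >= width:
        fx -= width
    if fy < 0:
        fy += height
    elif fy >= height:
        fy -= height
    j = _find_prey_in_cell(oi8, oi32, cell_head, fy * width + fx)
    if j < 0:
        return NO_TARGET, 0.0, -1
    pc = perceive(oi8, rs, j, pf[2])
    if mask & (1 << pc) == 0:
        return CLASS_MISMATCH, 0.0, -1
    delta = 0.0
    if oi8[j, TCLASS] == 2:  # poisonous victim: penalty scaled by poison level
        loss = pf[1] * of8[j, STORED]
        if loss > of8[i, STORED]:
            loss = of8[i, STORED]
        of8[i, STORED] -= loss
        delta = -loss
        if pi[7] != 0:  # optional: poisonous kills also yield the gain
            gain = pf[0] * of8[j, STORED]
            of8[i, STORED] += gain
            delta += gain
    else:  # non-poisonous or mimic: conversion gain
        gain = pf[0] * of8[j, STORED]
        of8[i, STORED] += gain
        delta = gain
    remove_organism(oi8, oi32, members, cell_head, free, meta, width, j)
    if oi8[i, ISPRED] == 0:
        oi8[i, ISPRED] = 1
        if oi8[i, TCLASS] >= 0:
            _members_remove(oi32, members, meta, i, oi8[i, TCLASS])
        meta[M_NPRED] += 1
    return KILL, delta, j


@njit(cache=True)
def assign_birth_class(rs, pf):
    """Categorical draw over (non-poisonous, mimic, poisonous) birth fractions."""
    u = _rand01(rs)
    if u < pf[9]:
        return 0
    if u < pf[9] + pf[10]:
        return 1
    return 2


@njit(cache=True)
def _enforce_class_cap(oi8, oi32, members, cell_head, free, meta, rs, pi, cls):
    """If class ``cls`` exceeds its cap, remove one uniformly random incumbent
    (the newborn, sitting in the last member slot, is excluded).  Returns the
    removed organism's id or -1."""
    if meta[M_CLASS0 + cls] <= pi[2]:
        return -1
    idx = _randbelow(rs, meta[M_CLASS0 + cls] - 1)
    victim = members[cls, idx]
    remove_organism(oi8, oi32, members, cell_head, free, meta, pi[0], victim)
    return victim


@njit(cache=True)
def _mutate_child_genome(genome, oi32, mut_pool, rs, pf, pi, parent, child):
    n = oi32[parent, GLEN]
    for k in range(n):
        genome[child, k] = genome[parent, k]
    if _rand01(rs) < pf[6]:
        genome[child, _randbelow(rs, n)] = mut_pool[_randbelow(rs, len(mut_pool))]
    if _rand01(rs) < pf[7] and n < pi[8]:
        pos = _randbelow(rs, n + 1)
        for k in range(n, pos, -1):
            genome[child, k] = genome[child, k - 1]
        genome[child, pos] = mut_pool[_randbelow(rs, len(mut_pool))]
        n += 1
    if _rand01(rs) < pf[8] and n > 1:
        pos = _randbelow(rs, n)
        for k in range(pos, n - 1):
            genome[child, k] = genome[child, k + 1]
        n -= 1
    oi32[child, GLEN] = n


@njit(cache=True)
def _reproduce(oi8, oi32, of8, genome, cell_head, members, free, meta, rs,
               pf, pi, mut_pool, i):
    """Attempt reproduction by organism ``i``.

    Refused (returns -1) below the resource threshold or when the slot pool is
    exhausted.  Otherwise the parent pays the threshold, the offspring genome
    passes through the mutation operator, and the newborn lands in a uniformly
    random neighboring cell.  Predator parents beget predators (outside the
    prey classes); prey offspring draw a birth class, display honestly, and
    their class cap is enforced immediately.
    """
    if of8[i, STORED] < pf[3]:
        return -1
    if meta[M_NFREE] == 0:
        meta[M_REFUSED] += 1
        return -1
    of8[i, STORED] -= pf[3]
    meta[M_NFREE] -= 1
    c = free[meta[M_NFREE]]
    _mutate_child_genome(genome, oi32, mut_pool, rs, pf, pi, i, c)
    width, height = pi[0], pi[1]
    d = _randbelow(rs, 8)
    cx = oi32[i, X] + DX[d]
    cy = oi32[i, Y] + DY[d]
    if cx < 0:
        cx += width
    elif cx >= width:
        cx -= width
    if cy < 0:
        cy += height
    elif cy >= height:
        cy -= height
    oi32[c, X] = cx
    oi32[c, Y] = cy
    oi32[c, FACING] = _randbelow(rs, 8)
    oi32[c, AGE] = 0
    oi32[c, IP] = 0
    of8[c, STORED] = 0.0
    of8[c, 1] = 0.0
    of8[c, 2] = 0.0
    of8[c, 3] = 0.0
    oi8[c, ALIVE] = 1
    _link(oi32, cell_head, c, cy * width + cx)
    if oi8[i, ISPRED] != 0:
        oi8[c, ISPRED] = 1
        oi8[c, TCLASS] = -1
        oi8[c, DISP] = -1
        meta[M_NPRED] += 1
    else:
        oi8[c, ISPRED] = 0
        cls = assign_birth_class(rs, pf)
        oi8[c, TCLASS] = cls
        oi8[c, DISP] = cls
        members[cls, meta[M_CLASS0 + cls]] = c
        oi32[c, CPOS] = meta[M_CLASS0 + cls]
        meta[M_CLASS0 + cls] += 1
        _enforce_class_cap(oi8, oi32, members, cell_head, free, meta, rs,
                           pi, cls)
    return c


@njit(cache=True)
def _dispatch(oi8, oi32, of8, genome, cell_head, members, free,
              meta, stock, rs, pf, pi, mut_pool, i, k, n):
    """Execute the instruction at position ``k`` of organism ``i``'s
    length-``n`` genome and return the advanced position.

    The caller owns the instruction pointer: the scheduler keeps it in a
    register across an organism's whole turn and persists it once, which is
    substantially cheaper than a load/store per instruction.  The position
    invariant ``0 <= k < n`` holds on entry and exit (genome length is fixed
    after birth), so pointer arithmetic uses compare-and-subtract instead of
    modulo.
    """
    width, height = pi[0], pi[1]
    op = genome[i, k]
    advance = 1
    if op < 8:
        pass  # modifier no-ops do nothing standalone
    elif op == MOVE:
        f = oi32[i, FACING]
        cx = oi32[i, X]
        cy = oi32[i, Y]
        _unlink(oi32, cell_head, i, cy * width + cx)
        cx += DX[f]
        cy += DY[f]
        if cx < 0:
            cx += width
        elif cx >= width:
            cx -= width
        if cy < 0:
            cy += height
        elif cy >= height:
            cy -= height
        oi32[i, X] = cx
        oi32[i, Y] = cy
        _link(oi32, cell_head, i, cy * width + cx)
    elif op == EAT:
        if oi8[i, ISPRED] == 0 and oi8[i, TCLASS] >= 0:
            layer = 0 if pi[9] != 0 else oi8[i, TCLASS]
            s = stock[layer, oi32[i, Y], oi32[i, X]]
            taken = 1.0 if s > 1.0 else s
            stock[layer, oi32[i, Y], oi32[i, X]] = s - taken
            of8[i, STORED] += taken
    elif op == TURN_LEFT:
        oi32[i, FACING] = (oi32[i, FACING] + 7) % 8
    elif op == TURN_RIGHT:
        oi32[i, FACING] = (oi32[i, FACING] + 1) % 8
    elif op == SENSE_FOOD:
        if oi8[i, TCLASS] >= 0:
            layer = 0 if pi[9] != 0 else oi8[i, TCLASS]
            f = oi32[i, FACING]
            fx = oi32[i, X] + DX[f]
            fy = oi32[i, Y] + DY[f]
            if fx < 0:
                fx += width
            elif fx >= width:
                fx -= width
            if fy < 0:
                fy += height
            elif fy >= height:
                fy -= height
            of8[i, 1] = stock[layer, fy, fx]
        else:
            of8[i, 1] = 0.0
    elif op == SENSE_CLASS:
        f = oi32[i, FACING]
        fx = oi32[i, X] + DX[f]
        fy = oi32[i, Y] + DY[f]
        if fx < 0:
            fx += width
        elif fx >= width:
            fx -= width
        if fy < 0:
            fy += height
        elif fy >= height:
            fy -= height
        j = _find_prey_in_cell(oi8, oi32, cell_head, fy * width + fx)
        of8[i, 2] = 0.0 if j < 0 else perceive(oi8, rs, j, pf[2]) + 1.0
    elif op == ATTACK:
        f = k + 1
        if f >= n:
            f -= n
        mask = _ATTACK_MASK[genome[i, f]]
        _resolve_attack(oi8, oi32, of8, cell_head, members, free, meta, rs,
                        pf, pi, i, mask)
    elif op == SET_DISPLAY:
        if oi8[i, TCLASS] == 1 and pi[6] != 0:
            f = k + 1
            if f >= n:
                f -= n
            req = _DISPLAY_REQUEST[genome[i, f]]
            oi8[i, DISP] = oi8[i, TCLASS] if req < 0 else req
    elif op == IF_LESS:
        if not (of8[i, 1] < of8[i, 2]):
            advance = 2
    elif op == IF_GREATER:
        if not (of8[i, 1] > of8[i, 2]):
            advance = 2
    elif op == ADD:
        of8[i, 1] = of8[i, 1] + of8[i, 2]
    elif op == SUB:
        of8[i, 1] = of8[i, 1] - of8[i, 2]
    elif op == SWAP:
        tmp = of8[i, 1]
        of8[i, 1] = of8[i, 2]
        of8[i, 2] = tmp
    elif op == REPRODUCE:
        if of8[i, STORED] >= pf[3]:
            _reproduce(oi8, oi32, of8, genome, cell_head, members, free,
                       meta, rs, pf, pi, mut_pool, i)
    k += advance
    if k >= n:
        k -= n
        if k >= n:  # length-1 genome with a skipping conditional
            k -= n
    return k


@njit(cache=True)
def step_update(oi8, oi32, of8, genome, cell_head, members, free, meta,
                stock, rs, pf, pi, mut_pool):
    """Advance the world one update.

    Alive organisms are visited in a freshly shuffled order, each executing
    the full per-update instruction budget (cut short only by its own death);
    organisms born during the update first run in the next one.  Then every
    resource layer regrows, ages advance and age-limit deaths are applied.
    """
    C = oi8.shape[0]
    n_alive = 0
    for i in range(C):
        if oi8[i, ALIVE] != 0:
            n_alive += 1
    order = np.empty(n_alive, dtype=np.int64)
    m = 0
    for i in range(C):
        if oi8[i, ALIVE] != 0:
            order[m] = i
            m += 1
    for t in range(n_alive - 1, 0, -1):  # Fisher-Yates shuffle
        j = _randbelow(rs, t + 1)
        tmp = order[t]
        order[t] = order[j]
        order[j] = tmp
    budget = pi[5]
    width, height = pi[0], pi[1]
    for t in range(n_alive):
        i = order[t]
        k = oi32[i, IP]
        n = oi32[i, GLEN]
        executed = 0
        for _ in range(budget):
            if oi8[i, ALIVE] == 0:
                break
            # --- instruction dispatch (kept in sync with _dispatch by a
            # parity test; a function boundary here would cost an order of
            # magnitude in throughput) ---
            op = genome[i, k]
            advance = 1
            if op < 8:
                pass  # modifier no-ops do nothing standalone
            elif op == MOVE:
                f = oi32[i, FACING]
                cx = oi32[i, X]
                cy = oi32[i, Y]
                _unlink(oi32, cell_head, i, cy * width + cx)
                cx += DX[f]
                cy += DY[f]
                if cx < 0:
                    cx += width
                elif cx >= width:
                    cx -= width
                if cy < 0:
                    cy += height
                elif cy >= height:
                    cy -= height
                oi32[i, X] = cx
                oi32[i, Y] = cy
                _link(oi32, cell_head, i, cy * width + cx)
            elif op == EAT:
                if oi8[i, ISPRED] == 0 and oi8[i, TCLASS] >= 0:
                    layer = 0 if pi[9] != 0 else oi8[i, TCLASS]
                    s = stock[layer, oi32[i, Y], oi32[i, X]]
                    taken = 1.0 if s > 1.0 else s
                    stock[layer, oi32[i, Y], oi32[i, X]] = s - taken
                    of8[i, STORED] += taken
            elif op == TURN_LEFT:
                oi32[i, FACING] = (oi32[i, FACING] + 7) % 8
            elif op == TURN_RIGHT:
                oi32[i, FACING] = (oi32[i, FACING] + 1) % 8
            elif op == SENSE_FOOD:
                if oi8[i, TCLASS] >= 0:
                    layer = 0 if pi[9] != 0 else oi8[i, TCLASS]
                    f = oi32[i, FACING]
                    fx = oi32[i, X] + DX[f]
                    fy = oi32[i, Y] + DY[f]
                    if fx < 0:
                        fx += width
                    elif fx >= width:
                        fx -= width
                    if fy < 0:
                        fy += height
                    elif fy >= height:
                        fy -= height
                    of8[i, 1] = stock[layer, fy, fx]
                else:
                    of8[i, 1] = 0.0
            elif op == SENSE_CLASS:
                f = oi32[i, FACING]
                fx = oi32[i, X] + DX[f]
                fy = oi32[i, Y] + DY[f]
                if fx < 0:
                    fx += width
                elif fx >= width:
                    fx -= width
                if fy < 0:
                    fy += height
                elif fy >= height:
                    fy -= height
                j = _find_prey_in_cell(oi8, oi32, cell_head, fy * width + fx)
                of8[i, 2] = 0.0 if j < 0 else perceive(oi8, rs, j, pf[2]) + 1.0
            elif op == ATTACK:
                f = k + 1
                if f >= n:
                    f -= n
                mask = _ATTACK_MASK[genome[i, f]]
                _resolve_attack(oi8, oi32, of8, cell_head, members, free, meta, rs,
                                pf, pi, i, mask)
            elif op == SET_DISPLAY:
                if oi8[i, TCLASS] == 1 and pi[6] != 0:
                    f = k + 1
                    if f >= n:
                        f -= n
                    req = _DISPLAY_REQUEST[genome[i, f]]
                    oi8[i, DISP] = oi8[i, TCLASS] if req < 0 else req
            elif op == IF_LESS:
                if not (of8[i, 1] < of8[i, 2]):
                    advance = 2
            elif op == IF_GREATER:
                if not (of8[i, 1] > of8[i, 2]):
                    advance = 2
            elif op == ADD:
                of8[i, 1] = of8[i, 1] + of8[i, 2]
            elif op == SUB:
                of8[i, 1] = of8[i, 1] - of8[i, 2]
            elif op == SWAP:
                tmp = of8[i, 1]
                of8[i, 1] = of8[i, 2]
                of8[i, 2] = tmp
            elif op == REPRODUCE:
                if of8[i, STORED] >= pf[3]:
                    _reproduce(oi8, oi32, of8, genome, cell_head, members, free,
                               meta, rs, pf, pi, mut_pool, i)
            k += advance
            if k >= n:
                k -= n
                if k >= n:  # length-1 genome with a skipping conditional
                    k -= n
            executed += 1
        oi32[i, IP] = k
        meta[M_INSTR] += executed
    L, H, W = stock.shape
    inflow, cap = pf[5], pf[4]
    for layer in range(L):
        for yy in range(H):
            for xx in range(W):
                s = stock[layer, yy, xx] + inflow
                stock[layer, yy, xx] = s if s < cap else cap
    for i in range(C):
        if oi8[i, ALIVE] != 0:
            oi32[i, AGE] += 1
            if oi32[i, AGE] >= pi[4]:
                remove_organism(oi8, oi32, members, cell_head, free, meta,
                                pi[0], i)
    meta[M_UPDATE] += 1


@njit(cache=True)
def run_updates(oi8, oi32, of8, genome, cell_head, members, free, meta,
                stock, rs, pf, pi, mut_pool, n_updates):
    for _ in range(n_updates):
        step_update(oi8, oi32, of8, genome, cell_head, members, free, meta,
                    stock, rs, pf, pi, mut_pool)


# ---------------------------------------------------------------------------
# Non-inlined entry points for the operation-level Python API.  They take the
# full canonical argument list so wrappers can splat ``*world.kargs`` and
# reach the exact code paths the scheduler loop runs.
# ---------------------------------------------------------------------------

@njit(cache=True)
def resolve_attack_entry(oi8, oi32, of8, genome, cell_head, members, free,
                         meta, stock, rs, pf, pi, mut_pool, i, mask):
    return _resolve_attack(oi8, oi32, of8, cell_head, members, free, meta,
                           rs, pf, pi, i, mask)


@njit(cache=True)
def reproduce_entry(oi8, oi32, of8, genome, cell_head, members, free, meta,
                    stock, rs, pf, pi, mut_pool, i):
    return _reproduce(oi8, oi32, of8, genome, cell_head, members, free, meta,
                      rs, pf, pi, mut_pool, i)


@njit(cache=True)
def enforce_class_cap_entry(oi8, oi32, of8, genome, cell_head, members, free,
                            meta, stock, rs, pf, pi, mut_pool, cls):
    return _enforce_class_cap(oi8, oi32, members, cell_head, free, meta, rs,
                              pi, cls)


@njit(cache=True)
def remove_organism_entry(oi8, oi32, of8, genome, cell_head, members, free,
                          meta, stock, rs, pf, pi, mut_pool, i):
    remove_organism(oi8, oi32, members, cell_head, free, meta, pi[0], i)


@njit(cache=True)
def execute_instruction_entry(oi8, oi32, of8, genome, cell_head, members,
                              free, meta, stock, rs, pf, pi, mut_pool, i):
    k = oi32[i, IP]
    op = genome[i, k]
    oi32[i, IP] = _dispatch(oi8, oi32, of8, genome, cell_head, members, free,
                            meta, stock, rs, pf, pi, mut_pool, i, k,
                            oi32[i, GLEN])
    meta[M_INSTR] += 1
    return op


@njit(cache=True)
def perceive_entry(oi8, oi32, of8, genome, cell_head, members, free, meta,
                   stock, rs, pf, pi, mut_pool, i, fidelity):
    return perceive(oi8, rs, i, fidelity)


@njit(cache=True)
def rand_below(rs, n):
    """Draw from the simulation RNG (exposed for scheduler replay tests)."""
    return _randbelow(rs, n)
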