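import numpy as np
import pytest
from scipy.stats import chisquare

from aposim import ecology as eco
from aposim.config import EcologyConfig, ExperimentConfig, ConfigError
from aposim.ecology import AttackResult, PreyClass
from aposim.world import World


def _world(**kw):
    cfg = ExperimentConfig(width=12, height=12, prey_floor=0, n_updates=0, **kw)
    return World(cfg, seed=55)


IDLE = np.zeros(1, dtype=np.int8)


class TestPerceiveClass:
    def test_non_mimic_always_truthful(self):
        w = _world()
        i = w.add_organism(IDLE, PreyClass.NON_POISONOUS, 0, 0)
        ov = w.organism(i)
        for f in (0.0, 0.3, 1.0):
            assert eco.perceive_class(ov, f) == PreyClass.NON_POISONOUS

    def test_perfect_fidelity_shows_display(self):
        w = _world()
        m = w.add_organism(IDLE, PreyClass.MIMIC, 0, 0,
                           displayed=PreyClass.POISONOUS)
        ov = w.organism(m)
        rng = np.random.default_rng(0)
        assert all(eco.perceive_class(ov, 1.0, rng) == PreyClass.POISONOUS
                   for _ in range(100))

    def test_low_fidelity_shows_display_ten_percent(self):
        w = _world()
        m = w.add_organism(IDLE, PreyClass.MIMIC, 0, 0,
                           displayed=PreyClass.POISONOUS)
        ov = w.organism(m)
        rng = np.random.default_rng(1)
        n = 10_000
        hits = sum(eco.perceive_class(ov, 0.1, rng) == PreyClass.POISONOUS
                   for _ in range(n))
        half = 2.576 * np.sqrt(0.1 * 0.9 / n)
        assert abs(hits / n - 0.1) < half

    def test_fidelity_validated(self):
        w = _world()
        ov = w.organism(w.add_organism(IDLE, PreyClass.MIMIC, 0, 0))
        with pytest.raises(ValueError):
            eco.perceive_class(ov, 1.5)


class TestResolveAttack:
    def test_poisonous_kill_applies_penalty_without_gain(self):
        w = _world(poison_level=0.1)
        pred = w.add_organism(IDLE, None, 2, 2, facing=2, stored=9.0, is_predator=True)
        w.add_organism(IDLE, PreyClass.POISONOUS, 3, 2, stored=10.0)
        out = eco.resolve_attack(w, pred, {0, 1, 2})
        assert out.result == AttackResult.KILL
        assert out.resource_delta_attacker == pytest.approx(-1.0)
        assert w.organism(pred).stored == pytest.approx(8.0)

    def test_penalty_floors_stores_at_zero(self):
        w = _world(poison_level=1.0)
        pred = w.add_organism(IDLE, None, 2, 2, facing=2, stored=0.5, is_predator=True)
        w.add_organism(IDLE, PreyClass.POISONOUS, 3, 2, stored=10.0)
        eco.resolve_attack(w, pred, {0, 1, 2})
        assert w.organism(pred).stored == 0.0

    def test_non_poisonous_kill_pays_conversion_gain(self):
        w = _world(conversion_efficiency=0.25)
        pred = w.add_organism(IDLE, None, 2, 2, facing=2, stored=0.0, is_predator=True)
        w.add_organism(IDLE, PreyClass.NON_POISONOUS, 3, 2, stored=8.0)
        out = eco.resolve_attack(w, pred, {0, 1, 2})
        assert out.resource_delta_attacker == pytest.approx(2.0)

    def test_mimic_displaying_poisonous_dies_to_poison_specialist(self):
        # predator preference matches the mimic's DISPLAYED class; the kill
        # pays the safe-prey benefit because the mimic is not actually toxic
        w = _world(conversion_efficiency=0.25, fidelity=1.0)
        pred = w.add_organism(IDLE, None, 2, 2, facing=2, stored=0.0, is_predator=True)
        w.add_organism(IDLE, PreyClass.MIMIC, 3, 2, stored=4.0,
                       displayed=PreyClass.POISONOUS)
        out = eco.resolve_attack(w, pred, {int(PreyClass.POISONOUS)})
        assert out.result == AttackResult.KILL
        assert out.resource_delta_attacker == pytest.approx(1.0)

    def test_display_mismatch_fails_attack(self):
        w = _world()
        pred = w.add_organism(IDLE, None, 2, 2, facing=2, is_predator=True)
        v = w.add_organism(IDLE, PreyClass.NON_POISONOUS, 3, 2, stored=5.0)
        out = eco.resolve_attack(w, pred, {int(PreyClass.POISONOUS)})
        assert out.result == AttackResult.CLASS_MISMATCH
        assert w.organism(v).alive

    def test_empty_cell_is_no_target(self):
        w = _world()
        pred = w.add_organism(IDLE, None, 2, 2, facing=2, is_predator=True)
        assert eco.resolve_attack(w, pred, {0, 1, 2}).result == AttackResult.NO_TARGET

    def test_floor_blocks_below_900_and_permits_at_900(self):
        cfg = ExperimentConfig(width=40, height=40, prey_floor=900,
                               class_cap=1000, n_updates=0)
        w = World(cfg, seed=3)
        pred = w.add_organism(IDLE, None, 2, 2, facing=2, is_predator=True)
        w.add_organism(IDLE, PreyClass.NON_POISONOUS, 3, 2, stored=1.0)
        for k in range(898):
            w.add_organism(IDLE, PreyClass.POISONOUS, 5 + k % 30, 5 + k // 30)
        assert w.total_prey == 899
        assert eco.resolve_attack(w, pred, {0, 1, 2}).result == AttackResult.BLOCKED_BY_FLOOR
        w.add_organism(IDLE, PreyClass.MIMIC, 30, 30)
        assert w.total_prey == 900
        assert eco.resolve_attack(w, pred, {0, 1, 2}).result == AttackResult.KILL

    def test_first_kill_promotes_prey_to_predator_irreversibly(self):
        w = _world()
        hunter = w.add_organism(IDLE, PreyClass.MIMIC, 2, 2, facing=2)
        w.add_organism(IDLE, PreyClass.NON_POISONOUS, 3, 2, stored=1.0)
        counts_before = w.prey_counts.copy()
        out = eco.resolve_attack(w, hunter, {0, 1, 2})
        assert out.result == AttackResult.KILL
        ov = w.organism(hunter)
        assert ov.is_predator
        assert w.n_predators == 1
        # leaves the mimic class and the victim's class both shrink
        assert w.prey_counts[PreyClass.MIMIC] == counts_before[PreyClass.MIMIC] - 1
        assert w.prey_counts[PreyClass.NON_POISONOUS] == counts_before[PreyClass.NON_POISONOUS] - 1


class TestDisplayChange:
    def test_mimic_changes_and_reverts(self):
        w = _world()
        m = w.add_organism(IDLE, PreyClass.MIMIC, 0, 0)
        eco.apply_display_change(w, m, PreyClass.POISONOUS)
        assert w.organism(m).displayed_class == PreyClass.POISONOUS
        eco.apply_display_change(w, m, PreyClass.MIMIC)
        assert w.organism(m).displayed_class == PreyClass.MIMIC

    def test_non_mimic_unchanged(self):
        w = _world()
        i = w.add_organism(IDLE, PreyClass.NON_POISONOUS, 0, 0)
        eco.apply_display_change(w, i, PreyClass.POISONOUS)
        assert w.organism(i).displayed_class == PreyClass.NON_POISONOUS

    def test_mimicry_disabled_control(self):
        w = _world(mimicry_enabled=False)
        m = w.add_organism(IDLE, PreyClass.MIMIC, 0, 0)
        eco.apply_display_change(w, m, PreyClass.POISONOUS)
        assert w.organism(m).displayed_class == PreyClass.MIMIC


class TestReproduce:
    def test_below_threshold_refused(self):
        w = _world()
        i = w.add_organism(IDLE, PreyClass.NON_POISONOUS, 5, 5, stored=9.99)
        assert eco.reproduce(w, i) is None
        assert w.organism(i).stored == pytest.approx(9.99)

    def test_at_threshold_spawns_and_spends(self):
        w = _world()
        i = w.add_organism(IDLE, PreyClass.NON_POISONOUS, 5, 5, stored=10.0)
        child = eco.reproduce(w, i)
        assert child is not None
        assert w.organism(i).stored == 0.0
        cv = w.organism(child)
        assert cv.stored == 0.0
        assert cv.true_class == cv.displayed_class  # offspring start honest

    def test_predator_offspring_inherit_predator_status(self):
        w = _world()
        i = w.add_organism(IDLE, None, 5, 5, stored=20.0, is_predator=True)
        child = eco.reproduce(w, i)
        cv = w.organism(child)
        assert cv.is_predator
        assert cv.true_class is None
        assert w.n_predators == 2

    def test_birth_class_frequencies(self):
        # births through the full reproduction kernel follow the configured
        # 25/25/50 split (binomial 99% CIs at n=6,000)
        cfg = ExperimentConfig(width=40, height=40, class_cap=10_000,
                               prey_floor=0, n_updates=0)
        w = World(cfg, seed=42)
        parent = w.add_organism(IDLE, PreyClass.NON_POISONOUS, 20, 20, stored=1e9)
        n = 6_000
        baseline = w.prey_counts.copy()
        for _ in range(n):
            eco.reproduce(w, parent)
        freqs = (w.prey_counts - baseline) / n
        for got, p in zip(freqs, (0.25, 0.25, 0.50)):
            half = 2.576 * np.sqrt(p * (1 - p) / n)
            assert abs(got - p) < half


class TestAssignBirthClass:
    def test_degenerate_fractions(self):
        cfg = EcologyConfig(birth_fractions=(0.0, 0.0, 1.0))
        rng = np.random.default_rng(0)
        assert all(eco.assign_birth_class(cfg, rng) == PreyClass.POISONOUS
                   for _ in range(50))

    def test_chi_square_goodness_of_fit(self):
        cfg = EcologyConfig()
        rng = np.random.default_rng(11)
        draws = [eco.assign_birth_class(cfg, rng) for _ in range(10_000)]
        counts = np.bincount(draws, minlength=3)
        _, p = chisquare(counts, f_exp=np.array([0.25, 0.25, 0.50]) * 10_000)
        assert p > 0.001

    def test_bad_fractions_rejected(self):
        cfg = EcologyConfig(birth_fractions=(0.5, 0.2, 0.2))
        with pytest.raises(ConfigError):
            eco.assign_birth_class(cfg, np.random.default_rng(0))


class TestClassCap:
    def test_no_removal_below_cap(self):
        w = _world(class_cap=1000)
        for k in range(999):
            w.add_organism(IDLE, PreyClass.POISONOUS, k % 12, k // 12 % 12)
        w.add_organism(IDLE, PreyClass.POISONOUS, 0, 0, enforce_cap=True)
        assert w.prey_counts[PreyClass.POISONOUS] == 1000

    def test_removal_keeps_count_at_cap_and_spares_newborn(self):
        w = _world(class_cap=50)
        for k in range(50):
            w.add_organism(IDLE, PreyClass.MIMIC, k % 12, k // 12)
        for _ in range(200):
            newborn = w.add_organism(IDLE, PreyClass.MIMIC, 1, 1, enforce_cap=False)
            removed = eco.enforce_class_cap(w, PreyClass.MIMIC)
            assert removed is not None and removed != newborn
            assert w.prey_counts[PreyClass.MIMIC] == 50

    def test_removal_uniform_over_incumbents(self):
        # the evicted member-list position is a uniform draw over incumbents;
        # chi-square at alpha = 0.001 over 5,000 evictions at cap 50
        w = _world(class_cap=50)
        ids = [w.add_organism(IDLE, PreyClass.POISONOUS, k % 12, k // 12)
               for k in range(50)]
        pos = {i: int(w._cpos[i]) for i in ids}
        counts = np.zeros(50)
        for _ in range(5_000):
            newborn = w.add_organism(IDLE, PreyClass.POISONOUS, 1, 1)
            removed = eco.enforce_class_cap(w, PreyClass.POISONOUS)
            p = pos.pop(removed)
            counts[p] += 1
            pos[newborn] = p
        _, pval = chisquare(counts)
        assert pval > 0.001


def test_interaction_invariants_over_random_event_sequences():
    """Sweep random ecology events; class counts never exceed the cap, only
    mimics are dishonest, predator flags never revert, stores stay >= 0."""
    cfg = ExperimentConfig(width=10, height=10, class_cap=15, prey_floor=0,
                           fidelity=0.5, n_updates=0)
    w = World(cfg, seed=77)
    rng = np.random.default_rng(77)
    prev_pred = set()
    for step in range(2_000):
        alive = w.alive_ids()
        ev = rng.integers(5)
        if ev == 0 or len(alive) < 2:
            w.add_organism(IDLE, PreyClass(int(rng.integers(3))),
                           int(rng.integers(10)), int(rng.integers(10)),
                           stored=float(rng.uniform(0, 12)), enforce_cap=True)
        elif ev == 1:
            i = int(rng.choice(alive))
            w._facing[i] = rng.integers(8)
            eco.resolve_attack(w, i, {0, 1, 2})
        elif ev == 2:
            eco.apply_display_change(w, int(rng.choice(alive)),
                                     PreyClass(int(rng.integers(3))))
        elif ev == 3:
            eco.reproduce(w, int(rng.choice(alive)))
        else:
            w.remove_organism(int(rng.choice(alive)))
        assert np.all(w.prey_counts <= cfg.class_cap)
        alive = w.alive_ids()
        assert np.all(w._stored[alive] >= 0)
        dishonest = alive[w._disp[alive] != w._tclass[alive]]
        assert np.all(w._tclass[dishonest] == int(PreyClass.MIMIC))
        now_pred = set(alive[w._is_pred[alive] != 0].tolist())
        # predators alive through this event are still predators (slots freed
        # by deaths may be recycled later, so compare against last iteration)
        assert prev_pred & set(alive.tolist()) <= now_pred
        prev_pred = now_pred
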