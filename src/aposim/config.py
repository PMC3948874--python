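"""Experiment configuration: every treatment knob, validated, with defaults
reproducing the full-scale study setup (251x251 grid, per-class caps of 1,000,
prey floor 900, reproduction threshold 10 units, 25% conversion efficiency,
perfect mimic fidelity, 500,000 updates, 30 replicates).

A configuration is a flat set of named fields; it loads from YAML (unknown
keys are rejected, missing keys take defaults) and echoes itself into every
output file so results are self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unparseable, unknown or out-of-range configuration values."""


# The poison-level sweep used by the avoidance-curve experiment.
POISON_LEVEL_SWEEP = (0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4, 0.75, 1.0)


@dataclass
class EcologyConfig:
    """Interaction and demographic rules.

    poison_level
        Fraction ``p`` of a poisonous victim's stores deducted from the
        attacker's stores on consumption (dimensionless, in [0, 1]).
    conversion_efficiency
        Fraction ``e`` of a non-poisonous or mimic victim's stores gained by
        the attacker.
    reproduction_threshold
        Resource units an organism must hold (and spend) to reproduce.
    class_cap
        Maximum organisms per prey class; a birth beyond it evicts a random
        incumbent of that class.
    prey_floor
        Total prey count below which all attacks are blocked (the boundary
        itself permits attacks).
    birth_fractions
        Probabilities a prey newborn is (non-poisonous, mimic, poisonous).
    fidelity
        Probability a predator perceives a mimic's displayed class rather
        than its true class (1.0 = perfect mimicry; the imperfect-mimicry
        treatment uses 0.1).
    mimicry_enabled
        When false the display-change instruction is inert even in mimics
        (the mimicry-disabled control).
    max_age
        Updates after which an organism dies; the only age-based mortality
        and the turnover that lets prey scarcity control predator numbers.
        The default (1,000 updates, roughly 25 desk-scale prey generation
        times) leaves room for several predator reproduction cycles per
        lifetime; much shorter lifespans extinguish heritable predator
        lineages entirely.
    poisonous_kills_yield_gain
        Off by default: a poisonous kill yields only the penalty, no
        conversion gain.
    """

    poison_level: float = 0.1
    conversion_efficiency: float = 0.25
    reproduction_threshold: float = 10.0
    class_cap: int = 1000
    prey_floor: int = 900
    birth_fractions: tuple[float, float, float] = (0.25, 0.25, 0.50)
    fidelity: float = 1.0
    mimicry_enabled: bool = True
    max_age: int = 1000
    poisonous_kills_yield_gain: bool = False

    def validate(self) -> None:
        for name in ("poison_level", "conversion_efficiency", "fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.reproduction_threshold <= 0:
            raise ConfigError("reproduction_threshold must be positive")
        if self.class_cap < 1:
            raise ConfigError("class_cap must be >= 1")
        if self.prey_floor < 0:
            raise ConfigError("prey_floor must be >= 0")
        if self.prey_floor > 3 * self.class_cap:
            raise ConfigError("prey_floor cannot exceed 3 * class_cap")
        bf = self.birth_fractions
        if len(bf) != 3 or any(not 0.0 <= f <= 1.0 for f in bf):
            raise ConfigError("birth_fractions must be three probabilities")
        if abs(sum(bf) - 1.0) > 1e-9:
            raise ConfigError(f"birth_fractions must sum to 1, got {sum(bf)}")
        if self.max_age < 1:
            raise ConfigError("max_age must be >= 1")


@dataclass
class ExperimentConfig(EcologyConfig):
    """One treatment: ecology rules plus world geometry, genetics and the run
    schedule."""

    width: int = 251
    height: int = 251
    max_per_cell: float = 1.0
    inflow_rate: float = 0.01
    initial_stock: float = 1.0
    per_class_resources: bool = True

    genome_length: int = 100
    exec_budget: int = 30
    max_genome_length: int = 400
    p_substitution: float = 0.25
    p_insertion: float = 0.05
    p_deletion: float = 0.05
    attack_enabled: bool = True

    n_updates: int = 500_000
    n_replicates: int = 30
    record_every: int = 100
    seed: int = 1
    predator_headroom: int = 0  # 0 -> defaults to 4 * class_cap
    treatment: str = ""

    def validate(self) -> None:
        super().validate()
        if self.width < 1 or self.height < 1:
            raise ConfigError("grid dimensions must be >= 1")
        if self.max_per_cell <= 0:
            raise ConfigError("max_per_cell must be positive")
        if self.inflow_rate < 0:
            raise ConfigError("inflow_rate must be >= 0")
        if not 0 <= self.initial_stock <= self.max_per_cell:
            raise ConfigError("initial_stock must be in [0, max_per_cell]")
        if self.genome_length < 1:
            raise ConfigError("genome_length must be >= 1")
        if self.max_genome_length < self.genome_length:
            raise ConfigError("max_genome_length must be >= genome_length")
        if self.exec_budget < 1:
            raise ConfigError("exec_budget must be >= 1")
        for name in ("p_substitution", "p_insertion", "p_deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_updates < 0:
            raise ConfigError("n_updates must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")
        if self.predator_headroom < 0:
            raise ConfigError("predator_headroom must be >= 0")

    @property
    def capacity(self) -> int:
        """Organism slot pool: three full prey classes plus predator headroom.

        Predators are deliberately uncapped by the ecology (prey scarcity
        limits them); the headroom only bounds memory and sits well above
        any observed predator equilibrium.
        """
        headroom = self.predator_headroom or 4 * self.class_cap
        return 3 * self.class_cap + headroom

    @property
    def label(self) -> str:
        return self.treatment or f"p{self.poison_level:g}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["birth_fractions"] = list(self.birth_fractions)
        return d

    def replace(self, **changes) -> "ExperimentConfig":
        cfg = dataclasses.replace(self, **changes)
        cfg.validate()
        return cfg


_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)}


def config_from_dict(data: dict) -> ExperimentConfig:
    """Build and validate a configuration from a plain mapping; unknown keys
    are rejected by name."""
    unknown = set(data) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    if "birth_fractions" in data:
        data = dict(data)
        data["birth_fractions"] = tuple(data["birth_fractions"])
    try:
        cfg = ExperimentConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML configuration file; an empty file yields the full defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a mapping of configuration keys")
    return config_from_dict(data)


def desk_scale(cfg: ExperimentConfig | None = None, **overrides) -> ExperimentConfig:
    """Desk-scale preset: 50x50 grid, caps 100, floor 90, 20,000 updates,
    10 replicates, recording every 10 updates."""
    base = cfg or ExperimentConfig()
    return base.replace(
        width=50, height=50, class_cap=100, prey_floor=90,
        n_updates=20_000, n_replicates=10, record_every=10,
        **overrides,
    )


def sweep_configs(base: ExperimentConfig | None = None,
                  poison_levels=POISON_LEVEL_SWEEP) -> list[ExperimentConfig]:
    """One treatment configuration per poison level."""
    base = base or ExperimentConfig()
    return [base.replace(poison_level=p, treatment=f"p{p:g}") for p in poison_levels]
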