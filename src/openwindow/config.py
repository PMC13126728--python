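"""Simulation configuration: dataclasses, defaults, YAML/JSON loading.

Every numeric parameter of the agent-based model lives here with its
shipped default.  The published model description names the entities,
the tick cycle and the constraint logic but no rate constants, so all
defaults are calibration choices — tuned only so the model reproduces the
qualitative validation patterns — and are surfaced in the config rather
than hard-coded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "MopParams",
    "PomParams",
    "SimulationConfig",
    "load_config",
    "dump_config",
    "high_stress_config",
    "control_config",
]

#: Pre-training (T0) cohort means the simulator is initialized from
#: (cells/uL): the CD4 and CD8 subset means of the 22-athlete panel.
BASELINE_CD4_MEAN = 811.92
BASELINE_CD8_MEAN = 611.08


@dataclass
class MopParams:
    """Decision-layer (multi-objective / clonal-expansion) parameters."""

    objective_weights: tuple[float, float] = (0.5, 0.5)
    archive_size: int = 20
    clone_budget: int = 10
    mutation_scale: float = 0.1
    #: expected attack-ticks a daughter cell contributes, used to value the
    #: proliferate action's future defense in f1
    proliferation_horizon: float = 3.0
    #: per-tick per-agent sample size feeding the NNIA archive
    archive_sample: int = 8


@dataclass
class PomParams:
    """Pattern-oriented-modeling thresholds (decided operationalizations)."""

    aic_margin: float = 2.0
    final_window_frac: float = 0.1
    clearance_frac: float = 0.1
    pass_fraction_required: float = 0.8  # psi


@dataclass
class SimulationConfig:
    """Full parameterization of one simulator run.

    Cell-count fields are agent counts on the grid (the empirical T0 means
    scaled by ``scale``); energies and glucose are abstract resource
    units; lactate is in mmol/L equivalents so the suppression threshold
    7.0 mirrors the severe-intensity-domain criterion (BLa > 7.0 mmol/L)
    of the training protocol.
    """

    grid_width: int = 33
    grid_height: int = 33
    initial_cd4: int = 81  # round(811.92 * 0.1)
    initial_cd8: int = 61  # round(611.08 * 0.1)
    initial_apc: int = 20
    initial_pathogen: int = 30
    glucose_init: float = 10.0  # per-patch amount and regeneration cap
    glucose_regen: float = 0.25  # per patch per tick; deliberately below CD4 upkeep
    lactate_decay: float = 0.2  # per-tick fractional decay
    suppression_threshold: float = 7.0  # mmol/L-equivalent proliferation block
    energy_init: float = 10.0
    energy_max: float = 10.0
    move_cost: float = 0.1
    attack_cost: float = 0.4  # kept above glucose_regen so attacks stall when drained
    proliferation_cost: float = 4.0
    proliferation_energy_min: float = 8.0
    proliferation_prob: float = 0.25  # per eligible agent per tick, before NNIA scaling
    refill_rate: float = 0.3  # energy recovered per fed tick, up to energy_max
    demand_cd4: float = 0.30  # helper T cells are the more glycolytic population
    demand_cd8: float = 0.20
    demand_apc: float = 0.20
    detect_radius: int = 1  # Chebyshev radius, torus wraparound
    kill_prob: float = 0.5  # CD8 per-attacker kill probability
    kill_prob_cd4: float = 0.25  # CD4-assisted kill probability
    infect_prob: float = 0.05  # pathogen damages a co-located immune agent
    infection_damage: float = 1.0
    pathogen_replication_rate: float = 0.05  # per pathogen per tick
    pathogen_cap: int = 150
    exhaustion_ticks: int = 30  # effector ticks under suppressive lactate
    exhaustion_grace_ticks: int = 10  # exhausted agents persist this long
    deactivation_ticks: int = 25  # effector reverts to naive after quiet spell
    stress_multiplier: float = 1.0
    stress_drain_scale: float = 1.5  # glucose drained per patch per unit zone weight
    ticks: int = 280  # 10 ticks/day x 28 days
    ticks_per_day: int = 10
    seed: int = 20220202
    mop: MopParams = field(default_factory=MopParams)
    pom: PomParams = field(default_factory=PomParams)

    def __post_init__(self) -> None:
        if self.grid_width < 3 or self.grid_height < 3:
            raise ValueError("grid must be at least 3x3")
        for name in (
            "kill_prob",
            "kill_prob_cd4",
            "infect_prob",
            "pathogen_replication_rate",
            "lactate_decay",
            "proliferation_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("initial_cd4", "initial_cd8", "initial_apc", "initial_pathogen", "ticks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _build(cls, data: dict, path: str = ""):
    """Recursively build a dataclass from a dict, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = f" in {path}" if path else ""
        raise KeyError(f"unknown config key(s){where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) or name in ("mop", "pom"):
            sub = {"mop": MopParams, "pom": PomParams}[name]
            if not isinstance(value, dict):
                raise TypeError(f"config key {name!r} must be a mapping")
            kwargs[name] = _build(sub, value, path=name)
        else:
            if name == "objective_weights" and isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # wrong value type for a field
        raise TypeError(f"invalid config value: {exc}") from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML or JSON config file; missing keys take shipped defaults.

    Unknown keys are rejected by name (typos fail loudly rather than being
    silently ignored).  An empty file yields the full default config.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise TypeError("config file must contain a mapping at top level")
    return _build(SimulationConfig, data)


def dump_config(config: SimulationConfig) -> dict:
    """Config as a plain JSON-serializable dict (tuples become lists)."""
    return json.loads(json.dumps(dataclasses.asdict(config)))


def high_stress_config(seed: int = 20220202, **overrides) -> SimulationConfig:
    """The shipped high-stress scenario: full 4-week training-load input."""
    return dataclasses.replace(SimulationConfig(seed=seed), stress_multiplier=1.0, **overrides)


def control_config(seed: int = 20220202, **overrides) -> SimulationConfig:
    """The shipped control scenario: identical but with zero stress input."""
    return dataclasses.replace(SimulationConfig(seed=seed), stress_multiplier=0.0, **overrides)
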