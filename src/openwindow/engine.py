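"""Agent-based immune-metabolic simulator.

A headless, array-based re-implementation of a NetLogo-style immune
model: CD4+ and CD8+ T cells, antigen-presenting cells (APCs) and
pathogens move on a 2-D torus of glucose-bearing patches while a global
systemic-lactate level — driven by the training-load stress series —
inhibits T-cell proliferation above a suppression threshold.

Every tick executes four phases in order:

1. **Movement** — each agent steps to a uniformly chosen Moore-neighbour
   patch (torus wraparound); immune agents pay ``move_cost`` energy.
2. **Metabolic** — immune agents consume patch glucose up to their
   kind-specific demand plus a small energy refill, with pro-rata
   rationing when a patch cannot cover the co-located agents' total
   appetite; the stress series then injects lactate and drains glucose
   globally, lactate decays geometrically and patches regenerate.
3. **Immune** — APCs that detect pathogens become antigen-loaded; naive
   T cells co-located with a loaded APC activate to effector; each
   non-exhausted T cell chooses an action through the multi-objective
   decision layer, and pathogens within the detection radius of
   attacking T cells are killed probabilistically (CD8 attacks carry a
   higher kill weight than CD4-assisted ones).  Pathogens damage
   co-located immune agents with a small infection probability.
4. **State update** — effector T cells whose decision was to proliferate
   (and that clear the energy, glucose and strict lactate gates) spawn a
   daughter; agents at zero energy undergo apoptosis; effectors that
   accumulate enough ticks under suppressive lactate become exhausted and
   are removed after a grace period; pathogens replicate up to a cap.

Emergent immunosuppression is not hard-coded: population contraction
arises from the competition between the training load's glucose drain
and the energetic cost of immune activity.  CD4 cells are modelled as
the more glycolytic population (higher per-tick demand), which is what
drives the CD4/CD8 ratio down under sustained substrate scarcity.

All stochasticity flows from a single seeded generator per run; the same
config and seed reproduce a trace exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import StressSeries, generate_stress_series, table_training_schedule
from .config import BASELINE_CD4_MEAN, BASELINE_CD8_MEAN, SimulationConfig, dump_config
from .decisions import ParetoArchive, nnia_update, DecisionVector

__all__ = [
    "ImmuneAgents",
    "Pathogens",
    "Environment",
    "SimulationTrace",
    "initialize_from_baseline",
    "init_state",
    "step",
    "run_simulation",
]

CD4, CD8, APC = 0, 1, 2
NAIVE, EFFECTOR, EXHAUSTED = 0, 1, 2
KIND_NAMES = {CD4: "cd4", CD8: "cd8", APC: "apc"}

_MOORE = np.array([(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)])

TALLY_COLUMNS = [
    "prolif_cd4",
    "prolif_cd8",
    "apoptosis_cd4",
    "apoptosis_cd8",
    "apoptosis_apc",
    "exhaustion_cd4",
    "exhaustion_cd8",
    "exhaustion_apc",
    "killed_pathogen",
    "pathogen_replication",
]


@dataclass
class ImmuneAgents:
    """Struct-of-arrays container for the immune agents."""

    kind: np.ndarray  # CD4 | CD8 | APC
    x: np.ndarray
    y: np.ndarray
    energy: np.ndarray
    activation: np.ndarray  # NAIVE | EFFECTOR | EXHAUSTED (T cells)
    supp_ticks: np.ndarray  # effector ticks spent under suppressive lactate
    exhausted_ticks: np.ndarray
    idle_ticks: np.ndarray  # ticks without a pathogen in the detect radius
    loaded: np.ndarray  # APC antigen-loaded flag

    def __len__(self) -> int:
        return self.kind.size

    def count(self, kind: int) -> int:
        return int((self.kind == kind).sum())

    def keep(self, mask: np.ndarray) -> None:
        for f in dataclasses.fields(self):
            setattr(self, f.name, getattr(self, f.name)[mask])

    def append(self, other: "ImmuneAgents") -> None:
        for f in dataclasses.fields(self):
            setattr(
                self,
                f.name,
                np.concatenate([getattr(self, f.name), getattr(other, f.name)]),
            )


@dataclass
class Pathogens:
    x: np.ndarray
    y: np.ndarray
    virulence: np.ndarray  # multiplies the replication rate

    def __len__(self) -> int:
        return self.x.size

    def keep(self, mask: np.ndarray) -> None:
        self.x, self.y, self.virulence = self.x[mask], self.y[mask], self.virulence[mask]


@dataclass
class Environment:
    glucose: np.ndarray  # (width, height) per-patch resource
    lactate: float  # single systemic scalar
    tick: int = 0


@dataclass
class SimulationTrace:
    """Per-tick population, resource and event-tally time series."""

    frame: pd.DataFrame
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SimulationTrace":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# initialization


def _empty_agents(n: int) -> ImmuneAgents:
    return ImmuneAgents(
        kind=np.zeros(n, dtype=np.int8),
        x=np.zeros(n, dtype=np.int64),
        y=np.zeros(n, dtype=np.int64),
        energy=np.zeros(n),
        activation=np.full(n, NAIVE, dtype=np.int8),
        supp_ticks=np.zeros(n, dtype=np.int64),
        exhausted_ticks=np.zeros(n, dtype=np.int64),
        idle_ticks=np.zeros(n, dtype=np.int64),
        loaded=np.zeros(n, dtype=bool),
    )


def init_state(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ImmuneAgents, Pathogens, Environment]:
    """Place agents uniformly at random on a uniform glucose field."""
    counts = [config.initial_cd4, config.initial_cd8, config.initial_apc]
    n = sum(counts)
    agents = _empty_agents(n)
    agents.kind = np.repeat(np.array([CD4, CD8, APC], dtype=np.int8), counts)
    agents.x = rng.integers(0, config.grid_width, n)
    agents.y = rng.integers(0, config.grid_height, n)
    # heterogeneous initial reserves stagger starvation under scarcity
    agents.energy = config.energy_init * rng.uniform(0.5, 1.0, n)
    m = config.initial_pathogen
    pathogens = Pathogens(
        x=rng.integers(0, config.grid_width, m),
        y=rng.integers(0, config.grid_height, m),
        virulence=rng.uniform(0.75, 1.25, m),
    )
    env = Environment(
        glucose=np.full((config.grid_width, config.grid_height), config.glucose_init),
        lactate=0.0,
    )
    return agents, pathogens, env


def initialize_from_baseline(
    scale: float = 0.1,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    baseline: tuple[float, float] = (BASELINE_CD4_MEAN, BASELINE_CD8_MEAN),
    **overrides,
) -> tuple[ImmuneAgents, Pathogens, Environment, SimulationConfig]:
    """Initial state with CD4/CD8 counts proportional to the T0 cohort means.

    With the default scale 0.1 the grid starts with round(811.92 * 0.1) = 81
    CD4 and round(611.08 * 0.1) = 61 CD8 agents (initial ratio 1.33).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    cd4 = round(baseline[0] * scale)
    cd8 = round(baseline[1] * scale)
    if cd4 == 0 or cd8 == 0:
        raise ValueError("scale too small: an initial population rounds to zero")
    cfg = dataclasses.replace(
        config or SimulationConfig(),
        initial_cd4=cd4,
        initial_cd8=cd8,
        **overrides,
    )
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    agents, pathogens, env = init_state(cfg, rng)
    return agents, pathogens, env, cfg


# ---------------------------------------------------------------------------
# helpers


def _occupancy(x: np.ndarray, y: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    grid = np.zeros(shape)
    np.add.at(grid, (x, y), 1.0)
    return grid


def _neighbourhood_sum(grid: np.ndarray, radius: int) -> np.ndarray:
    """Sum over the (2r+1)^2 Chebyshev neighbourhood with torus wraparound."""
    out = np.zeros_like(grid)
    for dx in range(-radius, radius + 1):
        rolled = np.roll(grid, dx, axis=0)
        for dy in range(-radius, radius + 1):
            out += np.roll(rolled, dy, axis=1)
    return out


def _batch_decide(
    kind: np.ndarray,
    pathogens_near: np.ndarray,
    local_glucose: np.ndarray,
    lactate: float,
    config: SimulationConfig,
    proliferation_drive: float,
) -> np.ndarray:
    """Vectorized action choice for T cells; mirrors decisions.decide_action.

    Returns an int array: 0 rest, 1 migrate, 2 attack, 3 proliferate.
    Equal-weight scalarization over the feasible candidates; because the
    weights are positive, the scalar minimizer is automatically Pareto
    non-dominated, so no explicit front construction is needed.  The
    clonal-expansion drive is credited to the proliferate candidate only
    where that candidate is on the front (at least one detectable
    pathogen), exactly as the scalar routine does.
    """
    w1, w2 = config.mop.objective_weights
    kw = np.where(kind == CD8, config.kill_prob, config.kill_prob_cd4)
    k = pathogens_near
    n = kind.size
    scores = np.zeros((n, 4))
    scores[:, 1] = w2 * config.move_cost
    scores[:, 2] = w1 * (-k * kw) + w2 * config.attack_cost
    scores[:, 3] = w1 * (-k * kw * config.mop.proliferation_horizon) + w2 * config.proliferation_cost
    scores[:, 3] -= np.where(k >= 1, proliferation_drive, 0.0)
    feasible = np.ones((n, 4), dtype=bool)
    feasible[:, 1] = local_glucose >= config.move_cost
    feasible[:, 2] = local_glucose >= config.attack_cost
    feasible[:, 3] = (local_glucose >= config.proliferation_cost) & (
        lactate < config.suppression_threshold
    )
    scores[~feasible] = np.inf
    return scores.argmin(axis=1)


REST, MIGRATE, ATTACK, PROLIFERATE = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# the tick cycle


def step(
    agents: ImmuneAgents,
    pathogens: Pathogens,
    env: Environment,
    config: SimulationConfig,
    rng: np.random.Generator,
    stress: StressSeries | None = None,
    proliferation_drive: float = 0.0,
    proliferation_intensity: float = 1.0,
) -> dict:
    """Advance the model by one tick (movement, metabolic, immune, update).

    Returns the tick's event tallies.  ``proliferation_drive`` and
    ``proliferation_intensity`` come from the clonal-expansion archive and
    modulate how eagerly eligible effectors divide; they never override
    the metabolic feasibility constraints.
    """
    W, H = config.grid_width, config.grid_height
    tallies = dict.fromkeys(TALLY_COLUMNS, 0)

    # -- phase 1: movement -------------------------------------------------
    n = len(agents)
    moving = agents.activation != EXHAUSTED  # exhausted agents no longer act
    if n:
        steps = _MOORE[rng.integers(0, 8, n)]
        agents.x = np.where(moving, (agents.x + steps[:, 0]) % W, agents.x)
        agents.y = np.where(moving, (agents.y + steps[:, 1]) % H, agents.y)
        agents.energy = np.where(moving, agents.energy - config.move_cost, agents.energy)
    m = len(pathogens)
    if m:
        psteps = _MOORE[rng.integers(0, 8, m)]
        pathogens.x = (pathogens.x + psteps[:, 0]) % W
        pathogens.y = (pathogens.y + psteps[:, 1]) % H

    # -- phase 2: metabolic ------------------------------------------------
    demand = np.choose(agents.kind, [config.demand_cd4, config.demand_cd8, config.demand_apc])
    refill = np.minimum(config.refill_rate, np.maximum(0.0, config.energy_max - agents.energy))
    appetite = demand + refill
    if n:
        patch_total = np.zeros((W, H))
        np.add.at(patch_total, (agents.x, agents.y), appetite)
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(
                patch_total > 0, np.minimum(1.0, env.glucose / patch_total), 0.0
            )
        intake = appetite * share[agents.x, agents.y]
        env.glucose -= np.minimum(env.glucose, patch_total)
        agents.energy = np.minimum(agents.energy + intake - demand, config.energy_max)
    inj, drain = (stress.at(env.tick) if stress is not None else (0.0, 0.0))
    env.lactate += inj * config.stress_multiplier
    env.glucose = np.maximum(env.glucose - drain * config.stress_multiplier, 0.0)
    env.lactate *= 1.0 - config.lactate_decay
    env.glucose = np.minimum(env.glucose + config.glucose_regen, config.glucose_init)

    # -- phase 3: immune interaction --------------------------------------
    pathogen_grid = _occupancy(pathogens.x, pathogens.y, (W, H)) if m else np.zeros((W, H))
    near = _neighbourhood_sum(pathogen_grid, config.detect_radius)
    k_near = near[agents.x, agents.y] if n else np.zeros(0)

    # idle bookkeeping (drives effector deactivation and APC unloading)
    agents.idle_ticks = np.where(k_near >= 1, 0, agents.idle_ticks + 1)

    is_apc = agents.kind == APC
    agents.loaded = np.where(is_apc & (k_near >= 1), True, agents.loaded)
    agents.loaded = np.where(
        is_apc & (agents.idle_ticks >= config.deactivation_ticks), False, agents.loaded
    )

    loaded_grid = _occupancy(
        agents.x[agents.loaded], agents.y[agents.loaded], (W, H)
    ) if agents.loaded.any() else np.zeros((W, H))
    is_t = (agents.kind == CD4) | (agents.kind == CD8)
    activate = is_t & (agents.activation == NAIVE) & (loaded_grid[agents.x, agents.y] >= 1)
    agents.activation = np.where(activate, EFFECTOR, agents.activation)
    agents.supp_ticks = np.where(activate, 0, agents.supp_ticks)

    decisions = np.full(n, REST, dtype=np.int64)
    deciders = is_t & (agents.activation != EXHAUSTED)
    if deciders.any():
        decisions[deciders] = _batch_decide(
            agents.kind[deciders],
            k_near[deciders],
            env.glucose[agents.x[deciders], agents.y[deciders]],
            env.lactate,
            config,
            proliferation_drive,
        )

    attackers = deciders & (decisions == ATTACK)
    if attackers.any() and m:
        agents.energy = np.where(attackers, agents.energy - config.attack_cost, agents.energy)
        a8 = _occupancy(
            agents.x[attackers & (agents.kind == CD8)],
            agents.y[attackers & (agents.kind == CD8)],
            (W, H),
        )
        a4 = _occupancy(
            agents.x[attackers & (agents.kind == CD4)],
            agents.y[attackers & (agents.kind == CD4)],
            (W, H),
        )
        n8 = _neighbourhood_sum(a8, config.detect_radius)[pathogens.x, pathogens.y]
        n4 = _neighbourhood_sum(a4, config.detect_radius)[pathogens.x, pathogens.y]
        p_survive = (1.0 - config.kill_prob) ** n8 * (1.0 - config.kill_prob_cd4) ** n4
        killed = rng.random(m) >= p_survive
        tallies["killed_pathogen"] = int(killed.sum())
        pathogens.keep(~killed)
        m = len(pathogens)
        pathogen_grid = _occupancy(pathogens.x, pathogens.y, (W, H)) if m else np.zeros((W, H))

    if m and n and config.infect_prob > 0:
        co_located = pathogen_grid[agents.x, agents.y] >= 1
        hit = co_located & (rng.random(n) < config.infect_prob)
        agents.energy = np.where(hit, agents.energy - config.infection_damage, agents.energy)

    # -- phase 4: state update ---------------------------------------------
    proliferators = (
        deciders
        & (decisions == PROLIFERATE)
        & (agents.activation == EFFECTOR)
        & (agents.energy >= config.proliferation_energy_min)
        & (env.lactate < config.suppression_threshold)
    )
    if proliferators.any():
        spawn_p = config.proliferation_prob * float(np.clip(proliferation_intensity, 0.0, 1.0))
        spawning = proliferators & (rng.random(n) < spawn_p)
        idx = np.flatnonzero(spawning)
        if idx.size:
            agents.energy[idx] -= config.proliferation_cost
            daughters = _empty_agents(idx.size)
            daughters.kind = agents.kind[idx].copy()
            daughters.x = agents.x[idx].copy()
            daughters.y = agents.y[idx].copy()
            daughters.energy = np.full(idx.size, config.proliferation_cost)
            daughters.activation = np.full(idx.size, EFFECTOR, dtype=np.int8)
            tallies["prolif_cd4"] = int((agents.kind[idx] == CD4).sum())
            tallies["prolif_cd8"] = int((agents.kind[idx] == CD8).sum())
            agents.append(daughters)
            n = len(agents)

    # exhaustion: effectors accumulate suppressive-lactate exposure
    if env.lactate >= config.suppression_threshold:
        eff = agents.activation == EFFECTOR
        agents.supp_ticks = np.where(eff, agents.supp_ticks + 1, agents.supp_ticks)
    newly_exhausted = (agents.activation == EFFECTOR) & (
        agents.supp_ticks >= config.exhaustion_ticks
    )
    agents.activation = np.where(newly_exhausted, EXHAUSTED, agents.activation)
    exhausted = agents.activation == EXHAUSTED
    agents.exhausted_ticks = np.where(exhausted, agents.exhausted_ticks + 1, 0)

    # effector deactivation after a quiet spell at low lactate
    deactivate = (
        (agents.activation == EFFECTOR)
        & (agents.idle_ticks >= config.deactivation_ticks)
        & (env.lactate < config.suppression_threshold)
    )
    agents.activation = np.where(deactivate, NAIVE, agents.activation)
    agents.supp_ticks = np.where(deactivate, 0, agents.supp_ticks)

    # deaths
    dead_energy = agents.energy <= 0
    dead_exhausted = agents.exhausted_ticks > config.exhaustion_grace_ticks
    for kind, name in KIND_NAMES.items():
        tallies[f"apoptosis_{name}"] = int((dead_energy & (agents.kind == kind)).sum())
        tallies[f"exhaustion_{name}"] = int(
            (dead_exhausted & ~dead_energy & (agents.kind == kind)).sum()
        )
    agents.keep(~(dead_energy | dead_exhausted))

    # pathogen replication with a carrying cap
    m = len(pathogens)
    if m and m < config.pathogen_cap:
        replicate = rng.random(m) < config.pathogen_replication_rate * pathogens.virulence
        idx = np.flatnonzero(replicate)[: config.pathogen_cap - m]
        if idx.size:
            tallies["pathogen_replication"] = int(idx.size)
            pathogens.x = np.concatenate([pathogens.x, pathogens.x[idx]])
            pathogens.y = np.concatenate([pathogens.y, pathogens.y[idx]])
            pathogens.virulence = np.concatenate(
                [pathogens.virulence, pathogens.virulence[idx]]
            )

    env.tick += 1
    return tallies


# ---------------------------------------------------------------------------
# full runs


def _record(
    agents: ImmuneAgents,
    pathogens: Pathogens,
    env: Environment,
    tallies: dict,
) -> dict:
    cd4, cd8, apc = agents.count(CD4), agents.count(CD8), agents.count(APC)
    row = {
        "tick": env.tick,
        "cd4": cd4,
        "cd8": cd8,
        "apc": apc,
        "pathogen": len(pathogens),
        "cd4_cd8_ratio": cd4 / cd8 if cd8 else np.nan,
        "total_immune": cd4 + cd8 + apc,
        "mean_energy": float(agents.energy.mean()) if len(agents) else 0.0,
        "lactate": env.lactate,
        "total_glucose": float(env.glucose.sum()),
    }
    row.update(tallies)
    return row


def _sample_archive_candidates(
    agents: ImmuneAgents,
    k_near: np.ndarray,
    glucose_local: np.ndarray,
    lactate: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[DecisionVector, tuple[float, float]]]:
    """Feasible candidate (decision, objectives) pairs from sampled T cells."""
    from .decisions import DecisionContext, candidate_actions, feasible, action_objectives

    is_t = np.flatnonzero(
        ((agents.kind == CD4) | (agents.kind == CD8)) & (agents.activation != EXHAUSTED)
    )
    if is_t.size == 0:
        return []
    take = min(config.mop.archive_sample, is_t.size)
    picked = rng.choice(is_t, size=take, replace=False)
    out = []
    for i in picked:
        ctx = DecisionContext(
            pathogens_in_radius=int(k_near[i]),
            local_glucose=float(glucose_local[i]),
            lactate=lactate,
            energy=float(agents.energy[i]),
            kill_weight=config.kill_prob if agents.kind[i] == CD8 else config.kill_prob_cd4,
            suppression_threshold=config.suppression_threshold,
            attack_cost=config.attack_cost,
            move_cost=config.move_cost,
            proliferation_cost=config.proliferation_cost,
            proliferation_horizon=config.mop.proliferation_horizon,
        )
        for x in candidate_actions(ctx):
            if feasible(x, ctx):
                out.append((x, action_objectives(x, ctx)))
    return out


def run_simulation(
    config: SimulationConfig,
    stress: StressSeries | None = None,
) -> SimulationTrace:
    """Run the full tick loop and return the per-tick trace.

    When no stress series is supplied and the config's stress multiplier
    is non-zero, the 4-week training-schedule series is generated from the
    run's own seed.  The trace has ``ticks + 1`` rows (the initial state
    plus one row per tick); identical config and seed give identical
    traces.
    """
    rng = np.random.default_rng(config.seed)
    if stress is None and config.stress_multiplier != 0.0:
        stress = generate_stress_series(
            table_training_schedule(),
            ticks_per_day=config.ticks_per_day,
            seed=config.seed % 2**31,
            drain_scale=config.stress_drain_scale,
        )
    agents, pathogens, env = init_state(config, rng)
    archive = ParetoArchive(max_size=config.mop.archive_size)
    drive, intensity = 0.0, 1.0
    rows = [_record(agents, pathogens, env, dict.fromkeys(TALLY_COLUMNS, 0))]
    W, H = config.grid_width, config.grid_height
    for _ in range(config.ticks):
        tallies = step(
            agents,
            pathogens,
            env,
            config,
            rng,
            stress=stress,
            proliferation_drive=drive,
            proliferation_intensity=intensity,
        )
        # clonal-expansion archive update from a sample of current contexts
        if len(agents):
            pgrid = (
                _occupancy(pathogens.x, pathogens.y, (W, H))
                if len(pathogens)
                else np.zeros((W, H))
            )
            k_near = _neighbourhood_sum(pgrid, config.detect_radius)[agents.x, agents.y]
            glucose_local = env.glucose[agents.x, agents.y]
            candidates = _sample_archive_candidates(
                agents, k_near, glucose_local, env.lactate, config, rng
            )
            archive, clones = nnia_update(
                archive,
                candidates,
                clone_budget=config.mop.clone_budget,
                mutation_scale=config.mop.mutation_scale,
                rng=rng,
            )
            prolif_clones = [c.intensity for c in clones if c.action == "proliferate"]
            intensity = float(np.mean(prolif_clones)) if prolif_clones else 1.0
            drive = 0.5 * intensity if prolif_clones else 0.0
        rows.append(_record(agents, pathogens, env, tallies))
    return SimulationTrace(pd.DataFrame(rows), config=dump_config(config))
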