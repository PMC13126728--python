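"""Multi-objective agent decision layer with an immune-algorithm archive.

Each tick, an immune agent faces a small menu of candidate actions —
proliferate, rest, attack, migrate, each with a continuous intensity in
[0, 1] — and chooses among them by solving a two-objective minimization:

    f1 = -(expected pathogens killed by the action this tick)
    f2 = metabolic cost in energy units

subject to metabolic feasibility constraints g_i(x) <= 0: the action's
energy demand must not exceed locally available glucose, and proliferation
is additionally forbidden whenever systemic lactate has reached the
suppression threshold (that constraint is strict — lactate exactly at the
threshold already blocks proliferation).  Feasible candidates are filtered
to the Pareto non-dominated set and one is picked by equal-weight
scalarization with seeded random tie-breaking, so runs are reproducible.

Clonal expansion is governed by a reduced non-dominated neighbor immune
algorithm (NNIA): an archive of non-dominated (decision, objective) pairs
is maintained across ticks; the clone budget is allocated proportionally
to each member's crowding isolation (most isolated first) and clone
intensities are Gaussian-perturbed.  The full published optimizer's
recombination and active-population machinery is deliberately reduced to
this archive + proportional cloning + mutation core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Action",
    "DecisionVector",
    "DecisionContext",
    "ParetoArchive",
    "dominates",
    "nondominated_front",
    "feasible",
    "action_objectives",
    "decide_action",
    "nnia_update",
    "ACTIONS",
]

ACTIONS = ("proliferate", "rest", "attack", "migrate")


@dataclass(frozen=True)
class DecisionVector:
    """A candidate action plus a continuous intensity in [0, 1]."""

    action: str
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")


Action = DecisionVector  # convenience alias


@dataclass(frozen=True)
class DecisionContext:
    """Everything an agent senses when choosing an action.

    ``kill_weight`` is the agent's per-pathogen kill probability (higher
    for cytotoxic CD8 cells than for CD4-assisted kills);
    ``pathogens_in_radius`` counts detectable targets.  Costs are energy
    units; ``local_glucose`` is the resource available on the agent's
    patch this tick, ``lactate`` the systemic inhibitory level.
    """

    pathogens_in_radius: int
    local_glucose: float
    lactate: float
    energy: float
    kill_weight: float = 0.6
    suppression_threshold: float = 7.0
    attack_cost: float = 0.4
    move_cost: float = 0.1
    proliferation_cost: float = 4.0
    #: expected attack-ticks a daughter cell contributes; values the
    #: proliferate action's future defense in f1
    proliferation_horizon: float = 3.0


def dominates(a, b) -> bool:
    """Pareto dominance under minimization.

    True iff ``a`` is <= ``b`` in every objective and strictly better in at
    least one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return bool((a <= b).all() and (a < b).any())


def nondominated_front(points) -> list[int]:
    """Indices of the non-dominated points of a list of objective vectors.

    A point dominated by no other point is on the front; duplicated points
    are all kept (a point never dominates its own copy).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("need a non-empty 2-D array of objective vectors")
    n = pts.shape[0]
    # vectorized pairwise dominance: dom[i, j] = i dominates j
    le = (pts[:, None, :] <= pts[None, :, :]).all(axis=2)
    lt = (pts[:, None, :] < pts[None, :, :]).any(axis=2)
    dom = le & lt
    return [j for j in range(n) if not dom[:, j].any()]


def constraint_values(x: DecisionVector, ctx: DecisionContext) -> list[float]:
    """The g_i(x) values; the action is feasible iff every one is <= 0.

    g1: energy demand of the action minus locally available glucose.
    g2 (proliferate only): lactate minus the suppression threshold, with a
    *strict* boundary — lactate equal to the threshold is infeasible, so a
    tiny epsilon is added to close the boundary against proliferation.
    """
    demand = {
        "rest": 0.0,
        "migrate": ctx.move_cost * x.intensity,
        "attack": ctx.attack_cost * x.intensity,
        "proliferate": ctx.proliferation_cost * x.intensity,
    }[x.action]
    g = [demand - ctx.local_glucose]
    if x.action == "proliferate":
        boundary = 0.0 if ctx.lactate < ctx.suppression_threshold else 1.0
        g.append(ctx.lactate - ctx.suppression_threshold + boundary * 1e-9)
    return g


def feasible(x: DecisionVector, ctx: DecisionContext) -> bool:
    """True iff every metabolic constraint g_i(x) <= 0 holds."""
    return all(g <= 0 for g in constraint_values(x, ctx))


def action_objectives(x: DecisionVector, ctx: DecisionContext) -> tuple[float, float]:
    """(f1, f2) for an action: negated expected kills, and energy cost.

    Attacking ``k`` detectable pathogens at intensity ``s`` is expected to
    kill ``k * kill_weight * s`` of them this tick.  A daughter cell from
    proliferation is credited with ``proliferation_horizon`` future
    attack-ticks against the currently detectable pathogens, so expanding
    is only worth its cost near an actual infection; migration contributes
    no kills.
    """
    if x.action == "attack":
        f1 = -ctx.pathogens_in_radius * ctx.kill_weight * x.intensity
        f2 = ctx.attack_cost * x.intensity
    elif x.action == "proliferate":
        f1 = (
            -ctx.pathogens_in_radius
            * ctx.kill_weight
            * ctx.proliferation_horizon
            * x.intensity
        )
        f2 = ctx.proliferation_cost * x.intensity
    elif x.action == "migrate":
        f1 = 0.0
        f2 = ctx.move_cost * x.intensity
    else:  # rest
        f1, f2 = 0.0, 0.0
    return f1, f2


def candidate_actions(ctx: DecisionContext) -> list[DecisionVector]:
    """The default candidate menu at full intensity."""
    return [DecisionVector(a, 1.0) for a in ACTIONS]


def decide_action(
    ctx: DecisionContext,
    rng: np.random.Generator,
    weights: tuple[float, float] = (0.5, 0.5),
    proliferation_drive: float = 0.0,
) -> DecisionVector:
    """Choose one feasible, non-dominated action for an agent.

    Candidates are enumerated, infeasible ones dropped (rest is always
    feasible, so the choice is total), the Pareto front computed, and the
    winner selected by weighted scalarization ``w1*f1 + w2*f2`` with
    seeded random tie-breaking.  ``proliferation_drive`` (from the clonal
    expansion archive) is subtracted from the proliferation candidate's
    scalar score, letting the NNIA layer modulate expansion intensity
    without ever overriding feasibility.
    """
    cands = [x for x in candidate_actions(ctx) if feasible(x, ctx)]
    if not cands:  # rest is always feasible, but stay total regardless
        return DecisionVector("rest", 0.0)
    objs = np.array([action_objectives(x, ctx) for x in cands])
    front = nondominated_front(objs)
    w = np.asarray(weights, dtype=float)
    scores = objs[front] @ w
    for k, i in enumerate(front):
        if cands[i].action == "proliferate":
            scores[k] -= proliferation_drive
    best = scores.min()
    ties = [front[k] for k in range(len(front)) if scores[k] <= best + 1e-12]
    pick = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
    return cands[pick]


# ---------------------------------------------------------------------------
# NNIA archive


@dataclass
class ParetoArchive:
    """Bounded archive of mutually non-dominated (decision, objective) pairs."""

    max_size: int = 20
    members: list[tuple[DecisionVector, tuple[float, ...]]] = field(default_factory=list)

    def objective_matrix(self) -> np.ndarray:
        return np.array([f for _, f in self.members], dtype=float)

    def crowding(self) -> np.ndarray:
        """Per-member isolation: nearest-neighbour distance in objective space.

        A lone member is maximally isolated by convention.
        """
        m = len(self.members)
        if m == 0:
            return np.empty(0)
        if m == 1:
            return np.array([np.inf])
        pts = self.objective_matrix()
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)


def _allocate_clones(isolation: np.ndarray, budget: int) -> np.ndarray:
    """Integer clone counts proportional to isolation, summing to budget.

    Infinite isolation (singleton archive) gets the whole budget; ties and
    rounding remainders go to the most isolated members first (largest
    remainder rule), so the allocation is deterministic.
    """
    m = isolation.size
    if m == 0:
        return np.zeros(0, dtype=int)
    iso = isolation.copy()
    if np.isinf(iso).any():
        iso = np.where(np.isinf(iso), 1.0, 0.0)
    if iso.sum() <= 0:
        iso = np.ones(m)
    share = iso / iso.sum() * budget
    counts = np.floor(share).astype(int)
    remainder = budget - counts.sum()
    if remainder > 0:
        frac = share - counts
        # stable: largest fractional part, then largest isolation, then index
        order = sorted(range(m), key=lambda i: (-frac[i], -iso[i], i))
        for i in order[:remainder]:
            counts[i] += 1
    return counts


def nnia_update(
    archive: ParetoArchive,
    candidates: list[tuple[DecisionVector, tuple[float, ...]]],
    clone_budget: int = 10,
    mutation_scale: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[ParetoArchive, list[DecisionVector]]:
    """One NNIA step: merge, prune to the front, truncate, clone, mutate.

    Candidates are merged into the archive; dominated members are removed;
    if the archive exceeds ``max_size`` the most *crowded* members (those
    with the smallest nearest-neighbour distance) are dropped; the clone
    budget is then split proportionally to isolation and each clone's
    intensity is perturbed by Gaussian noise of scale ``mutation_scale``,
    clipped back to [0, 1].  Returns the new archive and the clone list.
    """
    if clone_budget < 1:
        raise ValueError("clone_budget must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    pool = list(archive.members) + list(candidates)
    new = ParetoArchive(max_size=archive.max_size)
    if not pool:
        return new, []
    objs = np.array([f for _, f in pool], dtype=float)
    keep = nondominated_front(objs)
    # drop exact duplicates (same decision and objectives) to keep the
    # archive a set
    seen: set[tuple] = set()
    members = []
    for i in keep:
        key = (pool[i][0].action, round(pool[i][0].intensity, 12), tuple(pool[i][1]))
        if key not in seen:
            seen.add(key)
            members.append(pool[i])
    new.members = members
    while len(new.members) > new.max_size:
        iso = new.crowding()
        drop = int(np.argmin(iso))  # most crowded member goes first
        new.members.pop(drop)
    iso = new.crowding()
    counts = _allocate_clones(iso, clone_budget)
    clones: list[DecisionVector] = []
    for (x, _), c in zip(new.members, counts):
        for _ in range(int(c)):
            intensity = x.intensity
            if mutation_scale > 0:
                intensity = float(
                    np.clip(intensity + rng.normal(0.0, mutation_scale), 0.0, 1.0)
                )
            clones.append(DecisionVector(x.action, intensity))
    return new, clones
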