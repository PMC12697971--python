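"""The hybrid grey-wolf / chaotic dung-beetle wrapper search.

Continuous wolf positions live in a bounded box over the candidate-feature
dimensions and are binarized against the median of each wolf's own
components, so a mask is never empty and never full. Each iteration the
three leaders (alpha, beta, delta) are locally refined by a small chaotic
dung-beetle sub-swarm whose step length shrinks logarithmically with the
distance to the best-known position; the refined leaders then pull the rest
of the pack via the standard grey-wolf update with a linearly decaying
convergence factor a = 2(1 - t/T).

All stochasticity is either a per-agent logistic chaos stream or a numpy
Generator handed in by the caller, so runs are reproducible from one master
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import FitnessEvaluator, FitnessResult, compare_fitness


class SwarmError(ValueError):
    pass


@dataclass(frozen=True)
class SearchSpace:
    """Bounded continuous box: ``dim`` coordinates, each in [lower, upper]."""

    dim: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise SwarmError("dim must be >= 1")
        if not self.lower < self.upper:
            raise SwarmError("lower bound must be strictly below upper bound")


@dataclass
class ChaosStream:
    """Logistic-map pseudo-random stream x <- seed_param * x * (1 - x).

    With seed_param in (3, 4) the orbit is chaotic and stays inside (0, 1);
    its maximum is seed_param / 4.
    """

    seed_param: float = 3.9
    state: float = 0.5

    def __post_init__(self) -> None:
        if not (3.0 < self.seed_param < 4.0):
            raise SwarmError("seed_param must lie in (3, 4)")
        if not (0.0 < self.state < 1.0):
            raise SwarmError("chaos state must lie in (0, 1)")

    def next(self) -> float:
        self.state = self.seed_param * self.state * (1.0 - self.state)
        return self.state

    def draw(self, count: int) -> np.ndarray:
        return np.array([self.next() for _ in range(count)])


def logistic_sequence(stream: ChaosStream, count: int) -> np.ndarray:
    """Next ``count`` iterates of the stream's logistic map (stream advances)."""
    return stream.draw(count)


def spawn_streams(rng: np.random.Generator, n: int, seed_param: float = 3.9) -> list[ChaosStream]:
    """Independent chaos streams, one per agent, with rng-drawn initial states."""
    # keep states away from the 0/1 fixed points
    return [ChaosStream(seed_param, float(rng.uniform(0.05, 0.95))) for _ in range(n)]


def chaotic_init(
    space: SearchSpace, n_agents: int, streams: list[ChaosStream]
) -> np.ndarray:
    """Positions P_ij = l + (u - l) * delta_ij, delta from each agent's stream."""
    if len(streams) < n_agents:
        raise SwarmError(f"need {n_agents} streams, got {len(streams)}")
    pos = np.empty((n_agents, space.dim))
    for i in range(n_agents):
        pos[i] = space.lower + (space.upper - space.lower) * streams[i].draw(space.dim)
    return pos


def binarize_median(position: np.ndarray) -> np.ndarray:
    """Mask a continuous position against the median of its own components.

    Components strictly above the median (mean of the middle two for even
    length) are selected. A constant vector selects the ceil(J/2) lowest
    indices; if ties at the top make the strict comparison empty, the
    comparison relaxes to >= which is provably non-empty and non-full for a
    non-constant vector.
    """
    position = np.asarray(position, dtype=float)
    j = position.size
    if j < 2:
        raise SwarmError("position must have at least 2 components")
    if np.all(position == position[0]):
        mask = np.zeros(j, dtype=bool)
        mask[: math.ceil(j / 2)] = True
        return mask
    mu = float(np.median(position))
    mask = position > mu
    if not mask.any():  # median == max: >= selects the max ties, < all of J
        mask = position >= mu
    return mask


@dataclass
class WolfPack:
    """Population state: continuous positions, masks, fitness, leader indices."""

    positions: np.ndarray
    masks: np.ndarray
    fitness: list[FitnessResult]
    leaders: tuple[int, int, int]
    space: SearchSpace

    @property
    def alpha(self) -> FitnessResult:
        return self.fitness[self.leaders[0]]


def _rank_leaders(fitness: list[FitnessResult]) -> tuple[int, int, int]:
    import functools

    order = sorted(
        range(len(fitness)),
        key=functools.cmp_to_key(lambda a, b: compare_fitness(fitness[a], fitness[b])),
    )
    return order[0], order[1], order[2]


def evaluate_pack(
    positions: np.ndarray, space: SearchSpace, evaluator: FitnessEvaluator, feature_map
) -> WolfPack:
    """Binarize every position, score it, and rank the leaders.

    ``feature_map`` maps local dimensions to original feature indices so the
    fitness cache stays valid across filter restarts.
    """
    masks = np.stack([binarize_median(p) for p in positions])
    fitness = [
        evaluator.evaluate(tuple(feature_map[j] for j in np.flatnonzero(m)))
        for m in masks
    ]
    return WolfPack(positions, masks, fitness, _rank_leaders(fitness), space)


@dataclass
class GWOCoefficients:
    """Convergence factor a = 2(1 - t/T) plus the A/C random coefficients."""

    t: int
    T: int
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def a(self) -> float:
        return 2.0 * (1.0 - self.t / self.T)

    def draw_ac(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        """One (A, C) pair: A in [-a, a]^dim, C in [0, 2]^dim."""
        a = self.a
        A = 2.0 * a * self.rng.random(dim) - a
        C = 2.0 * self.rng.random(dim)
        return A, C


def gwo_position_update(
    xi: np.ndarray,
    leaders_pos: np.ndarray,
    coeffs: GWOCoefficients,
    fixed_ac: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Leader-averaged grey-wolf move for one wolf (no clipping here).

    X_k = X_leader - A_k * |C_k * X_leader - X_i| for each of the three
    leaders; the new position is their mean. ``fixed_ac`` injects
    deterministic (A, C) pairs for hand-checkable cases.
    """
    dim = xi.size
    cands = []
    for k in range(3):
        A, C = fixed_ac[k] if fixed_ac is not None else coeffs.draw_ac(dim)
        d = np.abs(C * leaders_pos[k] - xi)
        cands.append(leaders_pos[k] - A * d)
    return np.mean(cands, axis=0)


def gwo_step(
    pack: WolfPack,
    coeffs: GWOCoefficients,
    evaluator: FitnessEvaluator,
    feature_map,
) -> WolfPack:
    """Move every non-leader wolf toward the leaders; re-evaluate and re-rank."""
    lead_idx = set(pack.leaders)
    leaders_pos = np.stack([pack.positions[i] for i in pack.leaders])
    new_pos = pack.positions.copy()
    for i in range(pack.positions.shape[0]):
        if i in lead_idx:
            continue
        moved = gwo_position_update(pack.positions[i], leaders_pos, coeffs)
        new_pos[i] = np.clip(moved, pack.space.lower, pack.space.upper)
    return evaluate_pack(new_pos, pack.space, evaluator, feature_map)


@dataclass
class BeetleConfig:
    """Chaotic dung-beetle refinement budget around each leader."""

    swarm_size: int = 10
    n_steps: int = 5
    init_scale: float = 0.1  # initial perturbation, fraction of box width


def cdba_refine(
    leader_position: np.ndarray,
    leader_fitness: FitnessResult,
    space: SearchSpace,
    beetle_cfg: BeetleConfig,
    streams: list[ChaosStream],
    evaluator: FitnessEvaluator,
    feature_map,
) -> tuple[np.ndarray, FitnessResult]:
    """Local chaotic search around a leader; returns the best found.

    Beetles start at the leader perturbed by one chaotic draw per component,
    then move by x + delta * sign(x_best - x) * ln(1 + |x_best - x|) with
    delta a fresh scalar from the beetle's own stream each step. x_best is the
    best-so-far position (initialized to the leader) under the lexicographic
    fitness order; the input leader is returned unless something beats it.
    """
    if beetle_cfg.swarm_size < 1:
        return leader_position, leader_fitness
    width = space.upper - space.lower
    best_pos = leader_position.copy()
    best_fit = leader_fitness
    beetles = []
    for b in range(beetle_cfg.swarm_size):
        delta0 = streams[b].draw(space.dim)
        pos = leader_position + (2.0 * delta0 - 1.0) * beetle_cfg.init_scale * width
        pos = np.clip(pos, space.lower, space.upper)
        beetles.append(pos)
        fit = _score(pos, evaluator, feature_map)
        if compare_fitness(fit, best_fit) < 0:
            best_pos, best_fit = pos.copy(), fit
    for _ in range(beetle_cfg.n_steps):
        for b in range(beetle_cfg.swarm_size):
            delta = streams[b].next()
            diff = best_pos - beetles[b]
            step = delta * np.sign(diff) * np.log1p(np.abs(diff))
            beetles[b] = np.clip(beetles[b] + step, space.lower, space.upper)
            fit = _score(beetles[b], evaluator, feature_map)
            if compare_fitness(fit, best_fit) < 0:
                best_pos, best_fit = beetles[b].copy(), fit
    return best_pos, best_fit


def _score(position: np.ndarray, evaluator: FitnessEvaluator, feature_map) -> FitnessResult:
    mask = binarize_median(position)
    return evaluator.evaluate(tuple(feature_map[j] for j in np.flatnonzero(mask)))


def hgw_cdbw_iterate(
    pack: WolfPack,
    t: int,
    T: int,
    evaluator: FitnessEvaluator,
    feature_map,
    beetle_cfg: BeetleConfig,
    beetle_streams: list[list[ChaosStream]],
    rng: np.random.Generator,
) -> WolfPack:
    """One hybrid wrapper iteration: refine the leaders, then move the pack.

    Each leader gets its own beetle sub-swarm; refined leaders replace the
    originals in place (elitist: a leader only changes if the refinement beat
    it), the leader ranking is refreshed, and the grey-wolf update moves all
    non-leaders. The pack's best fitness never worsens.
    """
    positions = pack.positions.copy()
    fitness = list(pack.fitness)
    for rank, li in enumerate(pack.leaders):
        new_pos, new_fit = cdba_refine(
            positions[li],
            fitness[li],
            pack.space,
            beetle_cfg,
            beetle_streams[rank],
            evaluator,
            feature_map,
        )
        positions[li] = new_pos
        fitness[li] = new_fit
    leaders = _rank_leaders(fitness)
    interim = WolfPack(positions, pack.masks, fitness, leaders, pack.space)
    coeffs = GWOCoefficients(t=t, T=T, rng=rng)
    stepped = gwo_step(interim, coeffs, evaluator, feature_map)
    # elitism: keep the refined leaders' positions/fitness (gwo_step leaves
    # leader rows untouched, so only the ranking can change)
    return stepped
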