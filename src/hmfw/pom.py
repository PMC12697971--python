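"""Process-optimization mechanism and the top-level filter/wrapper loop.

The controller decides when the wrapper search has stagnated and the filter
should be re-run with a fresh chaotically initialized population. Its
patience schedule is borrowed from a physical model: a random-laser
intensity trace I(t) = I0 + sum_i A_i sin(2 pi f_i t + phi_i), whose
per-cycle extrema magnitudes are mapped to integer patience thresholds.
Stagnation is measured by the Average Improvement Rate (AIR) — the mean
relative fitness gain between consecutive wrapper iterations — and by CAD,
the count of AIR deteriorations since the last restart. Extremum control
moves the active threshold up while the search keeps improving and down
while it flatlines, so promising searches get more patience and stuck ones
are cut short.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .config import RunConfig
from .datasets import ExpressionDataset, minmax_normalize
from .evaluation import CVConfig, FitnessEvaluator, FitnessResult, compare_fitness
from .filters import SYSchedule, feature_budget, msmmi_select, rf_fim_rank
from .swarm import (
    BeetleConfig,
    SearchSpace,
    chaotic_init,
    evaluate_pack,
    hgw_cdbw_iterate,
    spawn_streams,
)


class POMError(ValueError):
    pass


@dataclass(frozen=True)
class RLIFParams:
    """Sum-of-sines intensity model around a mean level ``i0``."""

    i0: float = 1.0
    amplitudes: tuple[float, ...] = (2.743, 1.372, 0.914)
    frequencies: tuple[float, ...] = (0.1, 0.2, 0.4)
    phases: tuple[float, ...] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (len(self.amplitudes) == len(self.frequencies) == len(self.phases)):
            raise POMError("amplitudes, frequencies and phases must have equal length")
        if len(self.amplitudes) < 1:
            raise POMError("need at least one sine component")
        if any(f <= 0 for f in self.frequencies):
            raise POMError("frequencies must be positive")


def rlif_intensity(params: RLIFParams, t) -> float | np.ndarray:
    """I(t) = I0 + sum A_i sin(2 pi f_i t + phi_i)."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, params.i0)
    for a, f, p in zip(params.amplitudes, params.frequencies, params.phases):
        out = out + a * np.sin(2.0 * math.pi * f * t + p)
    return float(out) if out.ndim == 0 else out


def fundamental_period(params: RLIFParams) -> float:
    """Smallest T with f_i * T integral for all components."""
    fracs = [Fraction(f).limit_denominator(10**6) for f in params.frequencies]
    num = math.gcd(*[fr.numerator for fr in fracs])
    den = math.lcm(*[fr.denominator for fr in fracs])
    return den / num


@dataclass
class ExtremaSchedule:
    """Ascending integer patience thresholds with a movable cursor."""

    thresholds: list[int]
    cursor: int = 0

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise POMError("empty threshold schedule")
        if sorted(self.thresholds) != self.thresholds:
            raise POMError("thresholds must be sorted ascending")
        if any(t <= 0 for t in self.thresholds):
            raise POMError("thresholds must be positive")
        if not (0 <= self.cursor < len(self.thresholds)):
            raise POMError("cursor out of range")

    @property
    def current(self) -> int:
        return self.thresholds[self.cursor]

    def up(self) -> None:
        self.cursor = min(self.cursor + 1, len(self.thresholds) - 1)

    def down(self) -> None:
        self.cursor = max(self.cursor - 1, 0)


def extrema_deviations(params: RLIFParams, grid_points: int = 10_000) -> np.ndarray:
    """|I - I0| at each local extremum of I(t) over one fundamental period.

    Extrema are located as sign changes of the discrete derivative on a dense
    grid; the grid wraps around the period so a boundary extremum is counted
    once.
    """
    if grid_points < 1000:
        raise POMError("grid_points must be >= 1000")
    period = fundamental_period(params)
    t = np.linspace(0.0, period, grid_points, endpoint=False)
    inten = rlif_intensity(params, t)
    d = np.diff(np.concatenate([inten, inten[:1]]))  # periodic closure
    sign = np.sign(d)
    idx = np.where(sign != 0)[0]
    ext_dev = []
    prev_sign = sign[idx[-1]] if idx.size else 1.0  # wrap: period-continuous
    for i in idx:
        if sign[i] != prev_sign:
            ext_dev.append(abs(inten[i] - params.i0))
        prev_sign = sign[i]
    if not ext_dev:
        ext_dev = [float(np.max(np.abs(inten - params.i0)))]
    return np.array(ext_dev)


def extrema_schedule(
    params: RLIFParams,
    grid_points: int = 10_000,
    patience_min: int = 3,
    patience_max: int = 12,
) -> ExtremaSchedule:
    """Patience thresholds from the intensity trace's per-cycle extrema.

    Local extrema of I(t) over one fundamental period are located on a dense
    grid; their absolute deviations |I - I0| are affinely scaled to integers
    in [patience_min, patience_max], sorted ascending and deduplicated.
    """
    devs = extrema_deviations(params, grid_points)
    lo, hi = devs.min(), devs.max()
    if hi > lo:
        scaled = patience_min + (devs - lo) / (hi - lo) * (patience_max - patience_min)
    else:
        scaled = np.full_like(devs, patience_min, dtype=float)
    thresholds = sorted(set(int(round(v)) for v in scaled))
    return ExtremaSchedule(thresholds=thresholds)


def air(fitness_history: Sequence[float]) -> float:
    """Average Improvement Rate: mean relative gain between consecutive values."""
    f = np.asarray(fitness_history, dtype=float)
    if f.size < 2:
        raise POMError("need at least 2 fitness values")
    if np.any(f == 0):
        raise POMError("zero fitness value would divide by zero")
    return float(np.mean((f[1:] - f[:-1]) / f[:-1]))


@dataclass
class POMState:
    """Controller state: fitness/AIR history since restart, CAD, EC counters."""

    schedule: ExtremaSchedule
    ec_up: int = 3
    ec_down: int = 2
    fitness_history: list[float] = field(default_factory=list)
    air_history: list[float] = field(default_factory=list)
    cad: int = 0
    restarts: int = 0
    _since_restart: list[float] = field(default_factory=list)
    _up_streak: int = 0
    _down_streak: int = 0


def pom_step(state: POMState, new_best_fitness: float) -> tuple[POMState, str]:
    """Feed one wrapper iteration's best fitness; returns (state, action).

    AIR is recomputed over the history since the last restart. CAD counts
    steps whose AIR deteriorated (dropped below the previous AIR) or is
    non-positive. Extremum control: ``ec_up`` consecutive AIR increases raise
    the active threshold; ``ec_down`` consecutive non-positive AIRs lower it.
    CAD exceeding the active threshold triggers a restart and resets CAD.
    """
    state.fitness_history.append(new_best_fitness)
    state._since_restart.append(new_best_fitness)
    action = "continue"
    if len(state._since_restart) >= 2:
        hist = state._since_restart
        cur_air = air(hist) if all(v > 0 for v in hist) else 0.0
        prev_air = state.air_history[-1] if state.air_history else None
        state.air_history.append(cur_air)
        if (prev_air is not None and cur_air < prev_air) or cur_air <= 0:
            state.cad += 1
        # extremum control streaks
        if prev_air is not None and cur_air > prev_air:
            state._up_streak += 1
        else:
            state._up_streak = 0
        if cur_air <= 0:
            state._down_streak += 1
        else:
            state._down_streak = 0
        if state._up_streak >= state.ec_up:
            state.schedule.up()
            state._up_streak = 0
        if state._down_streak >= state.ec_down:
            state.schedule.down()
            state._down_streak = 0
        if state.cad > state.schedule.current:
            action = "restart"
            state.cad = 0
            state.restarts += 1
            state._since_restart = []
            state._up_streak = 0
            state._down_streak = 0
    return state, action


# ---------------------------------------------------------------------------
# top-level run
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Everything a single run produced, serializable to JSON."""

    dataset_name: str
    master_seed: int
    config_digest: str
    seeds: dict
    best_acc: float
    best_fold_accs: list[float]
    best_len: int
    best_feature_indices: list[int]
    best_feature_indices_1based: list[int]
    best_feature_ids: list[str]
    best_c: float
    best_gamma: float
    best_fitness_trace: list[float]
    air_trace: list[float]
    cad_trace: list[int]
    restarts: int
    n_filter_executions: int
    n_fitness_evaluations: int
    k1: int
    runtime_s: float

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def hmfw_run(
    ds: ExpressionDataset, config: RunConfig, dataset_name: str = "dataset"
) -> RunReport:
    """Run the full pipeline once: normalize, pre-screen, alternate filter/wrapper.

    Stages: (1) min-max normalize; (2) tree-importance screen keeps K1
    features (K1 from the stochastic budget formula, M1 range); (3) until the
    global wrapper-iteration budget T is spent, the bivariate filter picks K2
    of them under the current s/y weights, a chaotically initialized wolf
    pack searches that subspace, and the controller restarts the filter when
    the search stagnates. The s/y weights follow the *global* iteration
    counter, so successive restarts weight redundancy progressively more.
    The best mask ever evaluated is kept in an elite archive outside the
    population, so the reported best is monotone across restarts.
    """
    t_start = time.perf_counter()
    master = np.random.default_rng(config.master_seed)
    seed_of = {
        name: int(master.integers(2**31))
        for name in ("budget", "rf", "cv", "bounds", "chaos", "gwo")
    }
    budget_rng = np.random.default_rng(seed_of["budget"])
    bounds_rng = np.random.default_rng(seed_of["bounds"])
    chaos_rng = np.random.default_rng(seed_of["chaos"])
    gwo_rng = np.random.default_rng(seed_of["gwo"])

    ds_norm = minmax_normalize(ds)
    k1 = feature_budget(ds_norm, config.budget, "M1", budget_rng)
    f1 = rf_fim_rank(ds_norm, k1, seed_of["rf"])
    pool = f1.indices

    cv_cfg = CVConfig(
        k=config.cv.k,
        nested=config.cv.nested,
        c_grid=list(config.cv.c_grid),
        gamma_grid=list(config.cv.gamma_grid),
        seed=seed_of["cv"],
    )
    evaluator = FitnessEvaluator(ds_norm, cv_cfg)

    lower = float(bounds_rng.uniform(*config.wrapper.lower_range))
    upper = float(bounds_rng.uniform(*config.wrapper.upper_range))

    pom_cfg = config.pom
    if pom_cfg.thresholds is not None:
        schedule = ExtremaSchedule(list(pom_cfg.thresholds))
    else:
        schedule = extrema_schedule(
            RLIFParams(pom_cfg.i0, pom_cfg.amplitudes, pom_cfg.frequencies, pom_cfg.phases),
            patience_min=pom_cfg.patience_min,
            patience_max=pom_cfg.patience_max,
        )
    state = POMState(schedule=schedule, ec_up=pom_cfg.ec_up, ec_down=pom_cfg.ec_down)

    T = config.wrapper.iterations
    pop = config.wrapper.population
    beetle_cfg: BeetleConfig = config.wrapper.beetle
    sp = config.wrapper.chaos_seed_param

    elite: FitnessResult | None = None
    trace_best: list[float] = []
    trace_cad: list[int] = []
    n_filter_executions = 0
    global_iter = 0

    while global_iter < T:
        n_filter_executions += 1
        k2 = feature_budget(
            ds_norm, config.budget, "M2", budget_rng, available=len(pool)
        )
        k2 = min(k2, len(pool))
        sched = SYSchedule(i=global_iter, I=T)
        fj = msmmi_select(pool, ds_norm, k2, sched, bins=config.mi_bins)
        space = SearchSpace(dim=len(fj), lower=lower, upper=upper)
        streams = spawn_streams(chaos_rng, pop, sp)
        pack = evaluate_pack(chaotic_init(space, pop, streams), space, evaluator, fj)
        if elite is None or compare_fitness(pack.alpha, elite) < 0:
            elite = pack.alpha
        restarted = False
        while global_iter < T and not restarted:
            beetle_streams = [
                spawn_streams(chaos_rng, beetle_cfg.swarm_size, sp) for _ in range(3)
            ]
            pack = hgw_cdbw_iterate(
                pack, global_iter, T, evaluator, fj, beetle_cfg, beetle_streams, gwo_rng
            )
            global_iter += 1
            if compare_fitness(pack.alpha, elite) < 0:
                elite = pack.alpha
            trace_best.append(elite.acc_mean)
            if global_iter < T:
                state, action = pom_step(state, pack.alpha.acc_mean)
                trace_cad.append(state.cad)
                if action == "restart":
                    restarted = True
            else:
                trace_cad.append(state.cad)

    assert elite is not None
    best_idx = sorted(elite.feature_indices)
    return RunReport(
        dataset_name=dataset_name,
        master_seed=config.master_seed,
        config_digest=config.digest(),
        seeds=seed_of,
        best_acc=elite.acc_mean,
        best_fold_accs=list(elite.fold_accs),
        best_len=elite.subset_length,
        best_feature_indices=best_idx,
        best_feature_indices_1based=[j + 1 for j in best_idx],
        best_feature_ids=[ds.feature_ids[j] for j in best_idx],
        best_c=elite.chosen_c,
        best_gamma=elite.chosen_gamma,
        best_fitness_trace=trace_best,
        air_trace=list(state.air_history),
        cad_trace=trace_cad,
        restarts=state.restarts,
        n_filter_executions=n_filter_executions,
        n_fitness_evaluations=evaluator.n_evaluations,
        k1=k1,
        runtime_s=time.perf_counter() - t_start,
    )
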