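"""Pose optimisation: minimise the membrane pseudo-energy over the
3-parameter pose space with a genetic algorithm, Hooke-Jeeves pattern
search, or a grid scan.

All entry points are deterministic for a fixed seed.  The genetic search
runs several independent GA runs and reports the lowest-energy pose
found; the grid scan doubles as the exhaustive search and as the oracle
the stochastic methods are validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import Transform, z_components
from .potential import PotentialTable, centre_arrays, structure_energy
from .structure_io import ScoringCentre, Structure, scoring_centres, transform_structure

__all__ = [
    "SearchConfig",
    "OrientationResult",
    "EnergyEvaluator",
    "random_pose",
    "grid_search",
    "direct_search",
    "direct_search_multi",
    "hooke_jeeves",
    "probe_start",
    "genetic_search",
    "orient",
]


@dataclass(frozen=True)
class SearchConfig:
    method: str = "ga"  # ga | direct | grid | exhaustive
    pop_size: int = 10000
    n_runs: int = 5
    generations: int = 100
    crossover_rate: float = 0.5  # per-gene probability of taking parent 2's gene
    mutation_rate: float = 0.1  # per-gene probability of Gaussian mutation
    mutation_sigma_rot: float = 10.0  # degrees
    mutation_sigma_dz: float = 2.0  # Angstroms
    elite_fraction: float = 0.01
    hj_initial_steps: tuple[float, float, float] = (16.0, 16.0, 8.0)
    hj_resize_factor: float = 0.5
    hj_min_steps: tuple[float, float, float] = (0.1, 0.1, 0.05)
    hj_probe_size: int = 500  # random poses probed to seed each direct-search restart
    grid_rot_step: float = 1.0  # degrees
    grid_dz_step: float = 0.5  # Angstroms
    dz_bounds: tuple[float, float] = (-50.0, 50.0)
    seed: int = 0
    max_energy_calls: int | None = None
    hj_polish: bool = False  # refine the GA's best pose with a pattern search

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not (0.0 < self.hj_resize_factor < 1.0):
            raise ValueError("hj_resize_factor must be in (0, 1)")
        if any(s <= 0 for s in self.hj_initial_steps):
            raise ValueError("initial steps must be positive")
        if self.grid_rot_step <= 0 or self.grid_dz_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.dz_bounds[0] >= self.dz_bounds[1]:
            raise ValueError("dz_bounds must be an increasing pair")


@dataclass
class OrientationResult:
    best: Transform
    energy: float
    method: str
    runs: list[tuple[Transform, float]] = field(default_factory=list)
    n_energy_calls: int = 0
    init_pose: Transform | None = None


class EnergyEvaluator:
    """Batched membrane-energy evaluation for fixed scoring centres.

    Only the z-coordinate of a transformed point matters to the depth
    potential, so each pose costs one dot product with the third row of
    its rotation matrix.
    """

    def __init__(self, table: PotentialTable, centres: Sequence[ScoringCentre]):
        self.table = table
        self.aa_idx, self.coords = centre_arrays(centres)
        g = table.grid
        self._zlo = -g.half_thickness
        self._width = g.slice_width
        self._n_slices = g.n_slices
        self.n_calls = 0

    def batch(self, rot_x: np.ndarray, rot_y: np.ndarray, dz: np.ndarray) -> np.ndarray:
        rot_x = np.atleast_1d(np.asarray(rot_x, dtype=float))
        rot_y = np.atleast_1d(np.asarray(rot_y, dtype=float))
        dz = np.atleast_1d(np.asarray(dz, dtype=float))
        rows = z_components(rot_x, rot_y)  # (P, 3)
        z = rows @ self.coords.T + dz[:, None]  # (P, N)
        idx = np.floor((z - self._zlo) / self._width).astype(np.int64)
        inside = (idx >= 0) & (idx < self._n_slices)
        e = self.table.energy[self.aa_idx[None, :], np.where(inside, idx, 0)]
        energies = np.where(inside, e, 0.0).sum(axis=1)
        self.n_calls += energies.size
        return energies

    def __call__(self, pose) -> float:
        if isinstance(pose, Transform):
            rx, ry, dz = pose.as_tuple()
        else:
            rx, ry, dz = pose
        return float(self.batch(np.array([rx]), np.array([ry]), np.array([dz]))[0])


def random_pose(seed, dz_bounds: tuple[float, float] = (-50.0, 50.0)) -> Transform:
    """Uniform random pose: angles on [0, 360), dz on ``dz_bounds``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Transform(
        rot_x=rng.uniform(0.0, 360.0),
        rot_y=rng.uniform(0.0, 360.0),
        dz=rng.uniform(dz_bounds[0], dz_bounds[1]),
    )


def _finalise(table: PotentialTable, centres: Sequence[ScoringCentre],
              best: Transform, method: str, runs, n_calls,
              init_pose: Transform | None = None) -> OrientationResult:
    # Recompute the reported energy through the scalar path so the
    # result invariant holds independently of the batched evaluator.
    energy = structure_energy(table, centres, best)
    return OrientationResult(best=best, energy=energy, method=method,
                             runs=list(runs), n_energy_calls=int(n_calls),
                             init_pose=init_pose)


# ---------------------------------------------------------------------------
# Grid / exhaustive search
# ---------------------------------------------------------------------------

def grid_search(table: PotentialTable, centres: Sequence[ScoringCentre],
                cfg: SearchConfig) -> OrientationResult:
    """Evaluate every grid point; ties go to the first pose in
    lexicographic (rot_x, rot_y, dz) order."""
    ev = EnergyEvaluator(table, centres)
    rx_vals = np.arange(0.0, 360.0, cfg.grid_rot_step)
    ry_vals = np.arange(0.0, 360.0, cfg.grid_rot_step)
    lo, hi = cfg.dz_bounds
    dz_vals = np.arange(lo, hi + 1e-9, cfg.grid_dz_step)
    ry_grid, dz_grid = np.meshgrid(ry_vals, dz_vals, indexing="ij")
    ry_flat, dz_flat = ry_grid.ravel(), dz_grid.ravel()

    best_e = np.inf
    best_pose = (rx_vals[0], ry_vals[0], dz_vals[0])
    for rx in rx_vals:  # chunk per rot_x to bound memory
        energies = ev.batch(np.full_like(ry_flat, rx), ry_flat, dz_flat)
        i = int(np.argmin(energies))
        if energies[i] < best_e:
            best_e = float(energies[i])
            best_pose = (float(rx), float(ry_flat[i]), float(dz_flat[i]))
    best = Transform(*best_pose)
    return _finalise(table, centres, best, "grid", [(best, best_e)], ev.n_calls)


# ---------------------------------------------------------------------------
# Hooke-Jeeves direct search
# ---------------------------------------------------------------------------

def _hj_explore(f, x: np.ndarray, fx: float, steps: np.ndarray,
                dz_bounds: tuple[float, float]) -> tuple[np.ndarray, float]:
    x = x.copy()
    for i in range(3):
        for delta in (steps[i], -steps[i]):
            trial = x.copy()
            trial[i] += delta
            if i == 2:
                trial[2] = np.clip(trial[2], *dz_bounds)
            ft = f(trial)
            if ft < fx:
                x, fx = trial, ft
                break
    return x, fx


def hooke_jeeves(f, start: np.ndarray, cfg: SearchConfig) -> tuple[np.ndarray, float]:
    """Classic Hooke-Jeeves pattern search on a 3-parameter function.

    Exploratory moves vary one parameter at a time; a successful
    exploration triggers pattern moves; failure shrinks all steps by the
    resize factor until every step drops below its minimum.  The result
    never scores worse than the start.
    """
    base = np.array(start, dtype=float)
    f_base = f(base)
    steps = np.array(cfg.hj_initial_steps, dtype=float)
    min_steps = np.array(cfg.hj_min_steps, dtype=float)

    while np.any(steps >= min_steps):
        new, f_new = _hj_explore(f, base, f_base, steps, cfg.dz_bounds)
        if f_new < f_base:
            while True:
                pattern = new + (new - base)
                pattern[2] = np.clip(pattern[2], *cfg.dz_bounds)
                base, f_base = new, f_new
                trial, f_trial = _hj_explore(f, pattern, f(pattern), steps, cfg.dz_bounds)
                if f_trial < f_base:
                    new, f_new = trial, f_trial
                else:
                    break
        else:
            steps = steps * cfg.hj_resize_factor
    return base, f_base


def direct_search(table: PotentialTable, centres: Sequence[ScoringCentre],
                  cfg: SearchConfig, start: Transform) -> OrientationResult:
    """Hooke-Jeeves pattern search of the membrane energy from ``start``."""
    ev = EnergyEvaluator(table, centres)
    base, f_base = hooke_jeeves(ev, np.array(start.as_tuple()), cfg)
    best = Transform(*base)
    return _finalise(table, centres, best, "direct", [(best, f_base)], ev.n_calls,
                     init_pose=start)


def probe_start(ev: EnergyEvaluator, cfg: SearchConfig,
                rng: np.random.Generator) -> Transform:
    """Best pose out of ``hj_probe_size`` uniform random probes (or a single
    random pose when probing is disabled)."""
    if cfg.hj_probe_size <= 1:
        return random_pose(rng, cfg.dz_bounds)
    lo, hi = cfg.dz_bounds
    rx = rng.uniform(0.0, 360.0, cfg.hj_probe_size)
    ry = rng.uniform(0.0, 360.0, cfg.hj_probe_size)
    dz = rng.uniform(lo, hi, cfg.hj_probe_size)
    energies = ev.batch(rx, ry, dz)
    i = int(np.argmin(energies))
    return Transform(float(rx[i]), float(ry[i]), float(dz[i]))


def direct_search_multi(table: PotentialTable, centres: Sequence[ScoringCentre],
                        cfg: SearchConfig, rng: np.random.Generator) -> OrientationResult:
    """``cfg.n_runs`` Hooke-Jeeves restarts, each seeded from the best of a
    random probe batch; lowest energy wins."""
    ev = EnergyEvaluator(table, centres)
    best: OrientationResult | None = None
    all_runs: list[tuple[Transform, float]] = []
    n_calls = 0
    for _ in range(cfg.n_runs):
        start = probe_start(ev, cfg, rng)
        res = direct_search(table, centres, cfg, start)
        all_runs.append((res.best, res.energy))
        n_calls += res.n_energy_calls
        if best is None or res.energy < best.energy:
            best = res
    assert best is not None
    n_calls += ev.n_calls  # probe evaluations
    return OrientationResult(best=best.best, energy=best.energy, method="direct",
                             runs=all_runs, n_energy_calls=n_calls)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _ga_run(ev: EnergyEvaluator, cfg: SearchConfig,
            rng: np.random.Generator) -> tuple[Transform, float]:
    n = cfg.pop_size
    lo, hi = cfg.dz_bounds
    pop = np.empty((n, 3))
    pop[:, 0] = rng.uniform(0.0, 360.0, n)
    pop[:, 1] = rng.uniform(0.0, 360.0, n)
    pop[:, 2] = rng.uniform(lo, hi, n)
    fit = ev.batch(pop[:, 0], pop[:, 1], pop[:, 2])
    i_best = int(np.argmin(fit))
    best_pose, best_fit = pop[i_best].copy(), float(fit[i_best])

    sigma = np.array([cfg.mutation_sigma_rot, cfg.mutation_sigma_rot, cfg.mutation_sigma_dz])
    n_elite = max(1, int(round(cfg.elite_fraction * n)))
    n_child = n - n_elite

    for _ in range(cfg.generations):
        if cfg.max_energy_calls is not None and ev.n_calls >= cfg.max_energy_calls:
            break
        order = np.argsort(fit, kind="stable")
        elites, elite_fit = pop[order[:n_elite]], fit[order[:n_elite]]

        # tournament selection, size 2, for each parent slot
        cand = rng.integers(0, n, size=(2, n_child, 2))
        p1 = np.where(fit[cand[0, :, 0]] <= fit[cand[0, :, 1]], cand[0, :, 0], cand[0, :, 1])
        p2 = np.where(fit[cand[1, :, 0]] <= fit[cand[1, :, 1]], cand[1, :, 0], cand[1, :, 1])

        take2 = rng.random((n_child, 3)) < cfg.crossover_rate
        children = np.where(take2, pop[p2], pop[p1])

        mutate = rng.random((n_child, 3)) < cfg.mutation_rate
        children = children + mutate * rng.normal(0.0, 1.0, (n_child, 3)) * sigma
        children[:, 0] %= 360.0
        children[:, 1] %= 360.0
        children[:, 2] = np.clip(children[:, 2], lo, hi)

        child_fit = ev.batch(children[:, 0], children[:, 1], children[:, 2])
        pop = np.vstack([elites, children])
        fit = np.concatenate([elite_fit, child_fit])
        i = int(np.argmin(fit))
        if fit[i] < best_fit:
            best_pose, best_fit = pop[i].copy(), float(fit[i])

    return Transform(*best_pose), best_fit


def genetic_search(table: PotentialTable, centres: Sequence[ScoringCentre],
                   cfg: SearchConfig) -> OrientationResult:
    """``cfg.n_runs`` independent GA runs; the lowest-energy pose wins."""
    ev = EnergyEvaluator(table, centres)
    root = np.random.SeedSequence(cfg.seed)
    runs: list[tuple[Transform, float]] = []
    for child in root.spawn(cfg.n_runs):
        runs.append(_ga_run(ev, cfg, np.random.default_rng(child)))
    best, best_e = min(runs, key=lambda r: r[1])
    n_calls = ev.n_calls
    if cfg.hj_polish:
        polished = direct_search(table, centres, cfg, best)
        n_calls += polished.n_energy_calls
        if polished.energy < best_e:
            best, best_e = polished.best, polished.energy
    return _finalise(table, centres, best, "ga", runs, n_calls)


# ---------------------------------------------------------------------------
# Top-level orientation
# ---------------------------------------------------------------------------

def orient(structure: Structure, table: PotentialTable,
           cfg: SearchConfig) -> tuple[OrientationResult, Structure]:
    """Randomise the input pose, then minimise with the selected method.

    The random initial pose guarantees no information from the input
    orientation leaks into the result.  Returns the search result (whose
    transform is relative to the randomised frame) and the oriented
    structure.
    """
    root = np.random.SeedSequence(cfg.seed)
    seed_init, seed_search = root.spawn(2)
    init = random_pose(np.random.default_rng(seed_init), cfg.dz_bounds)
    randomized = transform_structure(structure, init)
    centres = scoring_centres(randomized)

    method = cfg.method.lower()
    if method == "ga":
        sub = replace(cfg, seed=int(seed_search.generate_state(1)[0]))
        result = genetic_search(table, centres, sub)
    elif method == "direct":
        rng = np.random.default_rng(seed_search)
        result = direct_search_multi(table, centres, cfg, rng)
    elif method in ("grid", "exhaustive"):
        result = grid_search(table, centres, cfg)
        result.method = method
    else:
        raise ValueError(f"unknown search method {cfg.method!r}")

    result.init_pose = init
    oriented = transform_structure(randomized, result.best)
    return result, oriented
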