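"""Multi-objective management optimisation: non-dominated sorting coupled
with differential evolution.

A population of management decision vectors (e.g. fertiliser day and
amount) is evolved by rand/1/bin differential evolution; selection uses
combined-population non-dominated sorting with a crowding-distance
tie-break, so the survivor set approximates the Pareto front between the
simulator objectives (maximise yield, minimise nitrate leaching and N2O).
Convergence is declared when the front hypervolume is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class DecisionSpec:
    """Named continuous decision variables with inclusive bounds."""

    names: tuple
    lower: tuple
    upper: tuple

    def __post_init__(self):
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names and bounds must have equal length")
        for lo, hi in zip(self.lower, self.upper):
            if lo >= hi:
                raise ValueError("lower bound must be below upper bound")


@dataclass
class ParetoSolution:
    decision: np.ndarray
    objectives: np.ndarray
    rank: int = -1


def dominates(a: Sequence[float], b: Sequence[float],
              senses: Sequence[str]) -> bool:
    """True iff a is at least as good as b in every objective (per sense,
    'max' or 'min') and strictly better in at least one."""
    if not (len(a) == len(b) == len(senses)):
        raise ValueError("objective dimension mismatch")
    better = False
    for ai, bi, sense in zip(a, b, senses):
        if sense == "max":
            if ai < bi:
                return False
            if ai > bi:
                better = True
        elif sense == "min":
            if ai > bi:
                return False
            if ai < bi:
                better = True
        else:
            raise ValueError(f"unknown sense {sense!r}")
    return better


def non_dominated_sort(objectives: np.ndarray, senses: Sequence[str]
                       ) -> np.ndarray:
    """Assign each row a front rank (0 = non-dominated), peeling fronts."""
    n = objectives.shape[0]
    if n == 0:
        raise ValueError("population must be non-empty")
    ranks = np.full(n, -1, dtype=int)
    remaining = list(range(n))
    rank = 0
    while remaining:
        front = []
        for i in remaining:
            if not any(dominates(objectives[j], objectives[i], senses)
                       for j in remaining if j != i):
                front.append(i)
        for i in front:
            ranks[i] = rank
        remaining = [i for i in remaining if i not in front]
        rank += 1
    return ranks


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """NSGA-style crowding distance within one front."""
    n, m = objectives.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(objectives[:, k])
        span = objectives[order[-1], k] - objectives[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0:
            continue
        for idx in range(1, n - 1):
            dist[order[idx]] += (objectives[order[idx + 1], k]
                                 - objectives[order[idx - 1], k]) / span
    return dist


def de_generation(population: np.ndarray, f: float, cr: float,
                  lower: np.ndarray, upper: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """rand/1/bin offspring; out-of-bounds components reflect into range."""
    n, d = population.shape
    if n < 4:
        raise ValueError("differential evolution needs population >= 4")
    offspring = np.empty_like(population)
    for i in range(n):
        choices = [j for j in range(n) if j != i]
        r1, r2, r3 = rng.choice(choices, size=3, replace=False)
        mutant = population[r1] + f * (population[r2] - population[r3])
        cross = rng.random(d) < cr
        if cr > 0.0:
            cross[rng.integers(d)] = True   # classic forced component
        trial = np.where(cross, mutant, population[i])
        # reflect into bounds (repeat in case of large overshoot)
        for _ in range(100):
            below, above = trial < lower, trial > upper
            if not (below.any() or above.any()):
                break
            trial = np.where(below, 2 * lower - trial, trial)
            trial = np.where(above, 2 * upper - trial, trial)
        offspring[i] = np.clip(trial, lower, upper)
    return offspring


def hypervolume(front: np.ndarray, reference: Sequence[float]) -> float:
    """Hypervolume dominated by a minimisation front w.r.t. a reference.

    Exact recursive slicing; intended for the small fronts (<= a few
    hundred points, 2-3 objectives) this package produces.
    """
    ref = np.asarray(reference, dtype=float)
    pts = np.asarray(front, dtype=float)
    pts = pts[(pts <= ref).all(axis=1)]
    if pts.size == 0:
        return 0.0
    if pts.shape[1] == 1:
        return float(ref[0] - pts[:, 0].min())
    # sort by first objective and sweep slices
    order = np.argsort(pts[:, 0])
    pts = pts[order]
    volume = 0.0
    prev = None
    for i in range(len(pts) - 1, -1, -1):
        x = pts[i, 0]
        upper = ref[0] if prev is None else prev
        width = upper - x
        prev = x
        if width <= 0:
            continue
        sub = pts[: i + 1, 1:]
        volume += width * hypervolume(sub, ref[1:])
    return float(volume)


def _to_min(objectives: np.ndarray, senses: Sequence[str]) -> np.ndarray:
    out = objectives.copy()
    for k, sense in enumerate(senses):
        if sense == "max":
            out[:, k] = -out[:, k]
    return out


@dataclass
class OptimiseResult:
    front: list
    generations: int
    converged: bool
    history: list = field(default_factory=list)   # hypervolume per generation


def optimise(runner: Callable[[np.ndarray], Sequence[float]],
             decisions: DecisionSpec, senses: Sequence[str],
             generations: int = 60, pop_size: int = 40, seed: int = 0,
             f: float = 0.7, cr: float = 0.9, hv_tol: float = 1e-4,
             stable_gens: int = 5) -> OptimiseResult:
    """Evolve decisions against a (deterministic) simulator runner.

    Selection keeps the best pop_size of parents+offspring by front rank
    then crowding distance.  Converged once the relative hypervolume change
    of the rank-0 front stays below hv_tol for ``stable_gens`` generations.
    Returns the final rank-0 set (mutually non-dominated).
    """
    rng = np.random.default_rng(seed)
    lower = np.asarray(decisions.lower, dtype=float)
    upper = np.asarray(decisions.upper, dtype=float)
    pop = lower + rng.random((pop_size, len(lower))) * (upper - lower)
    obj = np.array([runner(x) for x in pop], dtype=float)
    history, stable, converged, gen = [], 0, False, 0
    for gen in range(1, generations + 1):
        off = de_generation(pop, f, cr, lower, upper, rng)
        off_obj = np.array([runner(x) for x in off], dtype=float)
        all_pop = np.vstack([pop, off])
        all_obj = np.vstack([obj, off_obj])
        ranks = non_dominated_sort(all_obj, senses)
        keep: list[int] = []
        for rank in range(ranks.max() + 1):
            idx = np.where(ranks == rank)[0]
            if len(keep) + len(idx) <= pop_size:
                keep.extend(idx.tolist())
            else:
                dist = crowding_distance(all_obj[idx])
                order = idx[np.argsort(-dist)]
                keep.extend(order[: pop_size - len(keep)].tolist())
                break
        pop, obj = all_pop[keep], all_obj[keep]
        front_obj = obj[non_dominated_sort(obj, senses) == 0]
        mins = _to_min(front_obj, senses)
        ref = mins.max(axis=0) + 1.0
        hv = hypervolume(mins, ref)
        history.append(hv)
        if len(history) >= 2 and abs(history[-1] - history[-2]) <= \
                hv_tol * max(abs(history[-2]), 1e-12):
            stable += 1
            if stable >= stable_gens:
                converged = True
                break
        else:
            stable = 0
    ranks = non_dominated_sort(obj, senses)
    front = [ParetoSolution(pop[i].copy(), obj[i].copy(), 0)
             for i in np.where(ranks == 0)[0]]
    return OptimiseResult(front, gen, converged, history)
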