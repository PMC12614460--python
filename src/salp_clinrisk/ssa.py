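"""Salp Swarm Algorithm over bounded mixed integer/continuous spaces.

The swarm mimics a salp chain: the leader (first salp) moves around the
food source F — the best position found so far — with a step whose scale
c1 = 2 exp(-(4 t / T)^2) decays from 2 toward 0 over the iteration horizon,
shifting the search from exploration to exploitation. Every follower moves
to the midpoint between itself and its predecessor, sweeping the chain
sequentially so updates propagate down it within one iteration. All
positions are clamped to the box after every move.

Minimization convention throughout: lower fitness is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Dimension",
    "SearchSpace",
    "OptimizationResult",
    "compute_c1",
    "update_leader",
    "update_followers",
    "decode_position",
    "optimize",
]


@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    kind: str = "continuous"  # 'continuous' | 'integer'

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: need lower < upper, got [{self.lower}, {self.upper}]")
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    def __init__(self, dimensions: Sequence[Dimension]):
        object.__setattr__(self, "dimensions", tuple(dimensions))

    def __len__(self) -> int:
        return len(self.dimensions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dimensions], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dimensions], dtype=float)

    def clamp(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.lower, self.upper
        return rng.uniform(lo, hi, size=(n, len(self)))


def compute_c1(t: float, horizon: float) -> float:
    """Leader step-scale schedule 2 exp(-(4 t / T)^2).

    Equals 2 at t = 0 and decays monotonically to 2 e^-16 at t = T,
    trading early exploration for late exploitation.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    return 2.0 * float(np.exp(-((4.0 * t / horizon) ** 2)))


def update_leader(
    food: np.ndarray,
    space: SearchSpace,
    c1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One leader move around the food source.

    Per dimension j, with fresh c2, c3 ~ U(0, 1):
    step_j = c1 * ((ub_j - lb_j) * c2 + lb_j), added to F_j when c3 < 0.5
    and subtracted otherwise; the result is clamped to the box.
    """
    lo, hi = space.lower, space.upper
    c2 = rng.uniform(size=len(space))
    c3 = rng.uniform(size=len(space))
    step = c1 * ((hi - lo) * c2 + lo)
    position = np.where(c3 < 0.5, food + step, food - step)
    return space.clamp(position)


def update_followers(positions: np.ndarray, space: SearchSpace | None = None) -> np.ndarray:
    """Sequential chain update: each follower averages with its predecessor.

    Row 0 (the leader) is untouched. Rows 2..N use the already-updated
    predecessor, so a displacement at the head propagates down the chain
    within one sweep.
    """
    if positions.shape[0] < 2:
        raise ValueError("need at least two salps for a follower sweep")
    out = positions.copy()
    for i in range(1, out.shape[0]):
        out[i] = 0.5 * (out[i] + out[i - 1])
    if space is not None:
        out = space.clamp(out)
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def decode_position(position: np.ndarray, space: SearchSpace) -> dict[str, float | int]:
    """Map a raw position to a named assignment.

    Integer dimensions are rounded half-away-from-zero and clamped;
    continuous dimensions pass through unchanged.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (len(space),):
        raise ValueError(f"position has {position.shape} coordinates, space has {len(space)}")
    out: dict[str, float | int] = {}
    for x, dim in zip(position, space.dimensions):
        if dim.kind == "integer":
            out[dim.name] = int(np.clip(_round_half_away(np.asarray(x)), dim.lower, dim.upper))
        else:
            out[dim.name] = float(x)
    return out


@dataclass
class OptimizationResult:
    best_assignment: dict[str, float | int]
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness per iteration, length T
    leader_steps: np.ndarray  # Euclidean leader displacement per iteration
    n_evaluations: int

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": np.arange(1, len(self.trace) + 1), "best_fitness": self.trace}
        )


class FitnessEvaluationError(RuntimeError):
    """A fitness call failed; carries the iteration and position context."""


def optimize(
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
    n_salps: int = 20,
    n_iterations: int = 50,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    sequential_followers: bool = True,
) -> OptimizationResult:
    """Run the salp swarm on a fitness function (minimized).

    Salps start uniformly in the box; ``x0`` optionally pins the leader to a
    user-supplied start (e.g. library-default hyperparameters). Each
    iteration evaluates the whole population, updates the food source to the
    best position seen so far (elitist), then moves the leader with the
    scheduled c1 and the followers along the chain. The trace records the
    best-so-far fitness after each iteration and is therefore non-increasing.
    """
    if n_salps < 2:
        raise ValueError("need at least 2 salps")
    if n_iterations < 1:
        raise ValueError("need at least 1 iteration")
    rng = np.random.default_rng(seed)
    positions = space.sample_uniform(n_salps, rng)
    if x0 is not None:
        positions[0] = space.clamp(np.asarray(x0, dtype=float))

    food = positions[0].copy()
    best_fitness = np.inf
    trace = np.empty(n_iterations)
    leader_steps = np.empty(n_iterations)
    n_evaluations = 0

    for t in range(1, n_iterations + 1):
        for i in range(n_salps):
            try:
                value = float(fitness(positions[i]))
            except Exception as exc:  # re-raise with search context
                raise FitnessEvaluationError(
                    f"fitness failed at iteration {t}, salp {i}, "
                    f"position {positions[i].tolist()}"
                ) from exc
            n_evaluations += 1
            if value < best_fitness:
                best_fitness = value
                food = positions[i].copy()
        trace[t - 1] = best_fitness

        c1 = compute_c1(t, n_iterations)
        old_leader = positions[0].copy()
        positions[0] = update_leader(food, space, c1, rng)
        leader_steps[t - 1] = float(np.linalg.norm(positions[0] - old_leader))
        if sequential_followers:
            positions = update_followers(positions, space)
        else:
            shifted = np.vstack([positions[0], positions[:-1]])
            positions[1:] = space.clamp(0.5 * (positions[1:] + shifted[1:]))

    return OptimizationResult(
        best_assignment=decode_position(food, space),
        best_position=food,
        best_fitness=best_fitness,
        trace=trace,
        leader_steps=leader_steps,
        n_evaluations=n_evaluations,
    )
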