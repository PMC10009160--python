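"""Particle swarm optimisation for the non-convex baseline models.

Global-best PSO with an adaptive random neighbourhood, following the
conventions of the widely used MATLAB-style implementation: each particle
is attracted to its own best position and to the best position found in a
random neighbourhood whose size grows while the swarm stalls; the inertia
weight adapts in [0.1, 1.1]. The default budget is 200 iterations per model
weight, swarm size min(100, 10 * n_weights), acceleration weights 1.49 for
both the self and social terms, and a minimum neighbourhood fraction of
0.25. Runs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["PSOConfig", "pso_optimize"]

_CLIP = 1e12  # guard against unbounded objectives (exponential blow-ups)


@dataclass
class PSOConfig:
    """PSO hyperparameters. ``max_iter`` and ``swarm_size`` default to the
    standard budget rules for ``n_weights`` parameters when left None."""

    bounds: Sequence[tuple[float, float]]
    max_iter: int | None = None
    swarm_size: int | None = None
    min_neighborhood_fraction: float = 0.25
    self_adjustment: float = 1.49
    social_adjustment: float = 1.49
    inertia_range: tuple[float, float] = (0.1, 1.1)
    n_restarts: int = 10
    seed: int = 0
    # stall-based termination (the reference implementation's defaults);
    # set max_stall_iter = max_iter to always exhaust the full budget
    max_stall_iter: int = 20
    function_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        if any(hi <= lo for lo, hi in self.bounds):
            raise ValueError("each bound must satisfy lo < hi")
        n = len(self.bounds)
        if self.max_iter is None:
            self.max_iter = 200 * n
        if self.swarm_size is None:
            self.swarm_size = min(100, 10 * n)
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not (0 < self.min_neighborhood_fraction <= 1):
            raise ValueError("min_neighborhood_fraction must be in (0, 1]")

    @property
    def n_weights(self) -> int:
        return len(self.bounds)


def _eval(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    v = float(objective(x))
    if not np.isfinite(v):
        return _CLIP
    return min(v, _CLIP)


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    config: PSOConfig,
) -> tuple[np.ndarray, float]:
    """Minimise ``objective`` over ``config.bounds``.

    Returns the best position and value found. A single swarm run — restart
    selection across runs lives in :func:`emgforce.baselines.fit_pso_model`.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    n, d = config.swarm_size, config.n_weights

    x = lo + rng.random((n, d)) * span
    v = (rng.random((n, d)) * 2 - 1) * span  # initial velocities within +/- range
    pbest_x = x.copy()
    pbest_f = np.array([_eval(objective, xi) for xi in x])
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

    w_lo, w_hi = config.inertia_range
    inertia = w_hi
    c1, c2 = config.self_adjustment, config.social_adjustment
    min_nb = max(2, int(np.floor(n * config.min_neighborhood_fraction)))
    nb_size = min_nb
    stall_counter = 0
    stall_iters = 0

    for _ in range(config.max_iter):
        improved = False
        for i in range(n):
            # random neighbourhood including the particle itself
            others = rng.choice(n, size=min(nb_size, n), replace=False)
            nb = np.append(others, i)
            best_nb = nb[np.argmin(pbest_f[nb])]
            u1 = rng.random(d)
            u2 = rng.random(d)
            v[i] = (
                inertia * v[i]
                + c1 * u1 * (pbest_x[i] - x[i])
                + c2 * u2 * (pbest_x[best_nb] - x[i])
            )
            x[i] = x[i] + v[i]
            # absorb at the bounds: clip position, zero the violating velocity
            low_viol = x[i] < lo
            high_viol = x[i] > hi
            x[i] = np.clip(x[i], lo, hi)
            v[i][low_viol | high_viol] = 0.0
            f = _eval(objective, x[i])
            if f < pbest_f[i]:
                pbest_f[i] = f
                pbest_x[i] = x[i].copy()
                if f < gbest_f - config.function_tolerance * max(1.0, abs(gbest_f)):
                    improved = True
                if f < gbest_f:
                    gbest_f = f
                    gbest_x = x[i].copy()
        if improved:
            stall_counter = max(0, stall_counter - 1)
            nb_size = min_nb
            stall_iters = 0
        else:
            stall_counter += 1
            nb_size = min(nb_size + min_nb, n)
            stall_iters += 1
        if stall_counter < 2:
            inertia = min(w_hi, 2.0 * inertia)
        elif stall_counter > 5:
            inertia = max(w_lo, inertia / 2.0)
        if stall_iters >= config.max_stall_iter:
            break
    return gbest_x, float(gbest_f)
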