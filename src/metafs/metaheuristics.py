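"""Four binarized population metaheuristics over feature masks.

All four algorithms share the same outer loop: initialize a random binary
population, evaluate it, and then alternate a continuous position update,
two-step binarization, and re-evaluation, keeping the best-so-far solution
under strict improvement.  Continuous positions start at the initial bits
and persist across iterations; each iteration samples a binary mask from
them for evaluation.  Feeding the sampled bits back as the next positions
(the other common reading of binarized-population pseudocode) collapses all
position magnitude information: an S-shaped transfer then maps a zero bit
to T(0) = 1/2 and a one bit to barely more, so solutions are largely
re-randomized every iteration and the search cannot hold a converged mask.
Persistent positions let coordinates saturate and the population converge.
The attractors (personal/global bests, wolf leaders, prey) are the binary
masks of the best evaluations.  The continuous update rules are:

- PSO: velocity with linearly decaying inertia, cognitive and social pulls
  toward the personal and global best masks, symmetric velocity clamp.
- GWO: average of three pulls toward the alpha/beta/delta leader masks with
  the exploration coefficient ``a`` decaying linearly 2 -> 0.
- PSA: harmonic pendulum displacement toward the best mask,
  ``pend = 2 e^{-t/t_max} cos(2 pi r)`` per coordinate (parameter-free).
- WOA: per agent, an even coin chooses between a logarithmic-spiral move
  around the best mask and an encircling/search move gated by ``|A|``.

The step functions take their random draws as explicit arguments so that
unit tests can pin them; :func:`run_search` feeds them from seeded
substreams, making whole runs bitwise reproducible.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

from .binarization import BinarizationConfig, binarize_population


class Algorithm(str, enum.Enum):
    PSO = "pso"
    GWO = "gwo"
    PSA = "psa"
    WOA = "woa"


@dataclass(frozen=True)
class PSOParams:
    c1: float = 2.0
    c2: float = 2.0
    w_max: float = 0.9
    w_min: float = 0.2
    v_max: float = 5000.0


@dataclass(frozen=True)
class WOAParams:
    b: float = 1.0  # logarithmic-spiral shape


@dataclass(frozen=True)
class MetaheuristicConfig:
    algorithm: Algorithm = Algorithm.PSO
    population_size: int = 20
    max_iter: int = 100
    seed: int = 0
    pso: PSOParams = field(default_factory=PSOParams)
    woa: WOAParams = field(default_factory=WOAParams)
    binarization: BinarizationConfig = field(default_factory=BinarizationConfig)

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be nonnegative")


def inertia_weight(t: int, max_iter: int, w_max: float = 0.9,
                   w_min: float = 0.2) -> float:
    """Linearly decreasing inertia: w_max at t=0 down to w_min at t=max_iter."""
    return w_max - (w_max - w_min) * t / max_iter


def pso_step(positions, velocities, pbest, gbest, *, w, c1, c2, v_max,
             r1, r2):
    """One PSO velocity/position update with explicit random draws.

    ``r1``/``r2`` must broadcast against ``positions`` (one fresh pair per
    agent-dimension in the run loop).
    """
    positions = np.asarray(positions, dtype=float)
    v = (w * np.asarray(velocities, dtype=float)
         + c1 * np.asarray(r1) * (np.asarray(pbest, dtype=float) - positions)
         + c2 * np.asarray(r2) * (np.asarray(gbest, dtype=float) - positions))
    v = np.clip(v, -v_max, v_max)
    return positions + v, v


def gwo_step(positions, leaders, *, a, r1, r2):
    """One grey-wolf update.

    ``leaders`` is a 3 x dims array (alpha, beta, delta masks); ``r1`` and
    ``r2`` have shape (3, agents) — one scalar pair per agent and leader.
    The new position is the mean of the three leader-guided moves
    ``X_k = L_k - A_k * |C_k * L_k - X|`` with ``A = 2 a r1 - a`` and
    ``C = 2 r2``.
    """
    positions = np.asarray(positions, dtype=float)
    leaders = np.asarray(leaders, dtype=float)
    if leaders.shape[0] != 3:
        raise ValueError("need exactly three leaders (alpha, beta, delta)")
    A = 2.0 * a * np.asarray(r1) - a            # (3, agents)
    C = 2.0 * np.asarray(r2)                    # (3, agents)
    L = leaders[:, None, :]                     # (3, 1, dims)
    D = np.abs(C[:, :, None] * L - positions[None, :, :])
    Xk = L - A[:, :, None] * D
    return Xk.mean(axis=0)


def psa_step(positions, best, *, t, max_iter, rand):
    """One pendulum-search update; ``rand`` is per agent-dimension."""
    positions = np.asarray(positions, dtype=float)
    pend = 2.0 * np.exp(-t / max_iter) * np.cos(2.0 * np.pi * np.asarray(rand))
    return positions + pend * (np.asarray(best, dtype=float) - positions)


def woa_step(positions, best, *, a, b, p, l, r1, r2, rand_idx):
    """One whale update with per-agent scalar coefficients.

    ``p`` (coin), ``l`` (spiral parameter in [-1, 1]), ``r1``/``r2``
    (coefficient draws) and ``rand_idx`` (random agent index for the search
    branch) are all vectors of length agents.  Spiral branch when
    ``p >= 0.5``; otherwise encircling if ``|A| < 1`` else search around a
    random agent.
    """
    positions = np.asarray(positions, dtype=float)
    best = np.asarray(best, dtype=float)
    p = np.asarray(p)
    l = np.asarray(l)
    A = 2.0 * a * np.asarray(r1) - a
    C = 2.0 * np.asarray(r2)
    out = np.empty_like(positions)

    spiral = p >= 0.5
    if spiral.any():
        Dp = np.abs(best[None, :] - positions[spiral])
        coef = (np.exp(b * l[spiral]) * np.cos(2.0 * np.pi * l[spiral]))
        out[spiral] = Dp * coef[:, None] + best[None, :]

    enc = (~spiral) & (np.abs(A) < 1.0)
    if enc.any():
        D = np.abs(C[enc, None] * best[None, :] - positions[enc])
        out[enc] = best[None, :] - A[enc, None] * D

    srch = (~spiral) & (np.abs(A) >= 1.0)
    if srch.any():
        Xr = positions[np.asarray(rand_idx)[srch]]
        D = np.abs(C[srch, None] * Xr - positions[srch])
        out[srch] = Xr - A[srch, None] * D

    return out


@dataclass
class SearchResult:
    best_mask: np.ndarray
    best_fitness: float
    best_record: object  # FitnessRecord or raw float fitness
    trace: list[float]
    n_evaluations: int

    def to_dict(self) -> dict:
        rec = self.best_record
        rec_dict = rec.to_dict() if hasattr(rec, "to_dict") else rec
        return {
            "best_mask": "".join(str(int(b)) for b in self.best_mask),
            "best_fitness": self.best_fitness,
            "best_record": rec_dict,
            "trace": list(self.trace),
            "n_evaluations": self.n_evaluations,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _fitness_of(result) -> float:
    return float(getattr(result, "fitness", result))


def run_search(objective, n_features: int, cfg: MetaheuristicConfig) -> SearchResult:
    """Run one binarized metaheuristic search over feature masks.

    ``objective`` is a callable ``mask -> FitnessRecord | float``
    (minimized).  The initial population is i.i.d. Bernoulli(0.5) bits;
    each iteration applies the continuous update to the current bits,
    binarizes, re-evaluates, and updates the incumbents under strict
    improvement, so the best-fitness trace is nonincreasing.  Identical
    seeds give bitwise-identical results.
    """
    alg = Algorithm(cfg.algorithm)
    pop, dims = cfg.population_size, int(n_features)
    if dims < 1:
        raise ValueError("need at least one feature")
    if alg is Algorithm.GWO and pop < 3:
        raise ValueError("GWO needs a population of at least 3 (leaders)")

    ss = np.random.SeedSequence(cfg.seed)
    init_ss, loop_ss = ss.spawn(2)
    rng_init = np.random.default_rng(init_ss)
    rng = np.random.default_rng(loop_ss)

    bits = (rng_init.random((pop, dims)) < 0.5).astype(np.int8)
    records = [objective(bits[i]) for i in range(pop)]
    fitness = np.array([_fitness_of(r) for r in records])
    n_evals = pop

    best_i = int(np.argmin(fitness))
    gbest_bits = bits[best_i].copy()
    gbest_fit = float(fitness[best_i])
    gbest_rec = records[best_i]

    if alg is Algorithm.PSO:
        velocities = np.zeros((pop, dims))
        pbest_bits = bits.copy()
        pbest_fit = fitness.copy()

    positions = bits.astype(float)  # persists across iterations
    trace = [gbest_fit]
    for t in range(1, cfg.max_iter + 1):
        if alg is Algorithm.PSO:
            w = inertia_weight(t, cfg.max_iter, cfg.pso.w_max, cfg.pso.w_min)
            r1 = rng.random((pop, dims))
            r2 = rng.random((pop, dims))
            positions, velocities = pso_step(
                positions, velocities, pbest_bits, gbest_bits,
                w=w, c1=cfg.pso.c1, c2=cfg.pso.c2, v_max=cfg.pso.v_max,
                r1=r1, r2=r2)
        elif alg is Algorithm.GWO:
            order = np.lexsort((np.arange(pop), fitness))  # ties by index
            leaders = bits[order[:3]].astype(float)
            a = 2.0 - 2.0 * t / cfg.max_iter
            r1 = rng.random((3, pop))
            r2 = rng.random((3, pop))
            positions = gwo_step(positions, leaders, a=a, r1=r1, r2=r2)
        elif alg is Algorithm.PSA:
            rand = rng.random((pop, dims))
            positions = psa_step(positions, gbest_bits, t=t,
                                 max_iter=cfg.max_iter, rand=rand)
        else:  # WOA
            a = 2.0 - 2.0 * t / cfg.max_iter
            p = rng.random(pop)
            l = rng.uniform(-1.0, 1.0, pop)
            r1 = rng.random(pop)
            r2 = rng.random(pop)
            rand_idx = rng.integers(0, pop, pop)
            positions = woa_step(positions, gbest_bits, a=a, b=cfg.woa.b,
                                 p=p, l=l, r1=r1, r2=r2, rand_idx=rand_idx)

        bits = binarize_population(positions, cfg.binarization, rng,
                                   current_bits=bits, best_bits=gbest_bits)
        records = [objective(bits[i]) for i in range(pop)]
        fitness = np.array([_fitness_of(r) for r in records])
        n_evals += pop

        if alg is Algorithm.PSO:
            improved = fitness < pbest_fit
            pbest_bits[improved] = bits[improved]
            pbest_fit[improved] = fitness[improved]
        best_i = int(np.argmin(fitness))
        if fitness[best_i] < gbest_fit:  # strict improvement keeps incumbents
            gbest_fit = float(fitness[best_i])
            gbest_bits = bits[best_i].copy()
            gbest_rec = records[best_i]
        trace.append(gbest_fit)

    return SearchResult(best_mask=gbest_bits.astype(np.int8),
                        best_fitness=gbest_fit, best_record=gbest_rec,
                        trace=trace, n_evaluations=n_evals)
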