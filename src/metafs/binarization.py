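"""Two-step binarization of continuous metaheuristic positions.

Population metaheuristics such as PSO or the grey wolf optimizer perturb
real-valued positions, but a feature-selection solution is a bit mask.  The
standard bridge is a two-step scheme: (1) a *transfer function* maps each
real coordinate to a probability in [0, 1]; (2) a *binarization rule* turns
that probability into a bit, possibly consulting the agent's current bit and
the global best solution.

Eight classic transfer functions are provided — four sigmoidal ("S-shaped",
``T(0) = 0.5``, strictly increasing) and four symmetric ("V-shaped",
``T(0) = 0``, ``T(-d) = T(d)``) — together with four binarization rules
(standard, complement, static-probability, elitist).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import erf, expit


class TransferFunction(str, enum.Enum):
    """The eight S-shaped / V-shaped transfer functions."""

    S1 = "s1"
    S2 = "s2"
    S3 = "s3"
    S4 = "s4"
    V1 = "v1"
    V2 = "v2"
    V3 = "v3"
    V4 = "v4"


class BinarizationRule(str, enum.Enum):
    """Probability-to-bit rules.

    ``ROULETTE_ELITIST`` is declared for completeness but not implemented:
    its published form depends on group-fitness quantities that are not
    well defined for a single solution update.
    """

    STANDARD = "standard"
    COMPLEMENT = "complement"
    STATIC_PROBABILITY = "static"
    ELITIST = "elitist"
    ROULETTE_ELITIST = "roulette_elitist"


# Sigmoid slopes: S1 = 1/(1+e^{-2d}), S2 = 1/(1+e^{-d}),
# S3 = 1/(1+e^{-d/2}), S4 = 1/(1+e^{-d/3}).
_S_SLOPES = {
    TransferFunction.S1: 2.0,
    TransferFunction.S2: 1.0,
    TransferFunction.S3: 0.5,
    TransferFunction.S4: 1.0 / 3.0,
}


@dataclass(frozen=True)
class BinarizationConfig:
    """Transfer function + rule pair used by a binary metaheuristic.

    The default pairing (S4, standard) is the one used throughout the
    feature-selection experiments.  ``static_alpha`` is the band threshold
    of the static-probability rule only; it is unrelated to the fitness
    weight ``alpha``.
    """

    transfer: TransferFunction = TransferFunction.S4
    rule: BinarizationRule = BinarizationRule.STANDARD
    static_alpha: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.static_alpha < 0.5):
            raise ValueError("static_alpha must lie in (0, 0.5)")


def transfer_value(tf: TransferFunction, d):
    """Map continuous position value(s) ``d`` to a probability in [0, 1].

    Accepts scalars or arrays.  V-shaped functions are the absolute values
    of odd sigmoid-like maps, so their range is [0, 1) and ``T(0) = 0``;
    S-shaped functions are logistic curves with ``T(0) = 0.5``.
    """
    tf = TransferFunction(tf)
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("transfer_value requires finite input")
    if tf in _S_SLOPES:
        out = expit(_S_SLOPES[tf] * d)
    elif tf is TransferFunction.V1:
        out = np.abs(erf(np.sqrt(np.pi) / 2.0 * d))
    elif tf is TransferFunction.V2:
        out = np.abs(np.tanh(d))
    elif tf is TransferFunction.V3:
        out = np.abs(d) / np.sqrt(1.0 + d * d)
    else:  # V4
        out = np.abs(2.0 / np.pi * np.arctan(np.pi / 2.0 * d))
    if out.ndim == 0:
        return float(out)
    return out


def apply_rule(
    rule: BinarizationRule,
    t_val: float,
    rand: float,
    current_bit: int = 0,
    best_bit: int = 0,
    static_alpha: float = 1.0 / 3.0,
) -> int:
    """Turn a transfer probability into a bit.

    - standard: 1 iff ``rand <= t_val``.
    - complement: flip of ``current_bit`` iff ``rand <= t_val``, else 0.
    - static: three bands on ``t_val`` — 0 below ``static_alpha``, keep the
      current bit in the middle band, 1 at or above ``(1 + static_alpha)/2``
      (``rand`` is ignored but still consumed by the population API so the
      draw stream is rule-independent).
    - elitist: copy the best solution's bit iff ``rand < t_val``, else 0.
    """
    rule = BinarizationRule(rule)
    if not (0.0 <= t_val <= 1.0) or not (0.0 <= rand <= 1.0):
        raise ValueError("t_val and rand must lie in [0, 1]")
    if rule is BinarizationRule.STANDARD:
        return int(rand <= t_val)
    if rule is BinarizationRule.COMPLEMENT:
        return int(1 - current_bit) if rand <= t_val else 0
    if rule is BinarizationRule.STATIC_PROBABILITY:
        if t_val <= static_alpha:
            return 0
        if t_val < 0.5 * (1.0 + static_alpha):
            return int(current_bit)
        return 1
    if rule is BinarizationRule.ELITIST:
        return int(best_bit) if rand < t_val else 0
    raise NotImplementedError(
        "the roulette-elitist rule is unsupported: its group-fitness "
        "quantities are not defined for a per-solution update"
    )


def binarize_population(
    positions: np.ndarray,
    cfg: BinarizationConfig,
    rng: np.random.Generator,
    current_bits: np.ndarray,
    best_bits: np.ndarray,
) -> np.ndarray:
    """Binarize an agents x dims matrix of continuous positions.

    One uniform draw is consumed per (agent, dimension) in row-major order
    from ``rng`` regardless of the rule, which makes the bit stream
    reproducible and independent of rule internals.
    """
    positions = np.asarray(positions, dtype=float)
    current_bits = np.asarray(current_bits)
    best_bits = np.asarray(best_bits)
    if positions.ndim != 2:
        raise ValueError("positions must be a 2-D agents x dims matrix")
    if current_bits.shape != positions.shape:
        raise ValueError("current_bits shape mismatch")
    if best_bits.shape != (positions.shape[1],):
        raise ValueError("best_bits must be a vector of length dims")

    t = transfer_value(cfg.transfer, positions)
    draws = rng.random(positions.shape)  # row-major fill

    rule = BinarizationRule(cfg.rule)
    if rule is BinarizationRule.STANDARD:
        bits = draws <= t
    elif rule is BinarizationRule.COMPLEMENT:
        bits = np.where(draws <= t, 1 - current_bits, 0)
    elif rule is BinarizationRule.STATIC_PROBABILITY:
        a = cfg.static_alpha
        bits = np.where(
            t <= a, 0, np.where(t < 0.5 * (1.0 + a), current_bits, 1)
        )
    elif rule is BinarizationRule.ELITIST:
        bits = np.where(draws < t, best_bits[None, :], 0)
    else:
        raise NotImplementedError("roulette_elitist is unsupported")
    return bits.astype(np.int8)
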