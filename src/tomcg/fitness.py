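"""Expected pairwise game payoffs between strategies.

The fitness of strategy X against strategy Y is the expected payoff per
interaction when each interaction consists of playing the game once in each
seat (X as Player 1 against Y as Player 2, and vice versa), averaged over
both seats.  Both a Monte-Carlo estimator (fresh threshold samples per
repetition) and the exact expectation (summing over the product of the two
players' threshold distributions in each seat assignment) are provided; the
exact engine is the default.

An optional linear reasoning cost ``c`` subtracts ``c * k`` from a
strategy's payoff after seat averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .game import PLAYER_1, PLAYER_2, CentipedeSpec
from .reasoning import (
    ActionDistribution,
    ToMStrategy,
    action_distribution,
    sample_thresholds,
    threshold_distribution,
)

__all__ = ["PairwisePayoffMatrix", "exact_fitness", "mc_fitness", "payoff_matrix"]

#: Monte-Carlo repetition count used for fidelity runs.
DEFAULT_R = 50_000


@dataclass(frozen=True)
class PairwisePayoffMatrix:
    """Expected per-interaction payoff for every ordered strategy pair."""

    strategies: tuple[ToMStrategy, ...]
    pay: np.ndarray  # pay[i, j] = payoff of strategies[i] against strategies[j]

    def __post_init__(self):
        n = len(self.strategies)
        if self.pay.shape != (n, n):
            raise ValueError("payoff matrix shape mismatch")

    def index(self, strategy: ToMStrategy) -> int:
        return self.strategies.index(ToMStrategy(*strategy))

    def value(self, x: ToMStrategy, y: ToMStrategy) -> float:
        return float(self.pay[self.index(x), self.index(y)])

    def to_dataframe(self):
        import pandas as pd

        labels = [s.label() for s in self.strategies]
        return pd.DataFrame(self.pay, index=labels, columns=labels)


def _ending_payoff_table(spec: CentipedeSpec, role: int) -> np.ndarray:
    """payoff to ``role`` indexed by ending step (1..L, L+1 = pass-through)."""
    out = np.empty(spec.max_threshold + 1)
    for end in range(1, spec.L + 1):
        out[end] = float(spec.payoff_to(role, end))
    out[spec.max_threshold] = float(spec.payoff_to(role, "pass"))
    return out


def _seat_value(
    spec: CentipedeSpec, d1: ActionDistribution, d2: ActionDistribution, role: int
) -> float:
    """Expected payoff to ``role`` when P1 acts per d1 and P2 per d2."""
    table = _ending_payoff_table(spec, role)
    s1 = np.asarray(d1.steps)
    s2 = np.asarray(d2.steps)
    endings = np.minimum.outer(s1, s2)
    return float(d1.probs @ table[endings] @ d2.probs)


def action_pair(
    strategy: ToMStrategy, spec: CentipedeSpec, rp: str, eps: float
) -> tuple[ActionDistribution, ActionDistribution]:
    """The strategy's exact action distributions in both seats."""
    return tuple(
        action_distribution(
            threshold_distribution(strategy, spec, rp, eps, role), role, spec
        )
        for role in (PLAYER_1, PLAYER_2)
    )


def exact_fitness(
    X: ToMStrategy,
    Y: ToMStrategy,
    spec: CentipedeSpec,
    rp: str,
    eps: float,
    cost: float = 0.0,
) -> float:
    """Exact expected payoff of X against Y, averaged over both seats."""
    X, Y = ToMStrategy(*X), ToMStrategy(*Y)
    x1, x2 = action_pair(X, spec, rp, eps)
    y1, y2 = action_pair(Y, spec, rp, eps)
    v = 0.5 * (
        _seat_value(spec, x1, y2, PLAYER_1) + _seat_value(spec, y1, x2, PLAYER_2)
    )
    return v - cost * X.k


def mc_fitness(
    X: ToMStrategy,
    Y: ToMStrategy,
    spec: CentipedeSpec,
    rp: str,
    eps: float,
    R: int = DEFAULT_R,
    rng: np.random.Generator | None = None,
    cost: float = 0.0,
) -> float:
    """Monte-Carlo estimate of X's payoff against Y over ``R`` repetitions.

    Per repetition both individuals sample fresh thresholds for both seats
    and the seat-averaged payoff to X is recorded.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    rng = rng if rng is not None else np.random.default_rng()
    X, Y = ToMStrategy(*X), ToMStrategy(*Y)
    hi = spec.max_threshold

    def acts(s: ToMStrategy, role: int) -> np.ndarray:
        th = sample_thresholds(s, spec, rp, eps, role, rng, size=R)
        steps = np.array(
            [
                (spec.action_step(v, role) or hi)
                for v in range(1, hi + 1)
            ]
        )
        return steps[th - 1]

    x1, x2 = acts(X, PLAYER_1), acts(X, PLAYER_2)
    y1, y2 = acts(Y, PLAYER_1), acts(Y, PLAYER_2)
    t1 = _ending_payoff_table(spec, PLAYER_1)
    t2 = _ending_payoff_table(spec, PLAYER_2)
    pay = 0.5 * (t1[np.minimum(x1, y2)] + t2[np.minimum(y1, x2)])
    return float(pay.mean()) - cost * X.k


def payoff_matrix(
    strategies: Sequence[ToMStrategy],
    spec: CentipedeSpec,
    rp: str,
    eps: float,
    mode: str = "exact",
    R: int = DEFAULT_R,
    rng: np.random.Generator | None = None,
    cost: float = 0.0,
) -> PairwisePayoffMatrix:
    """Pairwise payoff matrix over a strategy set.

    ``mode="exact"`` (default) is deterministic; ``mode="mc"`` reproduces
    the Monte-Carlo protocol with ``R`` repetitions per ordered pair.
    """
    strategies = tuple(ToMStrategy(*s) for s in strategies)
    if not strategies:
        raise ValueError("strategy set must be nonempty")
    n = len(strategies)
    pay = np.empty((n, n))
    if mode == "exact":
        pairs = {s: action_pair(s, spec, rp, eps) for s in set(strategies)}
        for i, X in enumerate(strategies):
            x1, x2 = pairs[X]
            for j, Y in enumerate(strategies):
                y1, y2 = pairs[Y]
                pay[i, j] = 0.5 * (
                    _seat_value(spec, x1, y2, PLAYER_1)
                    + _seat_value(spec, y1, x2, PLAYER_2)
                ) - cost * X.k
    elif mode == "mc":
        rng = rng if rng is not None else np.random.default_rng()
        for i, X in enumerate(strategies):
            for j, Y in enumerate(strategies):
                pay[i, j] = mc_fitness(X, Y, spec, rp, eps, R=R, rng=rng, cost=cost)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PairwisePayoffMatrix(strategies=strategies, pay=pay)
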