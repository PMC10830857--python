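"""Recursive theory-of-mind strategies and stochastic reasoning processes.

A strategy is a duple ``(t, k)``: ``t`` is the prior belief about the
earliest step at which to Take (``t = L + 1`` encodes always-Postpone) and
``k`` the depth of recursive reasoning.  A ``(t, k)`` individual believes
every co-player uses ``(t, k - 1)``; at ``k = 0`` the belief is acted upon
directly.  Starting from the level-0 point belief, each reasoning level
applies a kernel that converts the believed co-player threshold into the
reasoner's own threshold, with seats alternating so that the final level is
evaluated in the focal individual's actual role.

Three kernels (reasoning processes, RPs) are implemented:

``unconditional``
    always undercut: respond with ``max(co - 1, 1)``.
``conditional``
    undercut only when the realized game outcome of holding threshold
    ``co - 1`` is at least as good (for the reasoner's seat) as holding
    ``co``; otherwise keep ``co``.
``inertia``
    undercut only on a *strict* payoff gain; otherwise fall back to what
    the same reasoning agent inferred at her previous (two levels lower)
    evaluation, bottoming out at the prior ``t``.

Candidate thresholds are scored by resolving the actual game: each
threshold maps to the seat's earliest feasible step and the game ends at
the earlier of the two mapped steps (pass-through if neither takes).
Payoff comparisons use the exact fractional schedule, so ties are exact.

Cognitive errors: with probability ``eps`` the kernel output at each level
(including the last) is displaced by one step (``eps/2`` up, ``eps/2``
down), clamped to ``[1, L + 1]``; the level-0 prior is a belief, not a
computation, and carries no error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .game import NEVER, PLAYER_1, PLAYER_2, CentipedeSpec, other_role

__all__ = [
    "RP_KINDS",
    "ToMStrategy",
    "ThresholdDistribution",
    "ActionDistribution",
    "rp_kernel",
    "threshold_trace",
    "threshold_distribution",
    "sample_threshold",
    "sample_thresholds",
    "action_distribution",
    "strategy_space",
]

RP_KINDS = ("unconditional", "conditional", "inertia")


class ToMStrategy(NamedTuple):
    """Prior belief threshold ``t`` and recursion depth ``k``."""

    t: int
    k: int

    def label(self) -> str:
        return f"({self.t},{self.k})"


def strategy_space(spec: CentipedeSpec, k_max: int | None = None) -> list[ToMStrategy]:
    """All ``(t, k)`` strategies: t in [1, L+1], k in [0, k_max] (default L)."""
    if k_max is None:
        k_max = spec.L
    return [
        ToMStrategy(t, k)
        for t in range(1, spec.max_threshold + 1)
        for k in range(k_max + 1)
    ]


@dataclass(frozen=True)
class ThresholdDistribution:
    """Probability distribution over take-thresholds ``1..L+1``."""

    spec: CentipedeSpec
    probs: np.ndarray  # shape (L+1,), index i -> threshold i+1

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.spec.max_threshold,):
            raise ValueError("probability vector has wrong length")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    def support(self) -> np.ndarray:
        """Thresholds with strictly positive probability."""
        return np.nonzero(self.probs > 0)[0] + 1

    def mean(self) -> float:
        return float(self.probs @ np.arange(1, self.spec.max_threshold + 1))


@dataclass(frozen=True)
class ActionDistribution:
    """Distribution over role-feasible take steps plus never-take.

    ``steps`` lists the seat's feasible steps followed by ``L + 1`` as the
    numeric stand-in for never-take; ``probs`` aligns with it.
    """

    spec: CentipedeSpec
    role: int
    steps: tuple[int, ...]
    probs: np.ndarray

    def as_dict(self) -> dict:
        out = {}
        for s, p in zip(self.steps, self.probs):
            out[NEVER if s > self.spec.L else s] = float(p)
        return out


def _mapped_outcome(spec: CentipedeSpec, theta: int, role: int, co_threshold: int):
    """Exact payoff to ``role`` holding ``theta`` against ``co_threshold``."""
    s_me = spec.action_step(theta, role)
    s_co = spec.action_step(co_threshold, other_role(role))
    pt = spec.max_threshold
    ending = min(s_me if s_me is not NEVER else pt, s_co if s_co is not NEVER else pt)
    return spec.payoff_to(role, ending if ending <= spec.L else "pass")


def rp_kernel(
    rp: str,
    spec: CentipedeSpec,
    reasoner_role: int,
    co_threshold: int,
    own_prev_threshold: int,
) -> int:
    """One noise-free reasoning step: the reasoner's response threshold.

    ``co_threshold`` is the threshold the reasoner believes her co-player
    (seated in the opposite role) holds; ``own_prev_threshold`` is the
    fallback carried by the inertia RP.
    """
    if rp not in RP_KINDS:
        raise ValueError(f"unknown reasoning process {rp!r}")
    hi = spec.max_threshold
    if not (1 <= co_threshold <= hi and 1 <= own_prev_threshold <= hi):
        raise ValueError("thresholds must lie in [1, L+1]")
    if rp == "unconditional":
        return max(co_threshold - 1, 1)
    if co_threshold == 1:
        # no step exists before the co-player's earliest take
        return 1 if rp == "conditional" else own_prev_threshold
    v_pre = _mapped_outcome(spec, co_threshold - 1, reasoner_role, co_threshold)
    v_stay = _mapped_outcome(spec, co_threshold, reasoner_role, co_threshold)
    if rp == "conditional":
        return co_threshold - 1 if v_pre >= v_stay else co_threshold
    return co_threshold - 1 if v_pre > v_stay else own_prev_threshold


def _level_role(final_role: int, k: int, j: int) -> int:
    """Seat of the imagined reasoner at level ``j``; level ``k`` is focal."""
    return final_role if (k - j) % 2 == 0 else other_role(final_role)


def threshold_trace(
    strategy: ToMStrategy, spec: CentipedeSpec, rp: str, role: int
) -> list[int]:
    """Noise-free recursion: thresholds ``[t0, t1, ..., tk]``.

    Level 0 is the prior belief; level ``j`` is the response computed by
    the imagined reasoner at that level (final level in ``role``).
    """
    t, k = strategy
    trace = [t]
    for j in range(1, k + 1):
        prev = trace[j - 2] if j >= 2 else t
        trace.append(rp_kernel(rp, spec, _level_role(role, k, j), trace[j - 1], prev))
    return trace


def _branch(eps: float):
    if eps == 0.0:
        return ((0, 1.0),)
    return ((-1, eps / 2.0), (0, 1.0 - eps), (1, eps / 2.0))


def threshold_distribution(
    strategy: ToMStrategy,
    spec: CentipedeSpec,
    rp: str,
    eps: float,
    role: int,
) -> ThresholdDistribution:
    """Exact threshold distribution by enumerating the error-branching tree.

    Dynamic programme over pairs ``(x_{j-1}, x_{j-2})`` of the two most
    recent (perturbed) levels: ``x_{j-1}`` is the believed co-player
    threshold consumed at level ``j`` and ``x_{j-2}`` the same-seat fallback
    used by the inertia RP.
    """
    if not (0.0 <= eps < 1.0):
        raise ValueError("eps must lie in [0, 1)")
    t, k = strategy
    hi = spec.max_threshold
    if not (1 <= t <= hi):
        raise ValueError(f"prior threshold {t} outside [1, {hi}]")
    if k < 0:
        raise ValueError("recursion depth must be nonnegative")
    states: dict[tuple[int, int], float] = {(t, t): 1.0}
    for j in range(1, k + 1):
        lev_role = _level_role(role, k, j)
        new: dict[tuple[int, int], float] = {}
        for (co, prev), p in states.items():
            x = rp_kernel(rp, spec, lev_role, co, prev)
            for dx, q in _branch(eps):
                y = min(max(x + dx, 1), hi)
                key = (y, co)
                new[key] = new.get(key, 0.0) + p * q
        states = new
    probs = np.zeros(hi)
    for (th, _), p in states.items():
        probs[th - 1] += p
    return ThresholdDistribution(spec=spec, probs=probs)


def sample_thresholds(
    strategy: ToMStrategy,
    spec: CentipedeSpec,
    rp: str,
    eps: float,
    role: int,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Vectorized realizations of the stochastic reasoning process."""
    t, k = strategy
    hi = spec.max_threshold
    co = np.full(size, t, dtype=np.int64)
    prev = np.full(size, t, dtype=np.int64)
    # kernel lookup table per (role, co, prev)
    for j in range(1, k + 1):
        lev_role = _level_role(role, k, j)
        table = np.empty((hi + 1, hi + 1), dtype=np.int64)
        for c in range(1, hi + 1):
            for pv in range(1, hi + 1):
                table[c, pv] = rp_kernel(rp, spec, lev_role, c, pv)
        x = table[co, prev]
        if eps > 0.0:
            u = rng.random(size)
            x = x - (u < eps / 2) + (u >= 1 - eps / 2)
            x = np.clip(x, 1, hi)
        prev = co
        co = x
    return co


def sample_threshold(
    strategy: ToMStrategy,
    spec: CentipedeSpec,
    rp: str,
    eps: float,
    role: int,
    rng: np.random.Generator,
) -> int:
    """One realization of the branching reasoning process."""
    return int(sample_thresholds(strategy, spec, rp, eps, role, rng, size=1)[0])


def action_distribution(
    tdist: ThresholdDistribution, role: int, spec: CentipedeSpec | None = None
) -> ActionDistribution:
    """Map a threshold distribution to the seat's take-step distribution.

    Each threshold maps to the earliest role-feasible step at or after it;
    thresholds beyond the seat's last step aggregate on never-take
    (represented numerically as ``L + 1``).
    """
    spec = spec or tdist.spec
    steps = spec.feasible_steps(role) + (spec.max_threshold,)
    probs = np.zeros(len(steps))
    index = {s: i for i, s in enumerate(steps)}
    for th in range(1, spec.max_threshold + 1):
        s = spec.action_step(th, role)
        probs[index[s if s is not NEVER else spec.max_threshold]] += tdist.probs[th - 1]
    return ActionDistribution(spec=spec, role=role, steps=steps, probs=probs)
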