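"""Centipede game payoff structures and outcome resolution.

Two players alternate deciding whether to Take (end the game, claiming the
larger share of the current resource) or Postpone (let the resource evolve
and hand the move over).  Player 1 moves at odd steps, Player 2 at even
steps; the total number of decision steps ``L`` is even, so Player 2 owns
the last one.  Two families are supported:

* the incremental game (ICG), where a resource ``M`` is multiplied by a
  growth factor at every step and the taker receives a fixed fraction
  (``take_split``) of the current resource, with one final growth applied
  when Player 2 postpones at step ``L`` and the result split in favour of
  Player 1; and
* constant-size / custom games, where an explicit per-step payoff table is
  supplied (the constant-sum centipede game is the canonical example).

Payoffs are stored internally as :class:`fractions.Fraction` so that the
payoff comparisons performed by the reasoning kernels are exact; the public
accessors return floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

__all__ = [
    "PASS_THROUGH",
    "NEVER",
    "PLAYER_1",
    "PLAYER_2",
    "CentipedeSpec",
    "GameOutcome",
    "make_icg",
    "make_custom",
    "game_outcome",
    "load_preset",
]

#: Sentinel ending step for a game in which nobody takes.
PASS_THROUGH = "pass"

#: Sentinel take step for a player who never takes.
NEVER = None

PLAYER_1 = 1
PLAYER_2 = 2


def other_role(role: int) -> int:
    """The co-player's seat."""
    return PLAYER_2 if role == PLAYER_1 else PLAYER_1


def _as_fraction(x) -> Fraction:
    """Exact conversion; floats go through their decimal string form."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class CentipedeSpec:
    """A two-player alternating take/postpone game.

    Attributes
    ----------
    L:
        Number of decision steps (positive even integer).
    schedule:
        Tuple of ``L`` payoff pairs ``(pi1, pi2)``: the players' payoffs if
        the game ends by a Take at that step (the mover at the step is the
        taker).
    pass_through:
        Payoff pair if both players always postpone.
    variant:
        ``"incremental"``, ``"constant"`` or ``"custom"``.
    M, growth_factor, take_split:
        Generating parameters (informational for custom schedules).
    """

    L: int
    schedule: tuple[tuple[Fraction, Fraction], ...]
    pass_through: tuple[Fraction, Fraction]
    variant: str = "custom"
    M: Fraction = field(default_factory=lambda: Fraction(0))
    growth_factor: Fraction = field(default_factory=lambda: Fraction(1))
    take_split: Fraction = field(default_factory=lambda: Fraction(1, 2))

    def __post_init__(self):
        if self.L < 2 or self.L % 2 != 0:
            raise ValueError(f"L must be a positive even integer, got {self.L}")
        if len(self.schedule) != self.L:
            raise ValueError(
                f"schedule has {len(self.schedule)} rows, expected L={self.L}"
            )
        for l, (a, b) in enumerate(self.schedule, start=1):
            if a < 0 or b < 0:
                raise ValueError(f"negative payoff at step {l}")
        if any(p < 0 for p in self.pass_through):
            raise ValueError("negative pass-through payoff")

    # -- payoff accessors -------------------------------------------------

    def payoffs_at(self, ending) -> tuple[Fraction, Fraction]:
        """Exact payoff pair for a game ending at ``ending``.

        ``ending`` is a step in ``[1, L]`` or :data:`PASS_THROUGH` (any
        integer above ``L`` is treated as pass-through).
        """
        if ending == PASS_THROUGH or (isinstance(ending, int) and ending > self.L):
            return self.pass_through
        return self.schedule[ending - 1]

    def payoff_to(self, role: int, ending) -> Fraction:
        """Exact payoff of ``role`` when the game ends at ``ending``."""
        pair = self.payoffs_at(ending)
        return pair[0] if role == PLAYER_1 else pair[1]

    # -- role/action helpers ----------------------------------------------

    def feasible_steps(self, role: int) -> tuple[int, ...]:
        """Decision steps owned by ``role`` (odd for Player 1, even for 2)."""
        start = 1 if role == PLAYER_1 else 2
        return tuple(range(start, self.L + 1, 2))

    def action_step(self, threshold: int, role: int):
        """Earliest role-feasible step at or after ``threshold``.

        Returns :data:`NEVER` when the threshold lies beyond the role's
        last step (always-postpone).
        """
        for s in self.feasible_steps(role):
            if s >= threshold:
                return s
        return NEVER

    @property
    def max_threshold(self) -> int:
        """Threshold value encoding always-postpone (``L + 1``)."""
        return self.L + 1

    def float_schedule(self) -> list[tuple[float, float]]:
        return [(float(a), float(b)) for a, b in self.schedule]


@dataclass(frozen=True)
class GameOutcome:
    """Resolved game: ending step (or :data:`PASS_THROUGH`) and payoffs."""

    ending_step: object
    payoff_p1: float
    payoff_p2: float


def make_icg(L: int = 4, M=0.5, growth=2, split=0.8) -> CentipedeSpec:
    """Incremental centipede game with exponentially growing resource.

    The resource at step ``l`` is ``growth**(l-1) * M``; a Take at step
    ``l`` gives the mover ``split`` of it and the co-player the remainder.
    If Player 2 postpones at step ``L`` one final growth is applied and the
    result is split with fraction ``split`` to Player 1.
    """
    M, growth, split = _as_fraction(M), _as_fraction(growth), _as_fraction(split)
    if L < 2 or L % 2 != 0:
        raise ValueError(f"L must be a positive even integer, got {L}")
    if M <= 0:
        raise ValueError("M must be positive")
    if growth <= 1:
        raise ValueError("growth must exceed 1")
    if not (Fraction(1, 2) <= split <= 1):
        raise ValueError("take_split must lie in [0.5, 1]")
    rows = []
    for l in range(1, L + 1):
        resource = M * growth ** (l - 1)
        taker, rest = split * resource, (1 - split) * resource
        rows.append((taker, rest) if l % 2 == 1 else (rest, taker))
    final = M * growth**L
    return CentipedeSpec(
        L=L,
        schedule=tuple(rows),
        pass_through=(split * final, (1 - split) * final),
        variant="incremental",
        M=M,
        growth_factor=growth,
        take_split=split,
    )


def make_custom(schedule: Sequence[Sequence], pass_through: Sequence) -> CentipedeSpec:
    """Game whose outcomes are read directly from a payoff table.

    ``schedule`` holds one ``(pi1, pi2)`` row per step; ``pass_through`` is
    the payoff pair when both players always postpone.  The variant is
    labelled ``"constant"`` when all rows (and the pass-through) share the
    same payoff sum.
    """
    rows = tuple((_as_fraction(a), _as_fraction(b)) for a, b in schedule)
    pt = tuple(_as_fraction(x) for x in pass_through)
    if len(pt) != 2:
        raise ValueError("pass_through must be a payoff pair")
    L = len(rows)
    sums = {a + b for a, b in rows} | {pt[0] + pt[1]}
    variant = "constant" if len(sums) == 1 else "custom"
    return CentipedeSpec(L=L, schedule=rows, pass_through=pt, variant=variant)


def _validate_take(take, role: int, L: int):
    if take is NEVER:
        return None
    take = int(take)
    if take > L:
        return None  # any step beyond L means always-postpone
    if take < 1 or take % 2 != (1 if role == PLAYER_1 else 0):
        raise ValueError(
            f"take step {take} is not feasible for Player {role} (L={L})"
        )
    return take


def game_outcome(spec: CentipedeSpec, take1, take2) -> GameOutcome:
    """Resolve the game given each player's intended take step.

    ``take1`` must be odd (or :data:`NEVER`), ``take2`` even (or NEVER);
    the game ends at the earlier of the two, or passes through if neither
    player ever takes.
    """
    t1 = _validate_take(take1, PLAYER_1, spec.L)
    t2 = _validate_take(take2, PLAYER_2, spec.L)
    if t1 is None and t2 is None:
        ending = PASS_THROUGH
    elif t1 is None:
        ending = t2
    elif t2 is None:
        ending = t1
    else:
        ending = min(t1, t2)
    p1, p2 = spec.payoffs_at(ending)
    return GameOutcome(ending_step=ending, payoff_p1=float(p1), payoff_p2=float(p2))


def load_preset(name: str) -> CentipedeSpec:
    """Load one of the shipped game presets (``icg4``, ``icg6``, ``ccg6``)."""
    from . import io  # local import to avoid a cycle

    return io.spec_from_config(io.read_preset(name))
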