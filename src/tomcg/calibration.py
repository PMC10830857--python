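"""Fitting selection intensity and error rate to ending-step data.

Behavioral centipede-game experiments report how often games end at each
step.  The model's counterpart is the stationary ending-step distribution:
the sigma-weighted mixture, over monomorphic states of the rare-mutation
chain, of the ending-step distribution of two independent same-strategy
individuals playing both seats.  ``fit`` grid-searches ``(beta, eps)`` for
the best match; ``make_fixture`` draws synthetic multinomial data from the
model for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolution import EmbeddedChain, embedded_chain
from .fitness import payoff_matrix
from .game import PLAYER_1, PLAYER_2, CentipedeSpec
from .reasoning import action_distribution, strategy_space, threshold_distribution

__all__ = [
    "EmpiricalStepDistribution",
    "model_step_distribution",
    "fit",
    "FitResult",
    "make_fixture",
]


@dataclass(frozen=True)
class EmpiricalStepDistribution:
    """Probabilities over ending steps ``1..L`` plus pass-through (last)."""

    spec: CentipedeSpec
    probs: np.ndarray  # length L + 1; final entry = pass-through
    source: str = ""

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.spec.L + 1,):
            raise ValueError("expected one probability per step plus pass-through")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)


def _self_play_step_distribution(
    strategy, spec: CentipedeSpec, rp: str, eps: float
) -> np.ndarray:
    """Ending-step distribution of two same-strategy individuals."""
    d1 = action_distribution(
        threshold_distribution(strategy, spec, rp, eps, PLAYER_1), PLAYER_1, spec
    )
    d2 = action_distribution(
        threshold_distribution(strategy, spec, rp, eps, PLAYER_2), PLAYER_2, spec
    )
    out = np.zeros(spec.L + 1)
    endings = np.minimum.outer(np.asarray(d1.steps), np.asarray(d2.steps))
    joint = np.outer(d1.probs, d2.probs)
    for e in range(1, spec.L + 1):
        out[e - 1] = joint[endings == e].sum()
    out[spec.L] = joint[endings > spec.L].sum()
    return out


def model_step_distribution(
    chain: EmbeddedChain, spec: CentipedeSpec, rp: str, eps: float
) -> EmpiricalStepDistribution:
    """Stationary ending-step distribution implied by the chain."""
    probs = np.zeros(spec.L + 1)
    for s, w in zip(chain.strategies, chain.sigma):
        if w > 0:
            probs += w * _self_play_step_distribution(s, spec, rp, eps)
    return EmpiricalStepDistribution(
        spec=spec, probs=probs / probs.sum(), source="model"
    )


def make_fixture(
    spec: CentipedeSpec,
    rp: str,
    beta: float,
    eps: float,
    Z: int,
    n: int,
    rng: np.random.Generator,
    k_max: int | None = None,
    source: str = "synthetic",
) -> EmpiricalStepDistribution:
    """Multinomial sample of ``n`` games from the model step distribution."""
    if n < 1:
        raise ValueError("n must be at least 1")
    model = _model_steps_at(spec, rp, beta, eps, Z, k_max)
    counts = rng.multinomial(n, model)
    return EmpiricalStepDistribution(spec=spec, probs=counts / n, source=source)


def _model_steps_at(spec, rp, beta, eps, Z, k_max=None) -> np.ndarray:
    strategies = strategy_space(spec, k_max)
    pay = payoff_matrix(strategies, spec, rp, eps)
    chain = embedded_chain(strategies, Z, beta, pay)
    return model_step_distribution(chain, spec, rp, eps).probs


@dataclass(frozen=True)
class FitResult:
    beta: float
    eps: float
    distance: float
    surface: "object"  # tidy DataFrame: beta, eps, sse, kl


def _distances(model: np.ndarray, emp: np.ndarray) -> tuple[float, float]:
    sse = float(((model - emp) ** 2).sum())
    mask = emp > 0
    kl = float((emp[mask] * np.log(emp[mask] / np.maximum(model[mask], 1e-300))).sum())
    return sse, kl


def fit(
    empirical: EmpiricalStepDistribution,
    spec: CentipedeSpec,
    rp: str,
    beta_grid,
    eps_grid,
    Z: int,
    metric: str = "sse",
    k_max: int | None = None,
    model_cache: dict | None = None,
) -> FitResult:
    """Grid search for the ``(beta, eps)`` best matching the data.

    The default distance is the sum of squared differences over ending-step
    categories; ``metric="kl"`` uses the Kullback-Leibler divergence from
    the data to the model.  Both are reported on the returned surface.
    ``model_cache`` may be supplied to reuse model distributions across
    repeated fits on the same grid (keyed by ``(beta, eps)``).
    """
    import pandas as pd

    beta_grid = list(beta_grid)
    eps_grid = list(eps_grid)
    if not beta_grid or not eps_grid:
        raise ValueError("grids must be nonempty")
    if metric not in ("sse", "kl"):
        raise ValueError("metric must be 'sse' or 'kl'")
    rows = []
    best = None
    for eps in eps_grid:
        for beta in beta_grid:
            key = (float(beta), float(eps))
            if model_cache is not None and key in model_cache:
                model = model_cache[key]
            else:
                model = _model_steps_at(spec, rp, beta, eps, Z, k_max)
                if model_cache is not None:
                    model_cache[key] = model
            sse, kl = _distances(model, empirical.probs)
            rows.append({"beta": beta, "eps": eps, "sse": sse, "kl": kl})
            d = sse if metric == "sse" else kl
            if best is None or d < best[0]:
                best = (d, float(beta), float(eps))
    surface = pd.DataFrame(rows)
    return FitResult(beta=best[1], eps=best[2], distance=best[0], surface=surface)
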