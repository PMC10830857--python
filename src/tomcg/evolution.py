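"""Finite-population evolutionary analysis in the rare-mutation limit.

Strategies spread by pairwise Fermi imitation: an individual imitates a
role model with probability ``1 / (1 + exp(-beta * (f_rolemodel - f_self)))``
where ``beta`` is the selection intensity.  When mutations are rare the
population is monomorphic almost always and the dynamics reduce to a Markov
chain over monomorphic states whose transitions are single-mutant fixation
probabilities; its stationary distribution gives the long-run prevalence of
every strategy.  The two-strategy gradient of selection
``G(i) = T+(i) - T-(i)`` locates finite-population attractors and
repellers, and a strategy is evolutionarily robust when every mutant fixes
with probability below the neutral value ``1/Z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitness import PairwisePayoffMatrix
from .game import PLAYER_1, PLAYER_2, CentipedeSpec
from .reasoning import ToMStrategy, action_distribution, threshold_distribution

__all__ = [
    "fermi_prob",
    "composition_fitness",
    "fixation_probability",
    "EmbeddedChain",
    "embedded_chain",
    "StationaryMarginals",
    "marginals",
    "GradientProfile",
    "gradient_of_selection",
    "is_evolutionarily_robust",
]


def fermi_prob(beta: float, f_role_model: float, f_focal: float) -> float:
    """Probability that the focal individual imitates the role model."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    x = np.clip(beta * (f_role_model - f_focal), -700.0, 700.0)
    return float(1.0 / (1.0 + np.exp(-x)))


def composition_fitness(
    A: ToMStrategy, B: ToMStrategy, i: int, Z: int, pay: PairwisePayoffMatrix
) -> tuple[float, float]:
    """Average payoffs of A- and B-players when ``i`` of ``Z`` play A.

    Interactions are well-mixed with self excluded, so each individual
    averages over the remaining ``Z - 1`` co-players.
    """
    if not (1 <= i <= Z - 1):
        raise ValueError("composition i must lie in [1, Z-1]")
    a, b = pay.index(A), pay.index(B)
    fA = ((i - 1) * pay.pay[a, a] + (Z - i) * pay.pay[a, b]) / (Z - 1)
    fB = (i * pay.pay[b, a] + (Z - 1 - i) * pay.pay[b, b]) / (Z - 1)
    return float(fA), float(fB)


def _fitness_profiles(a: int, b: int, Z: int, pay: np.ndarray):
    i = np.arange(1, Z)
    fA = ((i - 1) * pay[a, a] + (Z - i) * pay[a, b]) / (Z - 1)
    fB = (i * pay[b, a] + (Z - 1 - i) * pay[b, b]) / (Z - 1)
    return i, fA, fB

def fixation_probability(
    invader: ToMStrategy,
    resident: ToMStrategy,
    Z: int,
    beta: float,
    pay: PairwisePayoffMatrix,
) -> float:
    """Probability that a single invader takes over a resident population.

    Closed form for one-dimensional birth-death chains,
    ``rho = 1 / (1 + sum_m prod_{i<=m} exp(-beta (f_inv(i) - f_res(i))))``,
    accumulated in log space so that large ``beta * Z`` cannot overflow.
    """
    if Z < 2:
        raise ValueError("Z must be at least 2")
    _, fA, fB = _fitness_profiles(pay.index(invader), pay.index(resident), Z, pay.pay)
    log_lambda = np.clip(-beta * (fA - fB), -700.0, 700.0)
    cum = np.cumsum(log_lambda)
    m = cum.max()
    if m > 690.0:  # the sum dwarfs 1: rho underflows
        return 0.0
    return float(1.0 / (1.0 + np.exp(cum).sum()))


@dataclass(frozen=True)
class EmbeddedChain:
    """Rare-mutation Markov chain over monomorphic states."""

    strategies: tuple[ToMStrategy, ...]
    gamma: np.ndarray  # row-stochastic transition matrix
    sigma: np.ndarray  # stationary distribution
    Z: int
    beta: float

    def sigma_of(self, strategy: ToMStrategy) -> float:
        return float(self.sigma[self.strategies.index(ToMStrategy(*strategy))])


def _stationary(gamma: np.ndarray) -> np.ndarray:
    """Left fixed vector of a row-stochastic matrix via a linear solve."""
    n = gamma.shape[0]
    A = gamma.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        sigma = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        # reducible chain: fall back to the dominant left eigenvector
        w, v = np.linalg.eig(gamma.T)
        sigma = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        sigma = sigma / sigma.sum()
    if (sigma < -1e-9).any():
        raise ArithmeticError("chain is not ergodic: no valid stationary vector")
    sigma = np.clip(sigma, 0.0, None)
    return sigma / sigma.sum()


def embedded_chain(
    strategies,
    Z: int,
    beta: float,
    pay: PairwisePayoffMatrix,
    k_transition_weight: float | None = None,
) -> EmbeddedChain:
    """Transition matrix and stationary distribution of monomorphic states.

    ``gamma[i, j] = rho_{i -> j} / (n_S - 1)`` for ``i != j`` with the
    diagonal absorbing the remainder.  ``k_transition_weight`` (in
    ``(0, 1]``) optionally down-weights mutations that change the k-level,
    modelling beliefs being easier to change than cognitive capacity; rows
    are renormalized by adjusting the diagonal.
    """
    strategies = tuple(ToMStrategy(*s) for s in strategies)
    n = len(strategies)
    gamma = np.zeros((n, n))
    for i, res in enumerate(strategies):
        for j, inv in enumerate(strategies):
            if i == j:
                continue
            w = 1.0
            if k_transition_weight is not None and inv.k != res.k:
                w = float(k_transition_weight)
            gamma[i, j] = w * fixation_probability(inv, res, Z, beta, pay) / (n - 1)
        gamma[i, i] = 1.0 - gamma[i].sum()
    return EmbeddedChain(
        strategies=strategies, gamma=gamma, sigma=_stationary(gamma), Z=Z, beta=beta
    )


@dataclass(frozen=True)
class StationaryMarginals:
    """Stationary-distribution summaries of beliefs, reasoning and actions."""

    t_marginal: dict
    k_marginal: dict
    action_marginal: dict  # ending-step value L+1 denotes never-take
    avg_k: float
    avg_t: float
    belief_mismatch_by_k: dict = field(default_factory=dict)


def marginals(
    chain: EmbeddedChain, spec: CentipedeSpec, rp: str, eps: float
) -> StationaryMarginals:
    """Stationary marginals over ``t``, ``k`` and take steps ``T``.

    The action marginal pools both seats of each strategy's own action
    distribution.  The belief mismatch per k-level is the sigma-weighted
    mean prior belief ``t`` minus the mean realized take-threshold; it
    vanishes for ``k = 0`` strategies, whose threshold equals their belief.
    """
    tm: dict[int, float] = {}
    km: dict[int, float] = {}
    am: dict[int, float] = {}
    avg_k = avg_t = 0.0
    acc: dict[int, list[float]] = {}
    for s, w in zip(chain.strategies, chain.sigma):
        tm[s.t] = tm.get(s.t, 0.0) + w
        km[s.k] = km.get(s.k, 0.0) + w
        avg_k += w * s.k
        avg_t += w * s.t
        mean_th = 0.0
        for role in (PLAYER_1, PLAYER_2):
            td = threshold_distribution(s, spec, rp, eps, role)
            mean_th += 0.5 * td.mean()
            ad = action_distribution(td, role, spec)
            for step, p in zip(ad.steps, ad.probs):
                am[step] = am.get(step, 0.0) + 0.5 * w * float(p)
        rec = acc.setdefault(s.k, [0.0, 0.0])
        rec[0] += w * (s.t - mean_th)
        rec[1] += w
    mismatch = {k: (v[0] / v[1] if v[1] > 0 else 0.0) for k, v in acc.items()}
    return StationaryMarginals(
        t_marginal=dict(sorted(tm.items())),
        k_marginal=dict(sorted(km.items())),
        action_marginal=dict(sorted(am.items())),
        avg_k=avg_k,
        avg_t=avg_t,
        belief_mismatch_by_k=dict(sorted(mismatch.items())),
    )


@dataclass(frozen=True)
class GradientProfile:
    """Two-strategy gradient of selection over compositions 1..Z-1."""

    focal: ToMStrategy
    other: ToMStrategy
    Z: int
    beta: float
    counts: np.ndarray
    G: np.ndarray
    attractors: tuple[float, ...]
    repellers: tuple[float, ...]

    def has_interior_repeller(self) -> bool:
        return len(self.repellers) > 0


def gradient_of_selection(
    A: ToMStrategy, B: ToMStrategy, Z: int, beta: float, pay: PairwisePayoffMatrix
) -> GradientProfile:
    """``G(i) = T+(i) - T-(i)`` for the focal strategy A against B.

    ``T±`` are the one-step probabilities of the number of A-players
    increasing/decreasing under the pairwise Fermi rule.  Interior roots are
    classified on the discrete grid: a sign change from - to + as ``i``
    grows is a repeller (reported at the midpoint), + to - an attractor.
    """
    i, fA, fB = _fitness_profiles(pay.index(A), pay.index(B), Z, pay.pay)
    d = np.clip(beta * (fA - fB), -700.0, 700.0)
    pref = (i / Z) * ((Z - i) / Z)
    G = pref * (1.0 / (1.0 + np.exp(-d)) - 1.0 / (1.0 + np.exp(d)))
    sign = np.sign(G)
    attractors, repellers = [], []
    for j in range(len(i) - 1):
        if sign[j] < 0 and sign[j + 1] > 0:
            repellers.append((i[j] + i[j + 1]) / 2.0)
        elif sign[j] > 0 and sign[j + 1] < 0:
            attractors.append((i[j] + i[j + 1]) / 2.0)
    # boundary classification: flow direction at the edges
    if G[0] < 0:
        attractors.insert(0, 0.0)
    if G[-1] > 0:
        attractors.append(float(Z))
    return GradientProfile(
        focal=ToMStrategy(*A),
        other=ToMStrategy(*B),
        Z=Z,
        beta=beta,
        counts=i,
        G=G,
        attractors=tuple(attractors),
        repellers=tuple(repellers),
    )


def is_evolutionarily_robust(
    s: ToMStrategy,
    strategies,
    Z: int,
    beta: float,
    pay: PairwisePayoffMatrix,
    rel_tol: float = 1e-12,
) -> tuple[bool, dict]:
    """Whether no mutant invades ``s`` above the neutral rate ``1/Z``.

    Returns the verdict plus a per-mutant table of fixation probabilities;
    mutants within ``rel_tol`` of ``1/Z`` are reported as neutral edges and
    do not count as robust violations only if strictly below.
    """
    s = ToMStrategy(*s)
    neutral = 1.0 / Z
    table: dict[ToMStrategy, float] = {}
    robust = True
    for m in strategies:
        m = ToMStrategy(*m)
        if m == s:
            continue
        rho = fixation_probability(m, s, Z, beta, pay)
        table[m] = rho
        if rho >= neutral * (1.0 - rel_tol):
            robust = False
    return robust, table
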