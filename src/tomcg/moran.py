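"""Agent-based mutation-selection simulation with explicit mutation rate.

One update: pick an individual X uniformly; with probability ``mu`` replace
its strategy by one drawn uniformly from the full strategy set (including
the current one); otherwise pick a role model Y != X uniformly and let X
imitate Y with the Fermi probability based on their composition-dependent
average payoffs (precomputed pairwise payoff matrix, self excluded).

The simulator exploits two exact shortcuts so that the long horizons
needed to compare against the rare-mutation analytics stay affordable:
runs of mutation-free updates in monomorphic states are skipped by sampling
their geometric length, and while exactly two strategies are present the
update reduces to a one-dimensional birth-death step with precomputed
transition probabilities.  Both are distributionally identical to stepping
the naive update loop one tick at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitness import PairwisePayoffMatrix

__all__ = ["SimConfig", "SimResult", "simulate"]


@dataclass(frozen=True)
class SimConfig:
    Z: int
    mu: float
    beta: float
    steps: int
    burn_in: int = 0
    seed: int | None = None
    record_every: int | None = None  # defaults to one generation (Z updates)

    def __post_init__(self):
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (self.steps > self.burn_in >= 0):
            raise ValueError("steps must exceed burn_in >= 0")
        if self.Z < 2:
            raise ValueError("Z must be at least 2")


@dataclass(frozen=True)
class SimResult:
    strategies: tuple
    frequencies: np.ndarray  # time-averaged frequencies after burn-in
    generations: np.ndarray  # recorded update counts / Z
    trajectory: np.ndarray  # recorded composition snapshots (fractions)
    polymorphic_fraction: float  # fraction of post-burn-in time non-monomorphic

    def frequency_of(self, strategy) -> float:
        return float(self.frequencies[list(self.strategies).index(tuple(strategy))])


def _pair_tables(paym: np.ndarray, a: int, b: int, Z: int, mu: float, beta: float):
    """Birth-death transition probabilities for a two-strategy population.

    Returns ``(p_up, p_dn)`` indexed by the count ``i`` of strategy ``a``;
    each already includes the no-mutation factor ``1 - mu``.
    """
    i = np.arange(0, Z + 1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fA = ((i - 1) * paym[a, a] + (Z - i) * paym[a, b]) / (Z - 1)
        fB = (i * paym[b, a] + (Z - 1 - i) * paym[b, b]) / (Z - 1)
    d = np.clip(beta * (fA - fB), -700, 700)
    pick = (i / Z) * ((Z - i) / (Z - 1))
    p_up = (1 - mu) * pick * (1.0 / (1.0 + np.exp(-d)))
    p_dn = (1 - mu) * pick * (1.0 / (1.0 + np.exp(d)))
    p_up[[0, Z]] = p_dn[[0, Z]] = 0.0
    return p_up, p_dn


def simulate(config: SimConfig, pay: PairwisePayoffMatrix) -> SimResult:
    """Run the mutation-selection process; see the module docstring."""
    rng = np.random.default_rng(config.seed)
    strategies = pay.strategies
    n = len(strategies)
    Z, mu, beta = config.Z, config.mu, config.beta
    paym = pay.pay

    counts = np.zeros(n, dtype=np.int64)
    counts[rng.integers(n)] = Z  # start monomorphic at a random strategy

    record_every = config.record_every or Z
    snaps: list[np.ndarray] = []
    snap_times: list[int] = []
    occupancy = np.zeros(n, dtype=float)  # update-weighted counts after burn-in
    poly_time = 0

    def accumulate(t0: int, t1: int, cts: np.ndarray):
        """credit occupancy (in individual-updates) for updates in (t0, t1]."""
        nonlocal poly_time
        lo = max(t0, config.burn_in)
        if t1 > lo:
            span = t1 - lo
            occupancy[:] += span * cts
            if (cts > 0).sum() > 1:
                poly_time += span

    t = 0
    next_snap = record_every
    while t < config.steps:
        present = np.nonzero(counts)[0]
        if len(present) == 2:
            # dominant case in the rare-mutation regime: exact birth-death
            a, b = (int(x) for x in present)
            t, next_snap, poly = _run_pair(
                config, rng, paym, counts, a, b, t, next_snap,
                occupancy, snaps, snap_times,
            )
            poly_time += poly
            continue
        if len(present) == 1 and mu > 0.0:
            # monomorphic: nothing changes until the next mutation
            gap = rng.geometric(mu)  # updates until (and including) mutation
            t_new = min(t + gap, config.steps)
            accumulate(t, t_new, counts)
            while next_snap <= t_new:
                snaps.append(counts / Z)
                snap_times.append(next_snap)
                next_snap += record_every
            t = t_new
            if t >= config.steps:
                break
            # the mutation itself: mutate a random individual
            counts[present[0]] -= 1
            counts[rng.integers(n)] += 1
            continue
        if len(present) == 1 and mu == 0.0:
            # absorbed: fill remaining time
            accumulate(t, config.steps, counts)
            while next_snap <= config.steps:
                snaps.append(counts / Z)
                snap_times.append(next_snap)
                next_snap += record_every
            t = config.steps
            break
        # three or more strategies present: one generic update
        accumulate(t, t + 1, counts.copy())
        t += 1
        if mu > 0.0 and rng.random() < mu:
            x = _pick_individual(rng, counts, Z)
            counts[x] -= 1
            counts[rng.integers(n)] += 1
        else:
            x = _pick_individual(rng, counts, Z)
            y = _pick_individual(rng, counts, Z, exclude_one_of=x)
            if x != y:
                fx = _comp_fitness(paym, counts, x, Z)
                fy = _comp_fitness(paym, counts, y, Z)
                arg = np.clip(beta * (fy - fx), -700.0, 700.0)
                if rng.random() < 1.0 / (1.0 + np.exp(-arg)):
                    counts[x] -= 1
                    counts[y] += 1
        if t >= next_snap:
            snaps.append(counts / Z)
            snap_times.append(next_snap)
            next_snap += record_every

    horizon = config.steps - config.burn_in
    freqs = occupancy / (horizon * Z)
    return SimResult(
        strategies=strategies,
        frequencies=freqs,
        generations=np.asarray(snap_times, dtype=float) / Z,
        trajectory=np.asarray(snaps) if snaps else np.zeros((0, n)),
        polymorphic_fraction=poly_time / horizon if horizon else 0.0,
    )


def _run_pair(config, rng, paym, counts, a, b, t, next_snap, occupancy, snaps, snap_times):
    """Simulate updates while exactly strategies ``a`` and ``b`` are present.

    Mutates ``counts`` in place; returns ``(t, next_snap, poly_updates)``.
    Exits on absorption, on a mutation that changes the support, or at the
    horizon.  Distribution of the trajectory is identical to the generic
    per-update loop.
    """
    Z, mu = config.Z, config.mu
    n = occupancy.shape[0]
    p_up, p_dn = _pair_tables(paym, a, b, Z, mu, config.beta)
    p_event = mu + p_up + p_dn  # per-update probability the state changes
    i = int(counts[a])
    sum_i = 0  # post-burn-in occupancy accumulators for this phase
    n_upd = 0
    record_every = config.record_every or Z
    geometric, random = rng.geometric, rng.random
    while t < config.steps and 0 < i < Z:
        # sojourn in composition i: geometric number of updates to the next
        # state-changing event (mutation or accepted imitation)
        gap = geometric(p_event[i])
        t_ev = min(t + gap, config.steps)
        lo = t if t >= config.burn_in else config.burn_in
        if t_ev > lo:
            span = t_ev - lo
            sum_i += span * i
            n_upd += span
        while next_snap <= t_ev:
            comp = np.zeros(n)
            comp[a], comp[b] = i / Z, (Z - i) / Z
            snaps.append(comp)
            snap_times.append(next_snap)
            next_snap += record_every
        t = t_ev
        if t >= config.steps:
            break
        u = random() * p_event[i]
        if u < mu:
            # mutation: a uniformly chosen individual redraws its strategy
            x = a if random() * Z < i else b
            new = int(rng.integers(n))
            if new == x:
                continue
            if new not in (a, b):
                counts[a], counts[b] = i, Z - i
                counts[x] -= 1
                counts[new] += 1
                occupancy[a] += sum_i
                occupancy[b] += n_upd * Z - sum_i
                return t, next_snap, n_upd  # support changed: generic loop
            i += 1 if new == a else -1
        elif u < mu + p_up[i]:
            i += 1
        else:
            i -= 1
    counts[a], counts[b] = i, Z - i
    occupancy[a] += sum_i
    occupancy[b] += n_upd * Z - sum_i
    return t, next_snap, n_upd


def _pick_individual(rng, counts, Z, exclude_one_of: int | None = None):
    """Index of the strategy of a uniformly drawn individual."""
    if exclude_one_of is None:
        r = rng.integers(Z)
    else:
        r = rng.integers(Z - 1)
    c = 0
    for idx, k in enumerate(counts):
        k = int(k)
        if exclude_one_of == idx:
            k -= 1
        c += k
        if r < c:
            return idx
    return len(counts) - 1


def _comp_fitness(pay: np.ndarray, counts: np.ndarray, idx: int, Z: int) -> float:
    """Average payoff of an ``idx``-player against everyone else."""
    w = counts.astype(float).copy()
    w[idx] -= 1.0
    return float(pay[idx] @ w) / (Z - 1)
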