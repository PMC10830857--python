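# Methods

## Game representation

A centipede game is stored as an explicit per-step payoff table plus a
pass-through pair, generated either from the incremental rule (resource
`g^(l-1) M`, taker share `s`, final growth favouring Player 1) or supplied
directly for constant-sum and custom variants.  All payoffs are kept as
`fractions.Fraction`: the reasoning kernels branch on payoff comparisons,
and exact arithmetic guarantees that ties (which the conditional and
inertia processes resolve differently) are decided by the game, never by
floating-point rounding.  Decimal inputs such as `M = 0.5` are converted
through their string form, so the canonical presets are exact.

Thresholds live on the scale `1 .. L+1`, with `L + 1` meaning
always-Postpone.  A threshold maps to a seat's action as the earliest
role-feasible step at or after it; thresholds beyond the seat's last step
mean never taking.  With `L = 4`, Player 1 can therefore act at steps 1 and
3 or never, Player 2 at 2 and 4 or never.

## The reasoning recursion

A `(t, k)` strategy is evaluated per seat by a chain of `k` kernel
applications.  Level 0 is the prior `t`; at level `j` an imagined reasoner
— seated so that the final level carries the focal player's actual role,
with seats alternating below — responds to the (possibly error-displaced)
threshold produced at level `j - 1`.

The payoff comparison inside the conditional and inertia kernels is
resolved by playing the game out: candidate thresholds (`co - 1`, i.e. the
intention to act one step before the co-player, versus holding `co`) are
mapped to the reasoner's feasible action step, the believed co-player
threshold to the co-player's step, the game ends at the earlier of the two,
and the reasoner receives her seat's payoff at that ending.  This is the
one design point the verbal description of the process leaves open; the
outcome-based comparison is adopted here because it is the only reading
under which the worked recursion example, the four-threshold error support
and both gradient-of-selection transition points (see below) come out at
their published values simultaneously.  Two consequences are worth noting:
a Player-1 reasoner facing `co = 3` sees a *tie* (both candidate thresholds
map to her step 3), which the conditional kernel resolves toward the
earlier threshold and the inertia kernel toward its fallback; and a
Player-1 reasoner facing an always-postponer keeps postponing, because the
pass-through pays her more than her last feasible take.

The inertia fallback is tracked per reasoning agent: agents occupy
alternating levels, so the fallback at level `j` is the (realized) output
of level `j - 2`, bottoming out at the prior `t`.  Cognitive errors
displace each level's kernel output by one step with probability `ε/2` per
direction, are applied at every level including the last, never at level 0
(a belief, not a computation), and are clamped to `[1, L + 1]` with the
clamped mass merged at the boundary.  The exact threshold distribution is
obtained by dynamic programming over the joint state (last output,
second-to-last output), which is linear in `k` and quadratic in `L`; the
sampler realizes the same branching process and is validated against the
enumeration by goodness-of-fit tests.

## Fitness

`f_{X,Y}` is the expected payoff of `X` in a pairwise interaction played
once in each seat and averaged.  The exact engine integrates over the
product of the two players' per-seat action distributions; the Monte-Carlo
engine (default `R = 5 × 10⁴` repetitions, fresh threshold samples for both
seats of both players per repetition) is retained for fidelity runs and
agrees with the exact expectation within sampling error.  An optional
linear reasoning cost subtracts `c·k` after seat averaging; `c = 0`
recovers the baseline exactly.  The exact engine is the package default
because it removes estimator noise from downstream fixation probabilities
at no modelling cost.

## Evolutionary dynamics

Composition-dependent payoffs exclude self-interaction (denominator
`Z - 1`).  Fixation probabilities use the standard birth-death closed form
with `λ_i = e^{-β Δf(i)}` under the Fermi rule, accumulated in log space
with clamping at ±700 so that `β = 10, Z = 500` cannot overflow; they are
property-tested against direct absorbing-chain linear solves for `Z ≤ 12`.
The rare-mutation chain `Γ` is built from all ordered fixation
probabilities, optionally down-weighting transitions that change the
reasoning depth (modelling beliefs as more labile than cognitive capacity),
and its stationary vector is obtained by a direct linear solve of
`σ(Γ - I) = 0` with a normalization row — exact and reproducible for the
set sizes involved (25 and 49) — falling back to the dominant left
eigenvector if the solve is singular.

The gradient of selection uses
`T±(i) = (i/Z)((Z-i)/Z) · (1 + e^{∓βΔf})^{-1}`; on the discrete grid a sign
change of `G` from − to + (as the focal count grows) is reported as a
repeller at the midpoint, + to − as an attractor, and the boundaries are
classified by the flow direction adjacent to them.  Evolutionary
robustness demands every mutant's fixation probability be strictly below
`1/Z` (relative margin `10⁻¹²`); equalities are reported as neutral edges.

The agent-based simulator implements the textbook update (uniform focal
individual; mutation with probability `μ` to a uniformly drawn strategy
including the current one; otherwise Fermi imitation of a random role
model) with two distribution-preserving accelerations: geometric skipping
of mutation-free spans in monomorphic states, and, while exactly two
strategies are present, geometric sojourn sampling of the embedded
birth-death jump chain.  Identical seeds give identical trajectories.
Occupancies are accumulated update-by-update (pre-update composition),
so time-averaged frequencies match the naive loop exactly in distribution.

## Calibration

The model's ending-step distribution is the σ-weighted mixture, over
monomorphic states, of the ending-step law of two independent
same-strategy individuals (one per seat, thresholds drawn independently);
both roles are pooled into a single distribution.  `fit` grid-searches
`(β, ε)`, reporting both a least-squares and a Kullback–Leibler distance
(least squares is the default; the verbal description of the fitting step
names no metric, and both are returned on the full surface for
inspection).  Synthetic fixtures are multinomial draws from the model at a
known `(β₀, ε₀)`, used for parameter-recovery experiments; empirical data
enter as plain `step,count` CSV tables supplied by the user (the published
behavioral tables are referenced by citation, not embedded).

A caveat the recovery experiments make explicit: the ending-step
distribution changes slowly along a ridge in the `(β, ε)` plane (total
variation ≈ 0.04 between β-values 0.05 apart near the calibrated point),
so 200-game samples identify the pair only up to a few grid cells; exact
recovery holds for noiseless inputs, and the recovery error shrinks with
the sample size.

## Study conditions and problem sizes

Defaults mirror the headline analysis: four-step incremental game
(`M = 0.5`, doubling, 80% split), inertia RP, `Z = 500`, `β = 0.31`,
`ε = 0.19`, full `(L+1)²` strategy set, `R = 5 × 10⁴` for Monte-Carlo
fitness.  The agent-based validation runs at `Z = 50`, `μ = 10⁻³` for
4 × 10⁸ updates (10% burn-in), chosen so that the sampling error of the
time-averaged frequencies sits comfortably below the 0.05 total-variation
band used in the comparison.  The recovery experiment uses a grid of nine
β-values (0.11–0.51, step 0.05) and nine ε-values (0.07–0.31, step 0.03)
containing the generating point, 50 replicates of 200 games each.

## Known limitations

* The verbal specification of the reasoning process leaves micro-choices
  open (payoff-comparison seat conventions, fallback bookkeeping, error
  placement).  The conventions above reproduce the worked example, the
  error-branching support and the two-strategy gradient transitions
  exactly; they do not, however, make the optimistic `(5,3)` equilibrium
  uninvadable at very high selection intensity — under exact fitness a
  depth-0 mutant such as `(3,0)` invades the `(5,3)` resident above the
  neutral rate at `ε = 0.19` — and a grid search over all possible action
  distributions for `(5,3)` shows no distribution can both match the
  gradient transitions and resist those mutants.  The corresponding
  acceptance test is kept faithful to the claim and documents the failure
  rather than weakening it.
* Populations are well-mixed; no structure, assortment, belief updating
  across repeated games, or heterogeneous reasoning processes.
* The constant-sum game ships as an empty template; users supply the
  experimental table.  Tests use a synthetic constant-sum schedule.
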