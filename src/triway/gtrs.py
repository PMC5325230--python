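"""Game-theoretic threshold learning (GTRS).

Two players tug at the thresholds of a probabilistic trisection: one is
allowed to decrease α, the other to increase β, both starting from the
Pawlak point (1, 0).  Each strategy profile is scored by a pair of payoffs
evaluated at the profile-modified thresholds, and the players settle on a
pure-strategy Nash equilibrium — a profile where no unilateral deviation
helps.  Repeating the game from the equilibrium thresholds walks (α,β)
toward a trade-off configuration.

Three variants differ only in the payoff pair:

* ``gtrs_e`` / ``gtrs_g`` — player *I* (immediate regions) earns one minus
  the normalized uncertainty of POS ∪ NEG, player *D* (deferred region)
  earns one minus the boundary uncertainty; Shannon or Gini.
* ``gtrs_ag`` — the accuracy and generality of the trisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .table import Concept, ConfigurationError, Partition
from .regions import ThresholdPair, probabilistic_regions
from .itrs import region_uncertainty

__all__ = [
    "Strategy",
    "Game",
    "EquilibriumResult",
    "GtrsResult",
    "uncertainty_payoffs",
    "accuracy_generality_payoffs",
    "build_game",
    "find_pure_nash",
    "gtrs_learn_thresholds",
    "GTRS_VARIANTS",
]

GTRS_VARIANTS = ("gtrs_e", "gtrs_g", "gtrs_ag")

_FEASIBLE_GAP = 1e-9


def uncertainty_payoffs(
    partition: Partition,
    concept: Concept,
    thresholds: ThresholdPair,
    measure: str = "shannon",
) -> tuple[float, float]:
    """Payoffs (u_I, u_D) of the immediate and deferred decision regions.

    u_I = 1 − (Δ_P + Δ_N) / (P(POS) + P(NEG))  (0 when POS ∪ NEG is empty);
    u_D = 1 − δ_B                               (1 when BND is empty).
    """
    tri = probabilistic_regions(partition, concept, thresholds)
    rep = region_uncertainty(tri, concept, measure)
    pp, pn, _ = rep.region_probs
    wp, wn, _ = rep.weighted
    immediate = pp + pn
    u_i = 0.0 if immediate <= 0 else 1.0 - (wp + wn) / immediate
    u_d = 1.0 - rep.delta_b  # delta_b is 0 for an empty boundary
    return (u_i, u_d)


def accuracy_generality_payoffs(
    partition: Partition, concept: Concept, thresholds: ThresholdPair
) -> tuple[float, float]:
    """Payoffs (u_A, u_G): the accuracy and generality of the trisection.

    When no object receives an immediate decision the accuracy is
    undefined; the pair degrades to (0, 0).
    """
    from .evaluate import accuracy, generality

    tri = probabilistic_regions(partition, concept, thresholds)
    acc = accuracy(tri, concept)
    if acc is None:
        return (0.0, 0.0)
    return (acc, generality(tri, concept))


@dataclass(frozen=True)
class Strategy:
    """A threshold perturbation available to one player."""

    label: str
    dalpha: float = 0.0
    dbeta: float = 0.0

    @property
    def movement(self) -> float:
        return abs(self.dalpha) + abs(self.dbeta)


NO_CHANGE = Strategy("stay")


@dataclass(frozen=True)
class Game:
    """Two-player normal-form game over threshold perturbations."""

    players: tuple[str, str]
    strategies: tuple[tuple[Strategy, ...], tuple[Strategy, ...]]
    payoffs: tuple[tuple[tuple[float, float], ...], ...]  # [i][j] -> (u1, u2)
    base_thresholds: ThresholdPair
    variant: str = "custom"

    def profile_thresholds(self, i: int, j: int) -> tuple[float, float]:
        s1, s2 = self.strategies[0][i], self.strategies[1][j]
        a = self.base_thresholds.alpha + s1.dalpha + s2.dalpha
        b = self.base_thresholds.beta + s1.dbeta + s2.dbeta
        return (a, b)

    def feasible(self, i: int, j: int) -> bool:
        a, b = self.profile_thresholds(i, j)
        return 0.0 <= b and b < a - _FEASIBLE_GAP and a <= 1.0 + 1e-12


@dataclass(frozen=True)
class EquilibriumResult:
    equilibria: tuple[tuple[int, int], ...]
    selected: tuple[int, int] | None
    resulting_thresholds: ThresholdPair | None
    no_pure_equilibrium: bool = False


def build_game(
    partition: Partition,
    concept: Concept,
    variant: str,
    base: ThresholdPair,
    steps: Sequence[float] = (0.05, 0.10),
    measure: str | None = None,
    payoff: Callable[..., tuple[float, float]] | None = None,
) -> Game:
    """Construct the perturbation game at ``base``.

    Player 1 may decrease α by any step (or stay); player 2 may increase β
    likewise.  Profiles whose resulting thresholds violate 0 <= β < α <= 1
    are infeasible and score −inf for both players.
    """
    if variant not in GTRS_VARIANTS and payoff is None:
        raise ConfigurationError(f"unknown GTRS variant {variant!r}")
    if not steps or any(s < 0 for s in steps):
        raise ConfigurationError("steps must be a nonempty list of nonnegative values")
    s1 = (NO_CHANGE,) + tuple(Strategy(f"alpha-{s:g}", dalpha=-s) for s in steps)
    s2 = (NO_CHANGE,) + tuple(Strategy(f"beta+{s:g}", dbeta=+s) for s in steps)
    if payoff is None:
        if variant == "gtrs_ag":
            payoff = accuracy_generality_payoffs
            players = ("accuracy", "generality")
        else:
            measure = measure or ("shannon" if variant == "gtrs_e" else "gini")
            payoff = lambda part, con, thr: uncertainty_payoffs(part, con, thr, measure)
            players = ("immediate", "deferred")
    else:
        players = ("player1", "player2")

    table = []
    for i, a_strat in enumerate(s1):
        row = []
        for j, b_strat in enumerate(s2):
            a = base.alpha + a_strat.dalpha
            b = base.beta + b_strat.dbeta
            if 0.0 <= b and b < a - _FEASIBLE_GAP and a <= 1.0 + 1e-12:
                row.append(payoff(partition, concept, ThresholdPair(min(a, 1.0), b)))
            else:
                row.append((-math.inf, -math.inf))
        table.append(tuple(row))
    return Game((players[0], players[1]), (s1, s2), tuple(table), base, variant)


def find_pure_nash(game: Game) -> EquilibriumResult:
    """Enumerate all pure-strategy Nash equilibria by direct best-response check.

    A profile (s1, s2) is an equilibrium when u1(s1,s2) >= u1(s1',s2) for
    every deviation s1' and symmetrically for player 2.  Among equilibria,
    the selected one maximizes the payoff sum, then minimizes total
    threshold movement, then comes first in lexicographic strategy order.
    """
    n1, n2 = len(game.strategies[0]), len(game.strategies[1])
    equilibria = []
    for i in range(n1):
        for j in range(n2):
            u1, u2 = game.payoffs[i][j]
            if any(game.payoffs[k][j][0] > u1 for k in range(n1)):
                continue
            if any(game.payoffs[i][l][1] > u2 for l in range(n2)):
                continue
            equilibria.append((i, j))
    if not equilibria:
        return EquilibriumResult((), None, None, no_pure_equilibrium=True)

    def rank(ij: tuple[int, int]):
        i, j = ij
        u1, u2 = game.payoffs[i][j]
        move = game.strategies[0][i].movement + game.strategies[1][j].movement
        return (-(u1 + u2), move, i, j)

    selected = min(equilibria, key=rank)
    a, b = game.profile_thresholds(*selected)
    thresholds = ThresholdPair(min(a, 1.0), b) if game.feasible(*selected) else None
    return EquilibriumResult(tuple(equilibria), selected, thresholds)


@dataclass(frozen=True)
class GtrsResult:
    thresholds: ThresholdPair
    iterations: int
    trace: tuple = field(default_factory=tuple)  # (thresholds, selected labels, payoffs)
    stop_reason: str = ""


def gtrs_learn_thresholds(
    partition: Partition,
    concept: Concept,
    variant: str = "gtrs_e",
    initial: ThresholdPair = ThresholdPair(1.0, 0.0),
    steps: Sequence[float] = (0.05, 0.10),
    max_iterations: int = 50,
    stop_epsilon: float = 1e-6,
    measure: str | None = None,
) -> GtrsResult:
    """Repeated-game threshold learning.

    Iterate: build the game at the current thresholds, solve for the
    selected pure equilibrium, apply its perturbation, repeat.  Stops when
    (a) the selected profile is (stay, stay) — or no pure equilibrium
    exists, which is treated the same way; (b) the selected payoff sum
    improves by less than ``stop_epsilon``; (c) the next thresholds would
    be infeasible; or (d) ``max_iterations`` is reached.  The returned
    thresholds always satisfy 0 <= β < α <= 1.
    """
    current = initial
    trace = []
    prev_sum = None
    reason = "max_iterations"
    it = 0
    for it in range(max_iterations):
        game = build_game(partition, concept, variant, current, steps, measure=measure)
        eq = find_pure_nash(game)
        if eq.no_pure_equilibrium or eq.selected is None:
            reason = "no_pure_equilibrium"
            break
        i, j = eq.selected
        payoffs = game.payoffs[i][j]
        labels = (game.strategies[0][i].label, game.strategies[1][j].label)
        trace.append((current, labels, payoffs))
        if labels == ("stay", "stay"):
            reason = "no_change_equilibrium"
            break
        cur_sum = payoffs[0] + payoffs[1]
        if prev_sum is not None and cur_sum - prev_sum < stop_epsilon:
            reason = "no_improvement"
            break
        if eq.resulting_thresholds is None:
            reason = "infeasible_move"
            break
        current = eq.resulting_thresholds
        prev_sum = cur_sum
    return GtrsResult(current, it + 1 if max_iterations else 0, tuple(trace), reason)
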