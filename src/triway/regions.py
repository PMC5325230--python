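"""Pawlak and (α,β)-probabilistic three-way regions.

The positive region collects objects whose equivalence class is (probably)
inside the concept, the negative region those (probably) outside, and the
boundary the undecidable rest:

    POS(α,β)(C) = {x : P(C|[x]) >= α}
    NEG(α,β)(C) = {x : P(C|[x]) <= β}
    BND(α,β)(C) = {x : β < P(C|[x]) < α}

with 0 <= β < α <= 1.  The Pawlak model is the special case (α,β) = (1,0):
a block is accepted only when fully inside C and rejected only when fully
outside.  Region membership maps one-to-one onto the three-way decisions
accept / reject / defer.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Real

from .table import (
    Concept,
    ConfigurationError,
    Partition,
    ValidationError,
    conditional_probability,
)

__all__ = [
    "PAWLAK",
    "REGION_DECISIONS",
    "ThresholdPair",
    "TriPartition",
    "pawlak_regions",
    "probabilistic_regions",
    "decide",
]

#: Marker used in :class:`TriPartition.thresholds` for the Pawlak model.
PAWLAK = "pawlak"

#: Comparison slack for float thresholds (exact values compare exactly).
_TOL = 1e-12

REGION_DECISIONS = {"POS": "accept", "NEG": "reject", "BND": "defer"}


@dataclass(frozen=True)
class ThresholdPair:
    """An (α, β) pair with the region-disjointness constraint 0 <= β < α <= 1."""

    alpha: Real
    beta: Real

    def __post_init__(self) -> None:
        if not (0 <= self.beta < self.alpha <= 1):
            raise ConfigurationError(
                f"thresholds must satisfy 0 <= beta < alpha <= 1, got "
                f"(alpha={self.alpha}, beta={self.beta})"
            )

    def as_floats(self) -> tuple[float, float]:
        return float(self.alpha), float(self.beta)


@dataclass(frozen=True)
class TriPartition:
    """POS/NEG/BND regions of one concept at one threshold setting.

    ``pos`` is the lower approximation; ``pos | bnd`` the upper one.
    ``attribute_set`` records which attributes induced the partition (used
    by the iterative-refinement algorithm to validate feature growth).
    """

    pos: frozenset
    neg: frozenset
    bnd: frozenset
    thresholds: object  # ThresholdPair or the PAWLAK marker
    concept_label: object
    attribute_set: tuple = ()

    def __post_init__(self) -> None:
        if self.pos & self.neg or self.pos & self.bnd or self.neg & self.bnd:
            raise ValidationError("regions overlap")

    @property
    def universe(self) -> frozenset:
        return self.pos | self.neg | self.bnd

    @property
    def lower_approximation(self) -> frozenset:
        return self.pos

    @property
    def upper_approximation(self) -> frozenset:
        return self.pos | self.bnd

    def region_of(self, object_id) -> str:
        if object_id in self.pos:
            return "POS"
        if object_id in self.neg:
            return "NEG"
        if object_id in self.bnd:
            return "BND"
        raise KeyError(f"object {object_id!r} not in universe")


def _check_universe(partition: Partition, concept: Concept) -> None:
    if partition.universe != concept.universe:
        raise ValidationError("partition and concept cover different universes")


def pawlak_regions(partition: Partition, concept: Concept) -> TriPartition:
    """Classical trisection: block ⊆ C -> POS, block ∩ C = ∅ -> NEG, else BND."""
    _check_universe(partition, concept)
    pos, neg, bnd = set(), set(), set()
    for block in partition.blocks:
        inter = block.member_set & concept.members
        if len(inter) == len(block):
            pos.update(block.members)
        elif not inter:
            neg.update(block.members)
        else:
            bnd.update(block.members)
    return TriPartition(frozenset(pos), frozenset(neg), frozenset(bnd),
                        PAWLAK, concept.label, partition.attribute_set)


def probabilistic_regions(
    partition: Partition, concept: Concept, thresholds: ThresholdPair
) -> TriPartition:
    """(α,β)-trisection by comparing each block's P(C|[x]) to the thresholds.

    Ties at a threshold go to the decisive region (>= α accepts, <= β
    rejects), exactly as the defining inequalities read.  Exact rational
    probabilities are compared with a 1e-12 slack against float thresholds.
    """
    if not isinstance(thresholds, ThresholdPair):
        raise ConfigurationError("thresholds must be a ThresholdPair")
    _check_universe(partition, concept)
    alpha, beta = thresholds.alpha, thresholds.beta
    exact = isinstance(alpha, (int, Fraction)) and isinstance(beta, (int, Fraction))
    pos, neg, bnd = set(), set(), set()
    for block in partition.blocks:
        p = conditional_probability(block, concept)
        if exact:
            in_pos, in_neg = p >= alpha, p <= beta
        else:
            pf = float(p)
            in_pos = pf >= float(alpha) - _TOL
            in_neg = pf <= float(beta) + _TOL
        if in_pos:
            pos.update(block.members)
        elif in_neg:
            neg.update(block.members)
        else:
            bnd.update(block.members)
    return TriPartition(frozenset(pos), frozenset(neg), frozenset(bnd),
                        thresholds, concept.label, partition.attribute_set)


def decide(tri: TriPartition, object_id) -> str:
    """accept / reject / defer according to the region holding ``object_id``."""
    return REGION_DECISIONS[tri.region_of(object_id)]
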