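"""Iterative boundary refinement with evolving features.

When a new feature arrives, the previously decided regions may already be
good enough to keep: if the precision of the positive region
(Q_P = P(C|POS)) and of the negative region (Q_N = P(C^c|NEG)) both clear
their quality floors c1, c2, only the deferred objects are re-trisected —
thresholds are re-learned on the reduced table whose universe is the old
boundary, and the new sub-regions are merged into the kept POS/NEG.
Otherwise the whole table is re-partitioned and re-trisected from scratch.
Under the boundary-only branch POS and NEG can only grow and BND can only
shrink, which is exactly the evolving-information phenomenon the deferment
option exists for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .table import (
    Concept,
    ConfigurationError,
    InformationTable,
    ValidationError,
    compute_partition,
    concept_from_decision,
    restrict_attributes,
)
from .regions import TriPartition
from .evaluate import compute_regions, learn_thresholds

__all__ = [
    "QualityConfig",
    "EvolutionStage",
    "EvolutionTrace",
    "region_quality",
    "refine_with_new_feature",
    "evolve",
]


@dataclass(frozen=True)
class QualityConfig:
    """Quality floors for keeping the decided regions.

    c1 and c2 bound the positive/negative region precisions from below.
    Meaningful floors lie in [0, 1]; values above 1 can never be met and
    therefore force the full-recompute branch on every stage.  An empty
    region has undefined precision, which fails any positive floor — an
    empty positive region carries no evidence of adequacy.
    """

    c1: float = 0.9
    c2: float = 0.9
    quality_measure: str = "precision"

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ConfigurationError("quality floors must be nonnegative")
        if self.quality_measure != "precision":
            raise ConfigurationError("only the 'precision' quality measure is provided")


def region_quality(tri: TriPartition, concept: Concept) -> tuple[float | None, float | None]:
    """(Q_P, Q_N) region precisions; ``None`` marks an undefined (empty) region."""
    qp = len(tri.pos & concept.members) / len(tri.pos) if tri.pos else None
    qn = len(tri.neg & concept.complement) / len(tri.neg) if tri.neg else None
    return qp, qn


def _meets(quality: float | None, floor: float) -> bool:
    if quality is None:
        return floor <= 0
    return quality >= floor


def refine_with_new_feature(
    table: InformationTable,
    prior: TriPartition,
    model: str,
    quality: QualityConfig = QualityConfig(),
    **model_options,
) -> TriPartition:
    """One step of the iterative algorithm on a table with >= 1 new feature.

    Quality branch: thresholds (α',β') are learned on the reduced table
    whose universe is the old boundary (region probabilities included), the
    boundary is re-trisected with them, and the kept POS/NEG absorb the new
    sub-regions.  Otherwise thresholds and regions are recomputed on the
    full table.
    """
    prior_attrs = set(prior.attribute_set)
    if not prior_attrs <= set(table.attributes):
        raise ConfigurationError("table lacks attributes of the prior trisection")
    if not set(table.attributes) - prior_attrs:
        raise ConfigurationError("table contains no new attribute")
    if prior.universe != frozenset(table.object_ids):
        raise ValidationError("prior trisection covers a different universe")
    concept = concept_from_decision(table, prior.concept_label)
    qp, qn = region_quality(prior, concept)
    if _meets(qp, quality.c1) and _meets(qn, quality.c2):
        if not prior.bnd:
            return prior
        reduced = table.restrict_objects(prior.bnd)
        partition = compute_partition(reduced, table.attributes)
        sub_concept = concept_from_decision(reduced, prior.concept_label)
        thresholds = learn_thresholds(partition, sub_concept, model, **model_options)
        sub = compute_regions(partition, sub_concept, thresholds)
        return TriPartition(
            prior.pos | sub.pos,
            prior.neg | sub.neg,
            sub.bnd,
            thresholds,
            prior.concept_label,
            tuple(table.attributes),
        )
    partition = compute_partition(table, table.attributes)
    thresholds = learn_thresholds(partition, concept, model, **model_options)
    return compute_regions(partition, concept, thresholds)


@dataclass(frozen=True)
class EvolutionStage:
    feature_set: tuple[str, ...]
    tri: TriPartition
    thresholds: object
    branch: str  # "initial", "boundary-only" or "full-recompute"


@dataclass(frozen=True)
class EvolutionTrace:
    stages: tuple[EvolutionStage, ...]

    def __iter__(self):
        return iter(self.stages)

    def __len__(self) -> int:
        return len(self.stages)


def evolve(
    table: InformationTable,
    concept_label,
    schedule: Sequence[Sequence[str]],
    model: str,
    quality: QualityConfig = QualityConfig(),
    *,
    force_full: bool = False,
    **model_options,
) -> EvolutionTrace:
    """Run the iterative algorithm over an ordered feature-arrival schedule.

    Stage 0 is computed from scratch on the first group; each later stage
    sees the cumulative attribute set and either refines the previous
    boundary or recomputes fully, per the quality test (``force_full=True``
    pins every stage to the full-recompute branch).
    """
    groups = [tuple(g) for g in schedule]
    if not groups:
        raise ConfigurationError("schedule must contain at least one feature group")
    seen: set[str] = set()
    for g in groups:
        if not g:
            raise ConfigurationError("empty feature group in schedule")
        overlap = seen & set(g)
        if overlap:
            raise ConfigurationError(f"schedule groups overlap on {sorted(overlap)}")
        seen |= set(g)
    unknown = seen - set(table.attributes)
    if unknown:
        raise ConfigurationError(f"schedule names unknown attribute(s) {sorted(unknown)}")

    stages = []
    cumulative: tuple[str, ...] = ()
    prior: TriPartition | None = None
    for stage_idx, group in enumerate(groups):
        cumulative = cumulative + group
        sub = restrict_attributes(table, cumulative)
        if stage_idx == 0 or force_full:
            partition = compute_partition(sub, sub.attributes)
            concept = concept_from_decision(sub, concept_label)
            thresholds = learn_thresholds(partition, concept, model, **model_options)
            tri = compute_regions(partition, concept, thresholds)
            branch = "initial" if stage_idx == 0 else "full-recompute"
        else:
            concept = concept_from_decision(sub, concept_label)
            qp, qn = region_quality(prior, concept)
            branch = ("boundary-only"
                      if _meets(qp, quality.c1) and _meets(qn, quality.c2)
                      else "full-recompute")
            tri = refine_with_new_feature(sub, prior, model, quality, **model_options)
        stages.append(EvolutionStage(cumulative, tri, tri.thresholds, branch))
        prior = tri
    return EvolutionTrace(tuple(stages))
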