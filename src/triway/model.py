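"""Model/Results front end for three-way decision analysis.

:class:`ThreeWayModel` wraps an information table, a target concept and a
threshold-learning method; ``fit()`` returns a :class:`ThreeWayResults`
carrying the learned thresholds, the trisection, its uncertainty
decomposition and accuracy/generality, with a ``summary()`` table.
:func:`fit_evolving` runs the iterative boundary-refinement algorithm over
a feature-arrival schedule and returns per-stage results.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .table import (
    InformationTable,
    compute_partition,
    concept_from_decision,
    discretize,
    restrict_attributes,
)
from .regions import PAWLAK, TriPartition, decide
from .itrs import region_uncertainty
from .evaluate import MODELS, accuracy, compute_regions, generality, learn_thresholds
from .refine import EvolutionTrace, QualityConfig, evolve

__all__ = ["ThreeWayModel", "ThreeWayResults", "EvolutionResults", "fit_evolving"]


class ThreeWayModel:
    """Three-way (accept / reject / defer) classifier for one binary concept.

    Parameters
    ----------
    table : InformationTable
        The training data.
    concept_label : object
        Decision value defining the concept C (one-vs-rest).
    method : str
        One of ``pawlak, itrs_e, itrs_g, gtrs_e, gtrs_g, gtrs_ag``.
    attrs : sequence of str, optional
        Attribute subset to partition on (default: all attributes).
    discretization : str
        ``none`` (default), ``equal_frequency`` or ``equal_width``.
    bins : int
        Bin count for numeric attributes when discretizing.
    **options
        Passed to the threshold learner (e.g. ``steps=``, ``initial=``,
        ``max_iterations=`` for GTRS; ``search=`` for ITRS).
    """

    def __init__(self, table: InformationTable, concept_label, method: str = "pawlak",
                 attrs=None, discretization: str = "none", bins: int = 5, **options):
        if method not in MODELS:
            raise ValueError(f"unknown method {method!r}; valid: {MODELS}")
        self.table = table
        self.concept_label = concept_label
        self.method = method
        self.attrs = tuple(attrs) if attrs is not None else table.attributes
        self.discretization = discretization
        self.bins = bins
        self.options = options

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, decision_col: str, concept_label,
                       method: str = "pawlak", **kwargs) -> "ThreeWayModel":
        """Build directly from a DataFrame whose index holds the object ids."""
        decision = frame[decision_col]
        data = frame.drop(columns=[decision_col])
        table = InformationTable(data, decision, decision_col)
        return cls(table, concept_label, method, **kwargs)

    def fit(self) -> "ThreeWayResults":
        work = restrict_attributes(self.table, self.attrs)
        work = discretize(work, policy=self.discretization, bins=self.bins)
        partition = compute_partition(work, work.attributes)
        concept = concept_from_decision(work, self.concept_label)
        thresholds = learn_thresholds(partition, concept, self.method, **self.options)
        tri = compute_regions(partition, concept, thresholds)
        return ThreeWayResults(self, partition, concept, thresholds, tri)


@dataclass
class ThreeWayResults:
    """Fitted trisection with its diagnostics."""

    model: ThreeWayModel
    partition: object
    concept: object
    thresholds: object
    tripartition: TriPartition

    @property
    def alpha(self):
        return 1.0 if self.thresholds == PAWLAK else self.thresholds.alpha

    @property
    def beta(self):
        return 0.0 if self.thresholds == PAWLAK else self.thresholds.beta

    @property
    def accuracy(self):
        return accuracy(self.tripartition, self.concept)

    @property
    def generality(self) -> float:
        return generality(self.tripartition, self.concept)

    def uncertainty(self, measure: str = "shannon"):
        return region_uncertainty(self.tripartition, self.concept, measure)

    def decide(self, object_id) -> str:
        return decide(self.tripartition, object_id)

    def region_frame(self) -> pd.DataFrame:
        tri = self.tripartition
        rows = [(obj, tri.region_of(obj), decide(tri, obj))
                for obj in sorted(tri.universe, key=str)]
        return pd.DataFrame(rows, columns=["object", "region", "decision"]).set_index("object")

    def summary(self) -> str:
        tri = self.tripartition
        rep = self.uncertainty("shannon")
        acc = self.accuracy
        lines = [
            "Three-Way Decision Results",
            "=" * 44,
            f"method:            {self.model.method}",
            f"concept:           {self.model.table.decision_name} = {self.model.concept_label}",
            f"attributes:        {', '.join(self.model.attrs)}",
            f"objects:           {len(tri.universe)}",
            f"(alpha, beta):     ({self.alpha:.4g}, {self.beta:.4g})"
            + ("  [pawlak]" if self.thresholds == PAWLAK else ""),
            "-" * 44,
            f"|POS| (accept):    {len(tri.pos)}",
            f"|NEG| (reject):    {len(tri.neg)}",
            f"|BND| (defer):     {len(tri.bnd)}",
            f"accuracy:          {'undefined' if acc is None else f'{acc:.4f}'}",
            f"generality:        {self.generality:.4f}",
            f"uncertainty Delta: {rep.total:.4f} bits (shannon)",
            "=" * 44,
        ]
        return "\n".join(lines)


@dataclass
class EvolutionResults:
    """Per-stage trisections from the iterative refinement algorithm."""

    trace: EvolutionTrace
    concept_label: object
    table: InformationTable

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for stage in self.trace:
            tri = stage.tri
            concept = concept_from_decision(
                restrict_attributes(self.table, stage.feature_set), self.concept_label
            )
            acc = accuracy(tri, concept)
            rows.append({
                "feature_set": "+".join(stage.feature_set),
                "branch": stage.branch,
                "pos": len(tri.pos),
                "neg": len(tri.neg),
                "bnd": len(tri.bnd),
                "accuracy": float("nan") if acc is None else acc,
                "generality": generality(tri, concept),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return self.summary_frame().to_string(index=False)


def fit_evolving(
    table: InformationTable,
    concept_label,
    schedule,
    method: str = "pawlak",
    quality: QualityConfig = QualityConfig(),
    *,
    force_full: bool = False,
    **options,
) -> EvolutionResults:
    """Run the evolving-feature algorithm; returns stagewise results."""
    trace = evolve(table, concept_label, schedule, method, quality,
                   force_full=force_full, **options)
    return EvolutionResults(trace, concept_label, table)
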