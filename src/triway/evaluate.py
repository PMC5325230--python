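"""Accuracy/generality metrics, held-out classification and cross-validation.

Accuracy is the fraction of correct decisions among the objects that
received an immediate (accept/reject) decision:

    Accuracy(α,β) = |(POS ∩ C) ∪ (NEG ∩ C^c)| / |POS ∪ NEG|

and generality is the fraction of the universe that was decided at all:

    Generality(α,β) = |POS ∪ NEG| / |U|.

Held-out objects are classified by matching their (discretized) attribute
signature to a training block and inheriting that block's region decision;
an unseen signature defers — deferment is exactly the semantics of
"insufficient evidence".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .table import (
    Concept,
    ConfigurationError,
    InformationTable,
    ValidationError,
    compute_partition,
    concept_from_decision,
    discretize,
)
from .regions import PAWLAK, REGION_DECISIONS, TriPartition, pawlak_regions, probabilistic_regions
from .itrs import itrs_learn_thresholds
from .gtrs import gtrs_learn_thresholds

__all__ = [
    "MODELS",
    "EvaluationReport",
    "CrossValidationReport",
    "accuracy",
    "generality",
    "learn_thresholds",
    "compute_regions",
    "FittedThreeWay",
    "classify_holdout",
    "cross_validate",
]

MODELS = ("pawlak", "itrs_e", "itrs_g", "gtrs_e", "gtrs_g", "gtrs_ag")


def accuracy(tri: TriPartition, concept: Concept) -> float | None:
    """Correct fraction among decided objects; ``None`` when nothing is decided."""
    decided = tri.pos | tri.neg
    if not decided:
        return None
    correct = len(tri.pos & concept.members) + len(tri.neg & concept.complement)
    return correct / len(decided)


def generality(tri: TriPartition, concept: Concept) -> float:
    """Decided fraction of the universe."""
    n = len(tri.universe)
    if n == 0:
        raise ValidationError("generality undefined on an empty universe")
    return len(tri.pos | tri.neg) / n


# --------------------------------------------------------------------------
# model dispatch
# --------------------------------------------------------------------------


def learn_thresholds(partition, concept, model: str, **options):
    """Thresholds for a named model: the PAWLAK marker, or a learned pair."""
    if model == "pawlak":
        return PAWLAK
    if model in ("itrs_e", "itrs_g"):
        measure = "shannon" if model == "itrs_e" else "gini"
        return itrs_learn_thresholds(partition, concept, measure=measure,
                                     **options).thresholds
    if model in ("gtrs_e", "gtrs_g", "gtrs_ag"):
        return gtrs_learn_thresholds(partition, concept, variant=model,
                                     **options).thresholds
    raise ConfigurationError(f"unknown model {model!r}; valid models: {MODELS}")


def compute_regions(partition, concept, thresholds) -> TriPartition:
    """Trisect with either the PAWLAK marker or an (α,β) pair."""
    if thresholds == PAWLAK:
        return pawlak_regions(partition, concept)
    return probabilistic_regions(partition, concept, thresholds)


# --------------------------------------------------------------------------
# held-out classification
# --------------------------------------------------------------------------


@dataclass
class FittedThreeWay:
    """A trained trisection: discretization edges + signature -> decision map."""

    attributes: tuple[str, ...]
    thresholds: object
    tri: TriPartition
    signature_decisions: Mapping[tuple, str]
    bin_edges: Mapping[str, np.ndarray]
    policy: str
    bins: int

    def classify(self, record: Mapping) -> str:
        """Decision for one attribute-value record; unseen signatures defer."""
        missing = [a for a in self.attributes if a not in record]
        if missing:
            raise ConfigurationError(f"record lacks attribute(s) {missing}")
        sig = []
        for a in self.attributes:
            v = record[a]
            if a in self.bin_edges:
                from .table import _apply_edges

                v = _apply_edges(np.array([float(v)]), self.bin_edges[a])[0]
            sig.append(v)
        return self.signature_decisions.get(tuple(sig), "defer")


def fit_three_way(
    train: InformationTable,
    concept_label,
    model: str,
    *,
    policy: str = "equal_frequency",
    bins: int = 5,
    **options,
) -> FittedThreeWay:
    """Discretize, learn thresholds and trisect on a training table."""
    disc = discretize(train, policy=policy, bins=bins)
    partition = compute_partition(disc, disc.attributes)
    concept = concept_from_decision(disc, concept_label)
    thresholds = learn_thresholds(partition, concept, model, **options)
    tri = compute_regions(partition, concept, thresholds)
    sig_map = {}
    for block in partition.blocks:
        region = tri.region_of(block.members[0])
        sig_map[block.signature] = REGION_DECISIONS[region]
    return FittedThreeWay(disc.attributes, thresholds, tri, sig_map,
                          disc.meta.get("bin_edges", {}), policy, bins)


def classify_holdout(
    train_table: InformationTable,
    model: str,
    test_objects: Sequence[Mapping] | pd.DataFrame,
    *,
    concept_label=None,
    policy: str = "equal_frequency",
    bins: int = 5,
    **options,
) -> list[str]:
    """Per-object accept/reject/defer decisions for unseen records."""
    if concept_label is None:
        raise ConfigurationError("concept_label is required")
    fitted = fit_three_way(train_table, concept_label, model,
                           policy=policy, bins=bins, **options)
    if isinstance(test_objects, pd.DataFrame):
        test_objects = test_objects.to_dict(orient="records")
    return [fitted.classify(rec) for rec in test_objects]


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationReport:
    model: str
    feature_set: str
    accuracy: float | None
    generality: float
    region_sizes: tuple[int, int, int]


@dataclass(frozen=True)
class CrossValidationReport:
    model: str
    k: int
    seed: int
    fold_accuracy: tuple  # per-fold accuracy (None when no test object decided)
    fold_generality: tuple[float, ...]
    undefined_accuracy_folds: int = 0

    @property
    def mean_accuracy(self) -> float | None:
        vals = [a for a in self.fold_accuracy if a is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def std_accuracy(self) -> float | None:
        vals = [a for a in self.fold_accuracy if a is not None]
        return float(np.std(vals)) if vals else None

    @property
    def mean_generality(self) -> float:
        return float(np.mean(self.fold_generality))

    @property
    def std_generality(self) -> float:
        return float(np.std(self.fold_generality))


def cross_validate(
    table: InformationTable,
    concept_label,
    model: str,
    k: int = 10,
    seed: int = 0,
    *,
    policy: str = "equal_frequency",
    bins: int = 5,
    **options,
) -> CrossValidationReport:
    """Stratified k-fold evaluation of one model on one binary concept.

    Folds are stratified on concept membership from the stated seed.  Test
    accuracy counts only decided test objects (mirroring the immediate-
    region denominator); test generality is the decided fraction.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if table.n_objects < k:
        raise ConfigurationError("fewer objects than folds")
    y = (table.decision == concept_label).to_numpy().astype(int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = np.array(table.object_ids, dtype=object)
    fold_acc, fold_gen = [], []
    undefined = 0
    frame = table.to_frame()
    for train_idx, test_idx in splitter.split(ids, y):
        train = table.restrict_objects(ids[train_idx])
        fitted = fit_three_way(train, concept_label, model,
                               policy=policy, bins=bins, **options)
        test_rows = frame.iloc[test_idx]
        in_concept = (test_rows[table.decision_name] == concept_label).to_numpy()
        decisions = [
            fitted.classify(rec)
            for rec in test_rows[list(table.attributes)].to_dict(orient="records")
        ]
        decided = [(d, c) for d, c in zip(decisions, in_concept) if d != "defer"]
        fold_gen.append(len(decided) / len(test_idx))
        if decided:
            correct = sum(
                1 for d, c in decided if (d == "accept") == bool(c)
            )
            fold_acc.append(correct / len(decided))
        else:
            fold_acc.append(None)
            undefined += 1
    return CrossValidationReport(model, k, seed, tuple(fold_acc), tuple(fold_gen),
                                 undefined)


def top_frequent_labels(table: InformationTable, n: int) -> list:
    """Most frequent decision labels, frequency-desc then lexicographic."""
    counts = table.decision.value_counts()
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [label for label, _ in ordered[:n]]
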