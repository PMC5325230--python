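"""Synthetic evolving-feature information tables.

The generator emulates a protein-annotation setting: a latent binary
concept (does the object perform the function?), feature columns released
in cumulative groups, and label noise.  Each categorical feature has one
*marker* level per class plus background levels: with probability equal to
its informativeness the drawn value is the marker of the object's true
class, otherwise it comes from a shared background distribution.  The two
effective class-conditional multinomials therefore overlap by exactly
1 − informativeness: informativeness is the probability that a value is
concept-revealing rather than noise.  Numeric features follow the same
mixture with class-shifted Gaussians and are meant to pass through the
standard discretizer.

The worked 8-protein example table (three attributes arriving at t0, t1,
t2 and a Yes/No "Function" decision) ships as :func:`table1_fixture`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .table import ConfigurationError, InformationTable

__all__ = [
    "FeatureSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_table",
    "table1_fixture",
    "evolving_benchmark",
]

POSITIVE_LABEL = "Yes"
NEGATIVE_LABEL = "No"


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column: informativeness in [0,1] plus its value domain."""

    name: str
    informativeness: float
    kind: str = "categorical"  # or "numeric"
    cardinality: int = 3  # categorical: 2 marker levels + (cardinality-2) background

    def __post_init__(self) -> None:
        if not 0.0 <= self.informativeness <= 1.0:
            raise ConfigurationError("informativeness must lie in [0, 1]")
        if self.kind not in ("categorical", "numeric"):
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical" and self.cardinality < 3:
            raise ConfigurationError(
                "categorical features need cardinality >= 3 "
                "(two marker levels plus background)"
            )


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated table."""

    n_objects: int
    concept_prevalence: float
    feature_groups: tuple[tuple[FeatureSpec, ...], ...]
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ConfigurationError("n_objects must be positive")
        if not 0.0 < self.concept_prevalence < 1.0:
            raise ConfigurationError("concept_prevalence must lie in (0, 1)")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ConfigurationError("label_noise must lie in [0, 1]")
        if not self.feature_groups or any(not g for g in self.feature_groups):
            raise ConfigurationError("feature_groups must be nonempty groups")

    @property
    def schedule(self) -> list[list[str]]:
        return [[f.name for f in group] for group in self.feature_groups]


@dataclass(frozen=True)
class GroundTruth:
    """Pre-noise labels and the generating spec, for recovery tests."""

    true_concept: pd.Series  # boolean, indexed by object id
    spec: SyntheticSpec


def _draw_feature(rng: np.random.Generator, feat: FeatureSpec,
                  is_concept: np.ndarray) -> np.ndarray:
    n = len(is_concept)
    informative = rng.random(n) < feat.informativeness
    if feat.kind == "numeric":
        background = rng.normal(0.0, 1.5, size=n)
        signal = rng.normal(np.where(is_concept, 1.0, -1.0), 0.5, size=n)
        return np.where(informative, signal, background)
    n_background = feat.cardinality - 2
    background = np.array([f"b{i}" for i in rng.integers(0, n_background, size=n)])
    signal = np.where(is_concept, "pos", "neg")
    return np.where(informative, signal, background)


def generate_table(spec: SyntheticSpec) -> tuple[InformationTable, GroundTruth]:
    """Draw one table; deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    ids = pd.Index([f"S{i + 1}" for i in range(spec.n_objects)])
    true = rng.random(spec.n_objects) < spec.concept_prevalence
    flip = rng.random(spec.n_objects) < spec.label_noise
    observed = np.where(true ^ flip, POSITIVE_LABEL, NEGATIVE_LABEL)
    columns = {}
    for group in spec.feature_groups:
        for feat in group:
            columns[feat.name] = _draw_feature(rng, feat, true)
    data = pd.DataFrame(columns, index=ids)
    decision = pd.Series(observed, index=ids, name="Function")
    table = InformationTable(data, decision, "Function")
    return table, GroundTruth(pd.Series(true, index=ids), spec)


def table1_fixture() -> InformationTable:
    """The 8-protein worked example: three attributes arriving over time.

    Object ids O1..O8 so that region sets printed for the example match.
    """
    rows = [
        ("O1", "Mitochondria", 0, 0, "Yes"),
        ("O2", "Mitochondria", 0, 1, "No"),
        ("O3", "CytoPlasm", 1, 0, "Yes"),
        ("O4", "CytoPlasm", 2, 0, "No"),
        ("O5", "CytoPlasm", 2, 0, "No"),
        ("O6", "CytoPlasm", 0, 0, "Yes"),
        ("O7", "CytoPlasm", 2, 1, "No"),
        ("O8", "Mitochondria", 0, 1, "No"),
    ]
    frame = pd.DataFrame(
        rows,
        columns=["id", "Localization", "Interacting proteins", "No. of Domains",
                 "Function"],
    ).set_index("id")
    frame.index.name = None
    decision = frame.pop("Function")
    return InformationTable(frame, decision, "Function")


def evolving_benchmark(
    n_objects: int = 1000,
    informativeness: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    concept_prevalence: float = 0.4,
    label_noise: float = 0.1,
    seed: int = 7,
    cardinality: int = 3,
) -> tuple[InformationTable, list[list[str]], GroundTruth]:
    """Default evolving-feature benchmark: one feature per cumulative group.

    Later groups are more informative, emulating biological information
    that matures over time; a warning (not an error) flags a non-monotone
    informativeness sequence.  Returns (table, schedule, ground truth).
    """
    if len(informativeness) < 2:
        raise ConfigurationError("the benchmark needs at least two feature groups")
    if any(b < a for a, b in zip(informativeness, informativeness[1:])):
        warnings.warn("informativeness sequence is not non-decreasing", stacklevel=2)
    groups = tuple(
        (FeatureSpec(f"F{i + 1}", m, cardinality=cardinality),)
        for i, m in enumerate(informativeness)
    )
    spec = SyntheticSpec(n_objects, concept_prevalence, groups, label_noise, seed)
    table, truth = generate_table(spec)
    return table, spec.schedule, truth
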