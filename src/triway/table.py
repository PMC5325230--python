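"""Information tables, equivalence-class partitions and concepts.

An information table ``S = (U, At, {V_a}, {I_a})`` stores a finite universe
of objects ``U``, a finite attribute set ``At`` and, for each attribute, a
total information function assigning every object a value.  A *concept*
``C`` is the subset of objects carrying a target decision label; the
equivalence relation induced by an attribute subset ``A`` groups objects
that agree on every attribute in ``A`` into blocks (equivalence classes),
and the conditional probability ``P(C | [x]) = |[x] ∩ C| / |[x]|`` of each
block is the quantity every threshold-based trisection in this package is
built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "InformationTable",
    "Concept",
    "Block",
    "Partition",
    "read_information_table",
    "write_regions",
    "read_regions",
    "discretize",
    "restrict_attributes",
    "compute_partition",
    "concept_from_decision",
    "conditional_probability",
]


class ConfigurationError(ValueError):
    """Raised when a caller-supplied option or schema is invalid."""


class ValidationError(ValueError):
    """Raised when data violates an information-table invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InformationTable:
    """Objects x attributes with a total information function and a decision.

    Parameters
    ----------
    data : pandas.DataFrame
        Index = object ids (unique), columns = condition attributes.
    decision : pandas.Series
        Decision label per object, aligned with ``data.index``.
    decision_name : str
        Name of the decision column (not a member of the attributes).
    meta : dict
        Free-form metadata; the discretizer records its bin edges here so
        train-fitted edges can be re-applied to held-out objects.
    """

    data: pd.DataFrame
    decision: pd.Series
    decision_name: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate object ids: {dupes}")
        if self.decision_name in self.data.columns:
            raise ConfigurationError(
                f"decision column {self.decision_name!r} overlaps the attributes"
            )
        if not self.data.index.equals(self.decision.index):
            raise ValidationError("decision index does not match object ids")
        na = self.data.isna()
        if na.to_numpy().any():
            rows = self.data.index[na.any(axis=1)]
            cols = self.data.columns[na.any(axis=0)]
            raise ValidationError(
                f"missing cell(s) at rows {list(rows)}, columns {list(cols)}"
            )
        if self.decision.isna().any():
            rows = self.decision.index[self.decision.isna()].tolist()
            raise ValidationError(f"missing decision label for objects {rows}")

    # -- basic accessors ----------------------------------------------------

    @property
    def object_ids(self) -> tuple:
        return tuple(self.data.index)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_objects(self) -> int:
        return len(self.data)

    def value(self, obj, attribute: str):
        return self.data.at[obj, attribute]

    def restrict_objects(self, objects: Iterable) -> "InformationTable":
        """Sub-table over a subset of the universe (attribute set unchanged)."""
        keep = [o for o in self.data.index if o in set(objects)]
        return InformationTable(
            self.data.loc[keep], self.decision.loc[keep], self.decision_name, dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.data.copy()
        frame[self.decision_name] = self.decision
        return frame


@dataclass(frozen=True)
class Concept:
    """A decision class ``C`` (objects carrying ``label``) within a universe."""

    label: object
    members: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        if not self.members <= self.universe:
            raise ValidationError("concept members are not a subset of the universe")

    @property
    def complement(self) -> frozenset:
        return self.universe - self.members


@dataclass(frozen=True)
class Block:
    """An equivalence class ``[x]``: objects sharing one attribute signature."""

    members: tuple
    signature: tuple

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("empty block")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


@dataclass(frozen=True)
class Partition:
    """The quotient ``U/E_A`` for an attribute subset ``A``."""

    blocks: tuple[Block, ...]
    attribute_set: tuple[str, ...]

    @property
    def universe(self) -> frozenset:
        return frozenset(o for b in self.blocks for o in b.members)

    def block_of(self, obj) -> Block:
        for b in self.blocks:
            if obj in b.member_set:
                return b
        raise KeyError(f"object {obj!r} not in partition universe")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_information_table(
    path,
    decision_col: str,
    *,
    id_col: str | None = None,
    delimiter: str | None = None,
) -> InformationTable:
    """Load a delimited information table (header row required).

    Columns parse as numeric when every entry parses; otherwise they stay
    categorical.  ``id_col=None`` numbers objects O1, O2, ... in row order.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True)
    raw = raw.replace("", np.nan)
    if decision_col not in raw.columns:
        raise ConfigurationError(
            f"decision column {decision_col!r} not found; columns are {list(raw.columns)}"
        )
    if id_col is not None:
        if id_col not in raw.columns:
            raise ConfigurationError(f"id column {id_col!r} not found")
        raw = raw.set_index(id_col)
        raw.index.name = None
        if raw.index.hasnans:
            raise ValidationError("missing object id")
    else:
        raw.index = pd.Index([f"O{i + 1}" for i in range(len(raw))])
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].tolist()
        raise ValidationError(f"duplicate object ids: {dupes}")
    na = raw.isna()
    if na.to_numpy().any():
        row = raw.index[na.any(axis=1)][0]
        col = raw.columns[na.loc[row].to_numpy().nonzero()[0][0]]
        raise ValidationError(f"missing cell at row {row!r}, column {col!r}")
    parsed = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        parsed[col] = numeric if not numeric.isna().any() else raw[col]
    frame = pd.DataFrame(parsed, index=raw.index)
    decision = frame.pop(decision_col)
    return InformationTable(frame, decision, decision_col)


def write_regions(tri, path) -> None:
    """Write one row per object: id, region in {POS,NEG,BND}, decision."""
    from .regions import REGION_DECISIONS  # local import to avoid a cycle

    rows = []
    for region, members in (("POS", tri.pos), ("NEG", tri.neg), ("BND", tri.bnd)):
        for obj in members:
            rows.append((obj, region, REGION_DECISIONS[region]))
    rows.sort(key=lambda r: str(r[0]))
    frame = pd.DataFrame(rows, columns=["object", "region", "decision"])
    frame.to_csv(path, sep="\t", index=False)


def read_regions(path) -> pd.DataFrame:
    """Read a region-assignment TSV back (round trip of :func:`write_regions`)."""
    return pd.read_csv(path, sep="\t", dtype=str).set_index("object")


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------


def _fit_edges(values: np.ndarray, policy: str, bins: int) -> np.ndarray:
    """Interior cut points (len <= bins-1) for one numeric column."""
    if policy == "equal_width":
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            return np.array([])
        return np.linspace(lo, hi, bins + 1)[1:-1]
    if policy == "equal_frequency":
        qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
        return np.unique(qs)
    raise ConfigurationError(f"unknown discretization policy {policy!r}")


def _apply_edges(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # held-out values beyond the fitted range clamp into the extreme bins
    idx = np.searchsorted(edges, values, side="left")
    return np.array([f"b{i + 1}" for i in idx])


def discretize(
    table: InformationTable,
    policy: str = "equal_frequency",
    bins: int = 5,
    *,
    edges: Mapping[str, np.ndarray] | None = None,
) -> InformationTable:
    """Replace numeric attributes by bin labels; categoricals pass through.

    Fitted interior cut points are recorded in ``meta['bin_edges']`` so the
    same edges can be applied to held-out objects (pass them back via
    ``edges=``).  ``policy='none'`` is the identity.
    """
    if policy == "none":
        return table
    if bins < 1:
        raise ConfigurationError("bins must be >= 1")
    fitted: dict[str, np.ndarray] = {}
    new_cols = {}
    for col in table.attributes:
        series = table.data[col]
        if not pd.api.types.is_numeric_dtype(series):
            new_cols[col] = series
            continue
        vals = series.to_numpy(dtype=float)
        cuts = np.asarray(edges[col]) if edges is not None else _fit_edges(vals, policy, bins)
        fitted[col] = cuts
        new_cols[col] = pd.Series(_apply_edges(vals, cuts), index=series.index)
    meta = dict(table.meta)
    meta["bin_edges"] = fitted
    meta["discretization"] = {"policy": policy, "bins": bins}
    return InformationTable(pd.DataFrame(new_cols, index=table.data.index),
                            table.decision, table.decision_name, meta)


# --------------------------------------------------------------------------
# partitions and concepts
# --------------------------------------------------------------------------


def restrict_attributes(table: InformationTable, attrs: Sequence[str]) -> InformationTable:
    """Keep only ``attrs`` (order preserved); objects and decision unchanged."""
    unknown = [a for a in attrs if a not in table.attributes]
    if unknown:
        raise ConfigurationError(f"unknown attribute(s): {unknown}")
    keep = [a for a in table.attributes if a in set(attrs)]
    return InformationTable(table.data[keep], table.decision, table.decision_name,
                            dict(table.meta))


def _signature_key(signature: tuple) -> tuple:
    return tuple((type(v).__name__, str(v)) for v in signature)


def compute_partition(table: InformationTable, attrs: Sequence[str]) -> Partition:
    """Equivalence classes under agreement on every attribute in ``attrs``.

    ``attrs = ()`` yields the single block ``U``.  Blocks are ordered
    lexicographically by signature so the result is independent of row order.
    """
    attrs = tuple(attrs)
    unknown = [a for a in attrs if a not in table.attributes]
    if unknown:
        raise ConfigurationError(f"unknown attribute(s): {unknown}")
    if not attrs:
        members = tuple(sorted(table.object_ids, key=str))
        if not members:
            return Partition((), attrs)
        return Partition((Block(members, ()),), attrs)
    groups: dict[tuple, list] = {}
    sub = table.data[list(attrs)]
    for obj, row in zip(sub.index, sub.itertuples(index=False, name=None)):
        groups.setdefault(row, []).append(obj)
    blocks = [
        Block(tuple(sorted(members, key=str)), sig)
        for sig, members in groups.items()
    ]
    blocks.sort(key=lambda b: _signature_key(b.signature))
    return Partition(tuple(blocks), attrs)


def concept_from_decision(table: InformationTable, label) -> Concept:
    """The concept ``C`` = objects whose decision equals ``label``."""
    members = frozenset(table.decision.index[table.decision == label])
    if not members:
        import warnings

        warnings.warn(f"decision label {label!r} does not occur; concept is empty",
                      stacklevel=2)
    return Concept(label, members, frozenset(table.object_ids))


def conditional_probability(block: Block, concept: Concept) -> Fraction:
    """``P(C | [x]) = |[x] ∩ C| / |[x]|`` as an exact rational."""
    if not block.members:
        raise ValidationError("conditional probability undefined for an empty block")
    return Fraction(len(block.member_set & concept.members), len(block))
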