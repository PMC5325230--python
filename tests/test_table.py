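"""Information-table loading, partitioning and concept extraction."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_random_table
from triway.table import (
    Block,
    ConfigurationError,
    InformationTable,
    ValidationError,
    compute_partition,
    concept_from_decision,
    conditional_probability,
    discretize,
    read_information_table,
    read_regions,
    restrict_attributes,
    write_regions,
)
from triway.regions import pawlak_regions


# -- I/O --------------------------------------------------------------------


def test_read_minimal_file(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,color,size,Function\nA,red,2,Yes\nB,blue,3,No\n")
    t = read_information_table(p, "Function", id_col="id")
    assert t.n_objects == 2
    assert t.attributes == ("color", "size")
    assert t.decision.loc["A"] == "Yes"
    assert t.data["size"].dtype.kind in "if"  # fully numeric column parses


def test_round_trip_identity(table1, tmp_path):
    p = tmp_path / "t1.csv"
    table1.to_frame().to_csv(p, index_label="id")
    again = read_information_table(p, "Function", id_col="id")
    assert again.attributes == table1.attributes
    assert again.object_ids == table1.object_ids
    pd.testing.assert_frame_equal(again.to_frame(), table1.to_frame())


def test_missing_cell_cites_row(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("id,a,b,d\nr1,1,2,Yes\nr2,,2,No\n")
    with pytest.raises(ValidationError, match="r2"):
        read_information_table(p, "d", id_col="id")


def test_missing_decision_column_is_config_error(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,a\nr1,1\n")
    with pytest.raises(ConfigurationError):
        read_information_table(p, "nope", id_col="id")


def test_duplicate_object_id_rejected(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,a,d\nr1,1,Y\nr1,2,N\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_information_table(p, "d", id_col="id")


def test_write_regions_table2_t2_counts(table1, concept_yes, partition_t2, tmp_path):
    tri = pawlak_regions(partition_t2, concept_yes)
    out = tmp_path / "r.tsv"
    write_regions(tri, out)
    frame = read_regions(out)
    assert len(frame) == 8
    counts = frame["decision"].value_counts()
    assert counts.get("accept") == 3
    assert counts.get("reject") == 5
    assert "defer" not in counts
    # round trip reproduces the assignment
    for obj in tri.universe:
        assert frame.loc[obj, "region"] == tri.region_of(obj)


def test_write_regions_empty_universe(tmp_path):
    from triway.regions import TriPartition

    tri = TriPartition(frozenset(), frozenset(), frozenset(), "pawlak", "Yes")
    out = tmp_path / "empty.tsv"
    write_regions(tri, out)
    assert out.read_text().splitlines() == ["object\tregion\tdecision"]


# -- discretization ---------------------------------------------------------


@pytest.mark.parametrize(
    "values,policy,bins,expected",
    [
        ([1, 2, 3, 4, 5, 6], "equal_frequency", 2, ["b1", "b1", "b1", "b2", "b2", "b2"]),
        ([0, 0, 10], "equal_width", 2, ["b1", "b1", "b2"]),
    ],
)
def test_discretize_bin_assignment(values, policy, bins, expected):
    ids = [f"o{i}" for i in range(len(values))]
    t = InformationTable(
        pd.DataFrame({"f": values}, index=ids),
        pd.Series(["Y"] * len(values), index=ids),
        "d",
    )
    out = discretize(t, policy=policy, bins=bins)
    assert list(out.data["f"]) == expected
    assert "f" in out.meta["bin_edges"]


def test_discretize_heldout_value_clamps_to_top_bin():
    ids = list("abcdef")
    t = InformationTable(
        pd.DataFrame({"f": [1, 2, 3, 4, 5, 6]}, index=ids),
        pd.Series(["Y"] * 6, index=ids), "d")
    out = discretize(t, policy="equal_frequency", bins=3)
    edges = out.meta["bin_edges"]["f"]
    from triway.table import _apply_edges

    assert _apply_edges(np.array([999.0]), edges)[0] == sorted(set(out.data["f"]))[-1]


def test_discretize_constant_column_single_bin():
    ids = list("abc")
    t = InformationTable(pd.DataFrame({"f": [2, 2, 2]}, index=ids),
                         pd.Series(["Y"] * 3, index=ids), "d")
    out = discretize(t, policy="equal_frequency", bins=4)
    assert set(out.data["f"]) == {"b1"}


def test_discretize_invalid_bins():
    ids = list("ab")
    t = InformationTable(pd.DataFrame({"f": [1, 2]}, index=ids),
                         pd.Series(["Y", "N"], index=ids), "d")
    with pytest.raises(ConfigurationError):
        discretize(t, bins=0)


def test_discretize_categorical_passthrough(table1):
    out = discretize(table1, policy="equal_frequency", bins=2)
    assert list(out.data["Localization"]) == list(table1.data["Localization"])


# -- restriction, partitioning, concepts ------------------------------------


def test_restrict_to_single_attribute(table1):
    t = restrict_attributes(table1, ["Localization"])
    assert t.attributes == ("Localization",)
    assert t.n_objects == 8


def test_restrict_identity_and_empty(table1):
    assert restrict_attributes(table1, table1.attributes).attributes == table1.attributes
    empty = restrict_attributes(table1, [])
    assert empty.attributes == ()
    part = compute_partition(empty, ())
    assert len(part.blocks) == 1 and len(part.blocks[0]) == 8


def test_restrict_unknown_attribute(table1):
    with pytest.raises(ConfigurationError):
        restrict_attributes(table1, ["nope"])


def test_partition_on_localization_matches_worked_example(partition_t0):
    sets = {frozenset(b.members) for b in partition_t0.blocks}
    assert sets == {frozenset({"O1", "O2", "O8"}),
                    frozenset({"O3", "O4", "O5", "O6", "O7"})}


def test_partition_on_two_attributes(partition_t1):
    sets = {frozenset(b.members) for b in partition_t1.blocks}
    assert sets == {
        frozenset({"O1", "O2", "O8"}),
        frozenset({"O3"}),
        frozenset({"O4", "O5", "O7"}),
        frozenset({"O6"}),
    }


def test_all_distinct_rows_give_singletons():
    ids = list("abc")
    t = InformationTable(pd.DataFrame({"f": [1, 2, 3]}, index=ids),
                         pd.Series(["Y", "N", "Y"], index=ids), "d")
    part = compute_partition(t, ("f",))
    assert all(len(b) == 1 for b in part.blocks)


def test_concept_members(table1):
    c = concept_from_decision(table1, "Yes")
    assert c.members == frozenset({"O1", "O3", "O6"})
    assert c.complement == frozenset({"O2", "O4", "O5", "O7", "O8"})


def test_unused_label_gives_empty_concept_with_warning(table1):
    with pytest.warns(UserWarning):
        c = concept_from_decision(table1, "Maybe")
    assert c.members == frozenset()


def test_conditional_probability_examples(table1, concept_yes, partition_t1):
    block = next(b for b in partition_t1.blocks if "O1" in b.members)
    assert conditional_probability(block, concept_yes) == Fraction(1, 3)
    pure = next(b for b in partition_t1.blocks if b.members == ("O3",))
    assert conditional_probability(pure, concept_yes) == 1
    empty_overlap = next(b for b in partition_t1.blocks if "O4" in b.members)
    assert conditional_probability(empty_overlap, concept_yes) == 0


# -- properties -------------------------------------------------------------


@given(st.integers(0, 500))
def test_partition_blocks_disjoint_and_cover(seed):
    rng = np.random.default_rng(seed)
    t = make_random_table(rng)
    for k in range(len(t.attributes) + 1):
        part = compute_partition(t, t.attributes[:k])
        members = [o for b in part.blocks for o in b.members]
        assert len(members) == len(set(members)) == t.n_objects


@given(st.integers(0, 500))
def test_partition_refinement_monotonicity(seed):
    rng = np.random.default_rng(seed)
    t = make_random_table(rng, n_attrs=3)
    coarse = compute_partition(t, t.attributes[:1])
    fine = compute_partition(t, t.attributes)
    coarse_sets = [b.member_set for b in coarse.blocks]
    for b in fine.blocks:
        assert any(b.member_set <= cs for cs in coarse_sets)


@given(st.integers(0, 200))
def test_partition_invariant_to_row_order(seed):
    rng = np.random.default_rng(seed)
    t = make_random_table(rng)
    perm = rng.permutation(t.n_objects)
    shuffled = InformationTable(t.data.iloc[perm], t.decision.iloc[perm], "d")
    p1 = compute_partition(t, t.attributes)
    p2 = compute_partition(shuffled, t.attributes)
    assert [b.members for b in p1.blocks] == [b.members for b in p2.blocks]


@given(st.integers(0, 500))
def test_concept_mass_conservation(seed):
    rng = np.random.default_rng(seed)
    t = make_random_table(rng)
    c = concept_from_decision(t, "Y")
    part = compute_partition(t, t.attributes)
    mass = sum(len(b) * conditional_probability(b, c) for b in part.blocks)
    assert mass == len(c.members)


def test_empty_block_probability_is_error(concept_yes):
    with pytest.raises(Exception):
        b = Block((), ())  # construction itself must fail
        conditional_probability(b, concept_yes)
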