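import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from island_assembly import (
    ColonistRecord,
    IslandDataset,
    ValidationError,
    dataset_from_trees,
    read_dataset,
    write_dataset,
)
from island_assembly.island_data import ParseError


class TestColonistRecord:
    def test_status_enum(self):
        with pytest.raises(ValidationError, match="unknown status"):
            ColonistRecord(label="x", status=6, lineage_class="c")

    def test_status1_has_no_times(self):
        rec = ColonistRecord(label="x", status=1, lineage_class="c")
        assert rec.colonisation_time is None
        assert rec.n_species == 0
        with pytest.raises(ValidationError):
            ColonistRecord(label="x", status=1, lineage_class="c", colonisation_time=1.0)

    def test_branching_older_than_colonisation_rejected(self):
        with pytest.raises(ValidationError, match="not younger"):
            ColonistRecord(
                label="x",
                status=4,
                lineage_class="c",
                colonisation_time=3.0,
                branching_times=(5.0,),
            )

    def test_branching_sorted_strictly_decreasing(self):
        with pytest.raises(ValidationError, match="sorted oldest first"):
            ColonistRecord(
                label="x",
                status=4,
                lineage_class="c",
                colonisation_time=3.0,
                branching_times=(1.0, 2.0),
            )
        with pytest.raises(ValidationError, match="strictly decreasing"):
            ColonistRecord(
                label="x",
                status=4,
                lineage_class="c",
                colonisation_time=3.0,
                branching_times=(1.0, 1.0),
            )

    def test_statuses_2_3_carry_no_branching(self):
        with pytest.raises(ValidationError, match="no branching times"):
            ColonistRecord(
                label="x",
                status=3,
                lineage_class="c",
                colonisation_time=3.0,
                branching_times=(1.0,),
            )

    def test_max_age_tied_to_status2(self):
        with pytest.raises(ValidationError, match="max_age"):
            ColonistRecord(
                label="x", status=3, lineage_class="c", colonisation_time=1.0, max_age=True
            )
        rec = ColonistRecord(
            label="x", status=2, lineage_class="c", colonisation_time=1.0, max_age=True
        )
        assert rec.max_age

    def test_negative_missing_rejected(self):
        with pytest.raises(ValidationError, match="n_missing"):
            ColonistRecord(
                label="x", status=3, lineage_class="c", colonisation_time=1.0, n_missing=-1
            )

    def test_species_counts(self):
        rec = ColonistRecord(
            label="x",
            status=5,
            lineage_class="c",
            colonisation_time=3.0,
            branching_times=(2.0, 1.0),
            n_missing=2,
        )
        assert rec.n_in_phylogeny == 3
        assert rec.n_species == 6  # 3 in tree + 2 missing + re-immigrant


class TestIslandDataset:
    def test_eight_colonist_shape(self, eight_colonist_dataset):
        ds = eight_colonist_dataset
        assert len(ds.colonists) == 8
        assert ds.island_age == 4.0
        assert ds.M == 1000
        assert ds.total_species() == 16

    def test_empty_dataset_valid(self):
        ds = IslandDataset(island_age=4.0, M=10, class_fractions={"c": 1.0})
        assert ds.colonists == ()
        assert ds.total_species() == 0

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            IslandDataset(island_age=4.0, M=10, class_fractions={"a": 0.6, "b": 0.6})

    def test_unknown_class_rejected(self):
        rec = ColonistRecord(label="x", status=3, lineage_class="zzz", colonisation_time=1.0)
        with pytest.raises(ValidationError, match="unknown lineage class"):
            IslandDataset(island_age=4.0, M=10, class_fractions={"c": 1.0}, colonists=(rec,))

    def test_class_share_cap(self):
        recs = tuple(
            ColonistRecord(label=f"r{i}", status=3, lineage_class="a", colonisation_time=1.0)
            for i in range(3)
        )
        with pytest.raises(ValidationError, match="exceed the class share"):
            IslandDataset(
                island_age=4.0,
                M=10,
                class_fractions={"a": 0.2, "b": 0.8},
                colonists=recs,
            )

    def test_colonisation_beyond_island_age_rejected(self):
        rec = ColonistRecord(label="x", status=3, lineage_class="c", colonisation_time=5.0)
        with pytest.raises(ValidationError, match="exceeds island age"):
            IslandDataset(island_age=4.0, M=10, class_fractions={"c": 1.0}, colonists=(rec,))

    def test_duplicate_labels_rejected(self):
        recs = tuple(
            ColonistRecord(label="dup", status=3, lineage_class="c", colonisation_time=t)
            for t in (1.0, 2.0)
        )
        with pytest.raises(ValidationError, match="duplicate"):
            IslandDataset(island_age=4.0, M=10, class_fractions={"c": 1.0}, colonists=recs)


class TestReadWrite:
    @pytest.mark.parametrize("fmt", ["json", "tsv"])
    def test_round_trip_fixture(self, eight_colonist_dataset, tmp_path, fmt):
        path = tmp_path / f"ds.{fmt}"
        write_dataset(eight_colonist_dataset, path)
        assert read_dataset(path) == eight_colonist_dataset

    @pytest.mark.parametrize("fmt", ["json", "tsv"])
    def test_round_trip_empty(self, tmp_path, fmt):
        ds = IslandDataset(island_age=2.5, M=7, class_fractions={"c": 1.0})
        path = tmp_path / f"empty.{fmt}"
        write_dataset(ds, path)
        assert read_dataset(path) == ds

    def test_round_trip_preserves_max_age(self, tmp_path):
        rec = ColonistRecord(
            label="ub", status=2, lineage_class="c", colonisation_time=2.0, max_age=True
        )
        ds = IslandDataset(island_age=4.0, M=5, class_fractions={"c": 1.0}, colonists=(rec,))
        for fmt in ("json", "tsv"):
            path = tmp_path / f"ds.{fmt}"
            write_dataset(ds, path)
            back = read_dataset(path)
            assert back.colonists[0].max_age is True
            assert back == ds

    def test_malformed_json(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ParseError):
            read_dataset(p)

    def test_invariant_violation_names_record(self, tmp_path):
        p = tmp_path / "bad2.json"
        p.write_text(
            """
            {"island_age": 4.0, "M": 10, "class_fractions": {"c": 1.0},
             "colonists": [{"label": "broken", "status": 4, "lineage_class": "c",
                            "colonisation_time": 3.0, "branching_times": [5.0]}]}
            """
        )
        with pytest.raises(ValidationError, match="broken"):
            read_dataset(p)

    def test_tsv_missing_header(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("label\tstatus\n")
        with pytest.raises(ParseError):
            read_dataset(p)


_label = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyz_", min_size=1, max_size=8
)


@st.composite
def _records(draw, lineage_class: str, island_age: float):
    status = draw(st.sampled_from([1, 2, 3, 4, 5]))
    label = draw(_label)
    if status == 1:
        return ColonistRecord(label=label, status=1, lineage_class=lineage_class)
    col = draw(st.floats(0.05, island_age, allow_nan=False, allow_infinity=False))
    n_missing = draw(st.integers(0, 3))
    if status in (2, 3):
        return ColonistRecord(
            label=label,
            status=status,
            lineage_class=lineage_class,
            colonisation_time=col,
            max_age=(status == 2),
            n_missing=n_missing,
        )
    n_branch = draw(st.integers(0, 4))
    bts = sorted(
        draw(
            st.lists(
                st.floats(0.01, col * 0.95, allow_nan=False),
                min_size=n_branch,
                max_size=n_branch,
                unique=True,
            )
        ),
        reverse=True,
    )
    return ColonistRecord(
        label=label,
        status=status,
        lineage_class=lineage_class,
        colonisation_time=col,
        branching_times=tuple(bts),
        n_missing=n_missing,
    )


@st.composite
def _datasets(draw):
    age = draw(st.floats(1.0, 10.0, allow_nan=False))
    records = draw(st.lists(_records("c", age), max_size=5, unique_by=lambda r: r.label))
    return IslandDataset(
        island_age=age,
        M=max(10, len(records) * 2),
        class_fractions={"c": 1.0},
        colonists=tuple(records),
    )


class TestRoundTripProperty:
    @settings(max_examples=40, deadline=None)
    @given(ds=_datasets(), fmt=st.sampled_from(["json", "tsv"]))
    def test_round_trip_identity(self, ds, fmt, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / f"ds.{fmt}"
        write_dataset(ds, path)
        assert read_dataset(path) == ds


class TestFromTrees:
    def _build(self, tmp_path, newick, island, conspecific=(), name="t.nwk"):
        p = tmp_path / name
        p.write_text(newick + "\n")
        return dataset_from_trees(
            [p],
            {str(p): island},
            island_age=10.0,
            M=100,
            class_fractions={"c": 1.0},
            conspecific=conspecific,
        )

    def test_three_taxon_endemic_pair(self, tmp_path):
        ds = self._build(
            tmp_path, "((islandA:1,islandB:1):2,mainland:3);", ["islandA", "islandB"]
        )
        rec = ds.colonists[0]
        assert rec.status == 4
        assert rec.colonisation_time == pytest.approx(3.0)
        assert rec.branching_times == pytest.approx((1.0,))

    def test_two_taxon_conspecific(self, tmp_path):
        ds = self._build(
            tmp_path, "(island:2,mainland:2);", ["island"], conspecific=["island"]
        )
        rec = ds.colonists[0]
        assert rec.status == 3
        assert rec.colonisation_time == pytest.approx(2.0)
        assert rec.branching_times == ()

    def test_non_monophyletic_island_clade(self, tmp_path):
        nwk = "((islandA:1,mainland1:1):2,(islandB:2,mainland2:2):1);"
        with pytest.raises(ValidationError, match="monophyletic"):
            self._build(tmp_path, nwk, ["islandA", "islandB"])

    def test_missing_island_taxon(self, tmp_path):
        with pytest.raises(ValidationError, match="absent"):
            self._build(tmp_path, "(island:2,mainland:2);", ["ghost"])

    def test_non_ultrametric_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="ultrametric"):
            self._build(tmp_path, "(island:1,mainland:3);", ["island"])

    def test_taxon_order_invariance(self, tmp_path):
        a = self._build(
            tmp_path,
            "((islandA:1,islandB:1):2,mainland:3);",
            ["islandA", "islandB"],
            name="a.nwk",
        )
        b = self._build(
            tmp_path,
            "(mainland:3,(islandB:1,islandA:1):2);",
            ["islandB", "islandA"],
            name="b.nwk",
        )
        ra, rb = a.colonists[0], b.colonists[0]
        assert ra.status == rb.status
        assert ra.colonisation_time == pytest.approx(rb.colonisation_time)
        assert ra.branching_times == pytest.approx(rb.branching_times)
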