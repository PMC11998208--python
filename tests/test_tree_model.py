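"""Tree/table model: validation, terminals, table round-trips."""

import math

import pytest

from airwaymorph.errors import FormatError, IntegrityError, ValidationError
from airwaymorph.synthetic import SyntheticConfig, generate_cohort
from airwaymorph.tree_model import (
    AirwaySegment,
    EpitheliumProfile,
    read_segment_table,
    terminal_segments,
    tree_to_json,
    validate_tree,
    write_segment_table,
)

from conftest import caterpillar, make_tree


class TestInvariants:
    def test_nonpositive_lumen_rejected(self):
        with pytest.raises(ValidationError):
            AirwaySegment("a", None, lumen_diameter=0.0, wall_thickness=1.0)

    def test_negative_wall_rejected(self):
        with pytest.raises(ValidationError):
            AirwaySegment("a", None, lumen_diameter=10.0, wall_thickness=-1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            EpitheliumProfile(n_ciliated=-1)

    def test_zero_ruler_rejected(self):
        with pytest.raises(ValidationError):
            EpitheliumProfile(ruler_length=0.0)


class TestValidateTree:
    def test_single_segment_tree_is_valid(self):
        assert validate_tree(make_tree({"r": None})) == []

    def test_mutual_parents_reported_as_cycle(self):
        tree = make_tree({"a": "b", "b": "a"})
        violations = validate_tree(tree)
        assert violations
        assert any("cycle" in v for v in violations)

    def test_two_parentless_segments_reported_as_multiple_roots(self):
        tree = make_tree({"a": None, "b": None})
        violations = validate_tree(tree)
        assert any("multiple roots" in v for v in violations)
        assert any("'a'" in v or "a" in v for v in violations)

    def test_dangling_parent_names_segment(self):
        tree = make_tree({"r": None, "a": "ghost"})
        violations = validate_tree(tree)
        assert any("'a'" in v and "'ghost'" in v for v in violations)

    def test_self_parenting_detected(self):
        tree = make_tree({"r": None, "a": "a"})
        assert any("self-parenting" in v for v in validate_tree(tree))


class TestTerminals:
    def test_single_segment_is_its_own_terminal(self):
        assert terminal_segments(make_tree({"r": None})) == {"r"}

    def test_root_with_two_children(self):
        tree = make_tree({"r": None, "a": "r", "b": "r"})
        assert terminal_segments(tree) == {"a", "b"}

    def test_invalid_tree_raises(self):
        with pytest.raises(ValidationError):
            terminal_segments(make_tree({"a": "b", "b": "a"}))

    def test_monopodial_depth0_terminal_count(self):
        # trunk of 10 lateral-bearing nodes, laterals terminal:
        # terminals = 10 laterals + the trunk tip
        cfg = SyntheticConfig(seed=0, n_lobes=1, trunk_length=10, lateral_depth=0)
        cohort, _ = generate_cohort(cfg)
        tree = cohort.trees[0]
        assert len(terminal_segments(tree)) == 11

    def test_terminal_plus_internal_partition(self, small_cohort):
        cohort, _ = small_cohort
        for tree in cohort.trees:
            terms = terminal_segments(tree)
            internal = set(tree.segments) - terms
            assert len(terms) + len(internal) == len(tree)


class TestReadTable:
    def _write(self, tmp_path, text, name="t.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_minimal_three_segment_file(self, tmp_path):
        p = self._write(
            tmp_path,
            "subject_id,group,segment_id,parent_id,inner_diameter_um,outer_diameter_um\n"
            "s1,NOX,root,,100,120\n"
            "s1,NOX,a,root,50,60\n"
            "s1,NOX,b,root,40,50\n",
        )
        cohort = read_segment_table(p)
        assert len(cohort.trees) == 1
        tree = cohort.trees[0]
        assert len(tree) == 3
        assert tree.root_id == "root"
        assert tree.segments["a"].wall_thickness == pytest.approx(5.0)

    def test_missing_column_names_it(self, tmp_path):
        p = self._write(tmp_path, "subject_id,group,segment_id,parent_id\nx,N,a,\n")
        with pytest.raises(FormatError):
            read_segment_table(p)

    def test_dangling_parent_is_integrity_error(self, tmp_path):
        p = self._write(
            tmp_path,
            "subject_id,group,segment_id,parent_id,inner_diameter_um,outer_diameter_um\n"
            "s1,NOX,root,,100,120\n"
            "s1,NOX,a,ghost,50,60\n",
        )
        with pytest.raises(IntegrityError, match="a"):
            read_segment_table(p)

    def test_duplicate_measurement_key_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            "subject_id,group,segment_id,parent_id,image_index,"
            "inner_diameter_um,outer_diameter_um\n"
            "s1,NOX,root,,1,100,120\n"
            "s1,NOX,root,,1,101,121\n",
        )
        with pytest.raises(IntegrityError, match="duplicate"):
            read_segment_table(p)

    def test_nonpositive_diameter_reports_row(self, tmp_path):
        p = self._write(
            tmp_path,
            "subject_id,group,segment_id,parent_id,inner_diameter_um,outer_diameter_um\n"
            "s1,NOX,root,,0,120\n",
        )
        with pytest.raises(ValidationError, match="row 0"):
            read_segment_table(p)

    def test_multi_image_rows_are_averaged(self, tmp_path):
        p = self._write(
            tmp_path,
            "subject_id,group,segment_id,parent_id,image_index,"
            "inner_diameter_um,outer_diameter_um\n"
            "s1,NOX,root,,1,20,30\n"
            "s1,NOX,root,,2,22,30\n",
        )
        seg = read_segment_table(p).trees[0].segments["root"]
        assert seg.lumen_diameter == pytest.approx(21.0)
        assert seg.wall_thickness == pytest.approx(4.5)

    def test_dialect_renames_columns(self, tmp_path):
        p = self._write(
            tmp_path,
            "animal;grp;seg;par;din;dout\nr1;HYX;root;;100;110\n",
        )
        cohort = read_segment_table(
            p,
            dialect={
                "subject_id": "animal", "group": "grp", "segment_id": "seg",
                "parent_id": "par", "inner_diameter": "din", "outer_diameter": "dout",
            },
            delimiter=";",
        )
        assert cohort.groups == {"HYX"}


class TestRoundTrip:
    def test_synthetic_cohort_round_trips_exactly(self, tmp_path):
        cfg = SyntheticConfig(seed=3, n_subjects=1, trunk_length=5)
        cohort, _ = generate_cohort(cfg)
        path = write_segment_table(cohort, tmp_path / "cohort.csv")
        back = read_segment_table(path)
        assert back.n_segments() == cohort.n_segments()
        assert back.groups == cohort.groups
        for t0 in cohort.trees:
            t1 = next(t for t in back.trees if t.subject_id == t0.subject_id)
            assert set(t1.segments) == set(t0.segments)
            for sid, s0 in t0.segments.items():
                s1 = t1.segments[sid]
                assert s1.parent_id == s0.parent_id
                assert s1.lumen_diameter == s0.lumen_diameter  # full precision
                assert s1.wall_thickness == s0.wall_thickness
                assert (s1.epithelium is None) == (s0.epithelium is None)
                if s0.epithelium:
                    assert s1.epithelium.counts == s0.epithelium.counts
                    assert s1.epithelium.epithelium_height == s0.epithelium.epithelium_height

    def test_two_subject_cohort_groups(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_subjects=1, trunk_length=3, lateral_depth=1)
        cohort, _ = generate_cohort(cfg)
        path = write_segment_table(cohort, tmp_path / "two.csv")
        back = read_segment_table(path)
        assert back.groups == {"NOX", "HYX"}
        assert len(back.trees) == 2


def test_json_export_contains_topology():
    import json

    tree = caterpillar(3)
    doc = json.loads(tree_to_json(tree))
    assert doc["root"]["segment_id"] == "t1"
    kids = {c["segment_id"] for c in doc["root"]["children"]}
    assert kids == {"t2", "l1"}
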