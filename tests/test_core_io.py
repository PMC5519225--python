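"""Readers, writers, and domain-type invariants."""

from __future__ import annotations

import json

import pytest

from standspread.adjacency import DispersalEdge, DispersalGraph
from standspread.core_io import (
    DamageKind,
    FormatError,
    Stand,
    ValidationError,
    WindDay,
    WoodSectionRecord,
    format_section_spec,
    parse_section_spec,
    read_edge_table,
    read_stem_table,
    read_wind_rose_table,
    read_wind_table,
    write_results,
    write_wind_table,
)
from standspread.wind import WindRose, rank_and_percent
from tests.conftest import make_tree

BASE_ROW = {
    "tree_id": "T1",
    "genus": "Acer",
    "species": "rubrum",
    "dbh_cm": 12.0,
    "x_m": 0.0,
    "y_m": 0.0,
    "pit_count": 0,
    "exit_hole_spec": "",
}


def row(**kw):
    return {**BASE_ROW, **kw}


class TestStemTable:
    def test_counts_preserved(self, stem_csv):
        path = stem_csv([row(tree_id=f"T{i}") for i in range(3)])
        stand = read_stem_table(path)
        assert len(stand) == 3

    def test_duplicate_id_rejected(self, stem_csv):
        path = stem_csv([row(tree_id="T7"), row(tree_id="T7")])
        with pytest.raises(ValidationError, match="T7"):
            read_stem_table(path)

    def test_missing_column_named(self, stem_csv):
        path = stem_csv([{k: v for k, v in BASE_ROW.items() if k != "dbh_cm"}])
        with pytest.raises(FormatError, match="dbh_cm"):
            read_stem_table(path)

    def test_negative_dbh_rejected(self, stem_csv):
        path = stem_csv([row(dbh_cm=-3.0)])
        with pytest.raises(ValidationError):
            read_stem_table(path)

    def test_survey_rows_left_unresolved(self, stem_csv):
        path = stem_csv(
            [
                {
                    "tree_id": "T1",
                    "genus": "Acer",
                    "species": "rubrum",
                    "dbh_cm": 10.0,
                    "control_point": "cp1",
                    "bearing_deg": 45.0,
                    "distance_m": 3.0,
                }
            ]
        )
        stand = read_stem_table(path)
        tree = stand.tree("T1")
        assert not tree.has_coords
        assert tree.survey == ("cp1", 45.0, 3.0)

    def test_host_flag_derived_from_genus(self, stem_csv):
        path = stem_csv([row(tree_id="T1", genus="Acer"), row(tree_id="T2", genus="Quercus")])
        stand = read_stem_table(path)
        assert stand.tree("T1").is_host and not stand.tree("T2").is_host

    def test_generator_round_trip_counts(self, tmp_path):
        """The generator's own bookkeeping is the oracle for the reader."""
        from standspread.core_io import write_stem_table
        from standspread.synthetic_data import StandConfig, generate_stand

        cfg = StandConfig(n_trees=526, host_fraction=0.94, preferred_host_fraction=0.81, seed=5)
        stand = generate_stand(cfg)
        expected_hosts = sum(t.is_host for t in stand)
        path = tmp_path / "synthetic.csv"
        write_stem_table(stand, path)
        reread = read_stem_table(path)
        assert len(reread) == 526
        assert sum(t.is_host for t in reread) == expected_hosts


class TestSectionSpec:
    def test_round_trip(self):
        sections = [
            WoodSectionRecord(DamageKind.EXIT_HOLE, healed=True, rings_over=3),
            WoodSectionRecord(DamageKind.EXIT_HOLE, healed=False),
            WoodSectionRecord(DamageKind.OVIPOSITION_PIT, healed=True, rings_over=5),
        ]
        spec = format_section_spec(sections)
        assert spec == "h3;u;ph5"
        assert parse_section_spec(spec) == sections

    def test_bad_token_rejected(self):
        with pytest.raises(FormatError, match="x9"):
            parse_section_spec("h3;x9")

    def test_unhealed_with_rings_contradiction(self):
        with pytest.raises(ValidationError):
            WoodSectionRecord(DamageKind.EXIT_HOLE, healed=False, rings_over=2)


class TestWindTable:
    def test_blank_directions_skipped_and_counted(self, tmp_path):
        path = tmp_path / "wind.csv"
        rows = ["date,direction_deg"]
        rows += [f"2010-06-{d:02d},{45.0 + d}" for d in range(1, 9)]
        rows += ["2010-06-09,", "2010-06-10,"]
        path.write_text("\n".join(rows) + "\n")
        result = read_wind_table(path)
        assert len(result) == 8
        assert result.skipped == 2

    def test_direction_360_wraps_to_zero(self, tmp_path):
        path = tmp_path / "wind.csv"
        path.write_text("date,direction_deg\n2010-06-01,360.0\n")
        result = read_wind_table(path)
        assert result.days[0].direction_deg == 0.0

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "wind.csv"
        path.write_text("date,direction_deg\n")
        with pytest.warns(UserWarning):
            result = read_wind_table(path)
        assert len(result) == 0

    def test_bad_date_collected_not_fatal(self, tmp_path):
        path = tmp_path / "wind.csv"
        path.write_text("date,direction_deg\nnot-a-date,90.0\n2010-06-01,90.0\n")
        result = read_wind_table(path)
        assert len(result) == 1
        assert result.skipped == 1

    def test_write_read_round_trip(self, tmp_path):
        import datetime

        days = [WindDay(datetime.date(2010, 6, d), 10.0 * d) for d in range(1, 6)]
        path = tmp_path / "wind.csv"
        write_wind_table(days, path)
        assert read_wind_table(path).days == days


class TestResultsBundle:
    def _stand(self):
        return Stand(
            trees=[make_tree("A", 0.0, 0.0, pit_count=3), make_tree("B", 3.0, 4.0)],
            area_m2=50.0,
        )

    def test_empty_graph_writes_header_only(self, tmp_path):
        graph = DispersalGraph(root_id=None, edges=[])
        written = write_results(self._stand(), graph, None, None, tmp_path)
        lines = written["edges"].read_text().strip().splitlines()
        assert lines == ["source_id,target_id,distance_m,bearing_deg"]

    def test_single_edge_geojson_linestring(self, tmp_path):
        graph = DispersalGraph(
            root_id="A",
            edges=[DispersalEdge("A", "B", 5.0, 36.87)],
        )
        written = write_results(self._stand(), graph, None, None, tmp_path)
        payload = json.loads(written["geojson"].read_text())
        lines = [f for f in payload["features"] if f["geometry"]["type"] == "LineString"]
        assert len(lines) == 1
        assert lines[0]["geometry"]["coordinates"] == [[0.0, 0.0], [3.0, 4.0]]

    def test_edge_and_rose_round_trip_bit_identical(self, tmp_path):
        graph = DispersalGraph(
            root_id="A", edges=[DispersalEdge("A", "B", 5.0, 36.870001)]
        )
        rose = rank_and_percent(WindRose(frequencies=tuple(range(1, 17))))
        written = write_results(self._stand(), graph, rose, None, tmp_path)

        edges = read_edge_table(written["edges"])
        assert list(edges["source_id"]) == ["A"]
        assert list(edges["distance_m"]) == [5.0]
        assert list(edges["bearing_deg"]) == [36.870001]

        reread = read_wind_rose_table(written["wind_rose"])
        assert tuple(reread["frequency"]) == rose.frequencies
        assert tuple(reread["percentage"]) == rose.percentages
        assert tuple(reread["rank"]) == rose.ranks

    def test_rose_percentages_sum_to_100_within_rounding(self, tmp_path):
        rose = rank_and_percent(
            WindRose(frequencies=(110, 99, 117, 118, 20, 36, 68, 113, 149, 245, 289, 372, 351, 319, 113, 146))
        )
        written = write_results(None, None, rose, None, tmp_path)
        reread = read_wind_rose_table(written["wind_rose"])
        assert abs(reread["percentage"].sum() - 100.0) <= 0.05
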