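"""Occurrence records -> OGUs -> presence matrices."""
import json
import random

import pytest

from areagram import (
    GeoError,
    MatrixError,
    OccurrenceRecord,
    assign_provinces,
    build_matrix,
    grid_quadrats,
    read_occurrences,
)


def rec(taxon, lon, lat):
    return OccurrenceRecord(taxon=taxon, lon=lon, lat=lat)


class TestGrid:
    def test_interior_point_gets_integer_multiple_cell(self):
        ogus, assign = grid_quadrats([rec("t", -44.9, -12.1)], 5.0, (0.0, 0.0))
        assert len(ogus) == 1
        assert ogus[0].bounds == (-45.0, -40.0, -15.0, -10.0)

    def test_boundary_point_goes_to_cell_it_opens(self):
        # half-open [west, east) x [south, north)
        ogus, assign = grid_quadrats([rec("t", -45.0, -10.0)], 5.0, (0.0, 0.0))
        assert ogus[0].bounds == (-45.0, -40.0, -10.0, -5.0)

    def test_counts_match_brute_force_point_in_box(self):
        rng = random.Random(0)
        records = []
        boxes = [(-50, -45, -15, -10), (-45, -40, -15, -10), (-50, -45, -10, -5)]
        for i in range(100):
            w, e, s, n = boxes[i % 3]
            records.append(
                rec(f"t{i%4}", rng.uniform(w, e - 1e-9), rng.uniform(s, n - 1e-9))
            )
        ogus, assign = grid_quadrats(records, 5.0, (0.0, 0.0))
        assert len(ogus) == 3
        for ogu in ogus:
            brute = sum(1 for r in records if ogu.contains(r.lon, r.lat))
            got = sum(1 for i, a in assign.items() if a == ogu.id)
            assert got == brute

    def test_assignment_is_a_partition(self):
        rng = random.Random(1)
        records = [
            rec("t", rng.uniform(-60, -30), rng.uniform(-20, 0)) for _ in range(200)
        ]
        ogus, assign = grid_quadrats(records)
        assert sorted(assign) == list(range(200))
        per_ogu = {o.id: 0 for o in ogus}
        for a in assign.values():
            per_ogu[a] += 1
        assert sum(per_ogu.values()) == 200

    def test_output_invariant_to_record_order(self):
        rng = random.Random(2)
        records = [
            rec(f"t{i%3}", rng.uniform(-60, -30), rng.uniform(-20, 0))
            for i in range(50)
        ]
        ogus1, a1 = grid_quadrats(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        ogus2, a2 = grid_quadrats(shuffled)
        assert [o.id for o in ogus1] == [o.id for o in ogus2]
        assert [o.bounds for o in ogus1] == [o.bounds for o in ogus2]

    def test_empty_record_list_gives_empty_ogus(self):
        ogus, assign = grid_quadrats([])
        assert ogus == [] and assign == {}

    def test_bad_cell_size_rejected(self):
        with pytest.raises(GeoError, match="divide 360"):
            grid_quadrats([rec("t", 0, 0)], 7.0)

    def test_out_of_range_record_reported_with_index(self):
        bad = OccurrenceRecord(taxon="t", lon=250.0, lat=0.0)
        with pytest.raises(GeoError, match=r"\[1\]"):
            grid_quadrats([rec("t", 0, 0), bad])


class TestProvinces:
    def test_lookup_table_passthrough(self):
        assign, un = assign_provinces([rec("erythrocephalus", -40, -12)],
                                      {"erythrocephalus": "Caatinga"})
        assert assign == {0: "Caatinga"} and un == []

    def test_missing_lookup_entry_raises_with_taxon(self):
        with pytest.raises(GeoError, match="mystaxon"):
            assign_provinces([rec("mystaxon", -40, -12)], {"other": "Chaco"})

    def test_polygon_assignment_matches_brute_force(self, tmp_path):
        rects = {
            "West": (-50.0, -45.0, -15.0, -10.0),
            "East": (-44.0, -40.0, -15.0, -10.0),
        }
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": name},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[w, s], [e, s], [e, n], [w, n], [w, s]]],
                    },
                }
                for name, (w, e, s, n) in rects.items()
            ],
        }
        path = tmp_path / "prov.geojson"
        path.write_text(json.dumps(gj))
        rng = random.Random(3)
        records = []
        for i in range(50):
            name, (w, e, s, n) = list(rects.items())[i % 2]
            records.append(
                rec("t", rng.uniform(w + 0.01, e - 0.01), rng.uniform(s + 0.01, n - 0.01))
            )
        assign, un = assign_provinces(records, path)
        assert un == []
        for i, r in enumerate(records):
            brute = [
                name
                for name, (w, e, s, n) in rects.items()
                if w <= r.lon <= e and s <= r.lat <= n
            ]
            assert [assign[i]] == brute

    def test_point_outside_all_polygons_is_reported(self, tmp_path):
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": "Box"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]],
                    },
                }
            ],
        }
        path = tmp_path / "prov.geojson"
        path.write_text(json.dumps(gj))
        assign, un = assign_provinces([rec("t", 5.0, 5.0), rec("t", 0.5, 0.5)], path)
        assert un == [0]
        assert assign == {1: "Box"}


class TestBuildMatrix:
    def test_no_records_gives_outgroup_only_matrix(self):
        m = build_matrix([], {}, ["a", "b"])
        assert m.areas == ["Outgroup"]
        assert not m.data.any().any()

    def test_duplicate_records_collapse_to_single_presence(self):
        records = [rec("a", -44, -12), rec("a", -44.1, -12.1)]
        ogus, assign = grid_quadrats(records)
        m1 = build_matrix(records, assign, ["a"], ogus=ogus)
        m2 = build_matrix(records[:1], {0: assign[0]}, ["a"], ogus=ogus)
        assert m1 == m2

    def test_unknown_taxon_is_named_in_error(self):
        records = [rec("ghost", -44, -12)]
        ogus, assign = grid_quadrats(records)
        with pytest.raises(MatrixError, match="ghost"):
            build_matrix(records, assign, ["a", "b"], ogus=ogus)

    def test_reader_roundtrip(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("taxon,lon,lat,source\nsp1,-44.5,-12.25,museum\n")
        records = read_occurrences(p)
        assert records == [OccurrenceRecord("sp1", -44.5, -12.25, "museum")]
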