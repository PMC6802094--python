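import numpy as np
import pytest
from shapely.geometry import box

from baciveg.config import AnalysisConfig
from baciveg.matching import (
    MatchedPair,
    PARecord,
    PATable,
    candidate_wls,
    match_pairs,
    pa_mean_rainfall,
    separation_distance,
)
from baciveg.raster import PrecipGrid

KM = 1000.0


def pa(id, status, state="S1", area=100.0, rain=1200.0, year=None, geom=None):
    return PARecord(
        id=id,
        name=id,
        status=status,
        state=state,
        area_km2=area,
        rainfall_mm=rain,
        declaration_year=year,
        geometry=geom if geom is not None else box(0, 0, 10 * KM, 10 * KM),
    )


def at(x_km, side_km=10.0):
    return box(x_km * KM, 0, (x_km + side_km) * KM, side_km * KM)


class TestCandidateFilters:
    def test_rainfall_window(self):
        tr = pa("TR1", "TR", rain=1200, year=1990)
        table = PATable(
            [tr, pa("W1", "WLS", rain=1500), pa("W2", "WLS", rain=1900)]
        )
        ids = [w.id for w in candidate_wls(tr, table)]
        assert ids == ["W1"]  # |300| <= 500 < |700|

    def test_area_floor_is_inclusive_75(self):
        tr = pa("TR1", "TR", year=1990)
        table = PATable(
            [tr, pa("W74", "WLS", area=74.0), pa("W75", "WLS", area=75.0)]
        )
        assert [w.id for w in candidate_wls(tr, table)] == ["W75"]

    def test_same_state_required(self):
        tr = pa("TR1", "TR", state="S1", year=1990)
        table = PATable([tr, pa("W1", "WLS", state="S2")])
        assert candidate_wls(tr, table) == []

    def test_rainfall_window_boundary_inclusive(self):
        tr = pa("TR1", "TR", rain=1000, year=1990)
        table = PATable([tr, pa("W1", "WLS", rain=1500)])
        assert len(candidate_wls(tr, table)) == 1


class TestDistances:
    def test_overlapping_polygons_have_zero_distance(self):
        a = box(0, 0, 10 * KM, 10 * KM)
        b = box(5 * KM, 5 * KM, 15 * KM, 15 * KM)
        assert separation_distance(a, b) == 0.0

    def test_edge_to_edge_gap(self):
        a = box(0, 0, KM, KM)
        b = box(11 * KM, 0, 12 * KM, KM)
        assert separation_distance(a, b) == pytest.approx(10.0)

    def test_centroid_metric(self):
        a = box(0, 0, 2 * KM, 2 * KM)
        b = box(10 * KM, 0, 12 * KM, 2 * KM)
        assert separation_distance(a, b, metric="centroid") == pytest.approx(10.0)

    def test_planted_rectangles_closed_form(self):
        # diagonal offset: gap is the hypotenuse of (3, 4) km
        a = box(0, 0, KM, KM)
        b = box(4 * KM, 5 * KM, 5 * KM, 6 * KM)
        assert separation_distance(a, b) == pytest.approx(5.0)

    def test_invalid_geometry_raises(self):
        from shapely.geometry import Polygon

        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError):
            separation_distance(bowtie, box(0, 0, 1, 1))


class TestMeanRainfall:
    def test_uniform_grid(self):
        grid = PrecipGrid(
            monthly=np.full((12, 4, 4), 100.0), origin=(0, 40 * KM), cell_size=10 * KM
        )
        assert pa_mean_rainfall(box(5 * KM, 5 * KM, 25 * KM, 25 * KM), grid) == (
            pytest.approx(1200.0)
        )

    def test_polygon_within_single_cell(self):
        monthly = np.zeros((12, 1, 2))
        monthly[:, 0, 0] = 100.0  # 1200 mm annual
        monthly[:, 0, 1] = 200.0  # 2400 mm annual
        grid = PrecipGrid(monthly=monthly, origin=(0, 10 * KM), cell_size=10 * KM)
        poly = box(KM, KM, 3 * KM, 3 * KM)
        assert pa_mean_rainfall(poly, grid) == pytest.approx(1200.0)

    def test_area_weighting_across_two_cells(self):
        monthly = np.zeros((12, 1, 2))
        monthly[:, 0, 0] = 1000.0 / 12
        monthly[:, 0, 1] = 2000.0 / 12
        grid = PrecipGrid(monthly=monthly, origin=(0, 10 * KM), cell_size=10 * KM)
        poly = box(5 * KM, 0, 15 * KM, 10 * KM)  # 50/50 across the two cells
        assert pa_mean_rainfall(poly, grid) == pytest.approx(1500.0)

    def test_no_overlap_raises(self):
        grid = PrecipGrid(
            monthly=np.full((12, 1, 1), 100.0), origin=(0, KM), cell_size=KM
        )
        with pytest.raises(ValueError):
            pa_mean_rainfall(box(100 * KM, 0, 101 * KM, KM), grid)


class TestMatchPairs:
    def test_nearest_candidate_wins(self):
        tr = pa("TR1", "TR", year=1990, geom=at(0))
        table = PATable(
            [tr, pa("W40", "WLS", geom=at(50)), pa("W90", "WLS", geom=at(100))]
        )
        pairs, unmatched = match_pairs(table)
        assert unmatched == []
        assert pairs == [MatchedPair("TR1", "W40", 0.0, 40.0)]

    def test_conflict_resolved_injectively(self):
        # both TRs' nearest is W_mid; the earlier-declared TR keeps it
        t1 = pa("TR1", "TR", year=1980, geom=at(40))
        t2 = pa("TR2", "TR", year=1990, geom=at(60))
        table = PATable(
            [
                t1,
                t2,
                pa("W_mid", "WLS", geom=at(52)),
                pa("W_left", "WLS", geom=at(0)),
                pa("W_right", "WLS", geom=at(110)),
            ]
        )
        pairs, unmatched = match_pairs(table)
        assigned = {p.tr_id: p.wls_id for p in pairs}
        assert assigned == {"TR1": "W_mid", "TR2": "W_right"}
        assert unmatched == []

    def test_tr_with_no_candidates_is_unmatched(self):
        tr = pa("TR1", "TR", year=1990, rain=500, geom=at(0))
        table = PATable([tr, pa("W1", "WLS", rain=2500, geom=at(20))])
        pairs, unmatched = match_pairs(table)
        assert pairs == [] and unmatched == ["TR1"]

    def test_emitted_pairs_satisfy_all_constraints(self):
        from baciveg.synthetic import generate_pa_table

        cfg = AnalysisConfig()
        for seed in range(5):
            table = generate_pa_table(3, 4, 9, seed)
            pairs, _ = match_pairs(table, cfg)
            wls_ids = [p.wls_id for p in pairs]
            assert len(wls_ids) == len(set(wls_ids))  # injective
            for p in pairs:
                tr, wls = table.get(p.tr_id), table.get(p.wls_id)
                assert tr.state == wls.state
                assert wls.area_km2 >= cfg.wls_min_area_km2
                assert p.rainfall_difference_mm <= cfg.rainfall_window_mm
                assert p.separation_distance_km >= 0

    def test_planted_unique_nearest_recovered(self):
        # per state: one TR with exactly one admissible WLS nearby, decoys
        # excluded by state, area, or rainfall
        records = []
        for s in range(3):
            x0 = 200.0 * s
            records.append(
                pa(f"TR{s}", "TR", state=f"S{s}", rain=1000, year=1990, geom=at(x0))
            )
            records.append(
                pa(f"Wgood{s}", "WLS", state=f"S{s}", rain=1100, geom=at(x0 + 15))
            )
            records.append(  # nearer but too small
                pa(f"Wsmall{s}", "WLS", state=f"S{s}", area=50, rain=1000,
                   geom=at(x0 + 11))
            )
            records.append(  # nearer but too wet
                pa(f"Wwet{s}", "WLS", state=f"S{s}", rain=1800, geom=at(x0 + 12))
            )
        pairs, unmatched = match_pairs(PATable(records))
        assert unmatched == []
        assert {p.tr_id: p.wls_id for p in pairs} == {
            f"TR{s}": f"Wgood{s}" for s in range(3)
        }


def test_pa_table_geojson_round_trip(tmp_path):
    from baciveg.synthetic import generate_pa_table

    table = generate_pa_table(2, 2, 4, seed=3)
    table.write(tmp_path / "pa.csv", tmp_path / "pa.geojson")
    back = PATable.from_geojson(tmp_path / "pa.geojson")
    assert len(back) == len(table)
    for a, b in zip(table, back):
        assert (a.id, a.status, a.state) == (b.id, b.status, b.state)
        assert a.rainfall_mm == pytest.approx(b.rainfall_mm)
        assert a.geometry.equals_exact(b.geometry, tolerance=1e-6)
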