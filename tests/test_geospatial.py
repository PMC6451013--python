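"""Occurrence cleaning, EOO/AOO geometry and IUCN criterion B."""

import math
from datetime import date

import numpy as np
import pytest

from congenstatus.geospatial import (EARTH_RADIUS_KM, OccurrenceRecord,
                                     OccurrenceSet, aoo_area, dedupe_records,
                                     eoo_area, iucn_criterion_b,
                                     read_occurrences)
from congenstatus.synthdata import make_occurrences


def _rec(i, lat, lon, d=None, loc=""):
    return OccurrenceRecord(id=i, latitude=lat, longitude=lon,
                            date=d, locality=loc)


# -- dedupe -------------------------------------------------------------------


def test_dedupe_keeps_most_recent_per_locality():
    occ = OccurrenceSet([
        _rec("a", 0, 0, date(1990, 1, 1), "town"),
        _rec("b", 0.1, 0.1, date(2010, 1, 1), "town"),
        _rec("c", 1, 1, date(2000, 1, 1), "other"),
    ])
    out = dedupe_records(occ)
    assert [r.id for r in out.records] == ["b", "c"]
    assert [r.id for r in out.excluded] == ["a"]


def test_dedupe_undated_loses_to_dated_and_id_tiebreak():
    occ = OccurrenceSet([
        _rec("z", 0, 0, None, "town"),
        _rec("m", 0.1, 0, date(1950, 1, 1), "town"),
    ])
    assert [r.id for r in dedupe_records(occ).records] == ["m"]
    tie = OccurrenceSet([
        _rec("beta", 0, 0, date(2000, 1, 1), "town"),
        _rec("alpha", 0.1, 0, date(2000, 1, 1), "town"),
    ])
    assert [r.id for r in dedupe_records(tie).records] == ["alpha"]


def test_dedupe_distinct_localities_all_kept():
    occ = OccurrenceSet([_rec(f"r{k}", k, k, None, f"loc{k}")
                         for k in range(5)])
    assert len(dedupe_records(occ)) == 5


# -- EOO ----------------------------------------------------------------------


def test_eoo_planar_triangle_oracle():
    """3 km x 4 km right triangle near the equator -> 6 km^2."""
    dlat = math.degrees(4.0 / EARTH_RADIUS_KM)
    dlon = math.degrees(3.0 / EARTH_RADIUS_KM)
    occ = OccurrenceSet([_rec("a", 0, 0), _rec("b", dlat, 0),
                         _rec("c", 0, dlon)])
    area, hull = eoo_area(occ)
    assert area == pytest.approx(6.0, abs=0.05)


def test_eoo_degenerate_inputs():
    occ = OccurrenceSet([_rec("a", 1, 1), _rec("b", 1, 1), _rec("c", 1, 1)])
    area, hull = eoo_area(occ)
    assert area == 0.0 and hull is None


def test_eoo_hull_properties():
    rng = np.random.default_rng(2)
    pts = [(float(la), float(lo))
           for la, lo in rng.uniform(-5, 5, size=(12, 2))]
    occ = OccurrenceSet([_rec(f"r{k}", la, lo)
                         for k, (la, lo) in enumerate(pts)])
    area, hull = eoo_area(occ)
    # permutation invariance
    occ2 = OccurrenceSet([occ.records[k] for k in rng.permutation(12)])
    assert eoo_area(occ2)[0] == pytest.approx(area, rel=1e-12)
    # a point at the centroid is interior: removal leaves EOO unchanged
    cen_lat = np.mean([la for la, _ in pts])
    cen_lon = np.mean([lo for _, lo in pts])
    occ3 = OccurrenceSet(occ.records + [_rec("mid", cen_lat, cen_lon)])
    assert eoo_area(occ3)[0] == pytest.approx(area, rel=1e-9)


def test_interior_point_leaves_hull_with_three_vertices():
    occ = OccurrenceSet([_rec("a", 0, 0), _rec("b", 2, 0), _rec("c", 0, 2),
                         _rec("mid", 0.5, 0.5)])
    _, hull = eoo_area(occ)
    assert len(hull.exterior.coords) - 1 == 3


# -- AOO ----------------------------------------------------------------------


def test_aoo_grid_assignment():
    # two records inside one 2-km cell + one elsewhere -> 2 cells, 8 km^2
    d = math.degrees(0.5 / EARTH_RADIUS_KM)   # 0.5 km spacing
    far = math.degrees(50.0 / EARTH_RADIUS_KM)
    occ = OccurrenceSet([_rec("a", 0.0001, 0.0001), _rec("b", d, d),
                         _rec("c", far, far)])
    area, cells = aoo_area(occ)
    assert cells == 2 and area == pytest.approx(8.0)


def test_aoo_single_record_and_scaling():
    occ = OccurrenceSet([_rec("a", -19.0, -44.0)])
    area, cells = aoo_area(occ)
    assert cells == 1 and area == pytest.approx(4.0)


def test_aoo_nineteen_distinct_cells():
    occ = make_occurrences(19, clustering=0.0, seed=5)
    area, cells = aoo_area(occ)
    assert cells == 19          # records far apart at this extent
    assert area == pytest.approx(76.0)


def test_aoo_monotone_and_bounded():
    rng = np.random.default_rng(7)
    pts = rng.uniform(-3, 3, size=(15, 2))
    prev = 0.0
    for k in range(1, 16):
        occ = OccurrenceSet([_rec(f"r{j}", float(pts[j, 0]),
                                  float(pts[j, 1])) for j in range(k)])
        area, cells = aoo_area(occ)
        assert area >= prev
        assert cells <= k
        prev = area


def test_aoo_origin_scan_reports_range():
    occ = make_occurrences(10, seed=9)
    area, cells, scan = aoo_area(occ, origin_scan=True)
    assert scan["min_km2"] <= area <= scan["max_km2"]


# -- criterion B --------------------------------------------------------------


def test_criterion_b_printed_worked_values():
    """The published area estimates classify LC/NT on the EOO axis and EN on
    the AOO axis, with and without the doubtful outlying record."""
    a = iucn_criterion_b(263_905.0, 76.0, fragmentation_flag=True,
                         decline_flag=True)
    assert a.eoo_category == "LC/NT"      # EOO > 20 000
    assert a.aoo_category == "EN"         # AOO < 500
    assert a.final_category == "EN"
    b = iucn_criterion_b(174_936.0, 72.0, True, True)
    assert b.eoo_category == "LC/NT"
    assert b.aoo_category == "EN"


def test_criterion_b_threshold_table():
    assert iucn_criterion_b(50, 8).aoo_category == "CR"
    assert iucn_criterion_b(50, 8).eoo_category == "CR"
    assert iucn_criterion_b(4_000, 1_500).eoo_category == "EN"
    assert iucn_criterion_b(4_000, 1_500).aoo_category == "VU"
    assert iucn_criterion_b(25_000, 2_500).aoo_category == "LC/NT"


def test_criterion_b_subcondition_gate():
    a = iucn_criterion_b(100.0, 76.0, fragmentation_flag=False,
                         decline_flag=True)
    assert a.final_category == "LC/NT"    # needs both declared conditions


def test_degenerate_hull_adjustment():
    a = iucn_criterion_b(0.0, 8.0)
    assert a.eoo_km2 == 8.0               # EOO >= AOO enforced


def test_record_validation_and_csv_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        _rec("x", 95.0, 0.0)
    f = tmp_path / "occ.csv"
    f.write_text("id,locality,date,lat,lon\n"
                 "r1,town,1999,-19.5,-44.0\n"
                 "r2,city,2005-06-01,-20.0,-43.5\n")
    occ = read_occurrences(f)
    assert len(occ) == 2
    assert occ.records[0].date == date(1999, 1, 1)
    assert occ.without("r1").records[0].id == "r2"
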