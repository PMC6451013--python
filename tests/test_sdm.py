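"""Surface-range-envelope SDM: splits, envelope logic, AUC/TSS, ensemble
and projection."""

import numpy as np
import pytest

from congenstatus.sdm import (RasterStack, SdmEvaluation, ensemble, evaluate,
                              project, split_presences, sre_fit,
                              sre_fit_predict, sre_predict)
from congenstatus.synthdata import make_occurrences, make_rasters, shift_rasters


@pytest.fixture
def stack():
    return make_rasters(seed=1)


def _band_points(n, seed=0):
    """Presences restricted to a latitude band of the default extent."""
    occ = make_occurrences(n, extent=(-47.0, -41.0, -20.0, -16.0),
                           clustering=0.0, seed=seed)
    return occ.coords()


def test_split_rounding_and_determinism(stack):
    pts = _band_points(8)
    s1 = split_presences(pts, stack, runs=3, seed=5)
    s2 = split_presences(pts, stack, runs=3, seed=5)
    assert len(s1[0]["train_presence"]) == 6       # floor(0.75 * 8)
    assert len(s1[0]["test_presence"]) == 2
    for a, b in zip(s1, s2):
        assert np.array_equal(a["train_presence"], b["train_presence"])
        assert np.array_equal(a["train_background"], b["train_background"])
    # distinct substreams per run
    assert not np.array_equal(s1[0]["train_presence"],
                              s1[1]["train_presence"])


def test_background_avoids_presence_cells_and_nodata(stack):
    pts = _band_points(10)
    stack.layers["temp"][5, 5] = np.nan
    stack2 = RasterStack(layers=stack.layers, transform=stack.transform)
    splits = split_presences(pts, stack2, background_n=200, runs=1, seed=2)
    bg = np.concatenate([splits[0]["train_background"],
                         splits[0]["test_background"]])
    rows, cols = stack2.cell_of(bg[:, 0], bg[:, 1])
    prow, pcol = stack2.cell_of(pts[:, 0], pts[:, 1])
    pcells = set(zip(prow.tolist(), pcol.tolist()))
    for rc in zip(rows.tolist(), cols.tolist()):
        assert rc not in pcells
        assert rc != (5, 5)


def test_sre_q0_contains_all_training_presences(stack):
    pts = _band_points(12, seed=3)
    pred, env = sre_fit_predict(pts, stack, q=0.0)
    vals = stack.values_at(pts)
    for name, (lo, hi) in env.items():
        assert lo == pytest.approx(np.min(vals[name]))
        assert hi == pytest.approx(np.max(vals[name]))
    row, col = stack.cell_of(pts[:, 0], pts[:, 1])
    assert np.all(pred[row, col] == 1.0)


def test_sre_quantile_convention_single_layer():
    """Presences at values 1..100, q = 0.025: linear-interpolation quantiles
    cut below 3.475 and above 97.525, so cells < 3 or > 98 are unsuitable."""
    grid = np.arange(1.0, 101.0).reshape(10, 10)
    stack = RasterStack(layers={"v": grid.copy()},
                        transform=(0.0, 0.1, 10.0, -0.1))
    lon, lat = stack.cell_centers()
    pres = np.array([(lon[c], lat[r]) for r in range(10) for c in range(10)])
    pred, env = sre_fit_predict(pres, stack, q=0.025)
    assert env["v"][0] == pytest.approx(1 + 0.025 * 99)
    assert env["v"][1] == pytest.approx(1 + 0.975 * 99)
    vals = grid.ravel()
    suit = pred.ravel()
    assert np.all(suit[(vals < 3) | (vals > 98)] == 0.0)
    assert np.all(suit[(vals >= 4) & (vals <= 97)] == 1.0)


def test_sre_region_is_box_intersection(stack):
    pts = _band_points(15, seed=4)
    pred, env = sre_fit_predict(pts, stack, q=0.0)
    manual = np.ones(stack.shape, dtype=bool)
    for name, (lo, hi) in env.items():
        a = stack.layers[name]
        manual &= (a >= lo) & (a <= hi)
    assert np.array_equal(pred == 1.0, manual)


def test_sre_area_monotone_in_q(stack):
    pts = _band_points(30, seed=6)
    prev = None
    for q in (0.0, 0.05, 0.1, 0.2):
        pred, _ = sre_fit_predict(pts, stack, q=q)
        area = np.nansum(pred)
        if prev is not None:
            assert area <= prev
        prev = area


# -- evaluation ---------------------------------------------------------------


def test_auc_perfect_separation_and_definition():
    ev = evaluate([0.9, 0.8], [0.3, 0.2, 0.1])
    assert ev.auc == 1.0 and ev.tss == 1.0


def test_auc_pair_counting_example():
    # {P: 0.9, 0.7; B: 0.8, 0.1}: 3 of 4 pairs concordant
    ev = evaluate([0.9, 0.7], [0.8, 0.1])
    assert ev.auc == pytest.approx(0.75)


def test_auc_rank_formula_matches_pair_counting():
    rng = np.random.default_rng(8)
    for _ in range(20):
        p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 30))
        b = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 30))
        ev = evaluate(p, b)
        wins = sum((x > y) + 0.5 * (x == y) for x in p for y in b)
        assert ev.auc == pytest.approx(wins / (len(p) * len(b)), abs=1e-12)


def test_tss_invariant_to_monotone_transform():
    rng = np.random.default_rng(9)
    p = rng.random(20)
    b = rng.random(30) * 0.8
    e1 = evaluate(p, b)
    e2 = evaluate(np.exp(3 * p), np.exp(3 * b))
    assert e1.tss == pytest.approx(e2.tss, abs=1e-12)
    assert e1.auc == pytest.approx(e2.auc, abs=1e-12)


def test_identical_scores_no_skill():
    ev = evaluate([0.5, 0.5], [0.5, 0.5, 0.5])
    assert ev.auc == 0.5 and ev.tss == 0.0


# -- ensemble and projection --------------------------------------------------


def test_ensemble_rules():
    a = np.ones((2, 2))
    b = np.zeros((2, 2))
    e_hi = SdmEvaluation(auc=1, tss=0.8, threshold=0)
    e_hi2 = SdmEvaluation(auc=1, tss=0.8, threshold=0)
    e_lo = SdmEvaluation(auc=1, tss=0.6, threshold=0)
    assert np.allclose(ensemble([a], [e_hi]), a)
    assert np.allclose(ensemble([a, b], [e_hi, e_hi2]), 0.5)
    only_first = ensemble([a, b], [SdmEvaluation(1, 0.9, 0), e_lo])
    assert np.allclose(only_first, a)
    with pytest.raises(ValueError, match="threshold"):
        ensemble([a], [e_lo])


def test_project_idempotent_and_zero_shift(stack):
    pts = _band_points(12, seed=10)
    env = sre_fit(pts, stack, q=0.0)
    res = project(env, stack, shift_rasters(stack, {}))
    assert np.allclose(res["current"], res["future"], equal_nan=True)
    assert res["pct_change"] == pytest.approx(0.0)


def test_project_shift_outside_envelope_empty(stack):
    pts = _band_points(12, seed=11)
    env = sre_fit(pts, stack, q=0.0)
    res = project(env, stack, shift_rasters(stack, {"temp": 1e6}))
    assert res["area_future_km2"] == 0.0


def test_project_warming_moves_suitability_poleward():
    """Warming shifts the suitable temperature band toward higher latitude
    (southward here: the gradient increases toward the equator)."""
    stack = make_rasters(seed=12)
    pts = _band_points(25, seed=12)
    env = sre_fit(pts, stack, q=0.05)
    res = project(env, stack, shift_rasters(stack, {"temp": 1.5}))
    lon, lat = stack.cell_centers()
    lat_grid = np.repeat(lat[:, None], stack.shape[1], axis=1)

    def centroid(mask):
        return float(np.nansum(mask * lat_grid) / np.nansum(mask))

    assert centroid(res["future"]) < centroid(res["current"])


def test_project_missing_layer_named():
    stack = make_rasters(seed=13)
    env = sre_fit(_band_points(8, seed=13), stack, q=0.0)
    bad = RasterStack(layers={"temp": stack.layers["temp"].copy()},
                      transform=stack.transform)
    with pytest.raises(KeyError, match="precip"):
        sre_predict(env, bad)
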